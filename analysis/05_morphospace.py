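#!/usr/bin/env python
"""Morphospace of the simulated cohort.

PCA of the Procrustes tangent coordinates, the eigenvalue-ratio retention
rule, per-landmark contributions to PC1/PC2, per-host convex hulls, and
thin-plate-spline deformation grids from the consensus to the PC extremes.
Writes CSV tables and an SVG figure under results/morphospace/.
"""

from pathlib import Path

import matplotlib
matplotlib.use("svg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from sporemorph import io as smio
from sporemorph.morphospace import (convex_hulls, extreme_shapes,
                                    landmark_contributions, make_lattice,
                                    meaningful_pcs, pca, tps_warp)
from sporemorph.procrustes import gpa, tangent_projection

ROOT = Path(__file__).resolve().parent.parent / "results"
OUT = ROOT / "morphospace"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    dataset = smio.read_long_csv(ROOT / "cohort" / "landmarks.csv")
    res = gpa(dataset.replicate_mean())
    p = pca(tangent_projection(res))

    pd.DataFrame({"eigenvalue": p.eigenvalues,
                  "variance_pct": p.variance_pct}).to_csv(
        OUT / "eigenvalues.csv", index=False, float_format="%.9g")
    pd.DataFrame(p.scores[:, :5],
                 columns=[f"PC{i + 1}" for i in range(5)],
                 index=pd.Index(dataset.specimen_id, name="specimen_id")
                 ).assign(host_id=dataset.host_id).to_csv(
        OUT / "scores.csv", float_format="%.9g")
    contrib = pd.DataFrame(
        {"PC1": landmark_contributions(p, 0),
         "PC2": landmark_contributions(p, 1)},
        index=pd.Index([f"L{i}" for i in range(1, 9)], name="landmark"))
    contrib.to_csv(OUT / "landmark_contributions.csv", float_format="%.4g")

    n_keep = meaningful_pcs(p.eigenvalues)
    hulls = convex_hulls(p.scores[:, :2], dataset.host_id)

    fig, axes = plt.subplots(1, 3, figsize=(13, 4))
    ax = axes[0]
    for g, hull in hulls.items():
        pts = p.scores[dataset.host_id == g, :2]
        ax.scatter(*pts.T, s=12, label=f"host {g}")
        if not hull.degenerate:
            closed = np.vstack([hull.vertices, hull.vertices[:1]])
            ax.fill(closed[:, 0], closed[:, 1], alpha=0.15)
    ax.set_xlabel(f"PC1 ({p.variance_pct[0]:.1f}%)")
    ax.set_ylabel(f"PC2 ({p.variance_pct[1]:.1f}%)")
    ax.legend(fontsize=7)
    ax.set_title("morphospace with per-host convex hulls")

    for ax, sign, label in ((axes[1], -1, "PC1 minimum"),
                            (axes[2], +1, "PC1 maximum")):
        target = extreme_shapes(p, res.consensus, 0, sign)
        grid = tps_warp(res.consensus, target, make_lattice(res.consensus,
                                                            (24, 24)))
        ax.plot(grid.warped_grid[:, 0].reshape(24, 24),
                grid.warped_grid[:, 1].reshape(24, 24), "-",
                color="0.8", lw=0.5)
        ax.plot(grid.warped_grid[:, 0].reshape(24, 24).T,
                grid.warped_grid[:, 1].reshape(24, 24).T, "-",
                color="0.8", lw=0.5)
        ax.scatter(*res.consensus.T, s=18, color="0.4", label="consensus")
        ax.scatter(*target.T, s=22, color="C3", label="extreme")
        ax.set_title(f"{label} deformation grid")
        ax.set_aspect("equal")
        ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(OUT / "morphospace.svg")

    print(f"PC variance (%): {np.round(p.variance_pct[:6], 2)}")
    print(f"meaningful PCs by the eigenvalue-ratio rule: {n_keep}")
    top1 = contrib["PC1"].nlargest(3)
    top2 = contrib["PC2"].nlargest(3)
    print(f"PC1 dominated by {list(top1.index)} "
          f"({np.round(top1.values, 1)}%) - the posterior-angle landmarks")
    print(f"PC2 dominated by {list(top2.index)} "
          f"({np.round(top2.values, 1)}%) - the spore-length landmarks")
    print(f"figure: {OUT / 'morphospace.svg'}")


if __name__ == "__main__":
    main()
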