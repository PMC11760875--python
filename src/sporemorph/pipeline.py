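"""End-to-end analysis pipeline over a (generated or loaded) cohort.

Stage order: simulate (optional) -> digitize -> qc -> gpa -> symmetry ->
pca -> ancova -> size anova -> dispersion.  The report is a plain nested
dict, JSON-serialisable, with seeds recorded for reproducibility.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, replace
from pathlib import Path

import numpy as np

from . import __version__
from .morphospace import meaningful_pcs, landmark_contributions, pca
from .procrustes import centroid_size, gpa, tangent_projection, tangent_space_check
from .qc import qc_report
from .rrpp import ModelSpec, dispersion_test, rrpp_test, size_anova
from .simulate import PopulationSpec, default_calibration, digitize_replicates, sample_population
from .symmetry import decompose_symmetry

logger = logging.getLogger("sporemorph")

__all__ = ["run_pipeline", "spec_from_config"]


def spec_from_config(config: dict | None, seed: int | None = None) -> PopulationSpec:
    """Build a population spec from a config mapping over the defaults."""
    spec = default_calibration()
    if config:
        mean = config.pop("mean_params", None)
        if mean is not None:
            spec = replace(spec, mean_params=replace(spec.mean_params, **mean))
        spec = replace(spec, **config)
    if seed is not None:
        spec = replace(spec, seed=int(seed))
    return spec


def _table_dict(table) -> dict:
    out = {}
    for term, row in table.table.iterrows():
        out[term] = {k: (None if v != v else float(v))
                     for k, v in row.items()}
    return out


def run_pipeline(config: dict | None = None, seed: int | None = None,
                 dataset=None, n_perm: int = 10_000,
                 out_path=None) -> dict:
    """Run the full analysis and return (optionally write) the report.

    If ``dataset`` is None a synthetic cohort is generated from the config/
    default calibration.  Any stage failure raises with the stage named.
    """
    report: dict = {"version": __version__}
    stage = "configure"
    try:
        spec = spec_from_config(dict(config) if config else None, seed)
        report["seed"] = spec.seed

        if dataset is None:
            stage = "simulate"
            logger.info("simulate: seed=%d n=%d", spec.seed, spec.n_specimens)
            specimens = sample_population(spec)
            report["simulate"] = {
                "n_specimens": len(specimens),
                "n_resampled": specimens.n_resampled,
                "host_sizes": list(spec.host_sizes),
            }
            stage = "digitize"
            dataset = digitize_replicates(specimens, spec.n_replicates, spec)

        stage = "qc"
        qc = qc_report(dataset)
        report["qc"] = {
            "rpt_average": float(qc.rpt_average),
            "rpt_per_coordinate": [float(v) for v in qc.rpt_per_coordinate],
            "pct_me": float(qc.pct_me),
            "outlier_ids": [str(s) for s in qc.outlier_ids],
        }

        stage = "gpa"
        averaged = dataset.replicate_mean()
        result = gpa(averaged)
        cs = np.array([centroid_size(c) for c in averaged])
        slope, corr = tangent_space_check(result)
        report["gpa"] = {
            "converged": bool(result.converged),
            "iterations": int(result.iterations),
            "centroid_size_mean": float(cs.mean()),
            "centroid_size_cv_pct": float(100 * cs.std(ddof=1) / cs.mean()),
            "centroid_size_range": [float(cs.min()), float(cs.max())],
            "tangent_slope": float(slope),
            "tangent_correlation": float(corr),
        }

        stage = "symmetry"
        dec = decompose_symmetry(averaged)
        report["symmetry"] = {
            "pct_symmetric": float(dec.pct_symmetric),
            "pct_asymmetric": float(dec.pct_asymmetric),
        }

        stage = "pca"
        pcs = pca(tangent_projection(result))
        n_keep = meaningful_pcs(pcs.eigenvalues)
        report["pca"] = {
            "variance_pct": [float(v) for v in pcs.variance_pct],
            "meaningful_pcs": int(n_keep),
            "landmark_contributions_pc1":
                [float(v) for v in landmark_contributions(pcs, 0)],
            "landmark_contributions_pc2":
                [float(v) for v in landmark_contributions(pcs, 1)],
        }

        stage = "ancova"
        model = ModelSpec(response=dec.symmetric_tangent,
                          terms=("size", "host", "size:host"),
                          size=cs, host=dataset.host_id,
                          n_perm=n_perm, seed=spec.seed)
        report["ancova"] = _table_dict(rrpp_test(model))

        stage = "size_anova"
        report["size_anova"] = _table_dict(
            size_anova(cs, dataset.host_id, n_perm=n_perm, seed=spec.seed))

        stage = "dispersion"
        disp = dispersion_test(dec.symmetric_tangent, dataset.host_id,
                               n_perm=min(n_perm, 999), seed=spec.seed)
        report["dispersion"] = {
            "F": disp.f, "p": disp.p,
            "group_mean_distance": {str(k): v for k, v
                                    in disp.group_mean_distance.items()},
        }
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    if out_path is not None:
        Path(out_path).write_text(json.dumps(report, indent=2))
    return report
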