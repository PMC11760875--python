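"""Object-symmetry decomposition of shape variation.

Crescent myxospores are bilaterally symmetric about the suture line: a
single configuration contains both body halves, so shape variation splits
exactly into two orthogonal, complementary tangent subspaces — variation
among spores (symmetric component) and variation between the two shell
valves within each spore (asymmetric component).

The decomposition follows the standard object-symmetry construction: each
configuration is reflected about a fixed axis and its paired landmarks
relabelled; originals and mirrored copies are superimposed in one joint
GPA; the symmetric component of a specimen is the average of its two
aligned copies and the asymmetric component is the remainder.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .landmarks import PAIR_PERMUTATION
from .procrustes import GPAResult, LandmarkDataset, gpa, tangent_projection

__all__ = ["SymmetryDecomposition", "reflect_relabel", "decompose_symmetry"]


@dataclass
class SymmetryDecomposition:
    symmetric_coords: np.ndarray   # (m, k, 2) aligned symmetric component
    asymmetric_coords: np.ndarray  # (m, k, 2) asymmetry vectors
    symmetric_tangent: np.ndarray  # (m, 2k) tangent rows of the symmetric part
    consensus: np.ndarray
    centroid_sizes: np.ndarray     # of the original configurations
    ss_symmetric: float
    ss_asymmetric: float
    gpa_result: GPAResult

    @property
    def ss_total(self) -> float:
        return self.ss_symmetric + self.ss_asymmetric

    @property
    def pct_symmetric(self) -> float:
        return 100.0 * self.ss_symmetric / self.ss_total

    @property
    def pct_asymmetric(self) -> float:
        return 100.0 * self.ss_asymmetric / self.ss_total


def reflect_relabel(config: np.ndarray) -> np.ndarray:
    """Mirror a configuration and restore label order via the pairing map.

    The x-coordinates are negated (reflection about an arbitrary fixed axis;
    the joint GPA removes the arbitrariness) and the paired landmarks are
    swapped (2<->8, 3<->7, 4<->6), leaving L1 and L5 in place.  Applying the
    operation twice returns the original configuration.
    """
    c = np.asarray(config, dtype=float)
    out = c.copy()
    out[..., 0] = -out[..., 0]
    return out[..., PAIR_PERMUTATION, :]


def decompose_symmetry(dataset) -> SymmetryDecomposition:
    """Partition tangent-space variation into symmetric and asymmetric parts.

    Accepts a ``LandmarkDataset`` (replicates averaged per specimen first)
    or a plain (m, k, 2) stack.  The sums of squares are measured about the
    joint consensus over the 2m tangent rows, so by construction
    ``ss_symmetric + ss_asymmetric`` equals the total SS exactly.
    """
    if isinstance(dataset, LandmarkDataset):
        configs = dataset.replicate_mean()
    else:
        configs = np.asarray(dataset, dtype=float)
    if configs.ndim != 3 or len(configs) < 2:
        raise ValueError("need an (m, k, 2) stack with m >= 2")
    m = len(configs)
    mirrored = reflect_relabel(configs)
    joint = gpa(np.concatenate([configs, mirrored], axis=0))

    t = tangent_projection(joint)          # (2m, 2k)
    t_orig, t_mirr = t[:m], t[m:]
    grand = t.mean(axis=0)
    sym = 0.5 * (t_orig + t_mirr)
    asym = t_orig - sym
    ss_symmetric = 2.0 * float(np.sum((sym - grand) ** 2))
    ss_asymmetric = 2.0 * float(np.sum(asym ** 2))

    k = configs.shape[1]
    aligned_orig = joint.aligned[:m]
    aligned_mirr = joint.aligned[m:]
    sym_coords = 0.5 * (aligned_orig + aligned_mirr)
    asym_coords = aligned_orig - sym_coords
    return SymmetryDecomposition(
        symmetric_coords=sym_coords,
        asymmetric_coords=asym_coords,
        symmetric_tangent=sym,
        consensus=joint.consensus,
        centroid_sizes=joint.centroid_sizes[:m],
        ss_symmetric=ss_symmetric,
        ss_asymmetric=ss_asymmetric,
        gpa_result=joint,
    )
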