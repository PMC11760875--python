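"""Generalized Procrustes analysis and shape-space utilities.

Superimposition removes location (centering), size (unit centroid size) and
orientation (optimal rotation, reflections excluded).  The aligned
configurations live near the consensus on the unit pre-shape sphere; an
orthogonal projection onto the tangent space at the consensus yields
Euclidean shape coordinates for multivariate statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "LandmarkDataset",
    "GPAResult",
    "centroid_size",
    "gpa",
    "procrustes_distance",
    "tangent_projection",
    "tangent_space_check",
    "optimal_rotation",
]


@dataclass
class LandmarkDataset:
    """Digitized landmark data: specimens x replicates x landmarks x 2 (µm)."""

    coords: np.ndarray
    host_id: np.ndarray
    specimen_id: np.ndarray
    replicate_id: np.ndarray

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim == 3:  # single replicate
            coords = coords[:, None]
        if coords.ndim != 4 or coords.shape[-1] != 2:
            raise ValueError("coords must have shape (m, r, k, 2)")
        if coords.shape[0] < 2:
            raise ValueError("need at least two specimens")
        if not np.all(np.isfinite(coords)):
            raise ValueError("missing or non-finite landmarks")
        self.coords = coords
        self.host_id = np.asarray(self.host_id)
        self.specimen_id = np.asarray(self.specimen_id)
        self.replicate_id = np.asarray(self.replicate_id)

    @property
    def n_specimens(self) -> int:
        return self.coords.shape[0]

    @property
    def n_replicates(self) -> int:
        return self.coords.shape[1]

    @property
    def n_landmarks(self) -> int:
        return self.coords.shape[2]

    def flattened(self) -> np.ndarray:
        """All configurations as one (m * r, k, 2) stack, replicate-major
        within specimen."""
        m, r, k, _ = self.coords.shape
        return self.coords.reshape(m * r, k, 2)

    def replicate_mean(self) -> np.ndarray:
        """Per-specimen replicate-averaged configurations, (m, k, 2)."""
        return self.coords.mean(axis=1)


@dataclass
class GPAResult:
    """Aligned configurations (unit centroid size), consensus and sizes."""

    aligned: np.ndarray        # (n, k, 2)
    consensus: np.ndarray      # (k, 2)
    centroid_sizes: np.ndarray  # (n,)
    iterations: int
    converged: bool


def centroid_size(config: np.ndarray) -> float:
    """Square root of the summed squared landmark distances from the centroid."""
    x = np.asarray(config, dtype=float)
    if x.ndim != 2 or len(x) < 2:
        raise ValueError("need at least two landmarks")
    centered = x - x.mean(axis=0)
    cs = float(np.sqrt(np.sum(centered ** 2)))
    if cs == 0:
        raise ValueError("all landmarks coincide; centroid size undefined")
    return cs


def _center_scale(configs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    centered = configs - configs.mean(axis=-2, keepdims=True)
    cs = np.sqrt(np.sum(centered ** 2, axis=(-2, -1)))
    if np.any(cs == 0):
        raise ValueError("degenerate configuration with zero centroid size")
    return centered / cs[..., None, None], cs


def optimal_rotation(source: np.ndarray, target: np.ndarray) -> np.ndarray:
    """2-D rotation matrix minimising ||source @ R.T - target||, det = +1.

    Closed form: the rotation angle is atan2 of the summed cross and dot
    products of corresponding landmark vectors.
    """
    a = np.asarray(source, float)
    b = np.asarray(target, float)
    dot = float(np.sum(a * b))
    cross = float(np.sum(a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0]))
    theta = np.arctan2(cross, dot)
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, -s], [s, c]])


def _rotate_all(configs: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Optimally rotate each configuration in a stack onto a target."""
    dot = np.einsum("nij,ij->n", configs, target)
    cross = configs[:, :, 0] @ target[:, 1] - configs[:, :, 1] @ target[:, 0]
    theta = np.arctan2(cross, dot)
    c, s = np.cos(theta), np.sin(theta)
    rot = np.empty((len(configs), 2, 2))
    rot[:, 0, 0] = c
    rot[:, 0, 1] = -s
    rot[:, 1, 0] = s
    rot[:, 1, 1] = c
    return np.einsum("nkj,nij->nki", configs, rot)


def _principal_axis_frame(consensus: np.ndarray) -> np.ndarray:
    """Rotation aligning the consensus principal axes with x/y.

    Deterministic: the major axis goes to x; signs are fixed so that the
    first landmark has nonnegative y (falling back to x) after rotation.
    """
    cov = consensus.T @ consensus
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    axes = evecs[:, order]
    if np.linalg.det(axes) < 0:
        axes[:, 1] = -axes[:, 1]
    rotated = consensus @ axes
    if rotated[0, 1] < 0 or (rotated[0, 1] == 0 and rotated[0, 0] < 0):
        axes = -axes  # rotate by pi
    return axes


def gpa(dataset, tol: float = 1e-10, max_iter: int = 100) -> GPAResult:
    """Generalized Procrustes superimposition of a configuration stack.

    Accepts a ``LandmarkDataset`` (replicates flattened into the stack) or a
    plain (n, k, 2) array.  Iterates rotation-to-consensus / consensus
    re-estimation until the consensus RMS change drops below ``tol``; the
    final frame is aligned to the consensus principal axes.
    """
    if isinstance(dataset, LandmarkDataset):
        configs = dataset.flattened()
    else:
        configs = np.asarray(dataset, dtype=float)
    if configs.ndim != 3 or configs.shape[-1] != 2:
        raise ValueError("expected an (n, k, 2) stack of configurations")
    scaled, sizes = _center_scale(configs)

    consensus, _ = _center_scale(scaled[0])
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        aligned = _rotate_all(scaled, consensus)
        new_consensus = aligned.mean(axis=0)
        new_consensus, _ = _center_scale(new_consensus)
        # keep the frame stable across iterations
        new_consensus = new_consensus @ optimal_rotation(new_consensus,
                                                         consensus).T
        change = np.sqrt(np.mean((new_consensus - consensus) ** 2))
        consensus = new_consensus
        if change < tol:
            converged = True
            break
    aligned = _rotate_all(scaled, consensus)

    frame = _principal_axis_frame(consensus)
    consensus = consensus @ frame
    aligned = aligned @ frame
    return GPAResult(aligned=aligned, consensus=consensus,
                     centroid_sizes=sizes, iterations=iterations,
                     converged=converged)


def procrustes_distance(a: np.ndarray, b: np.ndarray,
                        kind: str = "chord") -> float:
    """Partial Procrustes distance between two configurations.

    Both configurations are centered and scaled to unit centroid size and
    optimally rotated (reflections excluded).  ``kind="chord"`` returns the
    Frobenius distance after superimposition; ``kind="geodesic"`` the
    great-circle distance rho = 2 arcsin(d / 2) on the pre-shape sphere.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError("configurations must share the landmark count")
    za, _ = _center_scale(a)
    zb, _ = _center_scale(b)
    rot = optimal_rotation(za, zb)
    d = float(np.linalg.norm(za @ rot.T - zb))
    if kind == "chord":
        return d
    if kind == "geodesic":
        return float(2.0 * np.arcsin(np.clip(d / 2.0, 0.0, 1.0)))
    raise ValueError(f"unknown distance kind: {kind}")


def tangent_projection(result: GPAResult) -> np.ndarray:
    """Orthogonally project aligned configurations onto the tangent space.

    Rows are flattened landmark-major (x1, y1, ..., xk, yk); the component
    along the (unit) consensus vector is removed, so the consensus itself
    maps to the zero vector.
    """
    c = result.consensus.reshape(-1)
    c = c / np.linalg.norm(c)
    x = result.aligned.reshape(len(result.aligned), -1)
    return x - np.outer(x @ c, c)


def _pairwise_distances(result: GPAResult) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs (geodesic Procrustes, tangent Euclidean) distances."""
    z = result.aligned[..., 0] + 1j * result.aligned[..., 1]
    gram = np.abs(z @ z.conj().T)
    d2 = np.clip(2.0 - 2.0 * np.clip(gram, None, 1.0), 0.0, None)
    chord = np.sqrt(d2)
    rho = 2.0 * np.arcsin(np.clip(chord / 2.0, 0.0, 1.0))
    t = tangent_projection(result)
    diff = t[:, None, :] - t[None, :, :]
    eucl = np.sqrt(np.sum(diff ** 2, axis=-1))
    iu = np.triu_indices(len(z), k=1)
    return rho[iu], eucl[iu]


def tangent_space_check(result: GPAResult) -> tuple[float, float]:
    """Adequacy of the Euclidean tangent-space approximation.

    Over all specimen pairs, regress tangent Euclidean distance on the
    Procrustes geodesic distance through the origin.  Returns
    ``(slope, uncentered correlation)``; both approach 1 as shape variation
    shrinks.
    """
    if len(result.aligned) < 3:
        raise ValueError("need at least three specimens")
    rho, eucl = _pairwise_distances(result)
    sxx = float(np.dot(rho, rho))
    sxy = float(np.dot(rho, eucl))
    syy = float(np.dot(eucl, eucl))
    if sxx == 0 or syy == 0:
        return 1.0, 1.0
    return sxy / sxx, sxy / np.sqrt(sxx * syy)
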