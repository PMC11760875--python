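"""Morphospace analysis: PCA of shape coordinates, PC retention, landmark
contributions, extreme-shape reconstruction, convex hulls and thin-plate-
spline deformation grids."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull, QhullError

__all__ = [
    "PCAResult",
    "DeformationGrid",
    "HullResult",
    "pca",
    "meaningful_pcs",
    "landmark_contributions",
    "extreme_shapes",
    "tps_warp",
    "make_lattice",
    "convex_hulls",
]


@dataclass
class PCAResult:
    eigenvalues: np.ndarray   # descending, nonnegative
    loadings: np.ndarray      # (p, k) orthonormal columns
    scores: np.ndarray        # (m, k)
    variance_pct: np.ndarray  # per PC, sums to 100
    mean: np.ndarray          # column means of the input


@dataclass
class DeformationGrid:
    source_grid: np.ndarray
    warped_grid: np.ndarray
    control_source: np.ndarray
    control_target: np.ndarray
    bending_energy: float


@dataclass
class HullResult:
    group: object
    vertices: np.ndarray
    degenerate: bool = False

    @property
    def area(self) -> float:
        if self.degenerate:
            return 0.0
        x, y = self.vertices[:, 0], self.vertices[:, 1]
        return 0.5 * abs(float(np.dot(x, np.roll(y, -1))
                               - np.dot(y, np.roll(x, -1))))


def pca(coords: np.ndarray) -> PCAResult:
    """Covariance PCA of an (m, p) coordinate matrix.

    Eigendecomposition via SVD of the centered data; the sign of each
    loading column is fixed so its largest-magnitude entry is positive.
    """
    x = np.asarray(coords, dtype=float)
    if x.ndim != 2 or len(x) < 3:
        raise ValueError("need an (m, p) matrix with m >= 3")
    mean = x.mean(axis=0)
    xc = x - mean
    total_var = float(np.sum(xc ** 2)) / (len(x) - 1)
    if total_var == 0:
        raise ValueError("zero-variance input")
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    eigenvalues = s ** 2 / (len(x) - 1)
    loadings = vt.T
    # deterministic sign convention
    flip = np.sign(loadings[np.argmax(np.abs(loadings), axis=0),
                            np.arange(loadings.shape[1])])
    flip[flip == 0] = 1.0
    loadings = loadings * flip
    scores = xc @ loadings
    variance_pct = 100.0 * eigenvalues / eigenvalues.sum()
    return PCAResult(eigenvalues=eigenvalues, loadings=loadings,
                     scores=scores, variance_pct=variance_pct, mean=mean)


def meaningful_pcs(eigenvalues: np.ndarray,
                   ratio_threshold: float = 1.32) -> int:
    """Leading run of PCs each at least ``ratio_threshold`` times its successor.

    A PC is retained while lambda_i >= threshold * lambda_{i+1}; the run
    stops at the first failure and the final eigenvalue (with no successor)
    is never counted.
    """
    lam = np.asarray(eigenvalues, dtype=float)
    if len(lam) < 2:
        raise ValueError("need at least two eigenvalues")
    count = 0
    for i in range(len(lam) - 1):
        if lam[i] >= ratio_threshold * lam[i + 1] and lam[i] > 0:
            count += 1
        else:
            break
    return count


def landmark_contributions(result: PCAResult, pc_index: int) -> np.ndarray:
    """Percent contribution of each landmark to one PC's variation.

    The squared x and y loadings of each landmark are summed and expressed
    as a percentage of the total squared loading of that PC; landmarks above
    100 / k percent contribute more than average.
    """
    load = result.loadings[:, pc_index]
    if load.size % 2:
        raise ValueError("loading length must be even (x, y per landmark)")
    per_lm = load.reshape(-1, 2)
    sq = np.sum(per_lm ** 2, axis=1)
    return 100.0 * sq / sq.sum()


def extreme_shapes(result: PCAResult, consensus: np.ndarray, pc_index: int,
                   sign: int) -> np.ndarray:
    """Reconstruct the observed extreme configuration along one PC.

    ``sign > 0`` uses the maximal observed score, ``sign < 0`` the minimal;
    the consensus is displaced by score x loading vector and reshaped to
    (k, 2).
    """
    scores = result.scores[:, pc_index]
    score = float(scores.max() if sign > 0 else scores.min())
    flat = np.asarray(consensus, float).reshape(-1) + score * result.loadings[:, pc_index]
    return flat.reshape(-1, 2)


def _tps_kernel(r2: np.ndarray) -> np.ndarray:
    out = np.zeros_like(r2)
    mask = r2 > 0
    out[mask] = r2[mask] * np.log(r2[mask])
    return out


def tps_warp(source: np.ndarray, target: np.ndarray,
             lattice: np.ndarray) -> DeformationGrid:
    """Exact interpolating thin-plate-spline warp of a lattice.

    Standard 2-D biharmonic spline with kernel U(r) = r^2 log r^2 plus an
    affine part; the warp maps each source landmark exactly onto its target.
    The bending energy is the quadratic form of the non-affine coefficients,
    summed over the two output coordinates.
    """
    src = np.asarray(source, float)
    tgt = np.asarray(target, float)
    lat = np.asarray(lattice, float)
    if src.shape != tgt.shape or src.ndim != 2 or src.shape[1] != 2:
        raise ValueError("source and target must be matching (k, 2) arrays")
    k = len(src)
    p = np.hstack([np.ones((k, 1)), src])
    if np.linalg.matrix_rank(p) < 3:
        raise ValueError("collinear source landmarks; TPS is singular")
    d2 = np.sum((src[:, None] - src[None]) ** 2, axis=-1)
    kmat = _tps_kernel(d2)
    lmat = np.zeros((k + 3, k + 3))
    lmat[:k, :k] = kmat
    lmat[:k, k:] = p
    lmat[k:, :k] = p.T
    rhs = np.zeros((k + 3, 2))
    rhs[:k] = tgt
    coef = np.linalg.solve(lmat, rhs)
    w, a = coef[:k], coef[k:]
    bending = float(np.trace(w.T @ kmat @ w))

    d2_lat = np.sum((lat[:, None] - src[None]) ** 2, axis=-1)
    warped = (_tps_kernel(d2_lat) @ w
              + np.hstack([np.ones((len(lat), 1)), lat]) @ a)
    return DeformationGrid(source_grid=lat, warped_grid=warped,
                           control_source=src, control_target=tgt,
                           bending_energy=bending)


def make_lattice(points: np.ndarray, shape: tuple[int, int] = (20, 20),
                 margin: float = 0.1) -> np.ndarray:
    """Regular lattice covering a point set with a relative margin."""
    pts = np.asarray(points, float)
    lo = pts.min(axis=0)
    hi = pts.max(axis=0)
    pad = margin * (hi - lo)
    xs = np.linspace(lo[0] - pad[0], hi[0] + pad[0], shape[0])
    ys = np.linspace(lo[1] - pad[1], hi[1] + pad[1], shape[1])
    gx, gy = np.meshgrid(xs, ys)
    return np.column_stack([gx.ravel(), gy.ravel()])


def convex_hulls(scores: np.ndarray, groups: np.ndarray) -> dict:
    """Per-group 2-D convex hulls of ordination scores.

    Returns a mapping group -> ``HullResult`` with counterclockwise hull
    vertices; groups with fewer than three non-collinear points yield a
    degenerate result flagged as such.
    """
    pts = np.asarray(scores, float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("scores must be (m, 2)")
    groups = np.asarray(groups)
    out = {}
    for g in np.unique(groups):
        sub = pts[groups == g]
        if len(sub) < 3:
            out[g] = HullResult(group=g, vertices=sub, degenerate=True)
            continue
        try:
            hull = ConvexHull(sub)
        except QhullError:
            out[g] = HullResult(group=g, vertices=sub, degenerate=True)
            continue
        out[g] = HullResult(group=g, vertices=sub[hull.vertices])
    return out
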