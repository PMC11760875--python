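"""Eight-landmark scheme for crescent-shaped myxospores in sutural view.

The landmark configuration covers the spore outline with two fixed suture
points, two valve-tip points, and four constructed points:

* L1 — suture point on the convex (anterior) side
* L5 — suture point on the concave (posterior) side
* L3, L7 — points of maximal boundary curvature at the left / right valve tips
* L2, L8 — outermost (anterior) boundary points, L4, L6 — innermost
  (posterior) boundary points, obtained from a line perpendicular to the
  segment joining the suture midpoint M with the respective tip, drawn
  through the midpoint of that segment.

The bilateral pairing is (L2, L8), (L3, L7), (L4, L6); L1 and L5 lie on the
symmetry axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import LineString, Point, Polygon

__all__ = [
    "LandmarkConfiguration",
    "TraditionalMeasures",
    "GeometryError",
    "PAIRING",
    "PAIR_PERMUTATION",
    "detect_tips",
    "construct_landmarks",
    "measure_traditional",
]

#: involution on 1-based landmark labels; L1 and L5 are fixed midline points
PAIRING = {1: 1, 2: 8, 3: 7, 4: 6, 5: 5, 6: 4, 7: 3, 8: 2}

#: 0-based index permutation implementing the relabelling part of the pairing
PAIR_PERMUTATION = np.array([PAIRING[i + 1] - 1 for i in range(8)])

LABELS = tuple(f"L{i}" for i in range(1, 9))


class GeometryError(ValueError):
    """Raised when a landmark cannot be constructed on an outline."""


@dataclass(frozen=True)
class LandmarkConfiguration:
    """Ordered 8 x 2 landmark coordinates (µm) with the bilateral pairing."""

    coords: np.ndarray
    labels: tuple[str, ...] = LABELS

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.shape != (8, 2):
            raise ValueError(f"expected 8x2 coordinates, got {coords.shape}")
        if not np.all(np.isfinite(coords)):
            raise ValueError("landmark coordinates must be finite")
        object.__setattr__(self, "coords", coords)

    def transformed(self, rotation: np.ndarray | None = None,
                    translation: np.ndarray | None = None,
                    scale: float = 1.0) -> "LandmarkConfiguration":
        out = self.coords * scale
        if rotation is not None:
            out = out @ np.asarray(rotation).T
        if translation is not None:
            out = out + np.asarray(translation)
        return LandmarkConfiguration(out)


@dataclass(frozen=True)
class TraditionalMeasures:
    """Length, thickness (µm) and posterior angle (degrees) of a spore."""

    length: float
    thickness: float
    posterior_angle: float


def _polygon_curvature(vertices: np.ndarray) -> np.ndarray:
    """Discrete curvature per vertex of a closed polygon.

    Three-point circumradius estimator: curvature at vertex i is the inverse
    circumradius of the triangle (v[i-1], v[i], v[i+1]).
    """
    a = np.roll(vertices, 1, axis=0)
    b = vertices
    c = np.roll(vertices, -1, axis=0)
    ab = b - a
    ac = c - a
    bc = c - b
    cross = np.abs(ab[:, 0] * ac[:, 1] - ab[:, 1] * ac[:, 0])
    denom = (np.linalg.norm(ab, axis=1) * np.linalg.norm(ac, axis=1)
             * np.linalg.norm(bc, axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        kappa = np.where(denom > 0, 2.0 * cross / denom, 0.0)
    return kappa


def _smooth_cyclic(values: np.ndarray, window: int) -> np.ndarray:
    if window % 2 == 0 or window < 1:
        raise ValueError("smoothing window must be a positive odd integer")
    if window == 1:
        return values
    kernel = np.ones(window) / window
    padded = np.concatenate([values[-(window // 2):], values,
                             values[: window // 2]])
    return np.convolve(padded, kernel, mode="valid")


def detect_tips(outline, smoothing_window: int = 7):
    """Locate the two valve tips as boundary points of maximal curvature.

    The outline is split into lateral halves by the suture axis (the line
    through the two suture points); the smoothed discrete curvature is
    maximised on each half.  Left/right is assigned by the sign of the cross
    product of the suture axis direction (posterior -> anterior) with the
    vertex offset.

    Returns ``(tip_left, tip_right)`` as length-2 arrays.
    """
    verts = np.asarray(outline.vertices, dtype=float)
    anterior = np.asarray(outline.suture_anterior, dtype=float)
    posterior = np.asarray(outline.suture_posterior, dtype=float)
    axis = anterior - posterior
    norm = np.linalg.norm(axis)
    if norm == 0:
        raise GeometryError("degenerate suture axis")
    axis = axis / norm

    kappa = _smooth_cyclic(_polygon_curvature(verts), smoothing_window)
    offset = verts - posterior
    side = axis[0] * offset[:, 1] - axis[1] * offset[:, 0]

    tips = []
    for mask in (side > 0, side < 0):
        if not np.any(mask):
            raise GeometryError("tips not resolvable: empty lateral half")
        k_half = kappa[mask]
        peak = float(np.max(k_half))
        typical = float(np.median(k_half))
        if typical > 0 and peak < 1.05 * typical:
            raise GeometryError(
                "tips not resolvable: no distinct curvature maximum "
                f"(max {peak:.4g} vs median {typical:.4g})")
        idx = np.flatnonzero(mask)[int(np.argmax(k_half))]
        tips.append(verts[idx])
    tip_left, tip_right = tips
    return tip_left, tip_right


def _perpendicular_intersections(polygon: Polygon, ring: LineString,
                                 q: np.ndarray, direction: np.ndarray,
                                 reach: float):
    """Signed offsets along ``direction`` where the line through q meets ring."""
    probe = LineString([q - reach * direction, q + reach * direction])
    inter = probe.intersection(ring)
    points: list[np.ndarray] = []
    if inter.is_empty:
        return np.array([])
    geoms = getattr(inter, "geoms", [inter])
    for g in geoms:
        if isinstance(g, Point):
            points.append(np.array([g.x, g.y]))
        else:  # grazing contact may produce tiny line fragments
            points.extend(np.asarray(g.coords))
    s = np.array([float(np.dot(p - q, direction)) for p in points])
    return np.sort(s)


def construct_landmarks(outline, smoothing_window: int = 7) -> LandmarkConfiguration:
    """Build the full eight-landmark configuration on a spore outline.

    L2/L4 (left valve) and L8/L6 (right valve) are the outer/inner boundary
    crossings of the line perpendicular to M-tip through the midpoint of
    M-tip, where M is the midpoint of the suture chord L1-L5.  "Outer" is the
    crossing reached last when travelling anteriorly (towards L1).
    """
    verts = np.asarray(outline.vertices, dtype=float)
    l1 = np.asarray(outline.suture_anterior, dtype=float)
    l5 = np.asarray(outline.suture_posterior, dtype=float)
    tip_left, tip_right = detect_tips(outline, smoothing_window)

    polygon = Polygon(verts)
    ring = LineString(np.vstack([verts, verts[:1]]))
    span = verts.max(axis=0) - verts.min(axis=0)
    reach = 4.0 * float(np.linalg.norm(span))

    m = 0.5 * (l1 + l5)
    anterior_dir = l1 - l5
    if np.linalg.norm(anterior_dir) == 0:
        raise GeometryError("suture points coincide")

    side_points = {}
    for tip, side in ((tip_left, "left"), (tip_right, "right")):
        q = 0.5 * (m + tip)
        chord = tip - m
        if np.linalg.norm(chord) == 0:
            raise GeometryError(f"{side} tip coincides with suture midpoint")
        perp = np.array([-chord[1], chord[0]])
        perp = perp / np.linalg.norm(perp)
        if np.dot(perp, anterior_dir) < 0:
            perp = -perp
        if abs(np.dot(perp, anterior_dir)) < 1e-9 * np.linalg.norm(anterior_dir):
            raise GeometryError(
                f"{side} perpendicular is orthogonal to the suture axis; "
                "anterior side undefined")
        s = _perpendicular_intersections(polygon, ring, q, perp, reach)
        if len(s) < 2:
            raise GeometryError(
                f"perpendicular misses the outline on the {side} side "
                f"(q={q}, direction={perp}, crossings={s})")
        # consecutive crossing pairs bracketing polygon interior
        candidates = []
        for s0, s1 in zip(s[:-1], s[1:]):
            if s1 - s0 < 1e-12:
                continue
            mid = q + 0.5 * (s0 + s1) * perp
            if polygon.contains(Point(mid)):
                gap = 0.0 if s0 <= 0.0 <= s1 else min(abs(s0), abs(s1))
                candidates.append((gap, s0, s1))
        if not candidates:
            raise GeometryError(
                f"no interior segment found on the {side} side "
                f"(q={q}, crossings={s})")
        candidates.sort()
        _, s_inner, s_outer = candidates[0]
        side_points[side] = (q + s_outer * perp, q + s_inner * perp)

    l2, l4 = side_points["left"]
    l8, l6 = side_points["right"]
    coords = np.vstack([l1, l2, tip_left, l4, l5, l6, tip_right, l8])
    return LandmarkConfiguration(coords)


def measure_traditional(config: LandmarkConfiguration) -> TraditionalMeasures:
    """Traditional measurements from the landmark configuration.

    length = |L1 - L5| (axial diameter), thickness = |L3 - L7| (straight
    tip-to-tip chord), posterior angle = angle at L5 between the rays to the
    two tips, in degrees.
    """
    c = config.coords if isinstance(config, LandmarkConfiguration) else np.asarray(config, float)
    l1, l3, l5, l7 = c[0], c[2], c[4], c[6]
    length = float(np.linalg.norm(l1 - l5))
    thickness = float(np.linalg.norm(l3 - l7))
    v1 = l3 - l5
    v2 = l7 - l5
    n1 = np.linalg.norm(v1)
    n2 = np.linalg.norm(v2)
    if length == 0 or thickness == 0 or n1 == 0 or n2 == 0:
        raise GeometryError("coincident landmarks; measures undefined")
    cosang = np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0)
    angle = float(np.degrees(np.arccos(cosang)))
    return TraditionalMeasures(length=length, thickness=thickness,
                               posterior_angle=angle)
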