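"""Synthetic populations of crescent-shaped myxospore outlines.

The shape family is a circular-arc crescent: a centerline arc of radius
``centerline_radius`` spanning ``±centerline_half_angle``, thickened by the
half-width profile ``w(t) = max_half_width * (1 - t^2)^taper_exponent``
offset along the centerline normals (t in [-1, 1]).  The suture axis is the
symmetry axis through the arc apex; valve tips sit at the arc endpoints,
where the width tapers to zero.

Population structure: two interpretable symmetric deformation modes (mode 1
perturbs the arc half-angle and hence the posterior angle; mode 2 perturbs
the half-width on a log scale and hence the spore length), a lognormal size
factor with host-specific shifts, an allometric coupling of size to mode 2,
host-specific mode-2 shifts, an antisymmetric (left/right differential)
perturbation emulating developmental noise, and per-replicate digitization
noise on landmark coordinates.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from shapely.geometry import Polygon

from .landmarks import LandmarkConfiguration, construct_landmarks
from .procrustes import LandmarkDataset, centroid_size

__all__ = [
    "CrescentParams",
    "PopulationSpec",
    "Outline",
    "SpecimenSet",
    "make_mean_outline",
    "sample_population",
    "digitize_replicates",
    "default_calibration",
    "solve_crescent_params",
]

# named substreams of the root seed
_STREAMS = {"sizes": 0, "modes": 1, "hosts": 2, "asymmetry": 3,
            "digitization": 4, "pose": 5}

# fixed standardized host-effect patterns (weighted mean 0, weighted SD 1
# under the default host sizes); hosts act as fixed effects of the study
# design rather than fresh random draws, so cohorts are comparable across
# seeds.  Patterns are deterministic functions of the host count.
def _host_patterns(host_sizes: tuple[int, ...]) -> tuple[np.ndarray, np.ndarray]:
    k = len(host_sizes)
    w = np.asarray(host_sizes, dtype=float)
    w = w / w.sum()

    def standardize(raw: np.ndarray) -> np.ndarray:
        raw = raw - np.dot(w, raw)
        sd = math.sqrt(float(np.dot(w, raw ** 2)))
        return raw / sd if sd > 0 else raw

    base = np.linspace(-1.0, 1.0, k)
    alt = np.array([(-1.0) ** i for i in range(k)]) * np.linspace(0.6, 1.4, k)
    return standardize(base), standardize(alt)


@dataclass(frozen=True)
class CrescentParams:
    """Parameters of the mean crescent outline (lengths in µm)."""

    centerline_radius: float
    centerline_half_angle: float
    max_half_width: float
    taper_exponent: float = 0.7

    def __post_init__(self) -> None:
        if self.centerline_radius <= 0 or self.max_half_width <= 0:
            raise ValueError("radius and half-width must be positive")
        if not 0 < self.centerline_half_angle < math.pi:
            raise ValueError("centerline_half_angle must lie in (0, pi)")
        if self.taper_exponent <= 0:
            raise ValueError("taper_exponent must be positive")


@dataclass(frozen=True)
class Outline:
    """Closed 2-D spore boundary (µm) with annotated suture-axis endpoints.

    Vertices are ordered counterclockwise; the polygon is closed implicitly
    (the first vertex is not repeated).  ``suture_anterior`` lies on the
    convex side, ``suture_posterior`` on the concave side.
    """

    vertices: np.ndarray
    suture_anterior: np.ndarray
    suture_posterior: np.ndarray

    def __post_init__(self) -> None:
        verts = np.asarray(self.vertices, dtype=float)
        if verts.ndim != 2 or verts.shape[1] != 2 or len(verts) < 200:
            raise ValueError("outline needs >= 200 two-dimensional vertices")
        object.__setattr__(self, "vertices", verts)
        object.__setattr__(self, "suture_anterior",
                           np.asarray(self.suture_anterior, dtype=float))
        object.__setattr__(self, "suture_posterior",
                           np.asarray(self.suture_posterior, dtype=float))

    @property
    def signed_area(self) -> float:
        x, y = self.vertices[:, 0], self.vertices[:, 1]
        return 0.5 * float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))

    def is_simple(self) -> bool:
        return Polygon(self.vertices).is_valid

    def transformed(self, rotation: np.ndarray | None = None,
                    translation: np.ndarray | None = None) -> "Outline":
        def move(p):
            p = np.asarray(p, dtype=float)
            if rotation is not None:
                p = p @ np.asarray(rotation).T
            if translation is not None:
                p = p + np.asarray(translation)
            return p
        return Outline(move(self.vertices), move(self.suture_anterior),
                       move(self.suture_posterior))


@dataclass(frozen=True)
class PopulationSpec:
    """Statistical specification of a synthetic spore population.

    ``mode1_sd`` (radians) and ``mode2_sd`` (log units) are the SDs of the
    two symmetric shape-mode scores.  ``size_cv`` is the within-host SD of
    the log size factor; ``host_size_shift_sd`` / ``host_shape_shift_sd``
    scale fixed standardized host-effect patterns.  ``allometric_slope`` is
    the mode-2 score change per µm of centroid size.  ``asymmetry_sd`` (µm)
    is the RMS landmark displacement of the fluctuating left/right
    perturbation and ``directional_asymmetry`` (µm) that of its constant
    component.  ``digitization_sd`` (µm) is per-replicate coordinate noise.
    """

    mean_params: CrescentParams
    mode1_sd: float
    mode2_sd: float
    host_count: int
    host_sizes: tuple[int, ...]
    host_shape_shift_sd: float
    host_size_shift_sd: float
    allometric_slope: float
    asymmetry_sd: float
    directional_asymmetry: float
    digitization_sd: float
    size_cv: float
    seed: int
    n_replicates: int = 2
    n_vertices: int = 400
    pose_jitter: bool = True

    def __post_init__(self) -> None:
        sizes = tuple(int(s) for s in self.host_sizes)
        object.__setattr__(self, "host_sizes", sizes)
        if len(sizes) != self.host_count:
            raise ValueError("host_sizes length must equal host_count")
        if any(s <= 0 for s in sizes):
            raise ValueError("host sizes must be positive")
        for name in ("mode1_sd", "mode2_sd", "host_shape_shift_sd",
                     "host_size_shift_sd", "asymmetry_sd", "digitization_sd",
                     "size_cv", "directional_asymmetry"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    @property
    def n_specimens(self) -> int:
        return sum(self.host_sizes)

    def rng(self, stream: str) -> np.random.Generator:
        key = _STREAMS[stream]
        return np.random.default_rng(
            np.random.SeedSequence(entropy=int(self.seed), spawn_key=(key,)))


@dataclass
class SpecimenSet:
    """Ground-truth synthetic cohort: outlines, hosts, noise-free landmarks."""

    outlines: list[Outline]
    host_id: np.ndarray
    true_landmarks: list[LandmarkConfiguration]
    true_mode_scores: np.ndarray  # (n, 2)
    true_sizes: np.ndarray        # size factors, mean ~ 1
    spec: PopulationSpec
    n_resampled: int = 0

    def __len__(self) -> int:
        return len(self.outlines)


def _build_outline(params: CrescentParams, n_vertices: int,
                   mode1: float = 0.0, mode2: float = 0.0,
                   asym_angle: float = 0.0, asym_width: float = 0.0,
                   scale: float = 1.0) -> Outline:
    """Construct a (possibly deformed) crescent outline in canonical pose.

    Mode 1 bends the valves: the half-angle grows by ``mode1`` (radians)
    while the centerline radius shrinks to preserve the centerline arc
    length, so bending is nearly size-neutral.  Mode 2 shifts the
    log half-width (spore length).  Asymmetric perturbations flip sign
    under the mirror map t -> -t: the polar angle gets the even term
    ``t^2 * asym_angle / 2`` (one valve arc lengthens, the other shortens)
    and the log-width the odd term ``t * asym_width / 2`` (one valve wider,
    the other narrower); the symmetric average stays at the unperturbed
    shape to first order.
    """
    phi0 = params.centerline_half_angle
    phi = phi0 + mode1
    if not 0 < phi < math.pi:
        raise ValueError("deformed half-angle outside (0, pi)")
    r = params.centerline_radius * phi0 / phi  # constant valve arc length
    width = params.max_half_width * math.exp(mode2)

    n_half = max(n_vertices // 2 + 1, 101)
    if n_half % 2 == 0:
        n_half += 1
    # sinusoidal clustering concentrates vertices at the tapering tips so the
    # discrete boundary resolves the tip caps where curvature peaks
    t = np.sin(np.linspace(-1.0, 1.0, n_half) * (math.pi / 2.0))
    theta = t * phi + t ** 2 * (asym_angle / 2.0)
    w = width * np.exp(t * (asym_width / 2.0)) * (1.0 - t ** 2) ** params.taper_exponent
    u = np.column_stack([np.sin(theta), np.cos(theta)])
    if np.any(r - w <= 0):
        raise ValueError("half-width exceeds centerline radius")
    outer = (r + w)[:, None] * u
    inner = (r - w)[:, None] * u
    # counterclockwise: outer boundary right tip -> left tip, inner back
    verts = np.vstack([outer[::-1], inner[1:-1]])
    suture_anterior = np.array([0.0, r + width])
    suture_posterior = np.array([0.0, r - width])
    verts = verts * scale
    return Outline(verts, suture_anterior * scale, suture_posterior * scale)


def make_mean_outline(params: CrescentParams, n_vertices: int = 400) -> Outline:
    """The noise-free mean crescent outline for a parameter set."""
    if n_vertices < 200:
        raise ValueError("n_vertices must be >= 200")
    outline = _build_outline(params, n_vertices)
    if not outline.is_simple() or outline.signed_area <= 0:
        raise ValueError(
            "parameter combination yields a self-intersecting outline: "
            f"{params}")
    return outline


def solve_crescent_params(length: float, thickness: float,
                          posterior_angle_deg: float,
                          taper_exponent: float = 0.7) -> CrescentParams:
    """Closed-form crescent parameters from traditional measures.

    With tips at the arc endpoints, length = 2 * max_half_width, thickness =
    2 * R * sin(phi), and the posterior angle at the concave suture point
    fixes the vertical drop from that point to the tips, which yields
    tan(phi / 2) = (W + drop) / (thickness / 2).
    """
    w = length / 2.0
    h = thickness / 2.0
    drop = h / math.tan(math.radians(posterior_angle_deg) / 2.0)
    phi = 2.0 * math.atan((w + drop) / h)
    radius = h / math.sin(phi)
    return CrescentParams(centerline_radius=radius, centerline_half_angle=phi,
                          max_half_width=w, taper_exponent=taper_exponent)


def _landmarks_for(params: CrescentParams, n_vertices: int,
                   **deform) -> np.ndarray:
    outline = _build_outline(params, n_vertices, **deform)
    return construct_landmarks(outline).coords


def asymmetry_unit_norms(params: CrescentParams, n_vertices: int = 400,
                         step: float = 1e-4) -> tuple[float, float]:
    """RMS landmark displacement (µm) per unit of each asymmetric score.

    Finite differences of the landmark map at the mean parameters; used to
    express the asymmetry magnitude in µm of landmark displacement.
    """
    base = _landmarks_for(params, n_vertices)
    norms = []
    for key in ("asym_angle", "asym_width"):
        plus = _landmarks_for(params, n_vertices, **{key: step})
        minus = _landmarks_for(params, n_vertices, **{key: -step})
        grad = (plus - minus) / (2.0 * step)
        norms.append(float(np.sqrt(np.mean(np.sum(grad ** 2, axis=1)))))
    del base
    return norms[0], norms[1]


# variance split of the fluctuating asymmetry between its angle-like and
# width-like directions (fractions of the asymmetric variance)
_ASYM_MIX = (math.sqrt(8.6 / 13.3), math.sqrt(4.7 / 13.3))

_MAX_RESAMPLE = 100


def sample_population(spec: PopulationSpec) -> SpecimenSet:
    """Draw a synthetic cohort from a population specification.

    Deterministic given ``spec`` (including its seed): all randomness comes
    from named substreams of the root seed.  Specimens whose deformation
    produces a non-simple outline are redrawn (at most 100 tries each), with
    the resample count reported on the result.
    """
    n = spec.n_specimens
    host_id = np.repeat(np.arange(1, spec.host_count + 1), spec.host_sizes)
    shape_pattern, size_pattern = _host_patterns(spec.host_sizes)

    rng_sizes = spec.rng("sizes")
    rng_modes = spec.rng("modes")
    rng_asym = spec.rng("asymmetry")
    rng_pose = spec.rng("pose")

    n1, n2 = asymmetry_unit_norms(spec.mean_params, spec.n_vertices)
    mean_lm = _landmarks_for(spec.mean_params, spec.n_vertices)
    cs0 = centroid_size(mean_lm)
    # center the lognormal width mode so the mean spore length stays at the
    # mean-parameter value: E[exp(m2)] = exp(var/2) without this shift
    var_m2 = (spec.mode2_sd ** 2 + spec.host_shape_shift_sd ** 2
              + (spec.allometric_slope * cs0 * spec.size_cv) ** 2)
    # the second term removes the allometric size-width covariance from the
    # expected length (E[s * exp(m2)] inflation)
    m2_center = (-0.5 * var_m2
                 - spec.allometric_slope * cs0 * spec.size_cv ** 2)

    outlines: list[Outline] = []
    true_lms: list[LandmarkConfiguration] = []
    scores = np.empty((n, 2))
    sizes = np.empty(n)
    n_resampled = 0

    for i in range(n):
        h = host_id[i] - 1
        for attempt in range(_MAX_RESAMPLE):
            log_s = (spec.host_size_shift_sd * size_pattern[h]
                     + spec.size_cv * rng_sizes.standard_normal()
                     - 0.5 * spec.size_cv ** 2)
            s = math.exp(log_s)
            m1 = spec.mode1_sd * rng_modes.standard_normal()
            # allometry acts on log size so within-host shape dispersion is
            # identical across hosts (the size factor is multiplicative)
            m2 = (m2_center
                  + spec.host_shape_shift_sd * shape_pattern[h]
                  + spec.allometric_slope * cs0 * (log_s + 0.5 * spec.size_cv ** 2)
                  + spec.mode2_sd * rng_modes.standard_normal())
            a_angle = ((spec.asymmetry_sd * _ASYM_MIX[0]
                        * rng_asym.standard_normal()
                        + spec.directional_asymmetry) / n1)
            a_width = (spec.asymmetry_sd * _ASYM_MIX[1]
                       * rng_asym.standard_normal()) / n2
            try:
                outline = _build_outline(spec.mean_params, spec.n_vertices,
                                         mode1=m1, mode2=m2,
                                         asym_angle=a_angle,
                                         asym_width=a_width, scale=s)
                if not outline.is_simple() or outline.signed_area <= 0:
                    raise ValueError("non-simple outline")
                lm = construct_landmarks(outline)
            except ValueError:
                n_resampled += 1
                continue
            break
        else:
            raise RuntimeError(
                f"specimen {i}: no simple outline in {_MAX_RESAMPLE} tries")

        if spec.pose_jitter:
            angle = rng_pose.uniform(0.0, 2.0 * math.pi)
            shift = rng_pose.normal(0.0, 20.0, size=2)
            rot = np.array([[math.cos(angle), -math.sin(angle)],
                            [math.sin(angle), math.cos(angle)]])
            outline = outline.transformed(rotation=rot, translation=shift)
            lm = lm.transformed(rotation=rot, translation=shift)

        outlines.append(outline)
        true_lms.append(lm)
        scores[i] = (m1, m2)
        sizes[i] = s

    if n_resampled:
        warnings.warn(f"resampled {n_resampled} degenerate outline draw(s)",
                      stacklevel=2)
    return SpecimenSet(outlines=outlines, host_id=host_id,
                       true_landmarks=true_lms, true_mode_scores=scores,
                       true_sizes=sizes, spec=spec, n_resampled=n_resampled)


def digitize_replicates(specimens: SpecimenSet, n_replicates: int | None = None,
                        spec: PopulationSpec | None = None) -> LandmarkDataset:
    """Digitize each specimen's landmarks with per-replicate noise.

    Landmarks are constructed once per outline; each replicate adds
    independent N(0, digitization_sd^2) noise to every coordinate,
    emulating repeated manual landmark placement on the same photograph.
    """
    spec = spec if spec is not None else specimens.spec
    r = int(n_replicates if n_replicates is not None else spec.n_replicates)
    if r < 1:
        raise ValueError("need at least one replicate")
    rng = spec.rng("digitization")
    base = np.stack([lm.coords for lm in specimens.true_landmarks])
    coords = np.repeat(base[:, None], r, axis=1)
    coords = coords + rng.normal(0.0, spec.digitization_sd, size=coords.shape)
    m = len(specimens)
    return LandmarkDataset(
        coords=coords,
        host_id=np.asarray(specimens.host_id),
        specimen_id=np.array([f"spore_{i + 1:03d}" for i in range(m)]),
        replicate_id=np.arange(1, r + 1),
    )


def default_calibration() -> PopulationSpec:
    """The frozen default population specification.

    Calibrated so that cohorts reproduce the study conditions: mean length
    8.6 µm, thickness 20.5 µm, posterior angle 104.3 degrees; five hosts of
    20/16/19/17/35 spores; centroid-size CV 15.2 % with host identity
    explaining ~25 % of size variation; a shape-variance budget giving
    PC1 ~ 64 %, PC1+PC2 ~ 83 %, a ~78 % symmetric component, repeatability
    > 0.99 and < 1 % digitization measurement error over two replicates.
    """
    mean_params = solve_crescent_params(8.6, 20.5, 104.3, taper_exponent=0.7)
    return PopulationSpec(
        mean_params=mean_params,
        mode1_sd=_CAL["mode1_sd"],
        mode2_sd=_CAL["mode2_sd"],
        host_count=5,
        host_sizes=(20, 16, 19, 17, 35),
        host_shape_shift_sd=_CAL["host_shape_shift_sd"],
        host_size_shift_sd=_CAL["host_size_shift_sd"],
        allometric_slope=_CAL["allometric_slope"],
        asymmetry_sd=_CAL["asymmetry_sd"],
        directional_asymmetry=_CAL["directional_asymmetry"],
        digitization_sd=_CAL["digitization_sd"],
        size_cv=_CAL["size_cv"],
        seed=20250116,
        n_replicates=2,
    )


# Frozen numeric calibration of the default population (see docs/methods.md).
_CAL = {
    "mode1_sd": 0.3424,
    "mode2_sd": 0.0820,
    "host_shape_shift_sd": 0.1117,
    "host_size_shift_sd": 0.0585,
    "allometric_slope": 0.0500,
    "asymmetry_sd": 0.7883,
    "directional_asymmetry": 0.7054,
    "digitization_sd": 0.05,
    "size_cv": 0.0979,
}
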