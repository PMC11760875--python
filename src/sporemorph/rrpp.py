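"""Procrustes ANOVA/ANCOVA with residual-randomization permutation inference.

Linear models on (multivariate) shape or (univariate) size responses are
fitted with sequential (type I) sums of squares based on Procrustes
distance: the SS of each term is the drop in residual trace when the term
is added to the preceding ones.  Significance comes from the residual
randomization permutation procedure (RRPP): for each term, the residuals of
its reduced model (the preceding terms) are permuted across specimens,
added back to the reduced-model fit, and the pseudo-F recomputed; the
p value is the proportion of the permutation distribution (the observed
arrangement included) at or above the observed statistic, and the effect
size Z standardizes the observed log F within the permuted log F
distribution.

A permutational test of multivariate dispersion homogeneity (distances to
group centroids, label permutation) is included as the assumption check
behind the permutation ANOVA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ModelSpec", "RRPPTable", "DispersionResult", "design_matrices",
           "fit_sequential", "rrpp_test", "size_anova", "dispersion_test"]

_TERMS = ("size", "host", "size:host")


@dataclass
class ModelSpec:
    """A sequential linear model for shape or size data.

    ``response`` is an (m, q) matrix (tangent shape coordinates) or an
    (m,) vector (e.g. centroid size); ``terms`` is an ordered subset of
    ``("size", "host", "size:host")``.
    """

    response: np.ndarray
    terms: tuple[str, ...]
    size: np.ndarray | None = None
    host: np.ndarray | None = None
    n_perm: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        y = np.asarray(self.response, dtype=float)
        if y.ndim == 1:
            y = y[:, None]
        self.response = y
        self.terms = tuple(self.terms)
        for t in self.terms:
            if t not in _TERMS:
                raise ValueError(f"unknown term {t!r}")
        if "size:host" in self.terms and not {"size", "host"} <= set(self.terms):
            raise ValueError("interaction requires both main effects")
        if "size" in self.terms and self.size is None:
            raise ValueError("size covariate missing")
        if "host" in self.terms and self.host is None:
            raise ValueError("host labels missing")


@dataclass
class RRPPTable:
    """Sequential-SS ANOVA/ANCOVA table with optional permutation columns."""

    table: pd.DataFrame
    n_perm: int | None = None
    seed: int | None = None

    def __getitem__(self, key):
        return self.table[key]

    @property
    def ss_total(self) -> float:
        return float(self.table.loc["Total", "SS"])

    def __repr__(self) -> str:  # Table-style layout: df, SS, MS, Rsq, F, Z, p
        return self.table.to_string(float_format=lambda v: f"{v:.4g}")


def _dummy(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels)
    levels = np.unique(labels)
    if len(levels) < 2:
        raise ValueError("factor needs at least two levels")
    return (labels[:, None] == levels[None, 1:]).astype(float)


def design_matrices(model: ModelSpec) -> list[tuple[str, np.ndarray]]:
    """Ordered term blocks of the design matrix (intercept excluded)."""
    blocks = []
    for term in model.terms:
        if term == "size":
            x = np.asarray(model.size, dtype=float).reshape(-1, 1)
        elif term == "host":
            x = _dummy(model.host)
        else:
            size = np.asarray(model.size, dtype=float).reshape(-1, 1)
            x = size * _dummy(model.host)
        blocks.append((term, x))
    return blocks


def _nested_bases(model: ModelSpec) -> tuple[list[np.ndarray], list[int]]:
    """Orthonormal bases Q_0 ... Q_K of the nested model sequence."""
    m = len(model.response)
    x = np.ones((m, 1))
    bases = []
    ranks = []
    q, _ = np.linalg.qr(x)
    bases.append(q)
    ranks.append(1)
    for term, block in design_matrices(model):
        x = np.hstack([x, block])
        u, s, _ = np.linalg.svd(x, full_matrices=False)
        q = u[:, s > 1e-9 * s[0]]
        if q.shape[1] == ranks[-1]:
            raise ValueError(f"term {term!r} is aliased with preceding terms")
        bases.append(q)
        ranks.append(q.shape[1])
    return bases, ranks


def fit_sequential(model: ModelSpec) -> RRPPTable:
    """Sequential (type I) sums of squares for an ordered model.

    SS of term k is RSS(terms 1..k-1) - RSS(terms 1..k) with RSS the trace
    of the residual cross-product (the summed squared Procrustes residual
    distances when the response is tangent shape coordinates); pseudo-F uses
    the full-model residual mean square.
    """
    y = model.response
    m = len(y)
    bases, ranks = _nested_bases(model)
    fit_ss = [float(np.sum((q.T @ y) ** 2)) for q in bases]
    yss = float(np.sum(y ** 2))
    rss = [yss - f for f in fit_ss]
    ss_total = rss[0]
    ss_terms = [rss[i] - rss[i + 1] for i in range(len(model.terms))]
    df_terms = [ranks[i + 1] - ranks[i] for i in range(len(model.terms))]
    df_res = m - ranks[-1]
    if df_res <= 0:
        raise ValueError("saturated model: no residual degrees of freedom")
    ms_res = rss[-1] / df_res

    rows = []
    for term, ss, df in zip(model.terms, ss_terms, df_terms):
        ms = ss / df
        rows.append({"df": df, "SS": ss, "MS": ms,
                     "Rsq": ss / ss_total if ss_total > 0 else np.nan,
                     "F": ms / ms_res if ms_res > 0 else np.inf,
                     "Z": np.nan, "p": np.nan})
    rows.append({"df": df_res, "SS": rss[-1], "MS": ms_res,
                 "Rsq": rss[-1] / ss_total if ss_total > 0 else np.nan,
                 "F": np.nan, "Z": np.nan, "p": np.nan})
    rows.append({"df": m - 1, "SS": ss_total, "MS": np.nan, "Rsq": np.nan,
                 "F": np.nan, "Z": np.nan, "p": np.nan})
    index = list(model.terms) + ["Residuals", "Total"]
    return RRPPTable(pd.DataFrame(rows, index=index))


def _perm_batches(n_perm: int, m: int, rng: np.random.Generator,
                  batch: int = 512):
    """Yield batches of permutation index arrays; the first row is identity."""
    done = 0
    first = True
    while done < n_perm:
        b = min(batch, n_perm - done)
        idx = np.empty((b, m), dtype=np.intp)
        start = 0
        if first:
            idx[0] = np.arange(m)
            start = 1
            first = False
        for j in range(start, b):
            idx[j] = rng.permutation(m)
        done += b
        yield idx


def rrpp_test(model: ModelSpec) -> RRPPTable:
    """Add permutation p values and effect sizes Z to the sequential fit.

    For term k the reduced model holds terms 1..k-1; reduced-model residuals
    are permuted across specimen rows (the same permutations for every term
    within an iteration) and the term SS and full-model residual SS are
    recomputed.  The observed arrangement counts as one iteration, so the
    smallest attainable p is 1 / n_perm.  Z is computed on the log-F scale.
    """
    if model.n_perm < 100:
        warnings.warn("fewer than 100 permutations; p values are coarse",
                      stacklevel=2)
    base = fit_sequential(model)
    y = model.response
    m = len(y)
    bases, ranks = _nested_bases(model)
    df_terms = [ranks[i + 1] - ranks[i] for i in range(len(model.terms))]
    df_res = m - ranks[-1]
    q_full = bases[-1]

    rng = np.random.default_rng(model.seed)
    n_terms = len(model.terms)
    f_perm = [[] for _ in range(n_terms)]
    resid_red = [y - bases[k] @ (bases[k].T @ y) for k in range(n_terms)]
    e_ss = [float(np.sum(e ** 2)) for e in resid_red]

    for idx in _perm_batches(model.n_perm, m, rng):
        for k in range(n_terms):
            e = resid_red[k][idx]            # (b, m, q)
            a_red = np.einsum("mr,bmq->brq", bases[k], e)
            a_add = np.einsum("mr,bmq->brq", bases[k + 1], e)
            ss_red = np.sum(a_red ** 2, axis=(1, 2))
            ss_add = np.sum(a_add ** 2, axis=(1, 2))
            ss_term = ss_add - ss_red
            a_full = np.einsum("mr,bmq->brq", q_full, e)
            rss_full = e_ss[k] - np.sum(a_full ** 2, axis=(1, 2))
            f = (ss_term / df_terms[k]) / (rss_full / df_res)
            f_perm[k].append(f)

    table = base.table.copy()
    for k, term in enumerate(model.terms):
        f = np.concatenate(f_perm[k])
        f_obs = f[0]
        tol = 1e-12 * max(abs(f_obs), 1.0)
        p = float(np.mean(f >= f_obs - tol))
        logf = np.log(np.clip(f, 1e-300, None))
        sd = float(np.std(logf, ddof=1))
        z = float((logf[0] - np.mean(logf)) / sd) if sd > 0 else 0.0
        table.loc[term, "p"] = p
        table.loc[term, "Z"] = z
    return RRPPTable(table, n_perm=model.n_perm, seed=model.seed)


def size_anova(sizes: np.ndarray, host_id: np.ndarray,
               n_perm: int = 10_000, seed: int = 0) -> RRPPTable:
    """One-way RRPP ANOVA of centroid size on host identity."""
    model = ModelSpec(response=np.asarray(sizes, dtype=float),
                      terms=("host",), host=np.asarray(host_id),
                      n_perm=n_perm, seed=seed)
    return rrpp_test(model)


@dataclass
class DispersionResult:
    f: float
    p: float
    group_mean_distance: dict
    n_perm: int


def dispersion_test(coords: np.ndarray, groups: np.ndarray,
                    n_perm: int = 999, seed: int = 0) -> DispersionResult:
    """Permutational test of multivariate dispersion homogeneity.

    Each specimen's Euclidean distance to its group centroid (in tangent
    space) is computed; a one-way ANOVA F on these distances measures
    dispersion differences, and its null distribution is built by permuting
    group labels (group centroids and distances recomputed each time).  The
    observed labelling counts as one iteration.
    """
    x = np.asarray(coords, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    groups = np.asarray(groups)
    levels, gidx = np.unique(groups, return_inverse=True)
    counts = np.bincount(gidx)
    if len(levels) < 2:
        raise ValueError("need at least two groups")
    if np.any(counts < 2):
        raise ValueError("every group needs at least two members")
    m = len(x)
    g = len(levels)

    def anova_f(order: np.ndarray) -> tuple[float, np.ndarray]:
        xp = x[order]
        cent = np.add.reduceat(xp, np.concatenate([[0], np.cumsum(counts)[:-1]]), axis=0)
        cent = cent / counts[:, None]
        rep = np.repeat(np.arange(g), counts)
        d = np.sqrt(np.sum((xp - cent[rep]) ** 2, axis=1))
        means = np.add.reduceat(d, np.concatenate([[0], np.cumsum(counts)[:-1]])) / counts
        grand = d.mean()
        ss_b = float(np.sum(counts * (means - grand) ** 2))
        ss_w = float(np.sum((d - means[rep]) ** 2))
        if ss_w == 0:
            return np.inf, means
        f = (ss_b / (g - 1)) / (ss_w / (m - g))
        return f, means

    order0 = np.argsort(gidx, kind="stable")
    f_obs, means_obs = anova_f(order0)

    rng = np.random.default_rng(seed)
    count_ge = 1  # observed arrangement
    for _ in range(n_perm - 1):
        order = order0[rng.permutation(m)]
        # permuting specimens within the fixed group layout == permuting labels
        f_p, _ = anova_f(order)
        if f_p >= f_obs - 1e-12 * max(abs(f_obs), 1.0):
            count_ge += 1
    p = count_ge / n_perm
    group_mean = {lvl: float(mu) for lvl, mu in zip(levels, means_obs)}
    return DispersionResult(f=float(f_obs), p=float(p),
                            group_mean_distance=group_mean, n_perm=n_perm)
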