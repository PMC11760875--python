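"""Digitization quality control.

Repeatability (intraclass correlation per Procrustes coordinate),
percent measurement error from a Procrustes ANOVA over replicates, and
outlier screening by Procrustes distance from the mean shape.  All
replicates are superimposed in one joint GPA so that replicate placements
are compared in a common frame.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .procrustes import GPAResult, LandmarkDataset, gpa, tangent_projection

__all__ = ["QCReport", "OutlierRule", "icc_oneway", "repeatability",
           "measurement_error", "flag_outliers", "qc_report"]


def icc_oneway(values: np.ndarray) -> float:
    """Intraclass correlation of a balanced (m, r) one-way layout.

    Random-effects estimator: s2_among = (MS_among - MS_within) / r,
    truncated at zero; ICC = s2_among / (s2_among + MS_within).
    """
    y = np.asarray(values, dtype=float)
    if y.ndim != 2 or y.shape[1] < 2:
        raise ValueError("need an (m, r) array with r >= 2 replicates")
    m, r = y.shape
    means = y.mean(axis=1)
    grand = y.mean()
    ms_among = r * np.sum((means - grand) ** 2) / (m - 1)
    ms_within = np.sum((y - means[:, None]) ** 2) / (m * (r - 1))
    s2_among = max((ms_among - ms_within) / r, 0.0)
    denom = s2_among + ms_within
    return s2_among / denom if denom > 0 else 0.0


class OutlierRule(str, Enum):
    #: Tukey fence: flag distances above Q3 + 1.5 IQR (default)
    IQR_FENCE = "iqr_fence"
    #: flag every distance above the upper quartile (~25 % of specimens)
    LITERAL_UPPER_QUARTILE = "literal_upper_quartile"


@dataclass
class QCReport:
    rpt_per_coordinate: np.ndarray
    rpt_average: float
    pct_me: float
    outlier_ids: list
    distances_to_mean: np.ndarray


def _replicate_anova_ss(dataset: LandmarkDataset) -> tuple[np.ndarray, np.ndarray, int, int]:
    """Per-coordinate among/within-specimen SS from a joint superimposition.

    Returns (ss_among, ss_within) per tangent coordinate plus the specimen
    count and (balanced) replicate count.
    """
    m, r = dataset.n_specimens, dataset.n_replicates
    if r < 2:
        raise ValueError("repeatability requires at least two replicates")
    joint = gpa(dataset)
    t = tangent_projection(joint).reshape(m, r, -1)
    spec_mean = t.mean(axis=1)
    grand = t.mean(axis=(0, 1))
    ss_among = r * np.sum((spec_mean - grand) ** 2, axis=0)
    ss_within = np.sum((t - spec_mean[:, None]) ** 2, axis=(0, 1))
    return ss_among, ss_within, m, r


def repeatability(dataset: LandmarkDataset) -> tuple[np.ndarray, float]:
    """Intraclass correlation of each Procrustes coordinate over replicates.

    One-way random-effects ANOVA with specimen as the grouping factor:
    s2_among = (MS_among - MS_within) / r, truncated at zero, and
    ICC = s2_among / (s2_among + s2_within).  Returns the per-coordinate
    ICCs and their average.
    """
    m, r = dataset.n_specimens, dataset.n_replicates
    if r < 2:
        raise ValueError("repeatability requires at least two replicates")
    joint = gpa(dataset)
    t = tangent_projection(joint).reshape(m, r, -1)
    icc = np.array([icc_oneway(t[:, :, c]) for c in range(t.shape[2])])
    return icc, float(np.mean(icc))


def measurement_error(dataset: LandmarkDataset) -> float:
    """Percent measurement error from the pooled Procrustes ANOVA.

    All tangent coordinates are pooled into one variance decomposition:
    the among-specimen (biological) and within-specimen (replicate, i.e.
    landmark-placement imprecision) variance components are estimated and
    the within share is returned as a percentage of their sum.
    """
    ss_a, ss_w, m, r = _replicate_anova_ss(dataset)
    q = len(ss_a)
    ms_a = float(np.sum(ss_a)) / ((m - 1) * q)
    ms_w = float(np.sum(ss_w)) / (m * (r - 1) * q)
    s2_a = max((ms_a - ms_w) / r, 0.0)
    s2_w = ms_w
    if s2_a + s2_w == 0:
        return 0.0
    return 100.0 * s2_w / (s2_a + s2_w)


def flag_outliers(result: GPAResult,
                  rule: OutlierRule | str = OutlierRule.IQR_FENCE
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Screen aberrant configurations by distance from the mean shape.

    Distances are Procrustes chord distances of each aligned configuration
    to the consensus.  The default Tukey fence flags d > Q3 + 1.5 IQR; the
    literal upper-quartile rule flags everything above Q3 (roughly a quarter
    of the sample) and is kept for comparison with published practice.

    Returns ``(outlier_indices, distances)``.
    """
    rule = OutlierRule(rule)
    diff = result.aligned - result.consensus[None]
    d = np.sqrt(np.sum(diff ** 2, axis=(1, 2)))
    q1, q3 = np.percentile(d, [25, 75])
    if rule is OutlierRule.IQR_FENCE:
        cut = q3 + 1.5 * (q3 - q1)
    else:
        cut = q3
    return np.flatnonzero(d > cut), d


def qc_report(dataset: LandmarkDataset,
              rule: OutlierRule | str = OutlierRule.IQR_FENCE) -> QCReport:
    """Full quality-control report for a replicated landmark dataset."""
    icc, icc_avg = repeatability(dataset)
    pct_me = measurement_error(dataset)
    result = gpa(dataset.replicate_mean())
    idx, d = flag_outliers(result, rule)
    ids = [dataset.specimen_id[i] for i in idx]
    return QCReport(rpt_per_coordinate=icc, rpt_average=icc_avg,
                    pct_me=pct_me, outlier_ids=ids, distances_to_mean=d)
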