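"""Screening-oriented model evaluation.

Implements the evaluation currency of cfDNA screening studies:

* AUC as the Mann-Whitney pair-winning probability (ties count 1/2), with
  DeLong structural-component variance, normal 95% CIs, and the paired
  DeLong test for correlated AUCs;
* Youden-index threshold selection (J = sensitivity + specificity - 1)
  on validation scores;
* sensitivity/specificity with Wald (optionally Wilson) confidence
  intervals, overall and per clinical subgroup, plus confusion matrices;
* single-marker threshold classifiers for head-to-head comparison with
  the multivariate models;
* baseline-comparability statistics: Pearson chi-square on contingency
  tables and the Kruskal-Wallis rank test.

The positive-call convention is uniform: score >= threshold => positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


def _validate_scores_labels(scores, labels):
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    if scores.shape != y.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be 1-D and aligned")
    if set(np.unique(y)) - {0, 1}:
        raise ValueError("labels must be binary 0/1")
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("both classes must be present")
    return scores, y


def auc(scores, labels) -> float:
    """Probability a random case outscores a random control (ties 1/2).

    Computed from midranks, which is exactly the Mann-Whitney U statistic
    scaled to [0, 1].
    """
    scores, y = _validate_scores_labels(scores, labels)
    n1 = int(y.sum())
    n0 = len(y) - n1
    ranks = stats.rankdata(scores)
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2) / (n0 * n1))


@dataclass
class RocCurve:
    """Operating points of the score >= threshold rule.

    Thresholds ascend and include -inf/+inf sentinels, so the curve always
    contains (sensitivity 1, specificity 0) and (sensitivity 0,
    specificity 1).
    """

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray


def roc_curve_points(scores, labels) -> RocCurve:
    scores, y = _validate_scores_labels(scores, labels)
    pos = scores[y == 1]
    neg = scores[y == 0]
    uniq = np.unique(scores)
    thresholds = np.concatenate(([-np.inf], uniq, [np.inf]))
    sens = np.array([(pos >= t).mean() for t in thresholds])
    spec = np.array([(neg < t).mean() for t in thresholds])
    return RocCurve(thresholds=thresholds, sensitivity=sens, specificity=spec)


def trapezoidal_auc(curve: RocCurve) -> float:
    """Area under the ROC polygon (sens vs 1 - spec)."""
    # integrate in threshold order: consecutive operating points are
    # adjacent on the staircase (tied scores give diagonal segments whose
    # trapezoids reproduce the half-credit tie convention)
    fpr = 1.0 - curve.specificity
    return float(abs(np.trapezoid(curve.sensitivity, fpr)))


def _delong_placements(scores, y):
    """Per-case and per-control placement values (DeLong structural
    components), computed with midranks."""
    pos = scores[y == 1]
    neg = scores[y == 0]
    m, n = len(pos), len(neg)
    all_ranks = stats.rankdata(np.concatenate([pos, neg]))
    pos_ranks = stats.rankdata(pos)
    neg_ranks = stats.rankdata(neg)
    v01 = (all_ranks[:m] - pos_ranks) / n  # placement of each case
    v10 = 1.0 - (all_ranks[m:] - neg_ranks) / m  # placement of each control
    return v01, v10


@dataclass
class AucEstimate:
    auc: float
    variance: float
    ci_lower: float
    ci_upper: float
    level: float = 0.95
    degenerate: bool = False  # zero variance with AUC strictly inside (0,1)


def delong_ci(scores, labels, level: float = 0.95) -> AucEstimate:
    """AUC with DeLong variance and a normal-approximation CI.

    The CI is clipped to [0, 1]; perfect separation gives variance 0 and a
    point CI.  Zero variance with an AUC strictly inside (0, 1) (all
    placements tied) is flagged ``degenerate``.
    """
    scores, y = _validate_scores_labels(scores, labels)
    m = int(y.sum())
    n = len(y) - m
    if m < 2 or n < 2:
        raise ValueError("need >= 2 samples per class for a DeLong CI")
    v01, v10 = _delong_placements(scores, y)
    estimate = float(v01.mean())
    variance = float(np.var(v01, ddof=1) / m + np.var(v10, ddof=1) / n)
    z = stats.norm.ppf(0.5 + level / 2)
    half = z * np.sqrt(variance)
    return AucEstimate(
        auc=estimate,
        variance=variance,
        ci_lower=float(np.clip(estimate - half, 0.0, 1.0)),
        ci_upper=float(np.clip(estimate + half, 0.0, 1.0)),
        level=level,
        degenerate=bool(variance == 0.0 and 0.0 < estimate < 1.0),
    )


@dataclass
class DeLongComparison:
    auc_a: float
    auc_b: float
    delta: float
    z: float
    p: float


def delong_paired_test(scores_a, scores_b, labels) -> DeLongComparison:
    """Paired DeLong test of two correlated AUCs over the same samples.

    The variance of the AUC difference uses the covariance of the shared
    structural components.  A degenerate zero-variance difference is
    reported as p = 1 when the AUCs are equal (e.g. a model against
    itself) and is an error otherwise.
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    if scores_a.shape != scores_b.shape:
        raise ValueError("paired score vectors must have identical shape")
    _, y = _validate_scores_labels(scores_a, labels)
    m = int(y.sum())
    n = len(y) - m
    va01, va10 = _delong_placements(scores_a, y)
    vb01, vb10 = _delong_placements(scores_b, y)
    auc_a = float(va01.mean())
    auc_b = float(vb01.mean())
    delta = auc_a - auc_b
    d01 = va01 - vb01
    d10 = va10 - vb10
    var = float(np.var(d01, ddof=1) / m + np.var(d10, ddof=1) / n)
    if var <= 0.0:
        if delta == 0.0:
            return DeLongComparison(auc_a, auc_b, 0.0, 0.0, 1.0)
        raise ValueError("zero variance of the AUC difference with nonzero delta")
    z = delta / np.sqrt(var)
    p = float(2 * stats.norm.sf(abs(z)))
    return DeLongComparison(auc_a, auc_b, delta, float(z), p)


def youden_threshold(scores, labels) -> tuple[float, float]:
    """Threshold maximising J = sensitivity + specificity - 1.

    Candidate cuts are midpoints between adjacent distinct sorted scores
    plus -inf/+inf sentinels.  Ties in J are broken toward higher
    sensitivity (screening favours not missing cases), then toward the
    lower threshold.  Returns (threshold, J).
    """
    scores, y = _validate_scores_labels(scores, labels)
    pos = scores[y == 1]
    neg = scores[y == 0]
    uniq = np.unique(scores)
    candidates = np.concatenate(([-np.inf], (uniq[:-1] + uniq[1:]) / 2, [np.inf]))
    best = None
    for t in candidates:
        sens = float((pos >= t).mean())
        spec = float((neg < t).mean())
        j = sens + spec - 1.0
        key = (j, sens, -t)
        if best is None or key > best[0]:
            best = (key, t, j)
    return float(best[1]), float(best[2])


# ---------------------------------------------------------------------------
# proportions and screening reports


def proportion_ci(
    k: int, n: int, level: float = 0.95, method: str = "wald"
) -> tuple[float, float]:
    """Binomial proportion CI on [0, 1], clipped.

    Wald (normal approximation, the default reporting choice here) or
    Wilson score by flag.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    p = k / n
    z = stats.norm.ppf(0.5 + level / 2)
    if method == "wald":
        half = z * np.sqrt(p * (1 - p) / n)
        lo, hi = p - half, p + half
    elif method == "wilson":
        denom = 1 + z**2 / n
        centre = (p + z**2 / (2 * n)) / denom
        half = z * np.sqrt(p * (1 - p) / n + z**2 / (4 * n**2)) / denom
        lo, hi = centre - half, centre + half
    else:
        raise ValueError(f"unknown CI method {method!r}")
    return float(np.clip(lo, 0.0, 1.0)), float(np.clip(hi, 0.0, 1.0))


@dataclass
class ProportionEstimate:
    numerator: int
    denominator: int
    percent: float
    ci_lower_percent: float
    ci_upper_percent: float


def _proportion(k: int, n: int, level: float, method: str) -> ProportionEstimate:
    lo, hi = proportion_ci(k, n, level=level, method=method)
    return ProportionEstimate(k, n, 100.0 * k / n, 100.0 * lo, 100.0 * hi)


@dataclass
class ScreeningReport:
    """Operating-point metrics of a screening rule at a fixed threshold."""

    threshold: float
    sensitivity: ProportionEstimate
    specificity: ProportionEstimate
    subgroup_sensitivity: dict = field(default_factory=dict)
    confusion: dict = field(default_factory=dict)  # tp/fp/fn/tn
    notes: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("overall_sensitivity", self.sensitivity),
            ("specificity", self.specificity),
        ] + [(f"sensitivity_{k}", v) for k, v in self.subgroup_sensitivity.items()]
        return pd.DataFrame(
            {
                "metric": [r[0] for r in rows],
                "numerator": [r[1].numerator for r in rows],
                "denominator": [r[1].denominator for r in rows],
                "percent": [r[1].percent for r in rows],
                "ci_lower": [r[1].ci_lower_percent for r in rows],
                "ci_upper": [r[1].ci_upper_percent for r in rows],
            }
        )


def screening_metrics(
    scores,
    meta: pd.DataFrame,
    threshold: float,
    level: float = 0.95,
    ci_method: str = "wald",
) -> ScreeningReport:
    """Sensitivity/specificity report at a fixed threshold.

    Cases are ESPL and ESCC samples (``group != control``); positive call
    iff score >= threshold.  Per-subgroup sensitivities cover the case
    subgroups present; empty subgroups are noted, never reported as NaN.
    """
    scores = np.asarray(scores, dtype=float)
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite for screening reports")
    if len(scores) != len(meta):
        raise ValueError("metadata must cover all scored samples")
    is_case = (meta["group"] != "control").to_numpy()
    calls = scores >= threshold
    tp = int((calls & is_case).sum())
    fn = int((~calls & is_case).sum())
    fp = int((calls & ~is_case).sum())
    tn = int((~calls & ~is_case).sum())
    report = ScreeningReport(
        threshold=float(threshold),
        sensitivity=_proportion(tp, tp + fn, level, ci_method),
        specificity=_proportion(tn, tn + fp, level, ci_method),
        confusion={"tp": tp, "fp": fp, "fn": fn, "tn": tn},
    )
    for subgroup in meta.loc[is_case, "subgroup"].unique():
        mask = (meta["subgroup"] == subgroup).to_numpy()
        n = int(mask.sum())
        if n == 0:
            report.notes.append(f"subgroup {subgroup}: empty, omitted")
            continue
        k = int((calls & mask).sum())
        report.subgroup_sensitivity[subgroup] = _proportion(k, n, level, ci_method)
    return report


def marker_threshold_classifier(
    values,
    meta: pd.DataFrame,
    threshold: float,
    direction: str = "high_is_positive",
    level: float = 0.95,
    ci_method: str = "wald",
) -> tuple[np.ndarray, ScreeningReport]:
    """Single-marker rule: positive iff value >= threshold (or <= when
    ``low_is_positive``).  Missing values exclude the sample, with the
    exclusion count noted.  Returns (calls over retained samples, report).
    """
    if direction not in ("high_is_positive", "low_is_positive"):
        raise ValueError(f"unknown direction {direction!r}")
    values = np.asarray(values, dtype=float)
    keep = np.isfinite(values)
    n_missing = int((~keep).sum())
    values = values[keep]
    meta = meta.loc[keep]
    oriented = values if direction == "high_is_positive" else -values
    t = threshold if direction == "high_is_positive" else -threshold
    report = screening_metrics(oriented, meta, t, level=level, ci_method=ci_method)
    report.threshold = float(threshold)
    if n_missing:
        report.notes.append(f"{n_missing} sample(s) excluded for missing values")
    calls = oriented >= t
    return calls, report


# ---------------------------------------------------------------------------
# baseline-comparability statistics


def chisq_independence(table, correction: bool = False) -> tuple[float, int, float]:
    """Pearson chi-square test of independence on a contingency table.

    Yates continuity correction is available for 2x2 tables only; larger
    tables always use the uncorrected statistic.  Returns (chi2, df, p).
    """
    table = np.asarray(table)
    if table.ndim != 2 or table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("need a table with >= 2 rows and >= 2 columns")
    if np.any(table < 0) or not np.issubdtype(table.dtype, np.number):
        raise ValueError("counts must be nonnegative numbers")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("zero row/column margin")
    if correction and table.shape != (2, 2):
        raise ValueError("continuity correction applies to 2x2 tables only")
    res = stats.chi2_contingency(table, correction=correction)
    return float(res.statistic), int(res.dof), float(res.pvalue)


def kruskal_wallis(values, groups) -> tuple[float, float]:
    """Kruskal-Wallis rank test across >= 2 groups (tie-corrected H,
    chi-square p with df = k-1).  All-identical values give H = 0, p = 1."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if len(labels) < 2:
        raise ValueError("need >= 2 groups")
    samples = [values[groups == g] for g in labels]
    if any(len(s) == 0 for s in samples):
        raise ValueError("each group must be nonempty")
    if np.all(values == values[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*samples)
    return float(h), float(p)
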