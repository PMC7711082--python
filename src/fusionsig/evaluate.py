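"""Evaluation of signature scores against clinical annotations.

Covers the analysis surfaces used to validate a fusion signature:

* group comparison of scores between fusion groups (Wilcoxon rank-sum),
* fusion-status / binary-outcome classification (ROC, AUC by pair
  counting),
* median-split survival stratification (Kaplan-Meier + log-rank),
* Spearman correlation of the score with continuous covariates
  (e.g. ERG expression, leukocyte fraction).

``evaluate_cohort`` composes these per configurable stratum (all
samples, fusion-positive only, Gleason-7 only, ...) into one
JSON-serializable report.  All p-values are two-sided and unadjusted.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats as sps

from .iokit import ValidationError

logger = logging.getLogger("fusionsig")

#: Exact Wilcoxon enumeration is used up to this combined sample size
#: (and only without ties); beyond it, the normal approximation with tie
#: correction applies.
EXACT_WILCOXON_MAX_N = 12


@dataclasses.dataclass(frozen=True)
class GroupComparison:
    """Two-group rank-sum contrast."""

    group_labels: tuple[str, str]
    n: tuple[int, int]
    medians: tuple[float, float]
    statistic: float  # Mann-Whitney U of the first group
    p_value: float
    method: str


@dataclasses.dataclass(frozen=True)
class ClassificationResult:
    """ROC curve and pair-counting AUC."""

    auc: float
    fpr: tuple[float, ...]
    tpr: tuple[float, ...]
    n_positive: int
    n_negative: int


@dataclasses.dataclass(frozen=True)
class KMCurve:
    """One Kaplan-Meier product-limit curve."""

    times: tuple[float, ...]
    survival: tuple[float, ...]
    at_risk: tuple[int, ...]


@dataclasses.dataclass(frozen=True)
class SurvivalStratification:
    """Median-split (or other-quantile) log-rank comparison."""

    threshold: float
    groups: pd.Series  # "high"/"low" per sample
    chi_square: float
    p_value: float
    curves: dict  # group -> KMCurve
    degenerate: bool
    n: tuple[int, int]  # (n_low, n_high)


def _exact_mannwhitney(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney p via the null count distribution.

    Valid only without ties: pooled ranks are the integers 1..n and the
    U statistic is integer-valued.  A subset-sum dynamic program counts,
    for every achievable rank sum, how many of the C(n, n_x) equally
    likely label assignments produce it; the two-sided p-value is
    ``min(1, 2 * min(P(U <= u), P(U >= u)))`` computed from those
    integer counts, so it is identical to explicit enumeration.
    """
    nx, n = x.size, x.size + y.size
    ranks = sps.rankdata(np.concatenate([x, y]))
    ranksum = int(round(ranks[:nx].sum()))
    u_obs = ranksum - nx * (nx + 1) // 2
    # counts[k][s] = number of k-subsets of {1..i} with rank sum s
    max_sum = n * (n + 1) // 2
    counts = [[0] * (max_sum + 1) for _ in range(nx + 1)]
    counts[0][0] = 1
    for rank in range(1, n + 1):
        for k in range(min(rank, nx), 0, -1):
            row, prev = counts[k], counts[k - 1]
            for s in range(max_sum, rank - 1, -1):
                if prev[s - rank]:
                    row[s] += prev[s - rank]
    dist = counts[nx]
    total = sum(dist)
    c_le = sum(dist[: ranksum + 1])
    c_ge = sum(dist[ranksum:])
    p = min(1.0, 2 * (min(c_le, c_ge) / total))
    return float(u_obs), p


def wilcoxon_rank_sum(
    x: Sequence[float],
    y: Sequence[float],
    labels: tuple[str, str] = ("x", "y"),
) -> GroupComparison:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) comparison.

    Exact null enumeration when the combined n is at most 12 and the
    pooled values carry no ties; otherwise the normal approximation with
    tie correction (no continuity correction, so identical groups give
    p = 1).
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    no_ties = np.unique(pooled).size == pooled.size
    if x.size + y.size <= EXACT_WILCOXON_MAX_N and no_ties:
        method = "exact"
        u, p = _exact_mannwhitney(x, y)
    else:
        method = "normal-approximation"
        res = sps.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=False
        )
        u, p = float(res.statistic), float(min(res.pvalue, 1.0))
    return GroupComparison(
        group_labels=labels,
        n=(int(x.size), int(y.size)),
        medians=(float(np.median(x)), float(np.median(y))),
        statistic=u,
        p_value=p,
        method=method,
    )


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> ClassificationResult:
    """AUC by pair counting with the ROC curve from a score sweep.

    The AUC equals the Mann-Whitney U statistic of the positive class
    divided by n_pos * n_neg; tied score pairs count 1/2.  The curve is
    traced by sweeping thresholds over distinct scores.
    """
    s = np.asarray(list(scores), dtype=float)
    yl = np.asarray(list(labels), dtype=int)
    if not np.isin(yl, (0, 1)).all():
        raise ValidationError("labels must be binary 0/1")
    n_pos = int((yl == 1).sum())
    n_neg = int((yl == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("both classes must be present")
    ranks = sps.rankdata(s)  # average ranks handle ties as half-wins
    u_pos = float(ranks[yl == 1].sum() - n_pos * (n_pos + 1) / 2.0)
    auc = u_pos / (n_pos * n_neg)

    # threshold sweep, descending scores; prepend the (0,0) corner
    order = np.argsort(-s, kind="mergesort")
    sorted_y = yl[order]
    sorted_s = s[order]
    distinct = np.r_[np.flatnonzero(np.diff(sorted_s)), sorted_y.size - 1]
    tps = np.cumsum(sorted_y)[distinct]
    fps = distinct + 1 - tps
    fpr = np.r_[0.0, fps / n_neg]
    tpr = np.r_[0.0, tps / n_pos]
    return ClassificationResult(
        auc=float(auc),
        fpr=tuple(float(v) for v in fpr),
        tpr=tuple(float(v) for v in tpr),
        n_positive=n_pos,
        n_negative=n_neg,
    )


def median_split(scores: pd.Series, quantile: float = 0.5) -> tuple[pd.Series, float]:
    """Assign samples to low/high groups at a score quantile.

    Samples with score <= threshold go to ``low``, the rest to ``high``
    (the tie-at-threshold rule is fixed to the low side for determinism).
    Returns the assignment and the threshold used.
    """
    s = scores.astype(float)
    if s.size < 2:
        raise ValidationError("need at least 2 samples to split")
    threshold = float(s.quantile(quantile))
    groups = pd.Series(np.where(s <= threshold, "low", "high"), index=s.index, name="group")
    return groups, threshold


def _km_curve(time: np.ndarray, event: np.ndarray) -> KMCurve:
    kmf = KaplanMeierFitter()
    kmf.fit(time, event_observed=event)
    table = kmf.event_table
    times = table.index.to_numpy(dtype=float)
    surv = kmf.survival_function_["KM_estimate"].to_numpy(dtype=float)
    at_risk = table["at_risk"].to_numpy(dtype=int)
    return KMCurve(
        times=tuple(float(t) for t in times),
        survival=tuple(float(v) for v in surv),
        at_risk=tuple(int(v) for v in at_risk),
    )


def km_logrank(
    groups: pd.Series,
    time: pd.Series,
    event: pd.Series,
    threshold: float = float("nan"),
) -> SurvivalStratification:
    """Two-group Kaplan-Meier curves and the log-rank test.

    The chi-square statistic (1 df) uses the standard
    observed-minus-expected sums over distinct event times with
    hypergeometric variances.  If neither group contributes any event,
    the statistic is undefined and the result is flagged degenerate
    (chi-square 0, p 1).
    """
    groups = groups.astype(str)
    t = time.astype(float)
    e = event.astype(int)
    if not set(groups.unique()) <= {"low", "high"}:
        raise ValidationError("groups must be labeled 'low'/'high'")
    if (t < 0).any():
        raise ValidationError("negative survival time")
    low = groups == "low"
    high = groups == "high"
    if low.sum() == 0 or high.sum() == 0:
        raise ValidationError("both groups must contain at least one sample")
    curves = {
        "low": _km_curve(t[low].to_numpy(), e[low].to_numpy()),
        "high": _km_curve(t[high].to_numpy(), e[high].to_numpy()),
    }
    degenerate = e[low].sum() == 0 or e[high].sum() == 0
    if e.sum() == 0:
        return SurvivalStratification(
            threshold=threshold,
            groups=groups,
            chi_square=0.0,
            p_value=1.0,
            curves=curves,
            degenerate=True,
            n=(int(low.sum()), int(high.sum())),
        )
    res = logrank_test(
        t[low].to_numpy(), t[high].to_numpy(), e[low].to_numpy(), e[high].to_numpy()
    )
    return SurvivalStratification(
        threshold=threshold,
        groups=groups,
        chi_square=float(res.test_statistic),
        p_value=float(res.p_value),
        curves=curves,
        degenerate=bool(degenerate),
        n=(int(low.sum()), int(high.sum())),
    )


def spearman_corr(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rho (average ranks on ties) with t-approximation p-value.

    Returns ``(rho, p_value)``; raises on zero variance in either input.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size != y.size:
        raise ValidationError("inputs must be aligned")
    if x.size < 3:
        raise ValidationError("need at least 3 pairs")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        raise ValidationError("zero variance input; correlation undefined")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)


# ---------------------------------------------------------------------------
# Cohort-level report
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class EvaluationConfig:
    """Settings for :func:`evaluate_cohort`.

    ``strata`` maps a stratum name to column->value filters applied to
    the clinical table (empty dict = all samples).  ``binary_outcomes``
    names 0/1 clinical columns to classify from the score (e.g. a
    lethal-vs-indolent indicator); ``continuous_covariates`` names
    numeric columns to correlate with the score; ``split_quantile`` sets
    the survival-split threshold (0.5 = median).
    """

    strata: Mapping[str, Mapping[str, object]] = dataclasses.field(
        default_factory=lambda: {
            "all": {},
            "fusion_positive": {"fusion_status": "positive"},
            "fusion_negative": {"fusion_status": "negative"},
            "gleason7": {"gleason": 7},
        }
    )
    binary_outcomes: tuple[str, ...] = ()
    continuous_covariates: tuple[str, ...] = ()
    split_quantile: float = 0.5


def _apply_filters(clinical: pd.DataFrame, filters: Mapping[str, object]) -> pd.Series:
    mask = pd.Series(True, index=clinical.index)
    for column, value in filters.items():
        if column not in clinical.columns:
            raise ValidationError(f"stratum filter references unknown column {column!r}")
        mask &= clinical[column] == value
    return mask


def evaluate_cohort(
    scores: pd.Series,
    clinical: pd.DataFrame,
    config: EvaluationConfig | None = None,
) -> dict:
    """Run the full evaluation battery per stratum; return a JSON-able report.

    Per stratum: score-by-fusion-status Wilcoxon comparison (positive vs
    negative, plus erg_other-vs-negative when present), fusion ROC/AUC,
    ROC/AUC for each configured binary outcome, median-split Kaplan-Meier
    log-rank, and Spearman correlation of the score against each
    configured continuous covariate.  Strata that are empty or
    single-class are recorded as skipped with the reason.
    """
    config = config or EvaluationConfig()
    missing = [s for s in scores.index if s not in clinical.index]
    if missing:
        raise ValidationError(f"clinical table missing scored sample(s): {missing[:5]}")
    clinical = clinical.loc[scores.index]

    report: dict = {"n_samples": int(scores.size), "strata": {}}
    for name, filters in config.strata.items():
        mask = _apply_filters(clinical, filters)
        sub = clinical.loc[mask]
        sub_scores = scores.loc[mask]
        entry: dict = {"n": int(mask.sum()), "filters": dict(filters)}
        if mask.sum() == 0:
            entry["skipped"] = "stratum is empty"
            report["strata"][name] = entry
            continue

        entry["fusion_comparison"] = _fusion_comparisons(sub_scores, sub)
        entry["fusion_classification"] = _fusion_auc(sub_scores, sub)
        entry["outcome_classification"] = {}
        for col in config.binary_outcomes:
            entry["outcome_classification"][col] = _binary_auc(sub_scores, sub, col)
        entry["survival"] = _survival(sub_scores, sub, config.split_quantile)
        entry["correlations"] = {}
        for col in config.continuous_covariates:
            entry["correlations"][col] = _correlation(sub_scores, sub, col)
        report["strata"][name] = entry
    return report


def _fusion_comparisons(scores: pd.Series, clinical: pd.DataFrame) -> dict:
    out: dict = {}
    status = clinical["fusion_status"]
    pos = scores[status == "positive"]
    neg = scores[status == "negative"]
    other = scores[status == "erg_other"]
    if pos.size and neg.size:
        cmp = wilcoxon_rank_sum(pos, neg, labels=("positive", "negative"))
        out["positive_vs_negative"] = _comparison_dict(cmp)
    else:
        out["positive_vs_negative"] = {"skipped": "needs both fusion classes"}
    if other.size and neg.size:
        cmp = wilcoxon_rank_sum(other, neg, labels=("erg_other", "negative"))
        out["erg_other_vs_negative"] = _comparison_dict(cmp)
    return out


def _comparison_dict(cmp: GroupComparison) -> dict:
    return {
        "groups": list(cmp.group_labels),
        "n": list(cmp.n),
        "medians": list(cmp.medians),
        "U": cmp.statistic,
        "p_value": cmp.p_value,
        "method": cmp.method,
    }


def _fusion_auc(scores: pd.Series, clinical: pd.DataFrame) -> dict:
    labels = (clinical["fusion_status"] == "positive").astype(int)
    if labels.nunique() < 2:
        return {"skipped": "single fusion class in stratum"}
    res = roc_auc(scores, labels)
    return {"auc": res.auc, "n_positive": res.n_positive, "n_negative": res.n_negative}


def _binary_auc(scores: pd.Series, clinical: pd.DataFrame, column: str) -> dict:
    if column not in clinical.columns:
        return {"skipped": f"no column {column!r}"}
    y = clinical[column].dropna()
    s = scores.loc[y.index]
    if y.nunique() < 2:
        return {"skipped": "single outcome class in stratum"}
    res = roc_auc(s, y.astype(int))
    return {"auc": res.auc, "n_positive": res.n_positive, "n_negative": res.n_negative}


def _survival(scores: pd.Series, clinical: pd.DataFrame, quantile: float) -> dict:
    has_surv = clinical[["time", "event"]].notna().all(axis=1)
    sub = clinical.loc[has_surv]
    s = scores.loc[has_surv]
    if s.size < 2:
        return {"skipped": "fewer than 2 samples with survival data"}
    groups, threshold = median_split(s, quantile)
    if groups.nunique() < 2:
        return {"skipped": "all scores on one side of the threshold"}
    strat = km_logrank(groups, sub["time"], sub["event"], threshold=threshold)
    # signed direction: positive means the high-score group has more
    # events per at-risk time (worse prognosis)
    high = groups == "high"
    rate_high = sub.loc[high, "event"].sum() / max(sub.loc[high, "time"].sum(), 1e-300)
    rate_low = sub.loc[~high, "event"].sum() / max(sub.loc[~high, "time"].sum(), 1e-300)
    return {
        "threshold": strat.threshold,
        "n_low": strat.n[0],
        "n_high": strat.n[1],
        "chi_square": strat.chi_square,
        "p_value": strat.p_value,
        "degenerate": strat.degenerate,
        "high_score_worse": bool(rate_high > rate_low),
    }


def _correlation(scores: pd.Series, clinical: pd.DataFrame, column: str) -> dict:
    if column not in clinical.columns:
        return {"skipped": f"no column {column!r}"}
    y = clinical[column].dropna().astype(float)
    s = scores.loc[y.index]
    if s.size < 3:
        return {"skipped": "fewer than 3 pairs"}
    try:
        rho, p = spearman_corr(s, y)
    except ValidationError as exc:
        return {"skipped": str(exc)}
    return {"rho": rho, "p_value": p, "n": int(s.size)}
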