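"""Statistical evaluation: rank-sum, ROC/AUC, survival split, correlation."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

from fusionsig import (
    EvaluationConfig,
    SimulationParams,
    ValidationError,
    evaluate_cohort,
    km_logrank,
    median_split,
    roc_auc,
    simulate_cohort,
    spearman_corr,
    truth_signature,
    wilcoxon_rank_sum,
)
from fusionsig.score import score_samples


# -- Wilcoxon rank-sum -------------------------------------------------------


def enum_wilcoxon_two_sided(x, y):
    """Enumerate all label assignments of the pooled sample (exact oracle)."""
    pooled = np.r_[x, y]
    nx = len(x)
    ranks = rankdata(pooled)
    u_obs = ranks[:nx].sum() - nx * (nx + 1) / 2
    us = np.array([
        ranks[list(c)].sum() - nx * (nx + 1) / 2
        for c in itertools.combinations(range(len(pooled)), nx)
    ])
    return min(1.0, 2 * min((us <= u_obs).mean(), (us >= u_obs).mean()))


def test_identical_groups_p_is_one():
    cmp = wilcoxon_rank_sum([1, 2, 3], [1, 2, 3])
    assert cmp.p_value == 1.0


def test_exact_small_sample():
    cmp = wilcoxon_rank_sum([1, 2], [10, 20])
    assert cmp.method == "exact"
    assert cmp.p_value == pytest.approx(1.0 / 3.0)


def test_exact_matches_enumeration_oracle():
    rng = np.random.default_rng(12)
    for _ in range(60):
        nx = int(rng.integers(2, 6))
        ny = int(rng.integers(2, 6))
        vals = rng.permutation(50)[: nx + ny].astype(float)
        x, y = vals[:nx], vals[nx:]
        cmp = wilcoxon_rank_sum(x, y)
        assert cmp.method == "exact"
        assert cmp.p_value == enum_wilcoxon_two_sided(x, y)


def test_normal_approximation_close_to_exact():
    """Beyond the exact regime the approximation should track enumeration."""
    rng = np.random.default_rng(13)
    for _ in range(20):
        vals = rng.normal(0, 1, 14)
        x, y = vals[:7], vals[7:]
        cmp = wilcoxon_rank_sum(x, y)
        assert cmp.method == "normal-approximation"
        assert abs(cmp.p_value - enum_wilcoxon_two_sided(x, y)) < 0.08


def test_empty_group_errors():
    with pytest.raises(ValidationError, match="non-empty"):
        wilcoxon_rank_sum([], [1.0])


# -- ROC / AUC ---------------------------------------------------------------


def pair_counting_auc(scores, labels):
    s = np.asarray(scores, float)
    y = np.asarray(labels, int)
    wins = 0.0
    pairs = 0
    for i in np.flatnonzero(y == 1):
        for j in np.flatnonzero(y == 0):
            pairs += 1
            if s[i] > s[j]:
                wins += 1.0
            elif s[i] == s[j]:
                wins += 0.5
    return wins / pairs


@pytest.mark.parametrize(
    "scores,labels,expected",
    [
        ((1, 2, 3, 4), (0, 0, 1, 1), 1.0),
        ((5, 5, 5, 5), (0, 1, 0, 1), 0.5),
        ((3, 1, 2, 4), (0, 0, 1, 1), 0.75),
    ],
)
def test_auc_examples(scores, labels, expected):
    assert roc_auc(scores, labels).auc == pytest.approx(expected)


def test_auc_matches_pair_counting_oracle():
    rng = np.random.default_rng(14)
    for _ in range(40):
        n = int(rng.integers(4, 31))
        scores = np.round(rng.normal(0, 1, n), 1)  # rounding creates ties
        labels = rng.integers(0, 2, n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        res = roc_auc(scores, labels)
        assert res.auc == pytest.approx(pair_counting_auc(scores, labels), abs=1e-12)
        # trapezoidal area under the swept curve equals the pair-count AUC
        assert np.trapezoid(res.tpr, res.fpr) == pytest.approx(res.auc, abs=1e-12)
        # curve is monotone in both coordinates
        assert np.all(np.diff(res.fpr) >= 0) and np.all(np.diff(res.tpr) >= 0)


def test_auc_complement_for_tie_free_scores():
    rng = np.random.default_rng(15)
    scores = rng.permutation(20).astype(float)
    labels = rng.integers(0, 2, 20)
    labels[:2] = [0, 1]
    a = roc_auc(scores, labels).auc
    b = roc_auc(-scores, labels).auc
    assert a + b == pytest.approx(1.0)


def test_auc_single_class_errors():
    with pytest.raises(ValidationError, match="both classes"):
        roc_auc([1.0, 2.0], [1, 1])


# -- median split ------------------------------------------------------------


def test_median_split_even():
    s = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
    groups, thr = median_split(s)
    assert thr == 2.5
    assert groups.tolist() == ["low", "low", "high", "high"]


def test_median_split_tie_at_median_goes_low():
    s = pd.Series([1.0, 2.0, 2.0, 3.0], index=list("abcd"))
    groups, thr = median_split(s)
    assert thr == 2.0
    assert groups.tolist() == ["low", "low", "low", "high"]


def test_median_split_odd():
    s = pd.Series([1.0, 2.0, 3.0], index=list("abc"))
    groups, _ = median_split(s)
    assert groups.tolist() == ["low", "low", "high"]


# -- Kaplan-Meier / log-rank -------------------------------------------------


def _strat(times_a, events_a, times_b, events_b):
    n = len(times_a) + len(times_b)
    groups = pd.Series(["low"] * len(times_a) + ["high"] * len(times_b))
    time = pd.Series(list(times_a) + list(times_b))
    event = pd.Series(list(events_a) + list(events_b))
    return km_logrank(groups, time, event)


def test_identical_groups_chi_square_zero():
    res = _strat([1, 2, 3], [1, 1, 0], [1, 2, 3], [1, 1, 0])
    assert res.chi_square == pytest.approx(0.0, abs=1e-12)
    assert res.p_value == pytest.approx(1.0)


def test_four_sample_hand_computed_chi_square():
    """O_A=2, E_A=5/6, Var=17/36 at event times 1..4 => chi2 = 49/17."""
    res = _strat([1, 2], [1, 1], [3, 4], [1, 1])
    assert res.chi_square == pytest.approx(49.0 / 17.0, abs=1e-6)


def test_all_censored_group_flagged_degenerate():
    res = _strat([1, 2, 3], [1, 1, 1], [0.5, 0.5], [0, 0])
    assert res.degenerate


def test_relabeling_groups_preserves_chi_square():
    rng = np.random.default_rng(16)
    t = rng.exponential(5, 30)
    e = rng.integers(0, 2, 30)
    g = pd.Series(np.where(rng.integers(0, 2, 30) == 1, "high", "low"))
    a = km_logrank(g, pd.Series(t), pd.Series(e))
    flipped = g.map({"high": "low", "low": "high"})
    b = km_logrank(flipped, pd.Series(t), pd.Series(e))
    assert a.chi_square == pytest.approx(b.chi_square, rel=1e-12)


def test_km_curve_properties():
    rng = np.random.default_rng(17)
    t = rng.exponential(5, 40)
    e = np.ones(40, dtype=int)  # no censoring
    g = pd.Series(["low"] * 20 + ["high"] * 20)
    res = km_logrank(g, pd.Series(t), pd.Series(e))
    for name, curve in res.curves.items():
        surv = np.asarray(curve.survival)
        assert surv[0] <= 1.0 and np.all(np.diff(surv) <= 1e-12)
        # without censoring the KM estimate is the empirical survival function
        mask = (g == name).to_numpy()
        times = np.asarray(curve.times)
        empirical = [(t[mask] > u).mean() for u in times]
        assert np.allclose(surv, empirical)


# -- Spearman ----------------------------------------------------------------


@pytest.mark.parametrize(
    "x,y,expected",
    [
        ((1, 2, 3), (10, 20, 30), 1.0),
        ((1, 2, 3), (30, 20, 10), -1.0),
        ((1, 2, 3, 4), (2, 1, 4, 3), 0.6),
    ],
)
def test_spearman_examples(x, y, expected):
    rho, _ = spearman_corr(x, y)
    assert rho == pytest.approx(expected)


def test_spearman_zero_variance_errors():
    with pytest.raises(ValidationError, match="variance"):
        spearman_corr([1, 1, 1], [1, 2, 3])


# -- cohort-level report -----------------------------------------------------


def test_evaluate_cohort_detects_prognostic_signal():
    params = SimulationParams(
        n_genes=300, n_samples=400, n_signal_genes=40, effect_size=1.5,
        hazard_coef=1.0, seed=3,
    )
    expr, clinical, truth = simulate_cohort(params)
    sv = score_samples(expr, truth_signature(truth), n_permutations=60, seed=0)
    report = evaluate_cohort(sv.scores, clinical)
    full = report["strata"]["all"]
    assert full["survival"]["p_value"] < 0.05
    assert full["fusion_classification"]["auc"] > 0.9
    assert full["fusion_comparison"]["positive_vs_negative"]["p_value"] < 1e-6


def test_empty_stratum_is_skipped(small_cohort):
    expr, clinical, truth = small_cohort
    scores = pd.Series(np.arange(expr.shape[1], dtype=float), index=expr.columns)
    clin = clinical.copy()
    clin["gleason"] = 6  # no Gleason-7 samples anywhere
    cfg = EvaluationConfig(strata={"gleason7": {"gleason": 7}})
    report = evaluate_cohort(scores, clin, cfg)
    entry = report["strata"]["gleason7"]
    assert entry["n"] == 0 and "skipped" in entry


def test_report_is_json_serializable(tmp_path, small_cohort):
    import json

    expr, clinical, truth = small_cohort
    sv = score_samples(expr, truth_signature(truth), n_permutations=30, seed=0)
    cfg = EvaluationConfig(continuous_covariates=("age",))
    report = evaluate_cohort(sv.scores, clinical, cfg)
    text = json.dumps(report, default=float)
    assert "strata" in json.loads(text)
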