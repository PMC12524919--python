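"""Outcome statistics against independent oracles."""
import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata
from statsmodels.stats.multitest import multipletests

from femcalc import stats
from femcalc.phantom import study_flow_cohort


# ---------------------------------------------------------------------------
# patency and summaries
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "psvr,tlr,expected",
    [
        (1.0, False, "patent"),
        (3.1, False, "restenosis"),
        (2.0, True, "restenosis"),  # clinically driven TLR overrides a good PSVR
        (2.4, False, "patent"),     # boundary: 2.4 or lower is patent
        (2.41, False, "restenosis"),
    ],
)
def test_patency_classification(psvr, tlr, expected):
    assert stats.classify_patency(psvr, tlr) == expected


def test_unevaluable_limb_flagged_and_excluded():
    assert stats.classify_patency(float("nan"), False) is not None
    assert pd.isna(stats.classify_patency(float("nan"), False))
    df = study_flow_cohort()
    out = stats.add_patency(df)
    assert out["patency"].isna().sum() == 6  # died + lost have no PSVR
    s = stats.summarize_cohort(df)
    assert s["n_evaluable"] == 84


def test_cohort_summary_reproduces_flow_arithmetic():
    s = stats.summarize_cohort(study_flow_cohort())
    assert s["patency_12m_pct"] == 77.4
    assert s["restenosis_12m_pct"] == 22.6
    assert s["followup_12m_pct"] == 93.3
    assert s["followup_1m_pct"] == 98.9
    assert s["claudication_pct"] == 78.9
    assert s["clti_pct"] == 21.1
    assert s["azema_pct"] == {"I": 1, "II": 43, "III": 56}


def test_all_patent_cohort_saturates_at_100():
    df = study_flow_cohort()
    df["psvr_12m"] = df["psvr_12m"].where(df["psvr_12m"].isna(), 1.0)
    assert stats.summarize_cohort(df)["patency_12m_pct"] == 100.0


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum
# ---------------------------------------------------------------------------

def _enumerated_two_sided_p(x, y):
    """Full enumeration of the rank-sum null over all group splits."""
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    n, N = len(x), len(pooled)
    obs = ranks[:n].sum()
    mean = n * (N + 1) / 2.0
    hits = total = 0
    for comb in itertools.combinations(range(N), n):
        total += 1
        if abs(ranks[list(comb)].sum() - mean) >= abs(obs - mean) - 1e-12:
            hits += 1
    return hits / total


def test_wilcoxon_separated_triplets_give_point_one():
    assert stats.wilcoxon_rank_sum([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)


def test_wilcoxon_identical_groups_p_is_one():
    assert stats.wilcoxon_rank_sum([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == pytest.approx(1.0)


def test_wilcoxon_exact_matches_full_enumeration():
    rng = np.random.default_rng(2024)
    for _ in range(25):
        n1 = rng.integers(3, 7)
        n2 = rng.integers(3, 13 - n1)
        vals = rng.choice(np.arange(1000), size=n1 + n2, replace=False).astype(float)
        x, y = vals[:n1], vals[n1:]
        assert stats.wilcoxon_rank_sum(x, y) == pytest.approx(
            _enumerated_two_sided_p(x, y)
        )


# ---------------------------------------------------------------------------
# Benjamini-Hochberg
# ---------------------------------------------------------------------------

def test_bh_hand_cases():
    assert stats.bh_fdr([0.03]) == pytest.approx([0.03])
    assert stats.bh_fdr([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)
    fam = [0.001] + [1.0] * 14
    assert stats.bh_fdr(fam)[0] == pytest.approx(0.015)
    assert stats.bh_fdr([0.2, 0.2, 0.2]) == pytest.approx([0.2] * 3)


def test_bh_monotone_order_invariant_and_matches_statsmodels():
    rng = np.random.default_rng(7)
    p = rng.random(40)
    q = stats.bh_fdr(p)
    # order preserved and monotone in p
    order = np.argsort(p)
    assert (np.diff(q[order]) >= -1e-12).all()
    perm = rng.permutation(len(p))
    assert stats.bh_fdr(p[perm]) == pytest.approx(q[perm])
    assert q == pytest.approx(multipletests(p, method="fdr_bh")[1])


def test_bh_rejects_invalid_p():
    with pytest.raises(ValueError):
        stats.bh_fdr([0.1, 1.2])
    with pytest.raises(ValueError):
        stats.bh_fdr([-0.1])


def test_compare_groups_q_within_single_family():
    rng = np.random.default_rng(5)
    df = pd.DataFrame(
        {
            "patency": ["patent"] * 30 + ["restenosis"] * 15,
            "m1": rng.normal(10, 1, 45),
            "m2": np.r_[rng.normal(12, 1, 30), rng.normal(8, 1, 15)],
        }
    )
    cmp_ = stats.compare_groups(df, ["m1", "m2"])
    tab = cmp_.table.set_index("metric")
    assert tab.loc["m2", "p_value"] < tab.loc["m1", "p_value"]
    assert (tab["q_value"] >= tab["p_value"] - 1e-12).all()
    assert tab.loc["m2", "q_value"] == pytest.approx(
        stats.bh_fdr(tab["p_value"].to_numpy())[1]
    )


# ---------------------------------------------------------------------------
# logistic regression
# ---------------------------------------------------------------------------

def _two_by_two_cohort(a, b, c, d):
    """a exposed events, b exposed non-events, c unexposed events, d unexposed non."""
    return pd.DataFrame(
        {
            "exposed": [1] * (a + b) + [0] * (c + d),
            "event": [1] * a + [0] * b + [1] * c + [0] * d,
        }
    )


def test_logistic_saturated_binary_model_equals_cross_product_ratio():
    df = _two_by_two_cohort(10, 10, 5, 20)
    fit = stats.fit_logistic(df, "event", ["exposed"])
    assert fit.odds_ratio("exposed") == pytest.approx((10 * 20) / (10 * 5), rel=1e-4)
    lo, hi = fit.table.loc["exposed", ["ci_low", "ci_high"]]
    assert lo <= 4.0 <= hi


def test_logistic_independent_predictor_gives_unit_odds_ratio():
    df = _two_by_two_cohort(10, 10, 10, 10)
    fit = stats.fit_logistic(df, "event", ["exposed"])
    assert fit.odds_ratio("exposed") == pytest.approx(1.0, abs=1e-6)


def test_logistic_degenerate_inputs_rejected():
    df = _two_by_two_cohort(0, 20, 0, 20)
    with pytest.raises(ValueError, match="both classes"):
        stats.fit_logistic(df, "event", ["exposed"])
    df2 = _two_by_two_cohort(10, 10, 5, 20).assign(flat=1.0)
    with pytest.raises(ValueError, match="constant"):
        stats.fit_logistic(df2, "event", ["flat"])
    sep = pd.DataFrame({"x": [0, 0, 0, 1, 1, 1] * 4, "y": [0, 0, 0, 1, 1, 1] * 4})
    with pytest.raises(ValueError, match="separation"):
        stats.fit_logistic(sep, "y", ["x"])


# ---------------------------------------------------------------------------
# ROC / Youden
# ---------------------------------------------------------------------------

def _brute_concordance(scores, pos):
    hits = 0.0
    ps = scores[pos]
    ns = scores[~pos]
    for p in ps:
        for q in ns:
            hits += 1.0 if p > q else (0.5 if p == q else 0.0)
    return hits / (len(ps) * len(ns))


def _brute_youden(scores, pos, direction):
    u = np.sort(np.unique(scores))
    best_j, best_t = -np.inf, None
    for t in 0.5 * (u[:-1] + u[1:]):
        pred = scores >= t if direction == "greater" else scores <= t
        sens = (pred & pos).sum() / pos.sum()
        spec = (~pred & ~pos).sum() / (~pos).sum()
        if sens + spec - 1 > best_j + 1e-12:
            best_j, best_t = sens + spec - 1, t
    return best_t, best_j


def test_perfect_separation_gives_unit_auc_and_j():
    r = stats.roc_youden([1, 2, 3, 10, 11, 12], ["n", "n", "n", "p", "p", "p"], positive="p")
    assert r.auc == 1.0
    assert r.youden_j == 1.0
    assert 3 < r.threshold < 10


def test_interleaved_scores_auc_three_quarters():
    r = stats.roc_youden([1, 2, 3, 4], ["n", "p", "n", "p"], positive="p")
    assert r.auc == pytest.approx(0.75)


def test_orientation_flips_when_low_scores_predict_positive():
    scores = [900, 850, 800, 1100, 1150, 1200]
    labels = ["restenosis"] * 3 + ["patent"] * 3
    r = stats.roc_youden(scores, labels, positive="restenosis")
    assert r.direction == "less"
    assert r.auc >= 0.5
    assert r.sensitivity == 1.0 and r.specificity == 1.0


def test_roc_requires_both_classes_and_distinct_scores():
    with pytest.raises(ValueError, match="both outcome classes"):
        stats.roc_youden([1, 2, 3], ["p", "p", "p"], positive="p")
    with pytest.raises(ValueError, match="distinct"):
        stats.roc_youden([5, 5, 5, 5], ["p", "p", "n", "n"], positive="p")


def test_auc_equals_concordance_and_trapezoid_on_random_instances():
    rng = np.random.default_rng(11)
    for _ in range(20):
        n = int(rng.integers(8, 50))
        scores = rng.integers(0, 12, n).astype(float)  # ties on purpose
        labels = rng.random(n) < 0.4
        if labels.all() or not labels.any() or len(np.unique(scores)) < 2:
            continue
        r = stats.roc_youden(scores, labels, positive=True, direction="greater")
        conc = _brute_concordance(scores, labels)
        assert r.auc == pytest.approx(conc)
        assert np.trapezoid(r.curve["tpr"], r.curve["fpr"]) == pytest.approx(conc)
        from sklearn.metrics import roc_auc_score
        assert r.auc == pytest.approx(roc_auc_score(labels, scores))
        thr, j = _brute_youden(scores, labels, "greater")
        assert r.threshold == pytest.approx(thr)
        assert r.youden_j == pytest.approx(j)


def test_predictive_values_follow_bayes_at_observed_prevalence():
    rng = np.random.default_rng(3)
    scores = np.r_[rng.normal(5, 1, 30), rng.normal(7, 1, 12)]
    labels = np.r_[np.zeros(30), np.ones(12)]
    r = stats.roc_youden(scores, labels, positive=1.0)
    prev, se, sp = r.prevalence, r.sensitivity, r.specificity
    ppv = se * prev / (se * prev + (1 - sp) * (1 - prev))
    npv = sp * (1 - prev) / ((1 - se) * prev + sp * (1 - prev))
    assert r.ppv == pytest.approx(ppv)
    assert r.npv == pytest.approx(npv)


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

def test_degenerate_scores_give_zero_width_interval():
    scores = np.array([1.0] * 6 + [2.0] * 6)
    labels = np.array(["p"] * 6 + ["n"] * 6)
    b = stats.bootstrap_threshold(scores, labels, B=50, seed=1, positive="p")
    assert b.estimate == 1.5
    assert b.ci_low == b.ci_high == 1.5
    assert (b.thresholds == 1.5).all()


def test_bootstrap_replicates_match_parallel_reimplementation():
    rng0 = np.random.default_rng(99)
    scores = np.round(rng0.normal(1000, 120, 12), 1)
    labels = np.array(["restenosis"] * 6 + ["patent"] * 6)
    pos = labels == "restenosis"
    B, seed = 200, 42
    res = stats.bootstrap_threshold(scores, labels, B=B, seed=seed, direction="less")

    # independent re-implementation of the resampling loop on the same stream
    rng = np.random.default_rng(seed)
    expected = []
    for _ in range(B):
        while True:
            idx = rng.integers(0, 12, 12)
            p = pos[idx]
            if p.any() and (~p).any() and len(np.unique(scores[idx])) >= 2:
                break
        t, _ = _brute_youden(scores[idx], p, "less")
        expected.append(t)
    assert res.thresholds == pytest.approx(np.asarray(expected))


def test_bootstrap_seed_determinism_and_b1_error():
    scores = np.r_[np.arange(10.0), np.arange(5.0, 15.0)]
    labels = np.array(["p"] * 10 + ["n"] * 10)
    a = stats.bootstrap_threshold(scores, labels, B=100, seed=5, positive="p")
    b = stats.bootstrap_threshold(scores, labels, B=100, seed=5, positive="p")
    assert np.array_equal(a.thresholds, b.thresholds)
    assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)
    with pytest.raises(ValueError, match="B must be"):
        stats.bootstrap_threshold(scores, labels, B=1, seed=0, positive="p")


# ---------------------------------------------------------------------------
# ICC
# ---------------------------------------------------------------------------

def test_icc_identical_raters_perfect_agreement():
    t = pd.DataFrame({"a": [3.0, 5, 7, 9, 11, 13], "b": [3.0, 5, 7, 9, 11, 13]})
    r = stats.icc_agreement(t)
    assert r.icc == 1.0


def test_icc_matches_anova_mean_squares_on_toy_table():
    """6 subjects x 2 raters; expected value from the two-way ANOVA mean
    squares (MSR 10.0833, MSC 0.75, MSE 0.75), cross-checked against an
    independent implementation."""
    t = pd.DataFrame({"a": [9.0, 2, 5, 8, 6, 7], "b": [10.0, 4, 6, 7, 5, 8]})
    r = stats.icc_agreement(t)
    assert r.icc == pytest.approx(0.8615384615, abs=1e-9)
    import pingouin as pg
    long = t.reset_index().melt(id_vars="index", var_name="rater", value_name="score")
    ref = pg.intraclass_corr(long, targets="index", raters="rater", ratings="score")
    ref_a1 = ref.set_index("Type").loc["ICC(A,1)"]
    assert r.icc == pytest.approx(ref_a1["ICC"])
    assert (r.ci_low, r.ci_high) == pytest.approx(tuple(ref_a1["CI95"]), abs=0.01)


def test_icc_zero_between_subject_variance_not_positive():
    t = pd.DataFrame({"a": [4.0] * 6, "b": [6.0] * 6})
    r = stats.icc_agreement(t)
    assert r.icc <= 0


def test_icc_input_validation():
    with pytest.raises(ValueError, match="missing"):
        stats.icc_agreement(pd.DataFrame({"a": [1, 2, 3, 4, np.nan], "b": [1, 2, 3, 4, 5]}))
    with pytest.raises(ValueError, match="at least 5 subjects"):
        stats.icc_agreement(pd.DataFrame({"a": [1, 2], "b": [1, 2]}))
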