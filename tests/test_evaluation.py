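"""ROC/Youden, effect sizes, heteroscedastic ANOVA, FDR, agreement, audit."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sbrkit import (DegenerateDataError, ValidationError, brown_forsythe_anova,
                    compare_methods, generate_cohort, hedges_g,
                    hedges_g_from_summary, method_agreement,
                    misclassification_audit, normality_test, posthoc_ttests_fdr,
                    roc_analysis)
from sbrkit.config import SynthConfig
from sbrkit.evaluation import benjamini_hochberg, classic_anova

from conftest import make_cohort


def brute_force_auc(scores, labels):
    """Exhaustive pair counting: P(PD < HC) + 0.5 P(tie)."""
    pd_scores = scores[labels == "PD"]
    hc_scores = scores[labels == "HC"]
    wins = sum((p < h) + 0.5 * (p == h) for p in pd_scores for h in hc_scores)
    return wins / (len(pd_scores) * len(hc_scores))


# -- ROC ---------------------------------------------------------------------

def test_perfect_separation():
    scores = np.array([1.0, 2.0, 3.0, 4.0])
    labels = np.array(["PD", "PD", "HC", "HC"])
    roc = roc_analysis(scores, labels)
    assert roc.auc == 1.0
    assert roc.youden_j == 1.0
    assert 2.0 < roc.youden_threshold < 3.0


@settings(deadline=None, max_examples=100, derandomize=True)
@given(st.data())
def test_auc_equals_exhaustive_pair_counting(data):
    n_pd = data.draw(st.integers(1, 25))
    n_hc = data.draw(st.integers(1, 25))
    pool = data.draw(st.lists(
        st.floats(min_value=0.1, max_value=9.9).map(lambda x: round(x, 1)),
        min_size=n_pd + n_hc, max_size=n_pd + n_hc))
    scores = np.array(pool)
    labels = np.array(["PD"] * n_pd + ["HC"] * n_hc)
    roc = roc_analysis(scores, labels)
    assert roc.auc == pytest.approx(brute_force_auc(scores, labels), abs=1e-12)


@settings(deadline=None, max_examples=100, derandomize=True)
@given(st.data())
def test_youden_threshold_is_optimal(data):
    n = data.draw(st.integers(4, 40))
    scores = np.array(data.draw(st.lists(
        st.floats(min_value=0.0, max_value=10.0).map(lambda x: round(x, 1)),
        min_size=n, max_size=n)))
    labels = np.array(["PD"] * (n // 2) + ["HC"] * (n - n // 2))
    roc = roc_analysis(scores, labels)
    pos, neg = labels == "PD", labels == "HC"
    distinct = np.unique(scores)
    candidates = np.concatenate([[-np.inf], (distinct[:-1] + distinct[1:]) / 2,
                                 [np.inf], distinct])
    best = max((scores[pos] <= t).mean() + (scores[neg] > t).mean() - 1
               for t in candidates)
    assert roc.youden_j == pytest.approx(best, abs=1e-12)


def test_null_labels_give_chance_auc():
    rng = np.random.default_rng(0)
    scores = rng.normal(size=2000)
    labels = np.where(rng.uniform(size=2000) < 0.5, "PD", "HC")
    roc = roc_analysis(scores, labels)
    n1, n0 = (labels == "PD").sum(), (labels == "HC").sum()
    se = np.sqrt((n1 + n0 + 1) / (12 * n1 * n0))
    assert abs(roc.auc - 0.5) < 3 * se


def test_auc_matches_sklearn():
    from sklearn.metrics import roc_auc_score
    rng = np.random.default_rng(1)
    scores = np.round(rng.normal(4, 1.5, 300), 1)
    labels = np.where(rng.uniform(size=300) < 0.55, "PD", "HC")
    roc = roc_analysis(scores, labels)
    assert roc.auc == pytest.approx(
        roc_auc_score((labels == "PD").astype(int), -scores), abs=1e-12)


def test_degenerate_roc_inputs():
    with pytest.raises(DegenerateDataError, match="both"):
        roc_analysis([1.0, 2.0], ["PD", "PD"])
    roc = roc_analysis([3.0, 3.0, 3.0], ["PD", "HC", "PD"])
    assert roc.auc == 0.5 and roc.degenerate


# -- Hedges's g --------------------------------------------------------------

def test_hedges_g_hand_values():
    assert hedges_g([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]).g == 0.0
    # x={0,1}, y={1,2}: pooled sd = sqrt(((1)(1/2)+(1)(1/2))/2) = 1/sqrt(2),
    # d = -1/(1/sqrt 2) = -sqrt(2), J = 1 - 3/(4*4-9) = 4/7 => g = -4*sqrt(2)/7
    eff = hedges_g([0.0, 1.0], [1.0, 2.0])
    assert eff.g == pytest.approx(-4.0 * np.sqrt(2.0) / 7.0)
    assert eff.correction_j == pytest.approx(1 - 3 / 7)
    assert eff.pooled_sd == pytest.approx(np.sqrt(0.5))


def test_hedges_g_published_group_summaries():
    assert hedges_g_from_summary(6.13, 1.54, 72, 2.03, 1.41, 81).g == \
        pytest.approx(2.76, abs=0.02)
    assert hedges_g_from_summary(5.25, 0.89, 72, 2.01, 0.73, 81).g == \
        pytest.approx(3.99, abs=0.02)


def test_hedges_g_recovers_true_standardized_difference():
    rng = np.random.default_rng(2)
    n = 4000
    x, y = rng.normal(1.0, 1.0, n), rng.normal(0.0, 1.0, n)
    eff = hedges_g(x, y)
    se = np.sqrt(2 / n)  # large-sample SE of d at d ~ 1
    assert abs(eff.g - 1.0) < 3 * se


def test_hedges_correction_shrinks_toward_zero():
    rng = np.random.default_rng(3)
    for n in (5, 20, 200):
        x, y = rng.normal(1, 1, n), rng.normal(0, 1, n)
        eff = hedges_g(x, y)
        d = (x.mean() - y.mean()) / eff.pooled_sd
        assert abs(eff.g) < abs(d)
        assert eff.correction_j < 1.0


def test_hedges_g_matches_pingouin():
    from pingouin import compute_effsize
    rng = np.random.default_rng(4)
    x, y = rng.normal(5, 1.2, 40), rng.normal(3, 0.8, 60)
    assert hedges_g(x, y).g == pytest.approx(
        compute_effsize(x, y, eftype="hedges"), abs=1e-10)


def test_hedges_degenerate_inputs():
    with pytest.raises(DegenerateDataError):
        hedges_g_from_summary(5.0, 0.0, 10, 3.0, 1.0, 10)
    with pytest.raises(DegenerateDataError):
        hedges_g([1.0, 1.0], [2.0, 2.0])
    with pytest.raises(DegenerateDataError):
        hedges_g([1.0], [2.0, 3.0])


# -- Brown-Forsythe ANOVA ----------------------------------------------------

def test_equal_groups_give_null_statistic():
    rng = np.random.default_rng(5)
    g = rng.normal(0, 1, 30)
    res = brown_forsythe_anova([g, g + 1e-9, g - 1e-9])
    assert res.f == pytest.approx(0.0, abs=1e-12)
    assert res.p == pytest.approx(1.0)


def test_reduces_to_classic_f_for_balanced_two_groups():
    rng = np.random.default_rng(6)
    a, b = rng.normal(0, 1, 40), rng.normal(0.5, 1, 40)
    bf = brown_forsythe_anova([a, b])
    classic = classic_anova([a, b])
    assert bf.f == pytest.approx(classic.f, rel=1e-10)
    assert bf.df1 == classic.df1


def test_fractional_denominator_df_under_heteroscedasticity():
    rng = np.random.default_rng(7)
    groups = [rng.normal(0, s, n) for s, n in ((1, 10), (3, 40), (0.5, 15))]
    res = brown_forsythe_anova(groups)
    assert res.variant == "brown_forsythe"
    assert res.df2 > 0 and res.df2 != round(res.df2)
    assert res.df2 < sum(len(g) for g in groups) - 3


def test_zero_variance_group_is_named():
    with pytest.raises(DegenerateDataError, match="flat"):
        brown_forsythe_anova([[1.0, 2.0, 3.0], [4.0, 4.0, 4.0]],
                             labels=["ok", "flat"])


# -- post-hoc t-tests with FDR ----------------------------------------------

def test_identical_groups_not_significant():
    g = np.linspace(0, 1, 20)
    res = posthoc_ttests_fdr({"a": g, "b": g.copy()})
    assert not res[0].significant
    assert res[0].p_adjusted > 0.9


def test_shifted_group_flags_exactly_its_two_pairs():
    rng = np.random.default_rng(8)
    groups = {
        "a": rng.normal(0, 1, 50),
        "b": rng.normal(0, 1, 50),
        "c": rng.normal(5, 1, 50),  # shifted by 5 SDs
    }
    res = posthoc_ttests_fdr(groups)
    sig_pairs = {frozenset((r.label_a, r.label_b)) for r in res if r.significant}
    assert sig_pairs == {frozenset(("a", "c")), frozenset(("b", "c"))}


def test_bh_step_up_hand_case():
    reject, p_adj = benjamini_hochberg([0.01, 0.02, 0.03, 0.8], alpha=0.05)
    assert list(reject) == [True, True, True, False]


@settings(deadline=None, max_examples=50, derandomize=True)
@given(st.lists(st.floats(min_value=1e-6, max_value=1.0), min_size=2, max_size=20))
def test_bh_adjusted_p_monotone_in_rank(pvals):
    _, p_adj = benjamini_hochberg(pvals)
    order = np.argsort(pvals)
    assert np.all(np.diff(np.asarray(p_adj)[order]) >= -1e-12)


# -- normality ----------------------------------------------------------------

def test_shapiro_bounds_and_power():
    with pytest.raises(DegenerateDataError):
        normality_test([1.0, 2.0])
    rng = np.random.default_rng(9)
    bimodal = np.concatenate([rng.normal(-3, 0.3, 75), rng.normal(3, 0.3, 75)])
    _, p = normality_test(bimodal)
    assert p < 0.01


def test_shapiro_null_calibration():
    rng = np.random.default_rng(10)
    rejections = sum(normality_test(rng.normal(size=500))[1] < 0.05
                     for _ in range(1000))
    assert 30 <= rejections <= 70  # ~5% +/- binomial noise


# -- agreement and misclassification ------------------------------------------

def test_agreement_exact_cases():
    x = np.linspace(1, 5, 20)
    res = method_agreement(x, x)
    assert res.pearson_r == pytest.approx(1.0)
    assert np.allclose(res.residuals, 0.0)
    res2 = method_agreement(x, 2 * x + 1)
    assert res2.pearson_r == pytest.approx(1.0)
    assert res2.slope == pytest.approx(2.0)
    assert res2.intercept == pytest.approx(1.0)
    with pytest.raises(DegenerateDataError):
        method_agreement(np.full(5, 2.0), x[:5])


def test_misclassification_audit_partitions():
    scores = np.array([5.0, 3.9, 1.5, 4.2])
    labels = np.array(["HC", "HC", "PD", "PD"])
    audit = misclassification_audit(scores, labels, threshold=4.0,
                                    ids=["h1", "h2", "p1", "p2"])
    assert [f["id"] for f in audit.false_positives] == ["h2"]
    assert audit.false_positives[0]["margin"] == pytest.approx(-0.1)
    assert [f["id"] for f in audit.false_negatives] == ["p2"]
    with pytest.raises(ValidationError):
        misclassification_audit(scores, labels, threshold=np.inf)


def test_perfect_separation_has_empty_audit():
    scores = np.array([1.0, 2.0, 5.0, 6.0])
    labels = np.array(["PD", "PD", "HC", "HC"])
    roc = roc_analysis(scores, labels)
    audit = misclassification_audit(scores, labels, roc.youden_threshold)
    assert audit.false_positives == [] and audit.false_negatives == []


def test_false_negatives_are_mildest_patients():
    """Scan-negative PDs concentrate at the mildest simulated severities:
    the classification margin tracks the latent (biological) SBR."""
    from scipy.stats import spearmanr
    ok = 0
    for seed in range(20):
        cohort, truth = generate_cohort(SynthConfig(), seed=seed)
        scores, labels = cohort.scores(), cohort.labels()
        roc = roc_analysis(scores, labels)
        pd_mask = labels == "PD"
        margins = scores[pd_mask] - roc.youden_threshold
        severity = truth.latent.mean(axis=1)[pd_mask]  # higher = milder
        ok += spearmanr(margins, severity).statistic > 0
    assert ok >= 18


# -- cross-method comparison ---------------------------------------------------

def test_identical_stages_compare_as_identical(default_cohort):
    cohort, _ = default_cohort
    c2 = cohort.with_values(cohort.values(), stage="prospective")
    c3 = cohort.with_values(cohort.values(), stage="combat")
    report = compare_methods({"original": cohort, "prospective": c2, "combat": c3})
    aucs = {s: m.roc.auc for s, m in report.stages.items()}
    assert len(set(aucs.values())) == 1
    for dx in ("HC", "PD"):
        assert report.method_mean_anova[dx]["anova"]["p"] > 0.99
        assert not any(p["significant"]
                       for p in report.method_mean_anova[dx]["posthoc"])
    assert report.agreement["pearson_r"] == pytest.approx(1.0)


def test_mismatched_ids_rejected(default_cohort):
    cohort, _ = default_cohort
    shorter = cohort.subset(np.arange(len(cohort)) > 0)
    with pytest.raises(ValidationError, match="differ in ids"):
        compare_methods({"original": cohort, "combat": shorter})
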