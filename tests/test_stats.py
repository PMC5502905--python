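"""Tests for the agreement / discrimination statistics, each against an
independent oracle (closed form, brute force, or a second library)."""

import numpy as np
import pandas as pd
import pytest

from plaquemap import stats as ps

# Reported plaque-type confusion matrix used as a worked example:
# rows = histology (IV-V, VI, VII, VIII), columns = T2-map classification.
TYPE_CONFUSION = np.array([
    [7, 2, 0, 0],
    [1, 7, 0, 0],
    [1, 0, 4, 1],
    [0, 0, 0, 3],
])


# --- Pearson ---------------------------------------------------------------

def test_pearson_affine():
    x = np.arange(10.0)
    assert ps.pearson_r(x, 2 * x + 3).r == pytest.approx(1.0)
    assert ps.pearson_r(x, -x).r == pytest.approx(-1.0)


def test_pearson_null():
    rng = np.random.default_rng(0)
    r = ps.pearson_r(rng.uniform(size=10_000), rng.uniform(size=10_000)).r
    assert abs(r) < 0.05


def test_pearson_guards():
    with pytest.raises(ValueError, match="zero variance in y"):
        ps.pearson_r([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])
    with pytest.raises(ValueError, match="n >= 3"):
        ps.pearson_r([1.0, 2.0], [1.0, 2.0])


# --- Bland-Altman ----------------------------------------------------------

def test_bland_altman_identity():
    v = np.array([1.0, 5.0, 9.0])
    res = ps.bland_altman(v, v)
    assert (res.bias, res.loa_low, res.loa_high) == (0.0, 0.0, 0.0)


def test_bland_altman_closed_form():
    res = ps.bland_altman([0.0, 2.0], [1.0, 1.0])  # differences -1, +1
    assert res.bias == pytest.approx(0.0)
    assert res.loa_high == pytest.approx(1.96 * np.sqrt(2.0))
    assert res.loa_low == pytest.approx(-1.96 * np.sqrt(2.0))


def test_bland_altman_consistency_and_mean_identity():
    rng = np.random.default_rng(1)
    ref = rng.uniform(10, 50, 2000)
    meas = ref + 3.0 + rng.normal(0, 1.0, ref.size)
    res = ps.bland_altman(meas, ref)
    assert res.bias == pytest.approx(3.0, abs=0.1)
    # bias + mean(reference) = mean(measured), exactly
    assert res.bias + ref.mean() == pytest.approx(meas.mean(), abs=1e-10)


# --- relative difference ---------------------------------------------------

@pytest.mark.parametrize("a, b, expected", [
    (31.5, 15.8, 99.4),
    (128.0, 105.6, 21.2),
    (7.0, 7.0, 0.0),
])
def test_relative_difference(a, b, expected):
    assert round(ps.relative_difference(a, b), 1) == expected


def test_relative_difference_zero_reference():
    with pytest.raises(ValueError, match="zero"):
        ps.relative_difference(1.0, 0.0)


# --- t test ----------------------------------------------------------------

def test_t_test_identical_and_separated():
    a = np.array([1.0, 2.0, 3.0])
    res = ps.two_sample_t(a, a)
    assert res.t == pytest.approx(0.0) and res.p == pytest.approx(1.0)
    far = ps.two_sample_t(a, a + 100.0)
    assert far.p < 1e-6
    assert far.sem_a == pytest.approx(np.std(a, ddof=1) / np.sqrt(3))


# --- ROC -------------------------------------------------------------------

def test_roc_perfect_separation():
    res = ps.roc_analysis([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
    assert res.auc == 1.0
    assert res.sensitivity == 1.0 and res.specificity == 1.0
    assert res.optimal_cutoff == 10.0  # lowest cutoff achieving maximal J


def test_roc_null_mean_half():
    rng = np.random.default_rng(2)
    aucs = []
    for _ in range(1000):
        scores = rng.normal(size=20)
        labels = np.r_[np.ones(10, bool), np.zeros(10, bool)]
        aucs.append(ps.roc_analysis(scores, labels).auc)
    assert np.mean(aucs) == pytest.approx(0.5, abs=0.02)


def test_roc_auc_equals_pairwise_count_oracle():
    """Rank-formula AUC equals the brute-force count over all between-class
    pairs, with ties worth one half."""
    rng = np.random.default_rng(3)
    for _ in range(30):
        n = rng.integers(6, 30)
        scores = rng.integers(0, 8, n).astype(float)  # integer scores force ties
        labels = rng.uniform(size=n) > 0.5
        if labels.all() or not labels.any():
            continue
        res = ps.roc_analysis(scores, labels)
        pos, neg = scores[labels], scores[~labels]
        wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
        assert res.auc == pytest.approx(wins / (pos.size * neg.size), abs=1e-12)


def test_roc_matches_sklearn():
    sklearn_metrics = pytest.importorskip("sklearn.metrics")
    rng = np.random.default_rng(4)
    scores = rng.normal(size=40)
    labels = rng.uniform(size=40) > 0.4
    res = ps.roc_analysis(scores, labels)
    assert res.auc == pytest.approx(
        sklearn_metrics.roc_auc_score(labels, scores), abs=1e-12)


def test_roc_single_class_raises():
    with pytest.raises(ValueError, match="both classes"):
        ps.roc_analysis([1.0, 2.0], [True, True])


# --- chi-square ------------------------------------------------------------

def test_chi2_hand_formula():
    """n(ad-bc)^2 / (row1*row2*col1*col2) on a 2x2 table."""
    t = np.array([[10, 5], [1, 10]])
    n = t.sum()
    expected = n * (10 * 10 - 5 * 1) ** 2 / (15 * 11 * 11 * 15)
    res = ps.chi2_from_table(t)
    assert res.chi2 == pytest.approx(expected, abs=1e-9)
    assert res.chi2 == pytest.approx(8.62, abs=0.01)
    assert res.chi2_yates < res.chi2  # continuity correction shrinks it


def test_chi2_independent_table_is_zero():
    assert ps.chi2_from_table([[5, 5], [5, 5]]).chi2 == pytest.approx(0.0)


def test_chi2_zero_margin_is_nan():
    res = ps.chi2_from_table([[5, 0], [3, 0]])
    assert np.isnan(res.chi2) and np.isnan(res.p)


def test_chi2_large_lrnc_inclusive_cutoff():
    """A plaque at exactly 25% counts as large (>= rule)."""
    df = pd.DataFrame({
        "symptomatic": [True, True, False, False],
        "mean_lipid_area_pct": [25.0, 40.0, 10.0, 24.99],
    })
    res = ps.chi2_large_lrnc(df)
    assert res.table.tolist() == [[2, 0], [0, 2]]


# --- ICC -------------------------------------------------------------------

def test_icc_exact_agreement():
    a = np.array([10.0, 20.0, 30.0, 40.0])
    res = ps.icc_absolute(a, a)
    assert res.icc == 1.0 and res.ci_low == 1.0


def test_icc_dominated_by_noise_is_near_zero():
    rng = np.random.default_rng(5)
    vals = []
    for _ in range(100):
        subj = rng.normal(0, 1.0, 20)
        vals.append(ps.icc_absolute(subj + rng.normal(0, 20, 20),
                                    subj + rng.normal(0, 20, 20)).icc)
    assert abs(np.mean(vals)) < 0.08


def test_icc_hand_worked_anova_table():
    """Direct ANOVA mean-square computation on a 4-pair toy table."""
    a = np.array([9.0, 6.0, 8.0, 7.0])
    b = np.array([2.0, 1.0, 4.0, 1.0])
    data = np.column_stack([a, b])
    n, k = data.shape
    grand = data.mean()
    msr = k * ((data.mean(1) - grand) ** 2).sum() / (n - 1)
    msc = n * ((data.mean(0) - grand) ** 2).sum() / (k - 1)
    mse = (((data - data.mean(1, keepdims=True) - data.mean(0, keepdims=True)
             + grand) ** 2).sum()) / ((n - 1) * (k - 1))
    expected = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    res = ps.icc_absolute(a, b)
    assert res.icc == pytest.approx(expected, abs=1e-12)


def test_icc_matches_pingouin():
    pingouin = pytest.importorskip("pingouin")
    rng = np.random.default_rng(6)
    subj = rng.normal(20, 8, 15)
    a = subj + rng.normal(0, 3, 15)
    b = subj + rng.normal(0, 3, 15)
    res = ps.icc_absolute(a, b)
    df = pd.DataFrame({
        "targets": np.r_[np.arange(15), np.arange(15)],
        "raters": ["a"] * 15 + ["b"] * 15,
        "scores": np.r_[a, b],
    })
    table = pingouin.intraclass_corr(df, targets="targets", raters="raters",
                                     ratings="scores").set_index("Type")
    icc2 = table.loc["ICC(A,1)"] if "ICC(A,1)" in table.index else table.loc["ICC2"]
    ci_col = "CI95" if "CI95" in table.columns else "CI95%"
    assert res.icc == pytest.approx(icc2["ICC"], abs=1e-6)
    # pingouin prints the CI rounded to two decimals
    assert res.ci_low == pytest.approx(icc2[ci_col][0], abs=0.006)
    assert res.ci_high == pytest.approx(icc2[ci_col][1], abs=0.006)


# --- CoV -------------------------------------------------------------------

def test_cov_identical_pairs_zero():
    a = np.array([10.0, 20.0, 30.0])
    assert ps.cov_within(a, a) == 0.0


def test_cov_hand_computation():
    a = np.array([10.0, 20.0, 30.0, 10.0])
    b = np.array([10.0, 20.0, 30.0, 12.0])
    d = a - b
    expected = np.sqrt((d ** 2).mean() / 2) / np.concatenate([a, b]).mean() * 100
    assert ps.cov_within(a, b) == pytest.approx(expected, abs=1e-12)


def test_cov_scale_invariance():
    rng = np.random.default_rng(7)
    a = rng.uniform(10, 40, 9)
    b = a + rng.normal(0, 2, 9)
    assert ps.cov_within(3 * a, 3 * b) == pytest.approx(ps.cov_within(a, b), abs=1e-10)


# --- Cohen's kappa ---------------------------------------------------------

def test_kappa_on_reported_type_table():
    res = ps.cohens_kappa(TYPE_CONFUSION)
    assert round(res.kappa, 2) == 0.73
    assert round(res.agreement_pct, 1) == 80.8


def test_kappa_identity_and_independence():
    assert ps.cohens_kappa(np.eye(4) * 5).kappa == pytest.approx(1.0)
    # outer product of margins -> observed equals chance -> kappa 0
    row = np.array([0.5, 0.3, 0.2])
    table = np.outer(row * 10, row * 10)
    table = np.round(table * 10)  # keep integers, still proportional
    assert ps.cohens_kappa(table).kappa == pytest.approx(0.0, abs=1e-9)


def test_kappa_permutation_invariance():
    rng = np.random.default_rng(8)
    t = rng.integers(0, 10, (4, 4))
    perm = rng.permutation(4)
    assert ps.cohens_kappa(t[perm][:, perm]).kappa == pytest.approx(
        ps.cohens_kappa(t).kappa, abs=1e-12)


def test_kappa_matches_sklearn():
    sklearn_metrics = pytest.importorskip("sklearn.metrics")
    pred, ref = [], []
    for i in range(4):
        for j in range(4):
            pred += [j] * TYPE_CONFUSION[i, j]
            ref += [i] * TYPE_CONFUSION[i, j]
    assert ps.cohens_kappa(TYPE_CONFUSION).kappa == pytest.approx(
        sklearn_metrics.cohen_kappa_score(ref, pred), abs=1e-12)


def test_kappa_degenerate_single_category():
    # every rating in one agreed category: chance agreement is 1, kappa
    # defined as 1 by convention
    t = np.zeros((3, 3))
    t[1, 1] = 7
    assert ps.cohens_kappa(t).kappa == 1.0
    with pytest.raises(ValueError, match="square"):
        ps.cohens_kappa(np.ones((2, 3)))
    with pytest.raises(ValueError, match="empty"):
        ps.cohens_kappa(np.zeros((2, 2)))
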