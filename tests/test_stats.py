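import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.stats as ss

from renaldwi import (
    egfr_ckd_epi,
    fit_score_model,
    group_compare,
    icc_two_observer,
    roc,
    spearman,
)
from renaldwi.errors import RenalDwiError
from renaldwi.stats import auc_band, creatinine_for_egfr, significance_stars


# ----------------------------------------------------------------- eGFR

def test_ckd_epi_reference_values():
    # direct evaluation of the published closed form
    assert egfr_ckd_epi(0.7, 50, "F") == pytest.approx(141 * 0.993**50 * 1.018, rel=1e-12)
    assert egfr_ckd_epi(0.7, 50, "F") == pytest.approx(101.0, abs=0.1)
    assert egfr_ckd_epi(0.9, 50, "M") == pytest.approx(99.2, abs=0.1)
    assert egfr_ckd_epi(0.9, 50, "M", black=True) == pytest.approx(99.24 * 1.159, abs=0.1)


def test_ckd_epi_monotone_decreasing_in_creatinine():
    values = [egfr_ckd_epi(scr, 60, "M") for scr in (0.5, 0.9, 2.0, 5.0, 15.0)]
    assert np.all(np.diff(values) < 0)
    assert values[-1] < 5.0


def test_ckd_epi_domain_errors():
    with pytest.raises(RenalDwiError):
        egfr_ckd_epi(0.0, 50, "F")
    with pytest.raises(RenalDwiError):
        egfr_ckd_epi(1.0, 15, "F")


def test_creatinine_inversion_roundtrip():
    for egfr in (25.0, 60.0, 95.0, 120.0):
        for sex in ("F", "M"):
            scr = creatinine_for_egfr(egfr, 55, sex)
            assert egfr_ckd_epi(scr, 55, sex) == pytest.approx(egfr, rel=1e-10)


# ------------------------------------------------------ group comparison

def test_mann_whitney_exact_extreme_separation():
    res = group_compare([1, 2, 3], [4, 5, 6], "mannwhitney")
    assert res.test == "mannwhitney_exact"
    assert res.statistic == 0.0
    assert res.p == pytest.approx(0.1)


def test_mann_whitney_exact_identical_groups():
    res = group_compare([1, 2, 3], [1, 2, 3], "mannwhitney")
    assert res.p == 1.0


def test_mann_whitney_asymptotic_close_to_exact():
    """Tie-corrected normal approximation within 10% of exact enumeration
    on small fixtures (including ties)."""
    rng = np.random.default_rng(4)
    for n1, n2 in ((5, 5), (6, 6), (5, 7)):
        x = np.round(rng.normal(0, 1, n1), 1)
        y = np.round(rng.normal(0.8, 1, n2), 1)
        exact = group_compare(x, y, "mannwhitney")
        asym = ss.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        assert asym.pvalue == pytest.approx(exact.p, rel=0.10, abs=0.02)


def test_t_test_and_chi_square():
    res = group_compare([1.0, 2.0, 3.0, 2.5], [4.0, 5.0, 4.5, 6.0], "t")
    oracle = ss.ttest_ind([1.0, 2.0, 3.0, 2.5], [4.0, 5.0, 4.5, 6.0])
    assert res.p == pytest.approx(oracle.pvalue, rel=1e-12)
    chi = group_compare([10, 10], [10, 10], "chi2")
    assert chi.statistic == 0.0 and chi.p == 1.0
    with pytest.raises(RenalDwiError):
        group_compare([], [1.0], "mannwhitney")
    with pytest.raises(RenalDwiError):
        group_compare([2.0, 2.0], [2.0, 2.0], "t")


def test_significance_stars_bands():
    assert significance_stars(0.2) == ""
    assert significance_stars(0.04) == "*"
    assert significance_stars(0.005) == "**"
    assert significance_stars(0.0005) == "***"


# -------------------------------------------------------------- spearman

def test_spearman_monotone_pairs():
    x = np.array([1.0, 2.0, 5.0, 9.0, 12.0])
    rho, _ = spearman(x, np.exp(x))
    assert rho == pytest.approx(1.0)
    rho_rev, _ = spearman(x, x[::-1])
    assert rho_rev == pytest.approx(-1.0)


def test_spearman_matches_rank_then_pearson_oracle_under_ties():
    x = np.array([1.0, 1.0, 2.0, 3.0, 3.0, 3.0, 4.0, 5.0, 5.0, 7.0, 8.0, 8.0])
    y = np.array([2.0, 3.0, 3.0, 1.0, 5.0, 5.0, 4.0, 6.0, 6.0, 6.0, 9.0, 8.0])
    rho, _ = spearman(x, y)
    oracle = np.corrcoef(ss.rankdata(x), ss.rankdata(y))[0, 1]
    assert rho == pytest.approx(oracle, abs=1e-12)


def test_spearman_small_n_exact_p_is_valid_probability():
    rho, p = spearman([1, 2, 3, 4, 5, 6], [2, 1, 4, 3, 6, 5])
    assert 0 < p <= 1
    # the exactly monotone pair at the same n has the smallest possible p
    _, p_perfect = spearman([1, 2, 3, 4, 5, 6], [10, 20, 30, 40, 50, 60])
    assert p_perfect < p


def test_spearman_constant_vector_rejected():
    with pytest.raises(RenalDwiError):
        spearman([1, 1, 1, 1], [1, 2, 3, 4])


# ------------------------------------------------------------------- ICC

def test_icc_perfect_agreement():
    icc, band = icc_two_observer([1.0, 2.0, 3.0, 4.0, 5.0], [1.0, 2.0, 3.0, 4.0, 5.0])
    assert icc == pytest.approx(1.0)
    assert band == "good"


def test_icc_independent_noise_near_zero(rng):
    icc, band = icc_two_observer(rng.normal(0, 1, 2000), rng.normal(0, 1, 2000))
    assert abs(icc) < 0.1
    assert band == "poor"


def test_icc_matches_anova_mean_squares_on_fixture():
    """Six-subject fixture cross-checked against brute-force two-way ANOVA
    sums computed from first principles."""
    m1 = np.array([9.0, 6.0, 8.0, 7.0, 10.0, 6.0])
    m2 = np.array([2.0, 1.0, 4.0, 1.0, 5.0, 2.0])
    data = np.column_stack([m1, m2])
    n, k = data.shape
    grand = data.mean()
    msr = k * ((data.mean(axis=1) - grand) ** 2).sum() / (n - 1)
    msc = n * ((data.mean(axis=0) - grand) ** 2).sum() / (k - 1)
    mse = (
        ((data - grand) ** 2).sum()
        - (n - 1) * msr - (k - 1) * msc
    ) / ((n - 1) * (k - 1))
    expected = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    icc, _ = icc_two_observer(m1, m2)
    assert icc == pytest.approx(expected, abs=1e-12)


def test_icc_requires_five_pairs():
    with pytest.raises(RenalDwiError):
        icc_two_observer([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])


# ------------------------------------------------------------------- ROC

def test_roc_perfect_separation():
    res = roc([1.0, 2.0, 3.0, 4.0], [0, 0, 1, 1])
    assert res.auc == 1.0
    assert res.youden_j == pytest.approx(1.0)
    assert res.cutoff == 3.0
    assert res.orientation == "higher"


def test_roc_all_ties_gives_half():
    res = roc([5.0, 5.0, 5.0, 5.0], [0, 1, 0, 1])
    assert res.auc == 0.5


def test_roc_matches_brute_force_pair_counting(rng):
    """AUC equals (concordant + 0.5 ties) / (n1 n0) counted over all pairs,
    on a 200-point fixture with ties."""
    marker = np.round(rng.normal(0, 1, 200), 1)
    label = (rng.uniform(0, 1, 200) < 0.45).astype(int)
    label[:2] = [0, 1]   # both classes present
    pos = marker[label == 1]
    neg = marker[label == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    brute = wins / (len(pos) * len(neg))
    oriented = max(brute, 1 - brute)
    assert roc(marker, label).auc == pytest.approx(oriented, abs=1e-12)


def test_roc_orientation_flip_and_complement(rng):
    from renaldwi.stats import _rank_auc

    marker = rng.normal(0, 1, 60)
    label = (rng.uniform(0, 1, 60) < 0.5).astype(int)
    label[:2] = [0, 1]
    raw = _rank_auc(marker, label)
    assert _rank_auc(-marker, label) == pytest.approx(1 - raw, abs=1e-12)
    res = roc(marker, label)
    assert res.auc >= 0.5


def test_roc_invariant_under_monotone_transform(rng):
    marker = rng.normal(50, 10, 80)
    label = (marker + rng.normal(0, 8, 80) > 52).astype(int)
    label[:2] = [0, 1]
    a = roc(marker, label)
    b = roc(np.exp(marker / 20.0), label)
    assert a.auc == pytest.approx(b.auc, abs=1e-12)
    assert a.sensitivity == pytest.approx(b.sensitivity, abs=1e-12)


def test_roc_single_class_rejected():
    with pytest.raises(RenalDwiError):
        roc([1.0, 2.0], [1, 1])


def test_auc_bands():
    assert [auc_band(v) for v in (0.55, 0.65, 0.75, 0.85, 0.95)] == [
        "poor", "acceptable", "moderate", "good", "excellent",
    ]


def test_empirical_auc_converges_to_gaussian_closed_form(rng):
    """Two Gaussian groups: AUC -> Phi(dmu / sqrt(s1^2 + s2^2))."""
    mu_d, s1, s2 = 11.6, 8.5, 8.4
    x = rng.normal(0, s1, 4000)
    y = rng.normal(mu_d, s2, 4000)
    marker = np.concatenate([x, y])
    label = np.concatenate([np.zeros(4000, int), np.ones(4000, int)])
    expected = ss.norm.cdf(mu_d / np.hypot(s1, s2))
    assert roc(marker, label).auc == pytest.approx(expected, abs=0.01)


# ----------------------------------------------------------- score model

def _toy_frame(rng, n=40):
    label = np.concatenate([np.zeros(n // 2, int), np.ones(n - n // 2, int)])
    a = rng.normal(0, 1, n) + 1.2 * label
    b = rng.normal(0, 1, n) - 0.8 * label
    return pd.DataFrame({"a": a, "b": b, "label": label})


def test_single_predictor_model_preserves_marker_auc(rng):
    frame = _toy_frame(rng)
    model = fit_score_model(frame, ["a"])
    marker_auc = roc(frame["a"].to_numpy(), frame["label"].to_numpy()).auc
    score_auc = roc(model.scores, frame["label"].to_numpy()).auc
    assert score_auc == pytest.approx(marker_auc, abs=1e-12)


def test_label_as_predictor_is_perfect():
    frame = pd.DataFrame({"x": [0.0, 0.0, 1.0, 1.0], "label": [0, 0, 1, 1]})
    model = fit_score_model(frame, ["x"])
    assert roc(model.scores, frame["label"].to_numpy()).auc == 1.0


def test_ols_coefficients_match_normal_equations(rng):
    frame = _toy_frame(rng)
    model = fit_score_model(frame, ["a", "b"])
    design = np.column_stack([np.ones(len(frame)), frame["a"], frame["b"]])
    beta = np.linalg.solve(design.T @ design, design.T @ frame["label"].to_numpy())
    assert model.intercept == pytest.approx(beta[0], abs=1e-10)
    assert model.coefficients == pytest.approx(beta[1:], abs=1e-10)


def test_score_model_rejects_bad_designs(rng):
    frame = _toy_frame(rng)
    frame["a2"] = frame["a"] * 2.0
    with pytest.raises(RenalDwiError, match="collinear"):
        fit_score_model(frame, ["a", "a2"])
    frame.loc[0, "b"] = np.nan
    with pytest.raises(RenalDwiError, match="finite"):
        fit_score_model(frame, ["b"])
    with pytest.raises(RenalDwiError):
        fit_score_model(frame, ["a", "b", "a2", "label"])
    with pytest.raises(RenalDwiError, match="not in table"):
        fit_score_model(frame, ["missing"])


def test_logistic_scores_rank_like_linear(rng):
    frame = _toy_frame(rng)
    lin = fit_score_model(frame, ["a", "b"], method="linear")
    logi = fit_score_model(frame, ["a", "b"], method="logistic")
    rho, _ = spearman(lin.scores, logi.scores)
    assert rho > 0.95
    # with a single predictor the two scores are exactly rank-equivalent
    lin1 = fit_score_model(frame, ["a"], method="linear")
    logi1 = fit_score_model(frame, ["a"], method="logistic")
    rho1, _ = spearman(lin1.scores, logi1.scores)
    assert abs(rho1) == pytest.approx(1.0)
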