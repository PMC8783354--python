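"""Paired summaries, Bland-Altman agreement, correlation, Holm stepdown."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from uevnorm.errors import DomainError, InsufficientDataError
from uevnorm.stats import (
    PairedSeries,
    bland_altman,
    correlation,
    holm_bonferroni,
    paired_percent_change_summary,
    paired_test,
    percent_decrease,
)


def _series(pre, post):
    pre = np.asarray(pre, dtype=float)
    return PairedSeries([f"s{i}" for i in range(pre.size)], pre, np.asarray(post, dtype=float))


# ---- percent change -------------------------------------------------------


def test_group_mean_percent_decrease_reproduces_rounded_figure():
    # group means 91 -> 58 ml/min: a 36% decrease once rounded
    assert percent_decrease(91.0, 58.0) == pytest.approx(36.26, abs=0.01)
    assert round(percent_decrease(91.0, 58.0)) == 36


def test_identical_pre_post_zero_change():
    summary = paired_percent_change_summary(_series([3.0, 5.0, 8.0], [3.0, 5.0, 8.0]))
    assert summary.center == 0.0
    assert summary.spread_high - summary.spread_low == 0.0


def test_summary_styles_differ_and_are_labelled():
    series = _series([10.0, 100.0], [5.0, 90.0])
    individual = paired_percent_change_summary(series, "mean_sd")
    grouped = paired_percent_change_summary(series, "group_mean")
    assert individual.center == pytest.approx(30.0)  # mean of 50% and 10%
    assert grouped.center == pytest.approx(100.0 * (110.0 - 95.0) / 110.0)
    assert individual.style == "mean_sd" and grouped.style == "group_mean"


def test_median_change_tracks_known_multiplicative_shift(rng):
    """Lognormal pairs with post = delta x pre: median decrease ~ 100(1-delta)."""
    delta = 0.7
    pre = np.exp(rng.normal(27.0, 0.4, size=4000))
    post = delta * pre * np.exp(rng.normal(0.0, 0.1, size=4000))
    summary = paired_percent_change_summary(_series(pre, post), "median_iqr")
    assert summary.center == pytest.approx(100.0 * (1.0 - delta), abs=2.0)


def test_percent_change_rejects_nonpositive_pre():
    with pytest.raises(DomainError):
        paired_percent_change_summary(_series([1.0, 0.0], [1.0, 1.0]))
    with pytest.raises(InsufficientDataError):
        paired_percent_change_summary(_series([2.0], [1.0]), "median_iqr")


# ---- Bland-Altman ---------------------------------------------------------


def test_perfect_agreement():
    x = np.array([1.0, 2.0, 3.0, 4.0])
    result = bland_altman(x, x)
    assert result.bias == 0.0
    assert result.loa_upper - result.loa_lower == 0.0


def test_bland_altman_analytic_limit(rng):
    mu, sigma = 2.5, 1.2
    y = rng.normal(50.0, 5.0, size=200_000)
    x = y + rng.normal(mu, sigma, size=y.size)
    result = bland_altman(x, y)
    assert result.bias == pytest.approx(mu, abs=0.02)
    assert result.loa_lower == pytest.approx(mu - 1.96 * sigma, abs=0.03)
    assert result.loa_upper == pytest.approx(mu + 1.96 * sigma, abs=0.03)
    assert result.proportion_within_loa == pytest.approx(0.95, abs=0.005)


def test_bland_altman_antisymmetry(rng):
    x = rng.normal(10.0, 2.0, 50)
    y = rng.normal(9.0, 2.0, 50)
    ab, ba = bland_altman(x, y), bland_altman(y, x)
    assert ba.bias == pytest.approx(-ab.bias)
    assert ba.loa_lower == pytest.approx(-ab.loa_upper)
    assert ba.loa_upper == pytest.approx(-ab.loa_lower)


def test_bland_altman_log_scale_handles_proportional_error(rng):
    y = np.exp(rng.normal(25.0, 0.5, size=5000))
    x = y * np.exp(rng.normal(0.1, 0.2, size=5000))
    result = bland_altman(x, y, log_scale=True)
    assert result.bias == pytest.approx(0.1, abs=0.02)


def test_bland_altman_needs_three_pairs():
    with pytest.raises(InsufficientDataError):
        bland_altman([1.0, 2.0], [1.0, 2.0])


# ---- correlation ----------------------------------------------------------


def test_monotone_relationship_spearman_one():
    x = np.array([1.0, 2.0, 5.0, 9.0])
    assert correlation(x, np.exp(x), "spearman").coefficient == pytest.approx(1.0)


def test_perfect_negative_pearson():
    x = np.array([1.0, 2.0, 3.0, 4.0])
    assert correlation(x, -x, "pearson").coefficient == pytest.approx(-1.0)


def test_bivariate_normal_estimate(rng):
    rho = 0.6
    cov = [[1.0, rho], [rho, 1.0]]
    xy = rng.multivariate_normal([0, 0], cov, size=10_000)
    result = correlation(xy[:, 0], xy[:, 1], "pearson")
    assert result.coefficient == pytest.approx(rho, abs=0.03)
    assert result.pvalue < 1e-10


def test_zero_variance_undefined():
    with pytest.raises(DomainError):
        correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


# ---- Holm-Bonferroni ------------------------------------------------------


def test_holm_hand_worked_example():
    result = holm_bonferroni([0.01, 0.04])
    assert result.adjusted == pytest.approx([0.02, 0.04])


@pytest.mark.parametrize(
    "pvalues, expected",
    [
        ([0.2], [0.2]),  # single test unchanged
        ([1.0, 1.0, 1.0], [1.0, 1.0, 1.0]),
        ([0.01, 0.005, 0.04], [0.02, 0.015, 0.04]),
    ],
)
def test_holm_examples(pvalues, expected):
    assert holm_bonferroni(pvalues).adjusted == pytest.approx(expected)


@given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=12))
def test_holm_dominates_bonferroni_and_respects_raw_p(pvalues):
    """Holm rejects a superset of Bonferroni and never rejects when the
    unadjusted p already exceeds alpha."""
    alpha = 0.05
    result = holm_bonferroni(pvalues, alpha=alpha)
    m = len(pvalues)
    for p, adj, rejected in zip(pvalues, result.adjusted, result.reject):
        if min(1.0, p * m) <= alpha:  # Bonferroni rejection
            assert rejected
        if p > alpha:
            assert not rejected
        assert adj >= p - 1e-12


def test_holm_rejects_bad_pvalues():
    with pytest.raises(DomainError):
        holm_bonferroni([0.5, 1.5])


# ---- test-choice contract -------------------------------------------------


def test_paired_test_choice_by_normality(rng):
    normal_diff = _series(rng.normal(10, 1, 40), rng.normal(9, 1, 40))
    assert paired_test(normal_diff).test == "paired_t"
    skewed = np.exp(rng.normal(0, 1, 40))
    skewed_series = _series(skewed + 10, 10 + np.zeros(40))
    assert paired_test(skewed_series).test == "wilcoxon"


def test_wilcoxon_null_rejection_near_alpha(rng):
    """Under no pre/post shift the delegated Wilcoxon test rejects at
    about the nominal 5% level."""
    rejections = 0
    reps = 400
    for _ in range(reps):
        pre = np.exp(rng.normal(0.0, 0.5, size=20))
        post = pre * np.exp(rng.normal(0.0, 0.3, size=20))
        from scipy.stats import wilcoxon

        rejections += wilcoxon(pre, post).pvalue <= 0.05
    rate = rejections / reps
    assert rate == pytest.approx(0.05, abs=0.04)
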