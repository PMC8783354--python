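"""CD9 gating threshold and size-distribution metrics."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from uevnorm.errors import DomainError, InsufficientDataError
from uevnorm.quantification import (
    BIN_EDGES,
    IntensitySample,
    SizeDistribution,
    cd9_threshold,
    classify_cd9,
    size_metrics,
)


def test_threshold_is_mean_plus_three_sample_sd():
    control = IntensitySample(np.array([90.0, 100.0, 110.0]), label="control")
    assert cd9_threshold(control) == pytest.approx(100.0 + 3.0 * 10.0)


def test_constant_control_threshold_is_the_constant():
    control = IntensitySample(np.full(50, 42.0), label="control")
    assert cd9_threshold(control) == pytest.approx(42.0)


def test_threshold_needs_two_particles():
    with pytest.raises(InsufficientDataError):
        cd9_threshold(IntensitySample(np.array([1.0]), label="control"))


def test_control_tail_above_threshold(rng):
    """For a large Gaussian control, ~0.13% of control particles exceed
    the mean + 3 SD threshold (the upper normal tail)."""
    control = IntensitySample(rng.normal(100.0, 12.0, size=400_000), label="control")
    threshold = cd9_threshold(control)
    frac_above = classify_cd9(control, threshold).cd9_pos_fraction
    assert frac_above == pytest.approx(0.00135, abs=3e-4)


def test_classification_partitions_and_tie_rule():
    sample = IntensitySample(np.array([1.0, 2.0, 3.0, 3.0, 4.0]))
    result = classify_cd9(sample, threshold=3.0)
    assert result.cd9_pos_count == 1  # ties count as negative
    assert result.cd9_neg_count == 4
    assert result.cd9_pos_count + result.cd9_neg_count == 5
    assert result.cd9_pos_fraction == pytest.approx(0.2)


@pytest.mark.parametrize("shift, expected", [(-10.0, 0.0), (10.0, 1.0)])
def test_all_below_or_above(shift, expected):
    values = np.linspace(1, 5, 20)
    sample = IntensitySample(values + shift)
    assert classify_cd9(sample, 5.5).cd9_pos_fraction == expected


def test_known_mixture_fraction_recovered(rng):
    """30% of particles carry a well-separated positive component."""
    n = 100_000
    labels = rng.random(n) < 0.30
    intensities = np.where(labels, rng.normal(300.0, 20.0, n), rng.normal(100.0, 10.0, n))
    control = IntensitySample(rng.normal(100.0, 10.0, n), label="control")
    result = classify_cd9(IntensitySample(intensities), cd9_threshold(control))
    assert result.cd9_pos_fraction == pytest.approx(0.30, abs=0.01)


@given(scale=st.floats(min_value=0.01, max_value=100.0), offset=st.floats(-50, 50))
def test_classification_invariant_under_monotone_rescaling(scale, offset):
    values = np.array([1.0, 2.0, 5.0, 7.0, 11.0])
    threshold = 4.0
    base = classify_cd9(IntensitySample(values), threshold)
    rescaled = classify_cd9(IntensitySample(values * scale + offset), threshold * scale + offset)
    assert rescaled.cd9_pos_count == base.cd9_pos_count
    assert rescaled.cd9_neg_count == base.cd9_neg_count


def test_histogram_conservation(rng):
    """Sum over bins plus overflow equals retained count / creatinine."""
    diameters = rng.uniform(40.0, 1200.0, size=5000)
    creat = 7.5
    metrics = size_metrics(diameters, creat)
    retained = np.sum(diameters >= 70.0)
    assert metrics.distribution.total_per_creat == pytest.approx(retained / creat, rel=1e-12)


def test_grid_convention():
    """Half-open 1-nm bins from 70 nm; >= 1000 nm pools into overflow."""
    metrics = size_metrics([69.9, 70.0, 70.999, 71.0, 999.9, 1000.0, 2000.0], creat_conc=1.0)
    dist = metrics.distribution
    assert dist.counts_per_creat[0] == 2  # [70, 71) holds 70.0 and 70.999
    assert dist.counts_per_creat[1] == 1  # [71, 72)
    assert dist.counts_per_creat[-1] == 1  # [999, 1000)
    assert dist.overflow_per_creat == 2
    assert dist.total_per_creat == 6  # the 69.9 nm particle is below detection
    assert BIN_EDGES[0] == 70.0 and BIN_EDGES[-1] == 1000.0


def test_all_small_particles_sub150_fraction_one():
    metrics = size_metrics(np.full(100, 100.0), creat_conc=2.0)
    assert metrics.sub_150_fraction == 1.0


def test_identical_distributions_zero_change(rng):
    diameters = rng.uniform(80.0, 300.0, size=2000)
    ref = size_metrics(diameters, 5.0).distribution
    change = size_metrics(diameters, 5.0, reference=ref).percent_change_per_bin
    defined = ~np.isnan(change)
    assert np.allclose(change[defined], 0.0)
    # bins with zero reference are undefined, not infinite
    assert np.all(np.isnan(change[~defined]))


def test_selective_thinning_below_150nm(rng):
    """Thinning only the sub-150-nm particles by 26% shows up as about
    -26% change restricted to those bins."""
    diameters = rng.uniform(75.0, 400.0, size=400_000)
    ref = size_metrics(diameters, 1.0).distribution
    small = diameters < 150.0
    keep = np.ones(diameters.size, dtype=bool)
    keep[small] = rng.random(small.sum()) > 0.26
    post = size_metrics(diameters[keep], 1.0, reference=ref)
    change = post.percent_change_per_bin
    centers = (BIN_EDGES[:-1] + BIN_EDGES[1:]) / 2
    in_range = (centers > 75.0) & (centers < 400.0)
    below = in_range & (BIN_EDGES[:-1] < 150.0) & (BIN_EDGES[1:] <= 150.0)
    above = in_range & (BIN_EDGES[:-1] >= 150.0)
    assert np.nanmean(change[below]) == pytest.approx(-26.0, abs=2.0)
    assert np.nanmean(change[above]) == pytest.approx(0.0, abs=2.0)


@pytest.mark.parametrize(
    "call",
    [
        lambda: size_metrics([], 5.0),
        lambda: size_metrics([50.0, 60.0], 5.0),  # nothing above detection limit
        lambda: size_metrics([100.0], 0.0),
        lambda: classify_cd9(IntensitySample([1.0]), np.inf),
        lambda: IntensitySample([np.nan]),
        lambda: SizeDistribution(np.full(10, 1.0)),  # wrong grid length
    ],
)
def test_invalid_inputs(call):
    with pytest.raises((DomainError, InsufficientDataError)):
        call()
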