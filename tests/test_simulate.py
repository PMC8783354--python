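"""Generative-model contracts of the synthetic cohort and rat study."""

import numpy as np
import pandas as pd
import pytest

import uevnorm
from uevnorm.errors import ConfigurationError
from uevnorm.io import donors_to_frame, rats_to_frame, samples_to_frame


def test_zero_noise_identity(noise_free_cfg):
    """kappa = 1e8, TKV = 300 ml, no noise -> exactly 3e10 uEVs/day."""
    cfg = noise_free_cfg
    cfg.uev_per_nephron_mass = 1e8
    cfg.female_kappa_scale = 1.0
    cfg.tkv_mean = {"M": 300.0, "F": 300.0}
    cohort = uevnorm.simulate_donor_cohort(cfg)
    for donor in cohort.donors:
        assert donor.true_uev_excretion == 3e10


def test_same_seed_identical_tables(default_cfg):
    a = uevnorm.simulate_donor_cohort(default_cfg)
    b = uevnorm.simulate_donor_cohort(default_cfg)
    pd.testing.assert_frame_equal(donors_to_frame(a.donors), donors_to_frame(b.donors))
    pd.testing.assert_frame_equal(samples_to_frame(a.samples), samples_to_frame(b.samples))
    ra = rats_to_frame(uevnorm.simulate_rat_study(default_cfg))
    rb = rats_to_frame(uevnorm.simulate_rat_study(default_cfg))
    pd.testing.assert_frame_equal(ra, rb)
    assert ra.to_csv() == rb.to_csv()  # byte-identical serialization


def test_sex_gap_matches_calibration():
    """At the default calibration the female median daily excretion sits
    about 49% below the male median (within 10 percentage points)."""
    cfg = uevnorm.default_config(seed=11)
    cfg.n_donors = 200
    cohort = uevnorm.simulate_donor_cohort(cfg)
    by_sex = {}
    for sex in ("M", "F"):
        by_sex[sex] = np.median(
            [d.true_uev_excretion for d in cohort.donors if d.sex == sex]
        )
    gap = 100.0 * (1.0 - by_sex["F"] / by_sex["M"])
    assert gap == pytest.approx(49.0, abs=10.0)


def test_kappa_monotonicity(default_cfg):
    """Raising kappa raises every subject's excretion, all else fixed."""
    lo = uevnorm.simulate_donor_cohort(default_cfg)
    hi_cfg = uevnorm.default_config(seed=default_cfg.seed)
    hi_cfg.uev_per_nephron_mass = default_cfg.uev_per_nephron_mass * 1.5
    hi = uevnorm.simulate_donor_cohort(hi_cfg)
    for a, b in zip(lo.donors, hi.donors):
        assert b.true_uev_excretion > a.true_uev_excretion
        assert b.true_uev_excretion_post > a.true_uev_excretion_post


def test_cd9_fraction_shifts_down_after_nephrectomy(default_cfg):
    """h_proximal > h_distal makes the CD9+ share of uEVs fall post-surgery."""
    assert default_cfg.h_proximal > default_cfg.h_distal
    cohort = uevnorm.simulate_donor_cohort(default_cfg)
    for donor in cohort.donors:
        assert donor.cd9_pos_fraction_post < donor.cd9_pos_fraction


def test_spot_concentrations_positively_correlated(default_cfg):
    """Shared urine flow induces a positive within-cohort correlation
    between spot creatinine and spot uEV concentration."""
    cfg = default_cfg
    cfg.n_donors = 80
    cohort = uevnorm.simulate_donor_cohort(cfg)
    spots = [s for s in cohort.samples if s.kind == "spot" and s.phase == "pre"]
    r = uevnorm.correlation(
        [s.creat_conc for s in spots], [s.uev_conc for s in spots], "pearson"
    )
    assert r.coefficient > 0.3


def test_noise_free_spot_round_trip(noise_free_cfg):
    """Noise-free spot samples invert exactly to the latent excretion."""
    cohort = uevnorm.simulate_donor_cohort(noise_free_cfg)
    for donor in cohort.donors:
        (spot,) = [s for s in cohort.samples_for(donor.id, "pre") if s.kind == "spot"]
        rate = uevnorm.calculated_spot_excretion(
            spot.uev_conc, spot.creat_conc, donor.creat_excretion
        )
        assert rate.per_day == pytest.approx(donor.true_uev_excretion, rel=1e-12)


def test_rat_unit_hypertrophy_forces_half_excretion(noise_free_cfg):
    """h = 1 everywhere and no growth: UNX post excretion is exactly half."""
    cfg = noise_free_cfg
    cfg.rat.hypertrophy_factor = {"sham": 1.0, "UNX": 1.0, "5/6NX": 1.0}
    cfg.rat.sham_growth_factor = 1.0
    cfg.rat.sham_uev_growth = 1.0
    for rat in uevnorm.simulate_rat_study(cfg):
        if rat.group == "UNX":
            assert rat.uev_excretion_post == pytest.approx(0.5 * rat.uev_excretion_pre, rel=1e-12)


def test_rat_56nx_model_arithmetic(noise_free_cfg):
    """h = 4 for 5/6NX gives post = (1/6) x 4 = 2/3 of baseline."""
    cfg = noise_free_cfg
    for rat in uevnorm.simulate_rat_study(cfg):
        if rat.group == "5/6NX":
            assert rat.uev_excretion_post == pytest.approx(
                (1.0 / 6.0) * 4.0 * rat.uev_excretion_pre, rel=1e-12
            )


def test_hypertrophy_recovery_is_unbiased():
    """Across many seeded studies at default noise the estimated change
    factor recovers the configured hypertrophy factor with <5% bias."""
    per_group = {"UNX": [], "5/6NX": []}
    for seed in range(120):
        cfg = uevnorm.default_config(seed=seed)
        estimates = uevnorm.estimate_rat_hypertrophy(uevnorm.simulate_rat_study(cfg))
        for group, values in per_group.items():
            values.append(
                estimates.loc[estimates["group"] == group, "uev_change_factor"].mean()
            )
    cfg = uevnorm.default_config()
    for group, values in per_group.items():
        configured = cfg.rat.hypertrophy_factor[group]
        bias = abs(np.mean(values) - configured) / configured
        assert bias < 0.05


@pytest.mark.parametrize(
    "mutate, field_name",
    [
        (lambda c: setattr(c, "n_donors", 0), "n_donors"),
        (lambda c: setattr(c, "sex_ratio_female", 1.4), "sex_ratio_female"),
        (lambda c: setattr(c, "h_proximal", 0.5), "h_proximal"),
        (lambda c: c.tkv_sd.update({"F": -1.0}), "tkv_sd"),
        (lambda c: c.rat.n_per_group.update({"UNX": 0}), "n_per_group"),
        (lambda c: c.rat.hypertrophy_factor.update({"5/6NX": 0.9}), "hypertrophy_factor"),
    ],
)
def test_invalid_config_names_field(mutate, field_name):
    cfg = uevnorm.default_config()
    mutate(cfg)
    with pytest.raises(ConfigurationError, match=field_name):
        cfg.validate()


def test_defaults_yaml_matches_dataclass_defaults():
    """The versioned defaults file and the in-code defaults are one
    calibration, not two."""
    assert uevnorm.default_config(seed=0) == uevnorm.SimulationConfig().validate()
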