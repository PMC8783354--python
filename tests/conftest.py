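import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import uevnorm

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20220122)


@pytest.fixture
def default_cfg():
    return uevnorm.default_config(seed=7)


@pytest.fixture
def noise_free_cfg():
    """A fully deterministic configuration: every SD / sigma is zero."""
    cfg = uevnorm.default_config(seed=0)
    cfg.tkv_sd = {"M": 0.0, "F": 0.0}
    cfg.creat_excretion_sd = {"M": 0.0, "F": 0.0}
    cfg.egfr_sd = {"M": 0.0, "F": 0.0}
    cfg.creat_clearance_sd = {"M": 0.0, "F": 0.0}
    cfg.kidney_split_sd = 0.0
    cfg.uev_noise_sd = 0.0
    cfg.measurement_noise_sd = 0.0
    cfg.urine_volume_sd = 0.0
    cfg.egfr_post_factor_sd = 0.0
    cfg.rat.kidney_weight_sd = 0.0
    cfg.rat.gfr_sd = 0.0
    cfg.rat.gfr_noise_sd = 0.0
    cfg.rat.uev_excretion_sd = 0.0
    cfg.rat.body_weight_gain_sd = 0.0
    cfg.rat.weight_noise_sd = 0.0
    cfg.rat.uev_noise_sd = 0.0
    return cfg


@pytest.fixture
def rat_cohort(default_cfg):
    return uevnorm.simulate_rat_study(default_cfg)
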