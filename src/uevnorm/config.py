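"""Simulation configuration with study-calibrated defaults.

The defaults encode the statistical structure of a paired donor-
nephrectomy cohort and a rat nephrectomy study: sex-dependent total
kidney volume (TKV) and creatinine excretion, uEV excretion
proportional to nephron mass with lognormal noise, spot and 24-h
sampling linked by urine flow, and segment-specific compensatory
hypertrophy after nephron loss. The packaged ``data/defaults.yaml``
records the same values; any field can be overridden from a user YAML
or JSON file.

Distributional choices: quantities that must stay positive and are
right-skewed in practice (urine flow, uEV noise) are lognormal;
physiological means with modest spread (TKV, creatinine excretion,
kidney weight, GFR) are normal truncated at zero.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Dict, Mapping, Union

import yaml

from .errors import ConfigurationError

RAT_GROUPS = ("sham", "UNX", "5/6NX")


@dataclass
class RatArmConfig:
    """Rat nephrectomy arm: group sizes, baselines and effect factors.

    ``hypertrophy_factor`` is the fold growth of the remnant tissue
    (weight and per-nephron uEV output alike); ``kidney_fraction`` is
    the fraction of the tracked remnant kidney left in place and
    ``nephron_fraction`` the fraction of all nephrons, assuming two
    equally contributing kidneys. Sham animals keep everything but grow:
    the sham growth factors for kidney weight and uEV excretion are
    independent dials because whole-animal growth need not move both
    proportionally.
    """

    n_per_group: Dict[str, int] = field(
        default_factory=lambda: {"sham": 10, "UNX": 8, "5/6NX": 8}
    )
    kidney_weight_mean: float = 1.2  # g, at uninephrectomy
    kidney_weight_sd: float = 0.1
    gfr_mean: float = 3.2  # ml/min, FITC-sinistrin clearance at baseline
    gfr_sd: float = 0.6
    gfr_change_factor: Dict[str, float] = field(
        default_factory=lambda: {"sham": 1.54, "UNX": 1.16, "5/6NX": 0.39}
    )
    gfr_noise_sd: float = 0.10  # lognormal sigma on the post/pre GFR ratio
    uev_excretion_mean: float = 7.5e11  # uEVs/day at baseline
    uev_excretion_sd: float = 1.3e11
    hypertrophy_factor: Dict[str, float] = field(
        default_factory=lambda: {"sham": 1.0, "UNX": 1.4, "5/6NX": 4.0}
    )
    sham_growth_factor: float = 1.4  # fold kidney-weight growth in sham animals
    sham_uev_growth: float = 1.33  # fold uEV-excretion growth in sham animals
    kidney_fraction: Dict[str, float] = field(
        default_factory=lambda: {"sham": 1.0, "UNX": 1.0, "5/6NX": 1.0 / 3.0}
    )
    nephron_fraction: Dict[str, float] = field(
        default_factory=lambda: {"sham": 1.0, "UNX": 0.5, "5/6NX": 1.0 / 6.0}
    )
    body_weight_gain_mean: Dict[str, float] = field(
        default_factory=lambda: {"sham": 183.0, "UNX": 186.0, "5/6NX": 145.0}
    )
    body_weight_gain_sd: float = 21.0  # g
    weight_noise_sd: float = 0.05  # lognormal sigma on terminal kidney weight
    uev_noise_sd: float = 0.08  # lognormal sigma on post uEV excretion

    def validate(self) -> None:
        for group in RAT_GROUPS:
            for name in (
                "n_per_group",
                "gfr_change_factor",
                "hypertrophy_factor",
                "kidney_fraction",
                "nephron_fraction",
                "body_weight_gain_mean",
            ):
                if group not in getattr(self, name):
                    raise ConfigurationError(f"rat.{name} is missing group {group!r}")
        for group, n in self.n_per_group.items():
            if n <= 0:
                raise ConfigurationError(f"rat.n_per_group[{group!r}] must be > 0, got {n}")
        for group, h in self.hypertrophy_factor.items():
            if h < 1:
                raise ConfigurationError(
                    f"rat.hypertrophy_factor[{group!r}] must be >= 1, got {h}"
                )
        for name in ("kidney_fraction", "nephron_fraction"):
            for group, frac in getattr(self, name).items():
                if not 0 < frac <= 1:
                    raise ConfigurationError(
                        f"rat.{name}[{group!r}] must lie in (0, 1], got {frac}"
                    )
        for name in (
            "kidney_weight_sd",
            "gfr_sd",
            "gfr_noise_sd",
            "uev_excretion_sd",
            "body_weight_gain_sd",
            "weight_noise_sd",
            "uev_noise_sd",
        ):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"rat.{name} must be >= 0, got {getattr(self, name)}")
        for name in ("kidney_weight_mean", "gfr_mean", "uev_excretion_mean"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"rat.{name} must be > 0, got {getattr(self, name)}")
        if self.sham_growth_factor < 1 or self.sham_uev_growth < 1:
            raise ConfigurationError("rat.sham_growth_factor and rat.sham_uev_growth must be >= 1")


@dataclass
class SimulationConfig:
    """Human-donor cohort (plus rat arm) generative parameters.

    uEV production is proportional to nephron mass: a donor's latent
    daily excretion is ``kappa x TKV x lognormal noise``, with
    ``female_kappa_scale`` shrinking the per-millilitre rate in women —
    nephron endowment per unit kidney volume is lower, so the sex gap in
    excretion exceeds the sex gap in TKV. Spot concentrations are daily
    amounts divided by a simulated urine flow, which makes spot uEV and
    creatinine concentrations positively correlated within a subject.
    After a nephrectomy the latent excretion is scaled by the remaining
    nephron fraction times a segment-weighted hypertrophy factor, with
    proximal (CD9-) tissue hypertrophying more than distal (CD9+), so
    the CD9+ fraction of uEVs drifts downward post-surgery.
    """

    seed: int = 0
    n_donors: int = 19
    sex_ratio_female: float = 12.0 / 19.0
    tkv_mean: Dict[str, float] = field(default_factory=lambda: {"M": 351.0, "F": 300.0})
    tkv_sd: Dict[str, float] = field(default_factory=lambda: {"M": 37.0, "F": 57.0})
    kidney_split_sd: float = 0.03  # SD of the removed-volume fraction
    creat_excretion_mean: Dict[str, float] = field(
        default_factory=lambda: {"M": 17.1, "F": 9.0}
    )  # mmol/day
    creat_excretion_sd: Dict[str, float] = field(default_factory=lambda: {"M": 1.3, "F": 2.6})
    egfr_mean: Dict[str, float] = field(default_factory=lambda: {"M": 99.0, "F": 89.0})
    egfr_sd: Dict[str, float] = field(default_factory=lambda: {"M": 18.0, "F": 25.0})
    creat_clearance_mean: Dict[str, float] = field(
        default_factory=lambda: {"M": 128.0, "F": 99.0}
    )
    creat_clearance_sd: Dict[str, float] = field(default_factory=lambda: {"M": 7.0, "F": 33.0})
    uev_per_nephron_mass: float = 1.225e8  # kappa: uEVs/day per ml TKV (male)
    female_kappa_scale: float = 0.599  # female kappa = scale x male kappa
    uev_noise_sd: float = 0.30  # lognormal sigma on latent excretion
    measurement_noise_sd: float = 0.10  # lognormal sigma on measured uEV concentration
    spot_flow_median: float = 1.5  # L/day equivalent urine flow at the spot void
    spot_flow_sigma: float = 0.4  # lognormal sigma of the spot flow
    urine_volume_mean: float = 2.0  # L, 24-h collection
    urine_volume_sd: float = 0.75
    nephrectomy_fraction_removed: float = 0.5
    h_proximal: float = 2.0  # fold hypertrophy of proximal (CD9-) output
    h_distal: float = 1.4  # fold hypertrophy of distal (CD9+) output
    cd9_pos_fraction: float = 0.6  # baseline CD9+ share of uEVs
    egfr_post_factor_mean: float = 0.64  # post/pre eGFR ratio
    egfr_post_factor_sd: float = 0.10
    rat: RatArmConfig = field(default_factory=RatArmConfig)

    def __post_init__(self) -> None:
        if isinstance(self.rat, dict):
            self.rat = RatArmConfig(**self.rat)

    def validate(self) -> "SimulationConfig":
        """Check every invariant; raise ConfigurationError naming the field."""
        if self.n_donors <= 0:
            raise ConfigurationError(f"n_donors must be > 0, got {self.n_donors}")
        for name in ("sex_ratio_female", "cd9_pos_fraction"):
            value = getattr(self, name)
            if not 0 <= value <= 1:
                raise ConfigurationError(f"{name} must lie in [0, 1], got {value}")
        if not 0 < self.nephrectomy_fraction_removed < 1:
            raise ConfigurationError(
                "nephrectomy_fraction_removed must lie in (0, 1), got "
                f"{self.nephrectomy_fraction_removed}"
            )
        for name in ("h_proximal", "h_distal"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1, got {getattr(self, name)}")
        for name in ("tkv_mean", "tkv_sd", "creat_excretion_mean", "creat_excretion_sd",
                     "egfr_mean", "egfr_sd", "creat_clearance_mean", "creat_clearance_sd"):
            mapping = getattr(self, name)
            for sex in ("M", "F"):
                if sex not in mapping:
                    raise ConfigurationError(f"{name} is missing sex {sex!r}")
                if name.endswith("_sd") and mapping[sex] < 0:
                    raise ConfigurationError(f"{name}[{sex!r}] must be >= 0, got {mapping[sex]}")
                if name.endswith("_mean") and mapping[sex] <= 0:
                    raise ConfigurationError(f"{name}[{sex!r}] must be > 0, got {mapping[sex]}")
        for name in ("uev_per_nephron_mass", "female_kappa_scale", "spot_flow_median",
                     "urine_volume_mean", "egfr_post_factor_mean"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0, got {getattr(self, name)}")
        for name in ("uev_noise_sd", "measurement_noise_sd", "spot_flow_sigma",
                     "urine_volume_sd", "kidney_split_sd", "egfr_post_factor_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0, got {getattr(self, name)}")
        self.rat.validate()
        return self

    def kappa_for_sex(self, sex: str) -> float:
        return self.uev_per_nephron_mass * (self.female_kappa_scale if sex == "F" else 1.0)

    # ---- serialization -------------------------------------------------

    def to_dict(self) -> Dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: Mapping) -> "SimulationConfig":
        base = cls()
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ConfigurationError(f"unknown configuration field(s): {sorted(unknown)}")
        merged = dataclasses.asdict(base)
        for key, value in data.items():
            if key == "rat" and isinstance(value, Mapping):
                rat_unknown = set(value) - {f.name for f in dataclasses.fields(RatArmConfig)}
                if rat_unknown:
                    raise ConfigurationError(
                        f"unknown rat configuration field(s): {sorted(rat_unknown)}"
                    )
                merged["rat"].update(value)
            else:
                merged[key] = value
        config = cls(**{k: v for k, v in merged.items() if k != "rat"}, rat=RatArmConfig(**merged["rat"]))
        return config.validate()

    @classmethod
    def from_file(cls, path: Union[str, Path]) -> "SimulationConfig":
        """Load from a YAML or JSON file (YAML parses JSON too)."""
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        if data is None:
            data = {}
        if not isinstance(data, Mapping):
            raise ConfigurationError(f"configuration file {path} must contain a mapping")
        return cls.from_dict(data)

    def to_yaml(self, path: Union[str, Path]) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    def sha256(self) -> str:
        import hashlib

        canonical = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()


def default_config(seed: int = 0) -> SimulationConfig:
    """The packaged calibration (``data/defaults.yaml``) with a chosen seed."""
    with resources.files("uevnorm.data").joinpath("defaults.yaml").open() as handle:
        data = yaml.safe_load(handle)
    data["seed"] = seed
    return SimulationConfig.from_dict(data)
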