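"""Synthetic donor cohorts and rat nephrectomy studies.

The generator produces data with the statistical structure the
downstream analysis assumes, so every stage of the pipeline is testable
without access to clinical data:

* a donor's latent 24-h uEV excretion is proportional to total kidney
  volume (``kappa x TKV``) with lognormal biological noise;
* spot and 24-h samples of the same donor share the latent daily
  amounts, divided by the urine flow of the collection — which makes
  spot uEV and creatinine concentrations positively correlated within
  a subject and makes the creatinine-based spot extrapolation exact in
  the noise-free limit;
* donor nephrectomy removes a fraction of nephron mass; the remnant
  responds with segment-specific compensatory hypertrophy (proximal,
  CD9-negative tissue more than distal, CD9-positive tissue), so total
  excretion falls by less than the nephron loss and the CD9+ fraction
  of uEVs drifts downward;
* the rat arm applies the same projection model to kidney weights and
  excretion in sham / uninephrectomy / 5/6th-nephrectomy groups.

All randomness flows from a single :class:`numpy.random.Generator`
seeded by ``config.seed``; the same seed yields byte-identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np
from scipy import stats as sps

from .config import RAT_GROUPS, SimulationConfig
from .errors import DomainError
from .normalization import MINUTES_PER_DAY, UrineSample

__all__ = ["Donor", "RatSubject", "DonorCohort", "simulate_donor_cohort", "simulate_rat_study"]


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float, low: float = 0.0) -> float:
    """Normal(mean, sd) truncated below at ``low``; degenerate when sd == 0."""
    if sd == 0:
        return mean
    a = (low - mean) / sd
    return float(sps.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, random_state=rng))


def _lognormal_factor(rng: np.random.Generator, sigma: float) -> float:
    """exp(Normal(0, sigma)); exactly 1 when sigma == 0 (median-preserving)."""
    if sigma == 0:
        return 1.0
    return float(np.exp(rng.normal(0.0, sigma)))


@dataclass
class Donor:
    """One human kidney donor with latent (simulation-only) excretion."""

    id: str
    sex: str  # "M" | "F"
    tkv_left: float  # ml
    tkv_right: float  # ml
    egfr: float  # ml/min, BSA-adjusted (consumed, never computed here)
    creatinine_clearance: float  # ml/min
    creat_excretion: float  # mmol/day
    true_uev_excretion: float  # uEVs/day, latent
    cd9_pos_fraction: float
    # post-nephrectomy latent state
    true_uev_excretion_post: float
    cd9_pos_fraction_post: float
    egfr_post: float
    removed_side: str  # "left" | "right"

    def __post_init__(self) -> None:
        if self.sex not in ("M", "F"):
            raise DomainError(f"sex must be 'M' or 'F', got {self.sex!r}")
        for name in ("tkv_left", "tkv_right", "creat_excretion", "true_uev_excretion"):
            if not getattr(self, name) > 0:
                raise DomainError(f"{name} must be > 0, got {getattr(self, name)}")
        if not 0 <= self.cd9_pos_fraction <= 1:
            raise DomainError(f"cd9_pos_fraction must lie in [0, 1], got {self.cd9_pos_fraction}")

    @property
    def tkv(self) -> float:
        """Total kidney volume (ml), both kidneys."""
        return self.tkv_left + self.tkv_right

    @property
    def tkv_removed(self) -> float:
        return self.tkv_left if self.removed_side == "left" else self.tkv_right

    @property
    def tkv_remaining(self) -> float:
        return self.tkv_right if self.removed_side == "left" else self.tkv_left


@dataclass
class RatSubject:
    """One animal of the rat nephrectomy study."""

    id: str
    group: str  # "sham" | "UNX" | "5/6NX"
    kidney_weight_at_unx: float  # g
    terminal_kidney_weight: float  # g
    gfr_pre: float  # ml/min
    gfr_post: float
    uev_excretion_pre: float  # uEVs/day
    uev_excretion_post: float
    body_weight_gain: float  # g

    def __post_init__(self) -> None:
        if self.group not in RAT_GROUPS:
            raise DomainError(f"group must be one of {RAT_GROUPS}, got {self.group!r}")
        for name in (
            "kidney_weight_at_unx",
            "terminal_kidney_weight",
            "uev_excretion_pre",
            "uev_excretion_post",
        ):
            if not getattr(self, name) > 0:
                raise DomainError(f"{name} must be > 0, got {getattr(self, name)}")


@dataclass
class DonorCohort:
    """Simulated donors with their paired pre/post urine samples."""

    donors: List[Donor]
    samples: List[UrineSample]
    config: SimulationConfig = field(repr=False, default=None)  # type: ignore[assignment]

    def samples_for(self, donor_id: str, phase: Optional[str] = None) -> List[UrineSample]:
        return [
            s
            for s in self.samples
            if s.subject_id == donor_id and (phase is None or s.phase == phase)
        ]


def _segment_weighted_hypertrophy(config: SimulationConfig) -> float:
    """Overall fold output change of the remnant: CD9 shares weight the
    proximal and distal hypertrophy factors."""
    p = config.cd9_pos_fraction
    return (1.0 - p) * config.h_proximal + p * config.h_distal


def simulate_donor_cohort(
    config: SimulationConfig, rng: Optional[np.random.Generator] = None
) -> DonorCohort:
    """Generate a donor cohort with paired pre/post spot and 24-h samples.

    Per donor and phase one complete 24-h collection and one spot urine
    are produced. Measured uEV concentrations carry multiplicative
    lognormal measurement noise (``measurement_noise_sd``); with all
    noise parameters at zero the samples invert exactly to the latent
    excretion through the normalization operations.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)

    donors: List[Donor] = []
    samples: List[UrineSample] = []
    weighted_h = _segment_weighted_hypertrophy(config)
    p = config.cd9_pos_fraction
    cd9_post = p * config.h_distal / weighted_h if weighted_h > 0 else p

    for i in range(config.n_donors):
        sex = "F" if rng.random() < config.sex_ratio_female else "M"
        tkv_total = _truncated_normal(rng, config.tkv_mean[sex], config.tkv_sd[sex], low=50.0)
        removed_fraction = float(
            np.clip(
                rng.normal(config.nephrectomy_fraction_removed, config.kidney_split_sd)
                if config.kidney_split_sd > 0
                else config.nephrectomy_fraction_removed,
                0.02,
                0.98,
            )
        )
        removed_side = "left" if rng.random() < 0.5 else "right"
        tkv_removed = tkv_total * removed_fraction
        tkv_remaining = tkv_total - tkv_removed
        tkv_left, tkv_right = (
            (tkv_removed, tkv_remaining) if removed_side == "left" else (tkv_remaining, tkv_removed)
        )

        creat_excretion = _truncated_normal(
            rng, config.creat_excretion_mean[sex], config.creat_excretion_sd[sex], low=1.0
        )
        egfr = _truncated_normal(rng, config.egfr_mean[sex], config.egfr_sd[sex], low=10.0)
        crcl = _truncated_normal(
            rng, config.creat_clearance_mean[sex], config.creat_clearance_sd[sex], low=10.0
        )

        true_uev = config.kappa_for_sex(sex) * tkv_total * _lognormal_factor(rng, config.uev_noise_sd)
        # (1 - removed_fraction) is the per-donor nephron fraction kept;
        # the remnant's output is scaled by the segment-weighted hypertrophy.
        true_uev_post = true_uev * (1.0 - removed_fraction) * weighted_h
        egfr_post = egfr * _truncated_normal(
            rng, config.egfr_post_factor_mean, config.egfr_post_factor_sd, low=0.05
        )

        donor = Donor(
            id=f"D{i + 1:03d}",
            sex=sex,
            tkv_left=tkv_left,
            tkv_right=tkv_right,
            egfr=egfr,
            creatinine_clearance=crcl,
            creat_excretion=creat_excretion,
            true_uev_excretion=true_uev,
            cd9_pos_fraction=p,
            true_uev_excretion_post=true_uev_post,
            cd9_pos_fraction_post=cd9_post,
            egfr_post=egfr_post,
            removed_side=removed_side,
        )
        donors.append(donor)

        for phase, excretion, cd9 in (
            ("pre", true_uev, p),
            ("post", true_uev_post, cd9_post),
        ):
            volume = _truncated_normal(rng, config.urine_volume_mean, config.urine_volume_sd, low=0.2)
            samples.append(
                UrineSample(
                    subject_id=donor.id,
                    phase=phase,
                    kind="24h",
                    volume=volume,
                    duration=MINUTES_PER_DAY,
                    creat_conc=creat_excretion / volume,
                    uev_conc=excretion / volume * _lognormal_factor(rng, config.measurement_noise_sd),
                    cd9_pos_fraction=cd9,
                )
            )
            spot_flow = config.spot_flow_median * _lognormal_factor(rng, config.spot_flow_sigma)
            samples.append(
                UrineSample(
                    subject_id=donor.id,
                    phase=phase,
                    kind="spot",
                    volume=None,
                    duration=None,
                    creat_conc=creat_excretion / spot_flow,
                    uev_conc=excretion / spot_flow * _lognormal_factor(rng, config.measurement_noise_sd),
                    cd9_pos_fraction=cd9,
                )
            )

    return DonorCohort(donors=donors, samples=samples, config=config)


def simulate_rat_study(
    config: SimulationConfig, rng: Optional[np.random.Generator] = None
) -> List[RatSubject]:
    """Generate the rat arm: sham, uninephrectomy and 5/6th nephrectomy.

    Terminal kidney weight is the weight at uninephrectomy times the
    fraction of that kidney left, times the group hypertrophy factor
    (times the sham growth factor for sham animals), with lognormal
    measurement noise. Post uEV excretion follows the same projection on
    the nephron fraction, assuming both kidneys contribute equally.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    rat = config.rat

    subjects: List[RatSubject] = []
    counter = 0
    for group in RAT_GROUPS:
        for _ in range(rat.n_per_group[group]):
            counter += 1
            kw = _truncated_normal(rng, rat.kidney_weight_mean, rat.kidney_weight_sd, low=0.3)
            growth = rat.sham_growth_factor if group == "sham" else 1.0
            terminal = (
                kw
                * rat.kidney_fraction[group]
                * rat.hypertrophy_factor[group]
                * growth
                * _lognormal_factor(rng, rat.weight_noise_sd)
            )
            gfr_pre = _truncated_normal(rng, rat.gfr_mean, rat.gfr_sd, low=0.5)
            gfr_post = gfr_pre * rat.gfr_change_factor[group] * _lognormal_factor(rng, rat.gfr_noise_sd)
            uev_pre = _truncated_normal(
                rng, rat.uev_excretion_mean, rat.uev_excretion_sd, low=rat.uev_excretion_mean * 0.1
            )
            uev_growth = rat.sham_uev_growth if group == "sham" else 1.0
            uev_post = (
                uev_pre
                * rat.nephron_fraction[group]
                * rat.hypertrophy_factor[group]
                * uev_growth
                * _lognormal_factor(rng, rat.uev_noise_sd)
            )
            body_gain = _truncated_normal(
                rng, rat.body_weight_gain_mean[group], rat.body_weight_gain_sd, low=0.0
            )
            subjects.append(
                RatSubject(
                    id=f"R{counter:03d}",
                    group=group,
                    kidney_weight_at_unx=kw,
                    terminal_kidney_weight=terminal,
                    gfr_pre=gfr_pre,
                    gfr_post=gfr_post,
                    uev_excretion_pre=uev_pre,
                    uev_excretion_post=uev_post,
                    body_weight_gain=body_gain,
                )
            )
    return subjects
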