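"""Compensatory-hypertrophy projection arithmetic.

After surgical loss of nephron mass (uninephrectomy removes one kidney;
5/6th nephrectomy removes one kidney plus two thirds of the other), the
remaining tissue grows. The degree of hypertrophy is estimated by
projecting what the remnant would weigh — and what it would excrete —
had no growth occurred, and comparing the observation with the
projection:

    hypertrophy factor    = terminal kidney weight / projected weight
    uEV change factor     = uEV excretion at sacrifice / projected excretion

with projections

    projected weight      = weight at surgery x fraction of that kidney left
    projected excretion   = baseline excretion x fraction of nephrons left

The nephron fractions assume both kidneys contribute equally to uEV
excretion with negligible extra-renal contribution, so uninephrectomy
leaves 1/2 of nephrons and 5/6th nephrectomy 1/6. For the remnant-kidney
weight projection the contralateral kidney's weight at uninephrectomy is
used as the proxy for the polectomized kidney (its remnant is 1/3 of a
kidney).

For humans, where kidneys are measured as volumes rather than weights,
:func:`nephron_reduction_fraction` gives the fraction of nephron mass
removed from the split of total kidney volume over the two kidneys.

Raw (unrounded) ratios are what the functions return; printed-precision
rounding is applied only in the report layer (:func:`reproduce_table2`),
which mimics the arithmetic convention of rounding the projected
excretion to two decimals before forming the change-factor ratio.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Mapping

import pandas as pd

from .errors import DomainError

#: Fraction of the tracked remnant kidney left in place, per group.
GROUP_KIDNEY_FRACTION: Mapping[str, float] = {"sham": 1.0, "UNX": 1.0, "5/6NX": 1.0 / 3.0}

#: Fraction of total nephrons left in place, per group (two equal kidneys).
GROUP_NEPHRON_FRACTION: Mapping[str, float] = {"sham": 1.0, "UNX": 0.5, "5/6NX": 1.0 / 6.0}


def _check_positive(**values: float) -> None:
    for name, value in values.items():
        if not value > 0:
            raise DomainError(f"{name} must be > 0, got {value}")


def _check_fraction(name: str, fraction: float) -> None:
    if not 0 < fraction <= 1:
        raise DomainError(f"{name} must lie in (0, 1], got {fraction}")


def projected_remaining_mass(mass_at_reference: float, fraction_remaining_of_kidney: float) -> float:
    """Remnant kidney mass (g) expected without any hypertrophy."""
    _check_positive(mass_at_reference=mass_at_reference)
    _check_fraction("fraction_remaining_of_kidney", fraction_remaining_of_kidney)
    return mass_at_reference * fraction_remaining_of_kidney


def hypertrophy_factor(terminal_mass: float, projected_mass: float) -> float:
    """Fold growth of the remnant: terminal mass over projected mass."""
    _check_positive(terminal_mass=terminal_mass, projected_mass=projected_mass)
    return terminal_mass / projected_mass


def projected_uev_excretion(baseline_excretion: float, fraction_nephrons_remaining: float) -> float:
    """uEV excretion (uEVs/day) expected from the remnant without hypertrophy."""
    _check_positive(baseline_excretion=baseline_excretion)
    _check_fraction("fraction_nephrons_remaining", fraction_nephrons_remaining)
    return baseline_excretion * fraction_nephrons_remaining


def uev_change_factor(excretion_at_sacrifice: float, projected_excretion: float) -> float:
    """Fold change in per-remnant-tissue uEV output: observed over projected."""
    _check_positive(
        excretion_at_sacrifice=excretion_at_sacrifice,
        projected_excretion=projected_excretion,
    )
    return excretion_at_sacrifice / projected_excretion


def nephron_reduction_fraction(removed_kidney_volume: float, remaining_kidney_volume: float) -> float:
    """Fraction of nephron mass removed, from the two kidney volumes.

    ``removed / (removed + remaining)``; with near-equal kidneys this is
    close to 0.5. Per-subject values are usually summarized as
    mean +/- SD across a cohort.
    """
    _check_positive(
        removed_kidney_volume=removed_kidney_volume,
        remaining_kidney_volume=remaining_kidney_volume,
    )
    return removed_kidney_volume / (removed_kidney_volume + remaining_kidney_volume)


@dataclass(frozen=True)
class HypertrophyEstimate:
    """The four derived quantities for one animal or group."""

    projected_remaining_mass: float  # g
    hypertrophy_factor: float  # fold
    projected_uev_excretion: float  # uEVs/day (or the table's 1e12 scale)
    uev_change_factor: float  # fold

    def __post_init__(self) -> None:
        for name in (
            "projected_remaining_mass",
            "hypertrophy_factor",
            "projected_uev_excretion",
            "uev_change_factor",
        ):
            if not getattr(self, name) > 0:
                raise DomainError(f"{name} must be > 0, got {getattr(self, name)}")


def estimate_hypertrophy(
    kidney_weight_at_unx: float,
    terminal_kidney_weight: float,
    baseline_uev_excretion: float,
    sacrifice_uev_excretion: float,
    group: str,
) -> HypertrophyEstimate:
    """Full projection for one animal (or one group of printed means).

    ``group`` selects the remnant-kidney fraction and nephron fraction
    ("UNX" or "5/6NX"; "sham" yields identity fractions).
    """
    if group not in GROUP_KIDNEY_FRACTION:
        raise DomainError(
            f"group must be one of {sorted(GROUP_KIDNEY_FRACTION)}, got {group!r}"
        )
    projected_mass = projected_remaining_mass(
        kidney_weight_at_unx, GROUP_KIDNEY_FRACTION[group]
    )
    projected_uev = projected_uev_excretion(
        baseline_uev_excretion, GROUP_NEPHRON_FRACTION[group]
    )
    return HypertrophyEstimate(
        projected_remaining_mass=projected_mass,
        hypertrophy_factor=hypertrophy_factor(terminal_kidney_weight, projected_mass),
        projected_uev_excretion=projected_uev,
        uev_change_factor=uev_change_factor(sacrifice_uev_excretion, projected_uev),
    )


def round_fold(value: float) -> float:
    """Round a fold ratio to the one-decimal style used in reports."""
    return round(value, 1)


def reproduce_table2(groups: pd.DataFrame) -> pd.DataFrame:
    """Derive the four projection rows from group-level inputs.

    Parameters
    ----------
    groups : DataFrame with one row per nephrectomy group and columns
        ``group`` ("UNX" / "5/6NX"), ``kidney_weight_at_unx`` (g),
        ``terminal_kidney_weight`` (g), ``uev_excretion_baseline`` and
        ``uev_excretion_sacrifice`` (1e12 uEVs/day scale, or any
        consistent unit).

    Returns
    -------
    DataFrame indexed by group with both raw and printed-precision
    columns. The printed change factor divides by the projected
    excretion *after* rounding it to two decimals, matching the
    convention of the published projection table; folds are rounded to
    one decimal.
    """
    required = {
        "group",
        "kidney_weight_at_unx",
        "terminal_kidney_weight",
        "uev_excretion_baseline",
        "uev_excretion_sacrifice",
    }
    missing = required - set(groups.columns)
    if missing:
        raise DomainError(f"missing required columns: {sorted(missing)}")

    rows = []
    for rec in groups.to_dict("records"):
        est = estimate_hypertrophy(
            kidney_weight_at_unx=rec["kidney_weight_at_unx"],
            terminal_kidney_weight=rec["terminal_kidney_weight"],
            baseline_uev_excretion=rec["uev_excretion_baseline"],
            sacrifice_uev_excretion=rec["uev_excretion_sacrifice"],
            group=rec["group"],
        )
        projected_uev_printed = round(est.projected_uev_excretion, 2)
        rows.append(
            {
                "group": rec["group"],
                "projected_remaining_mass_g": est.projected_remaining_mass,
                "projected_remaining_mass_printed": round(est.projected_remaining_mass, 1),
                "hypertrophy_factor": est.hypertrophy_factor,
                "hypertrophy_factor_printed": round_fold(est.hypertrophy_factor),
                "projected_uev_excretion": est.projected_uev_excretion,
                "projected_uev_excretion_printed": projected_uev_printed,
                "uev_change_factor": est.uev_change_factor,
                "uev_change_factor_printed": round_fold(
                    uev_change_factor(rec["uev_excretion_sacrifice"], projected_uev_printed)
                ),
            }
        )
    return pd.DataFrame(rows).set_index("group")


def estimate_rat_hypertrophy(rats: Iterable) -> pd.DataFrame:
    """Per-animal projection estimates for a collection of RatSubject.

    Sham animals are included with identity fractions so their change
    factors reflect growth alone.
    """
    rows: list[Dict[str, float]] = []
    for rat in rats:
        est = estimate_hypertrophy(
            kidney_weight_at_unx=rat.kidney_weight_at_unx,
            terminal_kidney_weight=rat.terminal_kidney_weight,
            baseline_uev_excretion=rat.uev_excretion_pre,
            sacrifice_uev_excretion=rat.uev_excretion_post,
            group=rat.group,
        )
        rows.append(
            {
                "rat_id": rat.id,
                "group": rat.group,
                "projected_remaining_mass_g": est.projected_remaining_mass,
                "hypertrophy_factor": est.hypertrophy_factor,
                "projected_uev_excretion": est.projected_uev_excretion,
                "uev_change_factor": est.uev_change_factor,
            }
        )
    return pd.DataFrame(rows)
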