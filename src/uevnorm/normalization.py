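"""Excretion rates and creatinine / kidney-volume normalization.

Urinary extracellular vesicles (uEVs) are counted as concentrations
(particles per litre), but biological questions are about *excretion
rates* (particles per day). A complete timed collection yields the rate
directly; a spot urine does not, because the urine flow at the time of
the void is unknown. The central statistic implemented here removes the
flow by using creatinine as an internal reference:

    calculated spot uEV excretion
        = spot uEV concentration x daily creatinine excretion
          / spot creatinine concentration

Both concentrations are diluted by the same urine flow, so the flow —
and any dilution of the sample — cancels exactly, while the subject's
24-h creatinine excretion restores the absolute scale (and absorbs
between-subject differences in muscle mass).

Biomarker densitometry values loaded per creatinine can additionally be
rescaled to a reference total kidney volume (TKV) so that abundances
measured before and after a nephrectomy are expressed per unit of the
*original* nephron mass; without that correction a doubling of a
per-nephron biomarker after removal of half the nephron mass is
invisible.

Canonical rate unit is uEVs/day; ``ExcretionRate.per_min`` converts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .errors import DomainError

MINUTES_PER_DAY = 1440.0

#: Spot creatinine concentrations below this (mmol/L) are flagged as too
#: dilute to normalize reliably; the computation still proceeds.
DEFAULT_CREATININE_FLOOR = 1.0

#: Nephron-segment markers accepted for biomarker measurements.
KNOWN_PROTEINS = frozenset(
    {"WT1", "NHE3", "NaPi-IIa", "cubilin", "NKCC2", "NCC", "AQP2", "CD9", "TSG101"}
)


@dataclass(frozen=True)
class ExcretionRate:
    """An excretion rate in canonical units of uEVs per day."""

    per_day: float

    def __post_init__(self) -> None:
        if self.per_day < 0:
            raise DomainError(f"excretion rate must be >= 0, got {self.per_day}")

    @property
    def per_min(self) -> float:
        """The same rate expressed in uEVs per minute."""
        return self.per_day / MINUTES_PER_DAY

    @classmethod
    def from_per_min(cls, per_min: float) -> "ExcretionRate":
        return cls(per_min * MINUTES_PER_DAY)


@dataclass
class UrineSample:
    """One urine collection (spot, timed, or complete 24-h).

    Spot samples have no volume or duration: no excretion rate can be
    derived from them without an external creatinine excretion (see
    :func:`calculated_spot_excretion`).
    """

    subject_id: str
    phase: str  # "pre" | "post"
    kind: str  # "spot" | "24h" | "timed"
    creat_conc: float  # mmol/L
    uev_conc: float  # uEVs/L
    volume: Optional[float] = None  # L; absent for spot
    duration: Optional[float] = None  # min; 1440 for 24h, absent for spot
    cd9_pos_fraction: Optional[float] = None
    size_histogram: Optional[object] = None  # quantification.SizeDistribution

    def __post_init__(self) -> None:
        if self.phase not in ("pre", "post"):
            raise DomainError(f"phase must be 'pre' or 'post', got {self.phase!r}")
        if self.kind not in ("spot", "24h", "timed"):
            raise DomainError(f"kind must be spot/24h/timed, got {self.kind!r}")
        if self.creat_conc <= 0:
            raise DomainError(f"creat_conc must be > 0, got {self.creat_conc}")
        if self.uev_conc <= 0:
            raise DomainError(f"uev_conc must be > 0, got {self.uev_conc}")
        if self.duration is not None and self.duration <= 0:
            raise DomainError(f"duration must be > 0, got {self.duration}")
        if self.cd9_pos_fraction is not None and not 0 <= self.cd9_pos_fraction <= 1:
            raise DomainError(
                f"cd9_pos_fraction must lie in [0, 1], got {self.cd9_pos_fraction}"
            )

    @property
    def is_dilute(self) -> bool:
        """True when spot creatinine is below the normalization floor."""
        return self.kind == "spot" and self.creat_conc < DEFAULT_CREATININE_FLOOR


@dataclass
class BiomarkerMeasurement:
    """Creatinine-normalized densitometry of one nephron-segment marker."""

    subject_id: str
    protein: str
    phase: str
    abundance_per_creat: float  # arbitrary units / creatinine

    def __post_init__(self) -> None:
        if self.protein not in KNOWN_PROTEINS:
            raise DomainError(
                f"unknown protein {self.protein!r}; expected one of {sorted(KNOWN_PROTEINS)}"
            )
        if self.phase not in ("pre", "post"):
            raise DomainError(f"phase must be 'pre' or 'post', got {self.phase!r}")
        if self.abundance_per_creat < 0:
            raise DomainError(
                f"abundance_per_creat must be >= 0, got {self.abundance_per_creat}"
            )


def _require_positive(**values: float) -> None:
    for name, value in values.items():
        if not value > 0:
            raise DomainError(f"{name} must be > 0, got {value}")


def excretion_rate_24h(uev_conc: float, volume: float, duration: float = MINUTES_PER_DAY) -> ExcretionRate:
    """Excretion rate from a timed collection, scaled to a full day.

    Parameters
    ----------
    uev_conc : uEVs/L measured in the pooled collection.
    volume : collected volume in litres.
    duration : collection duration in minutes (1440 for a 24-h urine).

    Returns
    -------
    ExcretionRate in uEVs/day: ``uev_conc * volume * (1440 / duration)``.
    """
    _require_positive(uev_conc=uev_conc, volume=volume, duration=duration)
    return ExcretionRate(uev_conc * volume * (MINUTES_PER_DAY / duration))


def uev_per_creatinine(uev_conc: float, creat_conc: float) -> float:
    """uEV-to-creatinine ratio (uEVs/mmol) for intra-individual comparison.

    Invariant under common dilution: scaling both concentrations by the
    same factor leaves the ratio unchanged, so spot urines of different
    concentration are comparable within a subject.
    """
    _require_positive(creat_conc=creat_conc)
    if uev_conc <= 0:
        raise DomainError(f"uev_conc must be > 0, got {uev_conc}")
    return uev_conc / creat_conc


def calculated_spot_excretion(
    spot_uev_conc: float, spot_creat_conc: float, creat_excretion: float
) -> ExcretionRate:
    """Estimate daily uEV excretion from a spot urine.

    Parameters
    ----------
    spot_uev_conc : uEVs/L in the spot urine.
    spot_creat_conc : mmol/L creatinine in the same spot urine.
    creat_excretion : the subject's 24-h creatinine excretion, mmol/day.

    Returns
    -------
    ExcretionRate in uEVs/day:
    ``spot_uev_conc * creat_excretion / spot_creat_conc``.
    Dividing by 1440 (``.per_min``) gives the per-minute form.

    Notes
    -----
    Exactly invariant to dilution of the spot urine — both
    concentrations scale with the urine flow, which cancels.
    """
    _require_positive(
        spot_uev_conc=spot_uev_conc,
        spot_creat_conc=spot_creat_conc,
        creat_excretion=creat_excretion,
    )
    return ExcretionRate(spot_uev_conc * creat_excretion / spot_creat_conc)


def tkv_corrected_abundance(
    abundance_per_creat: float, tkv: float, reference_tkv: float
) -> float:
    """Rescale a per-creatinine biomarker abundance to a reference TKV.

    ``corrected = abundance_per_creat * reference_tkv / tkv``

    With ``reference_tkv`` equal to the pre-nephrectomy total kidney
    volume, pre-phase values pass through unchanged while post-phase
    values are scaled up by the removed fraction: after losing half the
    nephron mass an unchanged raw abundance becomes a two-fold corrected
    increase. ``reference_tkv`` may be the individual's own baseline TKV
    or a group-level value.
    """
    _require_positive(tkv=tkv, reference_tkv=reference_tkv)
    if abundance_per_creat < 0:
        raise DomainError(
            f"abundance_per_creat must be >= 0, got {abundance_per_creat}"
        )
    return abundance_per_creat * reference_tkv / tkv
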