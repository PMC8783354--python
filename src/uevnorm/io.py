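"""Tables, configuration files, manifests and the pipeline driver.

Cohort data move between stages as five CSV tables — ``donors``,
``samples``, ``rats``, ``biomarkers`` and ``particles`` — each carrying
a one-line ``# units:`` header comment so files are self-describing.
Tables are schema-validated on read: a missing required column raises
:class:`~uevnorm.errors.SchemaError` naming the column, a unit header
that contradicts the schema raises :class:`~uevnorm.errors.UnitError`,
and unknown extra columns are preserved, never dropped.

Every simulation run also writes a JSON manifest recording the seed,
a hash of the full configuration and the package version, so any output
directory can be regenerated bit-for-bit.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Union

import numpy as np
import pandas as pd

from . import __version__
from .config import SimulationConfig, default_config
from .errors import SchemaError, UnitError, UevNormError
from .hypertrophy import estimate_rat_hypertrophy, reproduce_table2
from .normalization import (
    UrineSample,
    calculated_spot_excretion,
    excretion_rate_24h,
    uev_per_creatinine,
)
from .simulate import Donor, DonorCohort, RatSubject, simulate_donor_cohort, simulate_rat_study
from .stats import PairedSeries, correlation, holm_bonferroni, paired_percent_change_summary

logger = logging.getLogger("uevnorm")

PathLike = Union[str, Path]

#: Required columns and their units, per table.
SCHEMAS: Dict[str, Dict[str, str]] = {
    "donors": {
        "donor_id": "id",
        "sex": "M/F",
        "tkv_left": "ml",
        "tkv_right": "ml",
        "egfr": "ml/min",
        "creatinine_clearance": "ml/min",
        "creat_excretion": "mmol/day",
        "true_uev_excretion": "uEVs/day",
        "true_uev_excretion_post": "uEVs/day",
        "cd9_pos_fraction": "fraction",
        "removed_side": "left/right",
    },
    "samples": {
        "subject_id": "id",
        "phase": "pre/post",
        "kind": "spot/24h/timed",
        "volume": "L",
        "duration": "min",
        "creat_conc": "mmol/L",
        "uev_conc": "uEVs/L",
        "cd9_pos_fraction": "fraction",
    },
    "rats": {
        "rat_id": "id",
        "group": "sham/UNX/5-6NX",
        "kidney_weight_at_unx": "g",
        "terminal_kidney_weight": "g",
        "gfr_pre": "ml/min",
        "gfr_post": "ml/min",
        "uev_excretion_pre": "uEVs/day",
        "uev_excretion_post": "uEVs/day",
        "body_weight_gain": "g",
    },
    "biomarkers": {
        "subject_id": "id",
        "phase": "pre/post",
        "protein": "name",
        "abundance_per_creat": "A.U./creat",
    },
    "particles": {
        "subject_id": "id",
        "phase": "pre/post",
        "diameter_nm": "nm",
        "intensity": "A.U.",
    },
    "table2": {
        "group": "UNX/5-6NX",
        "kidney_weight_at_unx": "g",
        "terminal_kidney_weight": "g",
        "uev_excretion_baseline": "1e12_uEVs/day",
        "uev_excretion_sacrifice": "1e12_uEVs/day",
    },
}


@dataclass
class CohortTables:
    """In-memory bundle of the validated cohort tables."""

    donors: Optional[pd.DataFrame] = None
    samples: Optional[pd.DataFrame] = None
    rats: Optional[pd.DataFrame] = None
    biomarkers: Optional[pd.DataFrame] = None
    particles: Optional[pd.DataFrame] = None
    manifest: Dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# CSV round-trip with a "# units:" header line


def _units_line(schema: Mapping[str, str]) -> str:
    return "# units: " + " ".join(f"{col}={unit}" for col, unit in schema.items())


def write_table(frame: pd.DataFrame, path: PathLike, table: str) -> None:
    """Write a CSV with the table's unit header comment."""
    if table not in SCHEMAS:
        raise SchemaError(f"unknown table {table!r}")
    path = Path(path)
    with path.open("w") as handle:
        handle.write(_units_line(SCHEMAS[table]) + "\n")
        frame.to_csv(handle, index=False)


def read_table(path: PathLike, table: str) -> pd.DataFrame:
    """Read and validate one CSV table.

    Checks the required columns of the schema and, when a ``# units:``
    line is present, that the declared units match. Unknown columns are
    kept.
    """
    if table not in SCHEMAS:
        raise SchemaError(f"unknown table {table!r}")
    path = Path(path)
    schema = SCHEMAS[table]
    with path.open() as handle:
        first = handle.readline()
    if first.startswith("# units:"):
        declared = dict(
            item.split("=", 1) for item in first[len("# units:"):].split() if "=" in item
        )
        for col, unit in declared.items():
            if col in schema and unit != schema[col]:
                raise UnitError(
                    f"{path.name}: column {col!r} declared as {unit!r}, expected {schema[col]!r}"
                )
    frame = pd.read_csv(path, comment="#")
    for col in schema:
        if col not in frame.columns:
            raise SchemaError(f"{path.name}: missing required column {col!r}")
    logger.info("read %s: %d rows from %s", table, len(frame), path)
    return frame


def read_tables(paths: Mapping[str, PathLike]) -> CohortTables:
    """Read several tables at once; keys are table names."""
    tables = CohortTables()
    for name, path in paths.items():
        if name == "manifest":
            tables.manifest = json.loads(Path(path).read_text())
            continue
        setattr(tables, name, read_table(path, name))
    return tables


def load_table2_fixture() -> pd.DataFrame:
    """The packaged group-level rat nephrectomy inputs (two group rows)."""
    with resources.files("uevnorm.data").joinpath("table2.csv").open() as handle:
        frame = pd.read_csv(handle, comment="#")
    return frame


# ---------------------------------------------------------------------------
# object <-> frame conversion


def donors_to_frame(donors: List[Donor]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "donor_id": d.id,
                "sex": d.sex,
                "tkv_left": d.tkv_left,
                "tkv_right": d.tkv_right,
                "egfr": d.egfr,
                "creatinine_clearance": d.creatinine_clearance,
                "creat_excretion": d.creat_excretion,
                "true_uev_excretion": d.true_uev_excretion,
                "true_uev_excretion_post": d.true_uev_excretion_post,
                "cd9_pos_fraction": d.cd9_pos_fraction,
                "cd9_pos_fraction_post": d.cd9_pos_fraction_post,
                "egfr_post": d.egfr_post,
                "removed_side": d.removed_side,
            }
            for d in donors
        ]
    )


def samples_to_frame(samples: List[UrineSample]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "subject_id": s.subject_id,
                "phase": s.phase,
                "kind": s.kind,
                "volume": s.volume,
                "duration": s.duration,
                "creat_conc": s.creat_conc,
                "uev_conc": s.uev_conc,
                "cd9_pos_fraction": s.cd9_pos_fraction,
            }
            for s in samples
        ]
    )


def rats_to_frame(rats: List[RatSubject]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "rat_id": r.id,
                "group": r.group,
                "kidney_weight_at_unx": r.kidney_weight_at_unx,
                "terminal_kidney_weight": r.terminal_kidney_weight,
                "gfr_pre": r.gfr_pre,
                "gfr_post": r.gfr_post,
                "uev_excretion_pre": r.uev_excretion_pre,
                "uev_excretion_post": r.uev_excretion_post,
                "body_weight_gain": r.body_weight_gain,
            }
            for r in rats
        ]
    )


def rats_from_frame(frame: pd.DataFrame) -> List[RatSubject]:
    return [
        RatSubject(
            id=str(rec["rat_id"]),
            group=rec["group"],
            kidney_weight_at_unx=rec["kidney_weight_at_unx"],
            terminal_kidney_weight=rec["terminal_kidney_weight"],
            gfr_pre=rec["gfr_pre"],
            gfr_post=rec["gfr_post"],
            uev_excretion_pre=rec["uev_excretion_pre"],
            uev_excretion_post=rec["uev_excretion_post"],
            body_weight_gain=rec["body_weight_gain"],
        )
        for rec in frame.to_dict("records")
    ]


# ---------------------------------------------------------------------------
# pipeline driver

COMMANDS = ("simulate", "normalize", "hypertrophy", "stats", "reproduce-table2", "report")


def _manifest(config: SimulationConfig, tables: Mapping[str, pd.DataFrame]) -> Dict:
    return {
        "seed": config.seed,
        "config_sha256": config.sha256(),
        "package_version": __version__,
        "tables": {name: int(len(frame)) for name, frame in tables.items()},
    }


def _write_json(data: Dict, path: Path) -> None:
    path.write_text(json.dumps(data, indent=2, sort_keys=True) + "\n")


def _simulate_command(config: SimulationConfig, out: Path) -> Dict:
    rng = np.random.default_rng(config.seed)  # one stream feeds both arms
    cohort = simulate_donor_cohort(config, rng=rng)
    rats = simulate_rat_study(config, rng=rng)
    frames = {
        "donors": donors_to_frame(cohort.donors),
        "samples": samples_to_frame(cohort.samples),
        "rats": rats_to_frame(rats),
    }
    for name, frame in frames.items():
        write_table(frame, out / f"{name}.csv", name)
    manifest = _manifest(config, frames)
    _write_json(manifest, out / "manifest.json")
    return {"command": "simulate", "manifest": manifest}


def _normalize_command(config: SimulationConfig, out: Path, tables: CohortTables) -> Dict:
    if tables.samples is None or tables.donors is None:
        raise SchemaError("normalize needs 'samples' and 'donors' tables")
    donors = tables.donors.set_index("donor_id")
    rows = []
    for rec in tables.samples.to_dict("records"):
        creat_excretion = float(donors.loc[rec["subject_id"], "creat_excretion"])
        row = {
            "subject_id": rec["subject_id"],
            "phase": rec["phase"],
            "kind": rec["kind"],
            "uev_per_creat": uev_per_creatinine(rec["uev_conc"], rec["creat_conc"]),
        }
        if rec["kind"] == "spot":
            row["excretion_per_day"] = calculated_spot_excretion(
                rec["uev_conc"], rec["creat_conc"], creat_excretion
            ).per_day
            row["method"] = "calculated_spot_excretion"
        else:
            row["excretion_per_day"] = excretion_rate_24h(
                rec["uev_conc"], rec["volume"], rec["duration"]
            ).per_day
            row["method"] = "excretion_rate_24h"
        rows.append(row)
    normalized = pd.DataFrame(rows)
    normalized.to_csv(out / "normalized.csv", index=False)
    report = {
        "command": "normalize",
        "n_samples": len(normalized),
        "provenance": {
            "spot": "uev_conc x creat_excretion / creat_conc (uEVs/day)",
            "timed": "uev_conc x volume x 1440 / duration (uEVs/day)",
        },
    }
    _write_json(report, out / "normalize_report.json")
    return report


def _hypertrophy_command(out: Path, tables: CohortTables) -> Dict:
    if tables.rats is None:
        raise SchemaError("hypertrophy needs a 'rats' table")
    per_animal = estimate_rat_hypertrophy(rats_from_frame(tables.rats))
    per_animal.to_csv(out / "hypertrophy.csv", index=False)
    group_means = (
        per_animal.groupby("group")[["hypertrophy_factor", "uev_change_factor"]]
        .mean()
        .round(4)
        .to_dict("index")
    )
    report = {
        "command": "hypertrophy",
        "group_means": group_means,
        "provenance": {
            "hypertrophy_factor": "terminal weight / (weight at UNX x kidney fraction)",
            "uev_change_factor": "excretion at sacrifice / (baseline x nephron fraction)",
        },
    }
    _write_json(report, out / "hypertrophy_report.json")
    return report


def _stats_command(out: Path, tidy: pd.DataFrame) -> Dict:
    """Paired pre/post summaries plus Holm-adjusted paired tests.

    ``tidy`` columns: subject_id, phase, variable, value.
    """
    for col in ("subject_id", "phase", "variable", "value"):
        if col not in tidy.columns:
            raise SchemaError(f"stats input: missing required column {col!r}")
    from .stats import paired_test

    report: Dict = {"command": "stats", "variables": {}}
    pvalues, var_names = [], []
    for variable, sub in tidy.groupby("variable"):
        wide = sub.pivot_table(index="subject_id", columns="phase", values="value")
        if not {"pre", "post"} <= set(wide.columns):
            continue
        wide = wide.dropna(subset=["pre", "post"])
        series = PairedSeries(list(wide.index), wide["pre"].to_numpy(), wide["post"].to_numpy())
        summary = paired_percent_change_summary(series, "median_iqr")
        test = paired_test(series)
        report["variables"][variable] = {
            "n": len(series),
            "median_percent_decrease": summary.center,
            "iqr": [summary.spread_low, summary.spread_high],
            "group_mean_percent_decrease": paired_percent_change_summary(series, "group_mean").center,
            "test": test.test,
            "pvalue": test.pvalue,
        }
        pvalues.append(test.pvalue)
        var_names.append(variable)
    if pvalues:
        holm = holm_bonferroni(pvalues)
        for name, adj, rej in zip(var_names, holm.adjusted, holm.reject):
            report["variables"][name]["pvalue_holm"] = adj
            report["variables"][name]["reject_at_0.05"] = rej
    _write_json(report, out / "stats_report.json")
    return report


def _table2_command(out: Path, tables: Optional[CohortTables]) -> Dict:
    if tables is not None and tables.rats is not None:
        per_animal = estimate_rat_hypertrophy(rats_from_frame(tables.rats))
        grouped = (
            pd.DataFrame(
                {
                    "group": tables.rats["group"],
                    "kidney_weight_at_unx": tables.rats["kidney_weight_at_unx"],
                    "terminal_kidney_weight": tables.rats["terminal_kidney_weight"],
                    "uev_excretion_baseline": tables.rats["uev_excretion_pre"],
                    "uev_excretion_sacrifice": tables.rats["uev_excretion_post"],
                }
            )
            .groupby("group", as_index=False)
            .mean()
        )
        grouped = grouped[grouped["group"] != "sham"]
        source = "rats table (group means)"
    else:
        grouped = load_table2_fixture()
        source = "packaged group-level fixture"
    derived = reproduce_table2(grouped)
    derived.reset_index().to_csv(out / "table2_derived.csv", index=False)
    report = {
        "command": "reproduce-table2",
        "source": source,
        "derived": derived.reset_index().to_dict("records"),
        "provenance": {
            "projected mass": "weight at UNX x fraction of kidney remaining",
            "hypertrophy factor": "terminal weight / projected mass, printed to 1 decimal",
            "projected excretion": "baseline x nephron fraction, printed to 2 decimals",
            "change factor": "sacrifice / printed projected excretion, printed to 1 decimal",
        },
    }
    _write_json(report, out / "table2_report.json")
    return report


def _report_command(out: Path, tables: CohortTables) -> Dict:
    if tables.donors is None or tables.samples is None:
        raise SchemaError("report needs 'donors' and 'samples' tables")
    donors = tables.donors
    samples = tables.samples.merge(
        donors[["donor_id", "sex", "creat_excretion"]],
        left_on="subject_id",
        right_on="donor_id",
    )
    spot_pre = samples[(samples["kind"] == "spot") & (samples["phase"] == "pre")].copy()
    spot_pre["calculated_excretion"] = [
        calculated_spot_excretion(r.uev_conc, r.creat_conc, r.creat_excretion).per_day
        for r in spot_pre.itertuples()
    ]
    h24 = samples[(samples["kind"] == "24h") & (samples["phase"] == "pre")].copy()
    h24["measured_excretion"] = [
        excretion_rate_24h(r.uev_conc, r.volume, r.duration).per_day for r in h24.itertuples()
    ]
    by_sex = {
        sex: {
            "n": int((donors["sex"] == sex).sum()),
            "median_24h_excretion": float(
                h24.loc[h24["sex"] == sex, "measured_excretion"].median()
            ),
            "median_calculated_spot_excretion": float(
                spot_pre.loc[spot_pre["sex"] == sex, "calculated_excretion"].median()
            ),
        }
        for sex in sorted(donors["sex"].unique())
    }
    merged = h24.merge(spot_pre[["subject_id", "calculated_excretion"]], on="subject_id")
    agreement = correlation(
        merged["measured_excretion"], merged["calculated_excretion"], "spearman"
    )
    report = {
        "command": "report",
        "sex_stratified_excretion": by_sex,
        "spot_vs_24h_spearman": {"rho": agreement.coefficient, "p": agreement.pvalue},
    }
    _write_json(report, out / "cohort_report.json")
    return report


def run_pipeline(
    command: str,
    config: Optional[SimulationConfig] = None,
    out_dir: PathLike = ".",
    tables: Optional[CohortTables] = None,
    tidy: Optional[pd.DataFrame] = None,
) -> Dict:
    """Execute one pipeline stage and write its artifacts under ``out_dir``.

    Deterministic given the configuration seed; every report carries the
    provenance of its derived quantities.
    """
    if command not in COMMANDS:
        raise UevNormError(f"unknown command {command!r}; expected one of {COMMANDS}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if config is None:
        config = default_config()
    config.validate()

    if command == "simulate":
        return _simulate_command(config, out)
    if command == "normalize":
        return _normalize_command(config, out, tables or CohortTables())
    if command == "hypertrophy":
        return _hypertrophy_command(out, tables or CohortTables())
    if command == "stats":
        if tidy is None:
            raise SchemaError("stats needs a tidy input table")
        return _stats_command(out, tidy)
    if command == "reproduce-table2":
        return _table2_command(out, tables)
    return _report_command(out, tables or CohortTables())
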