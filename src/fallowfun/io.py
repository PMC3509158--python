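"""Reading, validating and writing the delimited input/output tables.

All tables are UTF-8 CSV with a header row, comma separator and '.'
decimal.  The survey table encodes the per-stem DBH list as a
semicolon-separated string in column ``dbh_cm``.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd
import yaml

from .errors import ValidationError
from .synth import FallowDataset

log = logging.getLogger(__name__)

SURVEY_COLUMNS = [
    "plot_id",
    "species_id",
    "growth_form",
    "avg_height_m",
    "cover_class",
    "dbh_cm",
    "biovolume_m3",
]
TRAIT_COLUMNS_IO = [
    "species_id",
    "growth_form",
    "n_pct",
    "lignin_pct",
    "polyphenol_pct",
    "green_fraction",
    "woody_fraction",
    "conv_factor",
]
SOIL_COLUMNS = ["plot_id", "subplot", "layer", "soc_pct", "mg", "ca", "k", "sand_pct"]
INFIL_COLUMNS = ["plot_id", "subplot", "time_min", "rate_mm_hr"]
PLOT_COLUMNS = ["plot_id", "fallow_type", "grazing_class", "grazing_intensity", "year"]


def _dbh_to_str(dbhs) -> str:
    if isinstance(dbhs, str):
        return dbhs
    return ";".join(f"{d:.2f}" for d in (dbhs or []))


def _dbh_from_str(s) -> list[float]:
    if s is None or (isinstance(s, float) and pd.isna(s)) or s == "":
        return []
    if isinstance(s, (list, tuple)):
        return [float(x) for x in s]
    return [float(x) for x in str(s).split(";") if x.strip()]


def write_dataset(dataset: FallowDataset, out_dir: str | Path) -> None:
    """Write the five input tables plus a YAML provenance file."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    survey = dataset.survey.copy()
    survey["dbh_cm"] = survey["dbh_cm"].map(_dbh_to_str)
    survey.to_csv(out / "survey.csv", index=False)
    dataset.traits.reset_index().to_csv(out / "traits.csv", index=False)
    dataset.soils.to_csv(out / "soils.csv", index=False)
    dataset.infiltration.to_csv(out / "infiltration.csv", index=False)
    dataset.plots.to_csv(out / "plots.csv", index=False)
    dataset.profiles.to_csv(out / "profiles_truth.csv", index=False)
    with open(out / "provenance.yaml", "w") as fh:
        yaml.safe_dump(dataset.provenance, fh, sort_keys=False)


def _require_columns(df: pd.DataFrame, cols: list[str], name: str, problems: list[str]) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        problems.append(f"{name}: missing columns {missing}")


def read_inputs(in_dir: str | Path) -> FallowDataset:
    """Read and validate the input tables from a directory.

    All schema violations are collected and reported together in a single
    :class:`ValidationError`, with row numbers (1-based, excluding header).
    """
    d = Path(in_dir)
    problems: list[str] = []

    def _read(name, cols):
        path = d / name
        if not path.exists():
            problems.append(f"{name}: file not found in {d}")
            return pd.DataFrame(columns=cols)
        df = pd.read_csv(path)
        _require_columns(df, cols, name, problems)
        return df

    survey = _read("survey.csv", SURVEY_COLUMNS)
    traits = _read("traits.csv", TRAIT_COLUMNS_IO)
    soils = _read("soils.csv", SOIL_COLUMNS)
    infiltration = _read("infiltration.csv", INFIL_COLUMNS)
    plots = _read("plots.csv", PLOT_COLUMNS)
    if problems:
        raise ValidationError("; ".join(problems))

    if "species_id" in traits.columns:
        traits = traits.set_index("species_id")

    # survey checks
    for i, row in survey.iterrows():
        rowno = i + 2
        cc = row["cover_class"]
        if not (pd.notna(cc) and float(cc) == int(cc) and 1 <= int(cc) <= 5):
            problems.append(f"survey.csv row {rowno}: cover_class {cc!r} not in 1..5")
        try:
            dbhs = _dbh_from_str(row["dbh_cm"])
        except ValueError:
            problems.append(f"survey.csv row {rowno}: unparseable dbh list {row['dbh_cm']!r}")
            dbhs = []
        if any(db < 2.5 for db in dbhs):
            problems.append(f"survey.csv row {rowno}: DBH below 2.5 cm")
        for col in ("avg_height_m", "biovolume_m3"):
            try:
                v = float(row[col])
                if v < 0:
                    problems.append(f"survey.csv row {rowno}: negative {col}")
            except (TypeError, ValueError):
                problems.append(f"survey.csv row {rowno}: non-numeric {col}")
        if row["species_id"] not in traits.index:
            problems.append(
                f"survey.csv row {rowno}: species {row['species_id']!r} absent from trait table"
            )
    # soil checks
    for i, row in soils.iterrows():
        rowno = i + 2
        if row["layer"] not in ("topsoil", "subsoil"):
            problems.append(f"soils.csv row {rowno}: unknown layer {row['layer']!r}")
        for col in ("soc_pct", "mg", "ca", "k", "sand_pct"):
            try:
                v = float(row[col])
                if v < 0:
                    problems.append(f"soils.csv row {rowno}: negative {col}")
            except (TypeError, ValueError):
                problems.append(f"soils.csv row {rowno}: non-numeric {col}")
    if problems:
        raise ValidationError("; ".join(problems))

    survey = survey.copy()
    survey["dbh_cm"] = survey["dbh_cm"].map(_dbh_from_str)

    prov_path = d / "provenance.yaml"
    provenance = {}
    if prov_path.exists():
        with open(prov_path) as fh:
            provenance = yaml.safe_load(fh) or {}
    profiles_path = d / "profiles_truth.csv"
    profiles = pd.read_csv(profiles_path) if profiles_path.exists() else pd.DataFrame()

    return FallowDataset(
        plots=plots,
        survey=survey,
        traits=traits,
        soils=soils,
        infiltration=infiltration,
        profiles=profiles,
        provenance=provenance,
    )
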