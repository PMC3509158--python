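"""Standing biomass from vegetation survey records.

Two estimation paths feed every biomass quantity:

* **allometric path** — every woody stem with DBH >= 2.5 cm contributes
  whole-tree biomass via the general humid-region allometry
  Y = exp(-2.134 + 2.53 ln DBH) (DBH in cm, Y in kg);
* **biovolume path** — every species' visually estimated biovolume
  (m^3 per 100 m^2 plot) times a growth-form/species conversion factor
  (kg per m^3).

Green (leaves + young green twigs) and woody fractions of aboveground
biomass split each species' total; 1 kg per 100 m^2 plot = 0.1 t/ha.

Two ecosystem-service-provider (ESP) sets partition the community:

* **wood**: woody-fraction biomass of trees/large shrubs — all stems
  >= 2.5 cm DBH plus the biovolume path of woody species with average
  height >= 0.7 m;
* **forage**: green-fraction biomass of herbaceous species and woody
  species < 0.7 m average height, restricted to higher-quality forage
  species with crude protein (N x 6.25) to lignin ratio >= 0.8.
"""

from __future__ import annotations

import logging
import math
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError, MissingTraitError, UndefinedRatioError

log = logging.getLogger(__name__)

#: kg per plot (100 m^2) -> t per ha
PLOT_TO_HA = 0.1

#: midpoints of the 5-point cover scale 1-4, 4-15, 15-40, 40-65, >65 %
#: (class 5 uses the midpoint of 65-100%)
COVER_CLASS_MIDPOINTS = {1: 0.025, 2: 0.095, 3: 0.275, 4: 0.525, 5: 0.825}

MIN_ALLOMETRY_DBH_CM = 2.5
WOODY_HEIGHT_THRESHOLD_M = 0.7
CP_PER_N = 6.25
CP_LIGNIN_THRESHOLD = 0.8
WOODY_FORMS = ("tree", "shrub")


def allometric_tree_biomass_kg(dbh_cm: float, enforce_min: bool = True) -> float:
    """Whole-tree aboveground biomass (kg) from DBH (cm).

    Evaluates exp(-2.134 + 2.53 ln DBH).  Stems below 2.5 cm DBH are outside
    the allometry's domain and must be routed to the biovolume path; pass
    ``enforce_min=False`` only to evaluate the bare formula.
    """
    if dbh_cm <= 0:
        raise InvalidArgumentError(f"DBH must be positive, got {dbh_cm}")
    if enforce_min and dbh_cm < MIN_ALLOMETRY_DBH_CM:
        raise InvalidArgumentError(
            f"DBH {dbh_cm} cm below allometry threshold {MIN_ALLOMETRY_DBH_CM} cm"
        )
    return math.exp(-2.134 + 2.53 * math.log(dbh_cm))


def cover_class_midpoint(cover_class: int) -> float:
    """Midpoint (proportion) of a 5-point cover class."""
    try:
        return COVER_CLASS_MIDPOINTS[int(cover_class)]
    except (KeyError, TypeError, ValueError):
        raise InvalidArgumentError(f"cover class must be 1..5, got {cover_class!r}") from None


def _trait_row(traits: pd.DataFrame, species_id: str) -> pd.Series:
    if species_id not in traits.index:
        raise MissingTraitError(f"species {species_id!r} absent from trait table")
    return traits.loc[species_id]


def is_quality_forage(trait_row: pd.Series) -> bool:
    """True when green-tissue CP:lignin = 6.25*N% / lignin% >= 0.8 (inclusive)."""
    lignin = float(trait_row["lignin_pct"])
    if lignin == 0:
        raise UndefinedRatioError(f"lignin 0 for species {trait_row.name!r}")
    return CP_PER_N * float(trait_row["n_pct"]) / lignin >= CP_LIGNIN_THRESHOLD


def species_biomass(survey: pd.DataFrame, traits: pd.DataFrame) -> pd.DataFrame:
    """Per-record aboveground, green and woody biomass (t/ha).

    ``survey`` holds one row per species x plot with columns ``plot_id``,
    ``species_id``, ``growth_form``, ``avg_height_m``, ``cover_class``,
    ``dbh_cm`` (list of floats, possibly empty) and ``biovolume_m3``.
    Both estimation paths are summed per record; the allometric share of a
    mixed-size species is assumed NOT to be included in its biovolume (split
    biovolumes); when both paths contribute the overlap risk is logged once.
    """
    rows = []
    for _, rec in survey.iterrows():
        sp = rec["species_id"]
        tr = _trait_row(traits, sp)
        biovol = float(rec["biovolume_m3"])
        if biovol < 0:
            raise InvalidArgumentError(f"negative biovolume for {sp} in {rec['plot_id']}")
        dbhs = rec["dbh_cm"] if isinstance(rec["dbh_cm"], (list, tuple, np.ndarray)) else []
        allom_kg = sum(allometric_tree_biomass_kg(d) for d in dbhs)
        biovol_kg = biovol * float(tr["conv_factor"])
        if allom_kg > 0 and biovol_kg > 0:
            log.debug(
                "species %s in %s has both DBH stems and biovolume; "
                "biovolume assumed to exclude large stems",
                sp,
                rec["plot_id"],
            )
        above = (allom_kg + biovol_kg) * PLOT_TO_HA
        rows.append(
            {
                "plot_id": rec["plot_id"],
                "species_id": sp,
                "growth_form": rec["growth_form"],
                "avg_height_m": float(rec["avg_height_m"]),
                "aboveground_t_ha": above,
                "green_t_ha": above * float(tr["green_fraction"]),
                "woody_t_ha": above * float(tr["woody_fraction"]),
                "allometric_t_ha": allom_kg * PLOT_TO_HA,
                "biovolume_t_ha": biovol_kg * PLOT_TO_HA,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "plot_id",
            "species_id",
            "growth_form",
            "avg_height_m",
            "aboveground_t_ha",
            "green_t_ha",
            "woody_t_ha",
            "allometric_t_ha",
            "biovolume_t_ha",
        ],
    )


def biovolume_to_biomass(record: pd.Series, traits: pd.DataFrame) -> pd.Series:
    """Biovolume-path biomass (t/ha) for a single record."""
    tr = _trait_row(traits, record["species_id"])
    biovol = float(record["biovolume_m3"])
    if biovol < 0:
        raise InvalidArgumentError("biovolume must be >= 0")
    above = biovol * float(tr["conv_factor"]) * PLOT_TO_HA
    return pd.Series(
        {
            "aboveground_t_ha": above,
            "green_t_ha": above * float(tr["green_fraction"]),
            "woody_t_ha": above * float(tr["woody_fraction"]),
        }
    )


def _is_wood_esp(growth_form: str, avg_height_m: float) -> bool:
    return growth_form in WOODY_FORMS and avg_height_m >= WOODY_HEIGHT_THRESHOLD_M


def _is_forage_candidate(growth_form: str, avg_height_m: float) -> bool:
    return growth_form == "herb" or (
        growth_form in WOODY_FORMS and avg_height_m < WOODY_HEIGHT_THRESHOLD_M
    )


def wood_biomass(plot_survey: pd.DataFrame, traits: pd.DataFrame) -> float:
    """Wood ecosystem function (t/ha) for one plot.

    Woody-fraction biomass summed over (a) allometric biomass of every stem
    >= 2.5 cm DBH and (b) the biovolume path of woody species with average
    height >= 0.7 m.  Herbs and short woody plants contribute nothing.
    """
    per = species_biomass(plot_survey, traits)
    total = 0.0
    for _, r in per.iterrows():
        wf = float(traits.loc[r["species_id"], "woody_fraction"])
        total += r["allometric_t_ha"] * wf
        if _is_wood_esp(r["growth_form"], r["avg_height_m"]):
            total += r["biovolume_t_ha"] * wf
    return total


def forage_biomass(plot_survey: pd.DataFrame, traits: pd.DataFrame) -> float:
    """Forage ecosystem function (t/ha) for one plot.

    Green-fraction biomass of herbaceous species and woody species < 0.7 m
    average height, restricted to higher-quality forage (CP:lignin >= 0.8).
    A ``forage_known`` trait flag, when present and contradicting the rule,
    is logged but the chemistry rule decides membership.
    """
    per = species_biomass(plot_survey, traits)
    total = 0.0
    for _, r in per.iterrows():
        if not _is_forage_candidate(r["growth_form"], r["avg_height_m"]):
            continue
        tr = traits.loc[r["species_id"]]
        quality = is_quality_forage(tr)
        if "forage_known" in tr.index and not pd.isna(tr["forage_known"]):
            if bool(tr["forage_known"]) != quality:
                log.warning(
                    "species %s: forage_known=%s contradicts CP:lignin rule (%s)",
                    r["species_id"],
                    tr["forage_known"],
                    quality,
                )
        if quality:
            total += r["green_t_ha"]
    return total


def green_biomass_by_species(plot_survey: pd.DataFrame, traits: pd.DataFrame) -> pd.Series:
    """Standing green biomass (t/ha) per species for one plot — the
    abundance weights for richness, FD and community-weighted means."""
    per = species_biomass(plot_survey, traits)
    return per.groupby("species_id")["green_t_ha"].sum()


def plot_biomass_summary(survey: pd.DataFrame, traits: pd.DataFrame) -> pd.DataFrame:
    """Plot-level biomass totals and the wood/forage functions (t/ha)."""
    rows = []
    for plot_id, grp in survey.groupby("plot_id", sort=True):
        per = species_biomass(grp, traits)
        rows.append(
            {
                "plot_id": plot_id,
                "aboveground_t_ha": per["aboveground_t_ha"].sum(),
                "green_t_ha": per["green_t_ha"].sum(),
                "woody_t_ha": per["woody_t_ha"].sum(),
                "wood_function_t_ha": wood_biomass(grp, traits),
                "forage_function_t_ha": forage_biomass(grp, traits),
            }
        )
    return pd.DataFrame(rows)
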