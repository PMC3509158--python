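"""End-to-end composition of the analysis stages.

Raw tables -> ecosystem-function profiles (wood, forage, cations,
infiltration) -> diversity metrics -> multifunctionality indicators and
jointness -> diversity-vs-environment model comparison.  Every stage is a
pure function over DataFrames; :func:`run_pipeline` wires them together and
writes the result bundle with a data dictionary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import biomass, diversity, inference, multifunc, soil
from .synth import FallowDataset

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    thresholds: tuple[float, ...] = (0.25, 0.5, 0.75)
    cation_scale: float = multifunc.DEFAULT_CATION_SCALE
    soil_layer: str = "topsoil"
    cwm_on_filtered: bool = False
    shared_k: bool = False
    #: 'midpoint' codes grazing intensity as the cover-class midpoint
    #: proportion (0-1); 'ordinal' uses the raw 1-5 class
    grazing_coding: str = "midpoint"
    #: SOC enters regressions as a fraction (g/g) when True, matching the
    #: magnitude of the printed soil-carbon coefficients
    soc_as_fraction: bool = True
    seed: int = 0


def compute_function_profiles(dataset: FallowDataset, config: PipelineConfig | None = None) -> pd.DataFrame:
    """Per-plot raw and transformed values of the four ecosystem functions."""
    config = config or PipelineConfig()
    bm = biomass.plot_biomass_summary(dataset.survey, dataset.traits)
    so = soil.aggregate_soil(dataset.soils, layer=config.soil_layer)
    inf = soil.infiltration_by_plot(dataset.infiltration, shared_k=config.shared_k)
    prof = (
        dataset.plots[["plot_id", "fallow_type"]]
        .merge(bm[["plot_id", "wood_function_t_ha", "forage_function_t_ha"]], on="plot_id", how="left")
        .merge(so, on="plot_id", how="left")
        .merge(inf, on="plot_id", how="left")
    )
    prof = prof.rename(
        columns={
            "wood_function_t_ha": "wood_raw",
            "forage_function_t_ha": "forage_raw",
            "base_cations": "cations_raw",
            "infiltration_mm_hr": "infiltration_raw",
        }
    )
    prof[["wood_raw", "forage_raw"]] = prof[["wood_raw", "forage_raw"]].fillna(0.0)
    for f in multifunc.FUNCTIONS:
        prof[f] = prof[f"{f}_raw"].map(
            lambda v: multifunc.transform_function(v, f, config.cation_scale)
        )
    return prof


def compute_diversity_metrics(dataset: FallowDataset, config: PipelineConfig | None = None) -> pd.DataFrame:
    """Richness, FD, CWMs and group-weighted trait means per plot."""
    config = config or PipelineConfig()
    std_traits = diversity.standardize_trait_matrix(dataset.traits)
    rows = []
    for plot_id, grp in dataset.survey.groupby("plot_id", sort=True):
        green = biomass.green_biomass_by_species(grp, dataset.traits)
        metrics = diversity.plot_diversity_metrics(
            grp, dataset.traits, std_traits, green, cwm_on_filtered=config.cwm_on_filtered
        )
        rows.append({"plot_id": plot_id, **metrics})
    return pd.DataFrame(rows)


def compute_indicators(profiles: pd.DataFrame, config: PipelineConfig | None = None):
    """Multifunctionality indicators and both jointness modes."""
    config = config or PipelineConfig()
    indicators, refs = multifunc.indicator_table(profiles, thresholds=config.thresholds)
    joint = pd.concat(
        [
            multifunc.jointness(profiles, refs, mode="half_max"),
            multifunc.jointness(profiles, refs, mode="above_mean"),
        ],
        ignore_index=True,
    )
    return indicators, joint, refs


def model_frame(
    dataset: FallowDataset,
    indicators: pd.DataFrame,
    div: pd.DataFrame,
    profiles: pd.DataFrame,
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Assemble the per-plot modelling frame (responses + predictors)."""
    config = config or PipelineConfig()
    frame = (
        indicators.merge(div[["plot_id", "richness", "fd"]], on="plot_id")
        .merge(profiles[["plot_id", "soc_pct"]], on="plot_id")
        .merge(
            dataset.plots[["plot_id", "grazing_class", "grazing_intensity"]],
            on="plot_id",
        )
    )
    frame["soc"] = frame["soc_pct"] / 100.0 if config.soc_as_fraction else frame["soc_pct"]
    if config.grazing_coding == "midpoint":
        frame["grazing"] = frame["grazing_intensity"]
    else:
        inv = {v: k for k, v in biomass.COVER_CLASS_MIDPOINTS.items()}
        frame["grazing"] = frame["grazing_intensity"].map(inv)
    return frame


@dataclass
class PipelineResult:
    profiles: pd.DataFrame
    diversity: pd.DataFrame
    indicators: pd.DataFrame
    jointness: pd.DataFrame
    models: pd.DataFrame
    frame: pd.DataFrame = field(default=None)


def run_pipeline(dataset: FallowDataset, config: PipelineConfig | None = None) -> PipelineResult:
    """Run every stage on a dataset; deterministic given inputs."""
    config = config or PipelineConfig()
    log.info(
        "pipeline config: thresholds=%s cation_scale=%s layer=%s cwm_filtered=%s "
        "shared_k=%s grazing=%s soc_fraction=%s",
        config.thresholds,
        config.cation_scale,
        config.soil_layer,
        config.cwm_on_filtered,
        config.shared_k,
        config.grazing_coding,
        config.soc_as_fraction,
    )
    profiles = compute_function_profiles(dataset, config)
    div = compute_diversity_metrics(dataset, config)
    indicators, joint, _ = compute_indicators(profiles, config)
    frame = model_frame(dataset, indicators, div, profiles, config)
    key = f"{0.5:g}".replace(".", "")
    responses = (f"prop_asin_{key}", "mpe") if 0.5 in config.thresholds else (
        f"prop_asin_{f'{config.thresholds[0]:g}'.replace('.', '')}",
        "mpe",
    )
    models = inference.run_model_suite(frame, indicators=responses)
    return PipelineResult(
        profiles=profiles,
        diversity=div,
        indicators=indicators,
        jointness=joint,
        models=models,
        frame=frame,
    )


DATA_DICTIONARY = [
    ("function_profiles.csv", "wood_raw", "standing woody biomass of trees/large shrubs, t/ha"),
    ("function_profiles.csv", "forage_raw", "quality-forage green biomass, t/ha"),
    ("function_profiles.csv", "cations_raw", "topsoil base cations Mg+Ca+K, meq/100 g"),
    ("function_profiles.csv", "infiltration_raw", "steady (Horton asymptote) infiltration, mm/hr"),
    ("function_profiles.csv", "wood/forage/cations/infiltration", "transformed-scale function values"),
    ("function_profiles.csv", "soc_pct", "topsoil soil organic carbon, %"),
    ("function_profiles.csv", "sand_pct", "topsoil sand content, %"),
    ("diversity_metrics.csv", "richness", "species with >=1% of standing green biomass"),
    ("diversity_metrics.csv", "fd", "UPGMA dendrogram summed branch length, ln-trait space"),
    ("diversity_metrics.csv", "cwm_*", "green-biomass-weighted mean of ln trait, all species"),
    ("diversity_metrics.csv", "gwm_trees_*/gwm_forage_*", "group-weighted ln-trait means, wood/forage ESP"),
    ("indicators.csv", "prop_above_*", "proportion of 4 functions >= tau * type maximum"),
    ("indicators.csv", "prop_asin_*", "arcsine-sqrt of the proportion (modelling scale)"),
    ("indicators.csv", "mpe", "mean % excess of transformed functions over type means"),
    ("jointness.csv", "incidence", "plots with both pair functions above threshold"),
    ("models.csv", "estimate/t/p/adj_r2", "OLS coefficient, t, two-sided P, adjusted R^2"),
]


def write_results(result: PipelineResult, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.profiles.to_csv(out / "function_profiles.csv", index=False)
    result.diversity.to_csv(out / "diversity_metrics.csv", index=False)
    result.indicators.to_csv(out / "indicators.csv", index=False)
    result.jointness.to_csv(out / "jointness.csv", index=False)
    result.models.to_csv(out / "models.csv", index=False)
    pd.DataFrame(DATA_DICTIONARY, columns=["file", "column", "description"]).to_csv(
        out / "data_dictionary.csv", index=False
    )


def text_report(result: PipelineResult) -> str:
    """Short plain-text summary of the model comparison."""
    lines = ["Fallow multifunctionality analysis", "=" * 34, ""]
    for ftype, grp in result.indicators.groupby("fallow_type"):
        lines.append(
            f"{ftype}: n={len(grp)}, prop above half-max mean="
            f"{grp['prop_above_05'].mean():.3f}, mpe mean={grp['mpe'].mean():.2f}% "
            f"(sd {grp['mpe'].std():.1f})"
        )
    lines.append("")
    lines.append("Univariate model adjusted R^2 by predictor:")
    uni = result.models[~result.models["model"].str.contains(r"\+")]
    for (ftype, resp), grp in uni.groupby(["fallow_type", "response"]):
        parts = ", ".join(
            f"{r.predictor}: {r.adj_r2:.3f} (P={r.p:.3f})" for r in grp.itertuples()
        )
        lines.append(f"  {ftype} / {resp}: {parts}")
    return "\n".join(lines) + "\n"
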