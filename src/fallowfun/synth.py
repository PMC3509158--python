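"""Seeded synthetic fallow datasets with the structure the analysis assumes.

The generator emulates a survey of smallholder fallows of two management
types: *improved* fallows dominated by 1-3 planted woody legumes holding at
least 80% of standing green biomass, and more species-rich *grazed* fallows
(5-15 species, uneven Dirichlet abundances, graded grazing intensity with
the moderate class over-represented).  Per-type raw-scale means of the four
ecosystem functions are calibrated to the study's descriptive table
(:data:`TABLE1_CALIBRATION`).

Effects are planted additively on the transformed-function scale,

    t_f = base_f + scale_f * (effect * z_cov + noise_sd * eps),

where ``z_cov`` is realized functional diversity (grazed) or topsoil SOC
(improved) standardised by its realized per-type moments, so the
calibration targets are preserved for any effect size; ``scale_f`` is the
calibration SD mapped to the transformed scale and ``base_f`` is solved so
the back-transformed raw value has the calibration mean in expectation
(the back-transforms are curved, so a naive base = T(mean) would bias raw
means).  Raw function targets are the inverse transforms, and survey
records, soil subplots and infiltration curves are constructed so that the
downstream pipeline recovers them.

Two output granularities:

* :func:`generate_profiles` — per-plot covariates and planted function
  values (fast path for Monte-Carlo power / type-I studies);
* :func:`generate_fallow_survey` — the full five-table dataset (survey,
  traits, soils, infiltration curves, plot metadata) for the end-to-end
  pipeline.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .biomass import COVER_CLASS_MIDPOINTS, allometric_tree_biomass_kg, is_quality_forage
from .diversity import abundance_filter, functional_diversity, standardize_trait_matrix
from .errors import InvalidArgumentError
from .multifunc import FUNCTIONS, inverse_transform, transform_function
from .soil import horton_rate

#: Per-type raw-scale (mean, SD) of the four ecosystem functions used as
#: default calibration targets: wood and forage in t/ha, base cations in
#: meq/100 g, steady infiltration in mm/hr.
TABLE1_CALIBRATION = {
    "grazed": {
        "wood": (3.0, 3.3),
        "forage": (2.4, 1.2),
        "cations": (4.8, 2.2),
        "infiltration": (261.8, 198.1),
    },
    "improved": {
        "wood": (24.2, 5.9),
        "forage": (1.7, 1.1),
        "cations": (3.7, 1.2),
        "infiltration": (371.0, 148.1),
    },
}

GRAZING_CLASSES = ("light", "moderate", "heavy")
#: 5-point cover classes backing each grazing group (4-40 / 40-65 / >65 %)
GRAZING_COVER_CLASSES = {"light": (2, 3), "moderate": (4,), "heavy": (5,)}

INFILTRATION_TIMES_MIN = (1, 2, 4, 6, 9, 12, 16, 21, 27, 34, 42, 51, 65, 85, 110, 140)


@dataclass(frozen=True)
class HortonRanges:
    """Admissible ranges for generated infiltration curves; ``noise_sd`` is
    the Gaussian measurement noise on rates (mm/hr)."""

    f0: tuple[float, float] = (100.0, 1600.0)
    fc: tuple[float, float] = (20.0, 800.0)
    k: tuple[float, float] = (0.02, 0.12)
    noise_sd: float = 8.0


@dataclass
class GeneratorConfig:
    n_grazed: int = 18
    n_improved: int = 21
    species_pool_size: int = 60
    #: slope of the standardised transformed-function response per SD of
    #: realized functional diversity in grazed fallows (dimensionless)
    effect_fd_grazed: float = 0.8
    #: slope per SD of realized topsoil SOC in improved fallows
    effect_soc_improved: float = 0.8
    #: residual SD per function as a fraction of its calibration SD
    #: (transformed scale)
    noise_sd: float = 0.7
    horton_params: HortonRanges = field(default_factory=HortonRanges)
    calibration_targets: dict = field(
        default_factory=lambda: copy.deepcopy(TABLE1_CALIBRATION)
    )
    seed: int = 0

    def validate(self) -> None:
        if self.n_grazed <= 0 or self.n_improved <= 0 or self.species_pool_size <= 0:
            raise InvalidArgumentError("plot counts and species pool must be positive")
        if self.noise_sd < 0:
            raise InvalidArgumentError("noise_sd must be >= 0")
        h = self.horton_params
        if h.fc[0] > h.f0[0] or h.fc[1] > h.f0[1]:
            raise InvalidArgumentError(
                f"fc range {h.fc} must lie at or below f0 range {h.f0} elementwise"
            )
        if h.k[0] <= 0 or h.k[1] < h.k[0]:
            raise InvalidArgumentError(f"invalid k range {h.k}")
        for ftype, targets in self.calibration_targets.items():
            for f in FUNCTIONS:
                mean, sd = targets[f]
                if mean <= 0 or sd < 0:
                    raise InvalidArgumentError(
                        f"bad calibration target {ftype}/{f}: ({mean}, {sd})"
                    )


@dataclass
class FallowDataset:
    """Synthetic survey bundle: plot metadata, the four input tables, and
    the generation-time truth (``profiles``) for parameter-recovery tests."""

    plots: pd.DataFrame
    survey: pd.DataFrame
    traits: pd.DataFrame
    soils: pd.DataFrame
    infiltration: pd.DataFrame
    profiles: pd.DataFrame
    provenance: dict


# --- trait table ----------------------------------------------------------

_LN_TRAIT_PARAMS = {
    # trait: (ln-mean, ln-sd, low, high) on the raw %-dry-mass scale
    "n_pct": (math.log(1.8), 0.42, 0.5, 5.0),
    "lignin_pct": (math.log(8.0), 0.48, 2.0, 25.0),
    "polyphenol_pct": (math.log(2.5), 0.52, 0.5, 10.0),
}


def generate_trait_table(n_species: int, seed: int) -> pd.DataFrame:
    """Species trait/conversion table with mutually near-uncorrelated traits.

    Tissue chemistry is log-normal within field-plausible ranges; the ln
    draws are whitened to zero sample correlation (for n >= 4) so pairwise
    |r| stays small by construction.  Growth form, green/woody fractions
    and the biovolume-to-biomass conversion factor (kg/m^3) depend on form.
    """
    if n_species < 1:
        raise InvalidArgumentError(f"n_species must be >= 1, got {n_species}")
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n_species, 3))
    if n_species >= 4:
        zc = z - z.mean(axis=0)
        cov = np.cov(zc, rowvar=False)
        try:
            L = np.linalg.cholesky(cov)
            z = zc @ np.linalg.inv(L).T  # exactly uncorrelated columns, unit var
        except np.linalg.LinAlgError:
            pass
    cols = {}
    for j, (trait, (mu, sd, lo, hi)) in enumerate(_LN_TRAIT_PARAMS.items()):
        ln_vals = np.clip(mu + sd * z[:, j], math.log(lo), math.log(hi))
        cols[trait] = np.clip(np.exp(ln_vals), lo, hi)

    forms = rng.choice(["herb", "shrub", "tree"], size=n_species, p=[0.5, 0.3, 0.2])
    green = np.empty(n_species)
    woody = np.empty(n_species)
    conv = np.empty(n_species)
    for i, gf in enumerate(forms):
        if gf == "tree":
            green[i] = rng.uniform(0.25, 0.35)
            woody[i] = rng.uniform(0.60, 0.70)
            conv[i] = rng.lognormal(math.log(3.5), 0.25)
        elif gf == "shrub":
            green[i] = rng.uniform(0.35, 0.50)
            woody[i] = rng.uniform(0.40, 0.55)
            conv[i] = rng.lognormal(math.log(2.5), 0.25)
        else:
            green[i] = rng.uniform(0.80, 0.92)
            woody[i] = 0.0
            conv[i] = rng.lognormal(math.log(1.5), 0.25)
        woody[i] = min(woody[i], 1.0 - green[i])

    table = pd.DataFrame(
        {
            "growth_form": forms,
            "n_pct": cols["n_pct"],
            "lignin_pct": cols["lignin_pct"],
            "polyphenol_pct": cols["polyphenol_pct"],
            "green_fraction": green,
            "woody_fraction": woody,
            "conv_factor": conv,
        },
        index=pd.Index([f"sp{i:03d}" for i in range(n_species)], name="species_id"),
    )
    return table


# --- infiltration curves --------------------------------------------------

def generate_infiltration_curve(
    f0: float,
    fc: float,
    k: float,
    times: Sequence[float],
    noise_sd: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Horton decay curve fc + (f0-fc) e^{-kt} plus Gaussian rate noise."""
    if fc > f0:
        raise InvalidArgumentError(f"fc {fc} exceeds f0 {f0}")
    if fc <= 0 or k <= 0:
        raise InvalidArgumentError("need fc > 0 and k > 0")
    t = np.asarray(times, dtype=float)
    if np.any(np.diff(t) <= 0):
        raise InvalidArgumentError("times must be increasing")
    if noise_sd < 0:
        raise InvalidArgumentError("noise_sd must be >= 0")
    rates = horton_rate(t, f0, fc, k)
    if noise_sd > 0:
        rates = rates + np.random.default_rng(seed).normal(0.0, noise_sd, t.size)
    return np.clip(rates, 0.0, None)


# --- core generation ------------------------------------------------------

def _transformed_scale(mean: float, sd: float, kind: str) -> float:
    """Calibration SD mapped to the transformed scale via a symmetric
    difference around the calibration mean."""
    lo = max(mean - sd, 0.0)
    hi = mean + sd
    if kind == "cations":
        hi = min(hi, 99.0)
    scale = (transform_function(hi, kind) - transform_function(lo, kind)) / 2.0
    return max(scale, 1e-9)


def _jensen_base(mean: float, s_tot: float, kind: str, cation_scale: float = 100.0) -> float:
    """Transformed-scale baseline such that, for t ~ N(base, s_tot), the
    back-transformed raw value has expectation ``mean`` (the back-transforms
    are convex/concave, so base = T(mean) would bias the raw-scale mean)."""
    if kind == "wood":  # E[e^t - 1] = e^{b + s^2/2} - 1
        return math.log1p(mean) - s_tot**2 / 2.0
    if kind in ("forage", "infiltration"):  # E[t^2] = b^2 + s^2
        return math.sqrt(max(mean - s_tot**2, 0.01 * mean))
    if kind == "cations":  # E[c sin^2 t] = c/2 (1 - e^{-2 s^2} cos 2b)
        arg = (1.0 - 2.0 * mean / cation_scale) * math.exp(2.0 * s_tot**2)
        return 0.5 * math.acos(float(np.clip(arg, -1.0, 1.0)))
    raise InvalidArgumentError(f"unknown function kind {kind!r}")


def _clip_transformed(t: float, kind: str, horton: HortonRanges) -> float:
    if kind == "cations":
        return float(np.clip(t, 1e-3, math.asin(math.sqrt(0.99))))
    if kind == "infiltration":
        return float(np.clip(t, math.sqrt(horton.fc[0]), math.sqrt(horton.fc[1])))
    if kind == "forage":
        # every fallow keeps a trace of quality forage so plots never end up
        # with zero standing green biomass
        return float(max(t, math.sqrt(0.05)))
    return float(max(t, 0.0))


def _generate_core(config: GeneratorConfig) -> tuple[pd.DataFrame, pd.DataFrame, list[dict]]:
    """Traits, standardized traits, and per-plot cores (community, covariates,
    planted transformed/raw function values)."""
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    trait_seed, core_seed = ss.spawn(2)
    traits = generate_trait_table(
        config.species_pool_size, int(trait_seed.generate_state(1)[0] % 2**31)
    )
    rng = np.random.default_rng(core_seed)

    # designated planted woody legumes: need >= 4 tall tree species in pool
    tree_ids = list(traits.index[traits["growth_form"] == "tree"])
    i = 0
    while len(tree_ids) < 4 and i < len(traits):
        sp = traits.index[i]
        if sp not in tree_ids:
            traits.loc[sp, "growth_form"] = "tree"
            traits.loc[sp, "green_fraction"] = rng.uniform(0.25, 0.35)
            traits.loc[sp, "woody_fraction"] = min(
                rng.uniform(0.60, 0.70), 1.0 - traits.loc[sp, "green_fraction"]
            )
            tree_ids.append(sp)
        i += 1
    dominant_pool = tree_ids[:4]
    # herbs qualifying as forage, for guaranteed forage presence
    herb_ids = [
        s
        for s in traits.index
        if traits.loc[s, "growth_form"] == "herb" and is_quality_forage(traits.loc[s])
    ]
    if not herb_ids:  # force one
        sp = traits.index[traits["growth_form"] == "herb"][0] if (traits["growth_form"] == "herb").any() else traits.index[-1]
        traits.loc[sp, "growth_form"] = "herb"
        traits.loc[sp, "n_pct"] = 2.5
        traits.loc[sp, "lignin_pct"] = 6.0
        herb_ids = [sp]

    std_traits = standardize_trait_matrix(traits)

    cores: list[dict] = []
    for ftype, n_plots, prefix in (
        ("grazed", config.n_grazed, "G"),
        ("improved", config.n_improved, "I"),
    ):
        for idx in range(n_plots):
            plot_id = f"{prefix}{idx + 1:02d}"
            if ftype == "grazed":
                n_sp = int(rng.integers(5, 16))
                species = list(rng.choice(traits.index, size=n_sp, replace=False))
                # guarantee a wood ESP and a quality forage herb
                woody = [s for s in species if traits.loc[s, "growth_form"] != "herb"]
                if not woody:
                    species[0] = rng.choice([s for s in traits.index if traits.loc[s, "growth_form"] != "herb"])
                if not any(s in herb_ids for s in species):
                    species[-1] = rng.choice(herb_ids)
                species = list(dict.fromkeys(species))
                shares = rng.dirichlet(np.full(len(species), 0.5))
                gclass = rng.choice(GRAZING_CLASSES, p=[0.22, 0.56, 0.22])
                cover = int(rng.choice(GRAZING_COVER_CLASSES[gclass]))
                intensity = COVER_CLASS_MIDPOINTS[cover]
            else:
                n_dom = int(rng.integers(1, 4))
                doms = list(rng.choice(dominant_pool, size=n_dom, replace=False))
                n_u = int(rng.integers(2, 6))
                others = [s for s in traits.index if s not in doms]
                under = list(rng.choice(others, size=n_u, replace=False))
                if not any(s in herb_ids for s in under):
                    under[-1] = rng.choice(herb_ids)
                under = [s for s in dict.fromkeys(under) if s not in doms]
                species = doms + under
                dom_total = 0.80 + 0.15 * rng.beta(2.0, 2.0)
                dom_shares = rng.dirichlet(np.full(n_dom, 4.0)) * dom_total
                und_shares = rng.dirichlet(np.full(len(under), 0.8)) * (1 - dom_total)
                shares = np.concatenate([dom_shares, und_shares])
                gclass = None
                intensity = float("nan")

            share_ser = pd.Series(shares, index=species)
            included = abundance_filter(share_ser)
            fd = functional_diversity(included, std_traits)
            richness = len(included)

            if ftype == "grazed":
                soc = float(np.clip(rng.normal(1.5, 0.40), 0.4, 3.5))
                sand = float(np.clip(rng.normal(62.0, 7.0), 20.0, 90.0))
            else:
                soc = float(np.clip(rng.normal(1.8, 0.45), 0.4, 3.5))
                sand = float(np.clip(rng.normal(52.0, 7.0), 20.0, 90.0))

            cores.append(
                {
                    "plot_id": plot_id,
                    "fallow_type": ftype,
                    "grazing_class": gclass,
                    "grazing_intensity": intensity,
                    "year": 2008 + idx % 2,
                    "species": species,
                    "shares": share_ser,
                    "dominants": doms if ftype == "improved" else [],
                    "fd": fd,
                    "richness": richness,
                    "soc": soc,
                    "sand": sand,
                }
            )

    # plant effects on the standardised covariate (FD for grazed, SOC for
    # improved), centred and scaled by the realized per-type moments so the
    # calibration means are preserved for any effect size
    for ftype, cov_key in (("grazed", "fd"), ("improved", "soc")):
        sub = [c for c in cores if c["fallow_type"] == ftype]
        covs = np.array([c[cov_key] for c in sub], dtype=float)
        covbar = float(covs.mean())
        cov_sd = float(covs.std())
        if cov_sd < 1e-9:
            cov_sd = 1.0
        effect = config.effect_fd_grazed if ftype == "grazed" else config.effect_soc_improved
        inner_sd = math.hypot(effect, config.noise_sd)
        for c in sub:
            dev = (c[cov_key] - covbar) / cov_sd
            for f in FUNCTIONS:
                mean, sd = config.calibration_targets[ftype][f]
                scale = _transformed_scale(mean, sd, f)
                base = _jensen_base(mean, scale * inner_sd, f)
                t = base + scale * (effect * dev + config.noise_sd * rng.standard_normal())
                t = _clip_transformed(t, f, config.horton_params)
                c[f] = t
                c[f + "_raw"] = inverse_transform(t, f)
    return traits, std_traits, cores


def _profiles_frame(cores: list[dict]) -> pd.DataFrame:
    cols = [
        "plot_id",
        "fallow_type",
        "grazing_class",
        "grazing_intensity",
        "year",
        "fd",
        "richness",
        "soc",
        "sand",
    ]
    rows = []
    for c in cores:
        row = {k: c[k] for k in cols}
        for f in FUNCTIONS:
            row[f] = c[f]
            row[f + "_raw"] = c[f + "_raw"]
        rows.append(row)
    return pd.DataFrame(rows)


def generate_profiles(config: GeneratorConfig) -> pd.DataFrame:
    """Per-plot covariates and planted (transformed and raw) function values.

    Fast path for simulation studies: skips record/soil/curve construction
    but uses the same communities, covariates and planted effects as the
    full dataset.
    """
    _, _, cores = _generate_core(config)
    return _profiles_frame(cores)


# --- full survey construction --------------------------------------------

def _draw_stems(rng, target_woody_t_ha: float, woody_frac: float, cap: float = 0.8) -> tuple[list, float]:
    """DBH stems whose woody-fraction biomass stays below ``cap`` of target."""
    stems: list[float] = []
    cum = 0.0
    while len(stems) < 60:
        d = 2.5 + rng.gamma(2.0, 1.5)
        m = allometric_tree_biomass_kg(d) * woody_frac * 0.1
        if cum + m > cap * target_woody_t_ha:
            break
        stems.append(round(d, 2))
        cum += m
    return stems, cum


def _cover_class_from(biovol: float, height: float) -> int:
    frac = min(max(biovol / (max(height, 0.1) * 100.0), 0.005), 0.95)
    for cls, ub in ((1, 0.04), (2, 0.15), (3, 0.40), (4, 0.65)):
        if frac <= ub:
            return cls
    return 5


def generate_fallow_survey(config: GeneratorConfig) -> FallowDataset:
    """Full synthetic dataset: survey, traits, soils, infiltration, metadata.

    Survey records are constructed so that the downstream biomass pipeline
    recovers the planted wood and forage targets; soil subplots are jittered
    symmetrically around plot values so subplot means recover SOC and base
    cations exactly; infiltration curves are Horton curves around the
    planted steady rate.
    """
    traits, std_traits, cores = _generate_core(config)
    ss = np.random.SeedSequence((config.seed, 1))
    rng = np.random.default_rng(ss)

    survey_rows = []
    soil_rows = []
    infil_rows = []
    for c in cores:
        plot_id = c["plot_id"]
        ftype = c["fallow_type"]
        share = c["shares"]
        heights = {}
        for sp in c["species"]:
            gf = traits.loc[sp, "growth_form"]
            if gf == "tree":
                heights[sp] = float(rng.uniform(2.5, 6.0)) if sp in c["dominants"] else float(rng.uniform(1.8, 7.0))
            elif gf == "shrub":
                if ftype == "grazed" and rng.random() < 0.3:
                    heights[sp] = float(rng.uniform(0.3, 0.65))
                else:
                    heights[sp] = float(rng.uniform(0.8, 2.5))
            else:
                heights[sp] = float(rng.uniform(0.15, 1.0))
        # at least one tall woody plant per plot so the wood target has a home
        woody_sp = [sp for sp in c["species"] if traits.loc[sp, "growth_form"] != "herb"]
        if woody_sp and not any(heights[sp] >= 0.7 for sp in woody_sp):
            heights[woody_sp[0]] = float(rng.uniform(0.8, 1.5))

        wood_esp = [
            sp
            for sp in c["species"]
            if traits.loc[sp, "growth_form"] != "herb" and heights[sp] >= 0.7
        ]
        if ftype == "improved":
            wood_esp = [sp for sp in wood_esp if sp in c["dominants"]] or wood_esp
        forage_esp = [
            sp
            for sp in c["species"]
            if (
                traits.loc[sp, "growth_form"] == "herb"
                or heights[sp] < 0.7
            )
            and is_quality_forage(traits.loc[sp])
        ]
        rest = [sp for sp in c["species"] if sp not in wood_esp and sp not in forage_esp]

        records: dict[str, dict] = {}

        def _add(sp, biovol_m3, dbhs=None):
            rec = records.setdefault(
                sp,
                {
                    "plot_id": plot_id,
                    "species_id": sp,
                    "growth_form": traits.loc[sp, "growth_form"],
                    "avg_height_m": heights[sp],
                    "biovolume_m3": 0.0,
                    "dbh_cm": [],
                },
            )
            rec["biovolume_m3"] += biovol_m3
            if dbhs:
                rec["dbh_cm"].extend(dbhs)

        # wood target split over the wood ESP proportional to shares
        W = c["wood_raw"]
        if wood_esp and W > 0:
            w_shares = share[wood_esp] / share[wood_esp].sum()
            for sp in wood_esp:
                target = float(W * w_shares[sp])
                wf = float(traits.loc[sp, "woody_fraction"])
                conv = float(traits.loc[sp, "conv_factor"])
                stems, cum = ([], 0.0)
                if traits.loc[sp, "growth_form"] == "tree" and heights[sp] >= 1.8 and target > 0.3:
                    stems, cum = _draw_stems(rng, target, wf)
                remainder = max(target - cum, 0.0)
                biovol = remainder / (wf * conv * 0.1) if wf > 0 else 0.0
                _add(sp, biovol, stems)
        elif wood_esp:
            for sp in wood_esp:
                _add(sp, 0.0)

        # forage target split over quality forage species
        F = c["forage_raw"]
        if forage_esp and F > 0:
            f_shares = share[forage_esp] / share[forage_esp].sum()
            for sp in forage_esp:
                gf_frac = float(traits.loc[sp, "green_fraction"])
                conv = float(traits.loc[sp, "conv_factor"])
                biovol = float(F * f_shares[sp]) / (gf_frac * conv * 0.1)
                _add(sp, biovol)
        elif forage_esp:
            for sp in forage_esp:
                _add(sp, 0.0)

        # remaining species: green biomass proportional to their generated
        # shares relative to the forage ESP, so realized abundance shares
        # track the generated community structure
        if rest:
            share_f = float(share[forage_esp].sum()) if forage_esp else 0.2
            green_total = F / max(share_f, 0.2)
            for sp in rest:
                gf_frac = float(traits.loc[sp, "green_fraction"])
                conv = float(traits.loc[sp, "conv_factor"])
                g_target = float(green_total * share[sp])
                biovol = g_target / (max(gf_frac, 0.05) * conv * 0.1)
                _add(sp, biovol)

        # improved dominance: cap non-dominant green biomass at 24% of the
        # dominants' green biomass (also induces the wood-forage trade-off)
        if ftype == "improved":
            def green_of(sp):
                rec = records[sp]
                allom = sum(allometric_tree_biomass_kg(d) for d in rec["dbh_cm"])
                above = (allom + rec["biovolume_m3"] * traits.loc[sp, "conv_factor"]) * 0.1
                return above * float(traits.loc[sp, "green_fraction"])

            dom_green = sum(green_of(sp) for sp in c["dominants"] if sp in records)
            nondom = [sp for sp in records if sp not in c["dominants"]]
            nd_green = sum(green_of(sp) for sp in nondom)
            if dom_green > 0 and nd_green > 0.24 * dom_green:
                factor = 0.24 * dom_green / nd_green
                for sp in nondom:
                    records[sp]["biovolume_m3"] *= factor

        for sp, rec in records.items():
            rec["cover_class"] = _cover_class_from(rec["biovolume_m3"], rec["avg_height_m"])
            survey_rows.append(rec)

        # soils: symmetric subplot jitter around plot values
        C = c["cations_raw"]
        p_split = rng.dirichlet([42.0, 48.0, 10.0])
        d_soc, d_cat, d_sand = rng.normal(0.0, 0.04, 3)
        for subplot, sgn in (("center", 1.0), ("edge", -1.0)):
            for layer, f_soc, f_cat, add_sand in (("topsoil", 1.0, 1.0, 0.0), ("subsoil", 0.55, 0.7, 5.0)):
                soc_v = c["soc"] * f_soc * (1 + sgn * d_soc)
                cat_v = C * f_cat * (1 + sgn * d_cat)
                sand_v = min(c["sand"] + add_sand, 100.0) * (1 + sgn * d_sand * 0.5)
                soil_rows.append(
                    {
                        "plot_id": plot_id,
                        "subplot": subplot,
                        "layer": layer,
                        "soc_pct": max(soc_v, 0.0),
                        "mg": max(cat_v * p_split[0], 0.0),
                        "ca": max(cat_v * p_split[1], 0.0),
                        "k": max(cat_v * p_split[2], 0.0),
                        "sand_pct": float(np.clip(sand_v, 0.0, 100.0)),
                    }
                )

        # infiltration: Horton curves around the planted steady rate
        fc_plot = c["infiltration_raw"]
        d_f = rng.normal(0.0, 0.03)
        h = config.horton_params
        for subplot, sgn in (("center", 1.0), ("edge", -1.0)):
            fc_sub = float(np.clip(fc_plot * (1 + sgn * d_f), h.fc[0], h.fc[1]))
            f0_sub = float(np.clip(fc_sub * rng.uniform(2.2, 3.2), fc_sub + 10.0, h.f0[1]))
            k_sub = float(rng.uniform(*h.k))
            rates = generate_infiltration_curve(
                f0_sub,
                fc_sub,
                k_sub,
                INFILTRATION_TIMES_MIN,
                noise_sd=h.noise_sd,
                seed=int(rng.integers(2**31)),
            )
            for t, r in zip(INFILTRATION_TIMES_MIN, rates):
                infil_rows.append(
                    {
                        "plot_id": plot_id,
                        "subplot": subplot,
                        "time_min": float(t),
                        "rate_mm_hr": float(r),
                    }
                )

    plots = pd.DataFrame(
        [
            {
                "plot_id": c["plot_id"],
                "fallow_type": c["fallow_type"],
                "grazing_class": c["grazing_class"] if c["grazing_class"] else "",
                "grazing_intensity": c["grazing_intensity"],
                "year": c["year"],
            }
            for c in cores
        ]
    )
    survey = pd.DataFrame(survey_rows)[
        ["plot_id", "species_id", "growth_form", "avg_height_m", "cover_class", "dbh_cm", "biovolume_m3"]
    ]
    prov = {
        "seed": config.seed,
        "n_grazed": config.n_grazed,
        "n_improved": config.n_improved,
        "species_pool_size": config.species_pool_size,
        "effect_fd_grazed": config.effect_fd_grazed,
        "effect_soc_improved": config.effect_soc_improved,
        "noise_sd": config.noise_sd,
        "horton_params": asdict(config.horton_params),
        "calibration_targets": config.calibration_targets,
    }
    return FallowDataset(
        plots=plots,
        survey=survey,
        traits=traits,
        soils=pd.DataFrame(soil_rows),
        infiltration=pd.DataFrame(infil_rows),
        profiles=_profiles_frame(cores),
        provenance=prov,
    )
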