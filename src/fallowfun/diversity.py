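"""Plant diversity metrics: richness, functional diversity, trait means.

Species richness counts the species comprising >= 1% of a fallow's standing
green biomass (rare species disproportionately affect evenness and would
bias diversity-function estimates).  Functional diversity (FD) is the
summed branch length of a UPGMA (average-linkage) dendrogram built from
Euclidean distances among species in the space of three ln-transformed
functional traits — green-tissue N, lignins, polyphenols — standardised to
unit SD across the pooled species set of the dataset (per-plot scaling
would make FD values incomparable across fallows).  Node height equals the
merge distance, leaves sit at height zero, and each branch contributes
(parent height - child height); FD is 0 for communities of <= 1 species and
is unchanged by adding a species with traits identical to a member.

Community-weighted means (CWM) average ln-trait values weighted by standing
green biomass, either over the whole community or within the wood ESP
(trees/large shrubs >= 0.7 m) or the forage ESP (herbs and short woody
species with CP:lignin >= 0.8).
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist

from .biomass import _is_forage_candidate, _is_wood_esp, is_quality_forage
from .errors import InvalidArgumentError, MissingDataError, MissingTraitError

log = logging.getLogger(__name__)

TRAIT_COLUMNS = ("n_pct", "lignin_pct", "polyphenol_pct")
ABUNDANCE_THRESHOLD = 0.01


def abundance_filter(green_biomass: pd.Series) -> list[str]:
    """Species comprising >= 1% (inclusive) of plot standing green biomass."""
    total = float(green_biomass.sum())
    if total <= 0:
        log.warning("zero total green biomass; abundance filter returns empty set")
        return []
    share = green_biomass / total
    return sorted(share.index[share >= ABUNDANCE_THRESHOLD])


def species_richness(green_biomass: pd.Series) -> int:
    """Count of species passing the 1% green-biomass filter."""
    return len(abundance_filter(green_biomass))


def standardize_trait_matrix(traits: pd.DataFrame, columns: Sequence[str] = TRAIT_COLUMNS) -> pd.DataFrame:
    """ln-transform traits and scale each to unit SD across all species.

    Mean-centering is applied as well; Euclidean distances are translation
    invariant, so only the SD scaling matters for FD.  Standardisation uses
    the pooled species set so that one common trait space underlies every
    plot's FD.
    """
    mat = traits[list(columns)].astype(float)
    if (mat <= 0).any().any():
        bad = mat.index[(mat <= 0).any(axis=1)].tolist()
        raise InvalidArgumentError(f"non-positive trait values for species {bad}")
    ln = np.log(mat)
    sd = ln.std(ddof=1)
    sd = sd.replace(0.0, 1.0)  # a constant trait carries no distance information
    return (ln - ln.mean()) / sd


def _branch_length_sum(Z: np.ndarray, n: int) -> float:
    """Total branch length of a scipy linkage matrix with leaves at height 0."""
    heights = np.zeros(2 * n - 1)
    total = 0.0
    for i in range(Z.shape[0]):
        a, b, h = int(Z[i, 0]), int(Z[i, 1]), Z[i, 2]
        total += (h - heights[a]) + (h - heights[b])
        heights[n + i] = h
    return float(total)


def functional_diversity(species: Sequence[str], std_traits: pd.DataFrame) -> float:
    """Summed UPGMA dendrogram branch length over the given species.

    ``std_traits`` is the output of :func:`standardize_trait_matrix`.
    Species order does not matter; ties in merge distances are resolved
    deterministically by sorting the species labels first.
    """
    species = sorted(set(species))
    missing = [s for s in species if s not in std_traits.index]
    if missing:
        raise MissingTraitError(f"species missing from trait table: {missing}")
    if len(species) <= 1:
        return 0.0
    X = std_traits.loc[species].to_numpy(dtype=float)
    # functionally identical species occupy one leaf: they contribute zero
    # branch length and must not re-weight the UPGMA averages
    X = np.unique(X, axis=0)
    if len(X) <= 1:
        return 0.0
    Z = linkage(pdist(X, metric="euclidean"), method="average")
    return _branch_length_sum(Z, len(X))


def community_weighted_mean(
    weights: pd.Series, traits: pd.DataFrame, trait_col: str
) -> float:
    """Green-biomass-weighted mean of an ln-transformed trait."""
    w = weights[weights > 0]
    if w.empty:
        raise MissingDataError("no species with positive weight in scope")
    missing = [s for s in w.index if s not in traits.index]
    if missing:
        raise MissingTraitError(f"species missing from trait table: {missing}")
    vals = traits.loc[w.index, trait_col].astype(float)
    if (vals <= 0).any():
        raise InvalidArgumentError(f"non-positive {trait_col} in CWM scope")
    return float(np.average(np.log(vals), weights=w.to_numpy(dtype=float)))


def scope_weights(
    plot_survey: pd.DataFrame,
    traits: pd.DataFrame,
    green_biomass: pd.Series,
    scope: str,
) -> pd.Series:
    """Green-biomass weights restricted to an ESP scope.

    ``scope`` is ``'all'``, ``'trees_shrubs'`` (woody, avg height >= 0.7 m)
    or ``'forage'`` (herbs/short woody with CP:lignin >= 0.8).
    """
    if scope == "all":
        return green_biomass
    keep = []
    for _, rec in plot_survey.iterrows():
        sp = rec["species_id"]
        if scope == "trees_shrubs":
            if _is_wood_esp(rec["growth_form"], float(rec["avg_height_m"])):
                keep.append(sp)
        elif scope == "forage":
            if _is_forage_candidate(rec["growth_form"], float(rec["avg_height_m"])) and is_quality_forage(traits.loc[sp]):
                keep.append(sp)
        else:
            raise InvalidArgumentError(f"unknown CWM scope {scope!r}")
    return green_biomass[green_biomass.index.isin(keep)]


def plot_diversity_metrics(
    plot_survey: pd.DataFrame,
    traits: pd.DataFrame,
    std_traits: pd.DataFrame,
    green_biomass: pd.Series,
    cwm_on_filtered: bool = False,
) -> dict:
    """All diversity metrics for one plot.

    Richness and FD always use the 1% abundance filter; CWMs use all
    species by default (``cwm_on_filtered=True`` restricts them too).
    Group-weighted means that have no qualifying species are NaN (logged).
    """
    included = abundance_filter(green_biomass)
    out = {
        "richness": len(included),
        "fd": functional_diversity(included, std_traits),
    }
    cwm_weights = green_biomass[included] if cwm_on_filtered else green_biomass
    for trait_col, short in (("n_pct", "n"), ("lignin_pct", "lignin"), ("polyphenol_pct", "polyphenol")):
        try:
            out[f"cwm_{short}"] = community_weighted_mean(cwm_weights, traits, trait_col)
        except MissingDataError:
            log.warning("no positive green biomass in a plot; CWM NaN")
            out[f"cwm_{short}"] = float("nan")
        for scope, tag in (("trees_shrubs", "trees"), ("forage", "forage")):
            w = scope_weights(plot_survey, traits, cwm_weights, scope)
            try:
                out[f"gwm_{tag}_{short}"] = community_weighted_mean(w, traits, trait_col)
            except MissingDataError:
                log.warning("empty %s scope for a plot; group mean NaN", scope)
                out[f"gwm_{tag}_{short}"] = float("nan")
    return out
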