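"""Ecosystem-function transformations and multifunctionality indicators.

Four ecosystem functions serve as indicators of ecosystem services in a
fallow: standing wood biomass (t/ha), quality forage biomass (t/ha), soil
base cations (meq/100 g) and steady infiltration rate (mm/hr).  Each is
variance-stabilised before indicator calculation:

    wood          ln(x + 1)
    forage        sqrt(x)
    cations       arcsin(sqrt(x / c)),  c = 100 (meq per 100 g)
    infiltration  sqrt(x)

Two multifunctionality indicators are computed on the transformed scale:

* **proportion above half-maximum** — the fraction of the four functions at
  or above tau times the function's maximum, the maximum being the mean of
  the 3 highest values within the fallow type (tau = 0.25, 0.50, 0.75);
* **mean percentage excess** — the mean over functions of the percentage by
  which a fallow's value exceeds the type-wise function mean.  By
  construction this averages to exactly zero over the fallows that define
  the means.

Pairwise *jointness* counts, for each unordered pair of functions, the
fallows holding both at or above half-maximum (or above the type mean).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import InsufficientSampleError, InvalidArgumentError, MissingDataError

log = logging.getLogger(__name__)

FUNCTIONS = ("wood", "forage", "cations", "infiltration")

#: scaling constant mapping base cations (meq/100 g) into [0, 1] for the
#: arcsine-square-root transform
DEFAULT_CATION_SCALE = 100.0


def transform_function(value: float, kind: str, cation_scale: float = DEFAULT_CATION_SCALE) -> float:
    """Apply the registered variance-stabilising transform for one function.

    ``wood`` uses ln(x+1) rather than a bare log because heavily grazed
    fallows can carry zero wood; a strict-log variant would need a positive
    floor and is not offered by default.
    """
    if value < 0:
        raise InvalidArgumentError(f"{kind}: negative function value {value}")
    if kind == "wood":
        return math.log1p(value)
    if kind == "forage" or kind == "infiltration":
        return math.sqrt(value)
    if kind == "cations":
        if value > cation_scale:
            raise InvalidArgumentError(
                f"cations {value} exceeds scaling constant {cation_scale}"
            )
        return math.asin(math.sqrt(value / cation_scale))
    raise InvalidArgumentError(f"unknown function kind {kind!r}")


def inverse_transform(t: float, kind: str, cation_scale: float = DEFAULT_CATION_SCALE) -> float:
    """Map a transformed-scale value back to the raw measurement scale."""
    if kind == "wood":
        return math.expm1(t)
    if kind == "forage" or kind == "infiltration":
        return t * t
    if kind == "cations":
        return cation_scale * math.sin(t) ** 2
    raise InvalidArgumentError(f"unknown function kind {kind!r}")


@dataclass(frozen=True)
class TypeReference:
    """Per fallow type and function: maximum M (mean of 3 highest transformed
    values) and mean mu (mean of all), pooled across sampling years."""

    maximum: float
    mean: float


def type_reference(values: Iterable[float]) -> TypeReference:
    """Maximum (mean of the 3 largest) and mean of transformed values.

    Raises :class:`InsufficientSampleError` with fewer than 3 plots.  M >= mu
    is expected for non-degenerate samples but not asserted (a warning is
    logged when it fails, e.g. on constant data it holds with equality).
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size < 3:
        raise InsufficientSampleError(f"need >=3 plots, got {arr.size}")
    top3 = np.sort(arr)[-3:]
    ref = TypeReference(maximum=float(top3.mean()), mean=float(arr.mean()))
    if ref.maximum < ref.mean:
        log.warning("degenerate sample: maximum %.4g < mean %.4g", ref.maximum, ref.mean)
    return ref


def proportion_above(
    profile: Mapping[str, float],
    reference: Mapping[str, TypeReference],
    tau: float = 0.5,
) -> tuple[float, float]:
    """Proportion of the four functions at or above ``tau`` times maximum.

    Returns ``(proportion, arcsine_sqrt(proportion))``; the transformed value
    is the modelling-stage response.  The threshold comparison is inclusive.
    """
    if not 0 < tau <= 1:
        raise InvalidArgumentError(f"tau must be in (0, 1], got {tau}")
    count = 0
    for f in FUNCTIONS:
        if f not in profile or profile[f] is None or not np.isfinite(profile[f]):
            raise MissingDataError(f"missing transformed value for {f}")
        if profile[f] >= tau * reference[f].maximum:
            count += 1
    prop = count / len(FUNCTIONS)
    return prop, math.asin(math.sqrt(prop))


def mean_percentage_excess(
    profile: Mapping[str, float], reference: Mapping[str, TypeReference]
) -> float:
    """Mean % by which transformed functions exceed their type means.

    Requires every type mean to be positive on the transformed scale; may be
    negative for below-average fallows.
    """
    excesses = []
    for f in FUNCTIONS:
        mu = reference[f].mean
        if mu <= 0:
            raise InvalidArgumentError(f"non-positive transformed mean for {f}: {mu}")
        excesses.append(100.0 * (profile[f] - mu) / mu)
    return float(np.mean(excesses))


def indicator_table(
    transformed: pd.DataFrame,
    thresholds: Iterable[float] = (0.25, 0.5, 0.75),
) -> tuple[pd.DataFrame, dict[str, dict[str, TypeReference]]]:
    """Per-plot multifunctionality indicators for a whole dataset.

    ``transformed`` must carry columns ``plot_id``, ``fallow_type`` and the
    four transformed function columns.  References (maxima/means) are
    computed per fallow type from the same table.  Returns the indicator
    frame (one row per plot: prop_above_<tau>, prop_asin_<tau>, mpe) and the
    reference dictionary keyed by fallow type.
    """
    refs: dict[str, dict[str, TypeReference]] = {}
    for ftype, grp in transformed.groupby("fallow_type"):
        refs[ftype] = {f: type_reference(grp[f]) for f in FUNCTIONS}

    rows = []
    for _, r in transformed.iterrows():
        ref = refs[r["fallow_type"]]
        profile = {f: r[f] for f in FUNCTIONS}
        row = {"plot_id": r["plot_id"], "fallow_type": r["fallow_type"]}
        for tau in thresholds:
            prop, asin_prop = proportion_above(profile, ref, tau)
            key = f"{tau:g}".replace(".", "")
            row[f"prop_above_{key}"] = prop
            row[f"prop_asin_{key}"] = asin_prop
        row["mpe"] = mean_percentage_excess(profile, ref)
        rows.append(row)
    return pd.DataFrame(rows), refs


def jointness(
    transformed: pd.DataFrame,
    refs: Mapping[str, Mapping[str, TypeReference]],
    mode: str = "half_max",
) -> pd.DataFrame:
    """Pairwise jointness counts per fallow type.

    ``mode='half_max'`` counts plots with both functions at or above 50% of
    the type maximum; ``mode='above_mean'`` uses the type mean as the
    threshold.  Returns one row per (fallow_type, pair) with the incidence
    count and the proportion of plots of that type.
    """
    if mode not in ("half_max", "above_mean"):
        raise InvalidArgumentError(f"unknown jointness mode {mode!r}")
    rows = []
    for ftype, grp in transformed.groupby("fallow_type"):
        n = len(grp)
        for fa, fb in itertools.combinations(FUNCTIONS, 2):
            if mode == "half_max":
                ta = 0.5 * refs[ftype][fa].maximum
                tb = 0.5 * refs[ftype][fb].maximum
            else:
                ta = refs[ftype][fa].mean
                tb = refs[ftype][fb].mean
            joint = int(((grp[fa] >= ta) & (grp[fb] >= tb)).sum())
            rows.append(
                {
                    "fallow_type": ftype,
                    "pair": f"{fa}-{fb}",
                    "mode": mode,
                    "incidence": joint,
                    "n": n,
                    "proportion": joint / n if n else float("nan"),
                }
            )
    return pd.DataFrame(rows)
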