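"""Statistical stage: linear models, correlations, ANOVA.

The diversity-versus-environment comparison fits, per fallow type and per
multifunctionality indicator, univariate ordinary-least-squares models on
each diversity variable (functional diversity, species richness) and each
environmental variable (soil carbon; grazing intensity in grazed fallows
only), plus additive bivariate models for each diversity x environment
combination — no interactions, raw two-sided P values, and total model R^2
adjusted for the number of parameters.  Pearson correlations are reported
with 95% confidence intervals from the Fisher z transform,
tanh(atanh(r) +/- 1.96/sqrt(n-3)).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import (
    CollinearityError,
    InsufficientSampleError,
    InvalidArgumentError,
)


@dataclass
class ModelFit:
    """OLS fit summary mirroring one table row block of the analysis."""

    response: str
    predictors: list[str]
    intercept: float
    estimates: dict[str, float]
    t_values: dict[str, float]
    p_values: dict[str, float]
    df_model: int
    df_resid: int
    adj_r2: float
    r2: float = field(default=float("nan"))


def fit_linear_model(y, X: pd.DataFrame, response_name: str = "y") -> ModelFit:
    """Ordinary least squares of ``y`` on one or two predictor columns."""
    y = np.asarray(y, dtype=float)
    X = pd.DataFrame(X).astype(float)
    n, p = X.shape
    if np.isnan(y).any() or X.isna().any().any():
        raise InvalidArgumentError("missing values in model input")
    if n <= p + 1:
        raise InsufficientSampleError(f"n={n} too small for {p} predictors")
    design = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(design.to_numpy()) < p + 1:
        raise CollinearityError("rank-deficient design matrix")
    res = sm.OLS(y, design).fit()
    return ModelFit(
        response=response_name,
        predictors=list(X.columns),
        intercept=float(res.params["const"]),
        estimates={c: float(res.params[c]) for c in X.columns},
        t_values={c: float(res.tvalues[c]) for c in X.columns},
        p_values={c: float(res.pvalues[c]) for c in X.columns},
        df_model=int(res.df_model),
        df_resid=int(res.df_resid),
        adj_r2=float(res.rsquared_adj),
        r2=float(res.rsquared),
    )


@dataclass
class CorrelationResult:
    r: float
    n: int
    ci_low: float
    ci_high: float
    df: tuple[int, int]


def fisher_ci(r: float, n: int, level: float = 0.95) -> tuple[float, float]:
    """Fisher-z confidence interval for a Pearson correlation."""
    if not -1 < r < 1:
        raise InvalidArgumentError(f"r must be in (-1, 1), got {r}")
    if n < 4:
        raise InsufficientSampleError("need n >= 4 for a Fisher-z interval")
    z = np.arctanh(r)
    crit = stats.norm.ppf(0.5 + level / 2)
    half = crit / np.sqrt(n - 3)
    return float(np.tanh(z - half)), float(np.tanh(z + half))


def pearson_fisher_ci(x, y, level: float = 0.95) -> CorrelationResult:
    """Pearson r with Fisher-z CI, reported with d.f. = (1, n-2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 4:
        raise InsufficientSampleError("need two equal-length vectors, n >= 4")
    if np.std(x) == 0 or np.std(y) == 0:
        raise InvalidArgumentError("zero variance: correlation undefined")
    r = float(np.corrcoef(x, y)[0, 1])
    lo, hi = fisher_ci(r, x.size, level)
    return CorrelationResult(r=r, n=x.size, ci_low=lo, ci_high=hi, df=(1, x.size - 2))


def oneway_anova(values, groups) -> tuple[float, tuple[int, int], float]:
    """One-way ANOVA F test; returns (F, (df_between, df_within), P)."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    levels = np.unique(groups)
    if levels.size < 2:
        raise InvalidArgumentError("need >= 2 groups")
    samples = [values[groups == g] for g in levels]
    if any(s.size < 2 for s in samples):
        raise InvalidArgumentError("each group needs >= 2 observations")
    F, P = stats.f_oneway(*samples)
    df = (levels.size - 1, values.size - levels.size)
    return float(F), df, float(P)


# --- model suite ----------------------------------------------------------

GRAZED_SPECS = [
    ["fd"],
    ["richness"],
    ["soc"],
    ["grazing"],
    ["fd", "soc"],
    ["richness", "soc"],
    ["fd", "grazing"],
    ["richness", "grazing"],
]
IMPROVED_SPECS = [
    ["fd"],
    ["richness"],
    ["soc"],
    ["fd", "soc"],
    ["richness", "soc"],
]


def run_model_suite(data: pd.DataFrame, indicators: tuple[str, str] = ("prop_asin_05", "mpe")) -> pd.DataFrame:
    """Fit the full diversity-vs-environment model set for both fallow types.

    ``data`` needs columns ``fallow_type``, the indicator responses (default:
    the arcsine-sqrt proportion above half-maximum and mean percentage
    excess) and predictors ``fd``, ``richness``, ``soc`` and — for grazed
    plots — ``grazing`` (cover-midpoint coding, 0-1 scale).  Returns a tidy
    frame, one row per coefficient, 8 models per indicator for grazed and 5
    for improved.
    """
    rows = []
    for ftype, grp in data.groupby("fallow_type"):
        specs = GRAZED_SPECS if ftype == "grazed" else IMPROVED_SPECS
        for response in indicators:
            for spec in specs:
                fit = fit_linear_model(grp[response], grp[list(spec)], response)
                for pred in spec:
                    rows.append(
                        {
                            "fallow_type": ftype,
                            "response": response,
                            "model": "+".join(spec),
                            "df_model": fit.df_model,
                            "df_resid": fit.df_resid,
                            "intercept": fit.intercept,
                            "predictor": pred,
                            "estimate": fit.estimates[pred],
                            "t": fit.t_values[pred],
                            "p": fit.p_values[pred],
                            "adj_r2": fit.adj_r2,
                        }
                    )
    return pd.DataFrame(rows)


def grazing_subgroup_fit(
    grazed: pd.DataFrame, response: str, group: str = "moderate"
) -> ModelFit:
    """Univariate FD fit within one grazing-intensity class of grazed plots."""
    sub = grazed[grazed["grazing_class"] == group]
    if len(sub) < 4:
        raise InsufficientSampleError(
            f"only {len(sub)} plots in {group!r} grazing group"
        )
    if float(np.std(sub["fd"])) == 0 or float(np.std(sub[response])) == 0:
        raise InvalidArgumentError("zero variance within grazing group")
    return fit_linear_model(sub[response], sub[["fd"]], response)
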