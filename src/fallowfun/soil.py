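"""Soil ecosystem functions: base cations and steady infiltration rate.

Infiltration was measured with ring infiltrometers over ~2.5 hours; the
steady infiltration rate is the lower asymptote fc of the Horton decay

    f(t) = fc + (f0 - fc) * exp(-k t)

fit per curve by bounded nonlinear least squares (the original analysis
pooled curves in a nonlinear mixed model; per-curve fits recover the same
per-plot quantity and are testable in isolation — a shared-k two-stage
variant is available via ``shared_k`` for the pooled flavour).

Soil chemistry (SOC %, exchangeable Mg/Ca/K in meq/100 g, sand %) arrives
per subplot and depth layer; base cations = Mg + Ca + K, and per-plot values
are the mean over the two nested subplots, topsoil (1-20 cm) by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import InvalidArgumentError, MissingDataError

log = logging.getLogger(__name__)


def horton_rate(t: np.ndarray, f0: float, fc: float, k: float) -> np.ndarray:
    """Horton infiltration rate at times ``t`` (minutes)."""
    return fc + (f0 - fc) * np.exp(-k * np.asarray(t, dtype=float))


@dataclass
class HortonFit:
    f0: float
    fc: float
    k: float
    rss: float
    converged: bool


def _self_start(times: np.ndarray, rates: np.ndarray) -> tuple[float, float, float]:
    """Initial values: f0 from the first rate, fc from the last, k from a
    log-linearisation of the early decline."""
    f0 = float(rates[0])
    fc = float(rates[-1])
    k = 0.05
    span = f0 - fc
    if span > 1e-9:
        # ln(f - fc) = ln(f0 - fc) - k t on the early points
        mask = rates - fc > 0.05 * span
        if mask.sum() >= 2:
            y = np.log(rates[mask] - fc + 1e-12)
            slope = np.polyfit(times[mask], y, 1)[0]
            if slope < 0:
                k = float(np.clip(-slope, 1e-4, 1.0))
    return f0, fc, k


def fit_horton(times: Sequence[float], rates: Sequence[float]) -> HortonFit:
    """Least-squares Horton fit of one infiltration curve.

    Bounds keep the asymptote physical: fc in [0, max(rates)], k in
    (1e-5, 1].  On optimiser failure the fallback estimate is the mean of
    the final quartile of rates with ``converged=False`` (logged).
    """
    t = np.asarray(times, dtype=float)
    r = np.asarray(rates, dtype=float)
    if t.size < 4 or np.unique(t).size < 4:
        raise InvalidArgumentError("need >= 4 distinct time points")
    if t.size != r.size:
        raise InvalidArgumentError("times and rates differ in length")
    if np.any(np.diff(t) <= 0):
        raise InvalidArgumentError("times must be strictly increasing")

    rmax = float(r.max())
    f0_0, fc_0, k_0 = _self_start(t, r)
    x0 = np.array([np.clip(f0_0, 0, 10 * rmax), np.clip(fc_0, 0, rmax), k_0])
    lo = np.array([0.0, 0.0, 1e-5])
    hi = np.array([10 * rmax + 1.0, rmax, 1.0])
    try:
        sol = least_squares(
            lambda p: horton_rate(t, *p) - r,
            x0=np.clip(x0, lo, hi),
            bounds=(lo, hi),
            xtol=1e-12,
            ftol=1e-12,
            gtol=1e-12,
        )
        if sol.success:
            f0, fc, k = sol.x
            return HortonFit(float(f0), float(fc), float(k), float(np.sum(sol.fun**2)), True)
    except Exception as exc:  # pragma: no cover - scipy failures are rare
        log.warning("Horton optimiser raised %s; using tail-mean fallback", exc)
    tail = r[-max(1, t.size // 4) :]
    fc = float(tail.mean())
    log.warning("Horton fit did not converge; fallback fc = %.3g", fc)
    return HortonFit(float(r[0]), fc, float("nan"), float("nan"), False)


def steady_infiltration_rate(fits: Iterable[HortonFit]) -> float:
    """Per-plot steady rate: mean fc over the (usually 2) subplot fits."""
    fcs = [f.fc for f in fits if np.isfinite(f.fc)]
    if not fcs:
        raise MissingDataError("no usable Horton fit for plot")
    if len(fcs) == 1:
        log.warning("single usable subplot; steady rate from one curve")
    return float(np.mean(fcs))


def base_cation_sum(mg: float, ca: float, k: float) -> float:
    """Soil base cations (meq/100 g) = Mg + Ca + K."""
    if mg < 0 or ca < 0 or k < 0:
        raise InvalidArgumentError(f"negative cation input ({mg}, {ca}, {k})")
    return mg + ca + k


def aggregate_soil(measurements: pd.DataFrame, layer: str = "topsoil") -> pd.DataFrame:
    """Per-plot soil summary: subplot means of SOC, base cations and sand.

    ``measurements`` is the long soil table (plot_id, subplot, layer,
    soc_pct, mg, ca, k, sand_pct).  Only the requested layer (default
    topsoil, 1-20 cm) enters the four-function analysis; the subsoil rows
    are simply not selected.
    """
    sel = measurements[measurements["layer"] == layer]
    rows = []
    for plot_id in measurements["plot_id"].unique():
        grp = sel[sel["plot_id"] == plot_id]
        if grp.empty:
            raise MissingDataError(f"no {layer} measurement for plot {plot_id}")
        if len(grp) == 1:
            log.warning("plot %s: single %s subplot", plot_id, layer)
        cations = [
            base_cation_sum(r["mg"], r["ca"], r["k"]) for _, r in grp.iterrows()
        ]
        rows.append(
            {
                "plot_id": plot_id,
                "soc_pct": float(grp["soc_pct"].mean()),
                "base_cations": float(np.mean(cations)),
                "sand_pct": float(grp["sand_pct"].mean()),
            }
        )
    return pd.DataFrame(rows)


def infiltration_by_plot(curves: pd.DataFrame, shared_k: bool = False) -> pd.DataFrame:
    """Steady infiltration rate per plot from the long curve table
    (plot_id, subplot, time_min, rate_mm_hr).

    With ``shared_k=True`` a pooled decay constant (median of per-curve k
    estimates) is imposed and fc/f0 re-fit per curve — a two-stage stand-in
    for the pooled mixed-model flavour of the original analysis.
    """
    fits: dict[tuple[str, str], HortonFit] = {}
    for (plot_id, subplot), grp in curves.groupby(["plot_id", "subplot"]):
        grp = grp.sort_values("time_min")
        fits[(plot_id, subplot)] = fit_horton(grp["time_min"].values, grp["rate_mm_hr"].values)

    if shared_k:
        ks = [f.k for f in fits.values() if f.converged and np.isfinite(f.k)]
        if ks:
            k_pool = float(np.median(ks))
            for key, fit in list(fits.items()):
                plot_id, subplot = key
                grp = curves[(curves["plot_id"] == plot_id) & (curves["subplot"] == subplot)]
                grp = grp.sort_values("time_min")
                t = grp["time_min"].values.astype(float)
                r = grp["rate_mm_hr"].values.astype(float)
                # linear in (fc, f0) given k: f = fc (1 - e) + f0 e
                e = np.exp(-k_pool * t)
                X = np.column_stack([1 - e, e])
                coef, *_ = np.linalg.lstsq(X, r, rcond=None)
                fits[key] = HortonFit(float(coef[1]), float(coef[0]), k_pool, float("nan"), True)

    rows = []
    for plot_id in curves["plot_id"].unique():
        plot_fits = [f for (p, _), f in fits.items() if p == plot_id]
        rows.append(
            {"plot_id": plot_id, "infiltration_mm_hr": steady_infiltration_rate(plot_fits)}
        )
    return pd.DataFrame(rows)
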