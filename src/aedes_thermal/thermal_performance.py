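"""Thermal performance: cumulative female survival and the Briere-1 model.

Performance at a rearing temperature T is defined as the product of survival
to adulthood and the female developmental rate (inverse mean age at
emergence), in day^-1 — "cumulative female survival". A zoo of candidate
thermal-performance models is fitted by nonlinear least squares and compared
by Akaike weights; the asymmetric Briere-1 curve

    y(T) = a T (T - T_min) (T_max - T)^(1/m),   T_min <= T <= T_max,  else 0

is the reference model. Its cardinal temperatures are T_min and T_max (the
curve's zeros) and T_opt, the unique interior root of dy/dT = 0, available
both by bracketed root-finding and in closed form.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .life_history import nls_aic

__all__ = [
    "BriereFit",
    "ModelSelectionReport",
    "build_tpc_points",
    "briere1",
    "briere1_topt_closed_form",
    "fit_briere1",
    "fit_model_zoo",
    "cardinal_temperatures",
]


def briere1(t, a, m, t_min, t_max):
    """Briere-1 performance curve; zero outside [t_min, t_max]."""
    t = np.asarray(t, dtype=float)
    scalar = t.ndim == 0
    t = np.atleast_1d(t)
    y = np.zeros_like(t)
    inside = (t >= t_min) & (t <= t_max)
    ti = t[inside]
    y[inside] = a * ti * (ti - t_min) * (t_max - ti) ** (1.0 / m)
    return float(y[0]) if scalar else y


def briere1_topt_closed_form(m: float, t_min: float, t_max: float) -> float:
    """Closed-form optimum of the Briere-1 curve.

    Setting dy/dT = 0 gives the quadratic
    (2 + 1/m) T^2 - (T_min + (1 + 1/m)(T_min + ... )) ... reduced to
    T_opt = [2 m T_max + (m+1) T_min + sqrt(4 m^2 T_max^2 + (m+1)^2 T_min^2
             - 4 m^2 T_min T_max)] / (4 m + 2).
    """
    disc = 4 * m * m * t_max * t_max + (m + 1) ** 2 * t_min * t_min - 4 * m * m * t_min * t_max
    return (2 * m * t_max + (m + 1) * t_min + math.sqrt(disc)) / (4 * m + 2)


@dataclass(frozen=True)
class BriereFit:
    """Fitted Briere-1 parameters with the derived optimum temperature."""

    a: float
    m: float
    t_min: float
    t_max: float
    t_opt: float
    aic: float
    aic_weight: float = math.nan

    def __post_init__(self) -> None:
        if not (self.t_min < self.t_opt < self.t_max):
            raise ValueError("cardinal temperatures must satisfy T_min < T_opt < T_max")
        if self.a <= 0 or self.m <= 0:
            raise ValueError("a and m must be positive")

    def __call__(self, t):
        return briere1(t, self.a, self.m, self.t_min, self.t_max)


@dataclass(frozen=True)
class CandidateFit:
    name: str
    params: dict[str, float]
    aic: float
    aic_weight: float
    converged: bool


@dataclass(frozen=True)
class ModelSelectionReport:
    candidates: tuple[CandidateFit, ...]

    @property
    def best(self) -> CandidateFit:
        return min(self.candidates, key=lambda c: c.aic)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([
            {"model": c.name, "aic": c.aic, "aic_weight": c.aic_weight,
             "converged": c.converged, **{f"param_{k}": v for k, v in c.params.items()}}
            for c in sorted(self.candidates, key=lambda c: c.aic)
        ])


def build_tpc_points(records: pd.DataFrame) -> pd.DataFrame:
    """Thermal-performance points from individual life-history records.

    Per temperature: survival = fraction of all individuals reaching
    adulthood; dev rate = 1 / mean female age at emergence (day^-1);
    performance = survival x dev rate. Temperatures where no female emerged
    get performance 0 (dev rate undefined -> NaN).
    """
    rows = []
    for temp, grp in records.groupby("temperature_C"):
        survival = float(grp["survived"].mean())
        females = grp[(grp["sex"] == "female") & grp["survived"]]
        if len(females) and females["age_emergence_days"].notna().any():
            dev_rate = 1.0 / float(females["age_emergence_days"].mean())
            performance = survival * dev_rate
        else:
            dev_rate = np.nan
            performance = 0.0
        rows.append((temp, survival, dev_rate, performance))
    return pd.DataFrame(
        rows, columns=["temperature_C", "survival", "dev_rate_per_day", "performance"]
    )


# ---------------------------------------------------------------------------
# candidate model zoo
# ---------------------------------------------------------------------------

def _gaussian(t, ymax, t_opt, sigma):
    return ymax * np.exp(-0.5 * ((t - t_opt) / sigma) ** 2)


def _quadratic(t, q, t_min, t_max):
    y = q * (t - t_min) * (t_max - t)
    return np.where((t >= t_min) & (t <= t_max), y, 0.0)


def _linear_mod(t, slope, t0):
    return np.maximum(slope * (t - t0), 0.0)


def _briere_free(t, a, m, t_min, t_max):
    return briere1(t, a, m, t_min, t_max)


def _briere_m2(t, a, t_min, t_max):
    return briere1(t, a, 2.0, t_min, t_max)


def _starts_briere(t, y, free_m: bool):
    pos = t[y > 0]
    lo = (pos.min() if len(pos) else t.min()) - 2.0
    hi = (pos.max() if len(pos) else t.max()) + 2.0
    peak = max(y.max(), 1e-12)
    t_peak = float(t[np.argmax(y)])
    a0 = peak / max(t_peak * (t_peak - lo) * (hi - t_peak) ** 0.5, 1e-9)
    starts = []
    for dlo, dhi, m0 in ((0.0, 0.0, 2.0), (-2.0, 2.0, 2.0), (0.0, 0.0, 5.0), (-4.0, 0.0, 1.0)):
        p = [a0, m0, lo + dlo, hi + dhi] if free_m else [a0, lo + dlo, hi + dhi]
        starts.append(p)
    return starts


DEFAULT_ZOO = ("briere1", "briere1_m2", "quadratic", "gaussian", "linear_mod")


def _zoo_spec(t, y):
    peak = max(float(y.max()), 1e-12)
    t_peak = float(t[np.argmax(y)])
    return {
        "briere1": (
            _briere_free, _starts_briere(t, y, True),
            ([0.0, 0.05, -50.0, t.min()], [np.inf, 100.0, t.max(), 80.0]),
        ),
        "briere1_m2": (
            _briere_m2, _starts_briere(t, y, False),
            ([0.0, -50.0, t.min()], [np.inf, t.max(), 80.0]),
        ),
        "quadratic": (
            _quadratic,
            [[peak / max((t_peak - t.min()) * (t.max() - t_peak), 1.0), t.min() - 2, t.max() + 2]],
            ([0.0, -50.0, t.min()], [np.inf, t.max(), 80.0]),
        ),
        "gaussian": (
            _gaussian,
            [[peak, t_peak, np.ptp(t) / 4], [peak, t_peak, np.ptp(t) / 8]],
            ([0.0, -50.0, 0.1], [np.inf, 80.0, 200.0]),
        ),
        "linear_mod": (
            _linear_mod,
            [[peak / max(t_peak - t.min(), 1.0), t.min()]],
            ([-np.inf, -100.0], [np.inf, 100.0]),
        ),
    }


def _fit_candidate(func, t, y, starts, bounds):
    """Multi-start bounded least squares; best RSS wins. None if all fail."""
    best = None
    for p0 in starts:
        p0 = np.clip(p0, np.asarray(bounds[0]) + 1e-9, np.asarray(bounds[1]) - 1e-9)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, _ = optimize.curve_fit(func, t, y, p0=p0, bounds=bounds, maxfev=20000)
            rss = float(np.sum((func(t, *popt) - y) ** 2))
        except (RuntimeError, ValueError):
            continue
        if not np.all(np.isfinite(popt)):
            continue
        if best is None or rss < best[1]:
            best = (tuple(float(v) for v in popt), rss)
    return best


def fit_model_zoo(points: pd.DataFrame, zoo: tuple[str, ...] = DEFAULT_ZOO) -> ModelSelectionReport:
    """Fit every candidate model and report AIC and Akaike weights.

    Candidates that fail to converge appear with infinite AIC and zero
    weight; selection never crashes on them. All-zero performance data are
    rejected (nothing to select between).
    """
    t = points["temperature_C"].to_numpy(dtype=float)
    y = points["performance"].to_numpy(dtype=float)
    if np.all(y <= 0):
        raise ValueError("all performance values are zero; model selection is degenerate")
    spec = _zoo_spec(t, y)
    param_names = {
        "briere1": ("a", "m", "t_min", "t_max"),
        "briere1_m2": ("a", "t_min", "t_max"),
        "quadratic": ("q", "t_min", "t_max"),
        "gaussian": ("ymax", "t_opt", "sigma"),
        "linear_mod": ("slope", "t0"),
    }
    raw = []
    for name in zoo:
        func, starts, bounds = spec[name]
        res = _fit_candidate(func, t, y, starts, bounds)
        if res is None:
            raw.append((name, {}, math.inf, False))
        else:
            params, rss = res
            aic = nls_aic(rss, len(y), len(params))
            raw.append((name, dict(zip(param_names[name], params)), aic, True))
    finite = [a for _, _, a, _ in raw if math.isfinite(a)]
    if not finite:
        raise RuntimeError("no candidate model converged")
    best_aic = min(finite)
    rel = [math.exp(-(a - best_aic) / 2.0) if math.isfinite(a) else 0.0 for _, _, a, _ in raw]
    total = sum(rel)
    candidates = tuple(
        CandidateFit(name, params, aic, w / total, ok)
        for (name, params, aic, ok), w in zip(raw, rel)
    )
    return ModelSelectionReport(candidates)


def fit_briere1(points: pd.DataFrame, fix_m: float | None = None,
                aic_weight: float = math.nan) -> BriereFit:
    """Fit the Briere-1 curve to TPC points (multi-start NLS).

    fix_m pins the shape constant (the study's selected fit used m = 2.0);
    otherwise m is free.
    """
    t = points["temperature_C"].to_numpy(dtype=float)
    y = points["performance"].to_numpy(dtype=float)
    if np.all(y <= 0):
        raise ValueError("all performance values are zero")
    if fix_m is None:
        func = _briere_free
        starts = _starts_briere(t, y, True)
        bounds = ([0.0, 0.05, -50.0, t.min()], [np.inf, 100.0, t.max(), 80.0])
    else:
        def func(tt, a, t_min, t_max):
            return briere1(tt, a, fix_m, t_min, t_max)
        starts = _starts_briere(t, y, False)
        bounds = ([0.0, -50.0, t.min()], [np.inf, t.max(), 80.0])
    res = _fit_candidate(func, t, y, starts, bounds)
    if res is None:
        raise RuntimeError("Briere-1 fit did not converge")
    params, rss = res
    if fix_m is None:
        a, m, t_min, t_max = params
    else:
        a, t_min, t_max = params
        m = float(fix_m)
    t_opt = _topt_root(m, t_min, t_max)
    return BriereFit(a, m, t_min, t_max, t_opt,
                     aic=nls_aic(rss, len(y), len(params)), aic_weight=aic_weight)


# ---------------------------------------------------------------------------
# cardinal temperatures
# ---------------------------------------------------------------------------

def _topt_root(m: float, t_min: float, t_max: float) -> float:
    """Interior root of dy/dT = 0 by bracketed root-finding.

    For y = a T (T - T_min) (T_max - T)^(1/m), the sign of dy/dT on
    (T_min, T_max) equals the sign of
        g(T) = (2T - T_min)(T_max - T) - T (T - T_min) / m.
    g is positive just above max(T_min, 0) (below 0 degC the curve itself is
    negative and irrelevant) and negative at T_max-, so brentq brackets the
    unique performance maximum.
    """
    if t_max <= 0:
        raise ValueError("T_max must be positive for a biological optimum")

    def g(t):
        return (2 * t - t_min) * (t_max - t) - t * (t - t_min) / m

    lo = max(t_min, 0.0)
    eps = 1e-9 * max(1.0, abs(t_max - lo))
    return float(optimize.brentq(g, lo + eps, t_max - eps, xtol=1e-10))


def cardinal_temperatures(fit: BriereFit) -> tuple[float, float, float]:
    """(T_min, T_opt, T_max) of a fitted Briere-1 curve.

    T_opt is recomputed from the analytic derivative by bracketed
    root-finding; it agrees with the closed form to numerical precision.
    """
    t_opt = _topt_root(fit.m, fit.t_min, fit.t_max)
    return fit.t_min, t_opt, fit.t_max
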