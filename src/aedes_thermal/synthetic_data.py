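"""Synthetic experimental and climate data generators.

The real study reared *Aedes japonicus japonicus* larvae at 16 constant water
temperatures (5 cups x 40 larvae each), cold-exposed eggs at four temperatures
for ten durations (5 cups x 20 eggs per cell), and drove its spatial models
with WorldClim monthly rasters and E-OBS daily temperature grids. None of the
raw data are deposited, so this module generates statistically equivalent
stand-ins: every downstream stage of the pipeline is exercised against data
whose ground truth is known exactly.

Ground truth defaults are the study's fitted curves: the Briere-1 thermal
performance parameters (a = 6e-6, m = 2.0, T_min = 7 degC, T_max = 31 degC),
the three hatch-vs-exposure curves, and the age-at-emergence exponential that
(shifted by the 14-day pre-oviposition period) becomes the generation-time
function G(T) = 290.75 exp(-0.17 T) + 22.32.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import xarray as xr

__all__ = [
    "ExperimentDesign",
    "HatchCurve",
    "ExponentialCurve",
    "GroundTruthParams",
    "DEFAULT_EGG_DESIGN",
    "DEFAULT_LIFE_DESIGN",
    "default_truth",
    "simulate_egg_experiment",
    "simulate_life_history",
    "simulate_monthly_raster",
    "simulate_daily_series",
    "simulate_daily_grid",
]

# Hours-scale exposures are carried as fractional days: 6 h = 0.25 d.
EXPOSURE_DURATIONS_DAYS = (0.0, 0.25, 0.5, 0.75, 1.0, 2.0, 3.0, 4.0, 7.0, 14.0)
EGG_TEMPERATURES_C = (5.0, 0.0, -5.0, -9.0)
LIFE_TEMPERATURES_C = (
    0.0, 5.0, 10.0, 12.0, 14.0, 15.0, 17.0, 19.0,
    20.0, 23.0, 25.0, 26.0, 27.0, 28.0, 29.0, 31.0,
)
MONTH_DAYS = (31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31)


@dataclass(frozen=True)
class ExperimentDesign:
    """Layout of the rearing / cold-exposure experiments.

    Counts are per treatment cell; exposure durations are in days (fractions
    allowed for hour-scale exposures).
    """

    temperatures_C: tuple[float, ...]
    cups_per_treatment: int = 5
    larvae_per_cup: int = 40
    eggs_per_cup: int = 20
    exposure_durations_days: tuple[float, ...] = EXPOSURE_DURATIONS_DAYS

    def __post_init__(self) -> None:
        if self.cups_per_treatment <= 0 or self.larvae_per_cup <= 0 or self.eggs_per_cup <= 0:
            raise ValueError("all design counts must be positive")
        if any(d < 0 for d in self.exposure_durations_days):
            raise ValueError("exposure durations must be >= 0")
        if not all(math.isfinite(t) for t in self.temperatures_C):
            raise ValueError("temperatures must be finite")


DEFAULT_EGG_DESIGN = ExperimentDesign(temperatures_C=EGG_TEMPERATURES_C)
DEFAULT_LIFE_DESIGN = ExperimentDesign(temperatures_C=LIFE_TEMPERATURES_C)


@dataclass(frozen=True)
class HatchCurve:
    """Hatch success (%) vs exposure duration (days).

    family 'exponential': y = A * exp(-k x) + c
    family 'logistic':    y = L / (1 + B * exp(r x))
    """

    family: str
    params: tuple[float, float, float]

    def __call__(self, x):
        x = np.asarray(x, dtype=float)
        if self.family == "exponential":
            a, k, c = self.params
            return a * np.exp(-k * x) + c
        if self.family == "logistic":
            big_l, b, r = self.params
            return big_l / (1.0 + b * np.exp(r * x))
        raise ValueError(f"unknown hatch curve family {self.family!r}")


@dataclass(frozen=True)
class ExponentialCurve:
    """age (days) = A * exp(-k T) + c, with T in degC."""

    A: float
    k: float
    c: float

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        return self.A * np.exp(-self.k * t) + self.c


def _briere(t, a, m, t_min, t_max):
    t = np.asarray(t, dtype=float)
    inside = (t >= t_min) & (t <= t_max)
    y = np.zeros_like(t, dtype=float)
    tt = np.where(inside, t, t_min)
    y = np.where(inside, a * tt * (tt - t_min) * np.abs(t_max - tt) ** (1.0 / m), 0.0)
    return y


@dataclass(frozen=True)
class GroundTruthParams:
    """Generative twins of every fitted quantity in the analysis.

    briere: (a, m, T_min, T_max) for performance y = a T (T-T_min)(T_max-T)^(1/m).
    hatch_curves: per cold temperature, hatch %(exposure days).
    age_curves: per trait, mean age (days) as a function of rearing T.
    sex_ratio_p: probability an emerging adult is female.
    age_cv / r1_cv: lognormal coefficients of variation for ages and wing length.
    r1_female_mm: (intercept, slope) of mean female R1 wing vein length vs T;
    males are r1_male_ratio times female size (sexual size dimorphism).
    """

    briere: tuple[float, float, float, float] = (6e-6, 2.0, 7.0, 31.0)
    hatch_curves: dict[float, HatchCurve] = field(default_factory=lambda: {
        5.0: HatchCurve("exponential", (0.0, 0.41, 85.0)),
        0.0: HatchCurve("exponential", (32.94, 0.41, 36.12)),
        -5.0: HatchCurve("exponential", (74.01, 0.22, 10.67)),
        -9.0: HatchCurve("logistic", (7.56e8, 7.25e8, 2.5621)),
    })
    age_curves: dict[str, ExponentialCurve] = field(default_factory=lambda: {
        # emergence curve + 14 d pre-oviposition shift = the G(T) function
        "pupation": ExponentialCurve(250.0, 0.17, 6.0),
        "emergence": ExponentialCurve(290.75, 0.17, 8.32),
        "adult_death": ExponentialCurve(320.0, 0.17, 28.32),
    })
    sex_ratio_p: float = 0.5
    age_cv: float = 0.1
    r1_cv: float = 0.05
    r1_female_mm: tuple[float, float] = (5.40375, -0.07625)
    r1_male_ratio: float = 0.88

    def __post_init__(self) -> None:
        a, m, t_min, t_max = self.briere
        if not (t_min < t_max):
            raise ValueError("T_min must be < T_max")
        if a <= 0 or m <= 0:
            raise ValueError("briere a and m must be positive")
        if not (0.0 < self.sex_ratio_p < 1.0):
            raise ValueError("sex_ratio_p must lie in (0, 1)")
        for t, curve in self.hatch_curves.items():
            if curve.family == "exponential" and not (0.0 <= curve.params[2] <= 100.0):
                raise ValueError(f"hatch asymptote at {t} degC outside [0, 100]%")

    # --- derived generative quantities -----------------------------------

    def briere_performance(self, t):
        a, m, t_min, t_max = self.briere
        return _briere(t, a, m, t_min, t_max)

    def dev_rate(self, t):
        """Female developmental rate, 1 / mean age at emergence (day^-1)."""
        return 1.0 / self.age_curves["emergence"](t)

    def survival(self, t):
        """Survival-to-adult so that survival x dev rate = the Briere curve.

        The study only defines the product ("cumulative female survival"),
        so the generator factorises it as performance / dev rate, clipped
        to [0, 1].
        """
        return np.clip(self.briere_performance(t) / self.dev_rate(t), 0.0, 1.0)

    def mean_r1_mm(self, t, sex: str):
        b0, b1 = self.r1_female_mm
        mean = b0 + b1 * np.asarray(t, dtype=float)
        if sex == "male":
            mean = mean * self.r1_male_ratio
        return mean


def default_truth(**overrides) -> GroundTruthParams:
    """Ground truth at the study's printed parameter values."""
    truth = GroundTruthParams()
    return replace(truth, **overrides) if overrides else truth


def _lognormal(rng: np.random.Generator, mean, cv: float):
    """Lognormal draws with the requested arithmetic mean and CV."""
    mean = np.asarray(mean, dtype=float)
    if cv <= 0:
        return mean.copy()
    sigma2 = math.log(1.0 + cv * cv)
    mu = np.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, math.sqrt(sigma2))


# ---------------------------------------------------------------------------
# egg cold-exposure experiment
# ---------------------------------------------------------------------------

def simulate_egg_experiment(
    design: ExperimentDesign = DEFAULT_EGG_DESIGN,
    truth: GroundTruthParams | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate cold-exposed egg cups with binomial hatch counts.

    One row per cup per (temperature, exposure duration) cell; the hatch
    probability is the truth curve evaluated at the duration, in percent,
    divided by 100. Truth curves whose value leaves [0, 100] % over the
    design's durations are rejected.
    """
    truth = truth or default_truth()
    rng = np.random.default_rng(seed)
    durations = np.asarray(design.exposure_durations_days, dtype=float)
    rows = []
    for temp in design.temperatures_C:
        if temp not in truth.hatch_curves:
            raise ValueError(f"no truth hatch curve defined for {temp} degC")
        curve = truth.hatch_curves[temp]
        pct = np.asarray(curve(durations), dtype=float)
        if np.any(pct < -1e-9) or np.any(pct > 100.0 + 1e-9):
            raise ValueError(
                f"truth hatch curve at {temp} degC leaves [0, 100]% over the design durations"
            )
        prob = np.clip(pct / 100.0, 0.0, 1.0)
        for dur, p in zip(durations, prob):
            hatched = rng.binomial(design.eggs_per_cup, p, size=design.cups_per_treatment)
            for cup, n_hatched in enumerate(hatched, start=1):
                rows.append((temp, dur, cup, design.eggs_per_cup, int(n_hatched)))
    return pd.DataFrame(
        rows, columns=["temperature_C", "exposure_days", "cup_id", "n_eggs", "n_hatched"]
    )


# ---------------------------------------------------------------------------
# larval life-history experiment
# ---------------------------------------------------------------------------

def simulate_life_history(
    design: ExperimentDesign = DEFAULT_LIFE_DESIGN,
    truth: GroundTruthParams | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate individual larval rearing records across temperatures.

    Survival to adulthood is Bernoulli with the truth survival probability;
    survivors get a sex, ordered ages (pupation < emergence < death, each
    stage increment lognormal around the truth means) and an R1 wing length.
    Non-survivors get a death age only and sex 'unknown' (sex is scored at
    emergence). Temperatures outside (T_min, T_max) have survival zero by
    construction.
    """
    truth = truth or default_truth()
    rng = np.random.default_rng(seed)
    rows = []
    for temp in design.temperatures_C:
        p_survive = float(truth.survival(temp))
        mean_pup = float(truth.age_curves["pupation"](temp))
        mean_em = float(truth.age_curves["emergence"](temp))
        mean_death = float(truth.age_curves["adult_death"](temp))
        if not (mean_pup < mean_em < mean_death):
            raise ValueError(f"truth age curves are not ordered at {temp} degC")
        for cup in range(1, design.cups_per_treatment + 1):
            survived = rng.random(design.larvae_per_cup) < p_survive
            for indiv, alive in enumerate(survived, start=1):
                if alive:
                    sex = "female" if rng.random() < truth.sex_ratio_p else "male"
                    age_pup = float(_lognormal(rng, mean_pup, truth.age_cv))
                    age_em = age_pup + float(
                        _lognormal(rng, mean_em - mean_pup, truth.age_cv)
                    )
                    age_death = age_em + float(
                        _lognormal(rng, mean_death - mean_em, truth.age_cv)
                    )
                    r1 = float(
                        _lognormal(rng, float(truth.mean_r1_mm(temp, sex)), truth.r1_cv)
                    )
                    rows.append(
                        (temp, cup, sex, True, age_pup, age_em, age_death, r1)
                    )
                else:
                    # larval/pupal death; well before the mean pupation age
                    age_death = float(_lognormal(rng, 0.5 * mean_pup, truth.age_cv))
                    rows.append(
                        (temp, cup, "unknown", False, np.nan, np.nan, age_death, np.nan)
                    )
    return pd.DataFrame(
        rows,
        columns=[
            "temperature_C", "cup_id", "sex", "survived",
            "age_pupation_days", "age_emergence_days", "age_death_days", "r1_mm",
        ],
    )


# ---------------------------------------------------------------------------
# climate inputs
# ---------------------------------------------------------------------------

def simulate_monthly_raster(
    extent: tuple[float, float, float, float] = (6.0, 15.0, 47.0, 55.0),
    shape: tuple[int, int] = (40, 40),
    mean_C: float = 9.0,
    amplitude_C: float = 9.0,
    lat_lapse_C_per_deg: float = 0.6,
    seed: int = 0,
) -> xr.DataArray:
    """Germany-like 12-band mean monthly temperature raster (degC).

    Each cell carries a smooth seasonal cosine peaking in July around a
    latitude-lapsed annual mean, plus smooth spatial noise. Values are
    clipped to [-20, 40] degC. Dimensions (month, lat, lon), WGS84 degrees.
    """
    lon_min, lon_max, lat_min, lat_max = extent
    ny, nx = shape
    rng = np.random.default_rng(seed)
    lat = np.linspace(lat_max, lat_min, ny)
    lon = np.linspace(lon_min, lon_max, nx)
    lat_mid = 0.5 * (lat_min + lat_max)
    annual_mean = mean_C - lat_lapse_C_per_deg * (lat[:, None] - lat_mid)
    # smooth spatial field: low-order 2-D cosine mixture with random phases
    xg, yg = np.meshgrid(np.linspace(0, 1, nx), np.linspace(0, 1, ny))
    noise = np.zeros((ny, nx))
    for fx, fy in ((1, 1), (2, 1), (1, 2)):
        px, py = rng.uniform(0, 2 * np.pi, size=2)
        noise += rng.normal(0, 0.5) * np.cos(2 * np.pi * fx * xg + px) * np.cos(
            2 * np.pi * fy * yg + py
        )
    annual_mean = annual_mean + noise
    months = np.arange(1, 13)
    seasonal = -np.cos(2 * np.pi * (months - 1) / 12.0)  # min in Jan, max in Jul
    data = annual_mean[None, :, :] + amplitude_C * seasonal[:, None, None]
    data = np.clip(data, -20.0, 40.0)
    return xr.DataArray(
        data,
        dims=("month", "lat", "lon"),
        coords={"month": months, "lat": lat, "lon": lon},
        name="temperature_C",
        attrs={"units": "degC", "description": "mean monthly air temperature"},
    )


def _daily_signal(n_days: int, mean_C: float, amplitude_C: float,
                  rng: np.random.Generator, ar_coef: float = 0.7,
                  noise_sd_C: float = 2.0) -> np.ndarray:
    t = np.arange(n_days)
    seasonal = mean_C - amplitude_C * np.cos(2 * np.pi * t / 365.0)  # day 0 = 1 Jan
    eps = rng.normal(0.0, noise_sd_C, size=n_days)
    noise = np.empty(n_days)
    acc = 0.0
    scale = math.sqrt(1.0 - ar_coef * ar_coef)
    for i in range(n_days):
        acc = ar_coef * acc + scale * eps[i]
        noise[i] = acc
    return seasonal + noise


def simulate_daily_series(
    n_years: int = 10,
    mean_C: float = 9.0,
    amplitude_C: float = 10.0,
    seed: int = 0,
    start: str = "1950-01-01",
) -> pd.Series:
    """Daily mean temperature series: seasonal sinusoid + AR(1) noise.

    365 days per year (no leap days); indexed by consecutive calendar dates.
    """
    rng = np.random.default_rng(seed)
    n_days = 365 * n_years
    values = _daily_signal(n_days, mean_C, amplitude_C, rng)
    idx = pd.date_range(start, periods=n_days, freq="D")
    return pd.Series(values, index=idx, name="temperature_C")


def simulate_daily_grid(
    n_years: int = 5,
    extent: tuple[float, float, float, float] = (6.0, 15.0, 47.0, 55.0),
    shape: tuple[int, int] = (10, 10),
    mean_C: float = 9.0,
    amplitude_C: float = 10.0,
    lat_lapse_C_per_deg: float = 0.6,
    seed: int = 0,
    start: str = "1950-01-01",
) -> xr.DataArray:
    """Daily temperature grid (time, lat, lon) with per-cell AR(1) noise."""
    lon_min, lon_max, lat_min, lat_max = extent
    ny, nx = shape
    rng = np.random.default_rng(seed)
    lat = np.linspace(lat_max, lat_min, ny)
    lon = np.linspace(lon_min, lon_max, nx)
    lat_mid = 0.5 * (lat_min + lat_max)
    n_days = 365 * n_years
    data = np.empty((n_days, ny, nx))
    for i in range(ny):
        cell_mean = mean_C - lat_lapse_C_per_deg * (lat[i] - lat_mid)
        for j in range(nx):
            data[:, i, j] = _daily_signal(n_days, cell_mean, amplitude_C, rng)
    idx = pd.date_range(start, periods=n_days, freq="D")
    return xr.DataArray(
        data,
        dims=("time", "lat", "lon"),
        coords={"time": idx, "lat": lat, "lon": lon},
        name="temperature_C",
        attrs={"units": "degC"},
    )
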