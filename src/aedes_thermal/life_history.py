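"""Life-trait summaries and hypothesis tests for larval rearing experiments.

Per-temperature mortality (cup-level means, arcsine-root transformed for
tests), one-way ANOVA and Bonferroni-corrected pairwise t-tests across
temperature treatments, exact binomial sex-ratio tests against 1:1, two-way
ANOVA of body size (R1 wing vein length) on temperature and sex, and the
exponential age-vs-temperature fits that feed the generation-time model.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import optimize, stats

__all__ = [
    "TestResult",
    "AgeTemperatureFit",
    "arcsine_sqrt",
    "mortality_table",
    "mortality_anova",
    "pairwise_t",
    "sex_ratio_test",
    "fit_age_curve",
    "size_summary",
    "size_anova",
    "nls_aic",
]

AGE_COLUMNS = {
    "pupation": "age_pupation_days",
    "emergence": "age_emergence_days",
    "adult_death": "age_death_days",
}


@dataclass(frozen=True)
class TestResult:
    """A single hypothesis-test outcome."""

    statistic_name: str  # "F" | "t" | "binomial"
    value: float
    dfs: tuple
    p: float
    adjustment: str = "none"  # "none" | "bonferroni"
    label: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0 or math.isnan(self.p)):
            raise ValueError("p-value outside [0, 1]")


@dataclass(frozen=True)
class AgeTemperatureFit:
    """age = A * exp(-k T) + c (days), fitted to per-temperature mean ages."""

    trait: str
    A: float
    k: float
    c: float
    aic: float
    degenerate: bool = False

    def __call__(self, t):
        return self.A * np.exp(-self.k * np.asarray(t, dtype=float)) + self.c


def arcsine_sqrt(p):
    """Variance-stabilising arcsin(sqrt(p)) transform for proportions."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("proportions must lie in [0, 1]")
    return np.arcsin(np.sqrt(p))


def nls_aic(rss: float, n: int, n_params: int) -> float:
    """AIC for a least-squares fit: n ln(RSS/n) + 2k, k = n_params + 1.

    The +1 counts the residual variance as an estimated parameter.
    """
    rss = max(float(rss), 1e-300)
    return n * math.log(rss / n) + 2 * (n_params + 1)


# ---------------------------------------------------------------------------
# mortality
# ---------------------------------------------------------------------------

def _per_cup_mortality(records: pd.DataFrame) -> pd.DataFrame:
    dead = records.groupby(["temperature_C", "cup_id"])["survived"].agg(
        mortality=lambda s: 1.0 - s.mean()
    )
    return dead.reset_index()


def mortality_table(records: pd.DataFrame) -> pd.DataFrame:
    """Mean and SD of per-cup mortality (%) for every temperature treatment.

    Mortality is averaged across cups (not pooled over individuals), matching
    a design where the cup is the replicate.
    """
    cups = _per_cup_mortality(records)
    out = cups.groupby("temperature_C")["mortality"].agg(["mean", "std", "count"])
    return pd.DataFrame({
        "temperature_C": out.index.to_numpy(),
        "mean_mortality_pct": out["mean"].to_numpy() * 100.0,
        "sd_pct": np.nan_to_num(out["std"].to_numpy(), nan=0.0) * 100.0,
        "n_cups": out["count"].to_numpy(),
    }).reset_index(drop=True)


def mortality_anova(records: pd.DataFrame) -> TestResult:
    """One-way ANOVA of arcsine-transformed per-cup mortality across temperatures."""
    cups = _per_cup_mortality(records)
    groups = [
        arcsine_sqrt(g["mortality"].to_numpy())
        for _, g in cups.groupby("temperature_C")
    ]
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least two temperature groups")
    f, p = stats.f_oneway(*groups)
    df1 = len(groups) - 1
    df2 = sum(len(g) for g in groups) - len(groups)
    if math.isnan(f):  # all groups constant and equal
        f, p = 0.0, 1.0
    return TestResult("F", float(f), (df1, df2), float(p), label="mortality ~ temperature")


def pairwise_t(records: pd.DataFrame) -> list[TestResult]:
    """Two-tailed t-tests for every temperature pair, Bonferroni-corrected.

    The correction multiplier m is the number of pairs tested.
    """
    cups = _per_cup_mortality(records)
    by_temp = {
        t: arcsine_sqrt(g["mortality"].to_numpy())
        for t, g in cups.groupby("temperature_C")
    }
    pairs = list(combinations(sorted(by_temp), 2))
    m = len(pairs)
    results = []
    for t1, t2 in pairs:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            tval, p = stats.ttest_ind(by_temp[t1], by_temp[t2])
        if math.isnan(tval):  # zero variance in both groups
            tval, p = 0.0, 1.0
        df = len(by_temp[t1]) + len(by_temp[t2]) - 2
        results.append(TestResult(
            "t", float(tval), (df,), float(min(1.0, p * m)),
            adjustment="bonferroni", label=f"{t1} degC vs {t2} degC",
        ))
    return results


# ---------------------------------------------------------------------------
# sex ratio
# ---------------------------------------------------------------------------

def sex_ratio_test(records: pd.DataFrame, temperature_C: float | None = None) -> TestResult:
    """Two-sided exact binomial test of a 1:1 sex ratio among emerged adults.

    Counts are pooled over the replicate cups of one temperature (or over the
    whole table when no temperature is given).
    """
    df = records
    if temperature_C is not None:
        df = df[df["temperature_C"] == temperature_C]
    adults = df[df["survived"] & df["sex"].isin(["female", "male"])]
    n_female = int((adults["sex"] == "female").sum())
    n_total = int(len(adults))
    if n_total == 0:
        raise ValueError("no emerged adults to test")
    res = stats.binomtest(n_female, n_total, p=0.5, alternative="two-sided")
    return TestResult(
        "binomial", float(n_female), (n_total,), float(res.pvalue),
        label=f"sex ratio at {temperature_C} degC" if temperature_C is not None else "sex ratio pooled",
    )


# ---------------------------------------------------------------------------
# age ~ temperature exponential fits
# ---------------------------------------------------------------------------

def mean_ages(records: pd.DataFrame, trait: str) -> pd.DataFrame:
    """Per-temperature mean age (days) for one trait, survivors only."""
    col = AGE_COLUMNS[trait]
    adults = records[records["survived"]]
    out = adults.groupby("temperature_C")[col].mean().dropna()
    return out.reset_index().rename(columns={col: "mean_age_days"})


def fit_age_curve(records: pd.DataFrame, trait: str) -> AgeTemperatureFit:
    """Exponential least-squares fit age = A exp(-k T) + c to mean ages.

    Requires survivors at >= 4 distinct temperatures. A flat age profile
    (k unidentifiable) is returned flagged degenerate with c = mean age.
    """
    if trait not in AGE_COLUMNS:
        raise ValueError(f"unknown trait {trait!r}")
    means = mean_ages(records, trait)
    t = means["temperature_C"].to_numpy(dtype=float)
    y = means["mean_age_days"].to_numpy(dtype=float)
    if len(t) < 4:
        raise ValueError("need mean ages at >= 4 temperatures")
    if np.ptp(y) < 1e-9 * max(1.0, abs(y.mean())):
        aic = nls_aic(float(np.sum((y - y.mean()) ** 2)), len(y), 3)
        return AgeTemperatureFit(trait, 0.0, 0.0, float(y.mean()), aic, degenerate=True)

    def model(tt, a, k, c):
        return a * np.exp(-k * tt) + c

    p0 = (max(np.ptp(y), 1e-3), 1.0 / max(np.median(t), 1.0), max(y.min(), 1e-3))
    popt, _ = optimize.curve_fit(
        model, t, y, p0=p0,
        bounds=([0.0, 0.0, 0.0], [np.inf, 10.0, np.inf]),
        maxfev=20000,
    )
    rss = float(np.sum((model(t, *popt) - y) ** 2))
    return AgeTemperatureFit(trait, *map(float, popt), nls_aic(rss, len(y), 3))


# ---------------------------------------------------------------------------
# body size
# ---------------------------------------------------------------------------

def size_summary(records: pd.DataFrame) -> pd.DataFrame:
    """Mean and SD of R1 wing vein length (mm) per temperature and sex."""
    adults = records[records["survived"] & records["r1_mm"].notna()]
    out = adults.groupby(["temperature_C", "sex"])["r1_mm"].agg(["mean", "std", "count"])
    out = out.rename(columns={"mean": "mean_r1_mm", "std": "sd_mm", "count": "n"})
    return out.reset_index()


def size_anova(records: pd.DataFrame, response: str = "r1_mm") -> list[TestResult]:
    """Two-way ANOVA of body size on temperature, sex and their interaction.

    response 'r1_mm' tests raw wing length; 'pct_diff_to_max' tests the
    percentage difference to the maximal observed R1 length, the scale on
    which a pure temperature-size-rule effect shows no sex term.
    """
    adults = records[records["survived"] & records["r1_mm"].notna()].copy()
    if adults["temperature_C"].nunique() < 2 or adults["sex"].nunique() < 2:
        raise ValueError("two-way ANOVA needs >= 2 temperature levels and both sexes")
    if response == "pct_diff_to_max":
        # distance to each sex's maximal group mean removes the dimorphism
        # offset (cell means are far less noisy than the individual maximum)
        cell_means = adults.groupby(["sex", "temperature_C"])["r1_mm"].mean()
        ref = adults["sex"].map(cell_means.groupby("sex").max())
        adults["y"] = (ref - adults["r1_mm"]) / ref * 100.0
    elif response == "r1_mm":
        adults["y"] = adults["r1_mm"]
    else:
        raise ValueError(f"unknown response {response!r}")
    adults["temp"] = adults["temperature_C"].astype("category")
    model = smf.ols("y ~ C(temp) * C(sex)", data=adults).fit()
    table = sm.stats.anova_lm(model, typ=2)
    results = []
    names = {"C(temp)": "temperature", "C(sex)": "sex", "C(temp):C(sex)": "interaction"}
    resid_df = int(table.loc["Residual", "df"])
    for row, label in names.items():
        if row not in table.index:
            continue
        results.append(TestResult(
            "F", float(table.loc[row, "F"]),
            (int(table.loc[row, "df"]), resid_df),
            float(table.loc[row, "PR(>F)"]),
            label=f"{response}: {label}",
        ))
    return results
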