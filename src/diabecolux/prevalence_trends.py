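"""Annual prevalence of treated type 2 diabetes, trends and projection.

A classified case counts as prevalent each calendar year from their first
A10 delivery (looked up over the full claims history) until death or the
end of the reporting period, whichever comes first; the death year itself
is prevalent.  Annual prevalence is the prevalent-case count divided by the
covered resident population on 31 December, reported in percent.

On top of the crude series the module provides sex/age stratification,
direct age-standardization against a reference population (EU15-style
weights), the mean annual relative increase, an ordinary-least-squares
linearity check (R²), and a short-horizon projection by Brown's double
exponential smoothing with the smoothing constant chosen by minimum
in-sample one-step RMSE.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .claims_io import count_deliveries
from .type_classification import Type2CaseSet

logger = logging.getLogger("diabecolux")

#: Default reporting period: detection uses history back to 1995, but rates
#: are only published for years with complete claims coverage.
DEFAULT_PERIOD = (2000, 2006)

DEFAULT_ALPHA_GRID = tuple(np.round(np.arange(0.05, 0.951, 0.05), 2))


def default_age_classes() -> list[tuple[int, int]]:
    """Ten-year age classes [0,10), …, [90,100]."""
    return [(lo, lo + 10) for lo in range(0, 100, 10)]


def age_class_label(age: int, classes: list[tuple[int, int]] | None = None) -> str | None:
    """Label for the class containing ``age``; the final class is closed."""
    classes = classes or default_age_classes()
    for i, (lo, hi) in enumerate(classes):
        last = i == len(classes) - 1
        if lo <= age < hi or (last and age == hi):
            return f"{lo}-{hi}"
    return None


def case_years(
    type2: Type2CaseSet,
    claims: pd.DataFrame,
    persons: pd.DataFrame,
    period: tuple[int, int] = DEFAULT_PERIOD,
    horizon: tuple[int, int] | None = None,
) -> dict[str, set[int]]:
    """Prevalent calendar years per case.

    Each case contributes the years ``{first A10 year, …,
    min(death year, period end)}`` intersected with ``period``.  The first
    A10 delivery is searched over ``horizon`` (default: from the earliest
    claim year through the period end), so treatment begun before the
    reporting period still anchors prevalence correctly.
    """
    if horizon is None:
        first_claim_year = int(pd.to_datetime(claims["delivery_date"]).dt.year.min())
        horizon = (min(first_claim_year, period[0]), period[1])
    a10 = count_deliveries(claims, "A10", horizon)
    firsts = a10.counts.reset_index().groupby("patient_id")["year"].min()
    first_year = {str(p): int(y) for p, y in firsts.items()}
    deaths = {
        str(pid): int(year)
        for pid, year in zip(
            persons.loc[persons["death_date"].notna(), "patient_id"],
            pd.to_datetime(persons.loc[persons["death_date"].notna(), "death_date"]).dt.year,
        )
    }
    out: dict[str, set[int]] = {}
    for pid in type2.patients():
        if pid not in first_year:
            raise ValueError(f"case {pid} has no A10 delivery in horizon {horizon}")
        start = first_year[pid]
        end = period[1]
        if pid in deaths:
            if deaths[pid] < start:
                raise ValueError(
                    f"case {pid}: death year {deaths[pid]} precedes first delivery {start}"
                )
            end = min(end, deaths[pid])
        out[pid] = set(range(max(start, period[0]), end + 1))
    return out


def _denominator(denominators: pd.DataFrame, year: int, sex: str = "all", age_class: str = "all") -> int:
    rows = denominators[
        (denominators["year"] == year)
        & (denominators["sex"] == sex)
        & (denominators["age_class"] == age_class)
    ]
    if len(rows) == 0:
        raise ValueError(
            f"no denominator for year={year}, sex={sex}, age_class={age_class}"
        )
    return int(rows["population"].iloc[0])


def annual_prevalence(
    years_by_case: dict[str, set[int]],
    denominators: pd.DataFrame,
    year: int,
) -> tuple[float, int]:
    """Crude prevalence for one year: percent rate and the numerator count."""
    n = sum(1 for ys in years_by_case.values() if year in ys)
    denom = _denominator(denominators, year)
    return 100.0 * n / denom, n


def prevalence_series(
    years_by_case: dict[str, set[int]],
    denominators: pd.DataFrame,
    period: tuple[int, int] = DEFAULT_PERIOD,
) -> pd.DataFrame:
    """Crude prevalence for every year of the period."""
    rows = []
    for year in range(period[0], period[1] + 1):
        rate, n = annual_prevalence(years_by_case, denominators, year)
        rows.append(
            {
                "year": year,
                "numerator": n,
                "denominator": _denominator(denominators, year),
                "rate_pct": rate,
            }
        )
    return pd.DataFrame(rows)


def stratified_prevalence(
    years_by_case: dict[str, set[int]],
    persons: pd.DataFrame,
    denominators: pd.DataFrame,
    year: int,
    by_sex: bool = True,
    age_classes: list[tuple[int, int]] | None = None,
) -> pd.DataFrame:
    """Prevalence by sex and/or age class for one year.

    Age is ``year - birth_year`` (only birth year is recorded in claims
    data).  Cases with missing sex or birth year are excluded from the
    affected stratification with a logged count.
    """
    classes = age_classes or default_age_classes()
    info = persons.set_index(persons["patient_id"].astype(str))
    prevalent = [pid for pid, ys in years_by_case.items() if year in ys]
    rows = []
    n_excluded = 0
    tallies: dict[tuple[str, str], int] = {}
    for pid in prevalent:
        if pid not in info.index:
            n_excluded += 1
            continue
        rec = info.loc[pid]
        sex = rec["sex"] if by_sex else "all"
        if by_sex and (pd.isna(sex) or sex not in ("male", "female")):
            n_excluded += 1
            continue
        if pd.isna(rec["birth_year"]):
            n_excluded += 1
            continue
        label = age_class_label(year - int(rec["birth_year"]), classes)
        if label is None:
            n_excluded += 1
            continue
        tallies[(sex, label)] = tallies.get((sex, label), 0) + 1
    if n_excluded:
        logger.info(
            "stratified_prevalence(%d): excluded %d case(s) with missing/out-of-range "
            "sex, birth year or age",
            year,
            n_excluded,
        )
    sexes = ["male", "female"] if by_sex else ["all"]
    for sex in sexes:
        for lo, hi in classes:
            label = f"{lo}-{hi}"
            denom = _denominator(denominators, year, sex, label)
            n = tallies.get((sex, label), 0)
            rows.append(
                {
                    "year": year,
                    "sex": sex,
                    "age_class": label,
                    "numerator": n,
                    "denominator": denom,
                    "rate_pct": 100.0 * n / denom,
                }
            )
    return pd.DataFrame(rows)


def age_standardize(
    stratum_rates: dict[str, float] | pd.Series,
    standard: pd.Series,
    impute_missing_as_zero: bool = False,
) -> float:
    """Directly age-standardized rate: Σ weight(class) × rate(class).

    ``standard`` maps age class to a weight (weights sum to 1).  Every
    standard class must have a rate, unless ``impute_missing_as_zero`` is
    set, in which case missing classes contribute zero with a warning.
    """
    rates = pd.Series(stratum_rates, dtype=float)
    missing = [c for c in standard.index if c not in rates.index]
    if missing and not impute_missing_as_zero:
        raise ValueError(f"no rate for standard age class(es): {missing}")
    if missing:
        logger.warning("age_standardize: imputing 0 rate for class(es) %s", missing)
    extra = [c for c in rates.index if c not in standard.index]
    if extra:
        raise ValueError(f"rates given for class(es) absent from the standard: {extra}")
    return float(sum(standard[c] * rates.get(c, 0.0) for c in standard.index))


def mean_annual_increase(rates: pd.Series | list[float], geometric: bool = False) -> float:
    """Mean annual relative increase of a rate series, in percent.

    The default is the arithmetic mean of year-over-year relative changes,
    ``100 * mean(rate_t / rate_{t-1} - 1)``; ``geometric`` switches to the
    compound (geometric-mean) growth rate.
    """
    r = np.asarray(rates, dtype=float)
    if len(r) < 2:
        raise ValueError("need at least two years")
    if np.any(r[:-1] <= 0):
        raise ValueError("zero or negative rate mid-series")
    ratios = r[1:] / r[:-1]
    if geometric:
        return 100.0 * (float(np.prod(ratios)) ** (1.0 / len(ratios)) - 1.0)
    return 100.0 * float(np.mean(ratios - 1.0))


def linear_trend_r2(rates: pd.Series | list[float]) -> float:
    """R² of an ordinary-least-squares fit of rate on time index."""
    r = np.asarray(rates, dtype=float)
    if len(r) < 3:
        raise ValueError("need at least three observations")
    if np.allclose(r, r[0]):
        raise ValueError("zero variance in rates; R^2 undefined")
    fit = stats.linregress(np.arange(len(r)), r)
    return float(fit.rvalue**2)


@dataclass(frozen=True)
class DESFit:
    """Brown's double-exponential-smoothing fit.

    ``level`` and ``trend`` are the final-state estimates; forecasts are
    linear in the horizon: ``forecast(h) = level + h * trend``.
    """

    alpha: float
    level: float
    trend: float
    rmse: float
    fitted: np.ndarray  # one-step-ahead in-sample forecasts, fitted[0] = x[0]

    def forecast(self, h: int) -> float:
        return self.level + h * self.trend


def brown_des(x: np.ndarray, alpha: float) -> DESFit:
    """Brown's double exponential smoothing with a single constant.

    Both smoothed statistics are initialized at the first observation; the
    in-sample RMSE is over one-step-ahead forecasts of observations 2..n.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least three observations")
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    s1 = s2 = x[0]
    fitted = np.empty_like(x)
    fitted[0] = x[0]
    for t in range(1, len(x)):
        level = 2 * s1 - s2
        trend = alpha / (1 - alpha) * (s1 - s2)
        fitted[t] = level + trend
        s1 = alpha * x[t] + (1 - alpha) * s1
        s2 = alpha * s1 + (1 - alpha) * s2
    level = 2 * s1 - s2
    trend = alpha / (1 - alpha) * (s1 - s2)
    rmse = float(np.sqrt(np.mean((x[1:] - fitted[1:]) ** 2)))
    return DESFit(alpha=alpha, level=level, trend=trend, rmse=rmse, fitted=fitted)


def fit_des(
    series: pd.Series | list[float] | np.ndarray,
    alpha_grid: tuple[float, ...] = DEFAULT_ALPHA_GRID,
) -> DESFit:
    """Grid-search the smoothing constant by minimum one-step RMSE."""
    grid = list(alpha_grid)
    if not grid:
        raise ValueError("alpha grid is empty")
    fits = [brown_des(np.asarray(series, dtype=float), a) for a in grid]
    return min(fits, key=lambda f: f.rmse)
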