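"""Prevalence arithmetic, standardization, trends and DES projection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from diabecolux import (
    Type2CaseSet,
    age_standardize,
    annual_prevalence,
    brown_des,
    case_years,
    denominators_from_persons,
    fit_des,
    linear_trend_r2,
    mean_annual_increase,
    prevalence_series,
    stratified_prevalence,
)
from diabecolux.prevalence_trends import DEFAULT_ALPHA_GRID

# national annual totals used as a worked arithmetic example: covered
# population and classified type-2 counts, 2000-2006
DENOMS = [418182, 424037, 428457, 433424, 439628, 444783, 450000]
T2_COUNTS = [13152, 13944, 14704, 15269, 16026, 16751, 17070]
YEARS = list(range(2000, 2007))


def table1_case_years() -> dict[str, set[int]]:
    """Per-case prevalent years reproducing the annual totals above.

    Cases stay prevalent once treated (until death/period end), so a series
    of non-decreasing annual counts is realized by a base cohort prevalent
    throughout plus yearly increments of incident cases.
    """
    out = {}
    for i in range(T2_COUNTS[0]):
        out[f"base{i}"] = set(YEARS)
    for j, year in enumerate(YEARS[1:], start=1):
        for i in range(T2_COUNTS[j] - T2_COUNTS[j - 1]):
            out[f"inc{year}_{i}"] = set(range(year, YEARS[-1] + 1))
    return out


def table1_denominators() -> pd.DataFrame:
    return pd.DataFrame(
        {"year": YEARS, "sex": "all", "age_class": "all", "population": DENOMS}
    )


def _claims(rows):
    return pd.DataFrame(rows, columns=["patient_id", "delivery_date", "atc_code"]).assign(
        delivery_date=lambda d: pd.to_datetime(d["delivery_date"])
    )


def _persons(rows):
    return pd.DataFrame(
        rows, columns=["patient_id", "sex", "birth_year", "death_date"]
    ).assign(
        death_date=lambda d: pd.to_datetime(d["death_date"]),
        birth_year=lambda d: pd.array(d["birth_year"], dtype="Int64"),
    )


def _t2(ids):
    return Type2CaseSet(pd.DataFrame({"patient_id": list(ids), "step": 2}), 66)


class TestCaseYears:
    def test_alive_case_prevalent_from_first_delivery(self):
        claims = _claims([("p", "2002-03-01", "A10BA02")])
        persons = _persons([("p", "male", 1950, None)])
        ys = case_years(_t2(["p"]), claims, persons, (2000, 2006))
        assert ys["p"] == {2002, 2003, 2004, 2005, 2006}

    def test_death_year_is_prevalent_and_truncates(self):
        claims = _claims([("p", "1998-03-01", "A10BA02")])
        persons = _persons([("p", "male", 1950, "2003-07-01")])
        ys = case_years(_t2(["p"]), claims, persons, (2000, 2006), horizon=(1995, 2006))
        assert ys["p"] == {2000, 2001, 2002, 2003}

    def test_single_final_year(self):
        claims = _claims([("p", "2006-03-01", "A10BA02")])
        persons = _persons([("p", "male", 1950, None)])
        ys = case_years(_t2(["p"]), claims, persons, (2000, 2006))
        assert ys["p"] == {2006}

    def test_death_before_first_delivery_is_error(self):
        claims = _claims([("p", "2004-03-01", "A10BA02")])
        persons = _persons([("p", "male", 1950, "2001-01-01")])
        with pytest.raises(ValueError, match="precedes"):
            case_years(_t2(["p"]), claims, persons, (2000, 2006))

    def test_removing_death_never_shrinks_years(self):
        claims = _claims([("p", "2001-03-01", "A10BA02")])
        dead = _persons([("p", "male", 1950, "2003-07-01")])
        alive = _persons([("p", "male", 1950, None)])
        ys_dead = case_years(_t2(["p"]), claims, dead, (2000, 2006))
        ys_alive = case_years(_t2(["p"]), claims, alive, (2000, 2006))
        assert ys_dead["p"] <= ys_alive["p"]


class TestAnnualPrevalence:
    def test_first_year_rate(self):
        rate, n = annual_prevalence(table1_case_years(), table1_denominators(), 2000)
        assert n == 13152
        assert round(rate, 2) == 3.15

    def test_last_year_rate(self):
        rate, n = annual_prevalence(table1_case_years(), table1_denominators(), 2006)
        assert n == 17070
        assert round(rate, 2) == 3.79

    def test_zero_cases_zero_rate(self):
        rate, n = annual_prevalence({}, table1_denominators(), 2000)
        assert (rate, n) == (0.0, 0)

    def test_missing_denominator_names_year(self):
        with pytest.raises(ValueError, match="1999"):
            annual_prevalence({}, table1_denominators(), 1999)


class TestStratified:
    def test_small_stratum_rate(self):
        ys = {f"p{i}": {2005} for i in range(10)}
        persons = _persons([(f"p{i}", "male", 1950, None) for i in range(10)])
        denoms = pd.DataFrame(
            [
                {"year": 2005, "sex": s, "age_class": f"{lo}-{lo+10}", "population": 100}
                for s in ("male", "female")
                for lo in range(0, 100, 10)
            ]
        )
        rows = stratified_prevalence(ys, persons, denoms, 2005)
        hit = rows[(rows["sex"] == "male") & (rows["age_class"] == "50-60")]
        assert hit["rate_pct"].iloc[0] == pytest.approx(10.0)

    def test_strata_numerators_partition_total(self, lux_sim):
        config, persons, claims, _ = lux_sim
        from diabecolux import count_deliveries, detect_cases, split_by_oha, classify_type2

        cases = detect_cases(count_deliveries(claims, "A10", config.horizon), persons)
        oha, ins = split_by_oha(cases, claims, config.horizon)
        t2 = classify_type2(oha, ins, 66, claims, persons, config.horizon)
        ys = case_years(t2, claims, persons, (2000, 2006), config.horizon)
        denoms = denominators_from_persons(persons, (2000, 2006))
        rows = stratified_prevalence(ys, persons, denoms, 2005)
        total = sum(1 for s in ys.values() if 2005 in s)
        assert rows["numerator"].sum() == total  # no missing sex/birth in simulation

    def test_age_profile_matches_simulated_onset_ages(self, lux_sim):
        """Type-2 onset is drawn at 40+, so rates are ~0 young and rise with age."""
        config, persons, claims, _ = lux_sim
        from diabecolux import count_deliveries, detect_cases, split_by_oha, classify_type2

        cases = detect_cases(count_deliveries(claims, "A10", config.horizon), persons)
        oha, ins = split_by_oha(cases, claims, config.horizon)
        t2 = classify_type2(oha, ins, 66, claims, persons, config.horizon)
        ys = case_years(t2, claims, persons, (2000, 2006), config.horizon)
        denoms = denominators_from_persons(persons, (2000, 2006))
        rows = stratified_prevalence(ys, persons, denoms, 2005)
        young = rows[rows["age_class"].isin(["0-10", "10-20", "20-30"])]
        older = rows[rows["age_class"].isin(["60-70", "70-80"])]
        assert young["rate_pct"].max() <= 1.0
        assert older["rate_pct"].mean() > young["rate_pct"].mean()


class TestAgeStandardize:
    def test_uniform_rate_is_fixed_point(self):
        std = pd.Series({"a": 0.3, "b": 0.7})
        assert age_standardize({"a": 2.5, "b": 2.5}, std) == pytest.approx(2.5)

    def test_two_class_average(self):
        std = pd.Series({"a": 0.5, "b": 0.5})
        assert age_standardize({"a": 2.0, "b": 4.0}, std) == pytest.approx(3.0)

    def test_class_mismatch_is_error(self):
        std = pd.Series({"a": 1.0})
        with pytest.raises(ValueError, match="b"):
            age_standardize({"a": 1.0, "b": 2.0}, std)
        with pytest.raises(ValueError, match="missing|no rate"):
            age_standardize({}, std)

    @given(
        weights=st.lists(st.floats(0.01, 1), min_size=2, max_size=6),
        rates=st.lists(st.floats(0, 20), min_size=6, max_size=6),
    )
    @settings(max_examples=100, derandomize=True)
    def test_convexity(self, weights, rates):
        k = len(weights)
        w = np.array(weights) / sum(weights)
        std = pd.Series(w, index=[str(i) for i in range(k)])
        r = {str(i): rates[i] for i in range(k)}
        out = age_standardize(r, std)
        assert min(rates[:k]) - 1e-9 <= out <= max(rates[:k]) + 1e-9

    def test_own_structure_reproduces_crude_rate(self):
        pops = np.array([100.0, 300.0, 600.0])
        cases = np.array([1.0, 9.0, 30.0])
        rates = 100 * cases / pops
        std = pd.Series(pops / pops.sum(), index=["a", "b", "c"])
        crude = 100 * cases.sum() / pops.sum()
        assert age_standardize(dict(zip(["a", "b", "c"], rates)), std) == pytest.approx(crude)


class TestTrends:
    def test_national_series_mean_annual_increase(self):
        rates = 100 * np.array(T2_COUNTS) / np.array(DENOMS)
        assert round(mean_annual_increase(rates), 1) == 3.2

    def test_constant_series_zero_increase(self):
        assert mean_annual_increase([2.0, 2.0, 2.0]) == pytest.approx(0.0)

    def test_exact_geometric_growth(self):
        assert mean_annual_increase([1, 1.1, 1.21]) == pytest.approx(10.0)
        assert mean_annual_increase([1, 1.1, 1.21], geometric=True) == pytest.approx(10.0)

    def test_zero_rate_mid_series_is_error(self):
        with pytest.raises(ValueError):
            mean_annual_increase([1.0, 0.0, 2.0])

    def test_r2_exact_line(self):
        assert linear_trend_r2([1, 2, 3, 4]) == pytest.approx(1.0)

    def test_r2_national_series(self):
        rates = 100 * np.array(T2_COUNTS) / np.array(DENOMS)
        assert linear_trend_r2(rates) >= 0.95

    def test_r2_noise_near_zero(self):
        rng = np.random.default_rng(1)
        assert linear_trend_r2(rng.normal(size=200)) < 0.05

    def test_r2_constant_series_flagged(self):
        with pytest.raises(ValueError, match="undefined"):
            linear_trend_r2([1.0, 1.0, 1.0])


class TestDES:
    def test_linear_series_forecast_continues_line(self):
        t = np.arange(40)
        x = 2.0 + 0.5 * t
        fit = fit_des(x)
        for h in (1, 2, 5):
            assert fit.forecast(h) == pytest.approx(2.0 + 0.5 * (39 + h), abs=1e-6)

    def test_constant_series_forecasts_constant(self):
        fit = fit_des(np.full(10, 3.3))
        assert fit.forecast(1) == pytest.approx(3.3)
        assert fit.forecast(5) == pytest.approx(3.3)

    def test_alpha_selection_matches_independent_grid_argmin(self):
        rng = np.random.default_rng(7)
        x = 1.0 + 0.3 * np.arange(25) + rng.normal(0, 0.2, 25)
        fit = fit_des(x)

        def independent_rmse(alpha):
            # plain-list re-statement of the smoothing recursions
            s1, s2 = x[0], x[0]
            errs = []
            for t in range(1, len(x)):
                pred = 2 * s1 - s2 + alpha / (1 - alpha) * (s1 - s2)
                errs.append((x[t] - pred) ** 2)
                s1 = alpha * x[t] + (1 - alpha) * s1
                s2 = alpha * s1 + (1 - alpha) * s2
            return float(np.sqrt(np.mean(errs)))

        best = min(DEFAULT_ALPHA_GRID, key=independent_rmse)
        assert fit.alpha == best
        assert fit.rmse == pytest.approx(independent_rmse(best))

    def test_forecast_error_bounded_by_noise_scale(self):
        rng = np.random.default_rng(5)
        noise = 0.05
        x = 1.0 + 0.2 * np.arange(30) + rng.normal(0, noise, 30)
        fit = fit_des(x)
        truth_h2 = 1.0 + 0.2 * 31
        assert abs(fit.forecast(2) - truth_h2) <= 10 * noise

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            fit_des([1.0, 2.0])
        with pytest.raises(ValueError):
            fit_des([1.0, 2.0, 3.0], alpha_grid=())
        with pytest.raises(ValueError):
            brown_des(np.arange(5.0), 1.0)


class TestSeries:
    def test_prevalence_series_monotone_in_inputs(self):
        ys = table1_case_years()
        series = prevalence_series(ys, table1_denominators(), (2000, 2006))
        assert series["numerator"].tolist() == T2_COUNTS
        assert (series["rate_pct"] == 100 * series["numerator"] / series["denominator"]).all()
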