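"""Tabular I/O for pharmacy-claims phenotyping.

The package works from three administrative tables, all plain CSV:

* **claims** — one row per reimbursed drug delivery:
  ``patient_id,delivery_date,atc_code`` (ISO dates, WHO ATC codes);
* **persons** — the insured-person registry:
  ``patient_id,sex,birth_year,death_date`` (empty ``death_date`` = alive);
* **denominators** — covered resident population on 31 December:
  ``year,sex,age_class,population`` (``all`` marks an unstratified margin);

plus a standard-population table ``age_class,weight`` for direct
age-standardization.

In memory each table is a :class:`pandas.DataFrame` with the column
contract above; this module reads, validates and writes them, and builds
the per-patient per-year delivery-count matrix that the case-definition
criteria consume.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger("diabecolux")

CLAIMS_COLUMNS = ["patient_id", "delivery_date", "atc_code"]
PERSONS_COLUMNS = ["patient_id", "sex", "birth_year", "death_date"]
DENOMINATOR_COLUMNS = ["year", "sex", "age_class", "population"]
STANDARD_COLUMNS = ["age_class", "weight"]

SEXES = ("male", "female")

#: Study window used throughout when none is given: claims history runs
#: 1995-2006, with detection phase 1 and prevalence reporting on 2000-2006.
DEFAULT_HORIZON = (1995, 2006)


def parse_year_range(text: str) -> tuple[int, int]:
    """Parse a ``"1995:2006"`` style inclusive year range."""
    try:
        first, last = (int(part) for part in text.split(":"))
    except ValueError as exc:
        raise ValueError(f"year range must look like '1995:2006', got {text!r}") from exc
    if first > last:
        raise ValueError(f"year range start {first} after end {last}")
    return first, last


@dataclass(frozen=True)
class DeliveryMatrix:
    """Per-patient, per-year counts of drug deliveries for one ATC prefix.

    ``counts`` maps ``(patient_id, year)`` to a non-negative integer; a
    missing patient-year means zero.  By default a "delivery" is a distinct
    ``(patient, date)`` pair among prefix-matched claims, so several claim
    lines from one pharmacy visit count once.
    """

    atc_prefix: str
    year_range: tuple[int, int]
    counts: pd.Series  # MultiIndex (patient_id, year) -> int

    def patient_years(self, patient_id: str) -> dict[int, int]:
        """Yearly counts for one patient as a plain ``{year: count}`` dict."""
        try:
            sub = self.counts.xs(patient_id, level="patient_id")
        except KeyError:
            return {}
        return {int(y): int(c) for y, c in sub.items()}

    def patients(self) -> list[str]:
        return list(self.counts.index.get_level_values("patient_id").unique())

    def total(self) -> int:
        return int(self.counts.sum())


def _require_columns(df: pd.DataFrame, required: list[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{what} file is missing column(s): {', '.join(missing)}")


def _parse_dates(raw: pd.Series, what: str) -> pd.Series:
    parsed = pd.to_datetime(raw, format="%Y-%m-%d", errors="coerce")
    bad = parsed.isna() & raw.notna() & (raw.astype(str).str.strip() != "")
    if bad.any():
        row = int(bad.idxmax()) + 2  # +1 header, +1 zero-based
        raise ValueError(
            f"malformed {what} date {raw[bad.idxmax()]!r} at file row {row} "
            "(expected YYYY-MM-DD)"
        )
    return parsed


def read_claims(path: str | Path, horizon: tuple[int, int] = DEFAULT_HORIZON) -> pd.DataFrame:
    """Read a claims CSV, validating codes and dates.

    Rows whose delivery year falls outside ``horizon`` are dropped with a
    logged count; a malformed date or a missing column is a hard error
    naming the offending row.
    """
    df = pd.read_csv(path, dtype={"patient_id": str, "atc_code": str})
    _require_columns(df, CLAIMS_COLUMNS, "claims")
    df = df[CLAIMS_COLUMNS].copy()
    df["delivery_date"] = _parse_dates(df["delivery_date"], "delivery")
    if df["delivery_date"].isna().any():
        row = int(df["delivery_date"].isna().idxmax()) + 2
        raise ValueError(f"missing delivery_date at file row {row}")
    df["atc_code"] = df["atc_code"].str.strip().str.upper()
    bad_code = df["atc_code"].isna() | (df["atc_code"] == "") | ~df["atc_code"].str.isalnum()
    if bad_code.any():
        row = int(bad_code.idxmax()) + 2
        raise ValueError(f"invalid ATC code {df['atc_code'][bad_code.idxmax()]!r} at file row {row}")
    years = df["delivery_date"].dt.year
    inside = years.between(horizon[0], horizon[1])
    n_out = int((~inside).sum())
    if n_out:
        logger.info("read_claims: dropped %d row(s) outside horizon %s", n_out, horizon)
    return df.loc[inside].reset_index(drop=True)


def write_claims(claims: pd.DataFrame, path: str | Path) -> None:
    out = claims.copy()
    out["delivery_date"] = pd.to_datetime(out["delivery_date"]).dt.strftime("%Y-%m-%d")
    out[CLAIMS_COLUMNS].to_csv(path, index=False)


def read_persons(path: str | Path) -> pd.DataFrame:
    """Read the person registry; empty ``death_date`` means alive."""
    df = pd.read_csv(path, dtype={"patient_id": str, "sex": str})
    _require_columns(df, PERSONS_COLUMNS, "persons")
    df = df[PERSONS_COLUMNS].copy()
    df["sex"] = df["sex"].str.strip().str.lower()
    bad_sex = df["sex"].notna() & ~df["sex"].isin(SEXES)
    if bad_sex.any():
        row = int(bad_sex.idxmax()) + 2
        raise ValueError(f"invalid sex {df['sex'][bad_sex.idxmax()]!r} at file row {row}")
    df["birth_year"] = pd.array(df["birth_year"], dtype="Int64")
    df["death_date"] = _parse_dates(df["death_date"], "death")
    alive = df["death_date"].isna()
    death_year = df.loc[~alive, "death_date"].dt.year
    birth = df.loc[~alive, "birth_year"]
    impossible = (death_year < birth) | (death_year - birth > 120)
    if impossible.fillna(False).any():
        pid = df.loc[impossible[impossible.fillna(False)].index[0], "patient_id"]
        raise ValueError(f"patient {pid}: death date inconsistent with birth year")
    n_missing_birth = int(df["birth_year"].isna().sum())
    if n_missing_birth:
        logger.info(
            "read_persons: %d person(s) without birth_year; retained for detection, "
            "excluded from age-dependent steps",
            n_missing_birth,
        )
    return df


def write_persons(persons: pd.DataFrame, path: str | Path) -> None:
    out = persons.copy()
    dd = pd.to_datetime(out["death_date"])
    out["death_date"] = dd.dt.strftime("%Y-%m-%d").where(dd.notna(), "")
    out[PERSONS_COLUMNS].to_csv(path, index=False)


def read_denominators(path: str | Path) -> pd.DataFrame:
    """Read covered-population denominators by year, sex and age class.

    Strata within a year must be positive and, when an ``all`` margin row is
    present alongside stratified rows, the strata must sum to it within
    rounding.
    """
    df = pd.read_csv(path, dtype={"sex": str, "age_class": str})
    _require_columns(df, DENOMINATOR_COLUMNS, "denominators")
    df = df[DENOMINATOR_COLUMNS].copy()
    df["sex"] = df["sex"].str.strip().str.lower()
    df["age_class"] = df["age_class"].str.strip()
    if (df["population"] <= 0).any():
        raise ValueError("denominator populations must be positive")
    for year, grp in df.groupby("year"):
        margin = grp[(grp["sex"] == "all") & (grp["age_class"] == "all")]
        strata = grp[(grp["sex"] != "all") & (grp["age_class"] != "all")]
        if len(margin) and len(strata):
            total = int(strata["population"].sum())
            stated = int(margin["population"].iloc[0])
            if abs(total - stated) > max(1, len(strata)):  # rounding slack
                raise ValueError(
                    f"denominators for {year}: strata sum {total} != 'all' row {stated}"
                )
    return df


def read_standard_population(path: str | Path) -> pd.Series:
    """Read standard-population weights; returns ``age_class -> weight``."""
    df = pd.read_csv(path, dtype={"age_class": str})
    _require_columns(df, STANDARD_COLUMNS, "standard population")
    weights = df.set_index("age_class")["weight"].astype(float)
    if (weights < 0).any():
        raise ValueError("standard-population weights must be non-negative")
    if not np.isclose(weights.sum(), 1.0, atol=1e-6):
        raise ValueError(f"standard-population weights sum to {weights.sum():.6f}, not 1")
    return weights


def count_deliveries(
    claims: pd.DataFrame,
    atc_prefix: str,
    year_range: tuple[int, int],
    distinct_dates: bool = True,
) -> DeliveryMatrix:
    """Tally per-patient, per-year deliveries for one ATC prefix.

    Matching is case-insensitive string-prefix matching: prefix ``A10``
    covers insulins (``A10A…``) and oral agents (``A10B…``) alike.  With
    ``distinct_dates`` (the default) multiple claim lines on one day count
    as a single delivery.

    Parameters
    ----------
    claims
        Claims table with the :data:`CLAIMS_COLUMNS` contract.
    atc_prefix
        Non-empty ATC prefix, e.g. ``"A10"`` or ``"A10B"``.
    year_range
        Inclusive ``(first, last)`` calendar years to retain.
    distinct_dates
        Count distinct delivery dates (default) rather than raw claim lines.
    """
    if not atc_prefix:
        raise ValueError("atc_prefix must be non-empty")
    prefix = atc_prefix.upper()
    if len(claims) == 0:
        empty = pd.Series(
            [],
            index=pd.MultiIndex.from_arrays([[], []], names=["patient_id", "year"]),
            dtype=int,
        )
        return DeliveryMatrix(prefix, year_range, empty)
    sub = claims[claims["atc_code"].str.upper().str.startswith(prefix)]
    years = pd.to_datetime(sub["delivery_date"]).dt.year
    sub = sub[years.between(year_range[0], year_range[1])]
    if len(sub) == 0:
        empty = pd.Series(
            [],
            index=pd.MultiIndex.from_arrays([[], []], names=["patient_id", "year"]),
            dtype=int,
        )
        return DeliveryMatrix(prefix, year_range, empty)
    frame = pd.DataFrame(
        {
            "patient_id": sub["patient_id"],
            "year": pd.to_datetime(sub["delivery_date"]).dt.year,
            "date": pd.to_datetime(sub["delivery_date"]),
        }
    )
    grouped = frame.groupby(["patient_id", "year"])["date"]
    counts = grouped.nunique() if distinct_dates else grouped.size()
    counts = counts.astype(int)
    counts.index = counts.index.set_names(["patient_id", "year"])
    return DeliveryMatrix(prefix, year_range, counts)


def completeness_report(claims: pd.DataFrame, persons: pd.DataFrame) -> dict[str, float]:
    """Per-field missingness proportions for the two input tables.

    Returns one proportion in ``[0, 1]`` per required field; for an empty
    table the proportion is ``nan`` (undefined).  ``death_date`` is not a
    required field — absence means alive — so it is not reported.
    """
    report: dict[str, float] = {}
    for col in CLAIMS_COLUMNS:
        report[f"claims.{col}"] = (
            float(claims[col].isna().mean()) if len(claims) else float("nan")
        )
    for col in ["patient_id", "sex", "birth_year"]:
        report[f"persons.{col}"] = (
            float(persons[col].isna().mean()) if len(persons) else float("nan")
        )
    return report
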