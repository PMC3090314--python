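"""Steps 2-3 — separate type 2 from type 1 among detected cases.

Without diagnosis codes the split rests on pharmacology: oral hypoglycemic
agents (OHAs, ATC ``A10B``) are a type-2 treatment, so any detected case
with at least one A10B delivery is classified type 2 (step 2).  Cases who
only ever received insulin (``A10A``) are mostly type 1, except for elderly
patients whose OHA history predates the claims window or whose type 2 was
insulin-treated from the start.  Step 3 therefore re-claims insulin-only
cases whose age at first insulin delivery exceeds a threshold.

The threshold is data-driven: among cases who moved from OHAs to insulin
alone and stayed there (the "switch cohort"), the mean age at the year of
treatment change is taken, floored to an integer.  It reflects local
prescribing practice rather than a fixed clinical cutoff, which is what
makes the algorithm portable across insurance systems.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import pandas as pd

from .claims_io import DeliveryMatrix, count_deliveries

logger = logging.getLogger("diabecolux")

#: Threshold used when no qualifying switcher exists in the data.
DEFAULT_SWITCH_THRESHOLD = 66


@dataclass(frozen=True)
class SwitchCohort:
    """Cases who moved from OHAs to insulin-only treatment for good.

    ``table`` has one row per switcher: ``patient_id``, ``switch_year``
    (first insulin year after the last OHA year), ``age_at_switch``.
    """

    table: pd.DataFrame

    def __len__(self) -> int:
        return len(self.table)


@dataclass(frozen=True)
class Type2CaseSet:
    """Cases classified as treated type 2 diabetes.

    ``table`` columns: ``patient_id``, ``step`` (2 = OHA-exposed,
    3 = elderly insulin-only).  ``threshold_used`` is the age threshold
    applied in step 3.
    """

    table: pd.DataFrame
    threshold_used: int

    @property
    def step2(self) -> set[str]:
        return set(self.table.loc[self.table["step"] == 2, "patient_id"])

    @property
    def step3(self) -> set[str]:
        return set(self.table.loc[self.table["step"] == 3, "patient_id"])

    def patients(self) -> set[str]:
        return set(self.table["patient_id"])


def _first_years(matrix: DeliveryMatrix) -> dict[str, int]:
    """First year with any delivery, per patient."""
    firsts = matrix.counts.reset_index().groupby("patient_id")["year"].min()
    return {str(p): int(y) for p, y in firsts.items()}


def _last_years(matrix: DeliveryMatrix) -> dict[str, int]:
    lasts = matrix.counts.reset_index().groupby("patient_id")["year"].max()
    return {str(p): int(y) for p, y in lasts.items()}


def split_by_oha(
    cases: pd.DataFrame,
    claims: pd.DataFrame,
    horizon: tuple[int, int],
) -> tuple[set[str], set[str]]:
    """Partition cases into OHA-exposed and insulin-only sets.

    A case with >=1 A10B-prefixed delivery anywhere in the horizon goes to
    ``oha_set``; the rest (insulin only, by the detection precondition that
    every case has A10 claims) form ``insulin_only_set``.
    """
    case_ids = set(cases["patient_id"].astype(str))
    a10 = count_deliveries(claims, "A10", horizon)
    a10_patients = set(a10.patients())
    missing = case_ids - a10_patients
    if missing:
        raise ValueError(
            f"{len(missing)} case(s) have no A10 claims in the horizon "
            "(violates detection precondition)"
        )
    oha = count_deliveries(claims, "A10B", horizon)
    oha_set = case_ids & set(oha.patients())
    return oha_set, case_ids - oha_set


def estimate_switch_threshold(
    cases: pd.DataFrame,
    claims: pd.DataFrame,
    persons: pd.DataFrame,
    horizon: tuple[int, int],
    default: int = DEFAULT_SWITCH_THRESHOLD,
) -> tuple[int, SwitchCohort]:
    """Estimate the step-3 age threshold from OHA-to-insulin switchers.

    A switcher is an OHA-exposed case whose final treatment segment in the
    horizon is insulin-only: their last A10B year precedes at least one
    later A10A delivery, and no A10B follows.  The switch year is the first
    insulin year after the last OHA year; age at switch is switch year
    minus birth year.  The threshold is ``floor(mean age at switch)``.

    Switchers without a recorded birth year are excluded with a logged
    count.  With no qualifying switcher at all the configured ``default``
    is returned alongside an empty cohort.
    """
    oha_set, _ = split_by_oha(cases, claims, horizon)
    a10a = count_deliveries(claims, "A10A", horizon)
    a10b = count_deliveries(claims, "A10B", horizon)
    last_oha = _last_years(a10b)
    insulin_years = {
        str(pid): sorted(int(y) for (_, y) in grp.index)
        for pid, grp in a10a.counts.groupby(level="patient_id")
    }
    birth = dict(
        zip(persons["patient_id"].astype(str), persons["birth_year"])
    )
    rows = []
    n_no_birth = 0
    for pid in sorted(oha_set):
        if pid not in last_oha:
            continue
        later_insulin = [y for y in insulin_years.get(pid, []) if y > last_oha[pid]]
        if not later_insulin:
            continue  # never insulin-only after the last OHA
        switch_year = later_insulin[0]
        by = birth.get(pid)
        if by is None or pd.isna(by):
            n_no_birth += 1
            continue
        rows.append(
            {
                "patient_id": pid,
                "switch_year": switch_year,
                "age_at_switch": switch_year - int(by),
            }
        )
    if n_no_birth:
        logger.info(
            "estimate_switch_threshold: excluded %d switcher(s) without birth_year",
            n_no_birth,
        )
    cohort = SwitchCohort(
        pd.DataFrame(rows, columns=["patient_id", "switch_year", "age_at_switch"])
    )
    if len(cohort) == 0:
        logger.warning(
            "estimate_switch_threshold: no qualifying switcher; using default %d", default
        )
        return default, cohort
    threshold = math.floor(cohort.table["age_at_switch"].mean())
    return threshold, cohort


def classify_type2(
    oha_set: set[str],
    insulin_only_set: set[str],
    threshold: int,
    claims: pd.DataFrame,
    persons: pd.DataFrame,
    horizon: tuple[int, int],
    inclusive_threshold: bool = False,
) -> Type2CaseSet:
    """Build the type-2 case set from the OHA split and age threshold.

    Step 2 takes every OHA-exposed case.  Step 3 adds insulin-only cases
    strictly older than ``threshold`` at their first insulin delivery
    ("older than 66" read literally; set ``inclusive_threshold`` for >=).
    Insulin-only cases failing the age test — including those without a
    birth year — are labelled type 1 and excluded from the returned set.
    """
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    a10a = count_deliveries(claims, "A10A", horizon)
    first_insulin = _first_years(a10a)
    birth = dict(zip(persons["patient_id"].astype(str), persons["birth_year"]))
    rows = [{"patient_id": pid, "step": 2} for pid in sorted(oha_set)]
    n_no_birth = 0
    for pid in sorted(insulin_only_set):
        if pid not in first_insulin:
            raise ValueError(
                f"insulin-only case {pid} has no A10A claim (contradiction)"
            )
        by = birth.get(pid)
        if by is None or pd.isna(by):
            n_no_birth += 1
            continue
        age = first_insulin[pid] - int(by)
        included = age >= threshold if inclusive_threshold else age > threshold
        if included:
            rows.append({"patient_id": pid, "step": 3})
    if n_no_birth:
        logger.info(
            "classify_type2: %d insulin-only case(s) without birth_year "
            "excluded from step 3",
            n_no_birth,
        )
    table = pd.DataFrame(rows, columns=["patient_id", "step"])
    return Type2CaseSet(table.sort_values("patient_id").reset_index(drop=True), threshold)


def classification_summary(cases: pd.DataFrame, type2: Type2CaseSet) -> dict[str, float]:
    """Headline counts: cases, step-2/step-3 sizes and the type-2 share."""
    case_ids = set(cases["patient_id"].astype(str))
    if not type2.patients() <= case_ids:
        raise ValueError("type-2 set is not a subset of the case set")
    n_cases = len(case_ids)
    n2, n3 = len(type2.step2), len(type2.step3)
    return {
        "n_cases": n_cases,
        "n_step2": n2,
        "n_step3": n3,
        "n_type2": n2 + n3,
        "type2_share_pct": 100.0 * (n2 + n3) / n_cases if n_cases else 0.0,
    }
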