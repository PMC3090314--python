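"""Step 1 — detect patients treated for diabetes from delivery counts.

Diagnosis codes are absent from the claims, so treated diabetes is defined
purely from yearly counts of A10 (drugs-used-in-diabetes) deliveries.  A
patient is a case when at least one of four criteria holds on their yearly
delivery counts:

1. >=3 deliveries per year in >=2 years;
2. >=3 deliveries in one year AND >=2 deliveries per year in >=2 *other*
   years;
3. >=2 deliveries per year in >=3 years (patients who buy part of their
   supply abroad);
4. >=3 deliveries in the death year, the year before death, or either of
   the last two window years (rescues cases right-truncated by death or by
   the end of the study window).

Detection runs in two phases: criteria are first evaluated on the reporting
window (phase 1, default 2000-2006); patients not selected are re-evaluated
on the full claims history (phase 2, default 1995-2006), which recovers
patients who died early in the reporting window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .claims_io import DeliveryMatrix

logger = logging.getLogger("diabecolux")


@dataclass(frozen=True)
class DetectionWindow:
    """Year windows for the two detection phases.

    ``last_two_years`` are the final two years of phase 1, used by the
    right-truncation criterion (criterion 4); they default to exactly that.
    """

    phase1: tuple[int, int] = (2000, 2006)
    phase2: tuple[int, int] = (1995, 2006)
    last_two_years: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if not (self.phase2[0] <= self.phase1[0] and self.phase1[1] <= self.phase2[1]):
            raise ValueError(f"phase2 {self.phase2} must contain phase1 {self.phase1}")
        if self.last_two_years is None:
            object.__setattr__(
                self, "last_two_years", (self.phase1[1] - 1, self.phase1[1])
            )
        for y in self.last_two_years:
            if not (self.phase1[0] <= y <= self.phase1[1]):
                raise ValueError(f"last_two_years {self.last_two_years} outside phase1")


def evaluate_criteria(
    yearly_counts: dict[int, int],
    window: DetectionWindow,
    death_year: int | None = None,
    phase: int = 1,
    overlapping_criterion2: bool = False,
    consecutive_years: bool = False,
) -> set[int]:
    """Evaluate the four case-definition criteria for one patient.

    Parameters
    ----------
    yearly_counts
        ``{year: delivery count}``; only years inside the phase window are
        considered.
    window
        Phase windows; ``phase`` selects which one restricts the counts.
    death_year
        Calendar year of death, if the patient died.
    overlapping_criterion2
        If true, the >=3-delivery year of criterion 2 may also count toward
        its two >=2-delivery years (the stricter non-overlapping reading is
        the default).
    consecutive_years
        If true, the qualifying years of criteria 1-3 must be consecutive.

    Returns the set of satisfied criterion numbers, a subset of {1, 2, 3, 4}.
    """
    lo, hi = window.phase1 if phase == 1 else window.phase2
    counts = {y: c for y, c in yearly_counts.items() if lo <= y <= hi}
    if any(c < 0 for c in counts.values()):
        raise ValueError("negative delivery counts")

    years3 = sorted(y for y, c in counts.items() if c >= 3)
    years2 = sorted(y for y, c in counts.items() if c >= 2)  # superset of years3

    def has_run(years: list[int], length: int) -> bool:
        if len(years) < length:
            return False
        if not consecutive_years:
            return True
        run = 1
        for a, b in zip(years, years[1:]):
            run = run + 1 if b == a + 1 else 1
            if run >= length:
                return True
        return length <= 1

    matched: set[int] = set()
    if has_run(years3, 2):
        matched.add(1)
    if years3:
        if overlapping_criterion2:
            ok2 = has_run(years2, 2)
        else:
            # the >=3 year must not double-count toward the two >=2 years
            ok2 = any(has_run([y for y in years2 if y != y3], 2) for y3 in years3)
        if ok2:
            matched.add(2)
    if has_run(years2, 3):
        matched.add(3)

    c4_years = set(window.last_two_years)
    if death_year is not None:
        c4_years |= {death_year, death_year - 1}
    if any(counts.get(y, 0) >= 3 for y in c4_years):
        matched.add(4)
    return matched


def primary_criterion(criteria: set[int]) -> int:
    """Attribute a single criterion for breakdown reporting.

    Lowest-numbered first, except that the right-truncation rescue
    (criterion 4) is attributed only when nothing else matches.
    """
    if not criteria:
        raise ValueError("empty criterion set")
    others = criteria - {4}
    return min(others) if others else 4


def death_years(persons: pd.DataFrame) -> dict[str, int]:
    """``patient_id -> calendar year of death`` for deceased persons."""
    dead = persons[persons["death_date"].notna()]
    return {
        str(pid): int(year)
        for pid, year in zip(dead["patient_id"], pd.to_datetime(dead["death_date"]).dt.year)
    }


def detect_cases(
    matrix: DeliveryMatrix,
    persons: pd.DataFrame,
    window: DetectionWindow = DetectionWindow(),
    overlapping_criterion2: bool = False,
    consecutive_years: bool = False,
) -> pd.DataFrame:
    """Run both detection phases over an A10 delivery matrix.

    Returns the case set as a DataFrame with columns ``patient_id``,
    ``phase`` (1 or 2), ``criteria`` ('+'-joined sorted criterion numbers)
    and ``primary_criterion``.  Patients present in the matrix but absent
    from the person registry are processed with unknown death year, with a
    warning.
    """
    if not (matrix.year_range[0] <= window.phase2[0] and window.phase2[1] <= matrix.year_range[1]):
        raise ValueError(
            f"matrix year range {matrix.year_range} does not cover phase2 {window.phase2}"
        )
    deaths = death_years(persons)
    known = set(persons["patient_id"].astype(str))
    rows = []
    n_unknown = 0
    counts_by_patient = {
        pid: {int(y): int(c) for (_, y), c in grp.items()}
        for pid, grp in matrix.counts.groupby(level="patient_id")
    }
    for pid, counts in counts_by_patient.items():
        if pid not in known:
            n_unknown += 1
        dy = deaths.get(pid)
        kwargs = dict(
            overlapping_criterion2=overlapping_criterion2,
            consecutive_years=consecutive_years,
        )
        crit = evaluate_criteria(counts, window, dy, phase=1, **kwargs)
        phase = 1
        if not crit:
            crit = evaluate_criteria(counts, window, dy, phase=2, **kwargs)
            phase = 2
        if crit:
            rows.append(
                {
                    "patient_id": pid,
                    "phase": phase,
                    "criteria": "+".join(str(c) for c in sorted(crit)),
                    "primary_criterion": primary_criterion(crit),
                }
            )
    if n_unknown:
        logger.warning(
            "detect_cases: %d patient(s) in claims but not in person registry; "
            "processed with unknown death year",
            n_unknown,
        )
    cases = pd.DataFrame(rows, columns=["patient_id", "phase", "criteria", "primary_criterion"])
    return cases.sort_values("patient_id").reset_index(drop=True)


def preselect_a10(claims: pd.DataFrame) -> set[str]:
    """Patients with at least one A10-prefixed claim (the exhaustive pool).

    Any detected case necessarily belongs to this set; pre-selecting it
    keeps downstream passes over the claims small.
    """
    mask = claims["atc_code"].str.upper().str.startswith("A10")
    return set(claims.loc[mask, "patient_id"].astype(str))
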