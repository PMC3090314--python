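"""Gold-standard-free validity bounds for the type-1/type-2 split.

No clinical gold standard is available to validate the classification, so
sensitivity (SE), specificity (SPE) and predictive values (PPV, NPV) are
bounded instead of point-estimated.  Given the classifier's observed totals
— ``pop_total`` treated-diabetes cases, of which ``positives`` were
classified type 2 and ``negatives`` type 1 — and an assumed true proportion
of type 2 (``t2p``), the true case count is ``D2 = t2p * pop_total``.  The
unknown false negatives FN then pin down the whole confusion matrix:

    TP = D2 - FN,  FP = positives - TP,  TN = negatives - FN.

FN ranges over every value consistent with the margins and with optional
caps on misclassification (``fp_cap``, ``fn_cap``); by default the caps
encode the extreme scenarios at the endpoints of the plausible ``t2p``
range — "everybody wrongly or properly included" — so at ``t2p_min`` the
bounds force FN = 0 and at ``t2p_max`` they force FP = 0.  Sweeping ``t2p``
over a grid yields interval estimates of the four validity metrics and
their grid-wide minima ("SE always higher than …").
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping

import pandas as pd

logger = logging.getLogger("diabecolux")

#: Plausible true-type-2 proportion range used by default; derived from the
#: age structure of the case population (see the configuration docs).
DEFAULT_T2P_RANGE = (0.928, 0.967)

_DIABETES_ICD_ROOTS = {"E10", "E11", "E12", "E13", "E14"}


def round_half_up(x: float, decimals: int = 1) -> float:
    """Round with ties away from zero (display convention for percents)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ValidityInputs:
    """Observed classification totals and the assumed-true-proportion range.

    ``fp_cap`` / ``fn_cap`` bound how many classifier positives may truly be
    type 1 and how many negatives may truly be type 2.  When left ``None``
    they default to the slack implied by the ``t2p`` range itself:
    ``fp_cap = positives - t2p_min * pop_total`` and
    ``fn_cap = t2p_max * pop_total - positives`` (clipped at zero).
    """

    pop_total: int
    positives: int
    t2p_min: float = DEFAULT_T2P_RANGE[0]
    t2p_max: float = DEFAULT_T2P_RANGE[1]
    fp_cap: float | None = None
    fn_cap: float | None = None

    def __post_init__(self) -> None:
        if not (0 < self.positives <= self.pop_total):
            raise ValueError("need 0 < positives <= pop_total")
        if not (0 < self.t2p_min <= self.t2p_max < 1):
            raise ValueError("need 0 < t2p_min <= t2p_max < 1")
        if self.fp_cap is None:
            object.__setattr__(
                self, "fp_cap", max(0.0, self.positives - self.t2p_min * self.pop_total)
            )
        if self.fn_cap is None:
            object.__setattr__(
                self, "fn_cap", max(0.0, self.t2p_max * self.pop_total - self.positives)
            )

    @property
    def negatives(self) -> int:
        return self.pop_total - self.positives


def confusion_bounds(inputs: ValidityInputs, t2p: float) -> dict[str, tuple[float, float]]:
    """Feasible intervals for TP, FP, TN, FN at one assumed ``t2p``.

    ``D2 = t2p * pop_total`` is kept as a real number; displayed counts are
    rounded only for reporting.  The four intervals are mutually consistent:
    at either endpoint ``TP + FN = D2``, ``FP + TN = D1``,
    ``TP + FP = positives`` and ``FN + TN = negatives``.
    """
    if not (inputs.t2p_min - 1e-12 <= t2p <= inputs.t2p_max + 1e-12):
        raise ValueError(
            f"t2p={t2p} outside configured range [{inputs.t2p_min}, {inputs.t2p_max}]"
        )
    pop, pos, neg = inputs.pop_total, inputs.positives, inputs.negatives
    d2 = t2p * pop
    d1 = pop - d2
    fn_lo = max(0.0, d2 - pos)
    # FP = pos - d2 + FN must stay within min(d1, fp_cap)
    fn_hi = min(float(neg), d2, inputs.fn_cap, min(d1, inputs.fp_cap) - (pos - d2))
    fn_hi = max(fn_hi, fn_lo)  # caps can close the interval to a point
    return {
        "TP": (d2 - fn_hi, d2 - fn_lo),
        "FP": (pos - (d2 - fn_lo), pos - (d2 - fn_hi)),
        "TN": (neg - fn_hi, neg - fn_lo),
        "FN": (fn_lo, fn_hi),
    }


def metric_intervals(
    inputs: ValidityInputs,
    t2p_grid: Iterable[float],
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Validity-metric intervals over a grid of assumed ``t2p`` values.

    For each grid value the confusion bounds are converted to percent-scale
    intervals via SE = TP / D2, SPE = TN / D1, PPV = TP / positives,
    NPV = TN / negatives, displayed at one decimal (half-up).

    Returns the per-row table and the grid-wide minima of the interval
    lower bounds — the "always higher than" summary figures.
    """
    pop, pos, neg = inputs.pop_total, inputs.positives, inputs.negatives
    rows = []
    for t2p in t2p_grid:
        cb = confusion_bounds(inputs, t2p)
        d2 = t2p * pop
        d1 = pop - d2

        def pct(interval: tuple[float, float], denom: float) -> tuple[float, float]:
            if denom <= 0:
                return (float("nan"), float("nan"))
            return (
                round_half_up(100.0 * interval[0] / denom),
                round_half_up(100.0 * interval[1] / denom),
            )

        se = pct(cb["TP"], d2)
        spe = pct(cb["TN"], d1)
        ppv = pct(cb["TP"], pos)
        npv = pct(cb["TN"], neg)
        rows.append(
            {
                "t2p": t2p,
                "TP_lo": round(cb["TP"][0]),
                "TP_hi": round(cb["TP"][1]),
                "TN_lo": round(cb["TN"][0]),
                "TN_hi": round(cb["TN"][1]),
                "D2": round(d2),
                "D1": round(d1),
                "SE_lo": se[0],
                "SE_hi": se[1],
                "SPE_lo": spe[0],
                "SPE_hi": spe[1],
                "PPV_lo": ppv[0],
                "PPV_hi": ppv[1],
                "NPV_lo": npv[0],
                "NPV_hi": npv[1],
            }
        )
    table = pd.DataFrame(rows)
    minima = {
        metric: float(table[f"{metric}_lo"].min()) for metric in ("SE", "SPE", "PPV", "NPV")
    }
    return table, minima


def t2p_range_from_classes(
    class_shares: Mapping[str, float],
    class_t2p_bounds: Mapping[str, tuple[float, float]],
    tol: float = 1e-6,
) -> tuple[float, float]:
    """Pool per-age-class type-2 proportion bounds into a global range.

    The true type-2 proportion is not homogeneous over age (essentially
    zero among young-onset cases, near one among the elderly), so it is
    decomposed by age class and pooled back as the share-weighted sum of
    the class lower and upper bounds.
    """
    total = sum(class_shares.values())
    if abs(total - 1.0) > tol:
        raise ValueError(f"class shares sum to {total}, not 1")
    missing = set(class_shares) - set(class_t2p_bounds)
    if missing:
        raise ValueError(f"no t2p bounds for class(es): {sorted(missing)}")
    lo = sum(class_shares[c] * class_t2p_bounds[c][0] for c in class_shares)
    hi = sum(class_shares[c] * class_t2p_bounds[c][1] for c in class_shares)
    return lo, hi


def discharge_crosscheck(
    rejected: set[str],
    discharge_records: Mapping[str, Iterable[str]],
) -> dict[str, float]:
    """Cross-check rejected patients against diabetes discharge codes.

    Counts rejected patients with at least one hospital-discharge ICD-10
    code rooted in E10-E14 (diabetes mellitus).  A low count supports the
    case definition: patients the delivery criteria rejected rarely carry a
    diabetes diagnosis.  Malformed codes are skipped with a warning.  The
    proportion uses the rejected set as denominator; callers may prefer
    another.
    """
    n_hit = 0
    for pid in rejected:
        codes = discharge_records.get(pid, ())
        hit = False
        for code in codes:
            root = str(code).strip().upper()[:3]
            if len(root) != 3 or not root[0].isalpha() or not root[1:].isdigit():
                logger.warning("discharge_crosscheck: skipping malformed ICD code %r", code)
                continue
            if root in _DIABETES_ICD_ROOTS:
                hit = True
        if hit:
            n_hit += 1
    return {
        "n_rejected": len(rejected),
        "n_with_diabetes_discharge": n_hit,
        "proportion": n_hit / len(rejected) if rejected else 0.0,
    }
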