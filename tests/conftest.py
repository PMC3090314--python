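"""Shared fixtures: simulated populations and independent oracles."""

from __future__ import annotations

import itertools

import pytest

from diabecolux import count_deliveries, get_preset, simulate_population


@pytest.fixture(scope="session")
def lux_sim():
    """One luxembourg_like population (n=5000), shared across tests."""
    config = get_preset("luxembourg_like", seed=42)
    persons, claims, truth = simulate_population(config)
    return config, persons, claims, truth


@pytest.fixture(scope="session")
def tiny_sim():
    config = get_preset("tiny", seed=3)
    persons, claims, truth = simulate_population(config)
    return config, persons, claims, truth


@pytest.fixture(scope="session")
def lux_matrix(lux_sim):
    config, persons, claims, _ = lux_sim
    return count_deliveries(claims, "A10", config.horizon)


def oracle_criteria(
    counts: dict[int, int],
    last_two: tuple[int, int],
    death_year: int | None,
) -> set[int]:
    """Brute-force re-statement of the four case-definition predicates.

    Enumerates explicit year subsets instead of counting, so it shares no
    code path with the implementation under test.
    """
    years = sorted(y for y, c in counts.items() if c > 0)
    matched = set()
    if any(
        all(counts[y] >= 3 for y in pair) for pair in itertools.combinations(years, 2)
    ):
        matched.add(1)
    if any(
        counts[y3] >= 3 and all(counts[y] >= 2 for y in pair)
        for y3 in years
        for pair in itertools.combinations([y for y in years if y != y3], 2)
    ):
        matched.add(2)
    if any(
        all(counts[y] >= 2 for y in trio) for trio in itertools.combinations(years, 3)
    ):
        matched.add(3)
    c4_years = set(last_two)
    if death_year is not None:
        c4_years |= {death_year, death_year - 1}
    if any(counts.get(y, 0) >= 3 for y in c4_years):
        matched.add(4)
    return matched


def oracle_confusion_bounds(pop, pos, d2, fp_cap, fn_cap):
    """Exhaustive enumeration of consistent confusion matrices.

    For an integer true type-2 count ``d2``, lists every (TP, FP, TN, FN)
    respecting the classifier margins and the misclassification caps, and
    returns the elementwise min/max.
    """
    neg = pop - pos
    d1 = pop - d2
    feasible = []
    for fn in range(0, neg + 1):
        tp = d2 - fn
        if not (0 <= tp <= pos):
            continue
        fp = pos - tp
        tn = neg - fn
        if fp > min(d1, fp_cap) + 1e-9 or fn > fn_cap + 1e-9:
            continue
        feasible.append((tp, fp, tn, fn))
    assert feasible, "no consistent assignment"
    cols = list(zip(*feasible))
    return {
        name: (min(col), max(col))
        for name, col in zip(("TP", "FP", "TN", "FN"), cols)
    }
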