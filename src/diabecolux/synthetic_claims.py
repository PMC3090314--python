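"""Ground-truth-labelled synthetic pharmacy-claims populations.

No public claims database exists for this problem, so every downstream
stage is exercised on simulated populations with known labels.  The
generator emulates the structure that the case-definition criteria are
designed around:

* **type-2 patients** start oral agents (``A10B``) at a sampled onset year
  and refill regularly; a configurable subset later switches to insulin
  alone (``A10A``), at ages centred on ``switch_age_mean``;
* **type-1 patients** receive insulin only, from young onset ages;
* **travellers** are type-2 patients who fill only twice a year (part of
  their supply is bought abroad) — the population criterion 3 exists for;
* **noise users** are non-diabetics with one or two isolated A10 claims in
  a single year (prescription or coding errors) — the false positives the
  three-delivery rule exists to reject;
* deaths from an age-dependent (Gompertz) annual hazard truncate claim
  trajectories.

All randomness flows from one :func:`numpy.random.default_rng` generator
seeded by ``SimulationConfig.seed``; identical configs give identical
tables.  Delivery counts in a fully treated year are ``3 + Poisson(mean-3)``
for adherent patients: an adherent patient refills at least quarterly, so
any adherent patient treated for two or more full years satisfies
criterion 1 by construction.  Dates within a year are spaced by a minimum
28-day refill gap.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .claims_io import DEFAULT_HORIZON

OHA_CODES = ("A10BA02", "A10BB01", "A10BB12", "A10BG03")
INSULIN_CODES = ("A10AB01", "A10AC01", "A10AD01", "A10AE04")


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated insured population.

    Defaults describe a mid-size western-European covered population:
    ~4% treated type-2 prevalence, ~5% of diabetics type 1, regular
    refills averaging five per year, and OHA-to-insulin switches centred
    on age 66.3.
    """

    n_population: int = 5000
    frac_type2_treated: float = 0.04
    frac_type1_treated: float = 0.002
    frac_noise_users: float = 0.02
    frac_switchers: float = 0.15  # of type-2 patients
    frac_travellers: float = 0.03  # of type-2 patients
    deliveries_per_year_mean: float = 5.0
    horizon: tuple[int, int] = DEFAULT_HORIZON
    onset_age_mean_type2: float = 60.0
    onset_age_sd_type2: float = 12.0
    onset_age_mean_type1: float = 18.0
    onset_age_sd_type1: float = 8.0
    switch_age_mean: float = 66.3
    switch_age_sd: float = 5.0
    death_hazard_scale: float = 2e-5  # Gompertz: h(age) = scale * exp(shape * age)
    death_hazard_shape: float = 0.09
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_population <= 0:
            raise ValueError("n_population must be positive")
        fracs = (
            self.frac_type2_treated,
            self.frac_type1_treated,
            self.frac_noise_users,
            self.frac_switchers,
            self.frac_travellers,
        )
        if any(not (0 <= f <= 1) for f in fracs):
            raise ValueError("all fractions must lie in [0, 1]")
        if self.frac_type2_treated + self.frac_type1_treated + self.frac_noise_users > 1:
            raise ValueError("population fractions exceed 1")
        if self.deliveries_per_year_mean < 3:
            raise ValueError("adherent patients refill at least three times a year")


def scenario_presets() -> dict[str, SimulationConfig]:
    """Named study scenarios.

    ``tiny`` is a fast unit-test population; ``luxembourg_like`` matches a
    small-country insured population with ~4% treated type-2 prevalence
    and switch ages centred on 66.3; ``high_noise`` stresses the
    false-positive rejection with many sporadic users.
    """
    return {
        "tiny": SimulationConfig(n_population=400, seed=0),
        "luxembourg_like": SimulationConfig(
            n_population=5000, frac_type2_treated=0.04, switch_age_mean=66.3, seed=0
        ),
        "high_noise": SimulationConfig(n_population=2000, frac_noise_users=0.08, seed=0),
    }


def get_preset(name: str, seed: int | None = None) -> SimulationConfig:
    presets = scenario_presets()
    if name not in presets:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(presets)}")
    cfg = presets[name]
    return replace(cfg, seed=seed) if seed is not None else cfg


def _delivery_days(rng: np.random.Generator, n: int, last_day: int = 365) -> np.ndarray:
    """``n`` distinct days in 1..last_day with ~28-day refill gaps when feasible."""
    n = max(1, min(n, last_day))
    gap = min(28, max(1, (last_day - 1) // n))
    base = 1 + gap * np.arange(n) + rng.integers(0, max(1, gap // 2), size=n)
    for i in range(1, n):  # keep strictly increasing despite jitter
        if base[i] <= base[i - 1]:
            base[i] = base[i - 1] + 1
    span = int(base[-1] - base[0])
    start_max = last_day - span
    start = int(rng.integers(1, start_max + 1)) if start_max >= 1 else 1
    return np.clip(base - base[0] + start, 1, last_day)


def _dates_in_year(year: int, days: np.ndarray) -> list[pd.Timestamp]:
    base = pd.Timestamp(year=year, month=1, day=1)
    return [base + pd.Timedelta(days=int(d) - 1) for d in days]


def simulate_population(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate persons, claims and the ground-truth label table.

    Returns ``(persons, claims, truth)``.  ``truth`` has one row per person:
    ``patient_id``, ``label`` in {type1, type2, none}, ``subgroup`` in
    {adherent, traveller, switcher, noise, background}, ``onset_year`` and
    ``switch_year`` (NaN where not applicable).  Claims never post-date a
    patient's death.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_population
    h0, h1 = config.horizon
    ids = np.array([f"P{i:06d}" for i in range(1, n + 1)])

    p_bg = 1.0 - config.frac_type2_treated - config.frac_type1_treated - config.frac_noise_users
    roles = rng.choice(
        np.array(["type2", "type1", "noise", "background"]),
        size=n,
        p=[
            config.frac_type2_treated,
            config.frac_type1_treated,
            config.frac_noise_users,
            p_bg,
        ],
    )
    sex = rng.choice(np.array(["male", "female"]), size=n)

    birth_year = np.empty(n, dtype=int)
    onset_year = np.full(n, np.nan)
    switch_year = np.full(n, np.nan)
    subgroup = np.full(n, "background", dtype=object)

    for i in range(n):
        role = roles[i]
        if role == "type2":
            u = rng.random()
            if u < config.frac_switchers:
                subgroup[i] = "switcher"
                sw = int(rng.integers(h0 + 2, h1 + 1))
                age_sw = int(np.round(rng.normal(config.switch_age_mean, config.switch_age_sd)))
                age_sw = int(np.clip(age_sw, 30, 100))
                birth_year[i] = sw - age_sw
                onset_year[i] = max(h0, sw - int(rng.integers(2, 9)))
                switch_year[i] = sw
            else:
                traveller = u < config.frac_switchers + config.frac_travellers
                subgroup[i] = "traveller" if traveller else "adherent"
                last_onset = h1 - 3 if traveller else h1
                onset = int(rng.integers(h0, last_onset + 1))
                age_onset = int(
                    np.clip(
                        np.round(rng.normal(config.onset_age_mean_type2, config.onset_age_sd_type2)),
                        30,
                        95,
                    )
                )
                birth_year[i] = onset - age_onset
                onset_year[i] = onset
        elif role == "type1":
            subgroup[i] = "adherent"
            onset = int(rng.integers(h0, h1 + 1))
            age_onset = int(
                np.clip(
                    np.round(rng.normal(config.onset_age_mean_type1, config.onset_age_sd_type1)),
                    1,
                    35,
                )
            )
            birth_year[i] = onset - age_onset
            onset_year[i] = onset
        else:
            if role == "noise":
                subgroup[i] = "noise"
            age_2000 = int(rng.integers(0, 91))
            birth_year[i] = 2000 - age_2000

    # annual Gompertz death hazard, evaluated only inside the horizon
    death_year = np.full(n, -1, dtype=int)
    death_day = np.zeros(n, dtype=int)
    alive = np.ones(n, dtype=bool)
    for year in range(h0, h1 + 1):
        age = np.maximum(year - birth_year, 0)
        hazard = np.clip(
            config.death_hazard_scale * np.exp(config.death_hazard_shape * age), 0, 0.7
        )
        born = birth_year <= year
        dies = alive & born & (rng.random(n) < hazard)
        death_year[dies] = year
        death_day[dies] = rng.integers(1, 366, size=int(dies.sum()))
        alive &= ~dies

    mean_extra = config.deliveries_per_year_mean - 3.0
    claim_rows: list[tuple[str, pd.Timestamp, str]] = []

    for i in range(n):
        role = roles[i]
        if role == "background":
            continue
        died = death_year[i] >= 0
        if role == "noise":
            year = int(rng.integers(h0, h1 + 1))
            if died and year > death_year[i]:
                year = death_year[i]
            n_del = int(rng.integers(1, 3))
            last_day = death_day[i] if died and year == death_year[i] else 365
            if last_day < 1:
                continue
            days = rng.choice(np.arange(1, last_day + 1), size=min(n_del, last_day), replace=False)
            codes = rng.choice(np.array(OHA_CODES + INSULIN_CODES), size=len(days))
            for d, code in zip(_dates_in_year(year, np.sort(days)), codes):
                claim_rows.append((ids[i], d, str(code)))
            continue

        onset = int(onset_year[i])
        end = min(h1, death_year[i]) if died else h1
        for year in range(onset, end + 1):
            last_day = death_day[i] if died and year == death_year[i] else 365
            if last_day < 1:
                continue
            if subgroup[i] == "traveller":
                n_del = 2
            else:
                n_del = 3 + int(rng.poisson(mean_extra))
            days = _delivery_days(rng, n_del, last_day=365)
            days = days[days <= last_day]
            if len(days) == 0:
                continue
            if role == "type1":
                codes = rng.choice(np.array(INSULIN_CODES), size=len(days))
            elif subgroup[i] == "switcher" and year >= switch_year[i]:
                codes = rng.choice(np.array(INSULIN_CODES), size=len(days))
            else:
                codes = rng.choice(np.array(OHA_CODES), size=len(days))
            for d, code in zip(_dates_in_year(year, days), codes):
                claim_rows.append((ids[i], d, str(code)))

    claims = pd.DataFrame(claim_rows, columns=["patient_id", "delivery_date", "atc_code"])
    claims = claims.sort_values(["patient_id", "delivery_date"]).reset_index(drop=True)

    death_date = [
        pd.Timestamp(year=int(y), month=1, day=1) + pd.Timedelta(days=int(d) - 1)
        if y >= 0
        else pd.NaT
        for y, d in zip(death_year, death_day)
    ]
    persons = pd.DataFrame(
        {
            "patient_id": ids,
            "sex": sex,
            "birth_year": pd.array(birth_year, dtype="Int64"),
            "death_date": death_date,
        }
    )
    truth = pd.DataFrame(
        {
            "patient_id": ids,
            "label": np.where(roles == "type2", "type2", np.where(roles == "type1", "type1", "none")),
            "subgroup": subgroup,
            "onset_year": onset_year,
            "switch_year": switch_year,
        }
    )
    return persons, claims, truth


def denominators_from_persons(
    persons: pd.DataFrame,
    period: tuple[int, int],
    age_classes: list[tuple[int, int]] | None = None,
) -> pd.DataFrame:
    """Covered-population denominators implied by a simulated registry.

    Counts persons alive on 31 December of each year, overall ("all"/"all")
    and by sex × age class, in the denominators-CSV layout.  Persons with
    ages outside the class scheme fall only into the margins.
    """
    from .prevalence_trends import age_class_label, default_age_classes

    classes = age_classes or default_age_classes()
    rows = []
    dd = pd.to_datetime(persons["death_date"])
    for year in range(period[0], period[1] + 1):
        eoy = pd.Timestamp(year=year, month=12, day=31)
        alive = (dd.isna() | (dd > eoy)) & (persons["birth_year"] <= year)
        sub = persons[alive.fillna(False)]
        rows.append({"year": year, "sex": "all", "age_class": "all", "population": len(sub)})
        for s in ("male", "female"):
            by_sex = sub[sub["sex"] == s]
            ages = year - by_sex["birth_year"].astype(int)
            for lo, hi in classes:
                label = f"{lo}-{hi}"
                n = int(sum(age_class_label(int(a), classes) == label for a in ages))
                rows.append(
                    {"year": year, "sex": s, "age_class": label, "population": max(n, 1)}
                )
    return pd.DataFrame(rows)
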