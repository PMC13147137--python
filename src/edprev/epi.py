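"""Age-structured four-state Markov cohort engine.

Each eating disorder is modelled independently with four health states:
healthy, diseased, dead from the disease, and dead from other causes.
Annual per-person rates (incidence, remission, case fatality, all-cause
mortality) are embedded into one-cycle transition probabilities via the
matrix exponential of the competing-risk generator, which guarantees
row-stochastic matrices however large the rates are.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import expm

STATES = ("healthy", "diseased", "dead_disease", "dead_other")
DISEASES = ("AN", "BN", "BED")
SEXES = ("female", "male")

#: strict column order for delimited-text rate tables
RATE_COLUMNS = (
    "disease",
    "sex",
    "age",
    "incidence",
    "remission",
    "case_fatality",
    "all_cause_mortality",
)

_RATE_FIELDS = ("incidence", "remission", "case_fatality", "all_cause_mortality")


class InputValidationError(ValueError):
    """Raised when model inputs violate their domain contract."""


@dataclass(frozen=True)
class EpiRates:
    """Annual rates for one disease and sex over a contiguous age range.

    All rates are per person-year. ``all_cause_mortality`` is background
    mortality (it is *not* net of the disease's case fatality; see the
    ``net_other_mortality`` switch on the engine).
    """

    disease: str
    sex: str
    ages: np.ndarray
    incidence: np.ndarray
    remission: np.ndarray
    case_fatality: np.ndarray
    all_cause_mortality: np.ndarray

    def __post_init__(self) -> None:
        ages = np.asarray(self.ages, dtype=int)
        object.__setattr__(self, "ages", ages)
        if ages.size == 0:
            raise InputValidationError("EpiRates needs at least one age")
        if not np.array_equal(ages, np.arange(ages[0], ages[-1] + 1)):
            raise InputValidationError("ages must form a contiguous range")
        for name in _RATE_FIELDS:
            arr = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, arr)
            if arr.shape != ages.shape:
                raise InputValidationError(f"{name} must align with ages")
            if np.any(arr < 0) or not np.all(np.isfinite(arr)):
                bad = int(ages[np.flatnonzero((arr < 0) | ~np.isfinite(arr))[0]])
                raise InputValidationError(
                    f"negative or non-finite {name} at age {bad} "
                    f"({self.disease}, {self.sex})"
                )

    @property
    def min_age(self) -> int:
        return int(self.ages[0])

    @property
    def max_age(self) -> int:
        return int(self.ages[-1])

    def at(self, age: int) -> dict[str, float]:
        """Rates {i, r, f, m} at one integer age."""
        if not self.min_age <= age <= self.max_age:
            raise InputValidationError(
                f"age {age} outside defined range "
                f"[{self.min_age}, {self.max_age}] for {self.disease}/{self.sex}"
            )
        k = age - self.min_age
        return {
            "i": float(self.incidence[k]),
            "r": float(self.remission[k]),
            "f": float(self.case_fatality[k]),
            "m": float(self.all_cause_mortality[k]),
        }

    def scaled(self, incidence: float = 1.0, remission: float = 1.0,
               case_fatality: float = 1.0) -> "EpiRates":
        """Return a copy with whole-curve multiplicative factors applied."""
        return replace(
            self,
            incidence=self.incidence * incidence,
            remission=self.remission * remission,
            case_fatality=self.case_fatality * case_fatality,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "disease": self.disease,
                "sex": self.sex,
                "age": self.ages,
                "incidence": self.incidence,
                "remission": self.remission,
                "case_fatality": self.case_fatality,
                "all_cause_mortality": self.all_cause_mortality,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "EpiRates":
        """Build from a table holding exactly one (disease, sex)."""
        missing = set(RATE_COLUMNS) - set(df.columns)
        if missing:
            raise InputValidationError(f"rate table missing columns: {sorted(missing)}")
        keys = df[["disease", "sex"]].drop_duplicates()
        if len(keys) != 1:
            raise InputValidationError("expected a single (disease, sex) block")
        df = df.sort_values("age")
        return cls(
            disease=str(df["disease"].iloc[0]),
            sex=str(df["sex"].iloc[0]),
            ages=df["age"].to_numpy(dtype=int),
            incidence=df["incidence"].to_numpy(dtype=float),
            remission=df["remission"].to_numpy(dtype=float),
            case_fatality=df["case_fatality"].to_numpy(dtype=float),
            all_cause_mortality=df["all_cause_mortality"].to_numpy(dtype=float),
        )


def build_generator(rates: Mapping[str, float], net_other_mortality: bool = False) -> np.ndarray:
    """Continuous-time generator of the four-state competing-risk process.

    Off-diagonal flows: healthy->diseased = i, healthy->dead_other = m,
    diseased->healthy = r, diseased->dead_disease = f,
    diseased->dead_other = m (or max(m - f, 0) when ``net_other_mortality``
    nets the case fatality out of background mortality for the diseased).
    """
    i, r, f, m = (float(rates[k]) for k in ("i", "r", "f", "m"))
    for name, v in zip("irfm", (i, r, f, m)):
        if v < 0 or not np.isfinite(v):
            raise InputValidationError(f"rate '{name}' must be a finite non-negative number, got {v}")
    m_d = max(m - f, 0.0) if net_other_mortality else m
    g = np.zeros((4, 4))
    g[0, 1], g[0, 3] = i, m
    g[1, 0], g[1, 2], g[1, 3] = r, f, m_d
    np.fill_diagonal(g, -g.sum(axis=1))
    return g


def derive_transition_matrix(
    rates: Mapping[str, float],
    cycle_length: float = 1.0,
    net_other_mortality: bool = False,
) -> np.ndarray:
    """One-cycle 4x4 transition probability matrix from annual rates.

    Exact exponential embedding of the generator: rows are stochastic for
    any non-negative rates and dead states are absorbing. Note the embedded
    matrix carries a small healthy->dead_disease probability (falling ill
    and dying of the disease within the same cycle), of order i*f/2 — a
    feature of correct competing-risk embedding, not a defect.
    """
    if cycle_length <= 0:
        raise InputValidationError("cycle_length must be positive")
    g = build_generator(rates, net_other_mortality=net_other_mortality)
    p = expm(g * cycle_length)
    # harden against representable round-off only
    np.clip(p, 0.0, 1.0, out=p)
    return p


@dataclass
class CohortTrace:
    """State occupancy of one closed cohort over annual cycles.

    ``occupancy`` has shape (horizon + 1, 4) in the order of :data:`STATES`;
    row t is the start of cycle t (age = start_age + t). ``incident_cases``
    has length horizon: expected new disease onsets during cycle t.
    """

    arm: str
    disease: str
    sex: str
    start_age: int
    occupancy: np.ndarray
    incident_cases: np.ndarray
    cycle_length: float = 1.0

    @property
    def horizon(self) -> int:
        return self.occupancy.shape[0] - 1

    @property
    def cohort_size(self) -> float:
        return float(self.occupancy[0].sum())

    def conservation_error(self) -> float:
        """Max relative deviation of per-cycle occupancy totals from t=0."""
        totals = self.occupancy.sum(axis=1)
        n0 = totals[0]
        if n0 == 0:
            return float(np.abs(totals).max())
        return float(np.abs(totals - n0).max() / n0)

    def to_frame(self) -> pd.DataFrame:
        t = np.arange(self.horizon + 1)
        frames = []
        for k, state in enumerate(STATES):
            frames.append(
                pd.DataFrame(
                    {
                        "arm": self.arm,
                        "disease": self.disease,
                        "sex": self.sex,
                        "cohort_age": self.start_age,
                        "cycle": t,
                        "state": state,
                        "count": self.occupancy[:, k],
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)


def run_cohort(
    cohort_size: float,
    start_age: int,
    initial_diseased_fraction: float,
    rates: EpiRates,
    horizon: int,
    incidence_multiplier: Callable[[int], float] | None = None,
    arm: str = "control",
    cycle_length: float = 1.0,
    net_other_mortality: bool = False,
    matrix_cache: dict | None = None,
) -> CohortTrace:
    """Propagate a closed cohort through the four-state model.

    ``incidence_multiplier(t)`` scales the incidence rate during cycle t
    (t = 0 is the cycle starting at ``start_age``); the intervention arm
    passes the time-varying relative risk times the body-dissatisfaction
    adjustment, the control arm the adjustment alone. ``matrix_cache`` may
    be shared across cohorts to reuse embedded matrices for identical
    (age, multiplier) pairs.
    """
    if horizon < 1:
        raise InputValidationError("horizon must be at least 1 cycle")
    if not 0.0 <= initial_diseased_fraction <= 1.0:
        raise InputValidationError("initial_diseased_fraction must lie in [0, 1]")
    if start_age + horizon - 1 > rates.max_age:
        raise InputValidationError(
            f"horizon {horizon} from age {start_age} needs rates up to age "
            f"{start_age + horizon - 1}, but they stop at {rates.max_age}"
        )
    cache = matrix_cache if matrix_cache is not None else {}

    occ = np.zeros((horizon + 1, 4))
    occ[0, 0] = cohort_size * (1.0 - initial_diseased_fraction)
    occ[0, 1] = cohort_size * initial_diseased_fraction
    incident = np.zeros(horizon)

    for t in range(horizon):
        age = start_age + t
        mult = 1.0 if incidence_multiplier is None else float(incidence_multiplier(t))
        if mult < 0:
            raise InputValidationError(f"incidence multiplier at cycle {t} is negative")
        key = (age, mult)
        p = cache.get(key)
        if p is None:
            r = rates.at(age)
            r["i"] *= mult
            p = derive_transition_matrix(
                r, cycle_length=cycle_length, net_other_mortality=net_other_mortality
            )
            cache[key] = p
        incident[t] = occ[t, 0] * p[0, 1]
        occ[t + 1] = occ[t] @ p

    return CohortTrace(
        arm=arm,
        disease=rates.disease,
        sex=rates.sex,
        start_age=start_age,
        occupancy=occ,
        incident_cases=incident,
        cycle_length=cycle_length,
    )


def steady_state_prevalence(
    rates: EpiRates,
    target_age: int,
    entry_age: int | None = None,
    incidence_multiplier_by_age: Callable[[int], float] | None = None,
    net_other_mortality: bool = False,
    matrix_cache: dict | None = None,
) -> float:
    """Diseased fraction among the living at ``target_age``.

    Runs an all-healthy cohort from ``entry_age`` (default: youngest age with
    defined rates) forward under the given age-specific incidence adjustment.
    Used to seed each starting cohort's initial diseased fraction when no
    prevalence input is supplied.
    """
    entry = rates.min_age if entry_age is None else entry_age
    if target_age < entry:
        raise InputValidationError("target_age precedes entry_age")
    if target_age == entry:
        return 0.0
    mult = None
    if incidence_multiplier_by_age is not None:
        mult = lambda t: incidence_multiplier_by_age(entry + t)  # noqa: E731
    trace = run_cohort(
        1.0,
        entry,
        0.0,
        rates,
        horizon=target_age - entry,
        incidence_multiplier=mult,
        net_other_mortality=net_other_mortality,
        matrix_cache=matrix_cache,
    )
    h, d = trace.occupancy[-1, 0], trace.occupancy[-1, 1]
    alive = h + d
    return float(d / alive) if alive > 0 else 0.0


def aggregate_traces(
    traces: Sequence[CohortTrace],
    half_cycle_correction: bool = False,
) -> pd.DataFrame:
    """Sum per-cohort traces into population totals per calendar cycle.

    All cohorts share calendar t = 0 (the intervention year). Returns one
    row per (arm, sex, disease, cycle) with alive and prevalent
    person-years, cumulative dead counts per cause, and incident cases.
    Person-years use start-of-cycle occupancy, or the mean of adjacent
    occupancies when the half-cycle correction is on.
    """
    if not traces:
        raise InputValidationError("no traces to aggregate")
    lengths = {t.cycle_length for t in traces}
    if len(lengths) != 1:
        raise InputValidationError(f"mixed cycle lengths: {sorted(lengths)}")

    rows = []
    for tr in traces:
        occ = tr.occupancy
        if half_cycle_correction:
            py = 0.5 * (occ[:-1] + occ[1:])
            n = py.shape[0]
            dead = occ[1:]
            incident = tr.incident_cases
        else:
            py = occ
            n = occ.shape[0]
            dead = occ
            incident = np.append(tr.incident_cases, 0.0)
        rows.append(
            pd.DataFrame(
                {
                    "arm": tr.arm,
                    "sex": tr.sex,
                    "disease": tr.disease,
                    "cycle": np.arange(n),
                    "alive_py": py[:, 0] + py[:, 1],
                    "prevalent_py": py[:, 1],
                    "dead_disease": dead[:, 2],
                    "dead_other": dead[:, 3],
                    "incident_cases": incident[:n],
                }
            )
        )
    out = (
        pd.concat(rows, ignore_index=True)
        .groupby(["arm", "sex", "disease", "cycle"], as_index=False)
        .sum()
    )
    return out
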