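"""Participant cascade, intervention costing, and treatment-cost offsets.

The eligible population funnels through three proportions — response to
recruitment materials, screening positive for high body image concerns,
and acceptance of the offered program — and the survivors are grouped for
delivery. Intervention costs are built bottom-up from unit costs: school
counselor time for recruitment, screening and delivery (with employer
on-costs), per-school facilitator training, and a national project
coordinator. Future treatment costs averted by prevented cases enter the
economics as discounted cost offsets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace

import numpy as np
import pandas as pd

from .epi import InputValidationError


def round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


class MissingCostError(KeyError):
    """Raised when the treatment-cost table has no cell for a (disease, age)."""


@dataclass(frozen=True)
class CascadeResult:
    """Counts derived from one population passing through the funnel."""

    population: int
    responders: int
    screened_eligible: int
    participants: int
    groups: int
    n_schools: int

    def __post_init__(self) -> None:
        chain = (
            self.population,
            self.responders,
            self.screened_eligible,
            self.participants,
        )
        if any(c < 0 for c in chain):
            raise InputValidationError("cascade counts cannot be negative")
        if any(a < b for a, b in zip(chain, chain[1:])):
            raise InputValidationError("cascade counts must be non-increasing")


def compute_cascade(
    population: int,
    response_rate: float = 0.10,
    high_bd_rate: float = 0.689,
    acceptance_rate: float = 0.45,
    n_schools: int = 1416,
    group_size: int = 8,
) -> CascadeResult:
    """Funnel the school population down to participants and groups.

    Counts are rounded half-up at each stage. Participants are allocated
    evenly across schools before the per-school group count is ceilinged
    at the given group size.
    """
    for name, p in (
        ("response_rate", response_rate),
        ("high_bd_rate", high_bd_rate),
        ("acceptance_rate", acceptance_rate),
    ):
        if not 0.0 <= p <= 1.0:
            raise InputValidationError(f"{name} must lie in [0, 1], got {p}")
    if population < 0 or n_schools < 1 or group_size < 1:
        raise InputValidationError("population, n_schools, group_size must be positive")

    responders = round_half_up(population * response_rate)
    screened = round_half_up(responders * high_bd_rate)
    participants = round_half_up(screened * acceptance_rate)
    if participants > 0:
        per_school = participants / n_schools
        groups = n_schools * math.ceil(per_school / group_size)
    else:
        groups = 0
    return CascadeResult(
        population=int(population),
        responders=responders,
        screened_eligible=screened,
        participants=participants,
        groups=groups,
        n_schools=n_schools,
    )


@dataclass(frozen=True)
class CostInputs:
    """Unit costs and delivery assumptions (2019 AUD).

    Defaults follow the published costing assumptions: counselor and
    coordinator hourly wages from national earnings statistics with 30%
    employer on-costs; 10 minutes of counselor time to introduce the
    program per 25-student class; 10 minutes of screening per responding
    student; per-school facilitator training (online fee, four hours of
    technical assistance, and 10 h 15 min of counselor time); four
    one-hour sessions plus a 12-minute make-up session per group of 8.
    Coordinator hours are not stated in the source costing and default to
    one full-time year (37.5 h/week x 46 working weeks).
    """

    counselor_hourly: float = 40.90
    coordinator_hourly: float = 87.99
    oncost_rate: float = 0.30
    recruit_minutes_per_class: float = 10.0
    class_size: int = 25
    screening_minutes_per_student: float = 10.0
    training_online_fee: float = 416.0
    tech_assist_hours: float = 4.0
    tech_assist_rate: float = 125.0
    counselor_training_hours: float = 10.25
    sessions: int = 4
    session_hours: float = 1.0
    makeup_session_hours: float = 0.2
    group_size: int = 8
    coordinator_hours_total: float = 37.5 * 46

    def __post_init__(self) -> None:
        for f in fields(self):
            if float(getattr(self, f.name)) < 0:
                raise InputValidationError(f"cost input {f.name} cannot be negative")

    @property
    def loaded_counselor_rate(self) -> float:
        return self.counselor_hourly * (1.0 + self.oncost_rate)

    @property
    def loaded_coordinator_rate(self) -> float:
        return self.coordinator_hourly * (1.0 + self.oncost_rate)

    def with_private_cost_factor(self, factor: float) -> "CostInputs":
        """Scale the priced unit costs (wages, training, tech assistance)."""
        return replace(
            self,
            counselor_hourly=self.counselor_hourly * factor,
            coordinator_hourly=self.coordinator_hourly * factor,
            training_online_fee=self.training_online_fee * factor,
            tech_assist_rate=self.tech_assist_rate * factor,
        )


@dataclass(frozen=True)
class CostBreakdown:
    recruitment: float
    screening: float
    training: float
    delivery: float
    coordination: float

    @property
    def total(self) -> float:
        return (
            self.recruitment
            + self.screening
            + self.training
            + self.delivery
            + self.coordination
        )

    def per_participant(self, participants: int) -> float | None:
        if participants <= 0:
            return None
        return self.total / participants

    def __add__(self, other: "CostBreakdown") -> "CostBreakdown":
        return CostBreakdown(
            self.recruitment + other.recruitment,
            self.screening + other.screening,
            self.training + other.training,
            self.delivery + other.delivery,
            self.coordination + other.coordination,
        )

    def to_dict(self) -> dict[str, float]:
        return {
            "recruitment": self.recruitment,
            "screening": self.screening,
            "training": self.training,
            "delivery": self.delivery,
            "coordination": self.coordination,
            "total": self.total,
        }


def intervention_cost(
    cascade: CascadeResult,
    costs: CostInputs,
    include_fixed: bool = True,
) -> CostBreakdown:
    """Bottom-up intervention cost from unit costs.

    Variable components (recruitment, screening, delivery) scale with the
    cascade; fixed components (per-school training, program coordination)
    are independent of the number of participants and can be excluded so a
    multi-population run counts them once.
    """
    rate = costs.loaded_counselor_rate
    recruitment = (
        (cascade.population / costs.class_size)
        * (costs.recruit_minutes_per_class / 60.0)
        * rate
    )
    screening = (
        cascade.responders * (costs.screening_minutes_per_student / 60.0) * rate
    )
    delivery = (
        cascade.groups
        * (costs.sessions * costs.session_hours + costs.makeup_session_hours)
        * rate
    )
    if include_fixed:
        training = cascade.n_schools * (
            costs.training_online_fee
            + costs.tech_assist_hours * costs.tech_assist_rate
            + costs.counselor_training_hours * rate
        )
        coordination = costs.coordinator_hours_total * costs.loaded_coordinator_rate
    else:
        training = 0.0
        coordination = 0.0
    return CostBreakdown(recruitment, screening, training, delivery, coordination)


#: strict column order for delimited-text treatment-cost tables
TREATMENT_COST_COLUMNS = ("disease", "sex", "age_lo", "age_hi", "annual_cost")


@dataclass(frozen=True)
class TreatmentCosts:
    """Annual management cost per prevalent case by disease, sex and age band."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(TREATMENT_COST_COLUMNS) - set(self.table.columns)
        if missing:
            raise InputValidationError(
                f"treatment-cost table missing columns: {sorted(missing)}"
            )
        if (self.table["annual_cost"] < 0).any():
            raise InputValidationError("treatment costs cannot be negative")

    def annual_cost(self, disease: str, sex: str, age: int) -> float:
        t = self.table
        hit = t[
            (t["disease"] == disease)
            & (t["sex"] == sex)
            & (t["age_lo"] <= age)
            & (t["age_hi"] >= age)
        ]
        if hit.empty:
            raise MissingCostError(
                f"no treatment cost for ({disease}, {sex}, age {age})"
            )
        return float(hit["annual_cost"].iloc[0])

    def scaled(self, factors: dict[str, float] | float) -> "TreatmentCosts":
        t = self.table.copy()
        if isinstance(factors, dict):
            f = t["disease"].map(factors).fillna(1.0)
        else:
            f = factors
        t["annual_cost"] = t["annual_cost"] * f
        return TreatmentCosts(t)


def treatment_cost_offsets(
    delta_prevalent_py: pd.DataFrame,
    treatment_costs: TreatmentCosts,
    discount_rate: float = 0.03,
    sex_cost_factors: dict[str, float] | None = None,
) -> float:
    """Discounted healthcare costs averted by reduced prevalence.

    ``delta_prevalent_py`` holds one row per (disease, sex, age, cycle)
    with column ``delta_py`` = control minus intervention prevalent
    person-years (positive when the intervention reduces prevalence).
    Each averted person-year is valued at the annual treatment cost for
    its (disease, sex, age) cell and discounted back to cycle 0.
    """
    required = {"disease", "sex", "age", "cycle", "delta_py"}
    missing = required - set(delta_prevalent_py.columns)
    if missing:
        raise InputValidationError(f"delta table missing columns: {sorted(missing)}")
    df = delta_prevalent_py

    # expand the band table once into a per-age lookup
    lookup: dict[tuple[str, str, int], float] = {}
    for row in treatment_costs.table.itertuples(index=False):
        for age in range(int(row.age_lo), int(row.age_hi) + 1):
            lookup.setdefault((row.disease, row.sex, age), float(row.annual_cost))

    keys = list(zip(df["disease"], df["sex"], df["age"].astype(int)))
    try:
        cost = np.array([lookup[k] for k in keys])
    except KeyError as exc:
        d, s, a = exc.args[0]
        raise MissingCostError(f"no treatment cost for ({d}, {s}, age {a})") from exc
    if sex_cost_factors:
        cost = cost * df["sex"].map(lambda s: sex_cost_factors.get(s, 1.0)).to_numpy()
    disc = (1.0 + discount_rate) ** (-df["cycle"].to_numpy(dtype=float))
    return float(np.sum(df["delta_py"].to_numpy() * cost * disc))
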