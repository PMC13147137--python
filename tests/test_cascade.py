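"""Participant cascade, bottom-up costing, treatment-cost offsets."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from edprev.cascade import (
    CostInputs,
    MissingCostError,
    TreatmentCosts,
    compute_cascade,
    intervention_cost,
    treatment_cost_offsets,
)
from edprev.epi import InputValidationError


class TestComputeCascade:
    def test_published_base_case(self):
        cas = compute_cascade(569_295, 0.10, 0.689, 0.45)
        assert cas.responders == 56_930
        assert cas.screened_eligible == 39_225
        assert cas.participants == 17_651
        assert cas.participants >= 17_000

    def test_zero_response_rate(self):
        cas = compute_cascade(1_000_000, 0.0, 0.689, 0.45)
        assert cas.responders == cas.screened_eligible == cas.participants == 0
        assert cas.groups == 0

    def test_powers_of_one_half(self):
        cas = compute_cascade(1000, 0.5, 0.5, 0.5)
        assert cas.participants == 125

    def test_zero_population_is_all_zero(self):
        cas = compute_cascade(0, 0.1, 0.689, 0.45)
        assert cas.participants == 0

    def test_even_allocation_group_count(self):
        # 17651 participants over 1416 schools: 12.47/school -> 2 groups of 8
        cas = compute_cascade(569_295, 0.10, 0.689, 0.45, n_schools=1416, group_size=8)
        assert cas.groups == 2 * 1416

    @given(
        pop=st.integers(0, 10**6),
        r1=st.floats(0, 1),
        r2=st.floats(0, 1),
        r3=st.floats(0, 1),
        bump=st.floats(0, 0.2),
    )
    def test_raising_any_rate_never_loses_participants(self, pop, r1, r2, r3, bump):
        base = compute_cascade(pop, r1, r2, r3)
        up = compute_cascade(pop, min(r1 + bump, 1.0), r2, r3)
        assert up.participants >= base.participants


class TestInterventionCost:
    def test_all_unit_costs_zero(self):
        costs = CostInputs(
            counselor_hourly=0, coordinator_hourly=0, training_online_fee=0,
            tech_assist_rate=0,
        )
        cas = compute_cascade(569_295, 0.10, 0.689, 0.45)
        assert intervention_cost(cas, costs).total == 0.0

    def test_recruitment_hand_example(self):
        # one 25-student class, 10 min at the loaded counselor rate $53.17
        cas = compute_cascade(25, 0.10, 0.689, 0.0, n_schools=1)
        bd = intervention_cost(cas, CostInputs(), include_fixed=False)
        assert bd.recruitment == pytest.approx(1 * (10 / 60) * 40.90 * 1.3, abs=1e-9)
        assert bd.recruitment == pytest.approx(8.86, abs=0.01)

    def test_component_breakdown_against_independent_arithmetic(self):
        cas = compute_cascade(569_295, 0.10, 0.689, 0.45)
        c = CostInputs()
        bd = intervention_cost(cas, c)
        loaded = 40.90 * 1.3
        assert bd.recruitment == pytest.approx(569_295 / 25 * 10 / 60 * loaded)
        assert bd.screening == pytest.approx(56_930 * 10 / 60 * loaded)
        assert bd.training == pytest.approx(1416 * (416 + 4 * 125 + 10.25 * loaded))
        assert bd.delivery == pytest.approx(2832 * (4 * 1.0 + 0.2) * loaded)
        assert bd.coordination == pytest.approx(37.5 * 46 * 87.99 * 1.3)
        assert bd.total == pytest.approx(
            bd.recruitment + bd.screening + bd.training + bd.delivery + bd.coordination
        )
        assert bd.per_participant(cas.participants) == pytest.approx(
            bd.total / 17_651
        )

    def test_zero_participants_leaves_per_participant_absent(self):
        cas = compute_cascade(1000, 0.0, 0.5, 0.5)
        bd = intervention_cost(cas, CostInputs())
        assert bd.per_participant(cas.participants) is None

    def test_doubling_unit_costs_doubles_total(self):
        cas = compute_cascade(569_295, 0.10, 0.689, 0.45)
        c1 = CostInputs()
        c2 = CostInputs(
            counselor_hourly=2 * c1.counselor_hourly,
            coordinator_hourly=2 * c1.coordinator_hourly,
            training_online_fee=2 * c1.training_online_fee,
            tech_assist_rate=2 * c1.tech_assist_rate,
        )
        assert intervention_cost(cas, c2).total == pytest.approx(
            2 * intervention_cost(cas, c1).total
        )

    def test_doubling_population_scales_variable_components(self):
        c = CostInputs()
        a = intervention_cost(compute_cascade(2_000_000, 0.1, 0.689, 0.45), c, include_fixed=False)
        b = intervention_cost(compute_cascade(4_000_000, 0.1, 0.689, 0.45), c, include_fixed=False)
        assert b.recruitment == pytest.approx(2 * a.recruitment, rel=1e-6)
        assert b.screening == pytest.approx(2 * a.screening, rel=1e-3)
        # delivery doubles only up to the per-school group ceiling
        assert b.delivery == pytest.approx(2 * a.delivery, rel=0.15)


def cost_table():
    return TreatmentCosts(
        pd.DataFrame(
            {
                "disease": ["AN", "AN"],
                "sex": ["female", "female"],
                "age_lo": [10, 40],
                "age_hi": [39, 100],
                "annual_cost": [1000.0, 500.0],
            }
        )
    )


class TestTreatmentCostOffsets:
    def _delta(self, rows):
        return pd.DataFrame(rows, columns=["disease", "sex", "age", "cycle", "delta_py"])

    def test_identical_traces_zero(self):
        d = self._delta([("AN", "female", 15, 0, 0.0), ("AN", "female", 16, 1, 0.0)])
        assert treatment_cost_offsets(d, cost_table()) == 0.0

    def test_no_discount_at_cycle_zero(self):
        d = self._delta([("AN", "female", 15, 0, 1.0)])
        assert treatment_cost_offsets(d, cost_table(), 0.03) == pytest.approx(1000.0)

    def test_discounting_closed_form(self):
        d = self._delta([("AN", "female", 17, 2, 1.0)])
        got = treatment_cost_offsets(d, cost_table(), 0.03)
        assert got == pytest.approx(1000 / 1.03**2, abs=1e-9)
        assert got == pytest.approx(942.60, abs=0.01)

    def test_age_band_lookup(self):
        d = self._delta([("AN", "female", 45, 0, 1.0)])
        assert treatment_cost_offsets(d, cost_table(), 0.0) == pytest.approx(500.0)

    def test_missing_cost_cell_names_disease_and_age(self):
        d = self._delta([("BN", "female", 15, 0, 1.0)])
        with pytest.raises(MissingCostError, match=r"BN.*age 15"):
            treatment_cost_offsets(d, cost_table())

    def test_sex_cost_factor(self):
        t = TreatmentCosts(
            pd.DataFrame(
                {
                    "disease": ["AN"], "sex": ["male"],
                    "age_lo": [10], "age_hi": [100], "annual_cost": [1000.0],
                }
            )
        )
        d = self._delta([("AN", "male", 15, 0, 1.0)])
        assert treatment_cost_offsets(d, t, 0.0, {"male": 0.5}) == pytest.approx(500.0)


class TestCostInputsValidation:
    def test_negative_unit_cost_rejected(self):
        with pytest.raises(InputValidationError):
            CostInputs(counselor_hourly=-1.0)

    def test_loaded_rates(self):
        c = CostInputs()
        assert c.loaded_counselor_rate == pytest.approx(53.17, abs=1e-9)
        assert c.loaded_coordinator_rate == pytest.approx(87.99 * 1.3, abs=1e-9)
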