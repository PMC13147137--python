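"""Cohort engine: rate embedding, propagation, conservation, aggregation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from edprev.epi import (
    EpiRates,
    InputValidationError,
    aggregate_traces,
    build_generator,
    derive_transition_matrix,
    run_cohort,
    steady_state_prevalence,
)

from conftest import expm_series, microsimulate_cohort


def flat_rates(i=0.0, r=0.0, f=0.0, m=0.0, ages=(0, 100), disease="AN", sex="female"):
    a = np.arange(ages[0], ages[1] + 1)
    return EpiRates(
        disease=disease,
        sex=sex,
        ages=a,
        incidence=np.full(a.size, i),
        remission=np.full(a.size, r),
        case_fatality=np.full(a.size, f),
        all_cause_mortality=np.full(a.size, m),
    )


class TestTransitionMatrix:
    def test_zero_rates_give_identity(self):
        p = derive_transition_matrix({"i": 0, "r": 0, "f": 0, "m": 0})
        assert np.array_equal(p, np.eye(4))

    def test_single_exit_closed_form(self):
        # only incidence flows: P(H->D) = 1 - exp(-i)
        p = derive_transition_matrix({"i": 0.02, "r": 0, "f": 0, "m": 0})
        assert p[0, 1] == pytest.approx(1 - np.exp(-0.02), abs=1e-12)
        assert p[0, 0] == pytest.approx(np.exp(-0.02), abs=1e-12)

    def test_full_matrix_matches_series_oracle(self):
        rates = {"i": 0.01, "r": 0.7, "f": 0.05, "m": 0.001}
        p = derive_transition_matrix(rates)
        oracle = expm_series(build_generator(rates))
        assert np.abs(p - oracle).max() < 1e-10

    def test_rows_stochastic_and_absorbing(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            i, r, f, m = rng.uniform(0, 2, size=4)
            p = derive_transition_matrix({"i": i, "r": r, "f": f, "m": m})
            assert np.allclose(p.sum(axis=1), 1.0, atol=1e-12)
            assert (p >= 0).all() and (p <= 1).all()
            assert p[2, 2] == pytest.approx(1.0) and p[3, 3] == pytest.approx(1.0)

    def test_negative_rate_rejected_with_field_name(self):
        with pytest.raises(InputValidationError, match="'f'"):
            derive_transition_matrix({"i": 0.1, "r": 0.2, "f": -0.05, "m": 0.01})

    def test_net_other_mortality_switch(self):
        # with the flag, diseased background mortality is m - f
        rates = {"i": 0.0, "r": 0.0, "f": 0.03, "m": 0.05}
        p = derive_transition_matrix(rates, net_other_mortality=True)
        total_exit = 1 - np.exp(-(0.03 + 0.02))
        assert p[1, 2] + p[1, 3] == pytest.approx(total_exit, abs=1e-12)
        assert p[1, 2] / p[1, 3] == pytest.approx(0.03 / 0.02, rel=1e-9)


class TestEpiRates:
    def test_noncontiguous_ages_rejected(self):
        with pytest.raises(InputValidationError, match="contiguous"):
            EpiRates(
                "AN", "female",
                np.array([10, 12]),
                np.zeros(2), np.zeros(2), np.zeros(2), np.zeros(2),
            )

    def test_negative_rate_names_age_and_field(self):
        inc = np.zeros(3)
        inc[1] = -0.1
        with pytest.raises(InputValidationError, match="incidence at age 11"):
            EpiRates(
                "AN", "female", np.arange(10, 13),
                inc, np.zeros(3), np.zeros(3), np.zeros(3),
            )

    def test_frame_round_trip(self):
        r = flat_rates(i=0.01, r=0.2, f=0.005, m=0.001, ages=(10, 20))
        r2 = EpiRates.from_frame(r.to_frame())
        assert np.array_equal(r.incidence, r2.incidence)
        assert r2.disease == "AN" and r2.min_age == 10


class TestRunCohort:
    def test_null_multiplier_identical_to_control(self):
        rates = flat_rates(i=0.05, r=0.3, f=0.01, m=0.002)
        a = run_cohort(1000, 15, 0.02, rates, 20)
        b = run_cohort(1000, 15, 0.02, rates, 20, incidence_multiplier=lambda t: 1.0)
        assert np.array_equal(a.occupancy, b.occupancy)

    def test_zero_rates_conserve_everyone_healthy(self):
        rates = flat_rates()
        tr = run_cohort(1000, 15, 0.0, rates, 5)
        assert np.array_equal(tr.occupancy[:, 0], np.full(6, 1000.0))
        assert tr.occupancy[:, 1:].sum() == 0

    def test_horizon_past_defined_rates_rejected(self):
        rates = flat_rates(ages=(10, 30))
        with pytest.raises(InputValidationError, match="stop at 30"):
            run_cohort(10, 15, 0.0, rates, 17)

    def test_matches_microsimulation_oracle(self):
        # 10-person, 3-cycle cohort vs 2e5 replicate stochastic cohorts
        rates = {"i": 0.1, "r": 0.2, "f": 0.05, "m": 0.01}
        er = flat_rates(**rates, ages=(15, 20))
        trace = run_cohort(10, 15, 0.2, er, 3)
        p = derive_transition_matrix(rates)
        occ, se = microsimulate_cohort(
            [p] * 3, n_healthy=8, n_diseased=2,
            reps=200_000, rng=np.random.default_rng(2024),
        )
        assert np.all(np.abs(trace.occupancy - occ) <= 3 * se + 1e-9)

    @given(
        i=st.floats(0, 0.05),
        r=st.floats(0, 0.5),
        f=st.floats(0, 0.02),
        m=st.floats(0, 0.05),
        p0=st.floats(0, 0.2),
    )
    def test_conservation_property(self, i, r, f, m, p0):
        rates = flat_rates(i=i, r=r, f=f, m=m)
        tr = run_cohort(1000, 15, p0, rates, 60)
        assert tr.conservation_error() < 1e-9

    def test_lower_incidence_multiplier_never_raises_prevalence(self):
        # pointwise monotonicity is exact for a non-fatal disease (both
        # arms then share the same survival), provided staying diseased
        # is likelier than becoming diseased — true at realistic rates
        rng = np.random.default_rng(7)
        for _ in range(20):
            rates = flat_rates(
                i=rng.uniform(0, 0.05),
                r=rng.uniform(0, 0.4),
                f=0.0,
                m=rng.uniform(0, 0.03),
            )
            cut = rng.integers(0, 10)
            lo = run_cohort(
                1000, 15, 0.05, rates, 40,
                incidence_multiplier=lambda t, c=cut: 0.5 if t == c else 1.0,
            )
            hi = run_cohort(1000, 15, 0.05, rates, 40)
            assert np.all(lo.occupancy[:, 1] <= hi.occupancy[:, 1] + 1e-9)

    def test_lower_incidence_reduces_cumulative_burden_with_fatality(self):
        # with case fatality, prevented cases survive and re-enter the
        # risk pool, so only the cumulative burden is guaranteed to drop
        rng = np.random.default_rng(8)
        for _ in range(20):
            rates = flat_rates(
                i=rng.uniform(0, 0.05),
                r=rng.uniform(0, 0.4),
                f=rng.uniform(0, 0.02),
                m=rng.uniform(0, 0.03),
            )
            lo = run_cohort(
                1000, 15, 0.05, rates, 40,
                incidence_multiplier=lambda t: 0.5 if t < 10 else 1.0,
            )
            hi = run_cohort(1000, 15, 0.05, rates, 40)
            assert lo.occupancy[:, 1].sum() < hi.occupancy[:, 1].sum()
            # and the intervention arm keeps more people alive
            assert lo.occupancy[-1, :2].sum() >= hi.occupancy[-1, :2].sum()


class TestSteadyStatePrevalence:
    def test_zero_incidence_zero_prevalence(self):
        rates = flat_rates(r=0.2, f=0.01, m=0.005)
        assert steady_state_prevalence(rates, 18) == 0.0

    def test_prevalence_accumulates_with_incidence(self):
        rates = flat_rates(i=0.01, r=0.2, f=0.005, m=0.002, ages=(10, 30))
        p15 = steady_state_prevalence(rates, 15)
        p25 = steady_state_prevalence(rates, 25)
        assert 0 < p15 < p25 < 0.05  # approaches i/(i+r) ~ 0.048 from below


class TestAggregateTraces:
    def _trace(self, n=100.0, horizon=4):
        rates = flat_rates(i=0.1, r=0.2, f=0.05, m=0.01)
        return run_cohort(n, 15, 0.1, rates, horizon)

    def test_single_trace_is_identity(self):
        tr = self._trace()
        agg = aggregate_traces([tr])
        assert np.allclose(agg["prevalent_py"], tr.occupancy[:, 1])
        assert np.allclose(agg["alive_py"], tr.occupancy[:, :2].sum(axis=1))

    def test_two_identical_traces_double(self):
        tr = self._trace()
        one = aggregate_traces([tr])
        two = aggregate_traces([tr, tr])
        assert np.allclose(two["alive_py"], 2 * one["alive_py"])
        assert np.allclose(two["incident_cases"], 2 * one["incident_cases"])

    def test_multi_cohort_totals_match_independent_summation(self):
        rates = flat_rates(i=0.02, r=0.2, f=0.01, m=0.003)
        traces = [run_cohort(100 + 10 * k, 15 + k, 0.02, rates, 10) for k in range(4)]
        agg = aggregate_traces(traces).set_index("cycle")
        # independent summation straight off the occupancy arrays
        for cycle in range(11):
            expected = sum(t.occupancy[cycle, 1] for t in traces)
            assert agg.loc[cycle, "prevalent_py"] == pytest.approx(expected, rel=1e-12)

    def test_half_cycle_correction_averages_adjacent(self):
        tr = self._trace()
        agg = aggregate_traces([tr], half_cycle_correction=True)
        expected = 0.5 * (tr.occupancy[:-1, 1] + tr.occupancy[1:, 1])
        assert np.allclose(agg["prevalent_py"], expected)

    def test_mixed_cycle_lengths_rejected(self):
        a = self._trace()
        b = self._trace()
        b.cycle_length = 0.5
        with pytest.raises(InputValidationError, match="mixed cycle lengths"):
            aggregate_traces([a, b])
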