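"""End-to-end deterministic evaluation of the prevention program.

One call to :func:`run_model` performs the whole comparison: the
participant cascade, bottom-up intervention costing, parallel four-state
cohort runs for each disease / sex / starting age under the control and
intervention incidence multipliers, incremental HALYs, discounted
treatment-cost offsets, and ICERs against the willingness-to-pay
thresholds.

Cohort structure: each single year of age in the target range is a
separate closed cohort followed to the model's end age (or a capped
follow-up). All cohorts share calendar cycle t = 0, the intervention
year, from which costs and benefits are discounted. The modelled
population is the screened high-body-dissatisfaction subgroup, so both
arms carry the body-dissatisfaction incidence adjustment; the arms differ
only by the time-varying intervention relative risk applied to incidence
over the first ``truncation_year`` cycles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cascade import (
    CascadeResult,
    CostBreakdown,
    compute_cascade,
    intervention_cost,
    treatment_cost_offsets,
)
from .config import ModelConfig
from .economics import (
    CEResult,
    classify_threshold,
    compute_halys,
    compute_icer,
    plane_quadrant,
)
from .epi import CohortTrace, InputValidationError, aggregate_traces, run_cohort, steady_state_prevalence
from .inputs import Inputs


@dataclass
class ArmTraces:
    """All cohort traces of one run, by arm, with their aggregates."""

    traces: dict[str, list[CohortTrace]]
    aggregates: dict[str, pd.DataFrame]


def _cohort_sizes(pop_counts: pd.Series, participants: int) -> pd.Series:
    """Allocate participants across starting ages in proportion to the
    population, keeping fractional sizes (cohort model, not individuals)."""
    total = float(pop_counts.sum())
    if total == 0 or participants == 0:
        return pop_counts * 0.0
    return pop_counts / total * participants


def run_model(config: ModelConfig, inputs: Inputs, keep_traces: bool = False):
    """Evaluate the program against no intervention.

    Returns a :class:`~edprev.economics.CEResult`; with ``keep_traces``
    the per-cohort traces and aggregates are attached as ``result.traces``.
    """
    bd = config.bd.adjustment()
    profiles = {d: config.effects.profile_for(d) for d in config.diseases}

    cascades: dict[str, CascadeResult] = {}
    cost_var = None
    all_traces: dict[str, list[CohortTrace]] = {"control": [], "intervention": []}
    delta_rows: list[pd.DataFrame] = []
    delta_halys_by_sex: dict[str, float] = {}
    offsets_by_sex: dict[str, float] = {}
    averted: dict[str, float] = {d: 0.0 for d in config.diseases}

    for sex in config.sexes:
        pop = inputs.population_counts(sex, config.target_ages)
        cas = compute_cascade(
            int(pop.sum()),
            response_rate=config.cascade.response_rate,
            high_bd_rate=config.cascade.high_bd_rate,
            acceptance_rate=config.cascade.acceptance_rate,
            n_schools=config.cascade.n_schools,
            group_size=config.costs.group_size,
        )
        cascades[sex] = cas
        part = intervention_cost(cas, config.costs, include_fixed=False)
        cost_var = part if cost_var is None else cost_var + part

        sizes = _cohort_sizes(pop, cas.participants)
        sex_traces: dict[str, list[CohortTrace]] = {"control": [], "intervention": []}
        for disease in config.diseases:
            rates = inputs.rates(disease, sex)
            profile = profiles[disease]
            cache: dict = {}
            prev_cache: dict[int, float] = {}
            for age in config.target_ages:
                horizon = config.horizon_for(age)
                if age not in prev_cache:
                    prev_cache[age] = steady_state_prevalence(
                        rates,
                        target_age=age,
                        incidence_multiplier_by_age=bd.incidence_factor,
                        net_other_mortality=config.net_other_mortality,
                        matrix_cache=cache,
                    )
                p0 = prev_cache[age]
                n = float(sizes.loc[age])

                def mult_ctrl(t, _age=age):
                    return bd.incidence_factor(_age + t)

                def mult_int(t, _age=age, _p=profile):
                    return bd.incidence_factor(_age + t) * _p.rr_at(t)

                common = dict(
                    cohort_size=n,
                    start_age=age,
                    initial_diseased_fraction=p0,
                    rates=rates,
                    horizon=horizon,
                    net_other_mortality=config.net_other_mortality,
                    matrix_cache=cache,
                )
                tr_c = run_cohort(arm="control", incidence_multiplier=mult_ctrl, **common)
                tr_i = run_cohort(
                    arm="intervention", incidence_multiplier=mult_int, **common
                )
                sex_traces["control"].append(tr_c)
                sex_traces["intervention"].append(tr_i)
                averted[disease] += float(
                    tr_c.incident_cases.sum() - tr_i.incident_cases.sum()
                )
                delta_rows.append(_delta_frame(tr_c, tr_i, config))

        agg_c = aggregate_traces(
            sex_traces["control"], half_cycle_correction=config.half_cycle_correction
        )
        agg_i = aggregate_traces(
            sex_traces["intervention"],
            half_cycle_correction=config.half_cycle_correction,
        )
        delta_halys_by_sex[sex] = compute_halys(
            agg_i, agg_c, config.disability_weights, config.discount_rate
        )
        all_traces["control"].extend(sex_traces["control"])
        all_traces["intervention"].extend(sex_traces["intervention"])

    # fixed (per-school / per-program) cost components counted once
    any_cascade = next(iter(cascades.values()))
    fixed = intervention_cost(any_cascade, config.costs, include_fixed=True)
    breakdown = CostBreakdown(
        recruitment=cost_var.recruitment,
        screening=cost_var.screening,
        training=fixed.training,
        delivery=cost_var.delivery,
        coordination=fixed.coordination,
    )

    delta_table = (
        pd.concat(delta_rows, ignore_index=True)
        if delta_rows
        else pd.DataFrame(columns=["disease", "sex", "age", "cycle", "delta_py"])
    )
    sex_factors = {"male": config.male_cost_factor} if "male" in config.sexes else None
    for sex in config.sexes:
        sub = delta_table[delta_table["sex"] == sex]
        offsets_by_sex[sex] = (
            treatment_cost_offsets(
                sub, inputs.treatment_costs, config.discount_rate, sex_factors
            )
            if len(sub)
            else 0.0
        )
    offsets = float(sum(offsets_by_sex.values()))
    delta_halys = float(sum(delta_halys_by_sex.values()))

    cost_excl = breakdown.total
    cost_incl = cost_excl - offsets
    icer_excl = compute_icer(cost_excl, delta_halys)
    icer_incl = compute_icer(cost_incl, delta_halys)

    result = CEResult(
        delta_halys=delta_halys,
        cost_breakdown=breakdown,
        offsets=offsets,
        icer_excl_offsets=icer_excl,
        icer_incl_offsets=icer_incl,
        plane_quadrant=plane_quadrant(delta_halys, cost_incl),
        cost_effective_excl=classify_threshold(icer_excl, config.wtp_thresholds),
        cost_effective_incl=classify_threshold(icer_incl, config.wtp_thresholds),
        cascade=cascades,
        averted_incidence=averted,
        delta_halys_by_sex=delta_halys_by_sex,
        offsets_by_sex=offsets_by_sex,
        participants=sum(c.participants for c in cascades.values()),
    )
    if keep_traces:
        result.traces = ArmTraces(
            traces=all_traces,
            aggregates={
                arm: aggregate_traces(
                    trs, half_cycle_correction=config.half_cycle_correction
                )
                for arm, trs in all_traces.items()
                if trs
            },
        )
    return result


def _delta_frame(
    tr_c: CohortTrace, tr_i: CohortTrace, config: ModelConfig
) -> pd.DataFrame:
    """Control-minus-intervention person-year (or incident-case) deltas
    by attained age and cycle, for the treatment-cost offsets."""
    if config.treatment_cost_basis == "prevalent":
        cycles = np.arange(tr_c.horizon + 1)
        delta = tr_c.occupancy[:, 1] - tr_i.occupancy[:, 1]
    else:  # incident basis: one-off cost at the onset cycle
        cycles = np.arange(tr_c.horizon)
        delta = tr_c.incident_cases - tr_i.incident_cases
    return pd.DataFrame(
        {
            "disease": tr_c.disease,
            "sex": tr_c.sex,
            "age": tr_c.start_age + cycles,
            "cycle": cycles,
            "delta_py": delta,
        }
    )
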