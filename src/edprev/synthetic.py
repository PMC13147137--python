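"""Synthetic epidemiological, demographic and cost inputs.

Real evaluations of this kind consume age-specific incidence, remission,
case-fatality and mortality schedules from burden-of-disease studies and
national treatment-cost surveys. Those inputs are not redistributable, so
this module fabricates stylised stand-ins with the structural features
the model relies on: unimodal incidence curves peaking in adolescence /
young adulthood, age-constant remission set by mean illness duration,
anorexia nervosa carrying the highest case fatality, Gompertz background
mortality, and treatment costs ordered AN >= BN >= BED. Everything is
deterministic given the seed.

The synthetic curves are deliberately parametric and smooth — they are
not a calibration to any published burden-of-disease estimates, and model
results on them are property-level, not headline-number, reproductions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cascade import CostInputs, TreatmentCosts
from .epi import DISEASES, SEXES, EpiRates, InputValidationError
from .inputs import Inputs

#: printed 2019 female population counts for the base-case target ages
FIXED_FEMALE_POPULATION = {15: 140_400, 16: 140_297, 17: 140_910, 18: 147_688}


@dataclass(frozen=True)
class SyntheticSpec:
    """Knobs of the synthetic world.

    Incidence follows a log-normal-shaped bell over age,
    i(a) = peak * exp(-(ln(a/peak_age))^2 / (2 w^2)), with per-disease
    peak ages and magnitudes (per person-year, order 1e-4..1e-3).
    Remission is 1/mean duration; case fatality is age-constant with
    AN > BN >= BED; background mortality is Gompertz m0*exp(b*age). Male
    incidence is scaled down by ``male_incidence_factor``.
    """

    seed: int = 0
    diseases: tuple[str, ...] = DISEASES
    sexes: tuple[str, ...] = SEXES
    age_lo: int = 10
    age_hi: int = 100
    incidence_peak_age: dict[str, float] = field(
        default_factory=lambda: {"AN": 16.0, "BN": 18.0, "BED": 20.0}
    )
    incidence_peak: dict[str, float] = field(
        default_factory=lambda: {"AN": 3e-4, "BN": 6e-4, "BED": 1e-3}
    )
    incidence_log_width: dict[str, float] = field(
        default_factory=lambda: {"AN": 0.20, "BN": 0.25, "BED": 0.30}
    )
    remission_mean_duration: dict[str, float] = field(
        default_factory=lambda: {"AN": 6.0, "BN": 5.0, "BED": 4.0}
    )
    case_fatality: dict[str, float] = field(
        default_factory=lambda: {"AN": 6e-3, "BN": 2e-3, "BED": 1e-3}
    )
    mortality_m0: float = 1.5e-5
    mortality_slope: float = 0.085
    male_incidence_factor: float = 0.25
    #: lognormal jitter (sd on log scale) applied age-wise to incidence
    incidence_jitter_sd: float = 0.02
    treatment_cost_level: dict[str, float] = field(
        default_factory=lambda: {"AN": 11_000.0, "BN": 8_000.0, "BED": 5_000.0}
    )
    treatment_cost_scale: float = 1.0
    population_per_age: float = 140_000.0
    population_noise_sd: float = 3_000.0
    fixed_population: bool = True

    def __post_init__(self) -> None:
        if not self.diseases:
            raise InputValidationError("at least one disease is required")
        for d in self.diseases:
            if not self.age_lo <= self.incidence_peak_age[d] <= self.age_hi:
                raise InputValidationError(f"incidence peak age for {d} out of range")
            if self.incidence_peak[d] <= 0:
                raise InputValidationError(f"incidence peak for {d} must be positive")
        if self.case_fatality["AN"] < max(
            self.case_fatality.get("BN", 0.0), self.case_fatality.get("BED", 0.0)
        ):
            raise InputValidationError(
                "AN case fatality must be the highest of the three disorders"
            )


def _rng(spec: SyntheticSpec, *stream: int) -> np.random.Generator:
    return np.random.default_rng([spec.seed, *stream])


def generate_epi_inputs(spec: SyntheticSpec) -> dict[tuple[str, str], EpiRates]:
    """Rate tables per (disease, sex) in the engine's input format."""
    ages = np.arange(spec.age_lo, spec.age_hi + 1)
    mortality = spec.mortality_m0 * np.exp(spec.mortality_slope * ages)
    out: dict[tuple[str, str], EpiRates] = {}
    for di, disease in enumerate(spec.diseases):
        log_dev = np.log(ages / spec.incidence_peak_age[disease])
        base = spec.incidence_peak[disease] * np.exp(
            -(log_dev**2) / (2.0 * spec.incidence_log_width[disease] ** 2)
        )
        for si, sex in enumerate(spec.sexes):
            rng = _rng(spec, 1, di, si)
            jitter = np.exp(
                rng.normal(0.0, spec.incidence_jitter_sd, size=ages.size)
            )
            inc = base * jitter
            if sex == "male":
                inc = inc * spec.male_incidence_factor
            out[(disease, sex)] = EpiRates(
                disease=disease,
                sex=sex,
                ages=ages,
                incidence=inc,
                remission=np.full(
                    ages.size, 1.0 / spec.remission_mean_duration[disease]
                ),
                case_fatality=np.full(ages.size, spec.case_fatality[disease]),
                all_cause_mortality=mortality,
            )
    return out


def generate_population(spec: SyntheticSpec) -> pd.DataFrame:
    """Population counts by sex and single year of age.

    In fixed-population mode the printed 2019 female counts for ages
    15-18 are used verbatim (other ages stay synthetic), so that the
    eligible-population total of 569,295 is reproduced exactly.
    """
    ages = np.arange(spec.age_lo, spec.age_hi + 1)
    rows = []
    for si, sex in enumerate(spec.sexes):
        rng = _rng(spec, 2, si)
        # only target-age counts feed the model (via the cascade), so a
        # flat age profile with seeded noise is sufficient structure
        counts = np.maximum(
            rng.normal(spec.population_per_age, spec.population_noise_sd, ages.size),
            1.0,
        ).round()
        if spec.fixed_population and sex == "female":
            for age, n in FIXED_FEMALE_POPULATION.items():
                counts[ages == age] = n
        rows.append(pd.DataFrame({"sex": sex, "age": ages, "count": counts.astype(int)}))
    return pd.concat(rows, ignore_index=True)


def generate_cost_inputs(spec: SyntheticSpec) -> tuple[TreatmentCosts, CostInputs]:
    """Treatment-cost schedule (synthetic) and unit costs (fixed defaults).

    Annual per-prevalent-case costs take the disease-specific level with
    mild seeded variation across three broad age bands; delivery unit
    costs are the published costing assumptions and do not vary with the
    seed.
    """
    bands = [(spec.age_lo, 24), (25, 49), (50, spec.age_hi)]
    rows = []
    for si, sex in enumerate(spec.sexes):
        rng = _rng(spec, 3, si)
        # one factor per age band, shared across diseases, so the
        # AN >= BN >= BED cost ordering survives the seeded variation
        factors = np.exp(rng.normal(0.0, 0.1, size=len(bands)))
        for disease in spec.diseases:
            level = spec.treatment_cost_level[disease] * spec.treatment_cost_scale
            for (lo, hi), factor in zip(bands, factors):
                rows.append(
                    {
                        "disease": disease,
                        "sex": sex,
                        "age_lo": lo,
                        "age_hi": hi,
                        "annual_cost": round(level * float(factor), 2),
                    }
                )
    return TreatmentCosts(pd.DataFrame(rows)), CostInputs()


def generate_world(seed: int = 0, **overrides) -> Inputs:
    """One-call synthetic input bundle for the pipeline."""
    spec = SyntheticSpec(seed=seed, **overrides)
    treatment_costs, _ = generate_cost_inputs(spec)
    return Inputs(
        population=generate_population(spec),
        epi=generate_epi_inputs(spec),
        treatment_costs=treatment_costs,
    )
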