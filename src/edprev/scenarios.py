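"""One-way sensitivity scenarios as declarative overrides of a base config.

The four scenarios mirror the published sensitivity analyses:

* ``s1_decay50`` — intervention effect decays by 50% per annum (instead of
  the fitted asymptotic curve), still truncated at 10 years;
* ``s2_no_an`` — the intervention does not prevent anorexia nervosa
  (its incidence RR forced to 1; BN and BED unchanged);
* ``s3_males`` — males aged 15-18 join the target population with the
  same effect profile and their own epidemiological inputs;
* ``s4_expanded_ages`` — the female target population expands to ages
  12-25 (screening staffed by the same counselor cost class).
"""

from __future__ import annotations

from dataclasses import replace

from .config import ModelConfig
from .effects import FIXED
from .epi import InputValidationError
from .inputs import Inputs

SCENARIO_IDS = ("base", "s1_decay50", "s2_no_an", "s3_males", "s4_expanded_ages")

SCENARIO_LABELS = {
    "base": "Base case",
    "s1_decay50": "50% annual effect decay",
    "s2_no_an": "AN not prevented",
    "s3_males": "Males 15-18 included",
    "s4_expanded_ages": "Females 12-25",
}


def apply_scenario(config: ModelConfig, scenario_id: str) -> ModelConfig:
    """Resolve a scenario into a full configuration.

    Only the documented overrides differ from the base configuration;
    everything else is untouched.
    """
    if scenario_id not in SCENARIO_IDS:
        raise InputValidationError(
            f"unknown scenario {scenario_id!r}; expected one of {SCENARIO_IDS}"
        )
    if scenario_id == "base":
        return config
    if scenario_id == "s1_decay50":
        return config.replace(
            effects=replace(
                config.effects,
                decay_law=FIXED,
                annual_decay_fraction=0.5,
                truncation_year=10,
            )
        )
    if scenario_id == "s2_no_an":
        overrides = dict(config.effects.rr_override)
        overrides["AN"] = 1.0
        return config.replace(effects=replace(config.effects, rr_override=overrides))
    if scenario_id == "s3_males":
        return config.replace(sexes=("female", "male"))
    # s4_expanded_ages
    return config.replace(target_ages=tuple(range(12, 26)))


def check_scenario_inputs(config: ModelConfig, inputs: Inputs) -> None:
    """Fail early when a scenario needs inputs the bundle lacks."""
    for sex in config.sexes:
        for disease in config.diseases:
            if (disease, sex) not in inputs.epi:
                raise InputValidationError(
                    f"scenario requires epidemiological inputs for "
                    f"({disease}, {sex}) which are not supplied"
                )
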