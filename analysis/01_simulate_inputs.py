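#!/usr/bin/env python
"""Generate the synthetic input bundle the downstream analyses consume.

Writes population counts (with the printed 2019 female counts pinned for
ages 15-18), stylised age-specific epidemiological rate tables for AN, BN
and BED, a treatment-cost schedule, and a ready-to-run configuration to
``results/inputs/``.
"""

from pathlib import Path

from edprev.config import ModelConfig
from edprev.inputs import save_inputs
from edprev.synthetic import generate_world

OUT = Path(__file__).resolve().parent.parent / "results" / "inputs"
SEED = 0


def main() -> None:
    inputs = generate_world(SEED)
    save_inputs(inputs, OUT)
    ModelConfig().to_yaml(OUT / "config.yaml")

    pop1518 = inputs.population.query("sex == 'female' and 15 <= age <= 18")
    print(f"inputs written to {OUT}")
    print(f"eligible female population 15-18: {int(pop1518['count'].sum()):,}")
    for (d, s), r in sorted(inputs.epi.items()):
        peak_age = int(r.ages[r.incidence.argmax()])
        print(
            f"  {d}/{s}: incidence peaks at age {peak_age} "
            f"({r.incidence.max():.2e}/py), case fatality {r.case_fatality[0]:.1e}/py"
        )


if __name__ == "__main__":
    main()
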