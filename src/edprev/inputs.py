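"""Model input bundle and delimited-text readers/writers.

Every input the pipeline needs — population counts, epidemiological rate
tables and treatment-cost schedules — travels as plain tab-separated text
with strict headers, so a run is fully reproducible from a directory of
three files plus a YAML configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import pandas as pd

from .cascade import TREATMENT_COST_COLUMNS, TreatmentCosts
from .epi import RATE_COLUMNS, EpiRates, InputValidationError

POPULATION_COLUMNS = ("sex", "age", "count")

RATES_FILE = "epi_rates.tsv"
POPULATION_FILE = "population.tsv"
TREATMENT_COSTS_FILE = "treatment_costs.tsv"


@dataclass(frozen=True)
class Inputs:
    """Everything the deterministic model consumes besides the config."""

    population: pd.DataFrame  # sex, age, count
    epi: dict[tuple[str, str], EpiRates]  # keyed by (disease, sex)
    treatment_costs: TreatmentCosts

    def __post_init__(self) -> None:
        missing = set(POPULATION_COLUMNS) - set(self.population.columns)
        if missing:
            raise InputValidationError(
                f"population table missing columns: {sorted(missing)}"
            )
        if (self.population["count"] < 0).any():
            raise InputValidationError("population counts cannot be negative")

    def population_counts(self, sex: str, ages) -> pd.Series:
        """Counts indexed by age for one sex, restricted to ``ages``."""
        p = self.population
        sub = p[(p["sex"] == sex) & (p["age"].isin(list(ages)))]
        out = sub.set_index("age")["count"].reindex(list(ages))
        if out.isna().any():
            missing = [int(a) for a in out[out.isna()].index]
            raise InputValidationError(
                f"population counts missing for {sex} ages {missing}"
            )
        return out

    def rates(self, disease: str, sex: str) -> EpiRates:
        try:
            return self.epi[(disease, sex)]
        except KeyError:
            raise InputValidationError(
                f"no epidemiological rates supplied for ({disease}, {sex})"
            )


def _check_columns(df: pd.DataFrame, expected, what: str) -> None:
    if list(df.columns) != list(expected):
        raise InputValidationError(
            f"{what} must have exactly the columns {list(expected)}, "
            f"got {list(df.columns)}"
        )


def read_rates(path: str | Path) -> dict[tuple[str, str], EpiRates]:
    df = pd.read_csv(path, sep="\t")
    _check_columns(df, RATE_COLUMNS, "rate table")
    return {
        (d, s): EpiRates.from_frame(g)
        for (d, s), g in df.groupby(["disease", "sex"])
    }


def write_rates(epi: dict[tuple[str, str], EpiRates], path: str | Path) -> None:
    frames = [r.to_frame() for r in epi.values()]
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_population(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _check_columns(df, POPULATION_COLUMNS, "population table")
    return df


def read_treatment_costs(path: str | Path) -> TreatmentCosts:
    df = pd.read_csv(path, sep="\t")
    _check_columns(df, TREATMENT_COST_COLUMNS, "treatment-cost table")
    return TreatmentCosts(df)


def load_inputs(directory: str | Path) -> Inputs:
    d = Path(directory)
    return Inputs(
        population=read_population(d / POPULATION_FILE),
        epi=read_rates(d / RATES_FILE),
        treatment_costs=read_treatment_costs(d / TREATMENT_COSTS_FILE),
    )


def save_inputs(inputs: Inputs, directory: str | Path) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    inputs.population.to_csv(d / POPULATION_FILE, sep="\t", index=False)
    write_rates(inputs.epi, d / RATES_FILE)
    inputs.treatment_costs.table.to_csv(d / TREATMENT_COSTS_FILE, sep="\t", index=False)
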