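"""Run configuration: nested dataclasses with YAML round-tripping.

The configuration captures every tunable of the evaluation — target
population, cascade proportions, unit costs, effect sizes and decay law,
body-dissatisfaction adjustment, economics, and PSA settings — so that a
scenario is nothing but a set of declarative overrides on a base config.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .cascade import CostInputs
from .economics import DEFAULT_WTP_THRESHOLDS, DisabilityWeights
from .effects import (
    ASYMPTOTIC,
    BodyDissatAdjustment,
    EffectProfile,
    fit_asymptotic_decay,
    fixed_decay_profile,
    null_profile,
)
from .epi import InputValidationError


@dataclass(frozen=True)
class CascadeConfig:
    response_rate: float = 0.10
    high_bd_rate: float = 0.689
    acceptance_rate: float = 0.45
    n_schools: int = 1416


@dataclass(frozen=True)
class EffectConfig:
    rr_post: float = 0.85
    rr_post_ci: tuple[float, float] = (0.79, 0.92)
    rr_1yr: float = 0.94
    rr_1yr_ci: tuple[float, float] = (0.86, 1.03)
    decay_law: str = ASYMPTOTIC
    annual_decay_fraction: float | None = None
    truncation_year: int = 10
    #: per-disease RR overrides; value 1.0 switches a disease's effect off
    rr_override: dict[str, float] = field(default_factory=dict)

    def profile_for(self, disease: str) -> EffectProfile:
        rr_post = self.rr_override.get(disease, self.rr_post)
        if rr_post >= 1.0:
            return null_profile(self.truncation_year)
        if self.decay_law == ASYMPTOTIC:
            rr_1yr = max(self.rr_1yr, rr_post)
            if rr_1yr > 1.0:
                rr_1yr = 1.0
            return fit_asymptotic_decay(rr_post, rr_1yr, self.truncation_year)
        if self.annual_decay_fraction is None:
            raise InputValidationError(
                "fixed_annual_decay requires annual_decay_fraction"
            )
        return fixed_decay_profile(
            rr_post, self.annual_decay_fraction, self.truncation_year
        )


@dataclass(frozen=True)
class BDConfig:
    rr_age15: float = 1.44
    rr_age16plus: float = 1.57
    prevalence_high_bd: float = 0.689
    or_age15: float = 1.51
    or_age16: float = 1.67
    # PSA lognormal CIs for the two relative risks
    rr_age15_ci: tuple[float, float] = (1.00, 2.05)
    rr_age16plus_ci: tuple[float, float] = (1.17, 2.13)
    rr_age16plus_psa_point: float = 1.58

    def adjustment(self) -> BodyDissatAdjustment:
        return BodyDissatAdjustment(
            rr_age15=self.rr_age15,
            rr_age16plus=self.rr_age16plus,
            prevalence_high_bd=self.prevalence_high_bd,
            or_age15=self.or_age15,
            or_age16=self.or_age16,
        )


@dataclass(frozen=True)
class PSAConfig:
    n_draws: int = 5000
    seed: int = 1
    #: symmetric lognormal half-width (ratio) for synthetic epi rates
    epi_rate_ci_ratio: float = 1.2
    treatment_cost_ci_ratio: float = 1.2


@dataclass(frozen=True)
class ModelConfig:
    target_ages: tuple[int, ...] = (15, 16, 17, 18)
    sexes: tuple[str, ...] = ("female",)
    diseases: tuple[str, ...] = ("AN", "BN", "BED")
    end_age: int = 100
    #: None = lifetime follow-up to end_age; an integer caps the horizon
    follow_up_years: int | None = None
    discount_rate: float = 0.03
    wtp_thresholds: tuple[float, ...] = DEFAULT_WTP_THRESHOLDS
    half_cycle_correction: bool = False
    net_other_mortality: bool = False
    treatment_cost_basis: str = "prevalent"  # or "incident"
    male_cost_factor: float = 1.0
    cascade: CascadeConfig = field(default_factory=CascadeConfig)
    costs: CostInputs = field(default_factory=CostInputs)
    effects: EffectConfig = field(default_factory=EffectConfig)
    bd: BDConfig = field(default_factory=BDConfig)
    disability_weights: DisabilityWeights = field(default_factory=DisabilityWeights)
    psa: PSAConfig = field(default_factory=PSAConfig)

    def __post_init__(self) -> None:
        if self.discount_rate < 0:
            raise InputValidationError("discount rate cannot be negative")
        if self.treatment_cost_basis not in ("prevalent", "incident"):
            raise InputValidationError(
                "treatment_cost_basis must be 'prevalent' or 'incident'"
            )
        if self.follow_up_years is not None and self.follow_up_years < 1:
            raise InputValidationError("follow_up_years must be at least 1")
        if any(a < 0 or a >= self.end_age for a in self.target_ages):
            raise InputValidationError("target ages must lie below end_age")

    def horizon_for(self, start_age: int) -> int:
        h = self.end_age - start_age
        if self.follow_up_years is not None:
            h = min(h, self.follow_up_years)
        return h

    # -- serialisation -----------------------------------------------------

    def to_dict(self) -> dict:
        return _asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return _from_dict(cls, d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ModelConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def replace(self, **kwargs) -> "ModelConfig":
        return dataclasses.replace(self, **kwargs)


def _asdict(obj):
    if dataclasses.is_dataclass(obj):
        return {
            f.name: _asdict(getattr(obj, f.name)) for f in dataclasses.fields(obj)
        }
    if isinstance(obj, (list, tuple)):
        return [_asdict(x) for x in obj]
    if isinstance(obj, dict):
        return {k: _asdict(v) for k, v in obj.items()}
    return obj


def _from_dict(cls, d: dict):
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name not in d:
            continue
        v = d[f.name]
        ftype = f.type if isinstance(f.type, type) else None
        target = {
            "cascade": CascadeConfig,
            "costs": CostInputs,
            "effects": EffectConfig,
            "bd": BDConfig,
            "disability_weights": DisabilityWeights,
            "psa": PSAConfig,
        }.get(f.name, ftype)
        if dataclasses.is_dataclass(target) and isinstance(v, dict):
            kwargs[f.name] = _from_dict(target, v)
        elif isinstance(v, list):
            kwargs[f.name] = tuple(tuple(x) if isinstance(x, list) else x for x in v)
        else:
            kwargs[f.name] = v
    return cls(**kwargs)
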