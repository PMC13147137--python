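"""Intervention effect profiles and body-dissatisfaction risk adjustment.

The preventive effect enters the cohort model as a time-varying relative
risk (RR) on disease incidence. Trial evidence pins the RR at post-test
and one-year follow-up; between year one and a truncation horizon the
effect wanes either along an asymptotic-exponential approach to the null
(base case) or by a fixed annual fraction (scenario analysis). Beyond the
truncation year the effect is exactly null.

Because the program is offered only to adolescents screening positive for
high body dissatisfaction, population incidence rates must be re-scaled to
that higher-risk subgroup; the odds ratios reported for body
dissatisfaction are first converted to relative risks with the standard
baseline-risk formula RR = OR / (1 - p0 + p0*OR).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .epi import InputValidationError

ASYMPTOTIC = "asymptotic_exponential"
FIXED = "fixed_annual_decay"


def or_to_rr(odds_ratio: float, baseline_risk: float) -> float:
    """Convert an odds ratio to a relative risk at baseline risk ``p0``.

    RR = OR / (1 - p0 + p0*OR). As p0 -> 0 the RR approaches the OR; for
    OR > 1 the RR always lies between 1 and the OR.
    """
    if odds_ratio <= 0:
        raise InputValidationError("odds ratio must be positive")
    if not 0.0 < baseline_risk < 1.0:
        raise InputValidationError("baseline risk must lie strictly in (0, 1)")
    return odds_ratio / (1.0 - baseline_risk + baseline_risk * odds_ratio)


def calibrate_baseline_risk(odds_ratio: float, relative_risk: float) -> float:
    """Baseline risk p0 at which ``odds_ratio`` maps onto ``relative_risk``.

    Closed-form inversion of :func:`or_to_rr`:
    p0 = (OR/RR - 1) / (OR - 1). Feasible only when RR lies strictly
    between 1 and OR (same side of the null).
    """
    if odds_ratio <= 0 or relative_risk <= 0:
        raise InputValidationError("odds ratio and relative risk must be positive")
    if odds_ratio == 1.0:
        raise InputValidationError("odds ratio 1 carries no information about p0")
    feasible = (
        (odds_ratio > 1.0 and 1.0 < relative_risk < odds_ratio)
        or (odds_ratio < 1.0 and odds_ratio < relative_risk < 1.0)
    )
    if not feasible:
        raise InputValidationError(
            f"no baseline risk maps OR={odds_ratio} onto RR={relative_risk}: "
            "RR must lie strictly between 1 and the OR"
        )
    p0 = (odds_ratio / relative_risk - 1.0) / (odds_ratio - 1.0)
    return p0


@dataclass(frozen=True)
class EffectProfile:
    """Relative risk on incidence as a function of whole years post-program.

    ``rr_at(t)`` is the RR applied during cycle t of the cohort run: the
    post-test effect governs the first year (t = 0) and the profile
    approaches the null monotonically, reaching exactly 1 at
    ``truncation_year`` and beyond.
    """

    rr_post: float
    decay_law: str
    decay_rate: float  # lambda (asymptotic) or annual fraction (fixed)
    truncation_year: int = 10

    def rr_at(self, t: float) -> float:
        if t < 0:
            raise InputValidationError("time since intervention cannot be negative")
        if t >= self.truncation_year:
            return 1.0
        effect0 = 1.0 - self.rr_post
        if effect0 == 0.0:
            return 1.0
        if self.decay_law == ASYMPTOTIC:
            if math.isinf(self.decay_rate):
                return self.rr_post if t == 0 else 1.0
            return 1.0 - effect0 * math.exp(-self.decay_rate * t)
        if self.decay_law == FIXED:
            return 1.0 - effect0 * (1.0 - self.decay_rate) ** t
        raise InputValidationError(f"unknown decay law {self.decay_law!r}")


def null_profile(truncation_year: int = 10) -> EffectProfile:
    return EffectProfile(1.0, ASYMPTOTIC, 0.0, truncation_year)


def fit_asymptotic_decay(
    rr_post: float, rr_1yr: float, truncation_year: int = 10
) -> EffectProfile:
    """Asymptotic-exponential waning pinned to the two trial anchors.

    rr(t) = 1 - (1 - rr_post) * exp(-lambda*t) with
    lambda = ln((1 - rr_post)/(1 - rr_1yr)), so rr(0) = rr_post and
    rr(1) = rr_1yr exactly. ``rr_1yr = 1`` is the degenerate limit where
    the effect vanishes after the first year (lambda -> infinity).
    """
    if not 0.0 < rr_post <= 1.0 or not 0.0 < rr_1yr <= 1.0:
        raise InputValidationError("anchor RRs must lie in (0, 1]")
    if rr_1yr < rr_post:
        raise InputValidationError(
            "rr_1yr < rr_post would imply a growing effect; decay requires "
            "the one-year RR to be at least the post-test RR"
        )
    if truncation_year < 1:
        raise InputValidationError("truncation_year must be at least 1")
    if rr_post == 1.0:
        return null_profile(truncation_year)
    if rr_1yr == 1.0:
        lam = math.inf
    else:
        lam = math.log((1.0 - rr_post) / (1.0 - rr_1yr))
    return EffectProfile(rr_post, ASYMPTOTIC, lam, truncation_year)


def fixed_decay_profile(
    rr_post: float, annual_fraction: float, truncation_year: int = 10
) -> EffectProfile:
    """Effect shrinking by a fixed fraction each year.

    The effect size (1 - rr) is multiplied by (1 - annual_fraction) per
    year; an annual fraction of 1 removes the effect after the first year.
    """
    if not 0.0 < rr_post <= 1.0:
        raise InputValidationError("rr_post must lie in (0, 1]")
    if not 0.0 < annual_fraction <= 1.0:
        raise InputValidationError("annual decay fraction must lie in (0, 1]")
    if truncation_year < 1:
        raise InputValidationError("truncation_year must be at least 1")
    if rr_post == 1.0:
        return null_profile(truncation_year)
    return EffectProfile(rr_post, FIXED, annual_fraction, truncation_year)


@dataclass(frozen=True)
class BodyDissatAdjustment:
    """Incidence scaling for the high-body-dissatisfaction subgroup.

    Body dissatisfaction raises eating-disorder onset risk with odds ratios
    of 1.51 at age 15 and 1.67 at 16, converted to relative risks of 1.44
    and 1.57; the age-16 relative risk is carried through to age 100, and
    (for expanded target populations) the age-15 value is used below 15.
    ``prevalence_high_bd`` is the population share self-identifying with
    high body image concerns.
    """

    rr_age15: float = 1.44
    rr_age16plus: float = 1.57
    prevalence_high_bd: float = 0.689
    or_age15: float = 1.51
    or_age16: float = 1.67

    def __post_init__(self) -> None:
        if self.rr_age15 <= 0 or self.rr_age16plus <= 0:
            raise InputValidationError("body-dissatisfaction RRs must be positive")
        if not 0.0 <= self.prevalence_high_bd <= 1.0:
            raise InputValidationError("prevalence_high_bd must lie in [0, 1]")

    def rr_at_age(self, age: int) -> float:
        return self.rr_age15 if age <= 15 else self.rr_age16plus

    def incidence_factor(self, age: int) -> float:
        """Multiplier turning population incidence into subgroup incidence."""
        rr = self.rr_at_age(age)
        p = self.prevalence_high_bd
        if p == 0.0 and rr != 1.0:
            raise InputValidationError(
                "subgroup incidence undefined: zero prevalence with RR != 1"
            )
        return rr / (p * rr + 1.0 - p)


def adjust_incidence_for_target_group(
    pop_incidence: float, prevalence_high_bd: float, rr_bd: float
) -> float:
    """Incidence rate in the high-body-dissatisfaction subgroup.

    Solves the mixture identity
    p * i_high + (1 - p) * i_high/RR = i_pop, giving
    i_high = i_pop * RR / (p*RR + 1 - p).
    """
    if pop_incidence < 0:
        raise InputValidationError("incidence must be non-negative")
    if rr_bd < 1.0:
        raise InputValidationError("body-dissatisfaction RR below 1 is not supported")
    if not 0.0 < prevalence_high_bd <= 1.0:
        raise InputValidationError(
            "subgroup prevalence must lie in (0, 1] for the subgroup to exist"
        )
    return pop_incidence * rr_bd / (prevalence_high_bd * rr_bd + 1.0 - prevalence_high_bd)
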