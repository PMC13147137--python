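"""Discounting, health-adjusted life years, ICERs and threshold rules.

The health outcome is the health-adjusted life year (HALY): alive
person-years minus disability-weight-weighted prevalent person-years,
discounted to the intervention year. Because the three eating disorders
are modelled as parallel independent modules, only the *incremental*
HALYs (intervention minus control, summed over modules) are meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .cascade import CascadeResult, CostBreakdown
from .epi import InputValidationError

DOMINANT = "Dominant"
DOMINATED = "Dominated"
UNDEFINED = "Undefined"

#: Productivity-Commission style willingness-to-pay bands plus the primary
#: $50,000/HALY threshold (2019 AUD per HALY gained).
DEFAULT_WTP_THRESHOLDS = (50_000.0, 33_000.0, 64_000.0, 96_000.0)


def discount_factor(t, rate: float):
    """Present-value factor 1/(1+rate)^t for cycle(s) t (t = 0 undiscounted)."""
    if rate < 0:
        raise InputValidationError("discount rate cannot be negative")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise InputValidationError("cycle index cannot be negative")
    out = (1.0 + rate) ** (-t)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class DisabilityWeights:
    """GBD-style disability weights with 95% CIs for the three disorders."""

    AN: float = 0.22
    BN: float = 0.22
    BED: float = 0.05
    AN_ci: tuple[float, float] = (0.15, 0.31)
    BN_ci: tuple[float, float] = (0.15, 0.31)
    BED_ci: tuple[float, float] = (0.02, 0.08)

    def __post_init__(self) -> None:
        for d in ("AN", "BN", "BED"):
            w = getattr(self, d)
            lo, hi = getattr(self, f"{d}_ci")
            if not 0.0 <= w <= 1.0:
                raise InputValidationError(f"disability weight {d} outside [0, 1]")
            if not lo <= w <= hi:
                raise InputValidationError(f"CI for {d} does not bracket the point")

    def get(self, disease: str) -> float:
        try:
            return float(getattr(self, disease))
        except AttributeError:
            raise InputValidationError(f"no disability weight for {disease!r}")


def compute_halys(
    agg_intervention: pd.DataFrame,
    agg_control: pd.DataFrame,
    weights: DisabilityWeights,
    discount_rate: float = 0.03,
) -> float:
    """Incremental discounted HALYs, intervention minus control.

    Both inputs are aggregated traces (one row per sex/disease/cycle with
    ``alive_py`` and ``prevalent_py``). Per disease module d,
    HALY_d = sum_t disc(t) * [alive_py(t) - dw_d * prevalent_py(t)]; the
    increment is summed over modules. Traces must align exactly on
    (sex, disease, cycle).
    """
    keys = ["sex", "disease", "cycle"]
    a = agg_intervention.set_index(keys).sort_index()
    b = agg_control.set_index(keys).sort_index()
    if not a.index.equals(b.index):
        raise InputValidationError("intervention and control traces are misaligned")
    dw = a.index.get_level_values("disease").map(weights.get).to_numpy(dtype=float)
    disc = discount_factor(a.index.get_level_values("cycle").to_numpy(), discount_rate)
    haly_a = disc * (a["alive_py"].to_numpy() - dw * a["prevalent_py"].to_numpy())
    haly_b = disc * (b["alive_py"].to_numpy() - dw * b["prevalent_py"].to_numpy())
    return float(np.sum(haly_a - haly_b))


def compute_icer(delta_cost: float, delta_halys: float) -> float | str:
    """ICER in currency per HALY gained, or a dominance label.

    More effective and cheaper -> Dominant; less effective and costlier ->
    Dominated; zero health increment leaves the ratio undefined.
    """
    if delta_halys == 0.0:
        return UNDEFINED
    if delta_halys > 0.0 and delta_cost < 0.0:
        return DOMINANT
    if delta_halys < 0.0 and delta_cost > 0.0:
        return DOMINATED
    return delta_cost / delta_halys


def classify_threshold(
    icer_or_label: float | str, thresholds=DEFAULT_WTP_THRESHOLDS
) -> dict[float, bool]:
    """Cost-effectiveness verdict per willingness-to-pay threshold.

    Comparison is strict (< threshold); Dominant passes everywhere,
    Dominated and Undefined nowhere.
    """
    out: dict[float, bool] = {}
    for k in thresholds:
        if k <= 0:
            raise InputValidationError("thresholds must be positive")
        if icer_or_label == DOMINANT:
            out[float(k)] = True
        elif icer_or_label in (DOMINATED, UNDEFINED):
            out[float(k)] = False
        else:
            out[float(k)] = float(icer_or_label) < k
    return out


def plane_quadrant(delta_halys: float, delta_cost: float) -> str:
    """Cost-effectiveness-plane quadrant (east = more effective, north =
    more costly). Boundary values fall north/east."""
    ew = "E" if delta_halys > 0 else "W"
    ns = "N" if delta_cost >= 0 else "S"
    return ns + ew


@dataclass
class CEResult:
    """One deterministic cost-effectiveness evaluation."""

    delta_halys: float
    cost_breakdown: CostBreakdown
    offsets: float
    icer_excl_offsets: float | str
    icer_incl_offsets: float | str
    plane_quadrant: str
    cost_effective_excl: dict[float, bool]
    cost_effective_incl: dict[float, bool]
    cascade: dict[str, CascadeResult]
    averted_incidence: dict[str, float]
    delta_halys_by_sex: dict[str, float]
    offsets_by_sex: dict[str, float]
    participants: int

    @property
    def cost_excl_offsets(self) -> float:
        return self.cost_breakdown.total

    @property
    def cost_incl_offsets(self) -> float:
        return self.cost_breakdown.total - self.offsets

    def summary_frame(self) -> pd.DataFrame:
        """Key results as a two-column table for reports."""

        def fmt(x):
            return x if isinstance(x, str) else f"{x:,.2f}"

        rows = [
            ("participants", f"{self.participants:,}"),
            ("HALYs gained", f"{self.delta_halys:,.2f}"),
            ("cost excl. offsets ($)", f"{self.cost_excl_offsets:,.2f}"),
            ("healthcare cost offsets ($)", f"{self.offsets:,.2f}"),
            ("cost incl. offsets ($)", f"{self.cost_incl_offsets:,.2f}"),
            ("ICER excl. offsets ($/HALY)", fmt(self.icer_excl_offsets)),
            ("ICER incl. offsets ($/HALY)", fmt(self.icer_incl_offsets)),
            ("plane quadrant", self.plane_quadrant),
        ]
        for d, n in self.averted_incidence.items():
            rows.append((f"averted incident cases ({d})", f"{n:,.1f}"))
        for k, ok in self.cost_effective_excl.items():
            rows.append(
                (f"cost-effective excl. offsets at ${k:,.0f}/HALY", str(ok))
            )
        return pd.DataFrame(rows, columns=["quantity", "value"])
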