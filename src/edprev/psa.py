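"""Probabilistic sensitivity analysis.

Parameter uncertainty is propagated by Monte Carlo: each draw samples a
full parameter set from the declared uncertainty families (lognormal from
a 95% CI, beta by method of moments, beta-PERT from min/mode/max), the
deterministic model is re-run, and the per-draw incremental costs and
HALYs feed the cost-effectiveness plane, percentile intervals, and the
cost-effectiveness acceptability curve (CEAC).

Parameters are drawn independently except the two efficacy anchors
(post-test and one-year RR), which share a single normal quantile so a
draw cannot invert the decay curve; residual infeasibility is clipped and
counted. Each draw uses its own counter-derived RNG stream, making the
simulation reproducible and order-independent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .config import ModelConfig
from .economics import DOMINANT, plane_quadrant
from .epi import InputValidationError
from .inputs import Inputs
from .pipeline import run_model

Z975 = 1.959964  # standard normal 97.5th percentile


# -- distribution fits -----------------------------------------------------


def fit_lognormal_from_ci(point: float, lo: float, hi: float) -> tuple[float, float]:
    """(mu, sigma) of a lognormal with median ``point`` and 95% CI (lo, hi).

    sigma is read off the CI width on the log scale; a degenerate CI gives
    sigma = 0 (a point mass).
    """
    if not 0 < lo <= point <= hi:
        raise InputValidationError(
            f"need 0 < lo <= point <= hi, got ({point}, {lo}, {hi})"
        )
    return math.log(point), (math.log(hi) - math.log(lo)) / (2.0 * Z975)


def fit_beta_from_ci(point: float, lo: float, hi: float) -> tuple[float, float]:
    """(alpha, beta) by method of moments: mean = point, sd = CI width/3.92."""
    if not 0.0 < point < 1.0:
        raise InputValidationError("beta point estimate must lie in (0, 1)")
    if not 0.0 <= lo <= point <= hi <= 1.0:
        raise InputValidationError("beta CI must bracket the point within [0, 1]")
    sd = (hi - lo) / (2.0 * Z975)
    if sd == 0.0:
        return math.inf, math.inf  # degenerate: fixed value
    nu = point * (1.0 - point) / sd**2 - 1.0
    alpha, beta = point * nu, (1.0 - point) * nu
    if alpha <= 0 or beta <= 0:
        raise InputValidationError(
            "CI too wide for a beta fit (implied alpha or beta <= 0)"
        )
    return alpha, beta


def pert_params(lo: float, mode: float, hi: float) -> tuple[float, float]:
    """Beta-PERT (shape 4) alpha/beta for support [lo, hi] and the mode."""
    if not lo <= mode <= hi:
        raise InputValidationError("PERT needs lo <= mode <= hi")
    if lo == hi:
        return math.inf, math.inf
    return 1.0 + 4.0 * (mode - lo) / (hi - lo), 1.0 + 4.0 * (hi - mode) / (hi - lo)


def sample_pert(lo: float, mode: float, hi: float, rng: np.random.Generator, size=None):
    """Draw from the beta-PERT distribution on [lo, hi]; mean is
    (lo + 4*mode + hi)/6."""
    a, b = pert_params(lo, mode, hi)
    if math.isinf(a):
        return lo if size is None else np.full(size, lo)
    return lo + (hi - lo) * rng.beta(a, b, size=size)


def sample_lognormal_ci(point, lo, hi, rng, size=None):
    mu, sigma = fit_lognormal_from_ci(point, lo, hi)
    if sigma == 0.0:
        return point if size is None else np.full(size, point)
    return np.exp(rng.normal(mu, sigma, size=size))


def sample_beta_ci(point, lo, hi, rng, size=None):
    a, b = fit_beta_from_ci(point, lo, hi)
    if math.isinf(a):
        return point if size is None else np.full(size, point)
    return rng.beta(a, b, size=size)


@dataclass(frozen=True)
class ParamDistribution:
    """One uncertain parameter: a family tag plus its parameters."""

    name: str
    family: str  # lognormal_ci | beta_ci | pert | discrete | fixed
    args: tuple

    def sample(self, rng: np.random.Generator):
        if self.family == "lognormal_ci":
            return float(sample_lognormal_ci(*self.args, rng))
        if self.family == "beta_ci":
            return float(sample_beta_ci(*self.args, rng))
        if self.family == "pert":
            return float(sample_pert(*self.args, rng))
        if self.family == "discrete":
            values, probs = self.args
            return rng.choice(values, p=probs)
        if self.family == "fixed":
            return self.args[0]
        raise InputValidationError(f"unknown distribution family {self.family!r}")


@dataclass
class PSAOutput:
    """Per-draw results plus summaries of a PSA run."""

    draws: pd.DataFrame  # draw, delta_halys, cost_excl, cost_incl, quadrant
    summary: pd.DataFrame
    quadrant_shares: dict[str, float]
    n_clipped: int
    n_redrawn: int
    seed: int


def fixed_overrides(config: ModelConfig) -> dict[str, ParamDistribution]:
    """Overrides pinning every uncertain parameter at its point estimate.

    Running the PSA with these reproduces the deterministic result in
    every draw — the degenerate sanity case.
    """
    fixed = {
        "rr_post": config.effects.rr_post,
        "rr_1yr": config.effects.rr_1yr,
        "bd_rr_age15": config.bd.rr_age15,
        "bd_rr_age16plus": config.bd.rr_age16plus,
        "dw_AN": config.disability_weights.AN,
        "dw_BN": config.disability_weights.BN,
        "dw_BED": config.disability_weights.BED,
        "private_cost_factor": 1.0,
        "makeup_session_hours": config.costs.makeup_session_hours,
        "response_rate": config.cascade.response_rate,
        "high_bd_rate": config.cascade.high_bd_rate,
        "acceptance_scale": 1.0,
    }
    for d in config.diseases:
        for r in ("incidence", "remission", "case_fatality"):
            fixed[f"epi_{d}_{r}"] = 1.0
        fixed[f"treatcost_{d}"] = 1.0
    return {k: ParamDistribution(k, "fixed", (v,)) for k, v in fixed.items()}


def _draw_parameters(
    config: ModelConfig,
    rng: np.random.Generator,
    overrides: dict[str, ParamDistribution] | None = None,
) -> dict:
    """One joint parameter draw from the configured uncertainty families."""
    e, bd, dw, cas = config.effects, config.bd, config.disability_weights, config.cascade
    p: dict = {}
    # shared-quantile efficacy pair
    z = rng.normal()
    mu_p, sd_p = fit_lognormal_from_ci(e.rr_post, *e.rr_post_ci)
    mu_1, sd_1 = fit_lognormal_from_ci(e.rr_1yr, *e.rr_1yr_ci)
    p["rr_post"] = math.exp(mu_p + sd_p * z)
    p["rr_1yr"] = math.exp(mu_1 + sd_1 * z)
    p["bd_rr_age15"] = float(sample_lognormal_ci(bd.rr_age15, *bd.rr_age15_ci, rng))
    p["bd_rr_age16plus"] = float(
        sample_lognormal_ci(bd.rr_age16plus_psa_point, *bd.rr_age16plus_ci, rng)
    )
    for d in ("AN", "BN", "BED"):
        p[f"dw_{d}"] = float(
            sample_beta_ci(getattr(dw, d), *getattr(dw, f"{d}_ci"), rng)
        )
    p["private_cost_factor"] = float(sample_pert(0.8, 1.0, 1.2, rng))
    p["makeup_session_hours"] = float(sample_pert(0.15, 0.20, 0.25, rng))
    p["response_rate"] = float(sample_pert(0.09, 0.10, 0.12, rng))
    p["high_bd_rate"] = float(sample_pert(0.20, 0.689, 0.80, rng))
    # acceptance varies by the trial range relative to its mode (64-95 vs 83)
    p["acceptance_scale"] = float(sample_pert(64.0 / 83.0, 1.0, 95.0 / 83.0, rng))
    ratio = config.psa.epi_rate_ci_ratio
    for d in config.diseases:
        for r in ("incidence", "remission", "case_fatality"):
            p[f"epi_{d}_{r}"] = float(
                sample_lognormal_ci(1.0, 1.0 / ratio, ratio, rng)
            )
        tratio = config.psa.treatment_cost_ci_ratio
        p[f"treatcost_{d}"] = float(
            sample_lognormal_ci(1.0, 1.0 / tratio, tratio, rng)
        )
    if overrides:
        unknown = set(overrides) - set(p)
        if unknown:
            raise InputValidationError(
                f"overrides reference unknown parameters: {sorted(unknown)}"
            )
        for name, dist in overrides.items():
            p[name] = dist.sample(rng)
    return p


def _apply_parameters(
    config: ModelConfig, inputs: Inputs, p: dict
) -> tuple[ModelConfig, Inputs, int]:
    """Materialise a drawn parameter set; returns the clip count."""
    clipped = 0
    rr_post = p["rr_post"]
    rr_1yr = p["rr_1yr"]
    if rr_post > 1.0:
        rr_post, clipped = 1.0, clipped + 1
    if rr_1yr > 1.0:
        rr_1yr, clipped = 1.0, clipped + 1
    if rr_1yr < rr_post:
        rr_1yr, clipped = rr_post, clipped + 1

    cfg = config.replace(
        effects=replace(config.effects, rr_post=rr_post, rr_1yr=rr_1yr),
        bd=replace(
            config.bd,
            rr_age15=p["bd_rr_age15"],
            rr_age16plus=p["bd_rr_age16plus"],
        ),
        disability_weights=replace(
            config.disability_weights,
            AN=p["dw_AN"],
            BN=p["dw_BN"],
            BED=p["dw_BED"],
            AN_ci=(0.0, 1.0),
            BN_ci=(0.0, 1.0),
            BED_ci=(0.0, 1.0),
        ),
        cascade=replace(
            config.cascade,
            response_rate=min(p["response_rate"], 1.0),
            high_bd_rate=min(p["high_bd_rate"], 1.0),
            acceptance_rate=min(
                config.cascade.acceptance_rate * p["acceptance_scale"], 1.0
            ),
        ),
        costs=replace(
            config.costs.with_private_cost_factor(p["private_cost_factor"]),
            makeup_session_hours=p["makeup_session_hours"],
        ),
    )
    epi = {
        key: r.scaled(
            incidence=p[f"epi_{r.disease}_incidence"],
            remission=p[f"epi_{r.disease}_remission"],
            case_fatality=p[f"epi_{r.disease}_case_fatality"],
        )
        for key, r in inputs.epi.items()
    }
    tc = inputs.treatment_costs.scaled(
        {d: p[f"treatcost_{d}"] for d in config.diseases}
    )
    return cfg, replace(inputs, epi=epi, treatment_costs=tc), clipped


def run_psa(
    config: ModelConfig,
    inputs: Inputs,
    n_draws: int | None = None,
    seed: int | None = None,
    overrides: dict[str, ParamDistribution] | None = None,
    max_redraws: int = 100,
) -> PSAOutput:
    """Monte Carlo re-evaluation of the model under parameter uncertainty."""
    n_draws = config.psa.n_draws if n_draws is None else n_draws
    seed = config.psa.seed if seed is None else seed
    if n_draws < 1:
        raise InputValidationError("n_draws must be at least 1")
    if overrides:
        # fail fast on bad names rather than burning the redraw budget
        known = set(_draw_parameters(config, np.random.default_rng(0)))
        unknown = set(overrides) - known
        if unknown:
            raise InputValidationError(
                f"overrides reference unknown parameters: {sorted(unknown)}"
            )

    records = []
    n_clipped = 0
    n_redrawn = 0
    for d in range(n_draws):
        for attempt in range(max_redraws):
            rng = np.random.default_rng([seed, d, attempt])
            try:
                params = _draw_parameters(config, rng, overrides)
                cfg_d, inputs_d, clips = _apply_parameters(config, inputs, params)
                res = run_model(cfg_d, inputs_d)
                break
            except InputValidationError:
                n_redrawn += 1
        else:
            raise InputValidationError(
                f"draw {d}: no valid parameter set in {max_redraws} attempts"
            )
        n_clipped += clips
        records.append(
            {
                "draw": d,
                "delta_halys": res.delta_halys,
                "cost_excl": res.cost_excl_offsets,
                "cost_incl": res.cost_incl_offsets,
                "quadrant": plane_quadrant(res.delta_halys, res.cost_incl_offsets),
            }
        )
    draws = pd.DataFrame.from_records(records)
    shares = (
        draws["quadrant"].value_counts(normalize=True).reindex(
            ["NE", "NW", "SE", "SW"], fill_value=0.0
        )
    )
    return PSAOutput(
        draws=draws,
        summary=summarize_draws(draws),
        quadrant_shares=shares.to_dict(),
        n_clipped=n_clipped,
        n_redrawn=n_redrawn,
        seed=seed,
    )


def summarize_draws(draws: pd.DataFrame) -> pd.DataFrame:
    """Mean and percentile 95% interval per quantity, plus the
    ratio-of-means ICER excluding offsets."""
    rows = []
    for col in ("delta_halys", "cost_excl", "cost_incl"):
        v = draws[col]
        rows.append(
            {
                "quantity": col,
                "mean": v.mean(),
                "ci_lo": v.quantile(0.025),
                "ci_hi": v.quantile(0.975),
            }
        )
    pos = draws["delta_halys"] > 0
    if pos.any():
        icer = draws.loc[pos, "cost_excl"] / draws.loc[pos, "delta_halys"]
        rows.append(
            {
                "quantity": "icer_excl (ratio of means)",
                "mean": draws["cost_excl"].mean() / draws["delta_halys"].mean(),
                "ci_lo": icer.quantile(0.025),
                "ci_hi": icer.quantile(0.975),
            }
        )
    return pd.DataFrame(rows)


def ceac(
    draws: pd.DataFrame,
    thresholds,
    cost_col: str = "cost_excl",
) -> pd.DataFrame:
    """Probability of cost-effectiveness per willingness-to-pay threshold.

    A draw counts at threshold k when it gains health (delta HALYs > 0)
    and its net monetary benefit k*dHALY - dCost is positive; dominant
    draws (negative cost) therefore always count.
    """
    if draws.empty:
        raise InputValidationError("CEAC needs at least one draw")
    dh = draws["delta_halys"].to_numpy()
    dc = draws[cost_col].to_numpy()
    rows = [
        {
            "threshold": float(k),
            "probability": float(np.mean((dh > 0) & (k * dh - dc > 0))),
        }
        for k in thresholds
    ]
    return pd.DataFrame(rows)
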