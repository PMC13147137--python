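# Methods

## Model structure

Each eating disorder — anorexia nervosa (AN), bulimia nervosa (BN),
binge-eating disorder (BED) — is modelled as an independent four-state
illness-death process over annual cycles: healthy, diseased, dead from
the disease, dead from other causes. There is no comorbidity interaction
between the disorders, mirroring the parallel-module design of cohort
cost-utility models in this area. Remitted individuals return to the
healthy state and can relapse through ordinary re-incidence.

Annual per-person rates are converted to one-cycle transition
probabilities by exponentiating the competing-risk generator
(`scipy.linalg.expm`), not by applying `1 − exp(−rate)` to each flow
independently. The exponential embedding is exact under the
constant-rates-within-a-cycle assumption, keeps every row stochastic for
arbitrarily large rates, and is validated in the tests against an
independent scaling-and-squaring series implementation and against a
stochastic per-individual microsimulation. A consequence worth knowing:
the embedded matrix carries a small healthy-to-disease-death probability
(onset and death within one cycle, order i·f/2); this is a feature of
correct competing-risk embedding.

Cohorts: one closed cohort per single year of age in the target range
(15–18 base case), followed from the intervention year (calendar t = 0
for all cohorts) to age 100. A `follow_up_years` switch caps the horizon
for shorter-follow-up readings. Each cohort's initial diseased fraction
is derived internally by running an all-healthy cohort from the youngest
age with defined rates up to the cohort's starting age — the modelled
population is the screened high-body-dissatisfaction subgroup, so this
seeding applies the same subgroup incidence adjustment as the main run.

Two optional engine flags, both off by default: a half-cycle correction
(person-years as the mean of adjacent occupancies) and netting the case
fatality out of background mortality for the diseased state (guards
against double-counting when all-cause inputs already include
disease-specific deaths).

## Intervention effect

The effect is a multiplicative relative risk on incidence only (never on
remission or case fatality), identical for all three disorders in the
base case. Anchors: RR 0.85 (95% CI 0.79–0.92) at post-test and 0.94
(0.86–1.03) at one-year follow-up, taken as inputs; the conversion of
standardised mean differences into these risk ratios is upstream
evidence synthesis and out of scope here.

Between the anchors the effect wanes along an exponential approach to
the null, RR(t) = 1 − (1 − RR₀)e^{−λt} with λ = ln[(1−RR₀)/(1−RR₁)];
with the default anchors λ ≈ 0.916, i.e. about 60% of the remaining
effect is shed each year. This is the simplest two-parameter asymptotic
family consistent with both anchors. The effect is exactly null from the
truncation year (default 10) onward. Cycle k of a cohort run uses
RR(k−1): the post-test effect governs the first year. An alternative
`fixed_annual_decay` law multiplies the effect size by (1 − d) per year;
scenario 1 uses d = 0.5. Note the geometry this implies: a 50%-per-annum
decay is *slower* than the default asymptotic curve beyond year one, so
on identical inputs scenario 1 retains more cumulative effect (and more
HALYs) than the base case. Published evaluations in which a 50% decay
halves the health gain imply a base-case decay much slower than either —
closer to a plateau at the one-year effect — but with only two anchors
stated, this package keeps the explicit two-anchor exponential and
documents the divergence rather than fitting an unidentified curve.

Because only students screening positive for high body dissatisfaction
participate, population incidence is rescaled to that subgroup using
i_high = i_pop·RR_bd/(p·RR_bd + 1 − p) with p = 0.689 and RR_bd = 1.44
at ages ≤ 15 and 1.57 from 16 up (held to age 100). These relative
risks derive from the published odds ratios 1.51 and 1.67 through
RR = OR/(1 − p₀ + p₀·OR); calibrating p₀ on the (1.51 → 1.44) pair and
converting 1.67 reproduces 1.57 to two decimals, which is the package's
acceptance-checked quantity. Both arms carry the subgroup adjustment;
the arms differ only by the intervention RR.

## Cascade and costs (2019 AUD)

Participant funnel, with half-up rounding at each stage: 10% of the
enrolled female population 15–18 (569,295 in the pinned 2019 counts)
respond to recruitment, 68.9% of responders screen positive, and 45%
accept (the conservative real-world value; trial acceptance was 83%,
range 64–95%). That yields 17,651 participants, allocated evenly across
1,416 schools and grouped in eights (the midpoint of the 6–10 group
format) — 2,832 groups.

Costs are built bottom-up from unit costs: counselor \$40.90/h and
coordinator \$87.99/h, both + 30% on-costs; 10 minutes of recruitment
per 25-student class across the whole eligible population; 10 minutes of
screening per responder; per-school training (\$416 online fee, 4 h of
technical assistance at \$125/h, 10.25 h of counselor time); delivery of
four one-hour sessions plus a 0.2 h make-up session per group.
Coordinator hours are not published; the default is one full-time year
(37.5 h/week × 46 weeks), configurable. With these inputs the bottom-up
total is ≈ \$3.6M — the published ≈ \$1.88M total is not recoverable
from the published unit costs alone (per-school training already exceeds
\$2M), so the package reports its own faithful decomposition and treats
the printed total as non-reproducible. Treatment-cost offsets value each
averted prevalent person-year (or, under a config switch, each averted
incident case once) at the disease/sex/age-band annual cost, discounted
to t = 0.

## Outcomes and decision rules

ΔHALY = Σ_d Σ_t disc(t)·[Δalive_d(t) − dw_d·Δprev_d(t)], summed over
disease modules, with disability weights 0.22 (AN), 0.22 (BN), 0.05
(BED) and 3%/yr discounting from the shared intervention year. Because
each disorder module carries its own survival, absolute per-arm HALY
levels are not meaningful (alive-years would be triple-counted); only
the increment is reported. ICERs are computed with and without offsets;
more effective and cheaper is Dominant, less effective and costlier is
Dominated, a zero health increment leaves the ratio undefined.
Threshold comparisons are strict (<): \$50,000/HALY primary, with
\$33,000/\$64,000/\$96,000 bands.

## Uncertainty analysis

Each Monte Carlo draw samples every uncertain parameter and re-runs the
full model. Families: lognormal-from-CI (median at the point estimate;
efficacy anchors, body-dissatisfaction RRs, epidemiological-rate and
treatment-cost multipliers), beta by method of moments (disability
weights), beta-PERT shape 4 (private cost factor ±20%, make-up duration
0.15–0.25 h, response 9–12%, screening-positive 20–80%, acceptance).
The two efficacy anchors share one normal quantile so a draw cannot
invert the decay curve; residual infeasibility (RR > 1 or crossed
anchors) is clipped and counted. The acceptance proportion is sampled as
a PERT *scale* with the trial range relative to its mode (64/83 to
95/83) applied to the configured base rate, keeping the sampled cascade
centred on the deterministic base case. The body-dissatisfaction age-16+
RR samples around 1.58 (1.17–2.13), the tabulated uncertainty row,
while the deterministic base keeps 1.57, the value the odds-ratio
conversion reproduces. Epidemiological and treatment-cost uncertainty
enter as whole-curve lognormal multipliers (default 95% ratio bounds
×/÷1.2) per disease and rate type, since the synthetic curves have no
per-age empirical CIs. Draw d, attempt k uses
`numpy.random.default_rng([seed, d, k])` — order-independent and
bit-reproducible. Summaries are percentile-based 95% intervals plus a
ratio-of-means ICER; the CEAC counts draws with positive health gain and
positive net monetary benefit, so dominant draws always count.

## Scenarios

Declarative overrides of the base configuration (the resolved config
differs in exactly the documented paths, which is itself asserted):
s1 fixed 50%-per-annum decay; s2 AN effect off (RR 1); s3 males 15–18
added with the same effect profile, their own synthetic epidemiology,
and a configurable male treatment-cost factor (default 1.0 with a
warning, as no male cost schedule is published) — training and
coordination are fixed program costs counted once, so health outcomes,
offsets and variable costs decompose exactly into female + male runs;
s4 female target ages 12–25, reusing the same cascade proportions and
cost template with the counselor cost class for screening.

## Synthetic inputs

The generator emulates the *structure* of burden-of-disease inputs, not
their values: log-bell incidence over age peaking at 16/18/20 (AN/BN/BED)
with peak magnitudes 3×10⁻⁴ / 6×10⁻⁴ / 1×10⁻³ per person-year and mild
seeded age-wise jitter; male incidence scaled by 0.25; age-constant
remission from mean durations 6/5/4 years; age-constant case fatality
6/2/1 ×10⁻³ with AN highest; Gompertz background mortality
1.5×10⁻⁵·e^{0.085·age}; treatment costs \$11k/\$8k/\$5k per prevalent
case-year with band-level seeded variation that preserves the
AN ≥ BN ≥ BED ordering; population ≈ 140,000 per single age with the
2019 female counts for 15–18 pinned exactly in fixed mode. Everything is
deterministic given the seed.

What passing tests therefore show: the engine, algebra, costing,
economics and uncertainty machinery are correct (oracle agreement,
conservation, identities, monotonicities, determinism), and published
desk-checkable quantities (cascade counts, effect algebra, odds-to-risk
conversion, distribution moments) are reproduced. What they do not show:
national-scale HALY, offset or ICER magnitudes, which depend entirely on
the unpublished epidemiological and cost inputs. On the synthetic world
the base case yields ≈ 6.7 HALYs and ≈ \$0.23M offsets against ≈ \$3.6M
cost — a north-east-quadrant result — whereas richer real-world inputs
an order of magnitude higher in incidence would move it toward the
published dominant/south-east findings.

## Numerical choices and edge cases

Cascade counts round half-up per stage; money is kept at full precision
and rounded for display only. Per-participant cost is reported as absent
when there are no participants. Degenerate distribution fits (zero-width
CIs, PERT with min = max) collapse to point masses. `rr_1yr = 1` is the
decay law's well-defined limit (effect only in the first year). A
vanishing violation of pointwise prevalence monotonicity is expected
with fatal diseases — individuals saved from onset survive and re-enter
the risk pool — so the invariant tests allow a per-capita excess of
10⁻⁶ while requiring the cumulative disease burden to fall strictly;
with case fatality zero, pointwise monotonicity is exact and tested so.
Problem sizes in the shipped analyses (85-year horizons, 500 PSA draws,
2×10⁵-replicate microsimulation oracle) were chosen to keep every run
interactive on a laptop; all are configuration knobs.

## Known limitations

No comorbidity between disorders; no relapse structure beyond ordinary
re-incidence; effects on incidence only; independent parameter draws (no
correlation beyond the shared efficacy quantile); the education sector
contributes costs but no quantified benefits; synthetic inputs are
stylised and uncalibrated, so absolute results are illustrative.
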