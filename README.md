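# edprev

A Markov cohort cost-utility model for school-based prevention of eating
disorders, built for health economists and prevention researchers who
want a transparent, fully testable re-implementation of the modelling
pipeline behind population-level evaluations of the Body Project — a
dissonance-based group program offered to secondary-school students with
high body image concerns.

## The model

Each disorder (anorexia nervosa, bulimia nervosa, binge-eating disorder)
is followed independently in a discrete-time, age-structured cohort model
with four states: *healthy*, *diseased*, *dead from the disease*, and
*dead from other causes*. Annual rates — incidence i(a), remission r(a),
case fatality f(a), background mortality m(a) — are embedded into
one-cycle transition probabilities as the matrix exponential of the
competing-risk generator

    G = [ -(i+m)   i        0    m ]
        [  r     -(r+f+m)   f    m ]
        [  0       0        0    0 ]
        [  0       0        0    0 ]

which keeps rows stochastic for any non-negative rates. Cohorts start at
each single year of age in the target range (15–18 in the base case) and
run to age 100, sharing calendar cycle t = 0.

The program's effect enters as a time-varying relative risk on incidence:
RR(0) = 0.85 at post-test, RR(1) = 0.94 at one-year follow-up, and
between anchors an asymptotic-exponential approach to the null,

    RR(t) = 1 − (1 − RR₀)·exp(−λt),   λ = ln[(1−RR₀)/(1−RR₁)] ≈ 0.916,

truncated to exactly 1 from year 10 onward. Because participants are the
screened high-body-dissatisfaction subgroup (68.9% of responders),
population incidence is rescaled with the subgroup relative risks 1.44
(age ≤ 15) and 1.57 (16+), themselves derived from the published odds
ratios 1.51/1.67 via RR = OR/(1 − p₀ + p₀·OR).

Outcomes are discounted (3%/yr) health-adjusted life years —
alive person-years minus disability-weighted prevalent person-years
(weights 0.22/0.22/0.05) — against bottom-up intervention costs (2019
AUD unit costs: counselor \$40.90/h + 30% on-costs, per-school training,
four one-hour group sessions, a national coordinator) and discounted
treatment-cost offsets. Results are reported as ICERs against
willingness-to-pay thresholds (\$50,000 primary; \$33,000/\$64,000/\$96,000
bands), with four one-way scenarios and a Monte Carlo probabilistic
sensitivity analysis (lognormal/beta/PERT families, counter-based RNG
streams, CE plane and CEAC).

Age-specific epidemiological rates and treatment-cost schedules are not
published, so `edprev.synthetic` generates stylised stand-ins (unimodal
adolescent-peaked incidence, Gompertz mortality, AN-dominant case
fatality and costs) — deterministic given a seed, with the printed 2019
female population counts for ages 15–18 pinned exactly.

## Worked example

```bash
python analysis/01_simulate_inputs.py
python analysis/02_base_case.py
```

prints, on the seed-0 synthetic world:

```
base case (lifetime horizon, 3% discount)
  cascade: 569,295 students -> 56,930 responders -> 39,225 screened eligible -> 17,651 participants in 2,832 groups
  intervention cost: $3,604,799 ($204 per participant)
  HALYs gained: 6.75
  healthcare cost offsets: $227,947
  averted incident cases: AN 1.2, BN 2.5, BED 3.7
  ICER excl. offsets: $534,193/HALY
  plane quadrant (incl. offsets): NE
```

The cascade line is the published recruitment funnel reproduced exactly:
10% of 569,295 students respond, 68.9% screen positive, 45% accept. The
health-gain and offset magnitudes are properties of the synthetic rate
curves (incidence peaks of order 10⁻⁴–10⁻³ per person-year), so they are
smaller than the published national estimates, which rest on unpublished
burden-of-disease inputs; directions, identities and orderings — not
these magnitudes — are what the test suite pins down.
`analysis/03_scenarios.py` and `analysis/04_psa.py` add the scenario
table and the 500-draw uncertainty analysis under `results/`.

The same pipeline is scriptable via a CLI:

```bash
edprev simulate-inputs --out inputs --seed 0
edprev run --inputs inputs --out run
edprev scenario s2_no_an --inputs inputs --out s2
edprev psa --inputs inputs --out psa --n-draws 500 --seed 1
```

## Layout

- `src/edprev/` — the library: `epi` (cohort engine), `effects` (decay
  and risk conversion), `cascade` (participants and costs), `economics`
  (HALYs, ICERs), `psa`, `scenarios`, `synthetic`, `config`, `inputs`,
  `pipeline`, `cli`.
- `analysis/` — numbered narrative drivers writing tables to `results/`.
- `docs/methods.md` — modelling assumptions, parameter defaults, and
  known limitations.
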