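# Methods

## Model structure

The model is a closed-cohort Markov chain with six states: controlled
asthma, three exacerbation states of increasing severity (OCS burst, ED
visit, hospitalization), asthma death, and other-cause death. The cohort
starts fully controlled at age 30 and advances in 4-week (28-day)
cycles until age 100 plus one absorbing cycle; with 365.25 days/year
that is 915 cycles. The structural assumptions are:

- **Competing risks, mortality first.** Each cycle, the per-cycle
  other-cause death probability (from the life table, constant-hazard
  conversion `1 − (1 − q_annual)^(28/365.25)`) is applied to every alive
  state; disease transitions act on the survivors. Some ordering must be
  fixed for rows to normalize; mortality-first is the common convention
  and the one used throughout, including in the independent test oracle.
- **One-cycle episode states.** OCS bursts, ED visits and
  hospitalizations are episodes much shorter than four weeks, so each
  exacerbation state is a tunnel: survivors either escalate one severity
  level or return to controlled in the next cycle. Row residuals always
  flow back to the controlled state.
- **Asthma death only after hospitalization**, with per-cycle
  probability 2×10⁻⁶ conditional on occupying the hospitalization state.
- **Treatment effects.** The exacerbation rate ratio (0.85) acts on the
  controlled → OCS-burst entry via the hazard-scale transform
  `p′ = 1 − (1−p)^RR`; the ED-visit effect (0.65) acts on the OCS-burst
  → ED escalation as an odds ratio (it is quoted as an OR in its source
  meta-analysis). A `ed_effect_scale: risk` configuration switch applies
  it on the hazard scale instead, for scenario analysis. Which
  transitions the two effects modify is itself an assumption; the
  chosen mapping (entry effect + escalation effect) is the one
  compatible with the effects' definitions (exacerbation rate; ED
  visits).
- **Adherence** enters drug cost only: maintenance dosing is 2
  doses/day × 62% adherence; as-needed use is 0.52 doses/day × 68%
  adherence, both priced at $53 per 120 doses. An optional
  `adherence_scales_effect` switch linearly interpolates the effect
  ratios toward the null at zero adherence, off by default because no
  effect-adherence mechanism is specified in the source inputs (the
  trial-observed effects already embody trial adherence).
- **Costs.** The $416/year controlled-management cost is charged to all
  alive states as background disease cost, prorated per cycle; episode
  costs ($94 mild / $191 moderate / $386 severe) are charged to the
  incident occupancy of the corresponding one-cycle exacerbation state,
  which equals episode incidence under the tunnel assumption.
- **Discounting and half-cycle correction.** The discount factor at
  cycle t is `(1+r)^(−t·28/365.25)` with r = 5%/yr (range 0–6%).
  Half-cycle correction integrates the discounted boundary payoff
  stream by the trapezoid rule; at r = 0 and full survival this makes
  total QALYs equal simulated person-years exactly.
- **Exacerbation-free survival** is a first-passage quantity, computed
  from a companion recursion in which any exacerbation entry (or death)
  is absorbing, reported at a 1-year landmark (13 cycles). The landmark
  is configurable (`efs_landmark_years`); a landmark is the only
  interpretation under which the quantity is a single per-arm
  probability.

## Mortality

All-cause mortality comes from a CSV life table (`age,qx[,sex]`; a sex
column is averaged because the cohort is not sex-stratified). When no
national table is supplied, a synthetic unisex Gompertz-Makeham table is
generated: `q(x) = 1 − exp(−(a + b·e^{c·x}))` with a = 5×10⁻⁴,
b = 3×10⁻⁵, c = 0.09 — constants chosen once to give a life expectancy
of ≈ 77 years at birth, matching an upper-middle-income population. The
final tabulated age is forced absorbing (q = 1) so the cohort is empty
at the horizon. The synthetic table is a smooth parametric stand-in: it
lacks infant/young-adult mortality structure, period shocks, and sex
differences, none of which materially affect a comparison whose arms
share the same background mortality.

## Sensitivity analyses

**One-way DSA.** Each of the 19 ranged inputs is set to its low and high
bound with everything else at base, and the full model is re-run. The
recorded outcome is incremental net monetary benefit at the configured
WTP ($19,000/QALY): the base case is dominant, so the ICER is undefined
there and cannot serve as a tornado metric; an ICER column is still
emitted for excursions where it is defined. Entries are sorted by swing.

**PSA distributions.** The published analysis names distribution
families but not fitting rules; the conventions here, applied uniformly:

| family | inputs | rule |
|---|---|---|
| beta | utilities | mean = base; (low, high) read as a central 95% interval (SD = range/3.92); moment matched |
| gamma | costs | mean pinned at base; shape fitted by least squares so the 2.5th/97.5th percentiles track (low, high) |
| rescaled beta | RR, OR | support = [low, high] (the 95% CI), mean = base, SD = range/4 |
| Dirichlet | transition rows | mean = base row; concentration set so the leading probability's SD = range/4 |

A beta for a ratio whose natural support is (0, ∞) is unusual; it is
implemented faithfully as the range-rescaled beta above (which cannot
exceed the CI), and the hazard-scale application makes any sampled value
well-defined. Adherence, dosing intensity and the discount rate are held
fixed in the PSA — they are outside the named families — but are varied
in the one-way analysis. Degenerate ranges become point masses.

**RNG protocol.** One root seed; iteration i uses the child stream
`SeedSequence(entropy=seed, spawn_key=(i,))` and samples parameters in
fixed registry order. Draws are therefore bit-reproducible, and
extending the iteration count or adding parameters never reshuffles
existing iterations. Invalid draws (none occur with the default
supports) would be redrawn, capped at 10× the iteration count.

**CE plane and CEAC.** Quadrants use the convention Q1 = costlier/more
effective, Q2 = cheaper/more effective, Q3 = cheaper/less effective,
Q4 = costlier/less effective, with zero deltas assigned to the
non-negative side. The CEAC reports `P(wtp·ΔQALY − ΔCost ≥ 0)` over a
grid from 0 to twice the WTP (steps of $1,000 at the default threshold).

## Problem sizes and numerics

The default deterministic run is 915 cycles per strategy (~2 ms); the
PSA default is 1,000 iterations, and the acceptance script and the
quadrant/CEAC acceptance tests use 10,000 iterations (~30 s on one CPU)
for tighter Monte-Carlo error. Row conservation holds to 10⁻¹⁰ over the
full horizon and the engine matches an independently coded pure-Python
matrix-power oracle to 10⁻¹² on 20-cycle problems. Probability
transforms use `log1p`/`expm1` forms to stay accurate near 0 and 1;
`q = 1` is pinned exactly. Ranged inputs printed with their bounds in
high-before-low order are canonicalized on load (validation reports a
normalization hint instead of silently accepting a reversed range).

## Scale of the base-case differences

With these inputs the between-arm differences are small per person-year
by construction: the largest utility gap between alive states is
0.92 − 0.74 = 0.18/year, and exacerbation-state occupancy differs
between arms by about one percentage point, so the QALY difference is
~8×10⁻⁴ per person-year (~0.016 over a discounted lifetime). The cost
difference (~$161/person-year) is dominated by the deterministic
drug-cost gap between 2 doses/day × 62% and 0.52 doses/day × 68%. The
qualitative findings — dominance of the as-needed strategy, a
quadrant-2-heavy CE plane, near-certain cost-effectiveness at every
threshold, and robustness of the NMB sign to every one-way excursion —
are the quantities the acceptance script recomputes.

## Known limitations

- The cohort is not sex- or severity-stratified; mild-to-moderate
  persistent asthma is treated as homogeneous.
- No treatment switching, waning of effect, or microsimulation mode.
- The maintenance arm's inhaler is priced with the same $53/120-dose
  unit as the combination inhaler (no separate plain-ICS price is
  available among the inputs).
- Transition probabilities are age-invariant; only background mortality
  is age-dependent.
- The synthetic life table approximates, not reproduces, any national
  table; results that depend on its exact level (person-years,
  discounted totals) shift slightly under a different table, while
  between-arm differences are insensitive to it.
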