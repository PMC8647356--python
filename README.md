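# asthmacea

A probabilistic Markov cohort model for the cost-utility of **as-needed
low-dose budesonide-formoterol** versus **daily maintenance inhaled
corticosteroids (ICS)** in mild-to-moderate persistent asthma, from a
middle-income-country (Colombian) payer setting. It is written for health
economists and methodologists who want a transparent, scriptable,
fully-tested implementation of this class of decision model: base-case
incremental analysis, one-way deterministic sensitivity analysis
(tornado), and second-order Monte-Carlo probabilistic sensitivity
analysis with cost-effectiveness-plane quadrants and acceptability
curves.

## The model

A closed cohort moves between six mutually exclusive states in 4-week
cycles over a lifetime horizon (ages 30–100 by default):

```
CONTROLLED ──p₁──▶ OCS_BURST ──p₂──▶ ED_VISIT ──p₃──▶ HOSPITALIZATION ──p₄──▶ ASTHMA_DEATH
     ▲__________________|________________|__________________|
                (survivors return after one cycle)          any alive state ──qₓ──▶ OTHER_DEATH
```

Exacerbation states are one-cycle episode states; asthma death is
reachable only from hospitalization; all-cause death (from an
age-indexed life table, applied first each cycle as a competing risk)
can occur from any alive state. Base-case inputs: p₁ = 0.11 per cycle,
p₂ = 0.02, p₃ = 0.0117, p₄ = 2×10⁻⁶; annual utilities 0.92 / 0.86 /
0.83 / 0.74; episode costs $94 / $191 / $386, background management
$416/yr, inhaler $53 per 120 doses.

The as-needed arm applies a rate ratio RR = 0.85 to the exacerbation
entry probability, `p′ = 1 − (1 − p)^RR`, and an odds ratio OR = 0.65 to
the OCS-burst → ED escalation, `odds′ = OR · p/(1 − p)`. Drug cost is
2 doses/day × 62% adherence (maintenance) versus 0.52 doses/day × 68%
adherence (as-needed). Costs and QALYs are discounted at 5%/yr with
half-cycle (trapezoid) correction; the decision metric is net monetary
benefit at a willingness-to-pay of $19,000/QALY (≈ 3× GDP per capita).

The PSA samples utilities from moment-matched beta distributions, costs
from gamma distributions fitted to the 95% range, effect ratios from
betas rescaled to their confidence intervals, and each transition row
from a Dirichlet — 1,000 iterations by default, counter-seeded for
bit-exact reproducibility.

## Worked example

```python
import asthmacea as ac

params = ac.base_case_parameters()
table = ac.synthetic_life_table(0, params.settings.horizon_age_years)

_, as_needed = ac.run_strategy(params, table, ac.Strategy.AS_NEEDED_ICS_FORMOTEROL)
_, maintenance = ac.run_strategy(params, table, ac.Strategy.MAINTENANCE_ICS)
result = ac.incremental_analysis(as_needed, maintenance,
                                 params.settings.wtp_per_qaly)
print(result.summary_text())

psa = ac.run_psa(params, table, iterations=1000, seed=2021)
print("quadrant 2 share:", psa.quadrant_proportions[1])
print("CEAC minimum:   ", psa.ceac["probability"].min())
```

prints

```
incremental cost (USD):        -2954.54
incremental QALYs:             +0.01554
incremental cost / person-yr:  -160.85
incremental QALYs / person-yr: +0.00085
dominance:                     intervention_dominant
ICER (USD/QALY):               not reported: intervention dominates
NMB at WTP 19,000:         +3249.86
quadrant 2 share: 0.72
CEAC minimum:    0.996
```

Read: under the base-case inputs, reliever-only budesonide-formoterol
costs $2,954 less per patient over a discounted lifetime and yields
0.016 more QALYs, i.e. it **dominates** maintenance ICS (no ICER is
reported for a dominant strategy). 72% of PSA draws land in quadrant 2
of the cost-effectiveness plane (cheaper *and* more effective), and the
strategy is cost-effective with probability ≥ 0.99 at every
willingness-to-pay threshold.

The same analyses are available from the shell:

```sh
asthma-cea run-base-case   --out runs/base
asthma-cea run-sensitivity --out runs/sens --mode both --iterations 1000 --seed 2021
asthma-cea make-fixtures   --out fixtures --seed 0
```

Every run directory gets a `manifest.json` (resolved configuration,
seed, version, input checksums) sufficient to reproduce it byte-for-byte.

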