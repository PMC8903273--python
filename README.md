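# spmscea

Health-economic modelling of disease-modifying therapy (DMT) for secondary
progressive multiple sclerosis (SPMS) from the Italian National Health
Service perspective. The package implements two linked analyses:

1. **Cost-effectiveness analysis (CEA).** An annual-cycle Markov cohort
   model on the Expanded Disability Status Scale (EDSS 0–9, each level split
   into on- and off-treatment states, plus death) compares siponimod with
   interferon beta-1b over a lifetime horizon. Treatment efficacy enters as
   a hazard ratio on 6-month confirmed disability progression (CDP-6),
   applied to the placebo-arm transition matrix on the rate scale,
   `p' = 1 − (1 − p)^HR`; relapse rates are scaled by a relative risk.
   Outcomes are discounted costs (€), life-years and QALYs, summarised as
   the incremental cost-effectiveness ratio ICER = ΔC/ΔE and net monetary
   benefit NMB = λ·ΔE − ΔC at λ = €40,000/QALY. One-way (tornado) and
   probabilistic sensitivity analyses, cost-effectiveness acceptability
   curves and a CDP-3 efficacy scenario are included.
2. **Budget-impact analysis (BIA).** A 3-year comparison of total payer
   expenditure between market scenarios with and without siponimod, over the
   eligible population derived from a multiplicative epidemiology funnel
   (Italian population → MS prevalence → SPMS → age/EDSS 3–6.5 → active →
   treated → siponimod-eligible).

It is written for health-economics researchers and HTA analysts who want a
tested, scriptable re-implementation of this model class rather than a
spreadsheet. Published inputs (cohort characteristics, relapse
probabilities, EDSS mortality multipliers, utilities, management and drug
costs, treatment-effect estimates, the epidemiology funnel) ship in a
packaged configuration file; inputs that were never published — the
placebo-arm EDSS transition matrix, the background life table, the baseline
discontinuation probability, adverse-event costs and year-by-year market
shares — are generated by a seeded synthetic-data module and are clearly
labelled as stand-ins (see `docs/methods.md`). Headline monetary results
therefore depend on those stand-ins and will differ from any specific
published figure.

## Worked example

```bash
spmscea run-cea --seed 0 --out results/
# dC=84,441 EUR  dQALY=0.907  ICER=93,078 EUR/QALY  NMB=-48,153 EUR (WTP 40,000)

spmscea run-bia --seed 0 --out results/
# eligible=5,827  y1: +1,221,704  y2: +1,715,624  y3: -152,481  total +2,784,847 EUR (+0.74%)
```

The first command runs both strategies through the lifetime cohort model on
the packaged inputs: siponimod adds 0.907 QALYs at an extra cost of €84,441
per patient, an ICER of €93,078 per QALY gained — above the €40,000
willingness-to-pay, hence the negative net monetary benefit on these
synthetic natural-history inputs. The second command reports the budget
difference from siponimod market entry: the eligible population is 5,827
patients, siponimod uptake grows from 405 to 2,236 treated patients, and the
budget impact is positive in years 1–2 (early uptake displaces cheaper
interferon beta-1b and newly started patients carry first-year monitoring
costs) and slightly negative in year 3 (late uptake displaces the more
expensive ocrelizumab), for a +0.74% total over three years.

Library use mirrors the CLI:

```python
from spmscea import load_and_validate, run_cea

loaded = load_and_validate(seed=0)       # packaged defaults
print(run_cea(loaded.params).comparison)
```

Other subcommands: `run-owsa` (tornado on NMB), `run-psa` (probabilistic
sensitivity analysis + CEAC), `run-cdp3` (3-month-confirmed-progression
efficacy scenario) and `gen-synthetic` (write the synthetic input bundle to
disk). All accept `--config` to supply your own YAML parameter file — for
example one pointing `transition_matrix: {csv: ...}` at a real trial matrix.

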