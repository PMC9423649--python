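# htncea

Societal-perspective cost-effectiveness analysis of treating hypertension
to guideline blood-pressure targets (ISH 2020: <130/80 mmHg under 65,
<140/90 mmHg at 65+), built as a tested, reusable Python pipeline for
health economists and modellers working in low-income settings.

The package couples five pieces:

- **Markov cohort model** — a discrete-time state-transition model of
  treated vs untreated hypertension: entry states settle into
  controlled/uncontrolled blood pressure; acute CVD events (MI, unstable
  angina, stable angina, stroke, TIA) are one-cycle *tunnel states* whose
  survivors move to chronic post-event states; death is absorbing. The
  default horizon is 80 one-year cycles.
- **DALY accounting** — GBD-2010 conventions:
  `YLD = cases × duration × disability weight`,
  `YLL = deaths × life expectancy at age of death`,
  `DALY(c,s,a,t) = YLL + YLD`, no time discounting and no age weights,
  with multiplicative comorbidity adjustment
  `DW₁₊₂ = 1 − (1 − DW₁)(1 − DW₂)` (same form for prevalences and
  per-person YLD rates).
- **Human-capital costing** — lost productive years monetized at twelve
  months of the sex-specific wage mix,
  `loss = years × 12 × (e·income + (1 − e)·wage)`, with employment rates
  0.88 (men) / 0.33 (women), employed income 2,059.078 ETB/month and the
  daily-laborer wage 796 ETB/month; premature mortality chains through
  `Z = max(LE − age at death, 0)` and `Xᵢ = Z × deaths`. Currency is ETB
  internally, converted at 43.5 ETB/USD (January 2021) for reporting;
  costs discount at 3 %/year (6 % in sensitivity runs).
- **CE metrics** — ACER (total cost / DALYs averted vs the null),
  ICER (incremental cost / incremental DALYs, with explicit dominance
  flags), net monetary benefit `NMB = wtp × ΔE − ΔC`, and WHO
  GDP-multiple thresholds (GDP per capita 936.30 USD: very cost-effective
  below 1×, cost-effective 1–3×, plus the stricter half-GDP rule at
  468.15 USD).
- **Sensitivity analysis** — one-way deterministic runs over printed
  ranges (prevalence 19.6–41.9 %, control rate 0.50–0.70, ±20 % drug
  cost, 6 % discounting), scenario transforms (adherence, 1-year BP lag,
  pill-taking disutility 0.049, linearly increasing risk), and a
  1000-draw probabilistic analysis with empirical 95 % uncertainty
  intervals and cost-effectiveness acceptability curves.

A synthetic-data module generates every input the pipeline needs —
stratified cohorts (treatment coverage 28.4 %), a 407-record facility
cost survey allocated 212/107/88 across three hospitals, and PSA draw
tables — plus the single-population-proportion sample-size calculator
(the chain 185 → 203.5 → 407 at p = 0.14, Z = 1.96, d = 0.05, 10 %
non-response, design effect 2).

## Worked example

```python
import htncea as h

ps = h.default_parameters()

# monetize 10,121 productive years lost to premature male deaths
etb = h.productivity_loss_annual(10_121, "male", ps.costs)
usd = h.convert_currency(etb, 43.5)
print(round(etb, 2), round(usd, 2))
# 231670739.35 5325764.12

# run the two-arm model on the default book
res = h.evaluate(ps)
c = res.comparisons["40-65"]
print(round(c.delta_dalys, 2), c.dominance.value, round(res.acer, 2))
# 207197.59 none 986.79
```

The first two numbers are the annual productivity loss of those years in
2021 ETB and USD. The model run reports, for the 40–64 age band, about
207,198 DALYs averted by treatment over the 80-year horizon with no
dominance (treatment costs more than it saves on this parameter book),
and an average cost-effectiveness ratio of 986.79 USD per DALY averted —
just above one GDP per capita.

The same pipeline is scriptable from a shell:

```sh
htn-cea run --config overrides.yaml --out results/ --psa-draws 1000
htn-cea synth --kind patients --seed 3 --out patients.csv
```

`htn-cea run` prints the overall ICER, ACER, NMB and threshold class and
writes `arm_outcomes.csv`, `comparisons.csv`, `icers.csv`, `summary.csv`
(plus `psa_draws.csv`/`ceac.csv` when a PSA is requested).

Note that age-specific transition probabilities and the BP dose-response
table ship as documented placeholder defaults of realistic magnitude (see
`docs/methods.md`); model-level outputs on the default book are
illustrative, while the costing, burden and CE arithmetic are exact.

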