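# Methods

## Model structure

The engine is a discrete-time cohort state-transition (Markov) model with
fifteen states: two entry states (`untreated`, `treated`), two steady
blood-pressure states (`controlled`, `uncontrolled`), five acute-event
tunnel states (MI, unstable angina, stable angina, stroke, TIA), five
matching post-event states, and absorbing `dead`. Entrants settle into
the controlled/uncontrolled pool in their first cycle: a treated entrant
reaches control with probability equal to the BP control rate, an
untreated entrant lands in the uncontrolled pool (the null arm is run
with control rate 0). Acute events are tunnels — survivors move to the
post-event state the next cycle and remain there until death; a person is
censored at the first event (no second-event pathways). The horizon is 80
one-year cycles, enough to extinguish a cohort entering at age 30+.

Death risks combine multiplicatively:
`q = 1 − (1 − q_background)(1 − q_disease)`. The uncontrolled state
carries excess all-cause mortality `(RR − 1) × q_background` with
RR = 3.13, the mortality relative risk of the high-blood-pressure group;
the all-hypertensives mortality ratio (1.39) is retained in the book but
describes a treated/untreated mixture and is not used for the
uncontrolled state. Event states apply event-specific case fatality on
top of background mortality; post-event states carry chronic excess
mortality.

Treatment acts through relative risks on event probabilities (RR 0.78
for CHD events, 0.62 for cerebrovascular events), applied to the
controlled fraction only by default (a flag extends partial benefit to
treated-uncontrolled patients; default off because the evidence base
measures controlled BP). Adherence `a` scales the risk *reduction*:
effective RR = 1 − a(1 − RR). A lag of `k` years withholds the risk
reduction for the first `k` cycles. Because the transition matrix depends
on the scenario only through its control rate and effective RRs, setting
RR = 1 with equal control rates makes the two arms bit-identical — a
property the tests exploit.

No half-cycle correction is applied: occupancy is counted at cycle start,
both for person-years (YLD) and for costs. This overstates person-time by
up to half a cycle relative to the lifetable convention; with an 80-cycle
horizon the effect on incremental quantities is second-order, and the
tally layer isolates the convention so it can be switched.

Re-entry of normotensives into the hypertensive pool is modelled as an
annual probability parameter, default 0: the phenomenon is asserted
qualitatively in the source literature but never quantified.

## Ten-year risks and annualization

First-event risks enter as 10-year probabilities and are annualized as
`p₁ = 1 − (1 − p₁₀)^(1/10)` (constant hazard). A scenario mode replaces
this with ten linearly increasing annual probabilities `p_k = k·s`, the
slope solved by root-finding so the cumulative 10-year risk matches
`p₁₀` to 1e−9.

## Blood-pressure response

Expected on-treatment SBP is a lookup on (baseline SBP, number of
standard-dose drugs) with linear interpolation between rows. The default
table is a placeholder anchored at one published endpoint — a baseline of
≥185 mmHg on four standard-dose drugs reaches about 143 mmHg, above the
<140 target — with intermediate rows chosen to be monotone in both axes
(more drugs never raise SBP, higher baselines never lower it). Outside
the table range the function raises unless clamping is requested.

## Burden accounting

GBD-2010 simplified conventions: prevalence YLDs
(person-years in state × disability weight), no discounting of health
outcomes, no age weights. Disability weights: untreated hypertension
0.323, treated-and-controlled 0.171, hypertensive heart disease 0.246
(0.201–0.300); acute-event and sequela weights are GBD-style placeholders
(acute MI 0.432, stroke 0.552, post-stroke 0.320, …). The entry cycle
uses the untreated weight in both arms, since it precedes any BP control.
The pill-taking disutility (0.049, CI 0.031–0.072) is folded into
treated-state weights multiplicatively via `1 − (1 − w)(1 − d)` rather
than added, keeping weights inside [0,1].

YLLs anchor to a normative residual-life-expectancy table keyed by age at
death (a placeholder lifetable of realistic magnitude, e.g. ~10 remaining
years for a man dying at 70), interpolated linearly; when no table is
configured the fallback is `max(LE_at_birth − age, 0)` with LE 66.7 years
(men) / 70.4 (women). The productivity-loss chain deliberately keeps the
latter convention (`Z = max(LE − age, 0)`) because that is how the
published costing formulas are defined; deaths above the life expectancy
therefore cost nothing while still contributing (table-based) YLLs.

Comorbidity combines pairwise and multiplicatively
(`P₁₊₂ = 1 − (1 − P₁)(1 − P₂)`, same for weights and per-person YLD
rates); with more than two conditions the fold proceeds in
descending-prevalence order — the formula is associative, so the order is
a reporting convention, not a numerical choice. The YLD-rate combinator
rejects inputs above 1: it is defined for per-person rates, and passing
absolute year totals is a category error the API refuses.

## Costing

Societal perspective, bottom-up. Treated person-years accrue: annual
antihypertensive cost 14.07 USD (a standard-dose regimen priced from the
unit-price book plus monthly dispensing; ±20 % band for sensitivity),
twelve outpatient visits at 0.49 USD, programmatic overhead, transport
(42 ETB/visit) and patient time (employed day wage 97 ETB mixed with the
daily-laborer wage 26.53 ETB at the sex-specific employment rate). Acute
events carry one-time costs (MI 1,040 USD, stroke 940 USD, …); post-event
states carry annual follow-up costs (IHD 45, stroke 67 USD). Both arms
accrue indirect costs: morbidity years and premature-mortality years
monetized by the human-capital formula. Program overhead per treated
person-year is the study-area program budget (1,024,759.24 USD/year,
3 % of the national 34,158,641.24) spread over the 750,533-person
hypertensive pool (~1.37 USD) — the printed per-person figure of
128.28 USD/year has no derivable denominator and is kept in the book only
for reproduction of the printed scaling arithmetic (128.28 / 12 = 10.69).

Costs discount at 3 %/year (base) or 6 % (sensitivity); DALYs are
undiscounted by default, with a flag for discounted-outcome runs. All
internal arithmetic is unrounded; two-decimal rounding happens only at
the reporting layer.

## CE metrics and orientation

The comparison stores both orientations. Result tables print incremental
quantities as comparator minus intervention (untreated − treated), so a
positive incremental cost is money the untreated arm loses; the
conventional intervention-minus-comparator deltas are exposed alongside,
and a dominance flag (dominant / dominated / none) always accompanies any
ratio. ICERs classify against 1×/3× GDP per capita (936.30 / 2,808.90
USD, both endpoints inside the cost-effective band) or the half-GDP rule
(468.15 USD); negative ratios from dominant results are reported with
their flag, not a threshold label.

## Uncertainty

CI-to-distribution fitting uses percentile matching under an exact mean
constraint: beta for [0,1] quantities (parametrized mean ×
concentration), gamma for costs (mean / shape), lognormal for relative
risks (σ free, μ tied to the mean); the single free shape parameter
minimizes squared 2.5th/97.5th-percentile mismatch (bounded scalar
optimization, tolerance 1e−10 on the knob). A fit whose residual exceeds
20 % of the interval width raises rather than silently misrepresenting
the interval. Point masses are allowed everywhere.

The PSA samples the included parameters independently (RR of CHD and of
stroke, drug cost, unemployed wage, hypertensive-heart-disease weight) —
1000 draws by default, explicit seed (default 20200901, arbitrary but
fixed). The BP control rate's printed 0.50–0.70 range is a deterministic
bound, not a 95 % interval (its mean sits on the upper endpoint), so it
is varied in the one-way DSA instead of the PSA. Uncertainty intervals
are empirical 2.5/97.5 percentiles with linear interpolation between
order statistics; the CEAC is the fraction of draws with positive NMB at
each willingness-to-pay.

## Synthetic data

The generators emulate the study's input structure: a stratified cohort
with band prevalences (23 % at 30–40, 41.9 % at 50+), 28.4 % treatment
coverage and a 70 % control rate among the treated; a 407-patient cost
survey allocated exactly 212/107/88 across three facilities with
Poisson(10) visit counts truncated to [1,12], categorical drug choice,
random laboratory panels and rare hospitalizations, every cost equal to
quantity × book price; and long-format PSA draw tables. They reproduce
the *shape* and bookkeeping invariants of real survey data — not its
correlation structure, measurement error, or missingness — so passing
tests demonstrate pipeline correctness, not epidemiological calibration.

The sample-size rule follows the published arithmetic: round the base
`Z²p(1−p)/d²` to the nearest integer (185 at p = 0.14), keep the
non-response intermediate fractional (203.5), apply the design effect and
round the final value up (407).

## Problem sizes and known limitations

Default runs use 6 strata × 2 arms × 80 cycles of a 15-state chain
(~10 ms per full evaluation); tests shorten horizons to 5–20 cycles where
the check is structural, and the PSA tests use tens of draws since every
draw exercises the identical code path as the thousandth.

Age-specific transition probabilities, the full lifetable and the BP
dose-response grid are placeholder defaults: model-level outputs (overall
ICER, NMB, deaths averted) on the default book are illustrative and
should be re-based on a jurisdiction's own parameter book before use.
The costing, burden and CE arithmetic, by contrast, are exact
implementations of their published formulas and are what the acceptance
script verifies. Other simplifications: no treatment-resistant
hypertension, no second CVD events, heart failure folded into post-event
cost/mortality modifiers rather than a separate state, independence of
PSA parameters, and no EVPI computation.
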