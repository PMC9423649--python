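"""Cost-effectiveness metrics and the end-to-end evaluation pipeline.

Metrics follow generalized CEA practice: the average cost-effectiveness
ratio (ACER) divides the intervention's total cost by DALYs averted versus
the null (no-treatment natural history); the ICER divides incremental cost
by incremental health gain between the two arms; net monetary benefit is
wtp x DALYs averted - incremental cost incurred.  Classification uses the
WHO GDP-multiple rule (very cost-effective below 1x GDP per capita per DALY
averted, cost-effective from 1x to 3x, otherwise not) or the stricter
half-GDP interim rule.

Orientation: the study's result tables print incremental quantities as
comparator minus intervention (untreated minus treated), so a positive
``delta_cost`` is money the untreated arm loses and a positive
``delta_dalys`` is DALYs averted by treatment.  :class:`CEComparison`
stores this table orientation and also exposes the conventional
intervention-minus-comparator deltas, plus an explicit dominance flag so
cost-saving, health-gaining results are never reported as bare ratios.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import costing
from .burden import combine_dw
from .markov import (
    EVENT_STATES,
    POST_STATES,
    STATES,
    TreatmentScenario,
    build_transition_matrix,
    run_cohort,
)
from .params import ParameterSet, band_label

__all__ = [
    "Dominance",
    "ThresholdClass",
    "CEComparison",
    "NMBResult",
    "incremental",
    "icer",
    "acer",
    "nmb",
    "classify",
    "ArmOutcome",
    "CEResult",
    "run_arm",
    "evaluate",
    "write_tables",
]


class Dominance(str, enum.Enum):
    NONE = "none"
    INTERVENTION_DOMINANT = "intervention_dominant"
    INTERVENTION_DOMINATED = "intervention_dominated"


class ThresholdClass(str, enum.Enum):
    VERY_COST_EFFECTIVE = "very_cost_effective"
    COST_EFFECTIVE = "cost_effective"
    NOT_COST_EFFECTIVE = "not_cost_effective"


@dataclass
class CEComparison:
    """Two-arm comparison in the table orientation (untreated minus treated)."""

    cost_treated: float
    cost_untreated: float
    dalys_treated: float
    dalys_untreated: float
    label: str = ""

    @property
    def delta_cost(self) -> float:
        """Incremental cost, comparator minus intervention (table orientation)."""
        return self.cost_untreated - self.cost_treated

    @property
    def delta_dalys(self) -> float:
        """Incremental DALYs averted by the intervention."""
        return self.dalys_untreated - self.dalys_treated

    @property
    def incremental_cost_incurred(self) -> float:
        """Conventional orientation: intervention minus comparator cost."""
        return self.cost_treated - self.cost_untreated

    @property
    def dominance(self) -> Dominance:
        saves_money = self.incremental_cost_incurred < 0
        averts_dalys = self.delta_dalys > 0
        if saves_money and averts_dalys:
            return Dominance.INTERVENTION_DOMINANT
        if (not saves_money and self.incremental_cost_incurred > 0
                and self.delta_dalys < 0):
            return Dominance.INTERVENTION_DOMINATED
        return Dominance.NONE


@dataclass
class NMBResult:
    wtp: float
    delta_dalys: float
    incremental_cost_incurred: float

    @property
    def nmb(self) -> float:
        return self.wtp * self.delta_dalys - self.incremental_cost_incurred


def incremental(
    cost_treated: float,
    cost_untreated: float,
    dalys_treated: float,
    dalys_untreated: float,
    label: str = "",
) -> CEComparison:
    """Assemble a two-arm comparison with the table orientation of deltas."""
    return CEComparison(cost_treated, cost_untreated, dalys_treated,
                        dalys_untreated, label)


def icer(c: CEComparison) -> float:
    """Incremental cost per DALY averted.

    The ratio is delta_cost / delta_dalys in the table orientation, which
    equals the conventional incremental-cost-incurred over DALYs-lost ratio.
    Callers should report :attr:`CEComparison.dominance` alongside.
    """
    if c.delta_dalys == 0:
        raise ZeroDivisionError("ICER undefined: incremental DALYs are zero")
    return c.delta_cost / c.delta_dalys


def acer(total_cost: float, dalys_averted: float) -> float:
    """Average cost-effectiveness ratio versus doing nothing."""
    if dalys_averted <= 0:
        raise ValueError("ACER requires positive DALYs averted")
    return total_cost / dalys_averted


def nmb(wtp: float, c: CEComparison) -> NMBResult:
    """Net monetary benefit at a willingness-to-pay threshold."""
    if wtp < 0:
        raise ValueError("willingness-to-pay must be non-negative")
    return NMBResult(wtp, c.delta_dalys, c.incremental_cost_incurred)


def classify(icer_value: float, thresholds, rule: str = "gdp_multiple") -> ThresholdClass:
    """Label an ICER against GDP-multiple or half-GDP thresholds.

    GDP-multiple rule: below 1x GDP per capita -> very cost-effective; from
    1x to 3x inclusive -> cost-effective; above 3x -> not cost-effective.
    Half-GDP rule: at or below half GDP per capita -> cost-effective,
    otherwise not.
    """
    if not np.isfinite(icer_value):
        raise ValueError("ICER must be finite to classify")
    if rule == "gdp_multiple":
        lo, hi = thresholds.ce_band
        if icer_value < lo:
            return ThresholdClass.VERY_COST_EFFECTIVE
        if icer_value <= hi:
            return ThresholdClass.COST_EFFECTIVE
        return ThresholdClass.NOT_COST_EFFECTIVE
    if rule == "half_gdp":
        if icer_value <= thresholds.half_gdp:
            return ThresholdClass.COST_EFFECTIVE
        return ThresholdClass.NOT_COST_EFFECTIVE
    raise ValueError(f"unknown threshold rule {rule!r}")


# --------------------------------------------------------------------------
# Pipeline: parameter book -> two-arm model run -> comparisons
# --------------------------------------------------------------------------

_IDX = {s: i for i, s in enumerate(STATES)}
_POST_OF = dict(zip(EVENT_STATES, POST_STATES))


@dataclass
class ArmOutcome:
    """Aggregate outcomes of one scenario arm for one stratum."""

    sex: str
    band: str
    cohort: float
    person_years: float
    deaths: float
    yll: float
    yld: float
    cost_usd: float  # discounted, societal

    @property
    def dalys(self) -> float:
        return self.yll + self.yld


@dataclass
class CEResult:
    """Full pipeline output: per-stratum arm outcomes and comparisons."""

    arms: pd.DataFrame          # one row per (sex, band, arm)
    comparisons: dict[str, CEComparison]
    overall: CEComparison
    acer: float
    icer_overall: float
    nmb_at_wtp: float
    params: ParameterSet = field(repr=False, default=None)

    def comparison_table(self) -> pd.DataFrame:
        rows = []
        for label, c in self.comparisons.items():
            try:
                r = icer(c)
            except ZeroDivisionError:
                r = np.nan
            rows.append(
                {
                    "group": label,
                    "cost_treated": c.cost_treated,
                    "cost_untreated": c.cost_untreated,
                    "dalys_treated": c.dalys_treated,
                    "dalys_untreated": c.dalys_untreated,
                    "incremental_cost": c.delta_cost,
                    "incremental_dalys": c.delta_dalys,
                    "icer": r,
                    "dominance": c.dominance.value,
                }
            )
        return pd.DataFrame(rows)


def _prevalence_for_band(params: ParameterSet, lo: float, hi: float) -> float:
    """Overlap-weighted hypertension prevalence for a model age band."""
    total, weight = 0.0, 0.0
    for key, frac in params.epidemiology.prevalence_by_band.items():
        b_lo, b_hi = (float(x) for x in key.split("-"))
        ov = max(0.0, min(hi, b_hi) - max(lo, b_lo))
        if ov > 0:
            total += ov * frac
            weight += ov
    return total / weight if weight else params.epidemiology.mean_prevalence


def _state_weights(params: ParameterSet, treated_arm: bool) -> np.ndarray:
    """Disability weight per model state for YLD accounting."""
    dw = params.disability_weights
    w = np.zeros(len(STATES))
    w_controlled = dw.treated_controlled
    w_uncontrolled = dw.untreated
    if treated_arm and params.treatment.pill_disutility_on:
        pill = dw.pill_disutility.mean
        w_controlled = combine_dw(w_controlled, pill)
        w_uncontrolled = combine_dw(w_uncontrolled, pill)
    # the entry cycle precedes any blood-pressure control
    w[_IDX["untreated"]] = dw.untreated
    w[_IDX["treated"]] = dw.untreated
    w[_IDX["controlled"]] = w_controlled
    w[_IDX["uncontrolled"]] = w_uncontrolled if treated_arm else dw.untreated
    for s, ws in dw.state_weights.items():
        w[_IDX[s]] = ws
    return w


def run_arm(
    params: ParameterSet, stratum, treated: bool, cohort: float | None = None
) -> ArmOutcome:
    """Run one scenario arm for one stratum and aggregate burden and cost."""
    epi = params.epidemiology
    tre = params.treatment
    scenario = TreatmentScenario(
        label="treated" if treated else "untreated",
        control_rate=epi.control_rate.mean if treated else 0.0,
        rr_events={
            "event_MI": tre.rr_chd.mean,
            "event_UA": tre.rr_chd.mean,
            "event_SA": tre.rr_chd.mean,
            "event_stroke": tre.rr_stroke.mean,
            "event_TIA": tre.rr_stroke.mean,
        },
        adherence=tre.adherence,
        lag_years=tre.lag_years,
    )
    if cohort is None:
        cohort = stratum.population * _prevalence_for_band(
            params, stratum.age_lo, stratum.age_hi
        )
    init = np.zeros(len(STATES))
    init[_IDX["treated" if treated else "untreated"]] = cohort

    cycles = params.cycles
    time_varying = (
        tre.lag_years > 0 or params.transitions.risk_mode != "constant"
    )
    if time_varying:
        mats = [
            build_transition_matrix(stratum, scenario, params, cycle=k)
            for k in range(cycles)
        ]
        trace = run_cohort(mats, init, cycles, stratum=stratum)
    else:
        M = build_transition_matrix(stratum, scenario, params, cycle=0)
        trace = run_cohort(M, init, cycles, stratum=stratum)

    occ = trace.occupancy
    costs = params.costs
    start_occ = occ[:-1]                       # cycle-start convention
    deaths_per_cycle = np.diff(occ[:, _IDX["dead"]])
    event_cols = [_IDX[e] for e in EVENT_STATES]
    incident = occ[1:, event_cols]            # inflow into tunnel states

    # ---- burden ----------------------------------------------------------
    w = _state_weights(params, treated)
    yld_per_cycle = start_occ @ w             # person-years x weight, no discounting
    yld_total = float(yld_per_cycle.sum())
    le = epi.life_expectancy[stratum.sex]
    age_at_death = np.minimum(stratum.midpoint + np.arange(1, cycles + 1), 100.0)
    residual_le = epi.residual_life_expectancy(stratum.sex, age_at_death)
    yll_total = float(np.sum(deaths_per_cycle * residual_le))

    # ---- costs (USD per cycle, then discounted) --------------------------
    treated_states = [_IDX[s] for s in ("treated", "controlled", "uncontrolled")]
    on_treatment_py = start_occ[:, treated_states].sum(axis=1) if treated else 0.0
    direct = np.zeros(cycles)
    if treated:
        # program costs are population-level: spread the study-area program
        # budget over the hypertensive pool rather than per treated patient
        program_per_py = (
            costs.program_cost_study_area / costs.hypertensive_population
            if costs.hypertensive_population > 0
            else 0.0
        )
        per_py = (
            costs.annual_drug_cost.mean
            + costing.annual_outpatient_cost(costs.outpatient_visit_cost)
            + program_per_py
        )
        # patient time cost per visit mixes the employed day wage with the
        # daily-laborer wage at the sex-specific employment rate
        e = costs.employment_rate[stratum.sex]
        time_cost_per_visit = (
            e * costs.daily_wage_patient + (1.0 - e) * costs.daily_wage_unemployed
        )
        nonmedical_etb_per_py = 12.0 * (
            costs.transport_cost_per_visit + time_cost_per_visit
        )
        per_py += nonmedical_etb_per_py / costs.exchange_rate[2021]
        direct = direct + per_py * on_treatment_py
    for j, ev in enumerate(EVENT_STATES):
        direct = direct + incident[:, j] * costs.event_costs.get(ev, 0.0)
    post_py = {s: start_occ[:, _IDX[s]] for s in POST_STATES}
    for s, py in post_py.items():
        direct = direct + py * costs.post_event_annual_costs.get(s, 0.0)

    # indirect productivity losses, monetized in ETB then converted;
    # the mortality chain uses the printed convention Z = max(LE - age, 0)
    z_per_cycle = np.maximum(le - age_at_death, 0.0)
    xi_per_cycle = deaths_per_cycle * z_per_cycle
    indirect_etb = np.array(
        [
            costing.productivity_loss_annual(y + x, stratum.sex, costs)
            for y, x in zip(yld_per_cycle, xi_per_cycle)
        ]
    )
    indirect = indirect_etb / costs.exchange_rate[2021]

    total_stream = direct + indirect
    cost_usd = costing.discount_stream(total_stream, costs.discount_rate)

    return ArmOutcome(
        sex=stratum.sex,
        band=stratum.band,
        cohort=float(cohort),
        person_years=float(start_occ[:, [_IDX[s] for s in STATES if s != "dead"]].sum()),
        deaths=float(deaths_per_cycle.sum()),
        yll=yll_total,
        yld=yld_total,
        cost_usd=float(cost_usd),
    )


def evaluate(params: ParameterSet) -> CEResult:
    """Run the full treated-vs-null comparison over every stratum."""
    records = []
    outcomes: dict[tuple[str, str, str], ArmOutcome] = {}
    for stratum in params.strata:
        for treated in (True, False):
            out = run_arm(params, stratum, treated)
            arm = "treated" if treated else "untreated"
            outcomes[(stratum.sex, stratum.band, arm)] = out
            records.append(
                {
                    "sex": out.sex,
                    "age_band": out.band,
                    "arm": arm,
                    "cohort": out.cohort,
                    "person_years": out.person_years,
                    "deaths": out.deaths,
                    "yll": out.yll,
                    "yld": out.yld,
                    "dalys": out.dalys,
                    "cost_usd": out.cost_usd,
                }
            )
    arms = pd.DataFrame(records)

    comparisons: dict[str, CEComparison] = {}
    for (lo, hi) in params.age_bands:
        band = band_label(lo, hi)
        sub = arms[arms["age_band"] == band]
        t = sub[sub["arm"] == "treated"]
        u = sub[sub["arm"] == "untreated"]
        comparisons[band] = incremental(
            t["cost_usd"].sum(), u["cost_usd"].sum(),
            t["dalys"].sum(), u["dalys"].sum(), label=band,
        )
        for sex in ("male", "female"):
            ts = t[t["sex"] == sex]
            us = u[u["sex"] == sex]
            comparisons[f"{band}/{sex}"] = incremental(
                ts["cost_usd"].sum(), us["cost_usd"].sum(),
                ts["dalys"].sum(), us["dalys"].sum(), label=f"{band}/{sex}",
            )

    t_all = arms[arms["arm"] == "treated"]
    u_all = arms[arms["arm"] == "untreated"]
    overall = incremental(
        t_all["cost_usd"].sum(), u_all["cost_usd"].sum(),
        t_all["dalys"].sum(), u_all["dalys"].sum(), label="overall",
    )
    averted = overall.delta_dalys
    acer_value = (
        acer(overall.cost_treated, averted) if averted > 0 else np.nan
    )
    try:
        icer_value = icer(overall)
    except ZeroDivisionError:
        icer_value = np.nan
    nmb_value = nmb(params.thresholds.wtp, overall).nmb
    return CEResult(
        arms=arms,
        comparisons=comparisons,
        overall=overall,
        acer=acer_value,
        icer_overall=icer_value,
        nmb_at_wtp=nmb_value,
        params=params,
    )


def write_tables(result: CEResult, out_dir) -> None:
    """Write the result tables (arm outcomes, comparisons, ICERs) as CSV."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    result.arms.to_csv(os.path.join(out_dir, "arm_outcomes.csv"), index=False)
    comp = result.comparison_table()
    comp.to_csv(os.path.join(out_dir, "comparisons.csv"), index=False)
    icers = comp[["group", "icer", "dominance"]]
    icers.to_csv(os.path.join(out_dir, "icers.csv"), index=False)
    summary = pd.DataFrame(
        [
            {
                "acer": result.acer,
                "icer_overall": result.icer_overall,
                "nmb_at_wtp": result.nmb_at_wtp,
                "wtp": result.params.thresholds.wtp if result.params else np.nan,
            }
        ]
    )
    summary.to_csv(os.path.join(out_dir, "summary.csv"), index=False)
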