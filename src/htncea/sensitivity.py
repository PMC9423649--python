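"""Deterministic and probabilistic sensitivity analysis.

One-way DSA re-runs the full pipeline at the lower and upper bound of a
single parameter, holding everything else at base case.  Scenario
transforms cover the study's stress tests: reduced adherence (scaling the
risk reduction), a lag before target blood pressure is reached, a
pill-taking disutility folded into treated-state disability weights, and a
linearly increasing CVD risk profile.  The PSA samples every uncertain
parameter from its fitted distribution (independently; 1000 draws by
default), re-evaluates the pipeline per draw, and summarizes the
(incremental cost, DALYs averted) cloud with empirical 95% uncertainty
intervals and a cost-effectiveness acceptability curve.

Percentile convention: linear interpolation between order statistics
(numpy's default).  The random seed is always explicit; the default
20200901 is arbitrary but documented.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import cea
from .burden import combine_dw
from .params import ParameterSet, SamplingSpec, UncertainParam, expand_uncertain

__all__ = [
    "DEFAULT_SEED",
    "DEFAULT_PSA_INCLUDE",
    "DSAResult",
    "PSAResult",
    "CEACCurve",
    "apply_scenario",
    "one_way_dsa",
    "run_psa",
    "ceac",
    "uncertainty_interval",
]

DEFAULT_SEED = 20200901

#: dotted paths of the uncertain parameters varied jointly in the PSA.
#: The blood-pressure control rate is a deterministic-sensitivity range
#: (0.50-0.70), not a 95% interval, so it is varied in the DSA instead.
DEFAULT_PSA_INCLUDE: tuple[str, ...] = (
    "treatment.rr_chd",
    "treatment.rr_stroke",
    "costs.annual_drug_cost",
    "costs.monthly_wage_unemployed",
    "disability_weights.hypertensive_heart_disease",
)

_SCENARIO_KEYS = (
    "adherence",
    "lag_years",
    "pill_disutility",
    "risk_mode",
    "control_rate",
    "discount_rate",
    "drug_cost_multiplier",
    "prevalence_multiplier",
)


# --------------------------------------------------------------------------
# Parameter addressing helpers
# --------------------------------------------------------------------------

def _resolve(ps: ParameterSet, dotted: str):
    obj = ps
    parts = dotted.split(".")
    for p in parts[:-1]:
        obj = getattr(obj, p)
    return obj, parts[-1]


def get_param(ps: ParameterSet, dotted: str):
    obj, leaf = _resolve(ps, dotted)
    return getattr(obj, leaf)


def set_param(ps: ParameterSet, dotted: str, value) -> None:
    """Set a parameter by dotted path; numbers assigned onto an
    :class:`UncertainParam` collapse it to a point mass."""
    obj, leaf = _resolve(ps, dotted)
    current = getattr(obj, leaf)
    if isinstance(current, UncertainParam) and isinstance(value, (int, float)):
        setattr(obj, leaf, UncertainParam(float(value)))
    else:
        setattr(obj, leaf, value)


# --------------------------------------------------------------------------
# Scenario transforms
# --------------------------------------------------------------------------

def apply_scenario(params: ParameterSet, scenario: dict) -> ParameterSet:
    """Return a transformed copy of the parameter book.

    Recognized keys: ``adherence`` (multiplier on the risk reduction),
    ``lag_years`` (cycles before the treated arm benefits),
    ``pill_disutility`` (True for the book's weight, or a numeric weight,
    combined multiplicatively into treated-state weights),
    ``risk_mode`` (``constant`` | ``linear_increasing``),
    ``control_rate``, ``discount_rate``,
    ``drug_cost_multiplier`` and ``prevalence_multiplier``.
    """
    unknown = set(scenario) - set(_SCENARIO_KEYS)
    if unknown:
        raise KeyError(f"unknown scenario keys: {sorted(unknown)}")
    ps = params.copy()
    if "adherence" in scenario:
        ps.treatment.adherence = float(scenario["adherence"])
    if "lag_years" in scenario:
        ps.treatment.lag_years = int(scenario["lag_years"])
    if "pill_disutility" in scenario:
        val = scenario["pill_disutility"]
        ps.treatment.pill_disutility_on = bool(val)
        if isinstance(val, float):
            ps.disability_weights.pill_disutility = UncertainParam(val)
    if "risk_mode" in scenario:
        ps.transitions.risk_mode = str(scenario["risk_mode"])
    if "control_rate" in scenario:
        ps.epidemiology.control_rate = UncertainParam(float(scenario["control_rate"]))
    if "discount_rate" in scenario:
        ps.costs.discount_rate = float(scenario["discount_rate"])
    if "drug_cost_multiplier" in scenario:
        k = float(scenario["drug_cost_multiplier"])
        base = ps.costs.annual_drug_cost
        ps.costs.annual_drug_cost = UncertainParam(
            base.mean * k, base.low * k, base.high * k, base.family
        )
    if "prevalence_multiplier" in scenario:
        k = float(scenario["prevalence_multiplier"])
        ps.epidemiology.prevalence_by_band = {
            b: min(1.0, f * k) for b, f in ps.epidemiology.prevalence_by_band.items()
        }
    ps.validate()
    return ps


def pill_adjusted_weight(base_weight: float, disutility: float) -> float:
    """Treated-state weight with the pill-taking disutility folded in
    multiplicatively (keeps the result inside [0,1])."""
    return combine_dw(base_weight, disutility)


# --------------------------------------------------------------------------
# One-way deterministic sensitivity analysis
# --------------------------------------------------------------------------

@dataclass
class DSAResult:
    parameter: str
    low_value: float
    high_value: float
    icer_base: float
    icer_low: float
    icer_high: float
    nmb_base: float
    nmb_low: float
    nmb_high: float

    @property
    def icer_range(self) -> float:
        return abs(self.icer_high - self.icer_low)


def _pipeline_metrics(result: cea.CEResult) -> tuple[float, float]:
    return result.icer_overall, result.nmb_at_wtp


def one_way_dsa(
    params: ParameterSet,
    parameter: str,
    low: float,
    high: float,
    pipeline=cea.evaluate,
) -> DSAResult:
    """Run the pipeline with one parameter at each bound, all else base."""
    if low > high:
        raise ValueError("one_way_dsa requires low <= high")
    try:
        base_icer, base_nmb = _pipeline_metrics(pipeline(params))
        results = {}
        for tag, value in (("low", low), ("high", high)):
            ps = params.copy()
            set_param(ps, parameter, value)
            ps.validate()
            results[tag] = _pipeline_metrics(pipeline(ps))
    except Exception as exc:
        raise RuntimeError(f"DSA pipeline failed for {parameter!r}: {exc}") from exc
    return DSAResult(
        parameter=parameter,
        low_value=low,
        high_value=high,
        icer_base=base_icer,
        icer_low=results["low"][0],
        icer_high=results["high"][0],
        nmb_base=base_nmb,
        nmb_low=results["low"][1],
        nmb_high=results["high"][1],
    )


# --------------------------------------------------------------------------
# Probabilistic sensitivity analysis
# --------------------------------------------------------------------------

@dataclass
class PSAResult:
    n_draws: int
    seed: int
    draws: pd.DataFrame  # delta_cost, delta_dalys, icer, nmb per draw
    intervals: dict[str, tuple[float, float]] = field(default_factory=dict)

    @property
    def fraction_cost_saving(self) -> float:
        return float((self.draws["delta_cost"] > 0).mean())

    def quadrant_fractions(self) -> dict[str, float]:
        """CE-plane quadrants in the incurred orientation (x = DALYs averted,
        y = incremental cost incurred by treatment)."""
        de = self.draws["delta_dalys"]
        dc_incurred = -self.draws["delta_cost"]
        return {
            "more_effective_more_costly": float(((de > 0) & (dc_incurred > 0)).mean()),
            "more_effective_cost_saving": float(((de > 0) & (dc_incurred <= 0)).mean()),
            "less_effective_more_costly": float(((de <= 0) & (dc_incurred > 0)).mean()),
            "less_effective_cost_saving": float(((de <= 0) & (dc_incurred <= 0)).mean()),
        }


@dataclass
class CEACCurve:
    wtp: np.ndarray
    probability: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"wtp": self.wtp, "probability_cost_effective": self.probability})


def uncertainty_interval(draws, level: float = 0.95) -> tuple[float, float]:
    """Empirical central interval: percentiles at (1-level)/2 and
    1-(1-level)/2 with linear interpolation between order statistics."""
    arr = np.asarray(draws, dtype=float)
    if arr.size < 2:
        raise ValueError("uncertainty interval needs at least 2 draws")
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0,1)")
    alpha = (1.0 - level) / 2.0
    lo, hi = np.percentile(arr, [100 * alpha, 100 * (1 - alpha)])
    return float(lo), float(hi)


def run_psa(
    params: ParameterSet,
    n_draws: int = 1000,
    seed: int = DEFAULT_SEED,
    pipeline=cea.evaluate,
    include: tuple[str, ...] = DEFAULT_PSA_INCLUDE,
) -> PSAResult:
    """Monte Carlo over the uncertain parameter book.

    Each draw independently samples every parameter in ``include`` from its
    fitted distribution, fixes it as a point value, re-runs the pipeline
    and records (delta_cost, delta_dalys, ICER, NMB) in the table
    orientation (positive delta_cost = savings from treatment).  Point-mass
    parameters make every draw identical to the deterministic run.
    """
    rng = np.random.default_rng(seed)
    specs: dict[str, SamplingSpec] = {}
    for path in include:
        p = get_param(params, path)
        if not isinstance(p, UncertainParam):
            raise TypeError(f"PSA include path {path!r} is not an UncertainParam")
        try:
            specs[path] = expand_uncertain(p)
        except Exception as exc:
            raise RuntimeError(f"sampling specification failed for {path!r}: {exc}") from exc

    records = []
    wtp = params.thresholds.wtp
    for _ in range(n_draws):
        ps = params.copy()
        for path, spec in specs.items():
            value = float(spec.rvs(rng=rng))
            if spec.family == "beta":
                value = min(max(value, 0.0), 1.0)
            set_param(ps, path, value)
        result = pipeline(ps)
        comp = result.overall
        try:
            icer_value = cea.icer(comp)
        except ZeroDivisionError:
            icer_value = np.nan
        records.append(
            {
                "delta_cost": comp.delta_cost,
                "delta_dalys": comp.delta_dalys,
                "icer": icer_value,
                "nmb": cea.nmb(wtp, comp).nmb,
            }
        )
    draws = pd.DataFrame(records)
    intervals = {
        col: uncertainty_interval(draws[col].dropna(), 0.95)
        for col in ("delta_cost", "delta_dalys", "icer", "nmb")
        if draws[col].dropna().size >= 2
    }
    return PSAResult(n_draws=n_draws, seed=seed, draws=draws, intervals=intervals)


def ceac(psa: PSAResult, wtp_grid) -> CEACCurve:
    """Probability cost-effective: fraction of draws with NMB(wtp) > 0."""
    grid = np.asarray(wtp_grid, dtype=float)
    if grid.size == 0:
        raise ValueError("wtp grid must be non-empty")
    de = psa.draws["delta_dalys"].to_numpy()
    dc_incurred = -psa.draws["delta_cost"].to_numpy()
    prob = np.array([float((w * de - dc_incurred > 0).mean()) for w in grid])
    return CEACCurve(grid, prob)
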