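"""Parameter book: load, validate and expose every model input.

All quantities the pipeline consumes live in a single :class:`ParameterSet`:
epidemiology (prevalence, coverage, control, mortality ratios), disability
weights, unit prices and wages, willingness-to-pay thresholds, the annual
transition-risk schedule for the Markov engine, and treatment-effect
parameters.  Defaults are hard-coded from the study's printed tables and
constants; anything the study drew from supplementary material that is not
printed (age-specific transition probabilities, the BP dose-response table)
carries documented placeholder defaults chosen to be epidemiologically
plausible — see ``docs/methods.md``.

Uncertain quantities are :class:`UncertainParam` (mean + 95% interval +
distribution family); :func:`expand_uncertain` turns one into a concrete
sampling specification by percentile matching under a mean constraint.

Currency convention: wages and the productivity-loss chain are in ETB
(Ethiopian birr); the unit-price book and program costs are in 2021 USD as
printed.  Conversion (43.5 ETB/USD, January 2021) happens only at the
reporting layer.
"""

from __future__ import annotations

import copy
import dataclasses
import io
import math
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import yaml
from scipy import optimize, stats

__all__ = [
    "ConfigurationError",
    "ValidationError",
    "FittingError",
    "Stratum",
    "UncertainParam",
    "EpidemiologyParams",
    "DisabilityWeightSet",
    "CostParams",
    "ThresholdSet",
    "TransitionSchedule",
    "TreatmentEffects",
    "ParameterSet",
    "SamplingSpec",
    "default_parameters",
    "load_parameters",
    "dump_parameters",
    "expand_uncertain",
]


class ConfigurationError(ValueError):
    """An override references an unknown key or the config does not parse."""


class ValidationError(ValueError):
    """A parameter violates its invariant; the message names the field."""


class FittingError(RuntimeError):
    """mean/CI combination cannot be matched by the requested family."""


# --------------------------------------------------------------------------
# Basic domain types
# --------------------------------------------------------------------------

def band_label(lo: float, hi: float) -> str:
    return f"{lo:g}-{hi:g}"


@dataclass
class Stratum:
    """One sex x age-band cell of the cohort."""

    sex: str
    age_lo: float
    age_hi: float
    population: float = 0.0

    @property
    def band(self) -> str:
        return band_label(self.age_lo, self.age_hi)

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.age_lo + self.age_hi)

    def validate(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValidationError(f"Stratum.sex: unknown sex {self.sex!r}")
        if not self.age_hi > self.age_lo:
            raise ValidationError("Stratum.age_band: empty interval")
        if self.population < 0:
            raise ValidationError("Stratum.population: must be non-negative")


@dataclass
class UncertainParam:
    """Mean with a 95% interval and a sampling family for PSA.

    ``family`` is one of ``beta`` (quantities on [0,1]), ``gamma``
    (non-negative costs/rates), ``lognormal`` (relative risks) or ``point``.
    """

    mean: float
    low: float | None = None
    high: float | None = None
    family: str = "point"

    def __post_init__(self) -> None:
        if self.low is None:
            self.low = self.mean
        if self.high is None:
            self.high = self.mean

    def validate(self, name: str = "UncertainParam") -> None:
        if not (self.low <= self.mean <= self.high):
            raise ValidationError(f"{name}: requires low <= mean <= high")
        if self.family not in ("beta", "gamma", "lognormal", "point"):
            raise ValidationError(f"{name}: unknown family {self.family!r}")
        if self.family == "beta" and not (0.0 <= self.low and self.high <= 1.0):
            raise ValidationError(f"{name}: beta family requires support in [0,1]")
        if self.family in ("gamma", "lognormal") and self.low < 0:
            raise ValidationError(f"{name}: {self.family} requires non-negative support")

    @property
    def is_point(self) -> bool:
        return self.family == "point" or (self.low == self.mean == self.high)


@dataclass
class EpidemiologyParams:
    prevalence_by_band: dict[str, float] = field(default_factory=dict)
    mean_prevalence: float = 0.2139
    treatment_coverage: float = 0.284
    control_rate: UncertainParam = field(
        default_factory=lambda: UncertainParam(0.70, 0.50, 0.70, "beta")
    )
    rr_mortality_htn: UncertainParam = field(
        default_factory=lambda: UncertainParam(1.39, 0.95, 1.95, "lognormal")
    )
    rr_high_bp: UncertainParam = field(
        default_factory=lambda: UncertainParam(3.13, 2.91, 3.37, "lognormal")
    )
    hr_high_bp: UncertainParam = field(
        default_factory=lambda: UncertainParam(2.96, 2.56, 3.42, "lognormal")
    )
    crude_death_rate: float = 6.29  # deaths per 1000 per year
    life_expectancy: dict[str, float] = field(
        default_factory=lambda: {"male": 66.7, "female": 70.4}
    )
    # annual background (non-CVD) death probability, by band label then sex
    background_mortality: dict[str, dict[str, float]] = field(default_factory=dict)
    # normative residual life expectancy at age of death, by sex: {age: years};
    # linearly interpolated.  Empty -> fall back to max(LE_at_birth - age, 0).
    residual_le_table: dict[str, dict[float, float]] = field(default_factory=dict)
    # annual probability a normotensive re-enters the hypertensive pool;
    # asserted qualitatively by the study but never quantified
    reentry_probability: float = 0.0

    def validate(self) -> None:
        for key, frac in self.prevalence_by_band.items():
            if not 0.0 <= frac <= 1.0:
                raise ValidationError(f"prevalence_by_band[{key}]: fraction outside [0,1]")
        for nm, val in (
            ("mean_prevalence", self.mean_prevalence),
            ("treatment_coverage", self.treatment_coverage),
            ("reentry_probability", self.reentry_probability),
        ):
            if not 0.0 <= val <= 1.0:
                raise ValidationError(f"{nm}: fraction outside [0,1]")
        self.control_rate.validate("control_rate")
        for nm in ("rr_mortality_htn", "rr_high_bp", "hr_high_bp"):
            p: UncertainParam = getattr(self, nm)
            p.validate(nm)
            if p.mean <= 0:
                raise ValidationError(f"{nm}: ratio must be positive")
        if self.crude_death_rate < 0:
            raise ValidationError("crude_death_rate: must be non-negative")
        for sex, le in self.life_expectancy.items():
            if le <= 0:
                raise ValidationError(f"life_expectancy[{sex}]: must be positive")
        for band, per_sex in self.background_mortality.items():
            for sex, q in per_sex.items():
                if not 0.0 <= q <= 1.0:
                    raise ValidationError(
                        f"background_mortality[{band}][{sex}]: probability outside [0,1]"
                    )
        for sex, table in self.residual_le_table.items():
            for age, years in table.items():
                if years < 0:
                    raise ValidationError(
                        f"residual_le_table[{sex}][{age}]: negative years"
                    )

    def residual_life_expectancy(self, sex: str, age):
        """Residual life expectancy at the age of death.

        Interpolates the normative table when one is configured, otherwise
        falls back to max(life expectancy at birth - age, 0).
        """
        age_arr = np.asarray(age, dtype=float)
        table = self.residual_le_table.get(sex)
        if table:
            xs = np.array(sorted(table), dtype=float)
            ys = np.array([table[x] for x in sorted(table)], dtype=float)
            return np.interp(age_arr, xs, ys)
        return np.maximum(self.life_expectancy[sex] - age_arr, 0.0)


@dataclass
class DisabilityWeightSet:
    """Per-state disability weights; 0 = full health, 1 = death-equivalent."""

    hypertensive_heart_disease: UncertainParam = field(
        default_factory=lambda: UncertainParam(0.246, 0.201, 0.300, "beta")
    )
    untreated: float = 0.323
    treated_controlled: float = 0.171
    pill_disutility: UncertainParam = field(
        default_factory=lambda: UncertainParam(0.049, 0.031, 0.072, "beta")
    )
    # acute-event and sequela weights; GBD-style placeholders (see methods)
    state_weights: dict[str, float] = field(
        default_factory=lambda: {
            "event_MI": 0.432,
            "event_UA": 0.224,
            "event_SA": 0.080,
            "event_stroke": 0.552,
            "event_TIA": 0.070,
            "post_MI": 0.080,
            "post_UA": 0.080,
            "post_SA": 0.080,
            "post_stroke": 0.320,
            "post_TIA": 0.020,
        }
    )

    def validate(self) -> None:
        self.hypertensive_heart_disease.validate("hypertensive_heart_disease")
        self.pill_disutility.validate("pill_disutility")
        for nm, w in (("untreated", self.untreated),
                      ("treated_controlled", self.treated_controlled)):
            if not 0.0 <= w <= 1.0:
                raise ValidationError(f"disability weight {nm}: outside [0,1]")
        if self.untreated < self.treated_controlled:
            raise ValidationError(
                "disability weights: untreated must be >= treated_controlled"
            )
        for state, w in self.state_weights.items():
            if not 0.0 <= w <= 1.0:
                raise ValidationError(f"state_weights[{state}]: outside [0,1]")


@dataclass
class CostParams:
    """Unit prices (2021 USD as printed), ETB wages, and macro cost knobs."""

    unit_price_book: dict[str, float] = field(default_factory=dict)
    exchange_rate: dict[int, float] = field(
        default_factory=lambda: {2016: 20.999, 2021: 43.5}
    )
    inflation_factor: float = 1.372
    discount_rate: float = 0.03
    discount_rate_alt: float = 0.06
    employment_rate: dict[str, float] = field(
        default_factory=lambda: {"male": 0.88, "female": 0.33}
    )
    monthly_income_employed: float = 2059.078  # ETB, inflation-adjusted
    monthly_wage_unemployed: UncertainParam = field(
        default_factory=lambda: UncertainParam(796.0, 420.0, 1172.0, "gamma")
    )
    daily_wage_patient: float = 97.0       # ETB/day, time cost of care
    daily_wage_unemployed: float = 26.53   # ETB/day
    transport_cost_per_visit: float = 42.0  # ETB
    program_cost_national: float = 34_158_641.24  # USD per year
    program_population_proportion: float = 0.03
    program_cost_per_person_year: float = 128.28  # USD, as printed
    program_cost_study_area: float = 1_024_759.24  # USD per year
    hypertensive_population: float = 750_533.0  # study-area hypertensives
    # annual per-person care costs used by the model arms (USD 2021)
    annual_drug_cost: UncertainParam = field(
        default_factory=lambda: UncertainParam(14.07, 11.26, 16.88, "gamma")
    )
    outpatient_visit_cost: float = 0.49    # USD, secondary hospital
    event_costs: dict[str, float] = field(
        default_factory=lambda: {
            "event_MI": 1040.0,
            "event_UA": 520.0,
            "event_SA": 260.0,
            "event_stroke": 940.0,
            "event_TIA": 235.0,
        }
    )
    post_event_annual_costs: dict[str, float] = field(
        default_factory=lambda: {
            "post_MI": 45.0,
            "post_UA": 45.0,
            "post_SA": 45.0,
            "post_stroke": 67.0,
            "post_TIA": 33.5,
        }
    )

    def validate(self) -> None:
        for item, price in self.unit_price_book.items():
            if price < 0:
                raise ValidationError(f"unit_price_book[{item}]: negative price")
        for year, rate in self.exchange_rate.items():
            if rate <= 0:
                raise ValidationError(f"exchange_rate[{year}]: must be positive")
        if self.inflation_factor <= 0:
            raise ValidationError("inflation_factor: must be positive")
        for nm in ("discount_rate", "discount_rate_alt"):
            r = getattr(self, nm)
            if not 0.0 <= r < 1.0:
                raise ValidationError(f"{nm}: must lie in [0,1)")
        for sex, e in self.employment_rate.items():
            if not 0.0 <= e <= 1.0:
                raise ValidationError(f"employment_rate[{sex}]: fraction outside [0,1]")
        self.monthly_wage_unemployed.validate("monthly_wage_unemployed")
        self.annual_drug_cost.validate("annual_drug_cost")
        for nm in ("monthly_income_employed", "daily_wage_patient",
                   "daily_wage_unemployed", "transport_cost_per_visit",
                   "program_cost_national", "program_cost_per_person_year",
                   "program_cost_study_area", "hypertensive_population",
                   "outpatient_visit_cost"):
            if getattr(self, nm) < 0:
                raise ValidationError(f"{nm}: negative price")
        if not 0.0 <= self.program_population_proportion <= 1.0:
            raise ValidationError("program_population_proportion: fraction outside [0,1]")
        for book in (self.event_costs, self.post_event_annual_costs):
            for item, price in book.items():
                if price < 0:
                    raise ValidationError(f"cost {item}: negative price")


@dataclass
class ThresholdSet:
    """Cost-effectiveness decision thresholds (USD per DALY averted)."""

    gdp_per_capita: float = 936.30
    ce_band: tuple[float, float] = (936.30, 2808.90)
    wtp: float = 50_000.0

    @property
    def half_gdp(self) -> float:
        return self.gdp_per_capita / 2.0

    def validate(self) -> None:
        lo, hi = self.ce_band
        if not lo <= hi:
            raise ValidationError("ce_band: must be ordered")
        if self.gdp_per_capita <= 0:
            raise ValidationError("gdp_per_capita: must be positive")
        if self.wtp < 0:
            raise ValidationError("wtp: must be non-negative")


@dataclass
class TransitionSchedule:
    """Annual CVD risk inputs for the Markov engine, by age band.

    The study took its transition probabilities from supplementary tables
    not reproduced in print; these defaults are placeholders of realistic
    magnitude for an untreated hypertensive cohort (see methods note).
    ``p10_*`` are 10-year first-event probabilities, annualized by
    :func:`htncea.markov.annualize_risk`.
    """

    p10_chd: dict[str, float] = field(
        default_factory=lambda: {"30-40": 0.04, "40-65": 0.12, "65-100": 0.25}
    )
    p10_stroke: dict[str, float] = field(
        default_factory=lambda: {"30-40": 0.02, "40-65": 0.08, "65-100": 0.20}
    )
    chd_split: dict[str, float] = field(
        default_factory=lambda: {"event_MI": 0.45, "event_UA": 0.35, "event_SA": 0.20}
    )
    cereb_split: dict[str, float] = field(
        default_factory=lambda: {"event_stroke": 0.75, "event_TIA": 0.25}
    )
    case_fatality: dict[str, float] = field(
        default_factory=lambda: {
            "event_MI": 0.30,
            "event_UA": 0.05,
            "event_SA": 0.02,
            "event_stroke": 0.25,
            "event_TIA": 0.01,
        }
    )
    post_event_mortality: dict[str, float] = field(
        default_factory=lambda: {
            "post_MI": 0.05,
            "post_UA": 0.03,
            "post_SA": 0.02,
            "post_stroke": 0.08,
            "post_TIA": 0.02,
        }
    )
    risk_mode: str = "constant"  # or "linear_increasing"

    def validate(self) -> None:
        for nm in ("p10_chd", "p10_stroke", "case_fatality", "post_event_mortality"):
            for key, p in getattr(self, nm).items():
                if not 0.0 <= p <= 1.0:
                    raise ValidationError(f"{nm}[{key}]: probability outside [0,1]")
        for nm in ("chd_split", "cereb_split"):
            split = getattr(self, nm)
            if abs(sum(split.values()) - 1.0) > 1e-9:
                raise ValidationError(f"{nm}: shares must sum to 1")
        if self.risk_mode not in ("constant", "linear_increasing"):
            raise ValidationError(f"risk_mode: unknown mode {self.risk_mode!r}")


@dataclass
class TreatmentEffects:
    """Relative risks of antihypertensive treatment and scenario knobs."""

    rr_chd: UncertainParam = field(
        default_factory=lambda: UncertainParam(0.78, 0.70, 0.87, "lognormal")
    )
    rr_stroke: UncertainParam = field(
        default_factory=lambda: UncertainParam(0.62, 0.52, 0.74, "lognormal")
    )
    adherence: float = 1.0        # scales the risk reduction, not the RR
    lag_years: int = 0            # cycles before the treated arm gets its RR
    pill_disutility_on: bool = False
    rr_applies_to_uncontrolled: bool = False

    def validate(self) -> None:
        for nm in ("rr_chd", "rr_stroke"):
            p: UncertainParam = getattr(self, nm)
            p.validate(nm)
            if p.mean <= 0:
                raise ValidationError(f"{nm}: ratio must be positive")
        if not 0.0 <= self.adherence <= 1.0:
            raise ValidationError("adherence: fraction outside [0,1]")
        if self.lag_years < 0:
            raise ValidationError("lag_years: must be non-negative")


# Table 1 unit-price book (2021 USD, retail/reference prices as printed).
_UNIT_PRICE_BOOK: dict[str, float] = {
    "amlodipine_5mg_100": 2.243,
    "amlodipine_10mg_100": 3.142,
    "nifedipine_20mg_100": 1.749,
    "enalapril_5mg_100": 1.905,
    "enalapril_10mg_100": 1.835,
    "enalapril_2.5mg_100": 0.595,
    "captopril_25mg_100": 0.802,
    "captopril_12.5mg_100": 1.000,
    "hct_25mg_100": 1.432,
    "atenolol_50mg_100": 1.749,
    "spironolactone_25mg_100": 2.440,
    "methyldopa_250mg_1000": 1.542,
    "metoprolol_50mg_100": 2.814,
    "propranolol_40mg_100": 2.013,
    "asa_81mg_100": 1.303,
    "atorvastatin_20mg_100": 5.831,
    "complete_blood_count": 1.72,
    "blood_sugar": 0.46,
    "lipid_profile": 3.68,
    "echocardiography": 2.76,
    "electrocardiogram": 8.05,
    "ct_scan": 27.59,
    "renal_function_test": 1.84,
    "chest_xray": 16.69,
    "urinalysis": 0.34,
    "bed_day_primary": 1.21,
    "bed_day_secondary": 1.26,
    "bed_day_tertiary": 1.63,
    "visit_primary": 0.43,
    "visit_secondary": 0.49,
    "visit_tertiary": 0.51,
    "visit_health_center": 0.53,
    "pci_intervention": 1448.28,
    "inpatient_mi": 1040.00,
    "inpatient_stroke": 940.00,
    "outpatient_ihd_annual": 45.00,
    "outpatient_stroke_annual": 67.00,
}

_DEFAULT_BANDS: tuple[tuple[float, float], ...] = ((30, 40), (40, 65), (65, 100))

# share of the adult (30+) hypertensive pool in each model band, and band
# prevalence mapped from the printed 15-30/30-40/40-50/50+ figures
_DEFAULT_POPULATION = {
    ("male", "30-40"): 120_000.0,
    ("female", "30-40"): 125_000.0,
    ("male", "40-65"): 95_000.0,
    ("female", "40-65"): 100_000.0,
    ("male", "65-100"): 28_000.0,
    ("female", "65-100"): 32_000.0,
}

_DEFAULT_BACKGROUND_MORTALITY = {
    "30-40": {"male": 0.0030, "female": 0.0025},
    "40-65": {"male": 0.0080, "female": 0.0065},
    "65-100": {"male": 0.0450, "female": 0.0400},
}

# normative residual life expectancy at exact ages (placeholder life table
# of realistic magnitude; anchored so that LE at 30 matches the national
# life expectancies at birth of 66.7 M / 70.4 F within a few years)
_DEFAULT_RESIDUAL_LE = {
    "male": {30.0: 39.0, 40.0: 31.0, 50.0: 23.0, 60.0: 16.0,
             70.0: 10.0, 80.0: 6.0, 90.0: 3.0, 100.0: 1.5},
    "female": {30.0: 42.0, 40.0: 34.0, 50.0: 26.0, 60.0: 18.0,
               70.0: 12.0, 80.0: 7.0, 90.0: 3.5, 100.0: 2.0},
}


@dataclass
class ParameterSet:
    """The full parameter book consumed by every downstream module."""

    age_bands: list[tuple[float, float]] = field(
        default_factory=lambda: [tuple(b) for b in _DEFAULT_BANDS]
    )
    strata: list[Stratum] = field(default_factory=list)
    epidemiology: EpidemiologyParams = field(default_factory=EpidemiologyParams)
    disability_weights: DisabilityWeightSet = field(default_factory=DisabilityWeightSet)
    costs: CostParams = field(default_factory=CostParams)
    thresholds: ThresholdSet = field(default_factory=ThresholdSet)
    transitions: TransitionSchedule = field(default_factory=TransitionSchedule)
    treatment: TreatmentEffects = field(default_factory=TreatmentEffects)
    cycles: int = 80

    def validate(self) -> None:
        # age bands must partition [30, 100) without overlap
        bands = sorted(self.age_bands)
        if not bands or bands[0][0] != 30 or bands[-1][1] != 100:
            raise ValidationError("age_bands: must cover [30, 100)")
        for (lo1, hi1), (lo2, hi2) in zip(bands, bands[1:]):
            if hi1 != lo2:
                raise ValidationError("age_bands: gaps or overlaps in partition")
        for s in self.strata:
            s.validate()
        self.epidemiology.validate()
        self.disability_weights.validate()
        self.costs.validate()
        self.thresholds.validate()
        self.transitions.validate()
        self.treatment.validate()
        if self.cycles < 1:
            raise ValidationError("cycles: must be at least 1")

    def stratum(self, sex: str, band: str) -> Stratum:
        for s in self.strata:
            if s.sex == sex and s.band == band:
                return s
        raise KeyError(f"no stratum for sex={sex!r}, band={band!r}")

    def copy(self) -> "ParameterSet":
        return copy.deepcopy(self)


def default_parameters() -> ParameterSet:
    """The documented default parameter book."""
    strata = [
        Stratum(sex, lo, hi, _DEFAULT_POPULATION[(sex, band_label(lo, hi))])
        for (lo, hi) in _DEFAULT_BANDS
        for sex in ("male", "female")
    ]
    epi = EpidemiologyParams(
        prevalence_by_band={
            "15-30": 0.196,
            "30-40": 0.23,
            "40-50": 0.259,
            "50-100": 0.419,
        },
        background_mortality=copy.deepcopy(_DEFAULT_BACKGROUND_MORTALITY),
        residual_le_table=copy.deepcopy(_DEFAULT_RESIDUAL_LE),
    )
    costs = CostParams(unit_price_book=dict(_UNIT_PRICE_BOOK))
    ps = ParameterSet(strata=strata, epidemiology=epi, costs=costs)
    ps.validate()
    return ps


# --------------------------------------------------------------------------
# Config I/O: nested-dict overlay onto the defaults
# --------------------------------------------------------------------------

def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_plain(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    return obj


def _apply_overrides(obj, overrides: Mapping, path: str = "") -> None:
    for key, value in overrides.items():
        here = f"{path}.{key}" if path else str(key)
        if dataclasses.is_dataclass(obj):
            if not hasattr(obj, key):
                raise ConfigurationError(f"unknown parameter key: {here}")
            current = getattr(obj, key)
            if dataclasses.is_dataclass(current) and isinstance(value, Mapping):
                _apply_overrides(current, value, here)
            elif isinstance(current, UncertainParam) and isinstance(value, (int, float)):
                setattr(obj, key, UncertainParam(float(value)))
            elif isinstance(current, dict) and isinstance(value, Mapping):
                merged = dict(current)
                merged.update(value)
                setattr(obj, key, merged)
            else:
                setattr(obj, key, value)
        else:
            raise ConfigurationError(f"cannot override non-section key: {here}")


def _rebuild_structured(ps: ParameterSet) -> None:
    """Re-coerce plain dicts/lists from YAML into their domain types."""
    ps.age_bands = [tuple(b) for b in ps.age_bands]
    ps.strata = [
        Stratum(**s) if isinstance(s, Mapping) else s for s in ps.strata
    ]
    for section in (ps.epidemiology, ps.disability_weights, ps.costs, ps.treatment):
        for f in dataclasses.fields(section):
            val = getattr(section, f.name)
            default = getattr(type(section)(), f.name)
            if isinstance(default, UncertainParam) and isinstance(val, Mapping):
                setattr(section, f.name, UncertainParam(**val))
    if isinstance(ps.thresholds.ce_band, list):
        ps.thresholds.ce_band = tuple(ps.thresholds.ce_band)
    ps.costs.exchange_rate = {int(k): v for k, v in ps.costs.exchange_rate.items()}


def load_parameters(config_source: str | os.PathLike | None = None) -> ParameterSet:
    """Return the defaults overlaid with overrides from YAML text or a path.

    ``config_source`` may be ``None`` (pure defaults), a path to a YAML
    file, or YAML text.  Override keys mirror the dataclass structure
    (``costs: {inflation_factor: 1.4}``); unknown keys raise
    :class:`ConfigurationError`, invariant violations raise
    :class:`ValidationError`.
    """
    ps = default_parameters()
    if config_source is None:
        return ps
    text = config_source
    if isinstance(config_source, os.PathLike) or (
        isinstance(config_source, str)
        and "\n" not in config_source
        and os.path.exists(config_source)
    ):
        with open(config_source, "r") as fh:
            text = fh.read()
    try:
        overrides = yaml.safe_load(io.StringIO(str(text)))
    except yaml.YAMLError as exc:  # pragma: no cover - passthrough
        raise ConfigurationError(f"config does not parse: {exc}") from exc
    if overrides is None:
        return ps
    if not isinstance(overrides, Mapping):
        raise ConfigurationError("config root must be a mapping")
    _apply_overrides(ps, overrides)
    _rebuild_structured(ps)
    ps.validate()
    return ps


def dump_parameters(ps: ParameterSet) -> str:
    """Serialize a ParameterSet to YAML; ``load_parameters`` round-trips it."""
    return yaml.safe_dump(_to_plain(ps), sort_keys=False)


# --------------------------------------------------------------------------
# Uncertain-parameter expansion (CI -> distribution, percentile matching)
# --------------------------------------------------------------------------

class SamplingSpec:
    """A concrete sampling specification for one uncertain parameter.

    Wraps a frozen scipy distribution (or a point mass) so PSA code can
    call ``rvs``/``ppf``/``mean`` uniformly.
    """

    def __init__(self, dist, mean: float, family: str):
        self._dist = dist
        self._mean = float(mean)
        self.family = family

    def mean(self) -> float:
        return self._mean

    def ppf(self, q):
        if self._dist is None:
            return np.full_like(np.asarray(q, dtype=float), self._mean)
        return self._dist.ppf(q)

    def rvs(self, size=None, rng: np.random.Generator | None = None):
        if self._dist is None:
            if size is None:
                return self._mean
            return np.full(size, self._mean)
        rng = np.random.default_rng() if rng is None else rng
        return self._dist.rvs(size=size, random_state=rng)


def _fit_one_parameter(make_dist, low: float, high: float, x0: float) -> tuple:
    """Minimize squared 2.5/97.5-percentile mismatch over one log-scale knob."""

    def objective(log_k: float) -> float:
        d = make_dist(math.exp(log_k))
        lo, hi = d.ppf(0.025), d.ppf(0.975)
        return (lo - low) ** 2 + (hi - high) ** 2

    res = optimize.minimize_scalar(
        objective, bracket=None, bounds=(math.log(x0) - 12, math.log(x0) + 12),
        method="bounded", options={"xatol": 1e-10},
    )
    if not res.success:  # pragma: no cover - scipy rarely fails here
        raise FittingError("percentile matching did not converge")
    return make_dist(math.exp(res.x)), float(res.fun)


def expand_uncertain(p: UncertainParam) -> SamplingSpec:
    """Fit a sampling distribution to (mean, 95% CI) by percentile matching.

    The mean is matched exactly by construction; the remaining free shape
    parameter is chosen to minimize the squared mismatch of the 2.5th and
    97.5th percentiles against (low, high).  Raises :class:`FittingError`
    when the family cannot approximate the interval (relative objective
    above ~20% of the interval width).
    """
    p.validate("expand_uncertain")
    if p.is_point:
        return SamplingSpec(None, p.mean, "point")

    m, lo, hi = float(p.mean), float(p.low), float(p.high)
    if p.family == "beta":
        if not (0.0 < m < 1.0):
            raise FittingError("beta family requires mean strictly inside (0,1)")

        def make(kappa):
            return stats.beta(m * kappa, (1.0 - m) * kappa)

        dist, obj = _fit_one_parameter(make, lo, hi, x0=10.0)
    elif p.family == "gamma":
        if m <= 0:
            raise FittingError("gamma family requires positive mean")

        def make(shape):
            return stats.gamma(shape, scale=m / shape)

        dist, obj = _fit_one_parameter(make, lo, hi, x0=10.0)
    elif p.family == "lognormal":
        if m <= 0:
            raise FittingError("lognormal family requires positive mean")

        def make(sigma):
            return stats.lognorm(sigma, scale=m * math.exp(-0.5 * sigma**2))

        dist, obj = _fit_one_parameter(make, lo, hi, x0=0.2)
    else:  # pragma: no cover - guarded by validate
        raise FittingError(f"unknown family {p.family!r}")

    width = hi - lo
    if width > 0 and math.sqrt(obj) > 0.2 * width:
        raise FittingError(
            f"family {p.family!r} cannot match mean {m} with CI ({lo}, {hi})"
        )
    return SamplingSpec(dist, m, p.family)
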