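"""Synthetic study inputs: sample-size arithmetic, stratified cohorts,
patient-level cost-survey records, and PSA draw tables.

The patient generator emulates the structure of a 407-record facility-based
cost survey allocated 212/107/88 across three general hospitals: ages,
comorbidity flags, medication lists, visit counts and per-item costs priced
from the unit-price book.  Content distributions (Poisson visit counts,
categorical drug choice) are simple documented defaults — the goal is
structural realism for exercising the costing pipeline, not epidemiological
fidelity.  Every generated dataset is fully determined by (spec, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .costing import CostLedger
from .params import ParameterSet, SamplingSpec, UncertainParam, expand_uncertain

__all__ = [
    "SampleSizeSpec",
    "SyntheticPopulationSpec",
    "sample_size",
    "generate_population",
    "generate_patient_records",
    "records_to_ledger",
    "generate_psa_fixture",
]

DEFAULT_FACILITIES = ("Arba Minch", "Jinka", "Sawula")
DEFAULT_ALLOCATION = (212, 107, 88)


@dataclass
class SampleSizeSpec:
    """Single-population-proportion sample size inputs.

    Defaults reproduce the study's chain: p = 0.14 (the reported BP control
    rate), Z = 1.96, d = 0.05, a 10% non-response allowance and a design
    effect of 2 for multi-stage sampling.
    """

    p: float = 0.14
    z: float = 1.96
    d: float = 0.05
    nonresponse_rate: float = 0.10
    design_effect: float = 2.0

    def validate(self) -> None:
        if not 0.0 < self.p < 1.0:
            raise ValueError("p must lie strictly in (0,1)")
        if self.d <= 0:
            raise ValueError("margin of error d must be positive")
        if self.nonresponse_rate < 0:
            raise ValueError("nonresponse_rate must be non-negative")
        if self.design_effect < 1.0:
            raise ValueError("design_effect must be at least 1")

    @property
    def q(self) -> float:
        return 1.0 - self.p


def sample_size(spec: SampleSizeSpec) -> int:
    """Sample size by the single-population-proportion formula.

    n0 = Z^2 p(1-p)/d^2, rounded to the nearest integer; the non-response
    allowance is applied keeping fractional intermediates (185 -> 203.5),
    then the design effect, and the final value is rounded up to an
    integer.  The defaults reproduce the chain 185 -> 203.5 -> 407.
    """
    spec.validate()
    n0 = round(spec.z**2 * spec.p * spec.q / spec.d**2)
    with_nonresponse = n0 * (1.0 + spec.nonresponse_rate)
    return int(math.ceil(with_nonresponse * spec.design_effect - 1e-9))


def base_sample_size(spec: SampleSizeSpec) -> int:
    """The unadjusted n0 = Z^2 p(1-p)/d^2, nearest integer."""
    spec.validate()
    return round(spec.z**2 * spec.p * spec.q / spec.d**2)


# --------------------------------------------------------------------------
# Stratified cohort
# --------------------------------------------------------------------------

@dataclass
class SyntheticPopulationSpec:
    """Cohort generator settings; defaults mirror the study conditions."""

    strata_counts: dict[tuple[str, str], int] = field(
        default_factory=lambda: {
            ("male", "30-40"): 1200,
            ("female", "30-40"): 1250,
            ("male", "40-65"): 950,
            ("female", "40-65"): 1000,
            ("male", "65-100"): 280,
            ("female", "65-100"): 320,
        }
    )
    prevalence_by_band: dict[str, float] = field(
        default_factory=lambda: {"30-40": 0.23, "40-65": 0.30, "65-100": 0.419}
    )
    treatment_coverage: float = 0.284
    control_rate: float = 0.70

    def validate(self) -> None:
        for key, n in self.strata_counts.items():
            if n < 0:
                raise ValueError(f"strata_counts[{key}]: negative count")
        for band, f in self.prevalence_by_band.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"prevalence_by_band[{band}]: outside [0,1]")
        for nm in ("treatment_coverage", "control_rate"):
            v = getattr(self, nm)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{nm}: outside [0,1]")


def generate_population(spec: SyntheticPopulationSpec, seed: int) -> pd.DataFrame:
    """Individual-level cohort with hypertension / treatment / control flags.

    One row per person: sex, age band, age (uniform within band),
    hypertensive (Bernoulli at the band prevalence), treated (Bernoulli at
    the coverage among hypertensives), controlled (Bernoulli at the control
    rate among the treated).  Deterministic under a fixed seed.
    """
    spec.validate()
    total = sum(spec.strata_counts.values())
    if total == 0:
        raise ValueError("spec yields an empty population")
    rng = np.random.default_rng(seed)
    frames = []
    for (sex, band), n in sorted(spec.strata_counts.items()):
        if n == 0:
            continue
        lo, hi = (float(x) for x in band.split("-"))
        ages = rng.uniform(lo, hi, size=n)
        prev = spec.prevalence_by_band.get(band, 0.0)
        htn = rng.random(n) < prev
        treated = htn & (rng.random(n) < spec.treatment_coverage)
        controlled = treated & (rng.random(n) < spec.control_rate)
        frames.append(
            pd.DataFrame(
                {
                    "sex": sex,
                    "age_band": band,
                    "age": ages,
                    "hypertensive": htn,
                    "treated": treated,
                    "controlled": controlled,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


# --------------------------------------------------------------------------
# Patient-level cost-survey records
# --------------------------------------------------------------------------

_DRUG_ITEMS = (
    "amlodipine_5mg_100",
    "nifedipine_20mg_100",
    "enalapril_5mg_100",
    "hct_25mg_100",
    "captopril_25mg_100",
)
_LAB_ITEMS = (
    "complete_blood_count",
    "blood_sugar",
    "lipid_profile",
    "renal_function_test",
    "urinalysis",
    "electrocardiogram",
)


def generate_patient_records(
    price_book: dict[str, float],
    n: int = 407,
    allocation: tuple[int, ...] = DEFAULT_ALLOCATION,
    facilities: tuple[str, ...] = DEFAULT_FACILITIES,
    seed: int = 0,
    diabetes_prevalence: float = 0.15,
    ckd_prevalence: float = 0.08,
) -> pd.DataFrame:
    """Synthetic facility-based cost-survey records.

    Facility counts match ``allocation`` exactly.  Visit counts are
    Poisson(10) truncated to [1, 12]; each patient carries one randomly
    chosen antihypertensive (with an annual pack quantity), a random subset
    of laboratory items, and a rare hospitalization (Bernoulli 0.1, with
    Poisson(4) bed days).  Every cost equals quantity x book price.
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    if sum(allocation) != n:
        raise ValueError(f"allocation {allocation} does not sum to n={n}")
    if len(allocation) != len(facilities):
        raise ValueError("allocation and facilities must align")
    rng = np.random.default_rng(seed)
    rows = []
    pid = 0
    for facility, count in zip(facilities, allocation):
        for _ in range(count):
            age = float(np.floor(rng.uniform(30, 90)))
            sex = "male" if rng.random() < 0.5 else "female"
            visits = int(np.clip(rng.poisson(10), 1, 12))
            drug = _DRUG_ITEMS[rng.integers(len(_DRUG_ITEMS))]
            packs = int(rng.integers(3, 7))  # ~100-tab packs per year
            n_labs = int(rng.integers(1, len(_LAB_ITEMS) + 1))
            labs = list(rng.choice(_LAB_ITEMS, size=n_labs, replace=False))
            hospitalized = bool(rng.random() < 0.10)
            bed_days = int(rng.poisson(4)) + 1 if hospitalized else 0
            rows.append(
                {
                    "patient_id": pid,
                    "facility": facility,
                    "age": age,
                    "sex": sex,
                    "diabetes": bool(rng.random() < diabetes_prevalence),
                    "ckd": bool(rng.random() < ckd_prevalence),
                    "medication": drug,
                    "medication_packs": packs,
                    "medication_cost": packs * price_book[drug],
                    "visit_count": visits,
                    "visit_cost": visits * price_book["visit_secondary"],
                    "lab_items": ";".join(labs),
                    "lab_cost": float(sum(price_book[i] for i in labs)),
                    "bed_days": bed_days,
                    "hospitalization_cost": bed_days * price_book["bed_day_secondary"],
                }
            )
            pid += 1
    return pd.DataFrame(
        rows,
        columns=[
            "patient_id", "facility", "age", "sex", "diabetes", "ckd",
            "medication", "medication_packs", "medication_cost",
            "visit_count", "visit_cost", "lab_items", "lab_cost",
            "bed_days", "hospitalization_cost",
        ],
    )


def records_to_ledger(records: pd.DataFrame, price_book: dict[str, float]) -> CostLedger:
    """Fold patient records into a validated direct-medical cost ledger."""
    ledger = CostLedger()
    for _, r in records.iterrows():
        ledger.add("direct_medical", r["medication"], r["medication_packs"],
                   price_book[r["medication"]])
        ledger.add("direct_medical", "visit_secondary", r["visit_count"],
                   price_book["visit_secondary"])
        for item in str(r["lab_items"]).split(";"):
            if item:
                ledger.add("direct_medical", item, 1, price_book[item])
        if r["bed_days"]:
            ledger.add("direct_medical", "bed_day_secondary", r["bed_days"],
                       price_book["bed_day_secondary"])
    ledger.validate()
    return ledger


# --------------------------------------------------------------------------
# PSA fixtures
# --------------------------------------------------------------------------

def generate_psa_fixture(
    params: ParameterSet,
    n_draws: int = 1000,
    seed: int = 0,
    include: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Long-format table of PSA parameter draws (draw, parameter, value)."""
    from .sensitivity import DEFAULT_PSA_INCLUDE, get_param

    include = DEFAULT_PSA_INCLUDE if include is None else include
    rng = np.random.default_rng(seed)
    frames = []
    for path in include:
        p = get_param(params, path)
        if not isinstance(p, UncertainParam):
            raise TypeError(f"{path!r} is not an UncertainParam")
        spec: SamplingSpec = expand_uncertain(p)
        values = np.atleast_1d(spec.rvs(size=n_draws, rng=rng))
        frames.append(
            pd.DataFrame(
                {"draw": np.arange(n_draws), "parameter": path, "value": values}
            )
        )
    return pd.concat(frames, ignore_index=True)
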