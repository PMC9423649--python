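"""DALY accounting: YLL, YLD, comorbidity adjustment, excess burden.

Follows the simplified GBD-2010 conventions: YLDs are prevalent cases x
duration x disability weight, YLLs are deaths x residual life expectancy at
the age of death, DALY = YLL + YLD, with no time discounting and no age
weighting.  Comorbidity is handled multiplicatively under an independence
assumption: combined prevalence 1-(1-P1)(1-P2), combined disability weight
1-(1-DW1)(1-DW2), and the same form for per-person YLD rates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "BurdenResult",
    "yld",
    "yll",
    "daly",
    "combine_prevalence",
    "combine_dw",
    "combine_yld_rates",
    "combine_many",
    "excess_burden",
]

_INDEX = ["cause", "sex", "age_band", "year"]


@dataclass
class BurdenResult:
    """YLL/YLD/DALY indexed by (cause, sex, age band, year).

    ``table`` is a DataFrame with the four index columns plus ``yll`` and
    ``yld``; ``daly`` is always recomputed as their exact sum.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.table.copy()
        missing = [c for c in (*_INDEX, "yll", "yld") if c not in df.columns]
        if missing:
            raise ValueError(f"BurdenResult missing columns: {missing}")
        df["daly"] = df["yll"] + df["yld"]
        self.table = df.reset_index(drop=True)

    @property
    def total_yll(self) -> float:
        return float(self.table["yll"].sum())

    @property
    def total_yld(self) -> float:
        return float(self.table["yld"].sum())

    @property
    def total_daly(self) -> float:
        return float(self.table["daly"].sum())

    def by(self, *keys: str) -> pd.DataFrame:
        return self.table.groupby(list(keys), as_index=False)[
            ["yll", "yld", "daly"]
        ].sum()

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def yld(cases: float, duration: float, dw: float) -> float:
    """Years lived with disability: cases x duration x disability weight."""
    if cases < 0 or duration < 0:
        raise ValueError("cases and duration must be non-negative")
    if not 0.0 <= dw <= 1.0:
        raise ValueError(f"disability weight must lie in [0,1], got {dw}")
    return cases * duration * dw


def yll(deaths, life_expectancy_at_death) -> float:
    """Years of life lost: deaths x residual life expectancy, summed over
    age groups when vectors are given."""
    d = np.atleast_1d(np.asarray(deaths, dtype=float))
    le = np.atleast_1d(np.asarray(life_expectancy_at_death, dtype=float))
    if (d < 0).any() or (le < 0).any():
        raise ValueError("deaths and life expectancy must be non-negative")
    return float(np.sum(d * le))


def daly(yll_years: float, yld_years: float) -> float:
    """DALYs are the exact sum of the mortality and morbidity components."""
    if yll_years < 0 or yld_years < 0:
        raise ValueError("burden components must be non-negative")
    return yll_years + yld_years


def _check_unit(name: str, x: float) -> None:
    if not 0.0 <= x <= 1.0:
        raise ValueError(f"{name} must lie in [0,1], got {x}")


def combine_prevalence(p1: float, p2: float) -> float:
    """Prevalence of either of two independent conditions: 1-(1-P1)(1-P2)."""
    _check_unit("p1", p1)
    _check_unit("p2", p2)
    return 1.0 - (1.0 - p1) * (1.0 - p2)


def combine_dw(dw1: float, dw2: float) -> float:
    """Multiplicative combined disability weight: 1-(1-DW1)(1-DW2)."""
    _check_unit("dw1", dw1)
    _check_unit("dw2", dw2)
    return 1.0 - (1.0 - dw1) * (1.0 - dw2)


def combine_yld_rates(y1: float, y2: float) -> float:
    """Combined per-person YLD *rate*: 1-(1-YLD1)(1-YLD2).

    Inputs must be rates in [0,1] (prevalence x weight per person);
    absolute year totals are rejected.
    """
    _check_unit("yld rate y1", y1)
    _check_unit("yld rate y2", y2)
    return 1.0 - (1.0 - y1) * (1.0 - y2)


def combine_many(values, combiner=combine_dw, prevalences=None):
    """Fold more than two conditions pairwise.

    When ``prevalences`` is given the values are combined in descending-
    prevalence order; the pairwise formula is associative, so ordering only
    fixes a convention for reporting intermediate pairs.
    """
    vals = list(values)
    if not vals:
        return 0.0
    if prevalences is not None:
        order = np.argsort(np.asarray(prevalences))[::-1]
        vals = [vals[i] for i in order]
    out = vals[0]
    for v in vals[1:]:
        out = combiner(out, v)
    return out


def excess_burden(cohort: BurdenResult, general_population: BurdenResult) -> BurdenResult:
    """Burden attributable to hypertension: cohort minus the age/sex-matched
    general population, element-wise and signed."""
    left = cohort.table.set_index(_INDEX)[["yll", "yld"]].sort_index()
    right = general_population.table.set_index(_INDEX)[["yll", "yld"]].sort_index()
    if not left.index.equals(right.index):
        raise ValueError("excess_burden: stratum mismatch between inputs")
    diff = (left - right).reset_index()
    return BurdenResult(diff)
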