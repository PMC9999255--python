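"""Pairwise strategy comparison: incremental ratios, WHO-threshold
classification and net monetary benefit.

Incrementals are computed as comparator minus baseline (here: AI-assisted
arm minus manual-grading arm) and reported both per person and per 100,000
people screened.  ICER divides the incremental cost by the incremental
years without blindness; ICUR divides it by the incremental QALYs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .markov import StrategySummary

__all__ = ["EconResult", "incremental_ratios", "who_classify",
           "net_monetary_benefit"]

PER_100K = 100_000.0


@dataclass
class EconResult:
    """Paired-strategy cost-effectiveness outcome (comparator vs baseline)."""

    comparator: StrategySummary
    baseline: StrategySummary
    delta_cost: float                 # per person
    delta_qaly: float
    delta_ywb: float
    icer: float                       # USD per year without blindness
    icur: float                       # USD per QALY
    classification: str

    @property
    def delta_cost_per_100k(self) -> float:
        return self.delta_cost * PER_100K

    @property
    def delta_qaly_per_100k(self) -> float:
        return self.delta_qaly * PER_100K

    @property
    def delta_ywb_per_100k(self) -> float:
        return self.delta_ywb * PER_100K

    @property
    def icer_defined(self) -> bool:
        return math.isfinite(self.icer)

    @property
    def icur_defined(self) -> bool:
        return math.isfinite(self.icur)

    def to_frame(self) -> pd.DataFrame:
        """One-row-per-arm table mirroring the usual base-case layout."""
        rows = [
            {
                "strategy": self.comparator.name,
                "cost_per_person_usd": self.comparator.cost,
                "incr_cost_per_100k_usd": self.delta_cost_per_100k,
                "years_without_blindness": self.comparator.years_without_blindness,
                "incr_years_without_blindness_per_100k": self.delta_ywb_per_100k,
                "qaly_per_person": self.comparator.qaly,
                "incr_qaly_per_100k": self.delta_qaly_per_100k,
                "icer_usd_per_year_without_blindness": self.icer,
                "icur_usd_per_qaly": self.icur,
                "classification": self.classification,
            },
            {
                "strategy": self.baseline.name,
                "cost_per_person_usd": self.baseline.cost,
                "years_without_blindness": self.baseline.years_without_blindness,
                "qaly_per_person": self.baseline.qaly,
            },
        ]
        return pd.DataFrame(rows)


def _safe_ratio(num: float, den: float) -> float:
    if den == 0.0:
        return math.nan
    return num / den


def who_classify(
    delta_cost: float,
    delta_qaly: float,
    gdp: float,
    favorable_boundary: bool = True,
) -> str:
    """WHO GDP-per-capita threshold classification of an incremental result.

    For an intervention that *gains* QALYs, the cost per QALY gained is
    compared with 1x and 3x GDP per capita: below 1x is highly
    cost-effective, between 1x and 3x cost-effective, above 3x not
    cost-effective (a cost-saving gain is dominant).  For an intervention
    that *loses* QALYs the rule reverses: it must save money, and the
    savings per QALY lost must exceed 3x GDP to be highly cost-effective,
    1-3x GDP to be cost-effective; smaller savings are not cost-effective
    (a costlier loss is dominated).

    Ratios exactly on a boundary take the more favorable class by default;
    set ``favorable_boundary=False`` for the opposite convention.
    """
    if gdp <= 0:
        raise ValueError("GDP per capita must be positive")
    if delta_qaly == 0.0:
        if delta_cost < 0:
            return "dominant"
        if delta_cost > 0:
            return "dominated"
        return "equivalent"

    ratio = delta_cost / delta_qaly
    lo, hi = gdp, 3.0 * gdp

    def below(x, bound):
        return x <= bound if favorable_boundary else x < bound

    def above(x, bound):
        return x >= bound if favorable_boundary else x > bound

    if delta_qaly > 0:
        if delta_cost <= 0:
            return "dominant"
        if below(ratio, lo):
            return "highly cost-effective"
        if below(ratio, hi):
            return "cost-effective"
        return "not cost-effective"
    # utility-losing arm: needs cost savings
    if delta_cost >= 0:
        return "dominated"
    savings_per_qaly_lost = ratio  # both deltas negative -> positive ratio
    if above(savings_per_qaly_lost, hi):
        return "highly cost-effective"
    if above(savings_per_qaly_lost, lo):
        return "cost-effective"
    return "not cost-effective"


def incremental_ratios(
    comparator: StrategySummary,
    baseline: StrategySummary,
    gdp: float,
) -> EconResult:
    """Incremental cost-effectiveness/cost-utility comparison.

    Undefined ratios (zero denominator) are reported as NaN; the
    classification then falls back to the cost comparison alone.
    """
    dc = comparator.cost - baseline.cost
    dq = comparator.qaly - baseline.qaly
    dy = (comparator.years_without_blindness - baseline.years_without_blindness)
    if dc == 0.0 and dq == 0.0 and dy == 0.0:
        classification = "equivalent"
    else:
        classification = who_classify(dc, dq, gdp)
    return EconResult(
        comparator=comparator,
        baseline=baseline,
        delta_cost=dc,
        delta_qaly=dq,
        delta_ywb=dy,
        icer=_safe_ratio(dc, dy),
        icur=_safe_ratio(dc, dq),
        classification=classification,
    )


def net_monetary_benefit(summary: StrategySummary, wtp: float) -> float:
    """Net monetary benefit ``NMB = wtp * QALY - cost`` at a
    willingness-to-pay threshold (USD per QALY)."""
    if wtp < 0:
        raise ValueError("willingness-to-pay threshold must be nonnegative")
    return wtp * summary.qaly - summary.cost
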