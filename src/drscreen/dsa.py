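"""One-way deterministic sensitivity analysis.

Each swept parameter is moved to its range endpoints with everything else
held at base, the paired model is re-run, and the excursion of the
incremental cost-utility ratio (and its classification) is recorded.
Entries are tornado-ordered by descending ICUR spread; endpoints where the
ratio changes meaning (dominance, sign flip of the QALY difference) are
flagged categorically and listed apart rather than plotted as spread —
in particular the AI compliance multiplier, whose excursions can make the
AI arm outright dominant or dominated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .params import load_parameters
from .run import base_case

__all__ = ["TornadoEntry", "one_way_sweep", "tornado", "compliance_threshold_scan"]


@dataclass
class TornadoEntry:
    """ICUR excursion of one parameter over its deterministic range."""

    parameter: str
    low: float
    high: float
    icur_at_low: float
    icur_at_high: float
    class_at_low: str
    class_at_high: str
    flagged: bool          # an endpoint is dominant/dominated/undefined

    @property
    def spread(self) -> float:
        if self.flagged:
            return math.nan
        return abs(self.icur_at_high - self.icur_at_low)


_FLAG_CLASSES = {"dominant", "dominated", "equivalent"}


def _endpoint(config, name: str, value: float) -> tuple[float, str, float]:
    res, _ = base_case(config, overrides={name: value})
    return res.icur, res.classification, res.delta_qaly


def one_way_sweep(config, name: str) -> TornadoEntry:
    """Re-run the paired model at one parameter's low and high endpoints."""
    params, _ = load_parameters(config)
    if name not in params.specs:
        raise KeyError(f"unknown parameter: {name}")
    spec = params.specs[name]
    icur_lo, cls_lo, dq_lo = _endpoint(config, name, spec.low)
    icur_hi, cls_hi, dq_hi = _endpoint(config, name, spec.high)
    base_res, _ = base_case(config)
    # an endpoint is flagged when the ratio stops being comparable with the
    # base-case quadrant: dominance, or a QALY-difference sign flip
    flagged = (
        cls_lo in _FLAG_CLASSES or cls_hi in _FLAG_CLASSES
        or not math.isfinite(icur_lo) or not math.isfinite(icur_hi)
        or math.copysign(1, dq_lo) != math.copysign(1, base_res.delta_qaly)
        or math.copysign(1, dq_hi) != math.copysign(1, base_res.delta_qaly)
    )
    return TornadoEntry(name, spec.low, spec.high, icur_lo, icur_hi,
                        cls_lo, cls_hi, flagged)


def tornado(config=None, parameters: Iterable[str] | None = None) -> pd.DataFrame:
    """Sweep every non-degenerate parameter; tornado-ordered table.

    Finite entries come first, sorted by descending ICUR spread; flagged
    entries follow.  The base case is re-verified after the sweep, so the
    analysis is side-effect-free by construction.
    """
    params, _ = load_parameters(config)
    if parameters is None:
        parameters = [n for n, s in params.specs.items() if s.high > s.low]
    entries = [one_way_sweep(config, n) for n in parameters]
    frame = pd.DataFrame([{
        "parameter": e.parameter,
        "low": e.low,
        "high": e.high,
        "icur_at_low": e.icur_at_low,
        "icur_at_high": e.icur_at_high,
        "class_at_low": e.class_at_low,
        "class_at_high": e.class_at_high,
        "flagged": e.flagged,
        "spread": e.spread,
    } for e in entries])
    frame = frame.sort_values(
        ["flagged", "spread"], ascending=[True, False], na_position="last"
    ).reset_index(drop=True)
    return frame


def compliance_threshold_scan(
    config=None,
    multipliers: Iterable[float] | None = None,
) -> pd.DataFrame:
    """Classification of the AI arm over a grid of compliance multipliers.

    The multiplier is applied to the AI arm's referral compliance only
    (it represents the behavioural change induced by immediate AI
    feedback).  Returns one row per multiplier with the incremental
    outcomes and WHO classification, so the smallest multiplier reaching
    each class transition can be read off the grid.
    """
    if multipliers is None:
        multipliers = np.round(np.arange(0.75, 1.2501, 0.025), 4)
    rows = []
    for m in multipliers:
        res, _ = base_case(config, overrides={"compliance_multiplier_ai": float(m)})
        rows.append({
            "multiplier": float(m),
            "delta_cost_per_person": res.delta_cost,
            "delta_qaly_per_person": res.delta_qaly,
            "icur": res.icur,
            "classification": res.classification,
        })
    return pd.DataFrame(rows)


def first_crossings(scan: pd.DataFrame) -> Mapping[str, float]:
    """Smallest multiplier at which each classification first appears."""
    out: dict[str, float] = {}
    for _, row in scan.sort_values("multiplier").iterrows():
        out.setdefault(row["classification"], row["multiplier"])
    return out
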