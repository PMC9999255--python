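"""Care-pathway cost flows from a societal perspective.

Each flow is split into direct medical, direct nonmedical and indirect
components.  First-year treatment and first-year blindness carry different
costs from subsequent years; rather than expanding the Markov state space
with tunnel states, the engine tracks inflows and this module charges
first-year costs on the inflow mass and follow-up costs on the continuing
mass (identical expected values, smaller state space).

Wage loss of the participants themselves and of accompanying family
members at screening and at referral is zero for this 65+ cohort, but the
component structure keeps the slots so other settings can populate them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import ModelParameters, StrategyConfig, STATES

__all__ = ["CostComponents", "PathwayCosts", "CycleTallies", "cycle_costs",
           "blindness_tunnel"]

_IDX = {s: i for i, s in enumerate(STATES)}


@dataclass(frozen=True)
class CostComponents:
    """A cost split into direct medical / direct nonmedical / indirect USD."""

    direct_medical: float
    direct_nonmedical: float
    indirect: float

    def __post_init__(self):
        for f, v in (("direct_medical", self.direct_medical),
                     ("direct_nonmedical", self.direct_nonmedical),
                     ("indirect", self.indirect)):
            if v < 0:
                raise ValueError(f"negative cost component {f}={v}")

    @property
    def total(self) -> float:
        return self.direct_medical + self.direct_nonmedical + self.indirect

    @classmethod
    def from_total(cls, total: float, shares: tuple[float, float, float]) -> "CostComponents":
        return cls(total * shares[0], total * shares[1], total * shares[2])

    def scaled(self, w: float) -> "CostComponents":
        return CostComponents(self.direct_medical * w, self.direct_nonmedical * w,
                              self.indirect * w)

    def __add__(self, other: "CostComponents") -> "CostComponents":
        return CostComponents(
            self.direct_medical + other.direct_medical,
            self.direct_nonmedical + other.direct_nonmedical,
            self.indirect + other.indirect,
        )


ZERO = CostComponents(0.0, 0.0, 0.0)


@dataclass(frozen=True)
class PathwayCosts:
    """Per-event / per-year cost blocks for one strategy arm."""

    screening_per_attendee: float
    referral_exam: CostComponents
    treatment_first_year_dme: CostComponents     # 3 anti-VEGF injections
    treatment_first_year_stdr: CostComponents    # photocoagulation or vitrectomy
    treatment_followup_dme: CostComponents       # 1 injection + annual review
    treatment_followup_stdr: CostComponents      # annual outpatient review
    blindness_first_year: CostComponents
    blindness_followup: CostComponents           # indirect costs only

    def __post_init__(self):
        if self.screening_per_attendee < 0:
            raise ValueError("negative screening cost")
        if self.blindness_followup.direct_medical or self.blindness_followup.direct_nonmedical:
            raise ValueError("blindness follow-up years carry indirect costs only")

    @classmethod
    def from_parameters(cls, params: ModelParameters,
                        strategy: StrategyConfig) -> "PathwayCosts":
        v = params.values
        ref = params.component_shares["referral_exam"]
        trt = params.component_shares["treatment"]
        blind = params.component_shares["blindness_first_year"]
        return cls(
            screening_per_attendee=strategy.screening_cost_per_attendee,
            referral_exam=CostComponents.from_total(v["cost_referral_exam"], ref),
            treatment_first_year_dme=CostComponents.from_total(
                v["cost_tx_first_year_dme"], trt),
            treatment_first_year_stdr=CostComponents.from_total(
                v["cost_tx_first_year_stdr"], trt),
            treatment_followup_dme=CostComponents.from_total(
                v["cost_tx_followup_dme"], trt),
            treatment_followup_stdr=CostComponents.from_total(
                v["cost_tx_followup_stdr"], trt),
            blindness_first_year=CostComponents.from_total(
                v["cost_blind_first_year"], blind),
            blindness_followup=CostComponents(
                0.0, 0.0, v["cost_blind_followup_indirect"]),
        )


@dataclass
class CycleTallies:
    """Per-cycle screening event bookkeeping (expected per-person mass)."""

    screened: float = 0.0
    true_positives: float = 0.0
    false_positives: float = 0.0
    referrals_completed: float = 0.0
    treatments_started_stdr: float = 0.0
    treatments_started_dme: float = 0.0


def blindness_tunnel(blind_occupancy: np.ndarray,
                     blind_inflow: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Split blind occupancy into first-year and continuing mass.

    ``blind_inflow[k]`` is the probability mass that entered the blind state
    during the transition into cycle ``k`` (for cycle 0 it is the initial
    blind occupancy).  Continuing mass is the remainder.
    """
    newly = np.asarray(blind_inflow, dtype=float)
    continuing = np.asarray(blind_occupancy, dtype=float) - newly
    if np.any(continuing < -1e-12):
        raise ValueError("blind inflow exceeds blind occupancy")
    return newly, np.clip(continuing, 0.0, None)


def cycle_costs(
    occupancy_pre: np.ndarray,
    tallies: CycleTallies,
    costs: PathwayCosts,
    newly_blind: float,
    continuing_blind: float,
) -> CostComponents:
    """Expected per-person cost flow for one cycle, undiscounted.

    ``occupancy_pre`` is the state occupancy at cycle start (before
    screening); treated-state follow-up costs accrue on that mass, while
    first-year treatment costs accrue on this cycle's screening inflow
    recorded in ``tallies``.
    """
    flow = CostComponents(costs.screening_per_attendee * tallies.screened, 0.0, 0.0)
    flow = flow + costs.referral_exam.scaled(tallies.referrals_completed)
    flow = flow + costs.treatment_first_year_stdr.scaled(tallies.treatments_started_stdr)
    flow = flow + costs.treatment_first_year_dme.scaled(tallies.treatments_started_dme)
    flow = flow + costs.treatment_followup_stdr.scaled(occupancy_pre[_IDX["stdr_treated"]])
    flow = flow + costs.treatment_followup_dme.scaled(occupancy_pre[_IDX["dme_treated"]])
    flow = flow + costs.blindness_first_year.scaled(newly_blind)
    flow = flow + costs.blindness_followup.scaled(continuing_blind)
    return flow
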