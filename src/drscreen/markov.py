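"""Discrete-time cohort state-transition engine.

The cohort of 65-year-old community residents with diabetes moves through
eight health states over annual cycles:

    no DR -> non-sight-threatening DR -> {STDR, DME} -> blindness -> death

STDR and DME are parallel severe branches, each split into an undetected
and a treated sub-state.  Disease never regresses: treatment (reached via
screening, referral and confirmation) only multiplies the annual
progression-to-blindness probability by a factor below one.  Death is
reachable from every state at the age-specific background probability,
adjusted per state through an odds-ratio transform.

Cycle event order: screening -> accrual of cycle costs and utilities ->
transition.  Screening detections feed treatment within the same annual
cycle, matching a programme that returns results and completes referrals
within weeks of the screening visit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np
import pandas as pd

from .costing import CostComponents, CycleTallies, PathwayCosts, cycle_costs
from .params import ModelParameters, StrategyConfig, STATES

__all__ = ["HealthState", "CohortTrace", "StrategySummary", "discount",
           "apply_mortality_or", "build_transition_matrix", "screening_update",
           "run_cohort"]


class HealthState(IntEnum):
    NO_DR = 0
    NON_STDR = 1
    STDR_UNDETECTED = 2
    STDR_TREATED = 3
    DME_UNDETECTED = 4
    DME_TREATED = 5
    BLIND = 6
    DEAD = 7


N_STATES = len(HealthState)
_ALIVE = slice(0, 7)
_NON_BLIND_ALIVE = slice(0, 6)


def discount(value: float, rate: float, cycle: int) -> float:
    """Present value of ``value`` accrued at cycle index ``cycle``."""
    if rate < 0:
        raise ValueError("discount rate must be nonnegative")
    if cycle < 0:
        raise ValueError("cycle index must be nonnegative")
    return value / (1.0 + rate) ** cycle


def apply_mortality_or(base_prob: float, odds_ratio: float) -> float:
    """Adjust an annual death probability by a state-specific odds ratio.

    The probability is mapped to odds, multiplied, and mapped back:
    ``q = OR*o / (1 + OR*o)`` with ``o = p / (1 - p)``.
    """
    if not 0.0 <= base_prob <= 1.0:
        raise ValueError(f"base probability {base_prob} outside [0, 1]")
    if odds_ratio <= 0:
        raise ValueError(f"odds ratio must be positive, got {odds_ratio}")
    if base_prob == 1.0:
        import warnings

        warnings.warn("base mortality probability is 1; state adjustment is moot")
        return 1.0
    o = base_prob / (1.0 - base_prob) * odds_ratio
    return o / (1.0 + o)


class ConfigurationError(ValueError):
    """A structurally invalid transition-row composition."""


def build_transition_matrix(
    params: ModelParameters,
    age: float,
    strategy: StrategyConfig | None = None,
) -> np.ndarray:
    """Row-stochastic annual transition matrix for the given age.

    Screening and referral are handled separately (see
    :func:`screening_update`), so the matrix does not depend on the
    strategy arm; the argument is accepted for interface symmetry.
    """
    t = params.transitions
    mult = params.rx_progression_multiplier
    base_q = params.background_mortality(age)
    q = np.array([
        apply_mortality_or(base_q, params.mortality_odds_ratios[s])
        for s in range(N_STATES - 1)
    ] + [1.0])

    M = np.zeros((N_STATES, N_STATES))
    rows: list[tuple[int, list[tuple[int, float]]]] = [
        (HealthState.NO_DR, [(HealthState.NON_STDR, t["p_no_dr_to_non_stdr"])]),
        (HealthState.NON_STDR, [
            (HealthState.STDR_UNDETECTED, t["p_non_stdr_to_stdr"]),
            (HealthState.DME_UNDETECTED, t["p_non_stdr_to_dme"]),
        ]),
        (HealthState.STDR_UNDETECTED, [(HealthState.BLIND, t["p_stdr_to_blind"])]),
        (HealthState.STDR_TREATED, [(HealthState.BLIND, t["p_stdr_to_blind"] * mult)]),
        (HealthState.DME_UNDETECTED, [(HealthState.BLIND, t["p_dme_to_blind"])]),
        (HealthState.DME_TREATED, [(HealthState.BLIND, t["p_dme_to_blind"] * mult)]),
        (HealthState.BLIND, []),
    ]
    for s, moves in rows:
        total = q[s]
        M[s, HealthState.DEAD] = q[s]
        for dest, p in moves:
            M[s, dest] = p
            total += p
        if total > 1.0 + 1e-12:
            raise ConfigurationError(
                f"outgoing probabilities from state {STATES[s]} at age {age} "
                f"sum to {total:.6f} > 1"
            )
        M[s, s] = max(0.0, 1.0 - total)
    M[HealthState.DEAD, HealthState.DEAD] = 1.0
    return M


def screening_update(
    occupancy: np.ndarray, strategy: StrategyConfig
) -> tuple[np.ndarray, CycleTallies]:
    """Apply one round of screening, grading, referral and treatment start.

    Undetected severe-disease mass is detected with the arm's sensitivity
    and completes the confirmatory hospital referral with the effective
    compliance; that mass starts treatment in the same cycle.  Disease-free
    and mild-disease mass generates false-positive referral events at
    ``(1 - specificity) * effective_compliance`` (an examination cost with
    no state change).  Detected-but-noncompliant patients stay in the
    undetected sub-state and are re-screened next year, as are all other
    alive states in an annual programme.
    """
    occ = np.asarray(occupancy, dtype=float)
    if occ.min() < -1e-12:
        raise ValueError("occupancy has negative mass")
    ec = strategy.effective_compliance
    move = strategy.sensitivity * ec
    fp_rate = (1.0 - strategy.specificity) * ec

    out = occ.copy()
    started_stdr = occ[HealthState.STDR_UNDETECTED] * move
    started_dme = occ[HealthState.DME_UNDETECTED] * move
    out[HealthState.STDR_UNDETECTED] -= started_stdr
    out[HealthState.STDR_TREATED] += started_stdr
    out[HealthState.DME_UNDETECTED] -= started_dme
    out[HealthState.DME_TREATED] += started_dme

    fp = (occ[HealthState.NO_DR] + occ[HealthState.NON_STDR]) * fp_rate
    tallies = CycleTallies(
        screened=float(occ[_ALIVE].sum()),
        true_positives=float(started_stdr + started_dme),
        false_positives=float(fp),
        referrals_completed=float(started_stdr + started_dme + fp),
        treatments_started_stdr=float(started_stdr),
        treatments_started_dme=float(started_dme),
    )
    return out, tallies


@dataclass
class StrategySummary:
    """Lifetime per-person outcomes for one strategy arm."""

    name: str
    cost: float                       # discounted USD per person
    qaly: float                       # discounted QALYs per person
    years_without_blindness: float    # per person (discounting per config)


@dataclass
class CohortTrace:
    """Per-cycle occupancy and accumulated outcomes of one cohort run."""

    strategy: str
    occupancy: np.ndarray             # (n_cycles + 1, 8) cycle-start occupancy
    discounted_cost: float
    undiscounted_cost: float
    discounted_qaly: float
    undiscounted_qaly: float
    years_without_blindness: float            # undiscounted accrual
    discounted_years_without_blindness: float
    discount_effects: bool
    tallies: list[CycleTallies] = field(default_factory=list)
    cost_flows: list[CostComponents] = field(default_factory=list)
    blind_inflow: np.ndarray | None = None    # per-cycle newly blind mass

    def summary(self) -> StrategySummary:
        ywb = (self.discounted_years_without_blindness
               if self.discount_effects else self.years_without_blindness)
        return StrategySummary(self.strategy, self.discounted_cost,
                               self.discounted_qaly, ywb)

    def occupancy_frame(self) -> pd.DataFrame:
        """Tidy (cycle, state, occupancy) table."""
        n = self.occupancy.shape[0]
        return pd.DataFrame({
            "cycle": np.repeat(np.arange(n), N_STATES),
            "state": np.tile(STATES, n),
            "occupancy": self.occupancy.ravel(),
        })

    def tally_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(t) for t in self.tallies]).assign(
            cycle=np.arange(len(self.tallies)))

    def cost_ledger(self, rate: float) -> pd.DataFrame:
        """Per-cycle cost components, undiscounted and discounted."""
        rows = []
        for k, flow in enumerate(self.cost_flows):
            d = discount(1.0, rate, k)
            for comp in ("direct_medical", "direct_nonmedical", "indirect"):
                v = getattr(flow, comp)
                rows.append({"cycle": k, "component": comp,
                             "undiscounted_usd": v, "discounted_usd": v * d})
        return pd.DataFrame(rows)


def run_cohort(params: ModelParameters, strategy: StrategyConfig) -> CohortTrace:
    """Run the cohort model over ``params.n_cycles`` annual cycles.

    Deterministic for fixed inputs.  Costs and utilities are discounted by
    cycle index at ``params.discount_rate``; years without blindness are
    accrued over all alive non-blind states and discounted only when
    ``params.discount_effects`` is set.  With ``params.half_cycle`` the
    state-membership accruals (utility and years without blindness) use the
    mean of cycle-start and cycle-end occupancy.
    """
    n = params.n_cycles
    costs = PathwayCosts.from_parameters(params, strategy)
    occupancy = np.zeros((n + 1, N_STATES))
    occupancy[0] = params.initial_distribution

    cost_d = cost_u = qaly_d = qaly_u = ywb_u = ywb_d = 0.0
    tallies_log: list[CycleTallies] = []
    flows: list[CostComponents] = []
    blind_inflow = np.zeros(n + 1)
    blind_inflow[0] = occupancy[0, HealthState.BLIND]

    occ = occupancy[0].copy()
    newly_blind = blind_inflow[0]
    for k in range(n):
        occ_pre = occ
        occ_post, tallies = screening_update(occ_pre, strategy)
        continuing_blind = occ_pre[HealthState.BLIND] - newly_blind
        flow = cycle_costs(occ_pre, tallies, costs, newly_blind,
                           max(0.0, continuing_blind))

        M = build_transition_matrix(params, params.start_age + k, strategy)
        occ_end = occ_post @ M
        inflow_next = float(
            occ_post[:HealthState.BLIND] @ M[:HealthState.BLIND, HealthState.BLIND]
        )

        membership = 0.5 * (occ_pre + occ_end) if params.half_cycle else occ_pre
        d = discount(1.0, params.discount_rate, k)
        u = float(membership @ params.utilities)
        alive_nonblind = float(membership[_NON_BLIND_ALIVE].sum())

        cost_u += flow.total
        cost_d += flow.total * d
        qaly_u += u
        qaly_d += u * d
        ywb_u += alive_nonblind
        ywb_d += alive_nonblind * d

        tallies_log.append(tallies)
        flows.append(flow)
        occupancy[k + 1] = occ_end
        blind_inflow[k + 1] = inflow_next
        occ = occ_end.copy()
        newly_blind = inflow_next

    return CohortTrace(
        strategy=strategy.name,
        occupancy=occupancy,
        discounted_cost=cost_d,
        undiscounted_cost=cost_u,
        discounted_qaly=qaly_d,
        undiscounted_qaly=qaly_u,
        years_without_blindness=ywb_u,
        discounted_years_without_blindness=ywb_d,
        discount_effects=params.discount_effects,
        tallies=tallies_log,
        cost_flows=flows,
        blind_inflow=blind_inflow,
    )
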