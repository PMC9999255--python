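"""Convenience drivers tying parameter loading, the cohort engine and the
economic comparison together."""

from __future__ import annotations

from typing import Mapping

from .econ import EconResult, incremental_ratios
from .markov import CohortTrace, run_cohort
from .params import ModelParameters, StrategyConfig, load_parameters

__all__ = ["run_strategies", "base_case"]


def run_strategies(
    params: ModelParameters, strategies: Mapping[str, StrategyConfig]
) -> dict[str, CohortTrace]:
    """Run the cohort once per strategy arm on a shared parameter set."""
    return {name: run_cohort(params, strat) for name, strat in strategies.items()}


def base_case(
    config=None,
    overrides: Mapping[str, float] | None = None,
    comparator: str = "ai",
    baseline: str = "manual",
) -> tuple[EconResult, dict[str, CohortTrace]]:
    """Load (or reuse) a configuration, run both arms and compare them.

    Returns the incremental comparison (comparator minus baseline) and the
    per-arm cohort traces.
    """
    params, strategies = load_parameters(config, overrides)
    traces = run_strategies(params, strategies)
    result = incremental_ratios(
        traces[comparator].summary(), traces[baseline].summary(),
        params.gdp_per_capita,
    )
    return result, traces
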