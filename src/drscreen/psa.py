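"""Probabilistic sensitivity analysis.

Each non-fixed parameter is given a parametric distribution by matching
moments: beta for probabilities and utilities, gamma for costs, log-normal
for odds ratios and multipliers.  The mean is the base-case value and the
standard deviation is derived from the deterministic range treated as a
95% interval, ``sd = (high - low) / (2 * 1.96)``.

A Monte Carlo run draws whole parameter sets (one shared draw feeds both
strategy arms, so incremental differences reflect strategy structure
rather than sampling noise), re-runs the paired model per draw, and
summarises the incremental cost/QALY scatter as cost-effectiveness
acceptability curves via net monetary benefit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .params import ParameterSpec, ValidationError, default_config, load_parameters
from .run import base_case

__all__ = ["DistributionFit", "PsaResult", "fit_distribution", "run_psa", "ceac"]

Z95 = 1.959963984540054  # two-sided 95% normal quantile


def range_sd(spec: ParameterSpec) -> float:
    return (spec.high - spec.low) / (2.0 * Z95)


@dataclass(frozen=True)
class DistributionFit:
    """Moment-matched sampling distribution for one parameter."""

    name: str
    family: str
    shape_a: float      # beta alpha / gamma shape / lognormal mu
    shape_b: float      # beta beta  / gamma rate  / lognormal sigma
    mean: float
    sd: float

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.sd == 0.0:
            return np.full(size, self.mean)
        if self.family == "beta":
            return rng.beta(self.shape_a, self.shape_b, size)
        if self.family == "gamma":
            return rng.gamma(self.shape_a, 1.0 / self.shape_b, size)
        if self.family == "lognormal":
            return rng.lognormal(self.shape_a, self.shape_b, size)
        raise ValueError(f"unsupported family {self.family}")


def fit_distribution(spec: ParameterSpec) -> DistributionFit:
    """Method-of-moments fit with mean = base and sd from the range.

    beta:      alpha = m (m(1-m)/v - 1),  beta = (1-m)(m(1-m)/v - 1)
    gamma:     shape = m^2 / v,           rate = m / v
    lognormal: sigma^2 = ln(1 + v/m^2),   mu = ln m - sigma^2 / 2
               (matching the mean and sd of the quantity itself)
    """
    if spec.dist == "fixed":
        raise ValueError(f"{spec.name}: fixed parameters have no distribution fit")
    m = spec.base
    sd = range_sd(spec)
    v = sd * sd
    if v == 0.0:
        return DistributionFit(spec.name, spec.dist, 0.0, 0.0, m, 0.0)
    if spec.dist == "beta":
        if not 0.0 < m < 1.0:
            raise ValueError(f"{spec.name}: beta mean must lie strictly in (0, 1)")
        if v >= m * (1.0 - m):
            raise ValueError(
                f"{spec.name}: variance {v:.3g} too large for a beta with mean "
                f"{m}; narrow the range"
            )
        nu = m * (1.0 - m) / v - 1.0
        return DistributionFit(spec.name, "beta", m * nu, (1.0 - m) * nu, m, sd)
    if spec.dist == "gamma":
        if m <= 0:
            raise ValueError(f"{spec.name}: gamma mean must be positive")
        return DistributionFit(spec.name, "gamma", m * m / v, m / v, m, sd)
    if spec.dist == "lognormal":
        if m <= 0:
            raise ValueError(f"{spec.name}: lognormal mean must be positive")
        sigma2 = np.log1p(v / (m * m))
        mu = np.log(m) - sigma2 / 2.0
        return DistributionFit(spec.name, "lognormal", mu, float(np.sqrt(sigma2)),
                               m, sd)
    raise ValueError(f"{spec.name}: unknown family {spec.dist}")


@dataclass
class PsaResult:
    """Monte Carlo incremental scatter plus bookkeeping."""

    draws: pd.DataFrame     # per-draw arm outcomes and incrementals
    seed: int
    n_rejected: int
    gdp_per_capita: float

    @property
    def n_draws(self) -> int:
        return len(self.draws)


def run_psa(
    config=None,
    n_draws: int = 10_000,
    seed: int = 0,
    comparator: str = "ai",
    baseline: str = "manual",
    max_reject_fraction_warn: float = 0.01,
) -> PsaResult:
    """Monte Carlo PSA: ``n_draws`` paired model runs on random parameter sets.

    Deterministic given ``seed``.  Draws whose parameter set fails
    validation (for example an outgoing-probability row exceeding one) are
    rejected and redrawn; more than ``max_reject_fraction_warn`` rejections
    triggers a warning naming the most frequently offending parameter.
    """
    if config is None:
        config = default_config()
    params, _ = load_parameters(config)
    fits = {
        name: fit_distribution(spec)
        for name, spec in params.specs.items()
        if spec.dist != "fixed" and spec.high > spec.low
    }
    rng = np.random.default_rng(seed)
    samples = {name: fit.sample(rng, n_draws) for name, fit in fits.items()}

    rows = []
    n_rejected = 0
    offenders: dict[str, int] = {}
    for i in range(n_draws):
        overrides = {name: float(col[i]) for name, col in samples.items()}
        while True:
            try:
                res, _ = base_case(config, overrides=overrides,
                                   comparator=comparator, baseline=baseline)
                break
            except (ValidationError, ValueError) as exc:
                n_rejected += 1
                for name in overrides:
                    if name in str(exc):
                        offenders[name] = offenders.get(name, 0) + 1
                overrides = {name: float(fit.sample(rng, 1)[0])
                             for name, fit in fits.items()}
        rows.append({
            "draw": i,
            "cost_comparator": res.comparator.cost,
            "qaly_comparator": res.comparator.qaly,
            "cost_baseline": res.baseline.cost,
            "qaly_baseline": res.baseline.qaly,
            "delta_cost": res.delta_cost,
            "delta_qaly": res.delta_qaly,
            "delta_ywb": res.delta_ywb,
        })
    if n_draws and n_rejected / n_draws > max_reject_fraction_warn:
        import warnings

        worst = max(offenders, key=offenders.get) if offenders else "unknown"
        warnings.warn(
            f"{n_rejected} of {n_draws} PSA draws rejected; worst offender: {worst}"
        )
    return PsaResult(pd.DataFrame(rows), seed, n_rejected, params.gdp_per_capita)


def default_thresholds(gdp: float, n: int = 200) -> np.ndarray:
    """0 to 3x GDP grid with the 1x and 3x GDP thresholds forced onto it."""
    grid = np.linspace(0.0, 3.0 * gdp, n)
    return np.unique(np.concatenate([grid, [gdp, 3.0 * gdp]]))


def ceac(psa: PsaResult, thresholds: np.ndarray | None = None) -> pd.DataFrame:
    """Cost-effectiveness acceptability curves.

    At each willingness-to-pay threshold, the probability a strategy is
    optimal is the fraction of draws in which it has the maximal net
    monetary benefit; exact ties are split equally.
    """
    if psa.n_draws == 0:
        raise ValueError("PSA contains no draws")
    if thresholds is None:
        thresholds = default_thresholds(psa.gdp_per_capita)
    dq = psa.draws["delta_qaly"].to_numpy()
    dc = psa.draws["delta_cost"].to_numpy()
    rows = []
    for lam in np.asarray(thresholds, dtype=float):
        dnmb = lam * dq - dc  # comparator NMB minus baseline NMB
        p_comp = float(np.mean(dnmb > 0) + 0.5 * np.mean(dnmb == 0))
        rows.append({
            "threshold": lam,
            "p_comparator_optimal": p_comp,
            "p_baseline_optimal": 1.0 - p_comp,
        })
    return pd.DataFrame(rows)
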