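#!/usr/bin/env python
"""Validate the cohort engine against the individual-level oracle.

For a handful of randomly generated parameter scenarios, compares the
cohort model's expected cost, QALYs and years without blindness with a
200,000-individual microsimulation sharing the same transition matrices,
and reports the z-scores.  Writes results/validation/oracle_comparison.csv.
"""

from pathlib import Path

import pandas as pd

from drscreen.markov import run_cohort
from drscreen.synthetic import generate_scenario, microsim_oracle

OUT = Path("results/validation")
N_SCENARIOS = 8
N_INDIVIDUALS = 200_000

if __name__ == "__main__":
    rows = []
    for seed in range(N_SCENARIOS):
        sc = generate_scenario(5000 + seed)
        micro = microsim_oracle(sc.params, sc.strategies,
                                n_individuals=N_INDIVIDUALS, seed=seed)
        for name, strat in sc.strategies.items():
            trace = run_cohort(sc.params, strat)
            m = micro[name]
            rows.append({
                "scenario": seed, "strategy": name,
                "cohort_cost": trace.discounted_cost, "microsim_cost": m.cost,
                "z_cost": (trace.discounted_cost - m.cost) / m.cost_se,
                "cohort_qaly": trace.discounted_qaly, "microsim_qaly": m.qaly,
                "z_qaly": (trace.discounted_qaly - m.qaly) / m.qaly_se,
                "z_ywb": (trace.years_without_blindness
                          - m.years_without_blindness)
                / m.years_without_blindness_se,
            })
    frame = pd.DataFrame(rows)
    OUT.mkdir(parents=True, exist_ok=True)
    frame.to_csv(OUT / "oracle_comparison.csv", index=False)
    zmax = frame[["z_cost", "z_qaly", "z_ywb"]].abs().max().max()
    print(frame.round(4).to_string(index=False))
    print(f"\nLargest |z| across {N_SCENARIOS} scenarios x 2 arms: {zmax:.2f}")
    print("Values within ~3 indicate the deterministic expectation "
          "bookkeeping matches the stochastic oracle.")
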