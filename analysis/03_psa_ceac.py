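#!/usr/bin/env python
"""Probabilistic sensitivity analysis and acceptability curves.

Draws 10,000 full parameter sets (beta for probabilities/utilities, gamma
for costs, log-normal for odds ratios and the compliance multiplier),
re-runs the paired model on each, and writes the incremental scatter and
the cost-effectiveness acceptability curves to results/psa/.  When
matplotlib is importable, the scatter and CEAC figures are rendered too.
"""

from pathlib import Path

import pandas as pd

from drscreen.cli import main

OUT = Path("results/psa")
SEED = 20260926 % (2**31)


def plot(scatter: pd.DataFrame, curves: pd.DataFrame, gdp: float) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    ax.scatter(scatter["delta_qaly"], scatter["delta_cost"], s=2, alpha=0.25)
    ax.axhline(0, color="k", lw=0.6)
    ax.axvline(0, color="k", lw=0.6)
    ax.set_xlabel("incremental QALYs (AI minus manual)")
    ax.set_ylabel("incremental cost, USD")
    fig.tight_layout()
    fig.savefig(OUT / "psa_scatter.png", dpi=150)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(curves["threshold"], curves["p_comparator_optimal"], label="AI")
    ax.plot(curves["threshold"], curves["p_baseline_optimal"], label="manual")
    for lam in (gdp, 3 * gdp):
        ax.axvline(lam, color="grey", lw=0.7, ls=":")
    ax.set_xlabel("willingness to pay, USD per QALY")
    ax.set_ylabel("probability optimal")
    ax.legend()
    fig.tight_layout()
    fig.savefig(OUT / "ceac.png", dpi=150)
    plt.close(fig)


if __name__ == "__main__":
    main(["run-psa", "--draws", "10000", "--seed", str(SEED),
          "--out-dir", str(OUT)])
    scatter = pd.read_csv(OUT / "psa_scatter.csv")
    curves = pd.read_csv(OUT / "ceac.csv")
    try:
        plot(scatter, curves, 22_600.0)
        print(f"Figures written under {OUT}/.")
    except ImportError:
        pass
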