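#!/usr/bin/env python
"""Periodogram amplitudes and periods across growth regimes.

Reads the cohorts written by 01_simulate_cohorts.py (scratch/data/), runs the
select/detrend/periodogram/dominant-component pipeline per cell, and
compares the three regimes (median + bootstrap CI, Dunn's test with
Holm adjustment). Writes per-cell components and summaries under
results/oscillometry/ plus an amplitude strip plot.
"""

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

import vacuoscope as v
from vacuoscope import io

ROOT = Path(__file__).resolve().parent.parent / "results"
SCRATCH = Path(__file__).resolve().parent.parent / "scratch"
OUT = ROOT / "oscillometry"
MEDIA = ("sdc", "sceg", "ynbd")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    components, rows = {}, []
    for i, medium in enumerate(MEDIA):
        traces = io.read_traces_csv(SCRATCH / "data" / f"traces_vsep_{medium}.csv")
        comps = v.analyze_cohort(traces, "vsep", min_span=500.0)
        components[medium] = comps
        summary = v.cohort_summary(comps, label=medium, seed=100 + i)
        rows.append(
            {
                "medium": medium,
                "n_cells": summary.n_cells,
                "median_amplitude_au2": summary.median_amplitude,
                "amplitude_ci_lo": summary.amplitude_ci[0],
                "amplitude_ci_hi": summary.amplitude_ci[1],
                "median_period_min": summary.median_period,
                "period_ci_lo": summary.period_ci[0],
                "period_ci_hi": summary.period_ci[1],
            }
        )
        print(
            f"{medium.upper()}: n={summary.n_cells} median amplitude "
            f"{summary.median_amplitude:.4g} AU^2 "
            f"(95% CI {summary.amplitude_ci[0]:.4g}-{summary.amplitude_ci[1]:.4g}), "
            f"median period {summary.median_period:.1f} min"
        )
        pd.DataFrame(
            {
                "cell_id": [t.cell_id for t in v.select_traces(traces)],
                "amplitude_au2": [c.amplitude for c in comps],
                "period_min": [c.period for c in comps],
            }
        ).to_csv(OUT / f"components_{medium}.csv", index=False)
    pd.DataFrame(rows).to_csv(OUT / "cohort_summaries.csv", index=False)

    groups = {m: [c.amplitude for c in components[m]] for m in MEDIA}
    cmp_ = v.dunn_holm_compare(groups)
    pd.DataFrame(
        {
            "pair": [f"{a}_vs_{b}" for a, b in cmp_.pairs],
            "z": cmp_.z,
            "p_raw": cmp_.p_raw,
            "p_holm": cmp_.p_adjusted,
        }
    ).to_csv(OUT / "dunn_holm.csv", index=False)
    for (a, b), z, p in zip(cmp_.pairs, cmp_.z, cmp_.p_adjusted):
        print(f"Dunn {a} vs {b}: z={z:+.2f}, Holm-adjusted p={p:.3g}")
    ratio = np.median(groups["sceg"]) / np.median(groups["sdc"])
    print(f"SCEG/SDC median amplitude fold change: {ratio:.2f}")

    fig, ax = plt.subplots(figsize=(5, 4))
    rng = np.random.default_rng(0)
    for i, m in enumerate(MEDIA):
        y = np.asarray(groups[m])
        ax.scatter(i + rng.uniform(-0.15, 0.15, len(y)), y, s=6, alpha=0.5)
        ax.hlines(np.median(y), i - 0.25, i + 0.25, color="red")
    ax.set_xticks(range(len(MEDIA)), [m.upper() for m in MEDIA])
    ax.set_yscale("log")
    ax.set_ylabel("dominant periodogram amplitude (AU$^2$)")
    fig.tight_layout()
    fig.savefig(OUT / "amplitudes.png", dpi=150)


if __name__ == "__main__":
    main()
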