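#!/usr/bin/env python
"""Cell-size-control regression: wild type versus a size-control mutant.

Reads the size cohorts from 01_simulate_cohorts.py (scratch/data/), regresses relative
G1 growth ln(V_bud/V_birth) on ln(birth volume) per cohort, and runs
the extra-sum-of-squares F-test comparing the two slopes. Writes fits
under results/size_control/ with a scatter + fit-line figure.
"""

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

import vacuoscope as v
from vacuoscope import io
from vacuoscope.size_control import records_frame

ROOT = Path(__file__).resolve().parent.parent / "results"
SCRATCH = Path(__file__).resolve().parent.parent / "scratch"
OUT = ROOT / "size_control"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cohorts = {
        name: io.read_sizes_csv(SCRATCH / "data" / f"sizes_{name}.csv") for name in ("wt", "mutant")
    }
    rows = {}
    for name, records in cohorts.items():
        fit = v.fit_size_control(records)
        rows[name] = fit
        print(
            f"{name}: slope {fit.slope:+.3f} +/- {fit.stderr:.3f} "
            f"(p={fit.pvalue:.2g}, r^2={fit.r_squared:.2f}, n={fit.n})"
        )
    pd.DataFrame(
        [
            {"cohort": k, "n": f.n, "slope": f.slope, "stderr": f.stderr,
             "pvalue": f.pvalue, "r_squared": f.r_squared}
            for k, f in rows.items()
        ]
    ).to_csv(OUT / "size_fits.csv", index=False)

    cmp_ = v.compare_slopes(cohorts["wt"], cohorts["mutant"])
    pd.DataFrame(
        [{"f_statistic": cmp_.f_statistic, "df_num": cmp_.df_num,
          "df_den": cmp_.df_den, "pvalue": cmp_.pvalue}]
    ).to_csv(OUT / "slope_comparison.csv", index=False)
    print(
        f"slope comparison: F(1,{cmp_.df_den}) = {cmp_.f_statistic:.1f}, p = {cmp_.pvalue:.2g}"
    )

    fig, ax = plt.subplots(figsize=(5, 4))
    for name, color in (("wt", "tab:blue"), ("mutant", "tab:red")):
        df = records_frame(cohorts[name])
        x, y = df["ln_v_birth"], df["rel_g1"]
        ax.scatter(x, y, s=8, alpha=0.5, color=color, label=name)
        xs = np.linspace(x.min(), x.max(), 20)
        ax.plot(xs, rows[name].intercept + rows[name].slope * xs, color=color)
    ax.set_xlabel("ln(birth volume)")
    ax.set_ylabel("relative G1 growth  ln($V_{bud}/V_{birth}$)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(OUT / "size_control.png", dpi=150)


if __name__ == "__main__":
    main()
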