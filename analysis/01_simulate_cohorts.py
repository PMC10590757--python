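#!/usr/bin/env python
"""Generate the synthetic study cohorts.

Writes, under scratch/data/ (bulky raw simulated data): v-SEP/mCherry trace cohorts for the three
growth regimes (SDC: regular cycle-locked pulses; SCEG: same but
sqrt(1.8)-fold pulse contrast; YNBD: brief stochastic pulses on a slow
drift), a ratiometric-dye cohort with cell-cycle annotations, the
in-situ calibration series, and two cell-size cohorts (wild-type sizer
and a slope -0.2 mutant-like cohort).
"""

from pathlib import Path

import vacuoscope as v
from vacuoscope import io
from vacuoscope._util import child_seed

SEED = 20260921
OUT = Path(__file__).resolve().parent.parent / "scratch" / "data"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    for i, medium in enumerate(("SDC", "SCEG", "YNBD")):
        cfg = v.cohort_config(medium, n_cells=150, seed=child_seed(SEED, i))
        traces, _ = v.make_cohort(cfg)
        io.write_traces_csv(traces, OUT / f"traces_vsep_{medium.lower()}.csv")
        print(f"{medium}: {len(traces)} cells x {traces[0].n} samples")

    cfg = v.cohort_config(
        "SDC", n_cells=15, seed=child_seed(SEED, 10), channels={"bcecf": v.BCECF, "ref": v.MCHERRY}
    )
    traces, _ = v.make_cohort(cfg)
    io.write_traces_csv(traces, OUT / "traces_bcecf_sdc.csv")
    io.write_annotations_csv(traces, OUT / "annotations_bcecf_sdc.csv")
    print(f"BCECF cohort: {len(traces)} annotated cells")

    series = v.make_calibration_series((v.BCECF, v.MCHERRY), seed=child_seed(SEED, 11))
    io.write_calibration_csv(series, OUT / "calibration_bcecf.csv")
    print(f"calibration series: {series.n} buffer points, pH {series.ph.min()}-{series.ph.max()}")

    wt = v.make_size_cohort(v.SizeCohortConfig(n=200, noise_sd=0.05, seed=child_seed(SEED, 12)))
    mut = v.make_size_cohort(
        v.SizeCohortConfig(n=200, mode="linear", slope=-0.2, noise_sd=0.12, seed=child_seed(SEED, 13))
    )
    io.write_sizes_csv(wt, OUT / "sizes_wt.csv")
    io.write_sizes_csv(mut, OUT / "sizes_mutant.csv")
    print(f"size cohorts: {len(wt)} wild-type (sizer), {len(mut)} mutant-like (slope -0.2)")


if __name__ == "__main__":
    main()
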