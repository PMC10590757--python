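# vacuoscope

Single-cell analysis of **cell-cycle-linked vacuolar pH oscillations** in
budding yeast.

The yeast vacuole — the cell's lysosome-like amino acid store — does not
hold a constant luminal pH. In cells growing with glucose and amino
acids, each cell cycle carries one transient alkalinization pulse: the
lumen rests near pH 5.82, rises to about pH 6.20 shortly before cell
separation (≈ 59 min after bud emergence, ≈ 6 min before separation),
and reacidifies — a ΔpH of ≈ 0.38 units per cycle with a period close to
85 min. The pulse regime depends on the medium: amino-acid-free medium
(YNBD) gives only brief stochastic pulses, and a respiratory carbon
source (SCEG) roughly doubles oscillation power. Loss of the oscillation
correlates with a breakdown of G1 cell-size control.

`vacuoscope` is the analysis stack for quantifying these dynamics from
timelapse fluorescence microscopy (or directly from per-cell trace
tables), plus a ground-truthed synthetic-data generator so every stage
is verifiable without microscope data:

| module | what it does |
| --- | --- |
| `vacuoscope.synthetic` | pH trajectories with per-cycle alkalinization pulses, fluorophore titration responses, rendered image stacks, calibration series, cell-size cohorts — all seeded and paired with ground truth |
| `vacuoscope.imaging` | rolling-ball background subtraction, translation registration, Laplacian-of-Gaussian blob detection (σ = d/2√2, default d = 27 px), motion-predictive one-to-one linking (gates 25/20 px), disk-aperture intensity extraction |
| `vacuoscope.oscillometry` | trace selection (≥ 500 min), OLS detrending, periodogram P(k) = \|X_k\|²/n, dominant (amplitude, period) per cell, bootstrap cohort medians, Dunn's test with Holm adjustment |
| `vacuoscope.ph_dynamics` | ratiometric calibration (linear or titration-sigmoid fit), ratio→pH conversion, peak detection with prominence and half-width, per-cycle min/peak/ΔpH, peak timing against bud emergence and cell separation |
| `vacuoscope.size_control` | ellipsoid volumes V = (4/3)·L·S², relative G1 growth ln(V_bud/V_birth), its regression on ln V_birth (slope −1 ⇔ sizer), extra-sum-of-squares F-test between cohorts |
| `vacuoscope.pipeline` / CLI | YAML-configured end-to-end runs with one fanned-out seed and CSV/JSON outputs |

## Core quantities

For a detrended trace x_t (n samples, spacing dt), the periodogram is

    P(k) = |Σ_t x_t e^(−2πi k t / n)|² / n ,  k = 1 … ⌊n/2⌋

and the **oscillatory vacuolar pH amplitude** is max_k P(k), with the
dominant period n·dt/k* at the argmax. Absolute pH comes from an in-situ
buffer series fit with the dye titration curve
R(pH) = R_min + (R_max − R_min) / (1 + 10^(pKa − pH)), inverted
analytically. Size control is the OLS slope β in
ln(V_bud/V_birth) = α + β·ln(V_birth): a cell that buds at a fixed
Start volume gives β = −1 exactly.

## Worked example

The numbered drivers under `analysis/` reproduce the whole study on
synthetic cohorts (raw simulated data lands in `scratch/`, derived
tables and figures in `results/`):

```bash
python analysis/01_simulate_cohorts.py
python analysis/02_track_rendered_stacks.py
python analysis/03_oscillation_spectra.py
python analysis/04_ph_cycle_metrics.py
python analysis/05_size_control.py
```

which prints, among other lines:

```
cells rendered: 12; full-length tracks: 12
mean localization error: 0.526 px (worst cell 1.268 px)
SCEG/SDC median amplitude fold change: 1.83
174 cycles from 15 cells: mean min pH 5.813, mean peak pH 6.196, mean delta pH 0.383
median half-maximal peak width: 11.5 min
bud emergence -> peak: 59.4 +/- 0.1 min; peak -> separation: 5.8 +/- 0.1 min (n=165 cycles)
wt: slope -1.003 +/- 0.015 (p=4.3e-137, r^2=0.96, n=200)
mutant: slope -0.208 +/- 0.048 (p=2.8e-05, r^2=0.09, n=200)
slope comparison: F(1,396) = 272.5, p = 6e-47
```

Read: every rendered vacuole is tracked to sub-pixel accuracy; the
respiratory-carbon cohort shows the expected ≈1.8-fold oscillation-power
increase; the calibrated ratiometric cohort recovers the acidic
baseline, alkaline peak, per-cycle ΔpH, pulse width and event timing it
was generated with; and the sizer cohort regresses to slope −1 while the
mutant-like cohort does not, a difference the F-test resolves decisively.

The same stages are available as a CLI for external data
(`vacuoscope simulate|track|quantify|ph|size-control|run`), e.g.

```bash
vacuoscope simulate --out-dir run --n-cells 20 --seed 7
vacuoscope quantify --out-dir run --min-span 500
vacuoscope ph --out-dir run --calibration calibration.csv
```

## Layout

```
src/vacuoscope/   library (all computation lives here)
analysis/         numbered narrative drivers over the library
tests/            pytest suite (unit, property and end-to-end recovery)
scripts/          acceptance script
docs/methods.md   models, parameter choices, numerical details, limitations
```
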