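# Methods

This note records the models behind `vacuoscope`, the defaults and why
they were chosen, the numerical conventions, and what the synthetic
benchmarks do and do not establish about real microscope data.

## 1. The oscillation model (`synthetic`)

A cell's vacuolar pH trajectory is an acidic baseline plus one Gaussian
alkalinization pulse per cell cycle:

    pH(t) = pH_base + c·t + h · Σ_k exp(−(t − t_k)² / 2σ²) + ε_t

* `ph_base = 5.82`, `ph_peak = 6.20` — the measured acidic baseline and
  alkaline maximum of cycling cells in glucose + amino acids (SDC).
  `h = (ph_peak − ph_base) · amplitude_multiplier`.
* `period = 85 min` — the observed median oscillation period (≈ 84.9).
  Regular-mode pulse maxima lie at `phase + k·period` on the half-open
  window (0, duration]; at phase 0 this gives exactly
  ⌊duration/period⌋ pulses. Per-cell phase is uniform over one period.
* `pulse_fwhm = 11 min` — pulses are parameterized by their
  full-width-at-half-maximum because that is the summary statistic the
  peak detector measures back (σ = FWHM / 2√(2 ln 2)). An asymmetry
  factor (trailing/leading width ratio) is available; the default is
  symmetric.
* `bud_to_peak = 59.4 min`, `peak_to_sep = 5.7 min` — event offsets used
  to synthesize bud-emergence and cell-separation annotations. Annotation
  times carry zero-mean Gaussian jitter of sd 1 min: events are read
  frame-accurately from a plasma-membrane marker, and the jitter must
  stay well below the 5.7-min peak→separation offset or the one-to-one
  matching of peaks to events becomes ambiguous by construction.
* `noise_sd = 0.01` pH per sample — additive Gaussian measurement noise
  on the pH scale, ~2.5% of the pulse height; a realistic figure for a
  ratio averaged over a whole vacuole.
* Modes: `regular` (one pulse per period), `stochastic_pulses` (Poisson
  pulse times, default rate 1/period; the YNBD regime with
  `pulse_fwhm = 2 min` and a slow drift of 3·10⁻⁴ pH/min standing in for
  the unexplained progressive intensity rise in amino-acid-free medium),
  and `flat` (no pulses).
* `amplitude_multiplier` scales the pulse height **in pH space**, which
  keeps the stored ground truth consistent with the traces. The SCEG
  preset uses √1.8 so that periodogram *power*, which scales with the
  squared waveform amplitude, sits 1.8-fold above SDC — matching the
  observed fold change between respiratory and fermentative carbon.

Fluorophores are Hill sigmoids, I(pH) = I_max / (1 + 10^(h·(pKa − pH)))
for pH-sensitive probes and constant for the reference channel. The
v-SEP-like reporter defaults to pKa 6.1, Hill 1 (no numeric pKa is
published; the value puts the 5.8–6.2 operating range on the steep
flank, which is the design goal of such low-pKa reporters). The
BCECF-like ratiometric dye uses the literature-typical pKa ≈ 6.98; only
the monotone shape matters for calibration testing.

The calibration series emulates the in-situ buffer titration: pH 5.0 to
7.5 in 0.5-unit steps (6 points). Each point is the **mean** ratio over
the many permeabilized vacuoles in one buffer image, so its noise is a
standard error of that mean; with ~100 vacuoles and ~1% per-vacuole
ratio scatter that is ≈ 0.001, the default. This matters: the 6-point
sigmoid fit amplifies ratio noise into acidic-end pH error by roughly
1/0.14 ≈ 7×, so treating the calibration point as a single noisy
measurement (e.g. sd 0.005) would make ±0.02 absolute pH unattainable
regardless of the pipeline.

Rendered image stacks paint each cell as an antialiased disk (diameter
27 px) whose interior intensity equals the cell's channel value at that
frame, random-walking with per-frame step sd 0.3 px; Poisson shot noise
is applied first, then Gaussian read noise — the standard camera model.
Initial placements are rejection-sampled with a clearance of one
diameter plus 12 px; an impossible packing raises after 5000 attempts.

Size cohorts: birth volumes are log-normal (mean ln 25, sd 0.2 in
arbitrary volume units). In `sizer` mode the cell buds at a fixed Start
volume (default 50, i.e. a volume doubling for the mean cell) times
lognormal noise (sd 0.05); birth draws at or above the Start volume are
redrawn, since a sizer cell is by definition born below its threshold.
In `linear` mode relative G1 growth is an explicit affine function of
ln(birth volume), used to calibrate the regression machinery itself.
Axis lengths are back-computed from volumes (aspect ratio uniform in
1.1–1.4) so that the ellipsoid-volume round trip is exact.

Every generator is a pure function of config + seed; per-cell streams
derive from the cohort seed through a counter-based `SeedSequence`.

## 2. Imaging (`imaging`)

* **Background**: grayscale opening with a disk (default radius 50 px),
  subtracted and clipped at zero — the morphological reading of
  rolling-ball subtraction.
* **Registration**: translation-only phase correlation to frame 0,
  integer-pixel shifts; sufficient for stage drift, and registering an
  already-registered stack returns zero shifts.
* **Detection**: scale-normalized LoG at σ = d/(2√2) — the response
  optimum for a disk of diameter d — on a min–max-normalized frame, so
  the quality threshold (default 0.3) is dimensionless. An ideal
  unit-contrast matched disk scores ≈ 2/e ≈ 0.74. Local maxima are
  refined to sub-pixel positions by a response-weighted centroid over a
  ±σ window.
* **Linking**: frame-to-frame optimal one-to-one assignment (Hungarian
  algorithm) on squared predicted-to-detection distance. Length-1 tracks
  predict their last position and are gated at 25 px (two-point
  initiation); longer tracks predict 2p_t − p_{t−1} (constant velocity)
  gated at 20 px. Unmatched tracks terminate — no gap closing, no
  splitting or merging. On frames with ≤ 5 spots the assignment is
  verified against brute-force enumeration in the tests.
* **Extraction**: mean intensity in a disk aperture at the tracked
  position, per channel. The default aperture is the detection radius
  minus 2 px: the rendered blob edge is antialiased and localization has
  sub-pixel error, so a full-radius aperture would dilute the mean by
  ~2% and a 1%-accurate round trip requires staying interior. Samples
  whose aperture leaves the frame are dropped; the longest contiguous
  run is kept so traces stay uniformly sampled.

Conventions: frames indexed from 0, time = frame·dt; coordinates are
(x = column, y = row) from the top-left.

## 3. Oscillometry (`oscillometry`)

Traces shorter than 500 min are excluded (≥ 5–6 cycles are needed for a
stable spectrum). Detrending subtracts the OLS line in time — intercept
and trend only; seasonal terms would remove the oscillation itself. The
periodogram uses P(k) = |X_k|²/n for k = 1…⌊n/2⌋, under which a pure
sinusoid of amplitude A on the Fourier grid carries P = A²n/4 and
Parseval's identity closes exactly (checked to 1e−9 in the tests).
Amplitudes are therefore comparable only within a fixed (n, dt) design,
which is how cohort contrasts are formed. The dominant component is the
maximal (power, period) pair; exact power ties break toward the smallest
k — deterministic, and conservative in favor of the longer period. An
off-grid generator period is recovered as the nearest grid period
(85 min → 1000/12 ≈ 83.3 min at n = 500, dt = 2).

Cohorts are summarized by medians with seeded bootstrap percentile 95%
CIs (2000 resamples; the upstream CI routine is unspecified, and the
bootstrap is assumption-free at these n). Pairwise comparisons use
Dunn's pooled-rank z with tie correction and two-sided normal p-values,
Holm-adjusted across pairs; the implementation is checked against a
hand-computed two-group example (z = −1.964). Bootstrap CIs are reported
for both amplitude and period.

## 4. Absolute pH (`ph_dynamics`)

Two calibration modes exist. The **linear** mode (pH = a + b·R) is the
conventional quick calibration and is kept as the plain-least-squares
contract; but over a 2.5-unit buffer range the dye titration is strongly
curved, and the linear map is off by ≈ 0.19 pH at pH 5.82 — systematic,
not noise. The **sigmoid** mode fits the titration curve itself
(R_min, R_max, pKa, Hill by least squares) and inverts it analytically;
it is exact on noise-free data and is what the absolute-pH pipeline
uses. Validity is the buffer range; conversions more than 0.25 pH
outside it are flagged as extrapolation.

Peak detection: Savitzky–Golay denoising (quadratic, default window 5
samples = 8 min, which attenuates an 11-min-FWHM pulse by < 1% — the
window must stay below the pulse width, so sampling-limited YNBD pulses
are detected unsmoothed), then local maxima with prominence ≥ 0.25 of
the trace's 5th–95th percentile range (robust to drift) and ≥ 20 min
separation (well under the shortest ~82-min period). Half-widths are
measured at half prominence with linear interpolation.

Cycle metrics take, for each peak, the trace minimum between the
previous peak (or trace start) and the peak — the minimum precedes its
peak, matching the acidic-trough-then-spike shape of the cycle. The
minimum is read from a more strongly denoised copy of the trace
(default window 2·5+1 = 11 samples): it lies on a flat baseline where
wider smoothing is unbiased, and a pointwise minimum of noisy samples is
otherwise biased low by ~2 noise sd. Peak heights keep the narrow
window.

Event intervals match each detected peak to the nearest preceding
unused bud-emergence and nearest following unused separation annotation,
one-to-one in time order; peaks lacking a partner (e.g. the first cycle
when its bud emergence predates the recording) are skipped and counted.
Interval dispersions are reported as both sd and s.e.m.; the "±" in
headline figures is the s.e.m.

## 5. Size control (`size_control`)

Volumes use the printed convention V = (4/3)·L·S² by default. The
geometric ellipsoid volume for full axis lengths is (π/6)·L·S², and a
`use_pi` flag provides it; since the two differ by a constant factor,
ln(V_bud/V_birth) and every regression statistic are identical between
modes, so nothing downstream depends on the choice. Relative G1 growth
is defined as ln(V_bud/V_birth) — under exponential single-cell growth
this is growth rate × G1 duration, i.e. a scaled G1 duration, and it is
the unique definition under which a perfect sizer yields slope exactly
−1 against ln(birth volume). Negative growth values are flagged but not
silently dropped. The slope fit is plain OLS with the two-sided t-test;
cohort slopes are compared with the extra-sum-of-squares F-test (full
model: separate intercepts and slopes; reduced: common slope), F(1,
n_a+n_b−4), the standard test commercial fitting software performs. Its
null calibration (rejection rate 0.05 ± 0.02 under equal true slopes)
is part of the test suite.

## 6. Orchestration

One global seed is fanned out per stage (and per cell, per auxiliary
series) through counter-based `SeedSequence` derivation, so runs are
byte-reproducible without user-side seed bookkeeping. All tables are
headered CSV — times in minutes, lengths in pixels or µm as labeled —
and each run writes a JSON report with versions, derived seeds and
record counts. Config errors, missing inputs and stage failures map to
distinct CLI exit codes (2/3/4).

## 7. Problem sizes

The bundled analyses and tests run at desk scale, chosen to keep the
statistics stable rather than to mimic full experimental throughput:
15-cell annotated cohorts (~170 cycles, comfortably above the ~129
analyzed in the motivating measurements), 150-cell cohorts per medium
for spectral contrasts (vs ~130–340), 20-cell/100-frame rendered stacks
for tracking validation, 200-cell size cohorts, and 500-replicate null
calibrations.

## 8. What the synthetic benchmarks do and do not show

The generator reproduces the statistical structure the analysis assumes:
cycle-locked Gaussian pulses with stated widths and offsets, titration
optics, a standard camera noise model, diffusive cell motion, lognormal
size distributions. Passing the recovery tests demonstrates that the
pipeline is internally consistent and unbiased under that model at the
stated noise levels. It does not demonstrate robustness to what real
timelapse data add: vacuole fission/fusion and non-disk morphologies,
photobleaching, focus drift, segmentation cross-talk between adjacent
cells, pulse-shape deviations from Gaussian, or annotation error
structure beyond Gaussian jitter. Vacuole fragmentation in particular is
known to defeat blob tracking and is out of scope, as are mother/daughter
lineage assignment, FLIM-based pH readout, irregular sampling
(Lomb–Scargle), and 3D volumetric segmentation.
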