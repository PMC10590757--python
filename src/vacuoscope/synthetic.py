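"""Ground-truthed synthetic inputs for every stage of the pipeline.

Generates single-cell vacuolar pH trajectories with one alkalinization
pulse per cell cycle (or stochastic pulses, or none), passes them
through a fluorophore titration model to produce reporter/reference
intensity channels, renders image stacks of moving vacuole blobs with a
camera noise model, and builds calibration series and cell-size cohorts
-- all pure functions of their configuration plus a seed, with the true
pulse times, event times and per-cycle pH extremes recorded alongside.

Default parameter values encode the measured biology of budding yeast
growing in rich glucose medium (SDC): acidic baseline pH 5.82 rising to
6.20 once per ~85-min cell cycle, an 11-min-FWHM alkaline pulse peaking
59.4 min after bud emergence and 5.7 min before cell separation, sampled
every 2 min for 1000 min. The ``YNBD`` regime (no amino acids) replaces
the regular cycle-locked pulse with brief (2-min) stochastic pulses and
a slow baseline drift; the ``SCEG`` regime (respiratory carbon source)
scales pulse contrast so oscillation power is 1.8-fold that of SDC.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from ._util import as_rng, child_seed, require
from .ph_dynamics import CalibrationSeries
from .size_control import SizeRecord, ellipsoid_volume
from .traces import TraceSeries


class GenerationError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# oscillation profile and fluorophores


@dataclass
class OscillationProfile:
    """Shape of the per-cell-cycle vacuolar pH oscillation.

    Pulses are Gaussian bumps of full-width-at-half-maximum
    ``pulse_fwhm`` (optionally asymmetric via ``pulse_asymmetry``, the
    ratio of trailing to leading width) on an acidic baseline; FWHM is
    the natural parameterization because it is the quantity the peak
    detector measures back.
    """

    ph_base: float = 5.82  # acidic inter-pulse baseline
    ph_peak: float = 6.20  # pulse maximum
    period: float = 85.0  # minutes per cell cycle (median observed 84.9)
    pulse_fwhm: float = 11.0  # minutes (SDC); 2.0 in the YNBD regime
    bud_to_peak: float = 59.4  # minutes from bud emergence to pulse maximum
    peak_to_sep: float = 5.7  # minutes from pulse maximum to cell separation
    drift_rate: float = 0.0  # pH per minute of slow baseline drift
    mode: str = "regular"  # regular | stochastic_pulses | flat
    noise_sd: float = 0.01  # pH units per sample, additive Gaussian
    pulse_rate: float | None = None  # pulses/min for stochastic mode (default 1/period)
    pulse_asymmetry: float = 1.0  # trailing/leading Gaussian width ratio
    # annotation timing noise; events are annotated frame-accurately from a
    # membrane marker, and must stay well below the 5.7-min peak-to-separation
    # offset or cycle matching becomes ambiguous
    event_jitter_sd: float = 1.0  # minutes

    def validate(self) -> None:
        require(self.ph_peak >= self.ph_base, "ph_peak must be >= ph_base")
        require(self.period > 0, "period must be positive")
        require(self.pulse_fwhm < self.period, "pulse_fwhm must be below the period")
        require(self.pulse_fwhm > 0, "pulse_fwhm must be positive")
        require(
            self.bud_to_peak + self.peak_to_sep <= self.period,
            "bud_to_peak + peak_to_sep must fit inside one period",
        )
        require(self.mode in {"regular", "stochastic_pulses", "flat"}, f"unknown mode {self.mode!r}")
        require(self.noise_sd >= 0, "noise_sd must be non-negative")
        require(self.pulse_asymmetry > 0, "pulse_asymmetry must be positive")


@dataclass
class FluorophoreModel:
    """Titration response of a fluorophore: a Hill sigmoid in pH.

    ``intensity(pH) = i_max / (1 + 10^(hill*(pka - pH)))`` for a
    pH-sensitive probe (brighter when less acidic); a pH-insensitive
    reference is constant at ``i_max``.
    """

    pka: float = 6.1
    hill: float = 1.0
    i_max: float = 1.0
    ph_sensitive: bool = True

    def intensity(self, ph) -> np.ndarray:
        ph = np.asarray(ph, dtype=float)
        if not self.ph_sensitive:
            out = np.full_like(ph, self.i_max)
            return float(out) if out.ndim == 0 else out
        require(self.hill > 0, "hill must be positive for a pH-sensitive fluorophore")
        out = self.i_max / (1.0 + 10.0 ** (self.hill * (self.pka - ph)))
        return float(out) if out.ndim == 0 else out


# v-SEP: pH-sensitive GFP variant with pKa lowered so the vacuolar
# operating range 5.8-6.2 sits on the steep flank of its titration curve.
VSEP = FluorophoreModel(pka=6.1, hill=1.0, i_max=1.0, ph_sensitive=True)
# mCherry-like pH-insensitive reference channel.
MCHERRY = FluorophoreModel(pka=0.0, hill=1.0, i_max=1.0, ph_sensitive=False)
# BCECF-like ratiometric dye; literature-typical pKa near 7.
BCECF = FluorophoreModel(pka=6.98, hill=1.0, i_max=1.0, ph_sensitive=True)

# Per-medium scale on pulse contrast. SCEG uses sqrt(1.8) so periodogram
# power (proportional to contrast squared) is 1.8-fold SDC's.
AMPLITUDE_MULTIPLIERS = {"SDC": 1.0, "SCEG": math.sqrt(1.8), "YNBD": 1.0}


def apply_fluorophore(ph_series, model: FluorophoreModel) -> np.ndarray:
    """Pointwise titration response of ``model`` to a pH series."""
    return model.intensity(ph_series)


# ---------------------------------------------------------------------------
# pH traces


@dataclass
class GroundTruth:
    """Everything the generator knows that the analysis must recover."""

    times: np.ndarray
    ph_true: np.ndarray  # noise-free pH series
    pulse_times: list
    bud_times: list
    sep_times: list
    period: float
    cycle_peak_ph: list  # noise-free pH at each pulse maximum
    cycle_min_ph: list  # noise-free baseline preceding each pulse
    ph_base: float
    pulse_fwhm: float

    def to_jsonable(self) -> dict:
        return {
            "times": self.times.tolist(),
            "ph_true": self.ph_true.tolist(),
            "pulse_times": list(self.pulse_times),
            "bud_times": list(self.bud_times),
            "sep_times": list(self.sep_times),
            "period": self.period,
            "cycle_peak_ph": list(self.cycle_peak_ph),
            "cycle_min_ph": list(self.cycle_min_ph),
            "ph_base": self.ph_base,
            "pulse_fwhm": self.pulse_fwhm,
        }


def _pulse_times(profile: OscillationProfile, duration: float, phase: float, rng) -> list:
    if profile.mode == "flat":
        return []
    if profile.mode == "regular":
        # pulse maxima on the half-open window (0, duration]: exactly
        # floor(duration/period) pulses at phase 0
        t = phase % profile.period
        if t == 0.0:
            t = profile.period
        out = []
        while t <= duration:
            out.append(t)
            t += profile.period
        return out
    rate = profile.pulse_rate if profile.pulse_rate is not None else 1.0 / profile.period
    out = []
    t = rng.exponential(1.0 / rate)
    while t < duration:
        out.append(t)
        t += rng.exponential(1.0 / rate)
    return out


def make_ph_trace(
    profile: OscillationProfile,
    duration: float = 1000.0,
    dt: float = 2.0,
    seed=0,
    amplitude_multiplier: float = 1.0,
    phase: float | None = None,
):
    """One cell's vacuolar pH series sampled every ``dt`` minutes.

    Returns ``(ph_series, GroundTruth)``. ``phase`` places the first
    pulse maximum (regular mode); by default it is drawn uniformly over
    one period so cohort cells are asynchronous.
    """
    profile.validate()
    require(dt > 0 and duration > 0, "duration and dt must be positive")
    require(duration >= dt, "duration must be at least dt")
    rng = as_rng(seed)
    n = int(round(duration / dt))
    require(abs(n * dt - duration) < 1e-9 * duration, "duration must be an integer multiple of dt")
    times = np.arange(n) * dt

    if phase is None:
        phase = float(rng.uniform(0.0, profile.period))
    pulses = _pulse_times(profile, duration, phase, rng)

    height = (profile.ph_peak - profile.ph_base) * amplitude_multiplier
    sigma = profile.pulse_fwhm / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    sigma_l = sigma * 2.0 / (1.0 + profile.pulse_asymmetry)
    sigma_r = sigma_l * profile.pulse_asymmetry

    ph_true = profile.ph_base + profile.drift_rate * times
    for tk in pulses:
        d = times - tk
        s = np.where(d < 0, sigma_l, sigma_r)
        ph_true = ph_true + height * np.exp(-0.5 * (d / s) ** 2)

    ph = ph_true + rng.normal(0.0, profile.noise_sd, size=n) if profile.noise_sd > 0 else ph_true.copy()

    buds = [tk - profile.bud_to_peak for tk in pulses]
    seps = [tk + profile.peak_to_sep for tk in pulses]
    truth = GroundTruth(
        times=times,
        ph_true=ph_true,
        pulse_times=pulses,
        bud_times=[t for t in buds if 0.0 <= t <= duration],
        sep_times=[t for t in seps if 0.0 <= t <= duration],
        period=profile.period,
        cycle_peak_ph=[profile.ph_base + profile.drift_rate * tk + height for tk in pulses],
        cycle_min_ph=[profile.ph_base + profile.drift_rate * tk for tk in pulses],
        ph_base=profile.ph_base,
        pulse_fwhm=profile.pulse_fwhm,
    )
    return ph, truth


# ---------------------------------------------------------------------------
# cohorts


@dataclass
class SynthCohortConfig:
    n_cells: int = 50
    duration: float = 1000.0  # minutes
    dt: float = 2.0  # minutes between frames
    seed: int = 0
    profile: OscillationProfile = field(default_factory=OscillationProfile)
    channels: dict = field(
        default_factory=lambda: {"vsep": VSEP, "ref": MCHERRY}
    )
    amplitude_multiplier: float = 1.0

    def validate(self) -> None:
        require(self.n_cells >= 1, "n_cells must be at least 1")
        self.profile.validate()
        n = self.duration / self.dt
        require(abs(n - round(n)) < 1e-9, "duration/dt must be an integer")


def cohort_config(medium: str = "SDC", **overrides) -> SynthCohortConfig:
    """Preset cohort for a growth medium: SDC, SCEG or YNBD.

    SDC/SCEG are regular cycle-locked oscillators differing in pulse
    contrast; YNBD has brief stochastic pulses and a slow baseline rise.
    """
    require(medium in AMPLITUDE_MULTIPLIERS, f"unknown medium {medium!r}")
    profile = OscillationProfile()
    if medium == "YNBD":
        profile = replace(profile, mode="stochastic_pulses", pulse_fwhm=2.0, drift_rate=3e-4)
    cfg = SynthCohortConfig(
        profile=profile, amplitude_multiplier=AMPLITUDE_MULTIPLIERS[medium]
    )
    return replace(cfg, **overrides) if overrides else cfg


def make_cohort(config: SynthCohortConfig):
    """Generate ``config.n_cells`` independent TraceSeries plus ground truth.

    Each cell gets its own phase and noise stream derived from the cohort
    seed, so the output is reproducible cell-by-cell. Event annotations
    (bud emergence, separation) carry zero-mean Gaussian timing jitter of
    ``profile.event_jitter_sd`` minutes, mimicking manual annotation.
    """
    config.validate()
    traces, truths = [], []
    for i in range(config.n_cells):
        rng = as_rng(child_seed(config.seed, i))
        ph, truth = make_ph_trace(
            config.profile,
            duration=config.duration,
            dt=config.dt,
            seed=rng,
            amplitude_multiplier=config.amplitude_multiplier,
        )
        channels = {name: apply_fluorophore(ph, model) for name, model in config.channels.items()}
        jit = config.profile.event_jitter_sd
        events = {}
        for key, src in (("bud_emergence", truth.bud_times), ("separation", truth.sep_times)):
            times = np.asarray(src, dtype=float)
            if jit > 0 and len(times):
                times = times + rng.normal(0.0, jit, size=len(times))
            events[key] = sorted(float(t) for t in times if 0.0 <= t <= config.duration)
        traces.append(
            TraceSeries(cell_id=f"cell{i:04d}", times=truth.times, channels=channels, events=events)
        )
        truths.append(truth)
    return traces, truths


# ---------------------------------------------------------------------------
# calibration series


def make_calibration_series(
    models,
    grid=None,
    noise_sd: float = 0.001,
    seed=0,
) -> CalibrationSeries:
    """Buffer-series calibration data: measured ratio at each buffer pH.

    ``models`` is either a (reporter, reference) FluorophoreModel pair --
    the ratio is their intensity quotient -- or a single model whose
    response is itself the ratio. The default grid is 5.0 to 7.5 in
    0.5-unit steps, the standard in-situ buffer series. Each point is
    the mean ratio over the many permeabilized vacuoles in one buffer
    image, so its noise is a standard error of that mean: ~100 vacuoles
    with ~1% per-vacuole ratio scatter gives the 0.001 default.
    """
    if grid is None:
        grid = np.arange(5.0, 7.5 + 1e-9, 0.5)
    grid = np.asarray(grid, dtype=float)
    require(len(grid) >= 2, "calibration grid needs at least 2 points")
    require(np.all(np.diff(grid) > 0), "calibration grid must be strictly increasing")
    if isinstance(models, FluorophoreModel):
        ratio = models.intensity(grid)
    else:
        reporter, reference = models
        ratio = reporter.intensity(grid) / reference.intensity(grid)
    if noise_sd > 0:
        ratio = ratio + as_rng(seed).normal(0.0, noise_sd, size=len(grid))
    return CalibrationSeries(ph=grid, ratio=ratio)


# ---------------------------------------------------------------------------
# rendered image stacks


@dataclass
class ImageSceneConfig:
    """Camera/scene model for rendering vacuole blobs into frames.

    Each cell is a disk whose interior intensity tracks the cell's
    channel value; cells random-walk frame to frame; Poisson shot noise
    is applied first, then additive Gaussian read noise.
    """

    frame_shape: tuple = (256, 256)  # (rows, cols)
    vacuole_diameter: float = 27.0  # pixels, matches the detector default
    cell_motion_sd: float = 0.3  # pixels/frame random-walk step sd
    background_level: float = 20.0  # AU
    background_gradient: tuple = (0.0, 0.0)  # AU/pixel along (row, col)
    poisson_noise: bool = True
    read_noise_sd: float = 2.0  # AU
    placement_margin: float = 12.0  # extra center-to-center clearance, pixels

    def validate(self) -> None:
        require(self.vacuole_diameter >= 3, "vacuole_diameter must be at least 3 px")
        require(len(self.frame_shape) == 2, "frame_shape must be 2-D")


@dataclass
class RenderTruth:
    centers: np.ndarray  # (n_frames, n_cells, 2) as (x, y) pixel coordinates
    radius: float

    def to_jsonable(self) -> dict:
        return {"centers": self.centers.tolist(), "radius": self.radius}


def _place_cells(n_cells: int, scene: ImageSceneConfig, rng) -> np.ndarray:
    h, w = scene.frame_shape
    r = scene.vacuole_diameter / 2.0
    border = r + 3.0
    min_sep = scene.vacuole_diameter + scene.placement_margin
    centers = []
    for _ in range(n_cells):
        for _attempt in range(5000):
            x = rng.uniform(border, w - border)
            y = rng.uniform(border, h - border)
            if all((x - cx) ** 2 + (y - cy) ** 2 >= min_sep**2 for cx, cy in centers):
                centers.append((x, y))
                break
        else:
            raise GenerationError(
                f"could not place {n_cells} non-overlapping cells in {scene.frame_shape}"
            )
    return np.array(centers, dtype=float).reshape(n_cells, 2)


def _paint_disk(frame: np.ndarray, x: float, y: float, radius: float, value: float) -> None:
    """Add an antialiased disk: interior pixels get the full value, edge
    pixels the sub-pixel coverage fraction."""
    h, w = frame.shape
    x0, x1 = int(max(0, math.floor(x - radius - 1))), int(min(w, math.ceil(x + radius + 2)))
    y0, y1 = int(max(0, math.floor(y - radius - 1))), int(min(h, math.ceil(y + radius + 2)))
    if x0 >= x1 or y0 >= y1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dist = np.sqrt((xx - x) ** 2 + (yy - y) ** 2)
    coverage = np.clip(radius + 0.5 - dist, 0.0, 1.0)
    frame[y0:y1, x0:x1] += value * coverage


def render_image_stack(cohort, scene: ImageSceneConfig, seed=0):
    """Render per-channel image stacks for a cohort of traces.

    Returns ``(stacks, truth)`` where ``stacks`` maps channel name to a
    float array of shape (n_frames, H, W) and ``truth`` records the
    per-frame (x, y) centers of every cell.
    """
    scene.validate()
    rng = as_rng(seed)
    n_cells = len(cohort)
    if n_cells > 0:
        n_frames = cohort[0].n
        require(all(tr.n == n_frames for tr in cohort), "all traces must share frame count")
        channel_names = list(cohort[0].channels)
    else:
        n_frames = 1
        channel_names = []

    h, w = scene.frame_shape
    radius = scene.vacuole_diameter / 2.0
    centers0 = _place_cells(n_cells, scene, rng) if n_cells else np.zeros((0, 2))
    steps = rng.normal(0.0, scene.cell_motion_sd, size=(n_frames, n_cells, 2))
    steps[0] = 0.0
    centers = centers0[None, :, :] + np.cumsum(steps, axis=0)
    # keep centers inside the frame with reflecting boundaries
    centers[..., 0] = np.clip(centers[..., 0], radius + 1, w - radius - 2)
    centers[..., 1] = np.clip(centers[..., 1], radius + 1, h - radius - 2)

    gy, gx = scene.background_gradient
    yy, xx = np.mgrid[0:h, 0:w]
    background = scene.background_level + gy * yy + gx * xx

    stacks = {}
    for name in channel_names:
        stack = np.empty((n_frames, h, w), dtype=float)
        for t in range(n_frames):
            frame = background.copy()
            for i, trace in enumerate(cohort):
                cx, cy = centers[t, i]
                _paint_disk(frame, cx, cy, radius, trace.channels[name][t])
            if scene.poisson_noise:
                frame = rng.poisson(np.clip(frame, 0, None)).astype(float)
            if scene.read_noise_sd > 0:
                frame = frame + rng.normal(0.0, scene.read_noise_sd, size=frame.shape)
            stack[t] = frame
        stacks[name] = stack
    if not channel_names:
        frame = background.copy()
        if scene.poisson_noise:
            frame = rng.poisson(np.clip(frame, 0, None)).astype(float)
        if scene.read_noise_sd > 0:
            frame = frame + rng.normal(0.0, scene.read_noise_sd, size=frame.shape)
        stacks["background"] = frame[None, :, :]
    return stacks, RenderTruth(centers=centers, radius=radius)


# ---------------------------------------------------------------------------
# size cohorts


@dataclass
class SizeCohortConfig:
    """Birth/budding size cohort generator.

    ``sizer`` mode: cells grow exponentially and commit to budding at a
    fixed Start volume ``v_start`` (times lognormal noise), producing the
    slope -1 signature. ``linear`` mode generates relative G1 growth as
    an explicit affine function of log birth volume, for calibrating the
    regression itself.
    """

    n: int = 200
    ln_vbirth_mean: float = math.log(25.0)
    ln_vbirth_sd: float = 0.2
    v_start: float = 50.0  # sizer threshold volume (arbitrary volume units)
    slope: float = -1.0  # linear mode target slope
    intercept: float | None = None  # linear mode; default centers growth at ln 2
    noise_sd: float = 0.05  # lognormal noise on budding volume / growth
    mode: str = "sizer"  # sizer | linear
    seed: int = 0
    aspect_range: tuple = (1.1, 1.4)  # long/short axis ratio of the ellipsoid
    use_pi: bool = False

    def validate(self) -> None:
        require(self.n >= 3, "need n >= 3")
        require(self.mode in {"sizer", "linear"}, f"unknown mode {self.mode!r}")
        require(self.v_start > 0 and self.ln_vbirth_sd >= 0, "bad size parameters")


def _axes_for_volume(volume: float, aspect: float, use_pi: bool):
    """Back-compute (L, S) so ellipsoid_volume(L, S) reproduces ``volume``."""
    factor = math.pi / 6.0 if use_pi else 4.0 / 3.0
    s = (volume / (factor * aspect)) ** (1.0 / 3.0)
    return aspect * s, s


def make_size_cohort(config: SizeCohortConfig):
    """Generate SizeRecords; axis lengths round-trip through ellipsoid_volume."""
    config.validate()
    rng = as_rng(config.seed)
    records = []
    intercept = (
        config.intercept
        if config.intercept is not None
        else math.log(2.0) - config.slope * config.ln_vbirth_mean
    )
    for i in range(config.n):
        ln_vb = rng.normal(config.ln_vbirth_mean, config.ln_vbirth_sd)
        if config.mode == "sizer":
            # a sizer cell is born below the Start threshold by construction
            while ln_vb >= math.log(config.v_start):
                ln_vb = rng.normal(config.ln_vbirth_mean, config.ln_vbirth_sd)
        for _ in range(1000):
            eps = rng.normal(0.0, config.noise_sd) if config.noise_sd > 0 else 0.0
            if config.mode == "sizer":
                ln_vbud = math.log(config.v_start) + eps
            else:
                ln_vbud = ln_vb + intercept + config.slope * ln_vb + eps
            if ln_vbud >= ln_vb:  # reject the rare negative-growth draw
                break
        else:
            ln_vbud = ln_vb
        aspect = rng.uniform(*config.aspect_range)
        lb, sb = _axes_for_volume(math.exp(ln_vb), aspect, config.use_pi)
        ld, sd = _axes_for_volume(math.exp(ln_vbud), aspect, config.use_pi)
        records.append(
            SizeRecord(
                cell_id=f"cell{i:04d}",
                l_birth=lb,
                s_birth=sb,
                l_bud=ld,
                s_bud=sd,
                use_pi=config.use_pi,
            )
        )
    return records
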