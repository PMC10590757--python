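"""From image stacks to per-cell traces.

The processing chain mirrors standard timelapse vacuole tracking:
rolling-ball background subtraction, translation-only registration by
phase correlation, scale-matched Laplacian-of-Gaussian blob detection,
motion-predictive one-to-one linking, and mean-intensity extraction in a
disk aperture around each tracked position.

Conventions: frames are indexed from 0 and frame ``i`` is at time
``i * dt`` minutes; pixel coordinates are (x=column, y=row) with the
origin at the top-left.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.optimize import linear_sum_assignment
from skimage.feature import peak_local_max
from skimage.morphology import disk as disk_footprint
from skimage.registration import phase_cross_correlation

from ._util import require
from .traces import TraceSeries

_BIG = 1e12


@dataclass
class Stack:
    frames: np.ndarray  # (T, H, W) intensities, AU
    dt: float = 2.0  # minutes between frames
    channel: str = ""

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        require(self.frames.ndim == 3, "frames must be a (T, H, W) array")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


@dataclass
class Detection:
    frame: int
    x: float  # column
    y: float  # row
    radius: float  # pixels
    quality: float  # normalized LoG response height

    @property
    def pos(self) -> np.ndarray:
        return np.array([self.x, self.y])


@dataclass
class Track:
    track_id: int
    detections: list = field(default_factory=list)

    @property
    def frames(self) -> list:
        return [d.frame for d in self.detections]

    def span(self, dt: float) -> float:
        """Minutes covered by the track."""
        f = self.frames
        return (f[-1] - f[0]) * dt if f else 0.0

    def __len__(self) -> int:
        return len(self.detections)


def subtract_background(stack: Stack, radius: int = 50) -> Stack:
    """Rolling-ball background subtraction (grayscale opening with a disk).

    The morphological opening with a disk of the given radius estimates
    the smooth background under features smaller than the disk; it is
    subtracted per frame and the result clipped at zero.
    """
    require(radius >= 1, "radius must be at least 1")
    h, w = stack.frames.shape[1:]
    require(2 * radius + 1 <= min(h, w), "radius larger than the frame")
    footprint = disk_footprint(int(radius))
    out = np.empty_like(stack.frames)
    for i, frame in enumerate(stack.frames):
        background = ndimage.grey_opening(frame, footprint=footprint)
        out[i] = np.clip(frame - background, 0.0, None)
    return Stack(frames=out, dt=stack.dt, channel=stack.channel)


def register_stack(stack: Stack):
    """Align every frame to frame 0 by integer-pixel translation.

    The shift of each frame is estimated by phase correlation. Returns
    ``(registered stack, shifts)`` where ``shifts[i] = (dx, dy)`` is the
    displacement frame ``i`` had relative to frame 0 (so the correction
    applied is ``-shifts[i]``).
    """
    require(stack.n_frames >= 1, "empty stack")
    ref = stack.frames[0]
    out = np.empty_like(stack.frames)
    out[0] = ref
    shifts = np.zeros((stack.n_frames, 2), dtype=int)
    for i in range(1, stack.n_frames):
        (dy, dx), _, _ = phase_cross_correlation(ref, stack.frames[i], upsample_factor=1)
        dy, dx = int(round(dy)), int(round(dx))
        # phase_cross_correlation returns the shift that moves frame i onto
        # the reference; the frame content moved by the negative of that.
        shifts[i] = (-dx, -dy)
        out[i] = ndimage.shift(stack.frames[i], (dy, dx), order=0, mode="constant", cval=0.0)
    return Stack(frames=out, dt=stack.dt, channel=stack.channel), shifts


def detect_vacuoles(
    frame: np.ndarray,
    diameter: float = 27.0,
    threshold: float = 0.3,
    frame_index: int = 0,
) -> list:
    """Scale-matched LoG blob detection on one frame.

    The frame is min-max normalized so the quality threshold is
    dimensionless; the scale-normalized negated Laplacian of Gaussian at
    sigma = diameter / (2*sqrt(2)) (the optimum for a disk of that
    diameter) is evaluated and its local maxima above ``threshold``
    returned, with sub-pixel localization by response-weighted centroid.
    """
    frame = np.asarray(frame, dtype=float)
    require(np.all(np.isfinite(frame)), "frame contains non-finite pixels")
    require(diameter >= 3, "diameter must be at least 3 px")
    lo, hi = frame.min(), frame.max()
    if hi <= lo:
        return []
    norm = (frame - lo) / (hi - lo)
    sigma = diameter / (2.0 * math.sqrt(2.0))
    response = -(sigma**2) * ndimage.gaussian_laplace(norm, sigma)
    coords = peak_local_max(
        response,
        min_distance=max(1, int(diameter // 2)),
        threshold_abs=threshold,
        exclude_border=False,
    )
    detections = []
    win = max(2, int(round(sigma)))
    h, w = frame.shape
    for r, c in coords:
        y0, y1 = max(0, r - win), min(h, r + win + 1)
        x0, x1 = max(0, c - win), min(w, c + win + 1)
        patch = np.clip(response[y0:y1, x0:x1], 0.0, None)
        total = patch.sum()
        if total > 0:
            yy, xx = np.mgrid[y0:y1, x0:x1]
            cy = float((patch * yy).sum() / total)
            cx = float((patch * xx).sum() / total)
        else:  # pragma: no cover - degenerate flat response
            cy, cx = float(r), float(c)
        detections.append(
            Detection(
                frame=frame_index,
                x=cx,
                y=cy,
                radius=diameter / 2.0,
                quality=float(response[r, c]),
            )
        )
    return detections


def detect_stack(stack: Stack, diameter: float = 27.0, threshold: float = 0.3) -> list:
    """Per-frame detections for a whole stack (list of lists)."""
    return [
        detect_vacuoles(frame, diameter=diameter, threshold=threshold, frame_index=i)
        for i, frame in enumerate(stack.frames)
    ]


def link_tracks(
    detections_per_frame,
    initial_radius: float = 25.0,
    radius: float = 20.0,
) -> list:
    """Link per-frame detections into tracks with constant-velocity prediction.

    Tracks of length 1 predict their last position and are gated at
    ``initial_radius`` (two-point initiation); longer tracks predict
    ``2*p_t - p_{t-1}`` and are gated at ``radius``. Each frame solves
    the optimal one-to-one assignment minimizing total squared
    predicted-to-detection distance; unmatched tracks terminate (no gap
    closing), unmatched detections seed new tracks.
    """
    finished, active = [], []
    next_id = 0
    for frame_dets in detections_per_frame:
        dets = list(frame_dets)
        assigned_track = {}
        if active and dets:
            preds, gates = [], []
            for tr in active:
                pts = tr.detections
                if len(pts) >= 2:
                    preds.append(2.0 * pts[-1].pos - pts[-2].pos)
                    gates.append(radius)
                else:
                    preds.append(pts[-1].pos)
                    gates.append(initial_radius)
            cost = np.full((len(active), len(dets)), _BIG)
            for i, (pred, gate) in enumerate(zip(preds, gates)):
                for j, d in enumerate(dets):
                    d2 = float(np.sum((pred - d.pos) ** 2))
                    if d2 <= gate**2:
                        cost[i, j] = d2
            rows, cols = linear_sum_assignment(cost)
            for i, j in zip(rows, cols):
                if cost[i, j] < _BIG:
                    assigned_track[j] = i
        matched_tracks = set(assigned_track.values())
        still_active = []
        for i, tr in enumerate(active):
            if i in matched_tracks:
                still_active.append(tr)
            else:
                finished.append(tr)
        for j, d in enumerate(dets):
            if j in assigned_track:
                active[assigned_track[j]].detections.append(d)
            else:
                tr = Track(track_id=next_id, detections=[d])
                next_id += 1
                still_active.append(tr)
        active = still_active
    finished.extend(active)
    finished.sort(key=lambda tr: tr.track_id)
    return finished


def extract_traces(tracks, stacks: dict, aperture: float | None = None) -> list:
    """Mean disk intensity per channel along each track.

    ``stacks`` maps channel name to a co-registered Stack of equal
    length. The aperture defaults to the detection radius minus two
    pixels, keeping the mask inside the antialiased blob edge even with
    sub-pixel localization error. Samples whose aperture leaves the
    frame are excluded.
    """
    require(len(stacks) >= 1, "need at least one channel stack")
    names = list(stacks)
    n_frames = stacks[names[0]].n_frames
    dt = stacks[names[0]].dt
    require(
        all(s.n_frames == n_frames for s in stacks.values()),
        "all channel stacks must have the same length",
    )
    h, w = stacks[names[0]].frames.shape[1:]
    traces = []
    for tr in tracks:
        samples = []  # (frame, {channel: mean}) for valid detections
        for d in tr.detections:
            ap = aperture if aperture is not None else max(1.0, d.radius - 2.0)
            x0, x1 = int(math.floor(d.x - ap)), int(math.ceil(d.x + ap)) + 1
            y0, y1 = int(math.floor(d.y - ap)), int(math.ceil(d.y + ap)) + 1
            if x0 < 0 or y0 < 0 or x1 > w or y1 > h:
                continue  # aperture outside the frame: flagged sample, excluded
            yy, xx = np.mgrid[y0:y1, x0:x1]
            mask = (xx - d.x) ** 2 + (yy - d.y) ** 2 <= ap**2
            if not mask.any():
                continue
            means = {
                name: float(stacks[name].frames[d.frame, y0:y1, x0:x1][mask].mean())
                for name in names
            }
            samples.append((d.frame, means))
        if not samples:
            continue
        # exclusions may punch holes in the frame sequence; keep the longest
        # contiguous run so the trace stays uniformly sampled
        best_start, best_len, start = 0, 1, 0
        for k in range(1, len(samples)):
            if samples[k][0] != samples[k - 1][0] + 1:
                start = k
            if k - start + 1 > best_len:
                best_start, best_len = start, k - start + 1
        run = samples[best_start : best_start + best_len]
        traces.append(
            TraceSeries(
                cell_id=f"track{tr.track_id:04d}",
                times=np.array([f * dt for f, _ in run]),
                channels={name: np.array([m[name] for _, m in run]) for name in names},
            )
        )
    return traces
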