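"""Per-cell intensity time series: the common currency of the pipeline.

A :class:`TraceSeries` holds one cell's uniformly sampled channel
intensities (arbitrary units) plus optional cell-cycle event annotations
(bud emergence, cell separation) as explicit time lists in minutes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._util import require


@dataclass
class TraceSeries:
    cell_id: str
    times: np.ndarray  # minutes, strictly increasing, uniform spacing
    channels: dict  # name -> intensity array (AU), same length as times
    events: dict = field(default_factory=dict)  # event name -> list of times

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        require(self.times.ndim == 1 and len(self.times) >= 1, "times must be a non-empty 1-D array")
        if len(self.times) > 1:
            steps = np.diff(self.times)
            require(np.all(steps > 0), "times must be strictly increasing")
            require(np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9), "times must be uniformly spaced")
        self.channels = {k: np.asarray(v, dtype=float) for k, v in self.channels.items()}
        for name, vals in self.channels.items():
            require(vals.shape == self.times.shape, f"channel {name!r} length mismatch")
            require(np.all(np.isfinite(vals)), f"channel {name!r} has non-finite values")

    @property
    def n(self) -> int:
        return len(self.times)

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0]) if self.n > 1 else np.nan

    @property
    def span(self) -> float:
        """Duration covered by the trace (last minus first timestamp), minutes."""
        return float(self.times[-1] - self.times[0])

    def ratio(self, numerator: str, denominator: str) -> np.ndarray:
        """Ratiometric signal, e.g. pH-sensitive over pH-insensitive channel."""
        den = self.channels[denominator]
        require(np.all(den != 0), "denominator channel contains zeros")
        return self.channels[numerator] / den

    def shifted(self, offset: float) -> "TraceSeries":
        """Copy with the time axis shifted by ``offset`` minutes."""
        return TraceSeries(
            cell_id=self.cell_id,
            times=self.times + offset,
            channels={k: v.copy() for k, v in self.channels.items()},
            events={k: [t + offset for t in v] for k, v in self.events.items()},
        )
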