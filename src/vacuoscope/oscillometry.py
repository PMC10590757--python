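"""Periodogram quantification of single-cell oscillations.

Per cell: keep traces long enough to cover several cell cycles, remove
the linear trend, compute the discrete periodogram P(k) = |X_k|^2 / n,
and report the dominant component -- the maximal power (the "oscillatory
vacuolar pH amplitude") and its period n*dt/k. Cohorts are summarized by
medians with bootstrap confidence intervals and compared pairwise with
Dunn's rank test under Holm multiplicity adjustment.

Amplitudes are in squared intensity units and are comparable only
within a fixed sampling design (same n and dt), which is how cohort
contrasts are reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._util import as_rng, require
from .traces import TraceSeries


def select_traces(traces, min_span: float = 500.0) -> list:
    """Keep traces whose time span (last - first sample) is >= min_span minutes.

    Five-plus cell cycles are needed for a meaningful spectrum; 500 min
    at an ~85-min period gives about six.
    """
    return [t for t in traces if t.span >= min_span]


def detrend_trace(values, times=None) -> np.ndarray:
    """Subtract the OLS line (intercept + slope * time) from a trace.

    Removes photobleaching/accumulation trends without touching the
    oscillation; the residual has zero mean and zero linear trend.
    """
    values = np.asarray(values, dtype=float)
    require(len(values) >= 3, "need at least 3 samples to detrend")
    t = np.arange(len(values), dtype=float) if times is None else np.asarray(times, dtype=float)
    slope, intercept = np.polyfit(t, values, 1)
    return values - (intercept + slope * t)


@dataclass
class Periodogram:
    n: int
    dt: float
    frequencies: np.ndarray  # cycles/minute, k/(n*dt) for k = 1..n//2
    power: np.ndarray  # |X_k|^2 / n
    power_dc: float  # k = 0 term, kept for the Parseval identity

    def total_power(self) -> float:
        """Sum x_t^2 reconstructed from the spectrum (Parseval)."""
        total = self.power_dc
        if self.n % 2 == 0:
            total += self.power[-1] + 2.0 * float(np.sum(self.power[:-1]))
        else:
            total += 2.0 * float(np.sum(self.power))
        return total


def periodogram(values, dt: float) -> Periodogram:
    """Discrete periodogram P(k) = |sum_t x_t e^(-2*pi*i*k*t/n)|^2 / n.

    Returned for k = 1..floor(n/2); the DC term is stored separately
    (it is zero for detrended input and only used in the Parseval
    check).
    """
    x = np.asarray(values, dtype=float)
    n = len(x)
    require(n >= 4, "need at least 4 samples")
    require(dt > 0, "dt must be positive")
    X = np.fft.rfft(x)
    power_all = np.abs(X) ** 2 / n
    k = np.arange(1, n // 2 + 1)
    return Periodogram(
        n=n,
        dt=float(dt),
        frequencies=k / (n * dt),
        power=power_all[1 : n // 2 + 1],
        power_dc=float(power_all[0]),
    )


@dataclass
class DominantComponent:
    amplitude: float  # power at the dominant frequency, AU^2
    period: float  # minutes; NaN when the spectrum is all-zero
    k: int  # harmonic index of the maximum (0 when undefined)

    @property
    def defined(self) -> bool:
        return self.k > 0


def dominant_component(pg: Periodogram) -> DominantComponent:
    """Maximal (power, period) pair of the spectrum.

    Ties break toward the smallest k, i.e. the longest period --
    deterministic and biologically the conservative choice. An all-zero
    spectrum yields amplitude 0 with an undefined (NaN) period.
    """
    require(len(pg.power) > 0, "empty periodogram")
    if np.all(pg.power == 0):
        return DominantComponent(amplitude=0.0, period=float("nan"), k=0)
    idx = int(np.argmax(pg.power))  # argmax returns the first (smallest-k) maximum
    k = idx + 1
    return DominantComponent(
        amplitude=float(pg.power[idx]), period=pg.n * pg.dt / k, k=k
    )


def analyze_trace(trace: TraceSeries, channel: str) -> DominantComponent:
    """Detrend -> periodogram -> dominant component for one trace channel."""
    values = trace.ratio(*channel.split("/")) if "/" in channel else trace.channels[channel]
    det = detrend_trace(values, trace.times)
    return dominant_component(periodogram(det, trace.dt))


def analyze_cohort(traces, channel: str, min_span: float = 500.0):
    """Run the selection + PSD pipeline over a cohort; returns per-cell components."""
    return [analyze_trace(t, channel) for t in select_traces(traces, min_span)]


@dataclass
class CohortSummary:
    label: str
    n_cells: int
    median_amplitude: float
    amplitude_ci: tuple
    median_period: float
    period_ci: tuple


def _boot_median_ci(values, n_boot, rng, level=0.95):
    values = np.asarray(values, dtype=float)
    n = len(values)
    idx = rng.integers(0, n, size=(n_boot, n))
    meds = np.median(values[idx], axis=1)
    alpha = (1.0 - level) / 2.0
    return float(np.quantile(meds, alpha)), float(np.quantile(meds, 1.0 - alpha))


def cohort_summary(components, label: str = "", n_boot: int = 2000, seed=0) -> CohortSummary:
    """Median amplitude and period with seeded bootstrap percentile 95% CIs."""
    require(len(components) >= 1, "empty cohort")
    amps = np.array([c.amplitude for c in components])
    periods = np.array([c.period for c in components if c.defined])
    rng = as_rng(seed)
    amp_ci = _boot_median_ci(amps, n_boot, rng)
    per_ci = _boot_median_ci(periods, n_boot, rng) if len(periods) else (np.nan, np.nan)
    return CohortSummary(
        label=label,
        n_cells=len(components),
        median_amplitude=float(np.median(amps)),
        amplitude_ci=amp_ci,
        median_period=float(np.median(periods)) if len(periods) else float("nan"),
        period_ci=per_ci,
    )


@dataclass
class GroupComparison:
    """Pairwise Dunn z statistics with Holm-adjusted two-sided p-values."""

    pairs: list  # (label_i, label_j)
    z: np.ndarray
    p_raw: np.ndarray
    p_adjusted: np.ndarray


def dunn_holm_compare(groups: dict) -> GroupComparison:
    """Dunn's rank-based post-hoc test across groups, Holm-adjusted.

    Pooled-rank z statistic with tie correction:
    z_ij = (Rbar_i - Rbar_j) / sqrt[(N(N+1)/12 - T) * (1/n_i + 1/n_j)],
    T = sum(t^3 - t) / (12 (N - 1)) over tied values; two-sided normal
    p-values, then Holm step-down across all pairs.
    """
    require(len(groups) >= 2, "need at least 2 groups")
    labels = list(groups)
    data = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for k, v in data.items():
        require(len(v) >= 1, f"group {k!r} is empty")
    pooled = np.concatenate([data[k] for k in labels])
    N = len(pooled)
    ranks = stats.rankdata(pooled)
    mean_ranks, sizes = {}, {}
    start = 0
    for k in labels:
        n_k = len(data[k])
        mean_ranks[k] = float(np.mean(ranks[start : start + n_k]))
        sizes[k] = n_k
        start += n_k
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (N - 1)) if N > 1 else 0.0
    var_factor = N * (N + 1) / 12.0 - tie_term

    pairs, zs, ps = [], [], []
    for a, b in combinations(labels, 2):
        denom2 = var_factor * (1.0 / sizes[a] + 1.0 / sizes[b])
        if denom2 <= 0:  # all pooled values identical
            z = 0.0
        else:
            z = (mean_ranks[a] - mean_ranks[b]) / np.sqrt(denom2)
        pairs.append((a, b))
        zs.append(z)
        ps.append(2.0 * stats.norm.sf(abs(z)))
    _, p_adj, _, _ = multipletests(ps, method="holm")
    return GroupComparison(
        pairs=pairs, z=np.array(zs), p_raw=np.array(ps), p_adjusted=np.asarray(p_adj)
    )


def holm_adjust(p_values) -> np.ndarray:
    """Holm step-down adjustment of a vector of raw p-values."""
    _, p_adj, _, _ = multipletests(np.asarray(p_values, dtype=float), method="holm")
    return np.asarray(p_adj)
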