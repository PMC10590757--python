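"""Cell-size-control analysis.

Budding yeast coordinates cell-cycle commitment (Start) with cell size:
under a "sizer" regime, small-born daughters grow proportionally more in
G1 before budding, so the regression of relative G1 growth,
``ln(V_bud / V_birth)``, on log birth volume has slope -1. Loss of size
control flattens that slope toward 0. This module computes ellipsoid
volumes from axis lengths, the relative G1 growth statistic, the OLS
slope with its t-test, and a nested-model F-test comparing slopes
between two cohorts (e.g. wild type versus a mutant).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._util import require


class SizeControlError(ValueError):
    pass


def ellipsoid_volume(long_axis: float, short_axis: float, use_pi: bool = False) -> float:
    """Cell volume from its long and short axis lengths (micrometers).

    The default reproduces the V = (4/3) * L * S^2 convention used with
    maximum-intensity-projected membrane-marker images. ``use_pi=True``
    gives the geometrically exact ellipsoid volume (pi/6) * L * S^2 for
    full axis lengths. Only a constant factor separates the two, so any
    statistic of log volume differences is identical between modes.
    """
    L = np.asarray(long_axis, dtype=float)
    S = np.asarray(short_axis, dtype=float)
    require(np.all(L >= 0) and np.all(S >= 0), "axis lengths must be non-negative")
    require(np.all(L >= S), "long axis must be >= short axis")
    factor = math.pi / 6.0 if use_pi else 4.0 / 3.0
    out = factor * L * S**2
    return float(out) if out.ndim == 0 else out


@dataclass
class SizeRecord:
    """Axis lengths (um) of one daughter cell at birth and at bud emergence."""

    cell_id: str
    l_birth: float
    s_birth: float
    l_bud: float
    s_bud: float
    use_pi: bool = False

    @property
    def v_birth(self) -> float:
        return ellipsoid_volume(self.l_birth, self.s_birth, self.use_pi)

    @property
    def v_bud(self) -> float:
        return ellipsoid_volume(self.l_bud, self.s_bud, self.use_pi)

    @property
    def rel_g1(self) -> float:
        return relative_g1_growth(self.v_birth, self.v_bud)


def relative_g1_growth(v_birth: float, v_bud: float) -> float:
    """Relative G1 growth: ln(V_bud / V_birth).

    Under exponential single-cell growth this equals growth rate times G1
    duration, i.e. a scaled G1 duration. Negative values (bud volume
    below birth volume) indicate a measurement problem; they are returned
    as-is so callers can flag them.
    """
    require(v_birth > 0, "birth volume must be positive")
    return float(np.log(v_bud / v_birth))


def records_frame(records) -> pd.DataFrame:
    """Tabulate records with volumes and growth; flags negative growth."""
    rows = []
    for r in records:
        vb, vd = r.v_birth, r.v_bud
        g = relative_g1_growth(vb, vd)
        rows.append(
            {
                "cell_id": r.cell_id,
                "l_birth_um": r.l_birth,
                "s_birth_um": r.s_birth,
                "l_bud_um": r.l_bud,
                "s_bud_um": r.s_bud,
                "v_birth": vb,
                "v_bud": vd,
                "ln_v_birth": np.log(vb),
                "rel_g1": g,
                "negative_growth": g < 0,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class SizeControlFit:
    slope: float
    intercept: float
    stderr: float
    pvalue: float  # two-sided t-test of slope == 0
    r_squared: float
    n: int
    rss: float


def _ols_line(x: np.ndarray, y: np.ndarray):
    X = np.column_stack([np.ones_like(x), x])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return beta, float(resid @ resid)


def fit_size_control(records) -> SizeControlFit:
    """OLS of relative G1 growth on ln(birth volume).

    Slope -1 is the signature of a pure sizer; slope 0 means birth size
    carries no information about subsequent G1 growth.
    """
    df = records if isinstance(records, pd.DataFrame) else records_frame(records)
    n = len(df)
    require(n >= 3, "need at least 3 records", SizeControlError)
    x = df["ln_v_birth"].to_numpy()
    y = df["rel_g1"].to_numpy()
    # tolerance absorbs float jitter from the volume round trip
    require(np.var(x) > 1e-12, "no variance in ln(birth volume)", SizeControlError)

    beta, rss = _ols_line(x, y)
    dof = n - 2
    sxx = float(np.sum((x - x.mean()) ** 2))
    sigma2 = rss / dof if dof > 0 else np.nan
    se = math.sqrt(sigma2 / sxx)
    tstat = beta[1] / se if se > 0 else np.inf
    pval = 2 * stats.t.sf(abs(tstat), dof)
    tss = float(np.sum((y - y.mean()) ** 2))
    # a numerically constant response carries no explainable variance
    r2 = 1.0 - rss / tss if tss > 1e-12 * n * max(1.0, float(np.mean(y**2))) else 0.0
    return SizeControlFit(
        slope=float(beta[1]),
        intercept=float(beta[0]),
        stderr=float(se),
        pvalue=float(pval),
        r_squared=float(r2),
        n=n,
        rss=rss,
    )


@dataclass
class SlopeComparison:
    f_statistic: float
    df_num: int
    df_den: int
    pvalue: float


def compare_slopes(records_a, records_b) -> SlopeComparison:
    """Extra-sum-of-squares F-test for equality of the two cohorts' slopes.

    Full model: separate intercepts and slopes (equivalent to fitting each
    cohort independently). Reduced model: separate intercepts, one common
    slope. F = [(RSS_reduced - RSS_full) / 1] / [RSS_full / (n_a+n_b-4)].
    """
    dfa = records_a if isinstance(records_a, pd.DataFrame) else records_frame(records_a)
    dfb = records_b if isinstance(records_b, pd.DataFrame) else records_frame(records_b)
    fit_a = fit_size_control(dfa)
    fit_b = fit_size_control(dfb)
    rss_full = fit_a.rss + fit_b.rss

    xa, ya = dfa["ln_v_birth"].to_numpy(), dfa["rel_g1"].to_numpy()
    xb, yb = dfb["ln_v_birth"].to_numpy(), dfb["rel_g1"].to_numpy()
    x = np.concatenate([xa, xb])
    y = np.concatenate([ya, yb])
    grp_b = np.concatenate([np.zeros(len(xa)), np.ones(len(xb))])
    X_red = np.column_stack([np.ones_like(x), grp_b, x])
    beta, *_ = np.linalg.lstsq(X_red, y, rcond=None)
    resid = y - X_red @ beta
    rss_red = float(resid @ resid)

    df_den = len(x) - 4
    require(df_den > 0, "too few records for slope comparison", SizeControlError)
    f = max(0.0, (rss_red - rss_full) / (rss_full / df_den))
    p = float(stats.f.sf(f, 1, df_den))
    return SlopeComparison(f_statistic=float(f), df_num=1, df_den=df_den, pvalue=p)
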