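"""Per-pixel trend detection: Theil–Sen slope and Mann–Kendall significance.

The slope estimator is the median of all pairwise slopes

    beta = median( (y_j - y_i) / (t_j - t_i) ),  j > i

which is robust to outliers and makes no distributional assumption. Trend
significance uses the Mann–Kendall sign statistic

    S = sum_{i<j} sign(y_j - y_i)

with the tie-corrected variance

    Var(S) = [ n(n-1)(2n+5) - sum_k t_k (t_k - 1)(2 t_k + 5) ] / 18

(t_k the size of the k-th group of tied values) and the continuity-corrected
standardization Z = (S - 1)/sqrt(Var S) for S > 0, 0 for S = 0 and
(S + 1)/sqrt(Var S) for S < 0. A pixel is significant when
|Z| >= z_{1-alpha/2}. Positive S means an increasing series: S counts later-
minus-earlier comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .grids import GridSpec, AnnualRasterSeries
from .preprocess import MaskLayer

TREND_CLASSES = ("sig_decrease", "decrease", "no_trend", "increase", "sig_increase")

#: |beta| below this is treated as no trend at all
ZERO_SLOPE_BAND = 1e-12


def theil_sen_slope(t, y) -> float:
    """Median of all pairwise slopes; NaN when fewer than 2 valid points.

    With an even number of pairs the mean of the two central order
    statistics is returned (the standard sample median).
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(y) & np.isfinite(t)
    t, y = t[ok], y[ok]
    if len(np.unique(t)) < 2:
        return float("nan")
    i, j = np.triu_indices(len(t), k=1)
    dt = t[j] - t[i]
    keep = dt != 0
    return float(np.median((y[j] - y[i])[keep] / dt[keep]))


def mk_test(y, alpha: float = 0.05):
    """Mann–Kendall trend test on a series (time order = array order).

    Returns ``(S, varS, Z, significant)``; all-NaN when fewer than 4 valid
    points, which is too short for the normal approximation to mean much.
    """
    y = np.asarray(y, dtype=float)
    y = y[np.isfinite(y)]
    n = len(y)
    if n < 4:
        return float("nan"), float("nan"), float("nan"), False
    s = float(np.sum(np.sign(y[None, :] - y[:, None])[np.triu_indices(n, k=1)]))
    var_s = _mk_variance(y)
    if s > 0:
        z = (s - 1.0) / np.sqrt(var_s)
    elif s < 0:
        z = (s + 1.0) / np.sqrt(var_s)
    else:
        z = 0.0
    crit = stats.norm.ppf(1.0 - alpha / 2.0)
    return s, var_s, float(z), bool(abs(z) >= crit)


def _mk_variance(y: np.ndarray) -> float:
    n = len(y)
    var_s = n * (n - 1) * (2 * n + 5)
    _, counts = np.unique(y, return_counts=True)
    ties = counts[counts > 1]
    if ties.size:
        var_s -= np.sum(ties * (ties - 1) * (2 * ties + 5))
    return float(var_s / 18.0)


def classify_trend(beta: float, significant: bool) -> str:
    if not np.isfinite(beta) or abs(beta) < ZERO_SLOPE_BAND:
        return "no_trend"
    if beta > 0:
        return "sig_increase" if significant else "increase"
    return "sig_decrease" if significant else "decrease"


@dataclass
class TrendResult:
    """Per-pixel trend layers on the analysis grid."""

    grid: GridSpec
    beta: np.ndarray
    S: np.ndarray
    varS: np.ndarray
    Z: np.ndarray
    significant: np.ndarray
    trend_class: np.ndarray  # indices into TREND_CLASSES, -1 = nodata
    alpha: float

    def class_name(self, r: int, c: int) -> str:
        idx = int(self.trend_class[r, c])
        return "nodata" if idx < 0 else TREND_CLASSES[idx]

    def class_fractions(self) -> dict[str, float]:
        """Share of valid pixels per trend class."""
        valid = self.trend_class >= 0
        n = int(valid.sum())
        out = {}
        for i, name in enumerate(TREND_CLASSES):
            out[name] = float((self.trend_class == i).sum() / n) if n else float("nan")
        return out


def zonal_summary(result: TrendResult, zones: np.ndarray):
    """Per-zone trend summary (e.g. administrative units from a zone raster).

    ``zones`` is an integer raster on the same grid; negative zone ids are
    ignored. Returns a DataFrame with pixel counts, mean/median slope and
    the significant fraction per zone.
    """
    import pandas as pd

    zones = np.asarray(zones)
    if zones.shape != result.beta.shape:
        raise ValueError("zone raster is not grid-aligned")
    rows = []
    valid = np.isfinite(result.beta) & (zones >= 0)
    for zone in np.unique(zones[valid]):
        sel = valid & (zones == zone)
        rows.append({
            "zone": int(zone),
            "n_pixels": int(sel.sum()),
            "mean_beta": float(result.beta[sel].mean()),
            "median_beta": float(np.median(result.beta[sel])),
            "significant_fraction": float(result.significant[sel].mean()),
        })
    return pd.DataFrame(rows)


def trend_raster(series: AnnualRasterSeries, mask: MaskLayer | None = None,
                 alpha: float = 0.05) -> TrendResult:
    """Apply the slope estimator and MK test independently per kept pixel."""
    grid = series.grid
    if mask is not None and mask.grid != grid:
        raise ValueError("mask grid differs from series grid")
    shape = grid.shape
    beta = np.full(shape, np.nan)
    s_arr = np.full(shape, np.nan)
    var_arr = np.full(shape, np.nan)
    z_arr = np.full(shape, np.nan)
    sig = np.zeros(shape, dtype=bool)
    cls = np.full(shape, -1, dtype=np.int8)
    keep = np.ones(shape, dtype=bool) if mask is None else mask.keep
    t = series.times
    crit = stats.norm.ppf(1.0 - alpha / 2.0)
    for r in range(shape[0]):
        for c in range(shape[1]):
            if not keep[r, c]:
                continue
            y = series.values[:, r, c]
            b = theil_sen_slope(t, y)
            if not np.isfinite(b):
                continue
            s, v, z, is_sig = mk_test(y, alpha=alpha)
            beta[r, c] = b
            s_arr[r, c] = s
            var_arr[r, c] = v
            z_arr[r, c] = z if np.isfinite(z) else np.nan
            is_sig = bool(np.isfinite(z) and abs(z) >= crit)
            sig[r, c] = is_sig
            cls[r, c] = TREND_CLASSES.index(classify_trend(b, is_sig))
    return TrendResult(grid, beta, s_arr, var_arr, z_arr, sig, cls, alpha)
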