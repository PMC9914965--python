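"""Composite-series smoothing, annual compositing and analysis masks.

Vegetation-index composites carry cloud and atmospheric artifacts that show
up as sharp negative spikes. They are suppressed with a Savitzky–Golay
filter: a moving least-squares polynomial fit that preserves genuine
seasonal shape while removing high-frequency drops. Smoothed composites are
then averaged to annual means (the growing season spans the whole year for
evergreen-dominated study areas), and two masks restrict the analysis:
a vegetated-area mask (multi-year mean index >= 0.2 by default, dropping
bare/water pixels) and an urban-zone mask from aggregated nighttime light.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from .grids import GridSpec, AnnualRasterSeries

DEFAULT_SG_WINDOW = 7
DEFAULT_SG_POLYORDER = 2
DEFAULT_VEGETATION_THRESHOLD = 0.2
DEFAULT_URBAN_THRESHOLD = 4000.0


@dataclass
class MaskLayer:
    """Boolean keep-mask with a human-readable provenance string."""

    grid: GridSpec
    keep: np.ndarray
    provenance: str

    def __post_init__(self) -> None:
        self.keep = np.asarray(self.keep, dtype=bool)
        if self.keep.shape != self.grid.shape:
            raise ValueError("mask shape does not match grid")

    @property
    def keep_count(self) -> int:
        return int(self.keep.sum())

    def apply(self, values: np.ndarray) -> np.ndarray:
        """NaN-out masked cells; idempotent."""
        out = np.asarray(values, dtype=float).copy()
        out[..., ~self.keep] = np.nan
        return out

    def intersect(self, other: "MaskLayer") -> "MaskLayer":
        if other.grid != self.grid:
            raise ValueError("mask grids differ")
        return MaskLayer(self.grid, self.keep & other.keep,
                         f"({self.provenance}) AND ({other.provenance})")


def sg_smooth(series: AnnualRasterSeries, window: int = DEFAULT_SG_WINDOW,
              polyorder: int = DEFAULT_SG_POLYORDER) -> AnnualRasterSeries:
    """Savitzky–Golay smooth each pixel series along time.

    Missing composites are filled by linear interpolation (edge values
    extended) before filtering and re-masked afterwards, so the filter
    window never mixes nodata into valid estimates. Series edges are
    handled by fitting the edge polynomial to the first/last window, which
    keeps the filter exact for polynomials up to ``polyorder`` everywhere.
    Requires an odd ``window`` with ``polyorder < window`` and ``window``
    no longer than the series.
    """
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if polyorder >= window:
        raise ValueError("polyorder must be smaller than window")
    if window > series.n_times:
        raise ValueError("window exceeds series length")
    n_t = series.n_times
    flat = series.values.reshape(n_t, -1)
    nan_mask = ~np.isfinite(flat)
    filled = pd.DataFrame(flat).interpolate(
        method="linear", axis=0, limit_direction="both").to_numpy()
    all_nan = nan_mask.all(axis=0)
    filled[:, all_nan] = 0.0  # placeholder; re-masked below
    smoothed = savgol_filter(filled, window, polyorder, axis=0, mode="interp")
    smoothed[nan_mask] = np.nan
    out = series.copy()
    out.values = smoothed.reshape(series.values.shape)
    return out


def annual_composite(series: AnnualRasterSeries) -> AnnualRasterSeries:
    """Mean-composite composite-level values to one layer per year.

    The per-pixel annual value is the arithmetic mean of that year's
    non-missing composites; a pixel-year with no valid composite is nodata.
    """
    years = np.floor(series.times).astype(int)
    uniq = np.unique(years)
    out = np.full((len(uniq), *series.grid.shape), np.nan)
    for k, yr in enumerate(uniq):
        block = series.values[years == yr]
        with np.errstate(invalid="ignore"):
            valid = np.isfinite(block)
            sums = np.nansum(np.where(valid, block, 0.0), axis=0)
            counts = valid.sum(axis=0)
            out[k] = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return AnnualRasterSeries(series.grid, uniq.astype(float), out,
                              [str(y) for y in uniq])


def vegetation_mask(annual_series: AnnualRasterSeries,
                    threshold: float = DEFAULT_VEGETATION_THRESHOLD) -> MaskLayer:
    """Keep pixels whose multi-year mean index reaches ``threshold``.

    The lower bound is closed: a mean exactly at the threshold is kept.
    """
    if not (-1.0 < threshold < 1.0):
        raise ValueError("vegetation threshold must lie in (-1, 1)")
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(annual_series.values, axis=0)
    keep = np.where(np.isfinite(mean), mean >= threshold, False)
    return MaskLayer(annual_series.grid, keep,
                     f"multi-year mean index >= {threshold}")


def urban_mask(nightlight_series: AnnualRasterSeries,
               threshold: float = DEFAULT_URBAN_THRESHOLD) -> MaskLayer:
    """Urban zone: summed nighttime light over the period strictly above
    ``threshold``."""
    with np.errstate(invalid="ignore"):
        total = np.nansum(np.where(np.isfinite(nightlight_series.values),
                                   nightlight_series.values, 0.0), axis=0)
    return MaskLayer(nightlight_series.grid, total > threshold,
                     f"summed nightlight > {threshold}")
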