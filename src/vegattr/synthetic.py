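"""Synthetic study-area generator with known ground truth.

Every downstream stage (smoothing, trend detection, mobility indices,
attribution engines) is exercised against data whose generating process is
known exactly, so parameter recovery can be asserted:

* vegetation-index composite series: per-pixel linear trend plus an annual
  seasonal cycle, Gaussian measurement noise, and cloud-like dropout
  composites modeled as sharp negative spikes;
* covariate surfaces (population, nighttime light, climate, pollution,
  GDP, road density, construction-land rate) for an early and a late epoch
  as spatially autocorrelated fields (Gaussian-filtered white noise);
* origin-destination flow records whose Poisson mean is a configured
  monotone function of origin- and destination-cell covariates.

The vegetation slope map can be tied to designated "causal" covariate
changes, and the truth manifest records which, so the attribution engines
have a known answer to recover.

Defaults mirror the structure of a 20-year, 23-composites-per-year
vegetation record on a 64x64 cell equal-area grid, with a mean greening
trend of 0.0024 index units per year.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .grids import GridSpec, AnnualRasterSeries

FACTOR_NAMES = ("Pop", "NLight", "Prec", "Temp", "Srad", "PM2.5",
                "GDP", "Road", "CLR")

#: attribution covariates that may be designated causal for the slope map
CAUSAL_CANDIDATES = ("Pop", "NLight", "Prec", "Temp", "Srad", "PM2.5")

EPOCH_EARLY = "2000"
EPOCH_LATE = "2019"

# per-factor (reference scale, log-growth of the late epoch) — arbitrary but
# fixed units; NLight is scaled so a summed-epoch threshold of 4000 splits
# the grid into urban and non-urban zones
_FACTOR_LEVELS = {
    "Pop": (800.0, 0.5),
    "NLight": (1500.0, 0.9),
    "Prec": (1500.0, 0.05),
    "Temp": (22.0, 0.03),
    "Srad": (180.0, 0.02),
    "PM2.5": (35.0, 0.25),
    "GDP": (50.0, 0.1),
    "Road": (2.0, 0.07),
    "CLR": (1.0, 0.0),  # handled separately (a rate in [0, 1])
}


@dataclass(frozen=True)
class FlowLink:
    """Monotone link from origin/destination covariates to the Poisson mean.

    ``id`` is one of ``constant`` (mean = scale everywhere), ``linear``
    (mean = scale * average of the scaled covariate intensities at origin
    and destination) or ``exp`` (exponential in the standardized
    intensities; sharper contrast between rich and poor cells).
    """

    id: str = "linear"
    scale: float = 6.0

    def __post_init__(self) -> None:
        if self.id not in ("constant", "linear", "exp"):
            raise ValueError(f"unknown flow link {self.id!r}")
        if not np.isfinite(self.scale) or self.scale < 0:
            raise ValueError("flow link scale must be finite and >= 0")


@dataclass(frozen=True)
class SyntheticScenario:
    """Full description of one synthetic study area."""

    grid: GridSpec = GridSpec(64, 64, cell_size=250.0, origin_y=64 * 250.0)
    n_years: int = 20
    composites_per_year: int = 23
    start_year: int = 2000
    base_level: float = 0.45
    trend_per_year: float = 0.0024
    seasonal_amplitude: float = 0.08
    noise_sigma: float = 0.02
    dropout_prob: float = 0.05
    factor_effects: tuple[tuple[str, str, float], ...] = (
        ("NLight", "linear", -0.004),)
    slope_residual_sigma: float = 0.001
    field_length_scale: float = 6.0  # cells, for covariate autocorrelation
    flow_link: FlowLink = FlowLink()
    flow_noise_sigma: float = 0.0  # extra lognormal jitter on the Poisson mean
    n_flow_records: int = 262144
    seed: int = 0

    def __post_init__(self) -> None:
        for name, value in (("base_level", self.base_level),
                            ("trend_per_year", self.trend_per_year),
                            ("seasonal_amplitude", self.seasonal_amplitude),
                            ("noise_sigma", self.noise_sigma),
                            ("dropout_prob", self.dropout_prob),
                            ("slope_residual_sigma", self.slope_residual_sigma),
                            ("flow_noise_sigma", self.flow_noise_sigma)):
            if not np.isfinite(value):
                raise ValueError(f"{name} must be finite, got {value!r}")
        if not (0.0 <= self.dropout_prob <= 1.0):
            raise ValueError("dropout_prob must lie in [0, 1]")
        if self.noise_sigma < 0 or self.slope_residual_sigma < 0:
            raise ValueError("noise sigmas must be >= 0")
        if self.grid.n_rows < 2 or self.grid.n_cols < 2:
            raise ValueError("grid must be at least 2x2")
        if self.n_years < 1 or self.composites_per_year < 1:
            raise ValueError("need at least one year and one composite")
        for fname, func, _size in self.factor_effects:
            if fname not in CAUSAL_CANDIDATES:
                raise ValueError(
                    f"unknown causal factor {fname!r}; choose from "
                    f"{CAUSAL_CANDIDATES}")
            if func not in ("linear", "quadratic", "exp"):
                raise ValueError(f"unknown effect function {func!r}")

    def with_seed(self, seed: int) -> "SyntheticScenario":
        return replace(self, seed=int(seed))


def _rng(scenario: SyntheticScenario, *tags: int) -> np.random.Generator:
    return np.random.default_rng([int(scenario.seed) % (2**31), *tags])


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int],
                  length_scale: float) -> np.ndarray:
    """Unit-variance Gaussian-filtered white noise.

    The length scale is capped at a quarter of the smaller grid dimension so
    small grids still yield spatial variation, and the standardized field is
    clipped to +-4 sd to keep the exponential level transforms finite.
    """
    ls = min(length_scale, min(shape) / 4.0)
    z = ndimage.gaussian_filter(rng.standard_normal(shape), ls, mode="wrap")
    sd = z.std()
    z = z / sd if sd > 0 else z
    return np.clip(z, -4.0, 4.0)


@dataclass
class FactorStack:
    """Early/late covariate surfaces on the shared grid."""

    grid: GridSpec
    epochs: dict[str, dict[str, np.ndarray]]

    @property
    def epoch_labels(self) -> list[str]:
        return list(self.epochs)

    def layer(self, epoch: str, name: str) -> np.ndarray:
        return self.epochs[epoch][name]

    def change(self, name: str) -> np.ndarray:
        """Late-minus-early change surface for one factor."""
        labels = self.epoch_labels
        return self.epochs[labels[-1]][name] - self.epochs[labels[0]][name]


def _effect_transform(z: np.ndarray, func: str) -> np.ndarray:
    """Standardized monotone/curved transform of a unit-variance field."""
    if func == "linear":
        out = z
    elif func == "quadratic":
        out = z ** 2
    else:  # exp
        out = np.exp(z)
    out = out - out.mean()
    sd = out.std()
    return out / sd if sd > 0 else out


def gen_factor_stack(scenario: SyntheticScenario
                     ) -> tuple[FactorStack, dict]:
    """Generate covariate surfaces and the ground-truth manifest.

    Returns ``(stack, manifest)``; ``manifest['true_slope_map']`` is the
    per-pixel vegetation slope (index units/year) built from the scenario's
    baseline trend plus the configured causal-factor effects, and
    ``manifest['causal_factors']`` lists exactly those factors.
    """
    epochs: dict[str, dict[str, np.ndarray]] = {EPOCH_EARLY: {}, EPOCH_LATE: {}}
    shape = scenario.grid.shape
    ls = scenario.field_length_scale
    for k, name in enumerate(FACTOR_NAMES):
        rng_base = _rng(scenario, 1, k, 0)
        rng_grow = _rng(scenario, 1, k, 1)
        base_z = _smooth_field(rng_base, shape, ls)
        grow_z = _smooth_field(rng_grow, shape, ls)
        scale, growth = _FACTOR_LEVELS[name]
        if name == "CLR":  # construction-land rate stays a share in [0, 1]
            early = 1.0 / (1.0 + np.exp(-(base_z - 1.0)))
            late = 1.0 / (1.0 + np.exp(-(base_z - 1.0 + 0.3 * grow_z + 0.2)))
        else:
            early = scale * np.exp(0.4 * base_z)
            late = early * np.exp(growth + 0.3 * grow_z)
        epochs[EPOCH_EARLY][name] = early
        epochs[EPOCH_LATE][name] = late
    stack = FactorStack(scenario.grid, epochs)

    slope = np.full(shape, scenario.trend_per_year, dtype=float)
    for fname, func, size in scenario.factor_effects:
        change = stack.change(fname)
        z = (change - change.mean()) / change.std()
        slope = slope + size * _effect_transform(z, func)
    if scenario.slope_residual_sigma > 0:
        slope = slope + scenario.slope_residual_sigma * _rng(
            scenario, 2).standard_normal(shape)
    manifest = {
        "causal_factors": [
            {"name": f, "effect": func, "effect_size": s}
            for f, func, s in scenario.factor_effects],
        "trend_per_year": scenario.trend_per_year,
        "epochs": [EPOCH_EARLY, EPOCH_LATE],
        "true_slope_map": slope,
    }
    return stack, manifest


def gen_vegetation_series(scenario: SyntheticScenario,
                          slope_map: np.ndarray | None = None
                          ) -> tuple[AnnualRasterSeries, np.ndarray]:
    """Composite-level vegetation-index series plus the true slope map.

    Per composite: value = base + slope * years_elapsed
    + amplitude * sin(2 pi doy / 365) + Gaussian noise; composites hit by
    dropout lose a uniform 30-70% of their value (cloud-like negative
    spike). Returns ``(series, slope_map)``.
    """
    grid = scenario.grid
    if slope_map is None:
        slope_map = np.full(grid.shape, scenario.trend_per_year)
    slope_map = np.asarray(slope_map, dtype=float)
    if slope_map.shape != grid.shape:
        raise ValueError("slope map shape does not match grid")
    cpy = scenario.composites_per_year
    n_t = scenario.n_years * cpy
    comp = np.arange(n_t)
    years_elapsed = comp / cpy
    doy = ((comp % cpy) + 0.5) * 365.0 / cpy
    seasonal = scenario.seasonal_amplitude * np.sin(2 * np.pi * doy / 365.0)
    values = (scenario.base_level
              + years_elapsed[:, None, None] * slope_map[None]
              + seasonal[:, None, None])
    rng = _rng(scenario, 3)
    if scenario.noise_sigma > 0:
        values = values + rng.normal(0.0, scenario.noise_sigma, values.shape)
    if scenario.dropout_prob > 0:
        hit = rng.random(values.shape) < scenario.dropout_prob
        frac = rng.uniform(0.3, 0.7, values.shape)
        values = np.where(hit, values - frac * np.abs(values), values)
    times = scenario.start_year + years_elapsed
    labels = [f"{scenario.start_year + c // cpy}_{c % cpy:02d}" for c in comp]
    series = AnnualRasterSeries(grid, times, values, labels)
    return series, slope_map


def gen_nightlight_series(scenario: SyntheticScenario,
                          stack: FactorStack) -> AnnualRasterSeries:
    """Two-epoch nighttime-light stack for the urban mask."""
    labels = stack.epoch_labels
    values = np.stack([stack.layer(lab, "NLight") for lab in labels])
    return AnnualRasterSeries(scenario.grid, [float(l) for l in labels],
                              values, list(labels))


def flow_covariate_names(kind: str) -> tuple[str, str]:
    """Vehicle flows follow GDP and road density; human travel flows follow
    GDP and the construction-land rate."""
    if kind == "vehicle":
        return ("GDP", "Road")
    if kind == "human":
        return ("GDP", "CLR")
    raise ValueError(f"unknown flow kind {kind!r}")


def flow_intensity(stack: FactorStack, epoch: str, kind: str) -> np.ndarray:
    """Per-cell activity intensity entering the flow link (dimensionless)."""
    f1, f2 = flow_covariate_names(kind)
    s1 = _FACTOR_LEVELS[f1][0]
    s2 = _FACTOR_LEVELS[f2][0]
    return 0.5 * (stack.layer(epoch, f1) / s1 + stack.layer(epoch, f2) / s2)


def _link_mean(link: FlowLink, phi_o: np.ndarray, phi_d: np.ndarray
               ) -> np.ndarray:
    if link.id == "constant":
        return np.full_like(phi_o, link.scale, dtype=float)
    if link.id == "linear":
        return link.scale * 0.5 * (phi_o + phi_d)
    # exp: standardized against a fixed reference intensity of 1
    return link.scale * np.exp(0.5 * (phi_o - 1.0) + 0.5 * (phi_d - 1.0))


def gen_flow_records(scenario: SyntheticScenario, stack: FactorStack,
                     epoch: str, kind: str) -> pd.DataFrame:
    """Draw origin-destination movement records for one epoch and kind.

    Endpoints follow a balanced design: every cell appears (as near as the
    record budget allows) equally often as an origin and as a destination,
    with the pairing randomized, so per-cell flow totals reflect the link
    function rather than endpoint-sampling noise. The record count is
    Poisson with the configured link mean evaluated at the two cells'
    covariates; zero-count draws produce no record. Coordinates are
    uniformly jittered inside their cell, so they always fall in the grid
    extent.
    """
    if epoch not in stack.epochs:
        raise ValueError(f"no covariate surfaces for epoch {epoch!r}")
    grid = scenario.grid
    kinds = ("human", "vehicle")
    rng = _rng(scenario, 4, kinds.index(kind), stack.epoch_labels.index(epoch))
    n = scenario.n_flow_records
    phi = flow_intensity(stack, epoch, kind).ravel()
    n_cells = grid.n_rows * grid.n_cols
    repeats = -(-n // n_cells)  # ceil
    o_idx = np.tile(rng.permutation(n_cells), repeats)[:n]
    d_idx = rng.permutation(o_idx)
    mean = _link_mean(scenario.flow_link, phi[o_idx], phi[d_idx])
    if scenario.flow_noise_sigma > 0:
        mean = mean * rng.lognormal(0.0, scenario.flow_noise_sigma, n)
    counts = rng.poisson(mean)
    o_r, o_c = np.divmod(o_idx, grid.n_cols)
    d_r, d_c = np.divmod(d_idx, grid.n_cols)
    jitter = rng.random((4, n))
    cs = grid.cell_size
    df = pd.DataFrame({
        "origin_x": grid.origin_x + (o_c + jitter[0]) * cs,
        "origin_y": grid.origin_y - (o_r + jitter[1]) * cs,
        "dest_x": grid.origin_x + (d_c + jitter[2]) * cs,
        "dest_y": grid.origin_y - (d_r + jitter[3]) * cs,
        "count": counts,
        "epoch": epoch,
    })
    return df[df["count"] > 0].reset_index(drop=True)


def write_truth_manifest(path, manifest: dict, grid: GridSpec) -> None:
    """Persist the ground-truth manifest as JSON plus a slope-map raster.

    The slope map is written next to the JSON as ``<stem>_slope.tif`` so
    the manifest itself stays a small text record.
    """
    import json
    from pathlib import Path

    from .grids import write_raster

    path = Path(path)
    slope_path = path.with_name(path.stem + "_slope.tif")
    write_raster(slope_path, manifest["true_slope_map"], grid)
    meta = {k: v for k, v in manifest.items() if k != "true_slope_map"}
    meta["true_slope_map_path"] = slope_path.name
    path.write_text(json.dumps(meta, indent=2, sort_keys=True))


def write_flow_csv(path, records: pd.DataFrame) -> None:
    records.to_csv(path, index=False)


def read_flow_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"epoch": str})
    required = {"origin_x", "origin_y", "dest_x", "dest_y", "count", "epoch"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"flow CSV missing columns: {sorted(missing)}")
    return df
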