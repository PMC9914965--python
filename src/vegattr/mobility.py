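"""Mobile-human-activity indices from origin-destination flow records.

Flow records (human travel, vehicle navigation) exist only for the recent
epoch. The historical epoch is reconstructed by regression backcasting:

1. ``grid_flows``   — bin record endpoints into per-cell inflow/outflow;
2. ``fit_flow_model`` — fit a bagged regression-tree ensemble from cell
   covariates (GDP + road density for vehicles, GDP + construction-land
   rate for human travel) to the observed late-epoch flows;
3. ``backcast_flows`` — apply the fitted model to historical covariates,
   producing simulated historical inflow/outflow surfaces;
4. ``mobility_change`` — late-minus-early per-cell differences (the
   attribution covariates) and aggregate late/early ratios (reporting).

The model is fitted on the late epoch, where flow observations exist, and
only evaluated on early covariates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from .grids import GridSpec

logger = logging.getLogger(__name__)

FLOW_KINDS = ("human", "vehicle")
DEFAULT_N_TREES = 500


@dataclass
class FlowGrid:
    """Per-cell inflow and outflow totals for one epoch and kind."""

    grid: GridSpec
    inflow: np.ndarray
    outflow: np.ndarray
    epoch: str
    kind: str
    simulated: bool = False
    n_dropped_origins: int = 0
    n_dropped_destinations: int = 0

    def __post_init__(self) -> None:
        if self.kind not in FLOW_KINDS:
            raise ValueError(f"kind must be one of {FLOW_KINDS}")
        for arr in (self.inflow, self.outflow):
            if arr.shape != self.grid.shape:
                raise ValueError("flow array shape does not match grid")

    @property
    def total_inflow(self) -> float:
        return float(self.inflow.sum())

    @property
    def total_outflow(self) -> float:
        return float(self.outflow.sum())


def grid_flows(records: pd.DataFrame, grid: GridSpec, kind: str,
               epoch: str | None = None) -> FlowGrid:
    """Aggregate OD records to per-cell inflow/outflow counts.

    Each record adds its count to the outflow of its origin cell and the
    inflow of its destination cell (a self-loop contributes to both in the
    same cell). Endpoints outside the grid extent are logged and dropped
    from the corresponding side only.
    """
    if epoch is None:
        epochs = records["epoch"].unique() if len(records) else []
        if len(epochs) > 1:
            raise ValueError("records span multiple epochs; pass one epoch")
        epoch = str(epochs[0]) if len(epochs) else "unknown"
    inflow = np.zeros(grid.shape)
    outflow = np.zeros(grid.shape)
    if len(records) == 0:
        logger.warning("empty record set for kind=%s epoch=%s; zero grids",
                       kind, epoch)
        return FlowGrid(grid, inflow, outflow, epoch, kind)
    counts = records["count"].to_numpy(dtype=float)
    if (counts < 0).any():
        raise ValueError("negative flow counts")
    o_in = grid.contains(records["origin_x"], records["origin_y"])
    d_in = grid.contains(records["dest_x"], records["dest_y"])
    n_bad_o = int((~o_in).sum())
    n_bad_d = int((~d_in).sum())
    if n_bad_o or n_bad_d:
        logger.warning("dropped %d origins and %d destinations outside the "
                       "grid extent", n_bad_o, n_bad_d)
    if o_in.any():
        r, c = grid.point_to_cell(records.loc[o_in, "origin_x"],
                                  records.loc[o_in, "origin_y"])
        np.add.at(outflow, (r, c), counts[o_in])
    if d_in.any():
        r, c = grid.point_to_cell(records.loc[d_in, "dest_x"],
                                  records.loc[d_in, "dest_y"])
        np.add.at(inflow, (r, c), counts[d_in])
    return FlowGrid(grid, inflow, outflow, epoch, kind,
                    n_dropped_origins=n_bad_o, n_dropped_destinations=n_bad_d)


@dataclass
class FlowModel:
    """Fitted covariates->flow ensembles for one kind (both directions)."""

    kind: str
    covariate_names: list[str]
    models: dict[str, RandomForestRegressor]
    oob_stats: dict[str, dict[str, float]]
    seed: int
    training_epoch: str = ""

    def predict(self, covariates: dict[str, np.ndarray], direction: str
                ) -> np.ndarray:
        X = _design_matrix(covariates, self.covariate_names)
        grid_shape = covariates[self.covariate_names[0]].shape
        pred = self.models[direction].predict(X).reshape(grid_shape)
        return np.clip(pred, 0.0, None)


def _design_matrix(covariates: dict[str, np.ndarray], names: list[str]
                   ) -> np.ndarray:
    missing = [n for n in names if n not in covariates]
    if missing:
        raise ValueError(f"missing covariate layers: {missing}")
    cols = [np.asarray(covariates[n], dtype=float).ravel() for n in names]
    if len({c.size for c in cols}) > 1:
        raise ValueError("covariate layers have inconsistent sizes")
    return np.column_stack(cols)


def fit_flow_model(flow: FlowGrid, covariates: dict[str, np.ndarray],
                   covariate_names: list[str] | None = None, *,
                   n_trees: int = DEFAULT_N_TREES, seed: int = 0) -> FlowModel:
    """Fit per-direction bagged-tree regressions of cell flows on covariates.

    Out-of-bag RMSE and R^2 are reported per direction; with at most four
    covariates every covariate is considered at each split.
    """
    names = covariate_names or list(covariates)
    X = _design_matrix(covariates, names)
    if X.shape[0] != flow.inflow.size:
        raise ValueError("covariate grids do not match the flow grid")
    models, stats = {}, {}
    for direction, y in (("in", flow.inflow.ravel()),
                         ("out", flow.outflow.ravel())):
        rf = RandomForestRegressor(
            n_estimators=n_trees,
            max_features=min(4, X.shape[1]),
            oob_score=True,
            bootstrap=True,
            random_state=int(seed) % (2**31),
            n_jobs=1,
        )
        rf.fit(X, y)
        oob_pred = rf.oob_prediction_
        resid = y - oob_pred
        sst = float(np.sum((y - y.mean()) ** 2))
        stats[direction] = {
            "oob_rmse": float(np.sqrt(np.mean(resid ** 2))),
            "oob_r2": float(1.0 - np.sum(resid ** 2) / sst) if sst > 0 else 0.0,
        }
        models[direction] = rf
    return FlowModel(flow.kind, names, models, stats, int(seed), flow.epoch)


def backcast_flows(model: FlowModel, covariates_historical: dict[str, np.ndarray],
                   epoch: str, grid: GridSpec) -> FlowGrid:
    """Predict historical inflow/outflow surfaces from historical covariates.

    Predictions are clipped at zero and the result is flagged as simulated.
    """
    inflow = model.predict(covariates_historical, "in")
    outflow = model.predict(covariates_historical, "out")
    return FlowGrid(grid, inflow, outflow, epoch, model.kind, simulated=True)


@dataclass
class MobilityIndex:
    """Late-minus-early flow change surfaces plus aggregate ratios."""

    grid: GridSpec
    kind: str
    delta_in: np.ndarray
    delta_out: np.ndarray
    ratio_in: float
    ratio_out: float
    epoch_late: str = ""
    epoch_early: str = ""


def mobility_change(flow_late: FlowGrid, flow_early: FlowGrid) -> MobilityIndex:
    """Change indices between two epochs of the same flow kind."""
    if flow_late.kind != flow_early.kind:
        raise ValueError(
            f"flow kinds differ: {flow_late.kind!r} vs {flow_early.kind!r}")
    if flow_late.grid != flow_early.grid:
        raise ValueError("flow grids differ")
    early_in = flow_early.total_inflow
    early_out = flow_early.total_outflow
    return MobilityIndex(
        flow_late.grid, flow_late.kind,
        delta_in=flow_late.inflow - flow_early.inflow,
        delta_out=flow_late.outflow - flow_early.outflow,
        ratio_in=flow_late.total_inflow / early_in if early_in > 0 else float("nan"),
        ratio_out=(flow_late.total_outflow / early_out
                   if early_out > 0 else float("nan")),
        epoch_late=flow_late.epoch, epoch_early=flow_early.epoch,
    )
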