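"""Pipeline orchestration: preprocessing -> trend detection -> mobility
indices -> attribution, driven by one serializable configuration.

The four stages mirror the analysis framework: (1) data preprocessing
(smoothing, annual compositing, masking), (2) vegetation change detection
(Theil-Sen + Mann-Kendall per pixel), (3) construction of the mobile-human-
activity indices (flow gridding, late-epoch model fit, historical
backcasting, change indices), (4) driving-mechanism analysis (PLSR,
permutation importance, geographical detector) per vegetation-change
pattern. Every threshold and model constant used in a run is logged and
echoed into the JSON report for auditability.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import attribution, mobility, preprocess, synthetic, trend
from .grids import GridSpec, write_raster, assert_shared_grid

logger = logging.getLogger(__name__)

STAGES = ("preprocessing", "change_detection", "mobility_indices",
          "attribution")

ATTRIBUTION_COVARIATES = ("HFlowIn", "HFlowOut", "TFlowIn", "TFlowOut",
                          "Pop", "NLight", "Prec", "Temp", "Srad", "PM2.5")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and prior artifacts."""

    def __init__(self, stage: str, completed: list[str], cause: Exception):
        super().__init__(f"stage {stage!r} failed after {completed}: {cause}")
        self.stage = stage
        self.completed = completed


@dataclass
class RunConfig:
    """Single source of truth for one pipeline run."""

    scenario: synthetic.SyntheticScenario = field(
        default_factory=synthetic.SyntheticScenario)
    sg_window: int = preprocess.DEFAULT_SG_WINDOW
    sg_polyorder: int = preprocess.DEFAULT_SG_POLYORDER
    alpha: float = 0.05
    vegetation_threshold: float = preprocess.DEFAULT_VEGETATION_THRESHOLD
    urban_threshold: float = preprocess.DEFAULT_URBAN_THRESHOLD
    n_strata: int = attribution.DEFAULT_STRATA
    n_components: int = attribution.DEFAULT_N_COMPONENTS
    n_trees: int = attribution.DEFAULT_N_TREES
    m_try: int = attribution.DEFAULT_M_TRY
    train_frac: float = attribution.DEFAULT_TRAIN_FRAC
    index_kind: str = "NDVI"
    seed: int = 0
    output_dir: str = "vegattr_run"
    write_rasters: bool = True

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["scenario"]["grid"] = self.scenario.grid.to_dict()
        d["scenario"]["flow_link"] = dataclasses.asdict(self.scenario.flow_link)
        d["scenario"]["factor_effects"] = [
            list(e) for e in self.scenario.factor_effects]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        sc = dict(d.pop("scenario", {}))
        if "grid" in sc:
            sc["grid"] = GridSpec.from_dict(sc["grid"])
        if "flow_link" in sc:
            sc["flow_link"] = synthetic.FlowLink(**sc["flow_link"])
        if "factor_effects" in sc:
            sc["factor_effects"] = tuple(tuple(e) for e in sc["factor_effects"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        try:
            scenario = synthetic.SyntheticScenario(**sc)
        except TypeError as exc:
            raise ValueError(f"bad scenario config: {exc}") from exc
        return cls(scenario=scenario, **d)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        return cls.from_dict(data)

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def run_pipeline(config: RunConfig, output_dir=None) -> dict:
    """Execute all four stages on the configured synthetic scenario.

    Writes rasters, CSV tables and a JSON report under ``output_dir`` and
    returns the report dict. A stage failure raises :class:`StageError`
    naming the failed stage and listing the stages already completed.
    """
    out = Path(output_dir or config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    scenario = config.scenario
    grid = scenario.grid
    report: dict = {
        "stages_completed": [],
        "config": config.to_dict(),
        "constants": {
            "vegetation_threshold": config.vegetation_threshold,
            "urban_threshold": config.urban_threshold,
            "alpha": config.alpha,
            "sg_window": config.sg_window,
            "sg_polyorder": config.sg_polyorder,
            "n_trees": config.n_trees,
            "m_try": config.m_try,
            "train_frac": config.train_frac,
            "n_strata": config.n_strata,
            "n_components": config.n_components,
        },
    }
    completed: list[str] = []

    def run_stage(name, fn):
        logger.info("stage %s ...", name)
        try:
            result = fn()
        except Exception as exc:  # noqa: BLE001 - report failing stage
            raise StageError(name, list(completed), exc) from exc
        completed.append(name)
        report["stages_completed"] = list(completed)
        return result

    # -- stage 1: preprocessing ------------------------------------------
    def _preprocess():
        stack, manifest = synthetic.gen_factor_stack(scenario)
        series, slope_map = synthetic.gen_vegetation_series(
            scenario, manifest["true_slope_map"])
        smoothed = preprocess.sg_smooth(series, config.sg_window,
                                        config.sg_polyorder)
        annual = preprocess.annual_composite(smoothed)
        veg_mask = preprocess.vegetation_mask(annual,
                                              config.vegetation_threshold)
        nlight = synthetic.gen_nightlight_series(scenario, stack)
        urb_mask = preprocess.urban_mask(nlight, config.urban_threshold)
        logger.info("vegetation mask keeps %d px; urban zone %d px "
                    "(thresholds %.3g / %.3g)", veg_mask.keep_count,
                    urb_mask.keep_count, config.vegetation_threshold,
                    config.urban_threshold)
        return stack, manifest, annual, veg_mask, urb_mask

    stack, manifest, annual, veg_mask, urb_mask = run_stage(
        STAGES[0], _preprocess)
    report["preprocessing"] = {
        "n_composites": scenario.n_years * scenario.composites_per_year,
        "n_years": int(annual.n_times),
        "vegetation_keep_count": veg_mask.keep_count,
        "urban_keep_count": urb_mask.keep_count,
    }

    # -- stage 2: vegetation change detection ----------------------------
    def _change_detection():
        assert_shared_grid([annual, veg_mask], grid)
        return trend.trend_raster(annual, veg_mask, alpha=config.alpha)

    trend_res = run_stage(STAGES[1], _change_detection)
    report["change_detection"] = {
        "alpha": config.alpha,
        "mean_slope": float(np.nanmean(trend_res.beta)),
        "class_fractions": trend_res.class_fractions(),
        "significant_fraction": float(
            np.mean(trend_res.significant[trend_res.trend_class >= 0]))
        if (trend_res.trend_class >= 0).any() else float("nan"),
    }

    # -- stage 3: mobility indices ---------------------------------------
    def _mobility():
        early, late = stack.epoch_labels[0], stack.epoch_labels[-1]
        indices, model_stats, truth = {}, {}, {}
        for k, kind in enumerate(mobility.FLOW_KINDS):
            cov_names = list(synthetic.flow_covariate_names(kind))
            records_late = synthetic.gen_flow_records(scenario, stack, late, kind)
            flow_late = mobility.grid_flows(records_late, grid, kind, late)
            covs_late = {n: stack.layer(late, n) for n in cov_names}
            covs_early = {n: stack.layer(early, n) for n in cov_names}
            model = mobility.fit_flow_model(
                flow_late, covs_late, cov_names,
                n_trees=config.n_trees, seed=scenario.seed + 11 * (k + 1))
            flow_early = mobility.backcast_flows(model, covs_early, early, grid)
            indices[kind] = mobility.mobility_change(flow_late, flow_early)
            model_stats[kind] = model.oob_stats
            # generative truth for the recovery report
            rec_early = synthetic.gen_flow_records(scenario, stack, early, kind)
            true_early = mobility.grid_flows(rec_early, grid, kind, early)
            truth[kind] = {
                "true_early_total_in": true_early.total_inflow,
                "predicted_early_total_in": flow_early.total_inflow,
            }
        return indices, model_stats, truth

    indices, model_stats, flow_truth = run_stage(STAGES[2], _mobility)
    report["mobility_indices"] = {
        kind: {
            "ratio_in": idx.ratio_in,
            "ratio_out": idx.ratio_out,
            "model_oob": model_stats[kind],
            **flow_truth[kind],
        } for kind, idx in indices.items()
    }

    # -- stage 4: attribution --------------------------------------------
    def _attribution():
        covariate_changes = {
            "HFlowIn": indices["human"].delta_in,
            "HFlowOut": indices["human"].delta_out,
            "TFlowIn": indices["vehicle"].delta_in,
            "TFlowOut": indices["vehicle"].delta_out,
        }
        for name in ("Pop", "NLight", "Prec", "Temp", "Srad", "PM2.5"):
            covariate_changes[name] = stack.change(name)
        assert_shared_grid(list(covariate_changes.values()), grid)
        table = attribution.build_sample_table(
            trend_res, covariate_changes, veg_mask,
            index_kind=config.index_kind, seed=scenario.seed,
            train_frac=config.train_frac)
        results = {}
        tables = {}
        for pattern in ("increase", "decrease"):
            sub = table.subset(pattern)
            pls = attribution.plsr_fit(sub.X, sub.y, config.n_components,
                                       sub.covariate_names)
            imp = attribution.rf_importance(
                sub, n_trees=config.n_trees, m_try=config.m_try,
                seed=scenario.seed)
            gd = attribution.gd_analysis(sub, L=config.n_strata)
            singles = gd[gd["factor_b"] == ""]
            pairs = gd[gd["factor_b"] != ""]
            top_pair = pairs.loc[pairs["q"].idxmax()] if len(pairs) else None
            results[pattern] = {
                "n_samples": sub.n,
                "plsr": {
                    "r2": pls.r2,
                    "coefficient_weight": dict(zip(
                        pls.covariate_names,
                        np.round(pls.coefficient_weight, 6))),
                    "ranking": pls.ranking(),
                },
                "rf": {
                    "r2": imp.r2,
                    "rmse": imp.rmse,
                    "inc_mse_pct": dict(zip(imp.covariate_names,
                                            np.round(imp.inc_mse_pct, 4))),
                    "ranking": imp.ranking(),
                },
                "gd": {
                    "q": dict(zip(singles["factor_a"],
                                  np.round(singles["q"], 6))),
                    "ranking": list(
                        singles.sort_values("q", ascending=False)["factor_a"]),
                    "max_interaction_q": (float(top_pair["q"])
                                          if top_pair is not None else None),
                    "max_interaction_pair": (
                        [top_pair["factor_a"], top_pair["factor_b"]]
                        if top_pair is not None else None),
                    "max_interaction_category": (
                        top_pair["category"] if top_pair is not None else None),
                },
            }
            tables[pattern] = (sub, gd)
        return table, results, tables

    table, attr_results, attr_tables = run_stage(STAGES[3], _attribution)
    report["attribution"] = attr_results
    report["attribution"]["n_valid_samples"] = table.n
    report["truth"] = {
        "causal_factors": manifest["causal_factors"],
        "trend_per_year": manifest["trend_per_year"],
    }

    _write_outputs(out, config, report, trend_res, indices, attr_tables)
    return report


def _write_outputs(out: Path, config: RunConfig, report: dict,
                   trend_res, indices, attr_tables) -> None:
    grid = config.scenario.grid
    if config.write_rasters:
        write_raster(out / "trend_beta.tif", trend_res.beta, grid)
        write_raster(out / "trend_z.tif", trend_res.Z, grid)
        write_raster(out / "trend_class.tif",
                     trend_res.trend_class.astype(np.float32), grid)
        for kind, idx in indices.items():
            write_raster(out / f"{kind}_delta_in.tif", idx.delta_in, grid)
            write_raster(out / f"{kind}_delta_out.tif", idx.delta_out, grid)
    engine_rows = []
    for pattern, (sub, gd) in attr_tables.items():
        gd.assign(pattern=pattern).to_csv(
            out / f"gd_{pattern}.csv", index=False)
        for engine in ("plsr", "rf", "gd"):
            block = report["attribution"][pattern][engine]
            stats = block.get("coefficient_weight") or block.get(
                "inc_mse_pct") or block.get("q")
            for name, value in stats.items():
                engine_rows.append({"engine": engine, "pattern": pattern,
                                    "index_kind": config.index_kind,
                                    "factor": name, "statistic": value})
    pd.DataFrame(engine_rows).to_csv(out / "attribution_stats.csv", index=False)
    config.save(out / "config_used.yaml")
    (out / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True, default=_jsonable))


def report_hash(report: dict) -> str:
    """Stable hash of a report for determinism checks."""
    blob = json.dumps(report, sort_keys=True, default=_jsonable)
    return hashlib.sha256(blob.encode()).hexdigest()
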