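"""End-to-end orchestration: simulate -> composite -> invert -> veg ->
correlate -> couple -> importance.

Runs the whole analysis on a synthetic basin at a scaled-down problem size
(default 48x48 cells, 120 sites, 8 years of monthly layers), writes every
intermediate product under an output directory, and returns a summary
dictionary that is deterministic for a fixed seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import composite, correlation, coupling, importance, inversion, io, synthetic
from . import timeseries as ts
from .grid import RasterGrid, nanmean_quiet
from .vegindices import INDEX_BANDS, compute_index

log = logging.getLogger("smveg")

#: band variables carried through QC and annual aggregation
_PIPE_BANDS = ("B2", "B3", "B4", "B6", "B8", "B12", "VH")
_OPTICAL = ("B2", "B3", "B4", "B6", "B8", "B12")


@dataclass
class PipelineConfig:
    """All knobs of a run, with the analysis defaults baked in."""

    n_rows: int = 48
    n_cols: int = 48
    cell_size: float = 20.0
    n_sites: int = 120
    noise_sd: float = 0.01
    years: tuple = tuple(range(2017, 2025))
    seed: int = 0
    alpha: float = 0.05                 # significance level everywhere
    rmse_gate: float = 0.05
    mae_gate: float = 0.02
    mape_gate: float = 20.0
    kmo_gate: float = 0.5
    r_gate: float = 0.6
    ccd_form: str = "sqrt"              # or "harmonic"
    weight_alpha: float = 0.5
    weight_beta: float = 0.5
    rf_trees: int = 200
    rf_min_leaf: int = 5
    rf_max_pixels: int = 20000
    low_threshold: float = 0.0
    spike_factor: float = 2.0
    out_dir: str = "smveg_run"

    @property
    def gates(self) -> dict:
        return {"rmse": self.rmse_gate, "mae": self.mae_gate, "mape": self.mape_gate}

    def to_yaml(self, path):
        Path(path).write_text(yaml.safe_dump(asdict(self)))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        raw["years"] = tuple(raw.get("years", cls.years))
        return cls(**raw)


def simulate(config: PipelineConfig, out_dir: Path | None = None):
    """Generate geometry, samples, monthly stacks and drivers; optionally write."""
    geom = synthetic.generate_geometry(
        config.n_rows, config.n_cols, config.cell_size, config.seed
    )
    truth = synthetic.TruthConfig(noise_sd=config.noise_sd, seed=config.seed)
    samples = synthetic.generate_soil_samples(config.n_sites, truth, geom)

    stacks: dict[str, ts.TimeSeriesStack] = {}
    times, layers = [], {v: [] for v in (*_PIPE_BANDS, "NPP", "LAI")}
    for year in config.years:
        for month in range(1, 13):
            bands = synthetic.generate_band_stack(geom, month, config.seed, year)
            prods = synthetic.generate_vegetation_products(geom, month, config.seed, year)
            times.append((year, month))
            for v in _PIPE_BANDS:
                layers[v].append(bands[v].data)
            layers["NPP"].append(prods["NPP"].data)
            layers["LAI"].append(prods["LAI"].data)
    for v, arrs in layers.items():
        stacks[v] = ts.TimeSeriesStack.from_arrays(v, times, np.array(arrs), geom)

    wet, veg, _ = synthetic.latent_fields(geom, config.seed)
    anchor = RasterGrid(0.5 * wet + 0.5 * veg, geom, "anchor")
    drivers = synthetic.generate_driver_stack(geom, seed=config.seed, anchor=anchor)

    if out_dir is not None:
        io.write_samples(samples, out_dir / "samples.csv")
        for name, grid in drivers.drivers.items():
            io.write_raster(grid, out_dir / "drivers" / f"{name}.tif")
    return geom, samples, stacks, drivers


def _quality_control(stack, config):
    flags = ts.flag_outliers(stack, config.low_threshold, config.spike_factor)
    return ts.linear_gapfill(stack, flags)


def _annual_stack(stack, years):
    grids = [ts.annual_mean(stack, y) for y in years]
    return ts.TimeSeriesStack.from_grids(stack.variable, [(y, 1) for y in years], grids)


def run_all(config: PipelineConfig) -> dict:
    """Run every stage and write products + ``summary.json`` under out_dir."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log.info("thresholds: alpha=%s gates=%s kmo>=%s r>%s form=%s",
             config.alpha, config.gates, config.kmo_gate, config.r_gate, config.ccd_form)

    try:
        geom, samples, stacks, drivers = simulate(config, out)
    except Exception as e:  # pragma: no cover
        raise RuntimeError(f"stage 'simulate' failed: {e}") from e

    # -- temporal QC and annual aggregation -------------------------------
    for v in (*_OPTICAL, "NPP", "LAI"):
        stacks[v] = _quality_control(stacks[v], config)
    annual = {v: _annual_stack(s, config.years) for v, s in stacks.items()}
    mean_grid = {
        v: RasterGrid(nanmean_quiet(annual[v].data, axis=0), geom, v) for v in annual
    }

    # -- soil-moisture inversion per depth --------------------------------
    soil_props = ("BD", "P_cap", "P_non", "TN", "TP", "TK", "AK", "clay", "silt", "sand")
    spatializable = set(soil_props) | set(_PIPE_BANDS)
    train, valid = inversion.split_samples(samples, (4, 1), config.seed)
    idw_cache = {
        p: inversion.idw_surface(samples, p, geom) for p in soil_props
    }

    # Soil-property surfaces are characterized through the moisture-sensitive
    # radar band: each year's surface is the IDW base plus the property's
    # site-level regression slope on VH times that year's VH anomaly, so
    # predicted moisture varies interannually at every depth.
    vh_annual = annual["VH"].data
    vh_clim = nanmean_quiet(vh_annual, axis=0)
    site_rows = samples.drop_duplicates("site")
    vh_sites = site_rows["VH"].to_numpy(dtype=float)
    vh_var = vh_sites.var()
    prop_beta = {
        p: (float(np.cov(vh_sites, site_rows[p].to_numpy(dtype=float))[0, 1] / vh_var)
            if vh_var > 0 else 0.0)
        for p in soil_props
    }

    def predictor_grid(name, year_idx=None):
        if name in idw_cache:
            base = idw_cache[name].data
            if year_idx is not None:
                base = base + prop_beta[name] * (vh_annual[year_idx] - vh_clim)
            return RasterGrid(base, geom, name)
        stack = annual[name]
        data = stack.data.mean(axis=0) if year_idx is None else stack.data[year_idx]
        scale = 1e4 if name in _OPTICAL else 1.0  # samples carry optical DN
        return RasterGrid(data * scale, geom, name)

    sm_models, sm_reports, sm_annual = {}, {}, {}
    for depth in synthetic.DEPTH_LAYERS:
        screened = inversion.screen_predictors(samples, depth, config.alpha)
        retained = [p for p in screened.index[screened["retained"]] if p in spatializable]
        if len(retained) < 2:
            raise RuntimeError(f"stage 'invert' failed at depth {depth}: "
                               f"fewer than 2 spatializable screened predictors")
        tr = train[train["depth"] == depth]
        va = valid[valid["depth"] == depth]
        candidates = [
            inversion.fit_smlr(tr, retained, depth),
            inversion.fit_ridge(tr, retained, depth, seed=config.seed),
            inversion.fit_plsr(tr, retained, depth, seed=config.seed),
        ]
        reports = [inversion.evaluate(m, va, n_train=len(tr)) for m in candidates]
        best, flags = inversion.select_model(reports, config.gates)
        model = candidates[[r.method for r in reports].index(best.method)]
        sm_models[depth] = model
        sm_reports[depth] = {r.method: r for r in reports}
        if flags:
            log.warning("depth %s: %s", depth, flags[0])
        layers = []
        for yi in range(len(config.years)):
            grids = {p: predictor_grid(p, yi) for p in model.coefficients}
            layers.append(inversion.predict_raster(model, grids).data)
        sm_annual[depth] = ts.TimeSeriesStack.from_arrays(
            f"SM_{depth}", [(y, 1) for y in config.years], np.array(layers), geom
        )
        io.write_raster(
            RasterGrid(nanmean_quiet(sm_annual[depth].data, axis=0), geom, f"SM_{depth}"),
            out / f"sm_{depth}.tif",
        )

    # -- composite vegetation index ---------------------------------------
    inside = ~geom.nodata_mask
    index_means = {
        name: compute_index(name, mean_grid) for name in INDEX_BANDS
    }
    cand_vals = {n: g.data[inside] for n, g in index_means.items()}
    chosen, index_report = composite.select_best_index(
        cand_vals,
        mean_grid["NPP"].data[inside],
        mean_grid["LAI"].data[inside],
        r_gate=config.r_gate,
        kmo_gate=config.kmo_gate,
        alpha=config.alpha,
    )
    matrix = pd.DataFrame(
        {
            "NPP": mean_grid["NPP"].data[inside],
            "LAI": mean_grid["LAI"].data[inside],
            chosen: cand_vals[chosen],
        }
    ).dropna()
    pca_res = composite.pca(matrix)
    weights, weight_flags = composite.composite_weights(pca_res)
    index_report.to_csv(out / "index_screening.csv")
    weights.to_csv(out / "veg_weights.csv")

    veg_layers = []
    for yi in range(len(config.years)):
        grids = {
            "NPP": annual["NPP"].grid(yi),
            "LAI": annual["LAI"].grid(yi),
            chosen: compute_index(
                chosen,
                {b: annual[b].grid(yi) for b in ("B2", "B3", "B4", "B8")},
            ),
        }
        veg_layers.append(composite.veg_raster(weights, grids).data)
    veg_stack = ts.TimeSeriesStack.from_arrays(
        "VEG", [(y, 1) for y in config.years], np.array(veg_layers), geom
    )
    veg_mean = RasterGrid(nanmean_quiet(veg_stack.data, axis=0), geom, "VEG")
    io.write_raster(veg_mean, out / "veg.tif")

    # -- correlation, coupling, importance per depth ----------------------
    corr_props, class_props, importances = {}, {}, {}
    reports_by_depth = {}
    for depth in synthetic.DEPTH_LAYERS:
        maps = correlation.correlate_stacks(sm_annual[depth], veg_stack, config.alpha)
        corr_props[depth] = correlation.area_proportions(maps)
        io.write_raster(maps.rho, out / f"rho_{depth}.tif")

        sm_mean = RasterGrid(nanmean_quiet(sm_annual[depth].data, axis=0), geom, "SM")
        cpl = coupling.couple_grids(
            veg_mean, sm_mean, config.weight_alpha, config.weight_beta, config.ccd_form
        )
        class_props[depth] = cpl.proportions
        io.write_raster(cpl.d, out / f"d_{depth}.tif")

        table = importance.driver_table(
            drivers.drivers, cpl.d, config.rf_max_pixels, config.seed
        )
        rep = importance.fit_forest(
            table,
            list(synthetic.DRIVER_NAMES),
            n_trees=config.rf_trees,
            min_leaf=config.rf_min_leaf,
            seed=config.seed,
        )
        importances[depth] = rep.shares.to_dict()
        reports_by_depth[depth] = rep
    rank_taus = importance.rank_importance(reports_by_depth)

    pd.DataFrame(importances).to_csv(out / "importance.csv")
    summary = {
        "seed": config.seed,
        "geometry": {"shape": list(geom.shape), "valid_fraction": geom.n_valid / (geom.n_rows * geom.n_cols)},
        "selected_models": {
            d: {
                "method": m.method,
                "intercept": m.intercept,
                "coefficients": m.coefficients,
            }
            for d, m in sm_models.items()
        },
        "validation_metrics": {
            d: {
                meth: {"r2": r.r2, "rmse": r.rmse, "mae": r.mae, "mape": r.mape}
                for meth, r in reps.items()
            }
            for d, reps in sm_reports.items()
        },
        "chosen_index": chosen,
        "veg_weights": weights.to_dict(),
        "veg_weight_flags": weight_flags,
        "correlation_proportions": corr_props,
        "coupling_class_proportions": class_props,
        "driver_importance": importances,
        "importance_rank_tau_min": float(rank_taus.to_numpy().min()),
        "thresholds": {
            "alpha": config.alpha,
            **config.gates,
            "kmo_gate": config.kmo_gate,
            "r_gate": config.r_gate,
            "ccd_form": config.ccd_form,
        },
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary
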