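"""End-to-end runner: simulate -> clean -> bioclim -> fit -> evaluate ->
project -> risk-area report, deterministic under one master seed."""

from __future__ import annotations

import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import evaluation, io, maxent, preprocess, risk, synthetic
from .grid import GridSpec

#: fixed offsets deriving stage seeds from the master seed
SEED_OFFSETS = {
    "climate": 1,
    "elevation": 2,
    "occurrences": 3,
    "background": 4,
    "replicates": 5,
}


@dataclass
class RegionDef:
    """Axis-aligned sub-extent of the grid, rows/cols half-open."""

    row0: int
    row1: int
    col0: int
    col1: int

    def mask(self, grid: GridSpec) -> np.ndarray:
        m = np.zeros(grid.shape, dtype=bool)
        m[self.row0 : self.row1, self.col0 : self.col1] = True
        return m


@dataclass
class ScenarioDef:
    warming_offset_C: float
    precip_factor: float = 1.0


@dataclass
class PipelineConfig:
    n_rows: int = 60
    n_cols: int = 120
    cell_size_km: float = 10.0
    # training ("native") and projection regions: disjoint halves by default
    training_region: RegionDef | None = None
    projection_region: RegionDef | None = None
    scenarios: dict[str, ScenarioDef] = field(
        default_factory=lambda: {
            "rcp60": ScenarioDef(warming_offset_C=2.2),
            "rcp85": ScenarioDef(warming_offset_C=3.7, precip_factor=0.95),
        }
    )
    classes: str = "LQ"
    rm: float = 1.0
    tune: bool = False
    n_replicates: int = 15
    test_fraction: float = 0.25
    elev_tolerance_m: float = 100.0
    cell_area_km2: float = risk.DEFAULT_CELL_AREA_KM2
    master_seed: int = 0
    n_occurrences: int = 500
    error_rates: dict[str, float] = field(
        default_factory=lambda: {"offgrid": 0.02, "elev_mismatch": 0.03, "duplicate": 0.05}
    )
    species: str = "synthetic_sp"
    truth_intercept: float = -1.0
    truth_linear: dict[str, float] = field(default_factory=lambda: {"gdd": 3.0})
    truth_quadratic: dict[str, float] = field(default_factory=dict)
    max_background: int = 10_000

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")
        if self.training_region is None:
            self.training_region = RegionDef(0, self.n_rows, 0, self.n_cols // 2)
        if self.projection_region is None:
            self.projection_region = RegionDef(0, self.n_rows, self.n_cols // 2, self.n_cols)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        for key in ("training_region", "projection_region"):
            if d.get(key) is not None and not isinstance(d[key], RegionDef):
                d[key] = RegionDef(**d[key])
        if "scenarios" in d:
            d["scenarios"] = {
                k: v if isinstance(v, ScenarioDef) else ScenarioDef(**v)
                for k, v in d["scenarios"].items()
            }
        return cls(**d)

    def to_dict(self) -> dict:
        return asdict(self)


def _region_bioclim(bioclim: preprocess.BioclimLayers, region: np.ndarray) -> preprocess.BioclimLayers:
    """Bioclim stack restricted to a region: same geometry, cells outside
    the region marked nodata."""
    g = bioclim.grid
    sub = GridSpec(
        n_rows=g.n_rows,
        n_cols=g.n_cols,
        cell_size_km=g.cell_size_km,
        origin_x=g.origin_x,
        origin_y=g.origin_y,
        nodata_mask=g.nodata_mask | ~region,
    )
    return preprocess.BioclimLayers(gdd=bioclim.gdd, tmin_abs=bioclim.tmin_abs,
                                    wbal=bioclim.wbal, grid=sub)


def average_logistic_map(
    models: list[maxent.MaxentModel], bioclim: preprocess.BioclimLayers, tau: float = 0.5
) -> np.ndarray:
    """Cellwise mean logistic prediction of several fitted models over the
    valid cells of a bioclim stack; NaN elsewhere."""
    X, flat = bioclim.values_valid()
    acc = np.zeros(X.shape[0])
    for model in models:
        acc += maxent.predict_logistic(model, X, tau=tau)
    out = np.full(bioclim.grid.shape, np.nan)
    out.ravel()[flat] = acc / len(models)
    return out


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run every stage; writes artifacts under ``outdir`` and returns the
    run manifest (config snapshot, stage timings, counts, file digests)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = config.master_seed
    manifest: dict = {"config": config.to_dict(), "stages": {}, "outputs": {}, "seeds": {}}
    timings: dict[str, float] = {}

    def stage(name):
        timings[name] = time.perf_counter()

    def done(name, **info):
        timings[name] = time.perf_counter() - timings[name]
        manifest["stages"][name] = {"seconds": timings[name], **info}

    grid = GridSpec(config.n_rows, config.n_cols, config.cell_size_km)
    train_mask = config.training_region.mask(grid)
    proj_mask = config.projection_region.mask(grid)
    manifest["seeds"] = {k: seed + v for k, v in SEED_OFFSETS.items()}

    # --- simulate ---------------------------------------------------------
    stage("simulate")
    climate = synthetic.generate_climate(grid, seed + SEED_OFFSETS["climate"])
    elevation = synthetic.generate_elevation(grid, seed + SEED_OFFSETS["elevation"])
    bioclim = preprocess.derive_bioclim(climate)
    truth_params = synthetic.TruthParams(
        intercept=config.truth_intercept,
        linear=config.truth_linear,
        quadratic=config.truth_quadratic,
        seed=seed,
    )
    truth = synthetic.true_suitability(bioclim, truth_params)
    truth_train = np.where(train_mask, np.nan_to_num(truth, nan=0.0), 0.0)
    records = synthetic.sample_occurrences(
        truth_train, grid, elevation, config.n_occurrences,
        seed + SEED_OFFSETS["occurrences"], config.error_rates, species=config.species,
    )
    io.write_occurrences(outdir / "occurrences.csv", records)
    io.write_raster(outdir / "elevation.asc", elevation, grid)
    io.write_raster(outdir / "truth.asc", np.nan_to_num(truth, nan=np.nan), grid)
    done("simulate", n_records=len(records))

    # --- clean ------------------------------------------------------------
    stage("clean")
    clean, report = preprocess.clean_records(records, grid, elevation, config.elev_tolerance_m)
    io.write_json(outdir / "cleaning_report.json", report.to_dict())
    done("clean", **report.to_dict())

    # --- bioclim ----------------------------------------------------------
    stage("bioclim")
    for name, layer in bioclim.layers().items():
        io.write_raster(outdir / f"{name}.asc", layer, grid)
    done("bioclim")

    # --- fit --------------------------------------------------------------
    stage("fit")
    rows = np.array([grid.cell_of(r.x, r.y)[0] for r in clean])
    cols = np.array([grid.cell_of(r.x, r.y)[1] for r in clean])
    X_pres = bioclim.values_at_cells(rows, cols)
    train_bioclim = _region_bioclim(bioclim, train_mask)
    settings = maxent.ModelSettings(classes=config.classes, rm=config.rm)
    if config.tune:
        X_bg, _ = maxent.select_background(
            train_bioclim, config.max_background, seed=[seed, SEED_OFFSETS["background"]]
        )
        tuning = maxent.tune_settings(X_pres, X_bg)
        settings = maxent.ModelSettings(
            classes=tuning.selected["classes"], rm=tuning.selected["rm"]
        )
        io.write_json(outdir / "tuning.json",
                      {"candidates": tuning.candidates,
                       "selected": {k: v for k, v in tuning.selected.items() if k != "model"}})
    suit_map, aucs, models = maxent.replicate_fit(
        X_pres, train_bioclim, settings,
        n_replicates=config.n_replicates, test_fraction=config.test_fraction,
        master_seed=seed + SEED_OFFSETS["replicates"], max_background=config.max_background,
    )
    io.write_raster(outdir / "suitability_training.asc", suit_map.values, grid)
    io.write_json(outdir / "model.json", models[0].to_dict())
    (outdir / "model.lambdas.txt").write_text(models[0].lambdas_text())
    done("fit", settings={"classes": settings.classes, "rm": settings.rm},
         n_presence=X_pres.shape[0])

    # --- evaluate ---------------------------------------------------------
    stage("evaluate")
    X_bg, _ = maxent.select_background(
        train_bioclim, config.max_background, seed=[seed, SEED_OFFSETS["background"]]
    )
    jack = evaluation.jackknife_importance(
        X_pres, X_bg, preprocess.PREDICTOR_NAMES, settings
    )
    proj_bioclim = _region_bioclim(bioclim, proj_mask)
    X_proj, _ = proj_bioclim.values_valid()
    reference = {n: X_bg[:, i] for i, n in enumerate(preprocess.PREDICTOR_NAMES)}
    query = {n: X_proj[:, i] for i, n in enumerate(preprocess.PREDICTOR_NAMES)}
    mess_res = evaluation.mess(reference, query)
    eval_report = evaluation.EvaluationReport(
        auc_per_replicate=aucs,
        jackknife_importance=jack["importance"],
        fraction_nonneg_mess=mess_res.fraction_nonneg,
        extras={"jackknife_gains": {"only": jack["gain_only"],
                                    "without": jack["gain_without"],
                                    "with_all": jack["gain_with_all"]}},
    )
    io.write_json(outdir / "evaluation.json", eval_report.to_dict())
    with open(outdir / "auc_replicates.csv", "w") as fh:
        fh.write("replicate,auc\n")
        for i, a in enumerate(aucs):
            fh.write(f"{i},{a}\n")
    done("evaluate", auc_median=eval_report.auc_median,
         auc_class=eval_report.auc_class,
         fraction_nonneg_mess=mess_res.fraction_nonneg)

    # --- project ----------------------------------------------------------
    stage("project")
    current_proj_map = average_logistic_map(models, proj_bioclim)
    io.write_raster(outdir / "suitability_projection_current.asc", current_proj_map, grid)
    scenario_maps: dict[str, np.ndarray] = {}
    for label, sc in config.scenarios.items():
        climate_f = synthetic.generate_climate(
            grid, seed + SEED_OFFSETS["climate"],
            warming_offset_C=sc.warming_offset_C, precip_factor=sc.precip_factor,
        )
        bioclim_f = _region_bioclim(preprocess.derive_bioclim(climate_f), proj_mask)
        scenario_maps[label] = average_logistic_map(models, bioclim_f)
        io.write_raster(outdir / f"suitability_projection_{label}.asc",
                        scenario_maps[label], grid)
    done("project", scenarios=list(config.scenarios))

    # --- har --------------------------------------------------------------
    stage("har")
    har = risk.har_report(
        current_proj_map, scenario_maps, grid,
        region_mask=proj_mask, cell_area=config.cell_area_km2,
    )
    io.write_json(outdir / "har_report.json", har.to_dict())
    with open(outdir / "har_table.csv", "w") as fh:
        fh.write("scenario,area_km2,delta_km2,percent_increase,percent_of_current\n")
        for row in har.to_table():
            fh.write(
                f"{row['scenario']},{row['area_km2']},{row.get('delta_km2', '')},"
                f"{row.get('percent_increase', '')},{row.get('percent_of_current', '')}\n"
            )
    for label, bm in har.binary_maps.items():
        io.write_raster(outdir / f"har_{label}.asc", bm, grid)
    done("har", threshold=har.threshold, areas=har.areas_km2)

    for f in sorted(outdir.iterdir()):
        if f.is_file() and f.name != "manifest.json":
            manifest["outputs"][f.name] = io.file_digest(f)
    io.write_json(outdir / "manifest.json", manifest)
    return manifest
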