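"""End-to-end orchestration: simulate -> derive -> fit -> project -> report.

Each stage persists its artifacts under the run's output directory in plain
formats (ESRI ASCII rasters, CSV tables, JSON metadata; fitted models as a
pickle with a JSON sidecar) and a run manifest records the configuration, the
per-stage seeds expanded from the single run seed, artifact paths and metric
summaries. Any stage can rerun from the persisted artifacts of its upstream
stages; missing upstream artifacts raise :class:`DependencyError` naming the
absent file.
"""

from __future__ import annotations

import hashlib
import json
import pickle
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import synthetic
from .climate import ClimateGrid, GcmScenario, compute_bioclim, BioclimGrid
from .config import RunConfig, TrueResponseParams, spawn_seed
from .ensemble import (CascadeModels, EnsembleSummary, HabitatProjection,
                       ensemble_median, project_scenario)
from .geometry import GridGeometry, read_ascii_grid, write_ascii_grid
from .habitat import TerritoryObservations, fit_habitat_model, iov_akaike
from .metrics import spearman_rho
from .terrain import TerrainGrid, derive_terrain
from .vegmodels import (fit_fraction_models, fit_zone_model,
                        fraction_training_table, increased_mse_importance,
                        make_zone_labels, predict_zone_probability,
                        zone_training_table)

__all__ = ["DependencyError", "Pipeline", "run_pipeline", "STAGES"]

STAGES = ("simulate", "derive", "fit", "project", "report")


class DependencyError(RuntimeError):
    """An upstream artifact required by the requested stage is missing."""


def _hash_config(config: RunConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


class Pipeline:
    """Stateful runner holding in-memory artifacts between stages."""

    def __init__(self, config: RunConfig, output_dir: str | Path | None = None):
        self.config = config
        self.out = Path(output_dir if output_dir is not None else config.output_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        base = config.seed
        self.seeds = {
            "dem": config.landscape.seed,
            "climate": config.landscape.seed,
            "scenarios": spawn_seed(base, 1),
            "vegetation": spawn_seed(base, 2),
            "territories": spawn_seed(base, 3),
            "surveys": spawn_seed(base, 4),
            "forest": spawn_seed(base, 5),
            "bootstrap": spawn_seed(base, 6),
            "importance": spawn_seed(base, 7),
            "daily": config.daily.seed,
        }
        self.manifest: dict = {"config": config.to_dict(),
                               "config_hash": _hash_config(config),
                               "seeds": self.seeds, "stages": [],
                               "artifacts": {}, "metrics": {}}
        # in-memory state
        self.dem = None
        self.terrain: TerrainGrid | None = None
        self.climate: ClimateGrid | None = None
        self.bioclim: BioclimGrid | None = None
        self.scenarios: list[GcmScenario] | None = None
        self.vegetation = None
        self.territories: TerritoryObservations | None = None
        self.models: CascadeModels | None = None
        self.zone_fine = None
        self.projections: list[HabitatProjection] | None = None
        self.current_projection: HabitatProjection | None = None
        self.summary: EnsembleSummary | None = None

    # -- helpers ---------------------------------------------------------

    def _path(self, name: str) -> Path:
        return self.out / name

    def _require(self, name: str) -> Path:
        p = self._path(name)
        if not p.exists():
            raise DependencyError(f"missing upstream artifact: {p}")
        return p

    def _record(self, stage: str, paths: dict[str, str]) -> None:
        self.manifest["stages"].append(stage)
        self.manifest["artifacts"].update(
            {k: str(self._path(v)) for k, v in paths.items()})

    # -- stages ----------------------------------------------------------

    def simulate(self) -> None:
        """Generate all synthetic inputs: DEM, climatology, scenarios,
        vegetation and territory observations (with their ground truth)."""
        cfg = self.config
        lc = cfg.landscape
        self.dem, fine_geom = synthetic.generate_dem(lc)
        self.climate = synthetic.generate_climatology(self.dem, lc)
        self.scenarios = synthetic.generate_gcm_anomalies(
            cfg.n_scenarios, cfg.warming_range_c, cfg.precip_ratio_range,
            cfg.scenario_lattice, lc.domain_width_m, lc.domain_height_m,
            seed=self.seeds["scenarios"])
        # the generator's own cascade: terrain + bioclim feed the truth models
        terrain = derive_terrain(self.dem, fine_geom, cfg.ridge_threshold_quantile)
        bioclim = compute_bioclim(self.climate, cfg.snow, cfg.daily)
        self.vegetation = synthetic.generate_vegetation(
            bioclim, terrain, cfg.truth, seed=self.seeds["vegetation"])
        territory_geom = fine_geom.coarsen(
            int(round(lc.territory_resolution_m / lc.terrain_resolution_m)))
        surveys = synthetic.draw_survey_counts(territory_geom,
                                               seed=self.seeds["surveys"])
        self.territories = synthetic.generate_territories(
            self.vegetation, terrain, cfg.truth, surveys,
            lc.territory_resolution_m, seed=self.seeds["territories"])
        self.terrain = terrain
        self.bioclim = bioclim
        # persist
        write_ascii_grid(self._path("dem.asc"), self.dem, fine_geom)
        self._write_climate()
        with open(self._path("scenarios.json"), "w") as fh:
            json.dump([s.to_dict() for s in self.scenarios], fh)
        for name, arr in self.vegetation.as_dict().items():
            write_ascii_grid(self._path(f"veg_{name}.asc"), arr, fine_geom)
        self.territories.to_csv(self._path("territories.csv"))
        with open(self._path("truth.json"), "w") as fh:
            json.dump(cfg.truth.to_dict(), fh, indent=1)
        self._record("simulate", {
            "dem": "dem.asc", "climate": "climate.csv",
            "scenarios": "scenarios.json", "territories": "territories.csv",
            "truth": "truth.json",
            **{f"veg_{n}": f"veg_{n}.asc" for n in ("pp", "sg", "ff")}})

    def _write_climate(self) -> None:
        cg = self.climate
        frames = []
        for m in range(12):
            df = pd.DataFrame({
                "month": m + 1,
                "row": np.repeat(np.arange(cg.geom.nrows), cg.geom.ncols),
                "col": np.tile(np.arange(cg.geom.ncols), cg.geom.nrows),
                "tmean": cg.monthly_mean_temp[m].ravel(),
                "tmin": cg.monthly_min_temp[m].ravel(),
                "precip": cg.monthly_precip[m].ravel(),
            })
            frames.append(df)
        pd.concat(frames).to_csv(self._path("climate.csv"), index=False)
        meta = {"nrows": cg.geom.nrows, "ncols": cg.geom.ncols,
                "cell_size_m": cg.geom.cell_size_m, "x0": cg.geom.x0,
                "y0": cg.geom.y0}
        with open(self._path("climate_geom.json"), "w") as fh:
            json.dump(meta, fh)

    def _load_climate(self) -> ClimateGrid:
        self._require("climate.csv")
        self._require("climate_geom.json")
        with open(self._path("climate_geom.json")) as fh:
            geom = GridGeometry(**json.load(fh))
        df = pd.read_csv(self._path("climate.csv"))
        shape = (12, geom.nrows, geom.ncols)
        arrays = {}
        df = df.sort_values(["month", "row", "col"])
        for key in ("tmean", "tmin", "precip"):
            arrays[key] = df[key].to_numpy().reshape(shape)
        return ClimateGrid(arrays["tmean"], arrays["tmin"], arrays["precip"], geom)

    def derive(self) -> None:
        """Topographic predictors from the DEM; bioclim from the climatology."""
        if self.dem is None:
            self.dem, fine_geom = read_ascii_grid(self._require("dem.asc"))
        else:
            fine_geom = GridGeometry(*self.dem.shape,
                                     self.config.landscape.terrain_resolution_m)
        if self.climate is None:
            self.climate = self._load_climate()
        self.terrain = derive_terrain(self.dem, fine_geom,
                                      self.config.ridge_threshold_quantile)
        self.bioclim = compute_bioclim(self.climate, self.config.snow,
                                       self.config.daily)
        t = self.terrain
        for name, arr in (("slope", t.slope), ("aspect", t.aspect),
                          ("curvature", t.curvature), ("twi", t.twi),
                          ("ridge_distance", t.ridge_distance),
                          ("ridge_mask", t.ridge_mask.astype(float))):
            write_ascii_grid(self._path(f"terrain_{name}.asc"), arr, fine_geom)
        for name, arr in zip(("wi", "tmc", "prs", "msw"),
                             self.bioclim.stack()):
            write_ascii_grid(self._path(f"bioclim_{name}.asc"), arr,
                             self.bioclim.geom)
        self._record("derive", {f"terrain_{n}": f"terrain_{n}.asc" for n in
                                ("slope", "aspect", "curvature", "twi",
                                 "ridge_distance", "ridge_mask")})

    def _ensure_derived(self) -> None:
        if self.terrain is None or self.bioclim is None:
            for f in ("dem.asc", "terrain_slope.asc"):
                self._require(f)
            self.derive()

    def _ensure_simulated(self) -> None:
        if self.vegetation is None:
            fine_geom = None
            grids = {}
            for n in ("pp", "sg", "ff"):
                arr, fine_geom = read_ascii_grid(self._require(f"veg_{n}.asc"))
                grids[n] = np.nan_to_num(arr)
            self.vegetation = synthetic.VegetationMap(pp=grids["pp"],
                                                      sg=grids["sg"],
                                                      ff=grids["ff"],
                                                      geom=fine_geom)
        if self.territories is None:
            lc = self.config.landscape
            factor = int(round(lc.territory_resolution_m / lc.terrain_resolution_m))
            geom = self.vegetation.geom.coarsen(factor)
            self.territories = TerritoryObservations.from_csv(
                self._require("territories.csv"), geom)
        if self.scenarios is None:
            with open(self._require("scenarios.json")) as fh:
                self.scenarios = [GcmScenario.from_dict(d) for d in json.load(fh)]

    def fit(self) -> None:
        """Fit the zone, fraction and habitat models on current-climate data."""
        self._ensure_derived()
        self._ensure_simulated()
        cfg = self.config
        labels = make_zone_labels(self.vegetation, self.bioclim.geom,
                                  cfg.zone_cover_threshold)
        ztab = zone_training_table(self.bioclim, labels)
        zone = fit_zone_model(ztab, cfg.sensitivity_cutoff, cfg.n_bootstrap,
                              seed=self.seeds["bootstrap"])
        _, zone_fine = predict_zone_probability(zone, self.bioclim,
                                                fine_geom=self.terrain.geom)
        self.zone_fine = zone_fine
        Xtab, valid = fraction_training_table(self.terrain, zone_fine)
        responses = {n: self.vegetation.as_dict()[n].ravel()[valid]
                     for n in ("pp", "sg", "ff")}
        fractions = fit_fraction_models(Xtab, responses, n_trees=cfg.n_trees,
                                        seed=self.seeds["forest"])
        importance = {}
        spearman = {}
        for name, rf in fractions.forests.items():
            imp = increased_mse_importance(rf, Xtab, responses[name],
                                           n_permutations=3,
                                           seed=self.seeds["importance"])
            fractions.importance[name] = imp
            importance[name] = imp.to_dict()
            rho, p = spearman_rho(rf.predict(Xtab.to_numpy()), responses[name])
            spearman[name] = {"rho": rho, "p": p}
        habitat = fit_habitat_model(self.territories, cfg.sensitivity_cutoff,
                                    cfg.n_bootstrap, seed=self.seeds["bootstrap"])
        iov_table = iov_akaike(self.territories)
        self.models = CascadeModels(zone=zone, fractions=fractions,
                                    habitat=habitat)
        with open(self._path("models.pkl"), "wb") as fh:
            pickle.dump(self.models, fh)
        sidecar = {
            "zone": {**zone.report.to_dict(), "terms": zone.model.term_labels,
                     "threshold": zone.threshold, **zone.model.summary()},
            "habitat": {**habitat.report.to_dict(),
                        "terms": habitat.model.term_labels,
                        "threshold": habitat.threshold,
                        **habitat.model.summary()},
            "fractions": {"oob_r2": fractions.oob_score,
                          "importance_increased_mse": importance,
                          "spearman": spearman,
                          "n_trees": cfg.n_trees},
            "iov": iov_table.attrs["iov"],
        }
        with open(self._path("models.json"), "w") as fh:
            json.dump(sidecar, fh, indent=1)
        iov_table.to_csv(self._path("model_selection.csv"), index=False)
        pd.DataFrame({k: fractions.importance[k] for k in fractions.importance}
                     ).to_csv(self._path("importance.csv"))
        self.manifest["metrics"].update(sidecar)
        self._record("fit", {"models": "models.pkl", "models_meta": "models.json",
                             "model_selection": "model_selection.csv",
                             "importance": "importance.csv"})

    def _ensure_models(self) -> None:
        if self.models is None:
            with open(self._require("models.pkl"), "rb") as fh:
                self.models = pickle.load(fh)

    def project(self) -> None:
        """Run the cascade for the current climate and every scenario."""
        self._ensure_derived()
        self._ensure_simulated()
        self._ensure_models()
        if self.climate is None:
            self.climate = self._load_climate()
        cfg = self.config
        args = (self.climate, self.terrain, self.models, cfg.snow, cfg.daily,
                cfg.landscape.territory_resolution_m)
        self.current_projection = project_scenario(None, *args)
        self.projections = [project_scenario(s, *args) for s in self.scenarios]
        self.summary = ensemble_median(self.projections, self.current_projection,
                                       threshold=self.models.habitat.threshold)
        tg = self.current_projection.territory_geom
        write_ascii_grid(self._path("habitat_current.asc"),
                         self.current_projection.habitat_probability, tg)
        write_ascii_grid(self._path("habitat_future_median.asc"),
                         self.summary.median_probability, tg)
        write_ascii_grid(self._path("habitat_agreement.asc"),
                         self.summary.agreement_count.astype(float), tg)
        self.summary.area_table.to_csv(self._path("areas.csv"), index=False)
        self._record("project", {"habitat_current": "habitat_current.asc",
                                 "habitat_future_median": "habitat_future_median.asc",
                                 "habitat_agreement": "habitat_agreement.asc",
                                 "areas": "areas.csv"})

    def report(self) -> dict:
        """Write the run-level summary JSON and return it."""
        if self.summary is None:
            raise DependencyError("missing upstream artifact: projections "
                                  "(run the project stage first)")
        cur = self.current_projection
        summary = {
            "current_habitat_cells": cur.habitat_cells,
            "current_habitat_km2": cur.habitat_km2,
            "current_zone_km2": cur.zone_km2,
            "future_median_habitat_cells": self.summary.median_habitat_cells,
            "future_median_habitat_km2": self.summary.median_habitat_km2,
            "future_pct_of_current": float(
                self.summary.area_table.iloc[-1]["pct_of_current"]),
            "n_scenarios": self.summary.n_scenarios,
            "max_agreement_count": int(self.summary.agreement_count.max()),
        }
        self.manifest["metrics"]["ensemble"] = summary
        with open(self._path("summary.json"), "w") as fh:
            json.dump(summary, fh, indent=1)
        self._record("report", {"summary": "summary.json"})
        return summary

    # -- entry point -----------------------------------------------------

    def run(self, stages: tuple[str, ...] = STAGES) -> dict:
        unknown = set(stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        for stage in STAGES:
            if stage in stages:
                getattr(self, stage)()
        self.manifest["timestamp"] = time.strftime("%Y-%m-%dT%H:%M:%S")
        with open(self._path("run_manifest.json"), "w") as fh:
            json.dump(self.manifest, fh, indent=1, default=str)
        return self.manifest


def run_pipeline(config: RunConfig, stages: tuple[str, ...] = STAGES,
                 output_dir: str | Path | None = None) -> dict:
    """Run the requested stages and return the run manifest."""
    return Pipeline(config, output_dir).run(stages)
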