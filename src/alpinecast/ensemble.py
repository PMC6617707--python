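"""Multi-scenario projection of the full cascade and ensemble summaries.

For each climate scenario the whole chain runs: delta-downscaled climatology
-> bioclimatic variables -> zone occurrence probability -> community area
fractions -> territory occurrence probability -> binary habitat at the
training threshold. Topography is held constant across scenarios and all
thresholds are frozen at their current-climate training values.

The ensemble is summarized by the cellwise median probability map (even
scenario counts average the two central order statistics), the binary habitat
of that median, and a scenario-agreement map counting in how many scenarios a
currently suitable cell remains ("is sustained as") habitat.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .climate import (ClimateGrid, GcmScenario, apply_gcm_delta,
                      compute_bioclim)
from .config import DailySynthesisConfig, SnowModelParams
from .geometry import GridGeometry, cell_area_km2
from .habitat import FittedHabitatModel, aggregate_predictors, predict_habitat_probability
from .terrain import TerrainGrid
from .vegmodels import FittedFractionModel, FittedZoneModel, predict_fractions, \
    predict_zone_probability

__all__ = [
    "CascadeModels",
    "HabitatProjection",
    "EnsembleSummary",
    "project_scenario",
    "ensemble_median",
    "habitat_area_summary",
]


class PipelineIncompleteError(RuntimeError):
    """A required fitted model is missing from the cascade."""


@dataclass
class CascadeModels:
    """The three fitted models of the cascade."""

    zone: FittedZoneModel
    fractions: FittedFractionModel
    habitat: FittedHabitatModel

    def validate(self) -> None:
        for name in ("zone", "fractions", "habitat"):
            if getattr(self, name) is None:
                raise PipelineIncompleteError(f"missing fitted model: {name}")


@dataclass
class HabitatProjection:
    """One scenario's grids and area accounting."""

    scenario: str
    zone_probability: np.ndarray          # climate lattice
    zone_binary: np.ndarray
    fractions: "object"                   # VegetationMap, fine lattice
    habitat_probability: np.ndarray       # territory lattice
    habitat_binary: np.ndarray
    territory_geom: GridGeometry
    climate_geom: GridGeometry

    @property
    def habitat_cells(self) -> int:
        return int(self.habitat_binary.sum())

    @property
    def habitat_km2(self) -> float:
        return self.habitat_cells * cell_area_km2(self.territory_geom.cell_size_m)

    @property
    def zone_km2(self) -> float:
        return int(self.zone_binary.sum()) * cell_area_km2(self.climate_geom.cell_size_m)


def project_scenario(scenario: GcmScenario | None, baseline: ClimateGrid,
                     terrain: TerrainGrid, models: CascadeModels,
                     snow_params: SnowModelParams,
                     daily_cfg: DailySynthesisConfig,
                     territory_resolution_m: float = 300.0) -> HabitatProjection:
    """Run the full cascade for one scenario (``None`` = current climate).

    Deterministic given inputs: the daily-weather seed is shared across
    scenarios, so an identity scenario reproduces the current-climate
    projection exactly.
    """
    models.validate()
    climate = baseline if scenario is None else apply_gcm_delta(baseline, scenario)
    bioclim = compute_bioclim(climate, snow_params, daily_cfg)
    zone_coarse, zone_fine = predict_zone_probability(models.zone, bioclim,
                                                      fine_geom=terrain.geom)
    veg = predict_fractions(models.fractions, terrain, zone_fine)
    factor = int(round(territory_resolution_m / terrain.geom.cell_size_m))
    territory_geom = terrain.geom.coarsen(factor)
    predictors = aggregate_predictors(veg.as_dict(), terrain.ridge_distance,
                                      terrain.geom, territory_geom)
    prob = predict_habitat_probability(models.habitat, predictors, effort=1.0)
    prob = prob.reshape(territory_geom.shape)
    return HabitatProjection(
        scenario=scenario.name if scenario is not None else "current",
        zone_probability=zone_coarse,
        zone_binary=zone_coarse >= models.zone.threshold,
        fractions=veg,
        habitat_probability=prob,
        habitat_binary=prob >= models.habitat.threshold,
        territory_geom=territory_geom,
        climate_geom=baseline.geom,
    )


@dataclass
class EnsembleSummary:
    """Median map, agreement counts and area tables over a scenario ensemble."""

    median_probability: np.ndarray
    median_binary: np.ndarray
    agreement_count: np.ndarray
    n_scenarios: int
    median_habitat_cells: int
    median_habitat_km2: float
    area_table: pd.DataFrame


def ensemble_median(projections: list[HabitatProjection],
                    current: HabitatProjection,
                    threshold: float | None = None) -> EnsembleSummary:
    """Summarize a scenario ensemble against the current-climate projection.

    The median probability grid is the cellwise median over scenarios (mean of
    the two central values for even counts); binary habitat applies the frozen
    training threshold to that median. The agreement count per cell is the
    number of scenarios under which a currently suitable cell is sustained
    (habitat both now and under the scenario). Results are invariant to the
    order of the scenario list.
    """
    if not projections:
        raise ValueError("empty ensemble")
    stack = np.stack([p.habitat_probability for p in projections])
    med = np.median(stack, axis=0)
    binaries = np.stack([p.habitat_binary for p in projections])
    if threshold is None:  # frozen training threshold, same model everywhere
        threshold = _infer_threshold(current)
    med_binary = med >= threshold
    sustained = binaries & current.habitat_binary[None]
    agreement = sustained.sum(axis=0)
    cell_km2 = cell_area_km2(current.territory_geom.cell_size_m)
    rows = [{"scenario": "current", "habitat_cells": current.habitat_cells,
             "habitat_km2": current.habitat_km2,
             "pct_of_current": 100.0}]
    for p in projections:
        rows.append({"scenario": p.scenario, "habitat_cells": p.habitat_cells,
                     "habitat_km2": p.habitat_km2,
                     "pct_of_current": _pct(p.habitat_km2, current.habitat_km2)})
    med_cells = int(med_binary.sum())
    rows.append({"scenario": "ensemble_median", "habitat_cells": med_cells,
                 "habitat_km2": med_cells * cell_km2,
                 "pct_of_current": _pct(med_cells * cell_km2, current.habitat_km2)})
    return EnsembleSummary(median_probability=med, median_binary=med_binary,
                           agreement_count=agreement,
                           n_scenarios=len(projections),
                           median_habitat_cells=med_cells,
                           median_habitat_km2=med_cells * cell_km2,
                           area_table=pd.DataFrame(rows))


def _infer_threshold(projection: HabitatProjection) -> float:
    """Training threshold implied by a projection's probability/binary pair."""
    probs = projection.habitat_probability
    inside = probs[projection.habitat_binary]
    if inside.size:
        return float(inside.min())
    # empty habitat: any threshold above the maximum probability reproduces it
    return float(np.nextafter(probs.max(), np.inf))


def _pct(value_km2: float, reference_km2: float) -> float:
    if reference_km2 <= 0:
        return float("nan")
    return round(100.0 * value_km2 / reference_km2, 1)


def habitat_area_summary(cells: int, cell_size_m: float,
                         current_reference_km2: float | None = None) -> dict:
    """Cell count, km^2 and (optionally) percent of a current reference.

    Percentages are rounded to one decimal: e.g. 18 km^2 of a 2464 km^2
    reference reports 0.7%.
    """
    km2 = cells * cell_area_km2(cell_size_m)
    out = {"habitat_cells": int(cells), "habitat_km2": km2}
    if current_reference_km2 is not None:
        out["pct_of_current"] = _pct(km2, current_reference_km2)
    return out
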