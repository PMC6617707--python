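"""Climate-zone and community-fraction models (sub-models B1 and B2 analogues).

Two scales, two models. At the coarse climate scale, an additive logistic
model predicts occurrence of the alpine vegetation zone from the four
bioclimatic variables, with the warmth index and coldest-month minimum
entering jointly as a bivariate combination smooth. At the fine terrain scale,
one random-forest regressor per community predicts its area fraction from the
five topographic variables plus the zone occurrence probability (resampled
nearest-neighbor from the climate lattice, so the coarse model's values are
preserved exactly). Forest variable importance is increased MSE: the mean rise
in mean-squared error when one predictor's column is randomly permuted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from sklearn.ensemble import RandomForestRegressor

from .climate import BioclimGrid
from .gam import AdditiveLogisticModel, DegenerateDataError, Smooth1D, Smooth2D
from .geometry import GridGeometry, block_mean, upsample_nearest
from .metrics import (ValidationReport, bootstrap_auc, sensitivity_specificity,
                      threshold_at_sensitivity)
from .terrain import TerrainGrid

logger = logging.getLogger(__name__)

__all__ = [
    "make_zone_labels",
    "zone_training_table",
    "FittedZoneModel",
    "fit_zone_model",
    "predict_zone_probability",
    "FittedFractionModel",
    "fraction_training_table",
    "fit_fraction_models",
    "increased_mse_importance",
    "predict_fractions",
]

ZONE_PREDICTORS = ["wi", "tmc", "prs", "msw"]
COMMUNITIES = ("pp", "sg", "ff")

ZONE_TERMS = (
    Smooth2D("wi", "tmc", df=(5, 5)),
    Smooth1D("prs", df=10),
    Smooth1D("msw", df=10),
)


def make_zone_labels(vegetation, climate_geom: GridGeometry,
                     cover_threshold: float = 0.0) -> np.ndarray:
    """Zone presence per climate cell from aggregated community cover.

    A climate cell is present when the mean total alpine-community fraction of
    its constituent fine cells exceeds ``cover_threshold`` (default: any
    cover).
    """
    factor = vegetation.geom.factor_to(climate_geom)
    mean_cover = block_mean(vegetation.total(), factor)
    return (mean_cover > cover_threshold).astype(int)


def zone_training_table(bioclim: BioclimGrid, labels: np.ndarray) -> pd.DataFrame:
    """Assemble the coarse-cell training table (WI, TMC, PRS, MSW, presence)."""
    if np.asarray(labels).shape != bioclim.geom.shape:
        raise ValueError("labels shape does not match the climate lattice")
    tab = pd.DataFrame(bioclim.table(), columns=ZONE_PREDICTORS)
    tab["zone_presence"] = np.asarray(labels).ravel().astype(int)
    return tab


@dataclass
class FittedZoneModel:
    """Fitted zone occurrence model plus its training threshold and metrics."""

    model: AdditiveLogisticModel
    threshold: float
    report: ValidationReport
    sensitivity_cutoff: float = 0.95


def fit_zone_model(table: pd.DataFrame, sensitivity_cutoff: float = 0.95,
                   n_bootstrap: int = 100, seed: int = 0) -> FittedZoneModel:
    """Fit the additive logistic zone model on the coarse training table."""
    if len(table) < 50:
        raise DegenerateDataError("zone model needs at least 50 training cells")
    y = table["zone_presence"].to_numpy(dtype=float)
    if y.min() == y.max():
        raise DegenerateDataError("zone labels contain a single class")
    model = AdditiveLogisticModel(list(ZONE_TERMS)).fit(table, y)
    scores = model.predict(table)
    threshold = threshold_at_sensitivity(scores, y, sensitivity_cutoff)
    sens, spec = sensitivity_specificity(scores, y, threshold)
    auc_mean, auc_sd = bootstrap_auc(model.predict, table, y.astype(int),
                                     n_reps=n_bootstrap, seed=seed)
    report = ValidationReport(auc=auc_mean, auc_sd=auc_sd, sensitivity=sens,
                              specificity=spec, threshold=threshold,
                              n_bootstrap=n_bootstrap)
    return FittedZoneModel(model=model, threshold=threshold, report=report,
                           sensitivity_cutoff=sensitivity_cutoff)


def predict_zone_probability(fitted: FittedZoneModel, bioclim: BioclimGrid,
                             fine_geom: GridGeometry | None = None
                             ) -> tuple[np.ndarray, np.ndarray | None]:
    """Zone occurrence probability on the climate lattice (and, optionally, fine).

    Fine-lattice values are nearest-neighbor replicates of the coarse cell
    values, preserving the coarse model's predictions exactly.
    """
    tab = pd.DataFrame(bioclim.table(), columns=ZONE_PREDICTORS)
    coarse = fitted.model.predict(tab).reshape(bioclim.geom.shape)
    fine = None
    if fine_geom is not None:
        fine = upsample_nearest(coarse, fine_geom.factor_to(bioclim.geom))
    return coarse, fine


# ---------------------------------------------------------------------------
# community area fractions (random forests)
# ---------------------------------------------------------------------------

FRACTION_PREDICTORS = ["slope", "aspect", "curvature", "twi", "ridge_distance",
                       "zone_probability"]


def fraction_training_table(terrain: TerrainGrid, zone_prob_fine: np.ndarray
                            ) -> tuple[pd.DataFrame, np.ndarray]:
    """Fine-cell predictor table and the valid-cell mask (border cells dropped)."""
    X, valid, names = terrain.predictor_table(zone_prob_fine)
    return pd.DataFrame(X, columns=names), valid


@dataclass
class FittedFractionModel:
    """One random forest per community plus importance tables."""

    forests: dict[str, RandomForestRegressor]
    feature_names: list[str] = field(default_factory=lambda: list(FRACTION_PREDICTORS))
    oob_score: dict[str, float] = field(default_factory=dict)
    importance: dict[str, pd.Series] = field(default_factory=dict)


def fit_fraction_models(X: pd.DataFrame, fractions: dict[str, np.ndarray],
                        n_trees: int = 500, seed: int = 0) -> FittedFractionModel:
    """Fit one random-forest regressor per community.

    ``X`` holds the topographic predictors plus zone probability for valid
    cells; ``fractions`` maps community code to the response vector in [0,1].
    Feature subsampling is the regression default of p/3 features per split;
    fits are deterministic given ``seed`` and record the out-of-bag R^2.
    """
    feature_names = list(X.columns)
    max_features = max(1, len(feature_names) // 3)
    forests: dict[str, RandomForestRegressor] = {}
    oob: dict[str, float] = {}
    for i, (name, y) in enumerate(sorted(fractions.items())):
        y = np.asarray(y, dtype=float)
        if len(y) != len(X):
            raise ValueError(f"response {name} length does not match predictors")
        rf = RandomForestRegressor(n_estimators=n_trees, max_features=max_features,
                                   oob_score=True, bootstrap=True,
                                   random_state=seed + i, n_jobs=1)
        rf.fit(X.to_numpy(), y)
        forests[name] = rf
        oob[name] = float(rf.oob_score_)
    return FittedFractionModel(forests=forests, feature_names=feature_names,
                               oob_score=oob)


def increased_mse_importance(forest: RandomForestRegressor, X: pd.DataFrame,
                             y: np.ndarray, n_permutations: int = 5,
                             seed: int = 0,
                             variables: list[str] | None = None) -> pd.Series:
    """Increased-MSE permutation importance.

    Importance of a predictor is the mean (over permutations) of the MSE with
    that predictor's column randomly permuted minus the unpermuted MSE.
    Only predictor columns may be permuted — naming the response is an error.
    """
    y = np.asarray(y, dtype=float)
    cols = list(X.columns)
    variables = cols if variables is None else list(variables)
    bad = [v for v in variables if v not in cols]
    if bad:
        raise ValueError(f"not predictor columns (responses cannot be permuted): {bad}")
    Xa = X.to_numpy()
    base_mse = float(np.mean((forest.predict(Xa) - y) ** 2))
    rng = np.random.default_rng(seed)
    out = {}
    for v in variables:
        j = cols.index(v)
        deltas = np.empty(n_permutations)
        for r in range(n_permutations):
            Xp = Xa.copy()
            Xp[:, j] = Xp[rng.permutation(len(Xp)), j]
            deltas[r] = np.mean((forest.predict(Xp) - y) ** 2) - base_mse
        out[v] = float(deltas.mean())
    return pd.Series(out).sort_values(ascending=False)


def _fill_invalid_nearest(grid: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """Fill invalid cells (border / flat) with the nearest valid value."""
    if valid.all():
        return grid
    _, (ri, ci) = ndimage.distance_transform_edt(~valid, return_indices=True)
    return grid[ri, ci]


def predict_fractions(fitted: FittedFractionModel, terrain: TerrainGrid,
                      zone_prob_fine: np.ndarray):
    """Predict the three community fraction grids on the fine lattice.

    Predictions are clipped to [0,1]; cells whose three fractions sum above 1
    are rescaled proportionally (logged). Border cells, where topographic
    derivatives are undefined, take the nearest valid prediction so the grids
    are complete for aggregation.
    """
    from .synthetic import VegetationMap  # local import to avoid a cycle

    X, valid, names = terrain.predictor_table(zone_prob_fine)
    if names != fitted.feature_names:
        raise ValueError("terrain predictors do not match the fitted forests")
    shape = terrain.geom.shape
    grids = {}
    for name, rf in fitted.forests.items():
        flat = np.full(shape[0] * shape[1], np.nan)
        flat[valid] = np.clip(rf.predict(X), 0.0, 1.0)
        grids[name] = _fill_invalid_nearest(flat.reshape(shape),
                                            valid.reshape(shape))
    total = sum(grids.values())
    over = total > 1.0
    if over.any():
        logger.info("rescaling %d cells whose fraction sum exceeds 1", int(over.sum()))
        scale = np.where(over, 1.0 / np.maximum(total, 1e-12), 1.0)
        grids = {k: v * scale for k, v in grids.items()}
    return VegetationMap(pp=grids["pp"], sg=grids["sg"], ff=grids["ff"],
                         geom=terrain.geom)
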