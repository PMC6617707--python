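"""Territory occurrence model with a survey-effort offset (sub-model A analogue).

The territory-scale occurrence of the bird is modelled as an additive logistic
model of the aggregated vegetation predictors:

    logit P(presence) = beta0 + s(DR, AF_Pp) + s(AF_Ff) + s(AF_Sg) + log(n_surveys)

where AF_* are mean community area fractions of the territory cell (stone-pine
scrub, fellfield, snowbed grassland), DR is mean ridge distance, and the
log-surveys offset absorbs unequal survey effort. The stone-pine fraction and
ridge distance enter jointly as a bivariate combination smooth: cover close to
the ridgeline is worth more than the same cover far from it. Variable
importance is Akaike-weight based over the all-subsets candidate model set.

Predicted maps are standardized at a reference effort of one survey
(offset = 0) so cells are comparable regardless of how often they were visited.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gam import AdditiveLogisticModel, Smooth1D, Smooth2D, DegenerateDataError
from .geometry import GridGeometry, block_mean
from .metrics import (ValidationReport, bootstrap_auc, roc_auc,
                      sensitivity_specificity, threshold_at_sensitivity)

__all__ = [
    "TerritoryObservations",
    "aggregate_predictors",
    "FittedHabitatModel",
    "fit_habitat_model",
    "predict_habitat_probability",
    "iov_akaike",
]

PREDICTOR_COLUMNS = ["AF_Pp", "AF_Sg", "AF_Ff", "DR_m"]

# candidate smooth terms; the combination smooth enters subsets as one unit
HABITAT_TERMS = (
    Smooth2D("DR_m", "AF_Pp", df=(5, 5)),
    Smooth1D("AF_Ff", df=10),
    Smooth1D("AF_Sg", df=10),
)


@dataclass
class TerritoryObservations:
    """Presence/absence observations with predictors on the territory lattice.

    ``table`` columns: cell_row, cell_col, presence (0/1), n_surveys,
    AF_Pp, AF_Sg, AF_Ff, DR_m, and optionally p_true (generator ground truth).
    Cells with zero surveys are excluded before construction.
    """

    table: pd.DataFrame
    geom: GridGeometry

    def __post_init__(self) -> None:
        required = {"cell_row", "cell_col", "presence", "n_surveys", *PREDICTOR_COLUMNS}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"territory table missing columns: {sorted(missing)}")
        if (self.table["n_surveys"] < 1).any():
            raise ValueError("included cells must have n_surveys >= 1")
        for col in ("AF_Pp", "AF_Sg", "AF_Ff"):
            if ((self.table[col] < -1e-9) | (self.table[col] > 1 + 1e-9)).any():
                raise ValueError(f"{col} outside [0,1]")

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, geom: GridGeometry) -> "TerritoryObservations":
        return cls(pd.read_csv(path), geom)


def aggregate_predictors(fractions: dict[str, np.ndarray],
                         ridge_distance: np.ndarray,
                         fine_geom: GridGeometry,
                         territory_geom: GridGeometry) -> pd.DataFrame:
    """Aggregate fine-cell fractions and ridge distance to territory cells.

    Each territory-cell predictor is the mean over its
    ``(territory/terrain)^2`` constituent fine cells, which conserves the
    domain-total community area across resolutions.
    """
    factor = fine_geom.factor_to(territory_geom)
    rows = {
        "AF_Pp": block_mean(fractions["pp"], factor).ravel(),
        "AF_Sg": block_mean(fractions["sg"], factor).ravel(),
        "AF_Ff": block_mean(fractions["ff"], factor).ravel(),
        "DR_m": block_mean(ridge_distance, factor).ravel(),
    }
    rr, cc = np.meshgrid(np.arange(territory_geom.nrows),
                         np.arange(territory_geom.ncols), indexing="ij")
    out = pd.DataFrame({"cell_row": rr.ravel(), "cell_col": cc.ravel(), **rows})
    return out


@dataclass
class FittedHabitatModel:
    """Fitted territory model plus its training threshold and metrics."""

    model: AdditiveLogisticModel
    threshold: float
    report: ValidationReport
    sensitivity_cutoff: float = 0.95


def fit_habitat_model(obs: TerritoryObservations,
                      sensitivity_cutoff: float = 0.95,
                      n_bootstrap: int = 100,
                      seed: int = 0) -> FittedHabitatModel:
    """Fit the territory occurrence model with a log-surveys offset.

    The training threshold is the fixed-sensitivity rule (default 95% of
    presences retained) evaluated on effort-standardized predictions over the
    full training set; bootstrap validation resamples the training rows and
    scores them with the single fitted model.
    """
    df = obs.table
    y = df["presence"].to_numpy(dtype=float)
    if y.min() == y.max():
        raise DegenerateDataError("territory data contain a single class")
    offset = np.log(df["n_surveys"].to_numpy(dtype=float))
    model = AdditiveLogisticModel(list(HABITAT_TERMS))
    model.fit(df, y, offset=offset)
    # maps are standardized at one survey (offset = 0)
    scores = model.predict(df, offset=0.0)
    threshold = threshold_at_sensitivity(scores, y, sensitivity_cutoff)
    sens, spec = sensitivity_specificity(scores, y, threshold)
    auc_mean, auc_sd = bootstrap_auc(lambda d: model.predict(d, offset=0.0),
                                     df, y.astype(int), n_reps=n_bootstrap,
                                     seed=seed)
    report = ValidationReport(auc=auc_mean, auc_sd=auc_sd, sensitivity=sens,
                              specificity=spec, threshold=threshold,
                              n_bootstrap=n_bootstrap)
    return FittedHabitatModel(model=model, threshold=threshold, report=report,
                              sensitivity_cutoff=sensitivity_cutoff)


def predict_habitat_probability(fitted: FittedHabitatModel,
                                predictors: pd.DataFrame,
                                effort: float = 1.0) -> np.ndarray:
    """Occurrence probabilities standardized at ``effort`` surveys.

    Changing the reference effort shifts every prediction by exactly
    ``log(effort)`` on the logit scale.
    """
    if effort <= 0:
        raise ValueError("effort must be positive")
    return fitted.model.predict(predictors, offset=float(np.log(effort)))


def iov_akaike(obs: TerritoryObservations) -> pd.DataFrame:
    """All-subsets Akaike-weight importance of the habitat model terms.

    Fits all 2^3 = 8 subset models (the combination smooth never splits),
    including the null model, each with the log-surveys offset. Returns a
    model-selection table with AIC, delta-AIC and Akaike weights; per-term
    importance (IOV) is the summed weight of the models containing the term,
    attached as ``DataFrame.attrs['iov']``.
    """
    df = obs.table
    y = df["presence"].to_numpy(dtype=float)
    offset = np.log(df["n_surveys"].to_numpy(dtype=float))
    records = []
    fitted_terms = []
    for mask in range(2 ** len(HABITAT_TERMS)):
        terms = [t for i, t in enumerate(HABITAT_TERMS) if mask & (1 << i)]
        model = AdditiveLogisticModel(terms).fit(df, y, offset=offset)
        label = " + ".join(t.label for t in terms) if terms else "Null"
        records.append({"model": label, "aic": model.aic_, "edf": model.edf_})
        fitted_terms.append({t.label for t in terms})
    table = pd.DataFrame(records)
    table["delta_aic"] = table["aic"] - table["aic"].min()
    w = np.exp(-0.5 * table["delta_aic"].to_numpy())
    table["akaike_weight"] = w / w.sum()
    iov = {}
    for term in HABITAT_TERMS:
        members = [i for i, s in enumerate(fitted_terms) if term.label in s]
        iov[term.label] = float(table["akaike_weight"].iloc[members].sum())
    table = table.sort_values("aic", ignore_index=True)
    table.attrs["iov"] = iov
    return table
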