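"""Discrimination and validation machinery shared by all occurrence models.

ROC/AUC (rank formulation, ties counted half), sensitivity/specificity at a
threshold, the fixed-sensitivity threshold rule used to turn probabilities into
binary habitat (the largest threshold retaining at least the required fraction
of presences), bootstrap validation of an already-fitted model, and Spearman
rank correlation for the area-fraction models.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats

__all__ = [
    "roc_auc",
    "threshold_at_sensitivity",
    "sensitivity_specificity",
    "bootstrap_auc",
    "spearman_rho",
    "ValidationReport",
]


class UndefinedMetricError(ValueError):
    """A metric is undefined for the supplied labels (e.g. one class only)."""


def _check_binary(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels)
    if set(np.unique(labels)) - {0, 1}:
        raise ValueError("labels must be 0/1")
    return labels.astype(int)


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve via the rank (Mann-Whitney) formulation.

    Equals the probability that a uniformly chosen presence outscores a
    uniformly chosen absence, counting ties as one half.
    """
    scores = np.asarray(scores, dtype=float)
    labels = _check_binary(labels)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError("AUC needs both presences and absences")
    ranks = stats.rankdata(scores)  # mid-ranks handle ties as one half
    rank_sum_pos = float(ranks[labels == 1].sum())
    return (rank_sum_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def threshold_at_sensitivity(scores, labels, cutoff: float = 0.95) -> float:
    """Largest threshold t with fraction of presences scoring >= t at least ``cutoff``.

    Candidate thresholds are the presence scores themselves, so training
    sensitivity at the returned threshold is always >= cutoff. Ties resolve to
    the largest qualifying threshold (the most conservative habitat extent).
    """
    scores = np.asarray(scores, dtype=float)
    labels = _check_binary(labels)
    pos = np.sort(scores[labels == 1])[::-1]
    if len(pos) == 0:
        raise UndefinedMetricError("no presences")
    if not 0.0 <= cutoff <= 1.0:
        raise ValueError("cutoff must be in [0,1]")
    k = max(1, int(np.ceil(cutoff * len(pos) - 1e-12)))
    return float(pos[k - 1])


def sensitivity_specificity(scores, labels, threshold: float
                            ) -> tuple[float, float]:
    """(sensitivity, specificity) counting score >= threshold as predicted presence."""
    scores = np.asarray(scores, dtype=float)
    labels = _check_binary(labels)
    pred = scores >= threshold
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError("needs both presences and absences")
    sens = float(pred[labels == 1].sum()) / n_pos
    spec = float((~pred[labels == 0]).sum()) / n_neg
    return sens, spec


def bootstrap_auc(score_fn, data, labels, n_reps: int = 100, seed: int = 0
                  ) -> tuple[float, float]:
    """Bootstrap validation AUC of an already-fitted model.

    Per repetition, rows are resampled with replacement as a validation set and
    scored with ``score_fn`` (the fitted model's predict); the model is *not*
    refitted, matching a fit-once / bootstrap-validate design (optimistic, and
    documented as such). Single-class resamples are redrawn. Returns
    (mean AUC, standard deviation).
    """
    labels = _check_binary(labels)
    n = len(labels)
    rng = np.random.default_rng(seed)
    aucs = np.empty(n_reps)
    for rep in range(n_reps):
        for _ in range(1000):
            idx = rng.integers(0, n, size=n)
            if 0 < labels[idx].sum() < n:
                break
        else:  # pragma: no cover - pathological label balance
            raise UndefinedMetricError("could not draw a two-class bootstrap sample")
        sub = data.iloc[idx] if hasattr(data, "iloc") else data[idx]
        aucs[rep] = roc_auc(score_fn(sub), labels[idx])
    return float(aucs.mean()), float(aucs.std(ddof=0))


def spearman_rho(predicted, actual) -> tuple[float, float]:
    """Spearman rank correlation (rho, p-value) between predicted and actual."""
    res = stats.spearmanr(np.asarray(predicted, float), np.asarray(actual, float))
    return float(res.statistic), float(res.pvalue)


@dataclass
class ValidationReport:
    """Summary of one model's discrimination performance."""

    auc: float
    auc_sd: float
    sensitivity: float
    specificity: float
    threshold: float
    n_bootstrap: int

    def to_dict(self) -> dict:
        return asdict(self)
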