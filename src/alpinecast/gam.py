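"""Penalized additive logistic regression with smooth terms.

The occurrence models in the cascade are additive logistic models of the form

    logit P(y=1) = beta0 + f1(x1) + f2(x2) + ... + offset

where each ``f`` is either a univariate penalized B-spline smooth or a
bivariate tensor-product smooth (the "combination" term of two interacting
predictors). Fitting is penalized IRLS: second-order difference penalties on
the spline coefficients, a single smoothing multiplier chosen on a fixed
log-grid by deviance-based GCV. The effective degrees of freedom (edf) are the
trace of the influence matrix, and AIC = deviance + 2*edf, the standard form
for penalized smooths — this is what drives Akaike-weight variable importance.

Everything here is deterministic: no random initialization, no stochastic
optimization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline
from scipy.special import expit, logit

__all__ = ["Smooth1D", "Smooth2D", "AdditiveLogisticModel", "DegenerateDataError"]

ETA_CLIP = 35.0
W_FLOOR = 1e-8


class DegenerateDataError(ValueError):
    """Training data cannot identify the model (e.g. a single response class)."""


@dataclass(frozen=True)
class Smooth1D:
    """Univariate penalized B-spline smooth of one predictor."""

    var: str
    df: int = 10

    @property
    def label(self) -> str:
        return f"s({self.var})"

    @property
    def vars(self) -> tuple[str, ...]:
        return (self.var,)


@dataclass(frozen=True)
class Smooth2D:
    """Bivariate tensor-product smooth — a combination term of two predictors."""

    var_x: str
    var_y: str
    df: tuple[int, int] = (5, 5)

    @property
    def label(self) -> str:
        return f"s({self.var_x},{self.var_y})"

    @property
    def vars(self) -> tuple[str, ...]:
        return (self.var_x, self.var_y)


def _knots(x: np.ndarray, n_basis: int, degree: int = 3) -> np.ndarray:
    """Quantile-based knot vector for ``n_basis`` cubic B-splines."""
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi - lo < 1e-12:  # constant predictor: widen artificially
        lo, hi = lo - 0.5, hi + 0.5
    n_interior = n_basis - degree - 1
    if n_interior > 0:
        qs = np.linspace(0, 1, n_interior + 2)[1:-1]
        interior = np.quantile(x, qs)
        # enforce strictly increasing interior knots inside (lo, hi)
        interior = np.clip(interior, lo + 1e-9, hi - 1e-9)
        interior = np.maximum.accumulate(interior + np.arange(n_interior) * 1e-9)
    else:
        interior = np.array([])
    return np.concatenate([np.full(degree + 1, lo), interior,
                           np.full(degree + 1, hi)])


def _basis(x: np.ndarray, knots: np.ndarray, degree: int = 3) -> np.ndarray:
    return BSpline.design_matrix(np.asarray(x, dtype=float), knots, degree,
                                 extrapolate=True).toarray()


def _second_diff_penalty(k: int) -> np.ndarray:
    d = np.diff(np.eye(k), n=2, axis=0)
    return d.T @ d


@dataclass
class _FittedTerm:
    term: Smooth1D | Smooth2D
    knots: tuple[np.ndarray, ...]
    col_means: np.ndarray
    sl: slice  # columns of this term in the design matrix (after intercept)

    def _var(self, data: pd.DataFrame, name: str, knots: np.ndarray) -> np.ndarray:
        # constant extrapolation: clamp to the training range so smooths do
        # not blow up polynomially outside the data hull (e.g. under strong
        # warming scenarios whose predictors exceed anything observed)
        return np.clip(data[name].to_numpy(dtype=float), knots[0], knots[-1])

    def design(self, data: pd.DataFrame, center: bool = True) -> np.ndarray:
        if isinstance(self.term, Smooth1D):
            b = _basis(self._var(data, self.term.var, self.knots[0]), self.knots[0])
        else:
            bx = _basis(self._var(data, self.term.var_x, self.knots[0]), self.knots[0])
            by = _basis(self._var(data, self.term.var_y, self.knots[1]), self.knots[1])
            b = (bx[:, :, None] * by[:, None, :]).reshape(len(bx), -1)
        return b - self.col_means if center else b


class AdditiveLogisticModel:
    """Additive logistic model with penalized smooth terms and a fixed offset.

    Parameters
    ----------
    terms:
        smooth terms; an empty list gives the intercept-only (null) model.
    lambda_grid:
        candidate global smoothing multipliers; the fit picks the GCV minimum.
    """

    def __init__(self, terms: Sequence[Smooth1D | Smooth2D] = (),
                 lambda_grid: Sequence[float] | None = None,
                 null_ridge: float = 1e-3) -> None:
        self.terms = list(terms)
        self.lambda_grid = (np.logspace(-4, 4, 9) if lambda_grid is None
                            else np.asarray(lambda_grid, dtype=float))
        self.null_ridge = float(null_ridge)
        self._fitted: list[_FittedTerm] = []
        self.beta: np.ndarray | None = None

    # -- fitting ---------------------------------------------------------

    def _build_design(self, data: pd.DataFrame, fit: bool
                      ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Assemble [1 | term blocks], the difference penalty and the ridge.

        The difference penalty is scaled by the smoothing parameter during
        fitting; the small fixed ridge is not — it bounds the otherwise
        unpenalized (linear) directions of each smooth, which diverge under
        separable data (a shrinkage smooth), without affecting a well-posed fit.
        """
        n = len(data)
        blocks = [np.ones((n, 1))]
        if fit:
            self._fitted = []
            penalties = [np.zeros((1, 1))]
            ridges = [np.zeros((1, 1))]
            col = 1
            for term in self.terms:
                if isinstance(term, Smooth1D):
                    knots = (_knots(data[term.var].to_numpy(), term.df),)
                    raw = _basis(data[term.var].to_numpy(), knots[0])
                    pen = _second_diff_penalty(raw.shape[1])
                else:
                    kx = _knots(data[term.var_x].to_numpy(), term.df[0])
                    ky = _knots(data[term.var_y].to_numpy(), term.df[1])
                    knots = (kx, ky)
                    bx = _basis(data[term.var_x].to_numpy(), kx)
                    by = _basis(data[term.var_y].to_numpy(), ky)
                    raw = (bx[:, :, None] * by[:, None, :]).reshape(n, -1)
                    sx = _second_diff_penalty(bx.shape[1])
                    sy = _second_diff_penalty(by.shape[1])
                    pen = (np.kron(sx, np.eye(by.shape[1]))
                           + np.kron(np.eye(bx.shape[1]), sy))
                means = raw.mean(axis=0)
                centered = raw - means
                # balance the penalty against the data scale of this block
                k = raw.shape[1]
                xtx_tr = float(np.einsum("ij,ij->", centered, centered))
                pen_tr = float(np.trace(pen))
                if pen_tr > 0:
                    pen = pen * (xtx_tr / pen_tr)
                ft = _FittedTerm(term, knots, means, slice(col, col + k))
                col += k
                self._fitted.append(ft)
                blocks.append(centered)
                penalties.append(pen)
                ridges.append(self.null_ridge * (xtx_tr / k) * np.eye(k))
            self._penalty_blocks = penalties
            self._ridge_blocks = ridges
        else:
            for ft in self._fitted:
                blocks.append(ft.design(data))
            penalties = self._penalty_blocks
            ridges = self._ridge_blocks
        X = np.concatenate(blocks, axis=1)
        p = X.shape[1]
        S = np.zeros((p, p))
        R = np.zeros((p, p))
        col = 0
        for pen, rid in zip(penalties, ridges):
            k = pen.shape[0]
            S[col:col + k, col:col + k] = pen
            R[col:col + k, col:col + k] = rid
            col += k
        return X, S, R

    @staticmethod
    def _pirls(X: np.ndarray, y: np.ndarray, S: np.ndarray,
               offset: np.ndarray, max_iter: int = 60, tol: float = 1e-9
               ) -> tuple[np.ndarray, float, float]:
        """Penalized IRLS; returns (beta, deviance, edf)."""
        n, p = X.shape
        mu = (y + 0.5) / 2.0
        eta = logit(mu) - offset
        beta = np.zeros(p)
        dev_old = np.inf
        for _ in range(max_iter):
            mu = expit(np.clip(eta + offset, -ETA_CLIP, ETA_CLIP))
            mu = np.clip(mu, 1e-12, 1 - 1e-12)
            w = np.maximum(mu * (1 - mu), W_FLOOR)
            z = eta + (y - mu) / w
            xw = X * w[:, None]
            a = X.T @ xw + S
            b = xw.T @ z
            try:
                beta = np.linalg.solve(a + 1e-10 * np.eye(p), b)
            except np.linalg.LinAlgError:
                beta = np.linalg.lstsq(a, b, rcond=None)[0]
            eta = np.clip(X @ beta, -ETA_CLIP, ETA_CLIP)
            mu_new = np.clip(expit(np.clip(eta + offset, -ETA_CLIP, ETA_CLIP)),
                             1e-12, 1 - 1e-12)
            dev = -2.0 * float(np.sum(y * np.log(mu_new)
                                      + (1 - y) * np.log(1 - mu_new)))
            if abs(dev_old - dev) < tol * (abs(dev) + 0.1):
                dev_old = dev
                break
            dev_old = dev
        mu = np.clip(expit(np.clip(eta + offset, -ETA_CLIP, ETA_CLIP)),
                     1e-12, 1 - 1e-12)
        w = np.maximum(mu * (1 - mu), W_FLOOR)
        xw = X * w[:, None]
        xtwx = X.T @ xw
        a = xtwx + S
        edf = float(np.trace(np.linalg.solve(a + 1e-10 * np.eye(p), xtwx)))
        return beta, dev_old, edf

    def fit(self, data: pd.DataFrame, y: np.ndarray,
            offset: np.ndarray | float = 0.0) -> "AdditiveLogisticModel":
        y = np.asarray(y, dtype=float)
        if set(np.unique(y)) - {0.0, 1.0}:
            raise ValueError("response must be binary 0/1")
        if y.min() == y.max():
            raise DegenerateDataError("both response classes must be present")
        offset = np.broadcast_to(np.asarray(offset, dtype=float), y.shape).copy()
        X, S0, R = self._build_design(data, fit=True)
        n = len(y)
        best = None
        for lam in self.lambda_grid:
            beta, dev, edf = self._pirls(X, y, lam * S0 + R, offset)
            denom = max(n - edf, 1.0)
            gcv = n * dev / denom**2
            if best is None or gcv < best[0]:
                best = (gcv, lam, beta, dev, edf)
        _, self.lambda_, self.beta, self.deviance_, self.edf_ = best
        self.aic_ = self.deviance_ + 2.0 * self.edf_
        self.n_obs_ = n
        self.fitted_values_ = self.predict(data, offset=offset)
        return self

    # -- prediction ------------------------------------------------------

    def _linear_predictor(self, data: pd.DataFrame) -> np.ndarray:
        if self.beta is None:
            raise RuntimeError("model is not fitted")
        X, _, _ = self._build_design(data, fit=False)
        return X @ self.beta

    def predict(self, data: pd.DataFrame,
                offset: np.ndarray | float = 0.0) -> np.ndarray:
        """Occurrence probabilities in (0,1) at the given offset."""
        eta = self._linear_predictor(data) + np.asarray(offset, dtype=float)
        return expit(np.clip(eta, -ETA_CLIP, ETA_CLIP))

    def partial_effect(self, label: str, data: pd.DataFrame) -> np.ndarray:
        """Centered contribution of one smooth term on the logit scale."""
        for ft in self._fitted:
            if ft.term.label == label:
                return ft.design(data) @ self.beta[ft.sl]
        raise KeyError(f"no term {label!r} in model")

    @property
    def term_labels(self) -> list[str]:
        return [t.label for t in self.terms]

    def summary(self) -> dict:
        return {
            "terms": self.term_labels,
            "lambda": float(self.lambda_),
            "edf": float(self.edf_),
            "deviance": float(self.deviance_),
            "aic": float(self.aic_),
            "n_obs": int(self.n_obs_),
        }
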