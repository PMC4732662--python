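"""Ridge-regression BLUP (RR-BLUP) for genomic prediction.

Model: y = W beta + X a + e, with W the fixed-effect design (an intercept,
optionally extra covariates such as subpopulation indicators), X the n x m
additive marker matrix, marker effects a ~ N(0, sigma2_a I) with
sigma2_a = sigma2_G / m (every marker shares the same prior variance), and
e ~ N(0, sigma2_e I).

The variance ratio delta = sigma2_e / sigma2_a is estimated by restricted
maximum likelihood profiled on the spectral decomposition of the genomic
cross-product K = X X^T projected off the fixed effects — an EMMA-style
single-parameter REML that costs one n x n eigendecomposition regardless of
the (much larger) marker count. Given delta, fixed effects come from GLS
against H = K + delta I and the marker BLUPs from
a = X^T H^{-1} (y - W beta). This is Henderson's mixed-model solution, so
for fixed delta it coincides with ridge regression at penalty lambda = delta.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize_scalar
from sklearn.base import BaseEstimator, RegressorMixin

logger = logging.getLogger(__name__)


@dataclass
class PredictionResult:
    line_ids: list
    predicted: np.ndarray

    def to_series(self) -> pd.Series:
        return pd.Series(self.predicted, index=self.line_ids, name="predicted")


def _as_matrix(X) -> tuple[np.ndarray, list | None]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), list(X.columns)
    return np.asarray(X, dtype=float), None


def _fixed_design(n: int, W=None) -> np.ndarray:
    cols = [np.ones((n, 1))]
    if W is not None:
        W = np.asarray(W, dtype=float)
        if W.ndim == 1:
            W = W[:, None]
        cols.append(W)
    design = np.hstack(cols)
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("fixed-effect design (intercept + covariates) is rank deficient")
    return design


class RRBLUP(RegressorMixin, BaseEstimator):
    """RR-BLUP genomic prediction as a scikit-learn regressor.

    Parameters
    ----------
    log10_delta_bounds : tuple of float
        Search interval for log10(delta), delta = sigma2_e / sigma2_a.
    tol : float
        Absolute tolerance of the bounded scalar REML search.

    Attributes (after fit)
    ----------------------
    mu_ : float                intercept
    beta_ : ndarray            covariate coefficients (empty without covariates)
    effects_ : ndarray         per-marker BLUPs, length m
    sigma2_a_, sigma2_e_ : float
    lambda_ : float            sigma2_e_ / sigma2_a_
    reml_loglik_ : float       restricted log-likelihood at the optimum
    marker_ids_ : list or None column ids when X was a DataFrame
    """

    def __init__(self, log10_delta_bounds: tuple = (-10.0, 10.0), tol: float = 1e-8):
        self.log10_delta_bounds = log10_delta_bounds
        self.tol = tol

    # -- fitting -----------------------------------------------------------

    def fit(self, X, y, W=None):
        Xm, marker_ids = _as_matrix(X)
        y = np.asarray(y, dtype=float).ravel()
        n, m = Xm.shape
        if len(y) != n:
            raise ValueError("X rows and y length differ")
        if n < 3:
            raise ValueError("need at least 3 lines to fit")
        if np.ptp(y) == 0.0:
            raise ValueError("constant response: genetic variance is zero")

        Wf = _fixed_design(n, W)
        p = Wf.shape[1]
        K = Xm @ Xm.T

        # project K and y off the fixed effects; restricted spectrum
        Q, _ = np.linalg.qr(Wf)
        S = np.eye(n) - Q @ Q.T
        vals, vecs = np.linalg.eigh((S @ K @ S + (S @ K @ S).T) / 2.0)
        order = np.argsort(vals)[::-1][: n - p]
        xi = np.clip(vals[order], 0.0, None)
        eta = vecs[:, order].T @ y
        eta2 = eta**2
        df = n - p

        def neg_restricted_ll(log10_delta: float) -> float:
            delta = 10.0**log10_delta
            denom = xi + delta
            r = float(np.sum(eta2 / denom))
            return 0.5 * (df * np.log(r) + float(np.sum(np.log(denom))))

        res = minimize_scalar(
            neg_restricted_ll,
            bounds=self.log10_delta_bounds,
            method="bounded",
            options={"xatol": self.tol},
        )
        delta = float(10.0**res.x)
        r = float(np.sum(eta2 / (xi + delta)))
        sigma2_a = r / df
        sigma2_e = delta * sigma2_a
        self.reml_loglik_ = 0.5 * (
            df * (np.log(df / (2.0 * np.pi)) - 1.0)
            - df * np.log(r)
            - float(np.sum(np.log(xi + delta)))
        )

        H = K + delta * np.eye(n)
        cf = cho_factor(H, lower=True)
        Hy = cho_solve(cf, y)
        HW = cho_solve(cf, Wf)
        beta_full = np.linalg.solve(Wf.T @ HW, Wf.T @ Hy)
        resid = y - Wf @ beta_full
        self.effects_ = Xm.T @ cho_solve(cf, resid)

        self.mu_ = float(beta_full[0])
        self.beta_ = beta_full[1:]
        self.sigma2_a_ = float(sigma2_a)
        self.sigma2_e_ = float(sigma2_e)
        self.lambda_ = delta
        self.marker_ids_ = marker_ids
        self.n_features_in_ = m
        self._n_covariates = p - 1
        return self

    # -- prediction --------------------------------------------------------

    def _align(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame) and self.marker_ids_ is not None:
            missing = [c for c in self.marker_ids_ if c not in X.columns]
            if missing:
                raise KeyError(
                    f"{len(missing)} marker columns missing from X_new, e.g. {missing[:5]}"
                )
            return X[self.marker_ids_].to_numpy(dtype=float)
        Xm, _ = _as_matrix(X)
        if Xm.shape[1] != self.n_features_in_:
            raise ValueError("X_new marker count differs from the fitted model")
        return Xm

    def predict(self, X, W=None) -> np.ndarray:
        Xm = self._align(X)
        out = self.mu_ + Xm @ self.effects_
        if self._n_covariates:
            if W is None:
                raise ValueError("model was fitted with covariates; W is required")
            W = np.asarray(W, dtype=float)
            if W.ndim == 1:
                W = W[:, None]
            out = out + W @ self.beta_
        elif W is not None:
            raise ValueError("model was fitted without covariates")
        return out

    def predict_result(self, X, W=None) -> PredictionResult:
        ids = list(X.index) if isinstance(X, pd.DataFrame) else list(range(len(X)))
        return PredictionResult(line_ids=ids, predicted=self.predict(X, W=W))

    # -- serialization -----------------------------------------------------

    def to_json_dict(self) -> dict:
        return {
            "mu": self.mu_,
            "beta": [float(b) for b in self.beta_],
            "sigma2_a": self.sigma2_a_,
            "sigma2_e": self.sigma2_e_,
            "lambda": self.lambda_,
            "reml_loglik": float(self.reml_loglik_),
            "n_markers": int(self.n_features_in_),
        }

    def save(self, model_path: str, effects_path: str) -> None:
        with open(model_path, "w") as fh:
            json.dump(self.to_json_dict(), fh, indent=2)
        ids = self.marker_ids_ or [f"m{j}" for j in range(self.n_features_in_)]
        pd.DataFrame({"marker_id": ids, "effect": self.effects_}).to_csv(
            effects_path, index=False
        )


def fit_rrblup(y, X, covariates=None, **kwargs) -> RRBLUP:
    """Fit the RR-BLUP model; thin wrapper over the RRBLUP estimator."""
    return RRBLUP(**kwargs).fit(X, y, W=covariates)


def predict(model: RRBLUP, X_new, covariates_new=None) -> PredictionResult:
    return model.predict_result(X_new, W=covariates_new)


def ridge_fixed_lambda(y, X, lam: float, covariates=None) -> tuple[np.ndarray, float]:
    """Exact mixed-model (ridge) solution at a fixed penalty, no REML.

    Solves the same GLS + BLUP system as :class:`RRBLUP` with delta pinned to
    ``lam``; with centered markers and intercept only this is the textbook
    ridge estimate (X^T X + lam I)^{-1} X^T (y - ybar). Returns (effects, mu).
    """
    if lam <= 0:
        raise ValueError("lambda must be positive")
    Xm, _ = _as_matrix(X)
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    Wf = _fixed_design(n, covariates)
    H = Xm @ Xm.T + lam * np.eye(n)
    cf = cho_factor(H, lower=True)
    HW = cho_solve(cf, Wf)
    beta = np.linalg.solve(Wf.T @ HW, Wf.T @ cho_solve(cf, y))
    effects = Xm.T @ cho_solve(cf, y - Wf @ beta)
    return effects, float(beta[0])
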