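"""Elastic-net linear regression with the objective

    L(alpha, lam, beta) = ||Y - X beta||^2
                          + lam * [(1 - alpha) ||beta||^2 + alpha ||beta||_1]

where ``lam`` (the subset-selecting factor) controls overall sparsity and
``alpha`` in [0, 1] mixes the L1 (selection) and L2 (grouping / smoothing of
selection from correlated variables) penalties.  Note this is the *raw*
residual-sum-of-squares convention — no 1/(2n) factor — so lambda grids are
defined relative to a lambda_max computed under the same convention.

Features are standardized to zero mean / unit variance inside ``fit`` using
training data only (penalties are scale-sensitive); the intercept is never
penalized.  Coefficients are stored on the standardized scale together with
the scaler, so prediction applies the stored scaler and never refits.

The solver delegates to scikit-learn's coordinate descent (after mapping
``(alpha, lam)`` onto its ``(l1_ratio, alpha)`` parametrization) and then
polishes with exact cyclic coordinate-descent passes until the elastic-net
subgradient (KKT) conditions hold to tight tolerance; :func:`check_kkt`
verifies optimality independently of the solver path.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import ElasticNet as _SkEN
from sklearn.utils.validation import check_is_fitted

from .errors import SchemaError, ValidationError

#: Floor on alpha when computing lambda_max (alpha -> 0 has no finite
#: lambda_max; the conventional path floor keeps grids finite).
_ALPHA_FLOOR = 1e-3


@dataclass(frozen=True)
class ENHyperparams:
    """(alpha, lam) pair: L1/L2 mixing weight and overall penalty strength."""

    alpha: float
    lam: float

    def __post_init__(self):
        if not (0.0 <= self.alpha <= 1.0):
            raise ValidationError(f"alpha must be in [0, 1], got {self.alpha}")
        if self.lam < 0:
            raise ValidationError(f"lam must be >= 0, got {self.lam}")


def _as_matrix(X, feature_ids=None):
    """Return (values, feature_ids) from a DataFrame or array."""
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(float), [str(c) for c in X.columns]
    X = np.asarray(X, float)
    if X.ndim != 2:
        raise ValidationError("X must be 2-dimensional")
    if feature_ids is None:
        feature_ids = [f"x{j}" for j in range(X.shape[1])]
    return X, list(feature_ids)


def _soft(z: np.ndarray, t: float) -> np.ndarray:
    return np.sign(z) * np.maximum(np.abs(z) - t, 0.0)


def _cd_polish(Z, yc, beta, alpha, lam, tol, max_passes=2000):
    """Exact cyclic coordinate descent on the raw-RSS elastic-net objective.

    Starts from `beta` (typically a near-optimal scikit-learn solution) and
    iterates until the relative KKT residual drops below `tol`.
    """
    n, p = Z.shape
    col_sq = np.einsum("ij,ij->j", Z, Z)
    denom = 2.0 * col_sq + 2.0 * lam * (1.0 - alpha)
    thresh = lam * alpha
    scale = max(1.0, 2.0 * np.abs(Z.T @ yc).max())
    r = yc - Z @ beta
    for _ in range(max_passes):
        for j in range(p):
            if denom[j] == 0.0:
                continue
            rho = 2.0 * (Z[:, j] @ r + col_sq[j] * beta[j])
            new = _soft(np.array([rho]), thresh)[0] / denom[j]
            if new != beta[j]:
                r += Z[:, j] * (beta[j] - new)
                beta[j] = new
        if _kkt_residuals(Z, yc, beta, alpha, lam).max() / scale < tol:
            break
    return beta


def _kkt_residuals(Z, yc, beta, alpha, lam):
    """Absolute per-coefficient subgradient residuals at `beta`."""
    g = 2.0 * Z.T @ (Z @ beta - yc)
    res = np.empty_like(beta)
    nz = beta != 0
    res[nz] = np.abs(
        g[nz] + 2.0 * lam * (1.0 - alpha) * beta[nz]
        + lam * alpha * np.sign(beta[nz])
    )
    res[~nz] = np.maximum(np.abs(g[~nz]) - lam * alpha, 0.0)
    return res


def lambda_max(X, Y, alpha: float) -> float:
    """Smallest lam for which all coefficients are zero at mixing `alpha`.

    Computed on standardized columns under the raw-RSS objective:
    ``lam_max = 2 * max_j |z_j^T (Y - mean(Y))| / max(alpha, 1e-3)``.
    """
    Xv, _ = _as_matrix(X)
    y = np.asarray(Y, float)
    mu = Xv.mean(axis=0)
    sd = Xv.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (Xv - mu) / sd
    yc = y - y.mean()
    return float(2.0 * np.abs(Z.T @ yc).max() / max(alpha, _ALPHA_FLOOR))


class ElasticNetRegressor(BaseEstimator, RegressorMixin):
    """Elastic net under the raw-RSS objective, scikit-learn estimator API.

    Parameters
    ----------
    alpha : float in [0, 1]
        Mixing weight: 1 = pure lasso, 0 = pure ridge.
    lam : float >= 0
        Overall penalty strength (0 = ordinary least squares).
    kkt_tol : float
        Relative subgradient tolerance the polished solution must satisfy.

    Attributes
    ----------
    coef_ : (n_features,) coefficients on the standardized feature scale.
    intercept_ : float, mean of the training outcome.
    feature_ids_ : feature identifiers in training order.
    scaler_mean_, scaler_scale_ : per-feature standardization parameters.
    dropped_features_ : zero-variance features forced to zero coefficient.
    """

    def __init__(self, alpha: float = 0.5, lam: float = 1.0, kkt_tol: float = 1e-9):
        self.alpha = alpha
        self.lam = lam
        self.kkt_tol = kkt_tol

    @property
    def hyperparams(self) -> ENHyperparams:
        return ENHyperparams(self.alpha, self.lam)

    def fit(self, X, y):
        ENHyperparams(self.alpha, self.lam)  # validates
        Xv, feature_ids = _as_matrix(X)
        y = np.asarray(y, float).ravel()
        if Xv.shape[0] != y.shape[0]:
            raise ValidationError("X and y have different sample counts")
        if Xv.shape[0] < 2:
            raise ValidationError("need at least 2 samples")
        if np.isnan(Xv).any():
            raise ValidationError("X contains missing values; impute first")
        if not np.isfinite(y).all():
            raise ValidationError("y must be finite")

        mu = Xv.mean(axis=0)
        sd = Xv.std(axis=0)
        dropped = sd == 0
        if dropped.any():
            names = [feature_ids[j] for j in np.flatnonzero(dropped)]
            warnings.warn(
                f"dropping {int(dropped.sum())} zero-variance feature(s): "
                f"{names[:5]}{'...' if len(names) > 5 else ''}"
            )
        sd_safe = np.where(dropped, 1.0, sd)
        Z = (Xv - mu) / sd_safe
        Z[:, dropped] = 0.0
        intercept = float(y.mean())
        yc = y - intercept

        beta = self._solve(Z, yc)
        beta[dropped] = 0.0

        self.coef_ = beta
        self.intercept_ = intercept
        self.feature_ids_ = feature_ids
        self.scaler_mean_ = mu
        self.scaler_scale_ = sd_safe
        self.dropped_features_ = [feature_ids[j] for j in np.flatnonzero(dropped)]
        self.n_features_in_ = Xv.shape[1]
        return self

    def _solve(self, Z, yc):
        n, p = Z.shape
        if self.lam == 0.0:
            beta, *_ = np.linalg.lstsq(Z, yc, rcond=None)
            return beta
        if self.alpha == 0.0:
            # ridge closed form under the raw-RSS convention
            A = 2.0 * Z.T @ Z + 2.0 * self.lam * np.eye(p)
            return np.linalg.solve(A, 2.0 * Z.T @ yc)
        sk_alpha = self.lam * (2.0 - self.alpha) / (2.0 * n)
        l1_ratio = self.alpha / (2.0 - self.alpha)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            est = _SkEN(
                alpha=sk_alpha, l1_ratio=l1_ratio, fit_intercept=False,
                max_iter=50_000, tol=1e-10,
            ).fit(Z, yc)
        beta = est.coef_.astype(float).copy()
        return _cd_polish(Z, yc, beta, self.alpha, self.lam, self.kkt_tol)

    def _transform(self, X):
        """Map new data onto the standardized training feature space."""
        check_is_fitted(self, "coef_")
        if isinstance(X, pd.DataFrame):
            cols = [str(c) for c in X.columns]
            missing = set(self.feature_ids_) - set(cols)
            if missing:
                raise SchemaError(f"missing features: {sorted(missing)[:5]}")
            extra = set(cols) - set(self.feature_ids_)
            if extra:
                raise SchemaError(f"unexpected features: {sorted(extra)[:5]}")
            Xv = X.loc[:, self.feature_ids_].to_numpy(float)
        else:
            Xv = np.asarray(X, float)
            if Xv.shape[1] != len(self.feature_ids_):
                raise SchemaError(
                    f"expected {len(self.feature_ids_)} features, "
                    f"got {Xv.shape[1]}"
                )
        return (Xv - self.scaler_mean_) / self.scaler_scale_

    def predict(self, X):
        Z = self._transform(X)
        return Z @ self.coef_ + self.intercept_

    def objective(self, X, y) -> float:
        """Value of the raw-RSS elastic-net objective at the fitted solution."""
        Z = self._transform(X)
        yc = np.asarray(y, float) - self.intercept_
        rss = float(((yc - Z @ self.coef_) ** 2).sum())
        pen = self.lam * (
            (1.0 - self.alpha) * float(self.coef_ @ self.coef_)
            + self.alpha * float(np.abs(self.coef_).sum())
        )
        return rss + pen

    # -- serialization -----------------------------------------------------
    def to_json_dict(self) -> dict:
        check_is_fitted(self, "coef_")
        return {
            "alpha": self.alpha,
            "lam": self.lam,
            "intercept": self.intercept_,
            "feature_ids": self.feature_ids_,
            "coefficients": self.coef_.tolist(),
            "scaler_mean": self.scaler_mean_.tolist(),
            "scaler_scale": self.scaler_scale_.tolist(),
            "dropped_features": self.dropped_features_,
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "ElasticNetRegressor":
        est = cls(alpha=d["alpha"], lam=d["lam"])
        est.coef_ = np.asarray(d["coefficients"], float)
        est.intercept_ = float(d["intercept"])
        est.feature_ids_ = list(d["feature_ids"])
        est.scaler_mean_ = np.asarray(d["scaler_mean"], float)
        est.scaler_scale_ = np.asarray(d["scaler_scale"], float)
        est.dropped_features_ = list(d.get("dropped_features", []))
        est.n_features_in_ = len(est.feature_ids_)
        return est

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json_dict(), fh, indent=1)

    @classmethod
    def load(cls, path) -> "ElasticNetRegressor":
        with open(path) as fh:
            return cls.from_json_dict(json.load(fh))


# ---------------------------------------------------------------------------
# Functional wrappers
# ---------------------------------------------------------------------------

def fit_en(X, Y, hp: ENHyperparams) -> ElasticNetRegressor:
    """Fit an elastic net at the given (alpha, lam)."""
    return ElasticNetRegressor(alpha=hp.alpha, lam=hp.lam).fit(X, Y)


def predict_en(model: ElasticNetRegressor, X) -> np.ndarray:
    """Predict with a fitted model; applies the stored scaler, never refits."""
    return model.predict(X)


def check_kkt(model: ElasticNetRegressor, X, Y, tol: float = 1e-6) -> dict:
    """Verify the elastic-net subgradient (optimality) conditions.

    For nonzero beta_j:  2 z_j^T (Z beta - yc) + 2 lam (1-alpha) beta_j
    + lam alpha sign(beta_j) = 0; for beta_j = 0 the gradient magnitude must
    not exceed lam * alpha.  Residuals are reported relative to the scale of
    the unpenalized gradient at beta = 0.

    Returns a dict with per-feature residuals, the max relative residual and
    a pass/fail flag at `tol`.
    """
    Z = model._transform(X)
    yc = np.asarray(Y, float).ravel() - model.intercept_
    res = _kkt_residuals(Z, yc, model.coef_, model.alpha, model.lam)
    scale = max(1.0, 2.0 * np.abs(Z.T @ yc).max())
    rel = res / scale
    return {
        "residuals": dict(zip(model.feature_ids_, rel.tolist())),
        "max_residual": float(rel.max()) if rel.size else 0.0,
        "tol": tol,
        "passed": bool(rel.size == 0 or rel.max() < tol),
    }
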