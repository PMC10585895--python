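"""Base learners and metrics shared by every selection stage.

All penalized fits standardize features internally, tune the penalty by
10-fold cross-validated RMSE, and report coefficients on the original scale.
The cross-validation fold split is seeded and can be shared across techniques
so comparisons within one trial see the same folds.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LassoCV, LinearRegression, Ridge
from sklearn.model_selection import KFold, cross_val_predict

logger = logging.getLogger(__name__)

__all__ = [
    "CVConfig",
    "FittedModel",
    "TECHNIQUES",
    "fit_model",
    "rmse",
    "r_squared",
]

TECHNIQUES = ("lasso", "ridge", "ols", "adaptive_ridge")

#: |coefficient| above this counts as "selected".
SELECTION_TOL = 1e-8

#: stabilizer in adaptive-ridge weights 1 / (|beta_ridge| + delta)
ADAPTIVE_DELTA = 1e-6


@dataclass(frozen=True)
class CVConfig:
    """Cross-validation settings for penalty tuning.

    ``n_alphas`` log-spaced penalty values are auto-scaled from the data for
    the LASSO path; ``ridge_alphas`` is the log-spaced grid for ridge fits.
    """

    n_folds: int = 10
    seed: int = 0
    n_alphas: int = 100
    ridge_alpha_range: tuple[float, float] = (1e-4, 1e4)
    #: subset-performance metric c for the wrapper stage: "cv" scores a subset
    #: by the 10-fold CV RMSE of its tuned model, "train" by the tuned model's
    #: RMSE on the training rows.
    c_metric: str = "cv"

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.c_metric not in ("train", "cv"):
            raise ValueError("c_metric must be 'train' or 'cv'")

    def folds(self, n: int) -> KFold:
        return KFold(
            n_splits=min(self.n_folds, n), shuffle=True, random_state=self.seed
        )

    def ridge_alphas(self) -> np.ndarray:
        lo, hi = self.ridge_alpha_range
        return np.logspace(np.log10(lo), np.log10(hi), self.n_alphas)


@dataclass
class FittedModel:
    """A fitted linear model with original-scale coefficients.

    ``cv_performance`` is the 10-fold CV RMSE on the training data and is the
    performance value ``c`` used throughout the wrapper search.
    """

    technique: str
    intercept: float
    coefficients: dict[str, float]
    hyperparameters: dict = field(default_factory=dict)
    cv_performance: float = float("nan")
    train_performance: float = float("nan")
    scaling: dict = field(default_factory=dict)

    def performance(self, metric: str = "cv") -> float:
        """The subset-performance value c under the chosen metric."""
        if metric == "cv":
            return self.cv_performance
        if metric == "train":
            return self.train_performance
        raise ValueError("metric must be 'cv' or 'train'")

    @property
    def feature_names(self) -> list[str]:
        return list(self.coefficients)

    def selected_features(self, tol: float = SELECTION_TOL) -> list[str]:
        return [f for f, b in self.coefficients.items() if abs(b) > tol]

    def predict(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        if len(self.coefficients) == 0:
            n = len(X)
            return np.full(n, self.intercept)
        if isinstance(X, pd.DataFrame):
            missing = [f for f in self.coefficients if f not in X.columns]
            if missing:
                raise KeyError(f"prediction input lacks columns {missing}")
            mat = X[list(self.coefficients)].to_numpy(dtype=float)
        else:
            mat = np.asarray(X, dtype=float)
            if mat.shape[1] != len(self.coefficients):
                raise ValueError("prediction input has wrong number of columns")
        beta = np.array(list(self.coefficients.values()))
        return self.intercept + mat @ beta

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {
                "schema": 1,
                "technique": self.technique,
                "intercept": self.intercept,
                "coefficients": self.coefficients,
                "hyperparameters": self.hyperparameters,
                "cv_performance": self.cv_performance,
                "train_performance": self.train_performance,
                "scaling": self.scaling,
            },
            indent=2,
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @classmethod
    def from_json(cls, source: str | Path) -> "FittedModel":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        d = json.loads(text)
        return cls(
            technique=d["technique"],
            intercept=d["intercept"],
            coefficients=d["coefficients"],
            hyperparameters=d.get("hyperparameters", {}),
            cv_performance=d.get("cv_performance", float("nan")),
            train_performance=d.get("train_performance", float("nan")),
            scaling=d.get("scaling", {}),
        )


def rmse(y: np.ndarray, yhat: np.ndarray) -> float:
    """Root mean squared error."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape:
        raise ValueError(f"length mismatch: {y.shape} vs {yhat.shape}")
    if y.size == 0:
        raise ValueError("empty input")
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


def r_squared(y: np.ndarray, yhat: np.ndarray) -> float:
    """Coefficient of determination 1 - SS_res / SS_tot (may be negative)."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape:
        raise ValueError("length mismatch")
    if y.size < 2:
        raise ValueError("need at least two observations")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("outcome is constant; R^2 undefined")
    ss_res = float(np.sum((y - yhat) ** 2))
    return 1.0 - ss_res / ss_tot


def _as_matrix(X) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), list(X.columns)
    mat = np.asarray(X, dtype=float)
    if mat.ndim == 1:
        mat = mat.reshape(-1, 1)
    return mat, [f"x{i + 1}" for i in range(mat.shape[1])]


def _intercept_only(y: np.ndarray, technique: str, cv: CVConfig) -> FittedModel:
    n = len(y)
    # CV RMSE of predicting each held-out fold by the training-fold mean
    if n >= 2:
        errs = []
        for tr, te in cv.folds(n).split(np.zeros((n, 1))):
            errs.append(np.mean((y[te] - y[tr].mean()) ** 2))
        cv_perf = float(np.sqrt(np.mean(errs)))
    else:
        cv_perf = 0.0
    return FittedModel(
        technique=technique,
        intercept=float(np.mean(y)),
        coefficients={},
        cv_performance=cv_perf,
        train_performance=float(np.std(y)),
    )


def _cv_rmse_fixed(estimator, Xs: np.ndarray, y: np.ndarray, cv: CVConfig) -> float:
    yhat = cross_val_predict(estimator, Xs, y, cv=cv.folds(len(y)))
    return rmse(y, yhat)


def _ridge_cv_select(
    Xs: np.ndarray, yc: np.ndarray, alphas: np.ndarray, cv: CVConfig
) -> tuple[float, float]:
    """10-fold CV over the whole ridge path at once via per-fold SVD.

    Matches a fold-by-fold grid search (each fold re-centered, penalty
    ||y - Xb||^2 + alpha ||b||^2) but costs one SVD per fold instead of one
    solve per (fold, alpha). Returns (best alpha, CV RMSE at best alpha).
    """
    n = len(yc)
    fold_mse = np.zeros(len(alphas))
    splits = list(cv.folds(n).split(Xs))
    for tr, te in splits:
        xm = Xs[tr].mean(axis=0)
        ym = yc[tr].mean()
        U, s, Vt = np.linalg.svd(Xs[tr] - xm, full_matrices=False)
        uty = U.T @ (yc[tr] - ym)
        d = s[None, :] / (s[None, :] ** 2 + alphas[:, None])  # (n_alphas, r)
        coefs = (d * uty[None, :]) @ Vt  # (n_alphas, q)
        preds = ym + coefs @ (Xs[te] - xm).T  # (n_alphas, n_te)
        fold_mse += np.mean((preds - yc[te][None, :]) ** 2, axis=1)
    fold_mse /= len(splits)
    best = int(np.argmin(fold_mse))
    return float(alphas[best]), float(np.sqrt(fold_mse[best]))


def fit_model(
    X: pd.DataFrame | np.ndarray,
    y: pd.Series | np.ndarray,
    technique: str = "lasso",
    cv: CVConfig | None = None,
) -> FittedModel:
    """Fit one base learner with internally standardized features.

    Penalized techniques choose their penalty by 10-fold CV RMSE; OLS refuses
    rank-deficient problems (q >= n) and the caller should fall back to ridge.
    Degenerate inputs (no features, constant outcome) yield an intercept-only
    model.
    """
    if technique not in TECHNIQUES:
        raise ValueError(f"unknown technique {technique!r}; expected one of {TECHNIQUES}")
    cv = cv or CVConfig()
    mat, names = _as_matrix(X)
    yv = np.asarray(y, dtype=float)
    if mat.shape[0] != yv.shape[0]:
        raise ValueError("X and y have different numbers of rows")
    if np.isnan(mat).any() or np.isnan(yv).any():
        raise ValueError("missing values are not supported")
    n, q = mat.shape

    if q == 0:
        warnings.warn("no features supplied; fitting intercept-only model")
        return _intercept_only(yv, technique, cv)
    if np.ptp(yv) == 0.0:
        return _intercept_only(yv, technique, cv)
    if technique == "ols" and q >= n:
        raise ValueError(
            f"OLS is rank-deficient with q={q} features and n={n} samples; use ridge"
        )

    mean = mat.mean(axis=0)
    scale = mat.std(axis=0)
    scale[scale == 0.0] = 1.0
    Xs = (mat - mean) / scale
    ymean = yv.mean()
    yc = yv - ymean

    hyper: dict = {}
    if technique == "lasso":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            est = LassoCV(
                alphas=cv.n_alphas,  # count of auto-scaled log-spaced penalties
                cv=cv.folds(n),
                max_iter=5000,
                random_state=cv.seed,
            ).fit(Xs, yc)
        beta_std = est.coef_
        icept_std = est.intercept_
        hyper["alpha"] = float(est.alpha_)
        # mse_path_ rows follow alphas_; take the mean across folds at alpha_
        idx = int(np.where(est.alphas_ == est.alpha_)[0][0])
        cv_perf = float(np.sqrt(est.mse_path_[idx].mean()))
    elif technique == "ridge":
        alpha, cv_perf = _ridge_cv_select(Xs, yc, cv.ridge_alphas(), cv)
        est = Ridge(alpha=alpha).fit(Xs, yc)
        beta_std = est.coef_
        icept_std = est.intercept_
        hyper["alpha"] = alpha
    elif technique == "adaptive_ridge":
        pre_alpha, _ = _ridge_cv_select(Xs, yc, cv.ridge_alphas(), cv)
        pre = Ridge(alpha=pre_alpha).fit(Xs, yc)
        w = 1.0 / (np.abs(pre.coef_) + ADAPTIVE_DELTA)
        # penalty sum_j w_j beta_j^2 == plain ridge after scaling X_j by 1/sqrt(w_j)
        Xw = Xs / np.sqrt(w)
        alpha, cv_perf = _ridge_cv_select(Xw, yc, cv.ridge_alphas(), cv)
        est = Ridge(alpha=alpha).fit(Xw, yc)
        beta_std = est.coef_ / np.sqrt(w)
        icept_std = est.intercept_
        hyper["alpha"] = alpha
        hyper["weights_from"] = "ridge"
    else:  # ols
        est = LinearRegression().fit(Xs, yc)
        beta_std = est.coef_
        icept_std = est.intercept_
        cv_perf = _cv_rmse_fixed(LinearRegression(), Xs, yc, cv)

    beta = beta_std / scale
    intercept = float(ymean + icept_std - np.dot(beta, mean))
    train_perf = rmse(yv, intercept + mat @ beta)
    logger.debug("fit %s model: n=%d q=%d cv_rmse=%.4f", technique, n, q, cv_perf)
    return FittedModel(
        technique=technique,
        intercept=intercept,
        coefficients={f: float(b) for f, b in zip(names, beta)},
        hyperparameters=hyper,
        cv_performance=cv_perf,
        train_performance=train_perf,
        scaling={"mean": mean.tolist(), "scale": scale.tolist()},
    )
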