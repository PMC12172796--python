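"""The age-prediction model suite behind one uniform fit/predict contract.

Five algorithms with a frozen hyperparameter table: ordinary linear
regression, lasso (penalty chosen by internal 5-fold cross-validation over a
logarithmic grid, 100 000 max iterations), RBF support-vector regression,
XGBoost, and LightGBM.  The table is pinned in :data:`DEFAULT_HYPERPARAMETERS`
so results do not drift with library upgrades.  Feature standardisation is
applied inside the lasso and SVM pipelines (train-side parameters reused at
prediction time); the SVM additionally standardises the target, since kernel
methods are scale-sensitive in both arguments.  Plain linear regression and
the tree ensembles run on raw features.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
from scipy import linalg
from sklearn.compose import TransformedTargetRegressor
from sklearn.linear_model import Lasso, LassoCV, LinearRegression
from sklearn.model_selection import KFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

__all__ = ["ALGORITHMS", "DEFAULT_HYPERPARAMETERS", "ModelSpec", "FittedModel",
           "fit_model", "predict_ages", "save_model", "load_model"]

ALGORITHMS = ("linear", "lasso", "svm", "xgboost", "lightgbm")

#: Pinned hyperparameters.  Library defaults except where noted; ``n_jobs=1``
#: and explicit seeds everywhere for reproducibility.
DEFAULT_HYPERPARAMETERS: dict[str, dict[str, Any]] = {
    "linear": {},
    "lasso": {
        "alphas": "logspace(-4, 1, 30)",
        "cv_folds": 5,
        "max_iter": 100_000,  # raised from the library default to reach the
        # optimal-penalty tolerance on 204 collinear features
        "alpha": None,  # set to a number to skip cross-validation
    },
    "svm": {
        "kernel": "rbf",
        "C": 1.0,
        "epsilon": 0.1,
        "gamma": "scale",
        "standardize_target": True,
    },
    "xgboost": {"n_estimators": 100, "max_depth": 6, "learning_rate": 0.3,
                "tree_method": "hist", "n_jobs": 1},
    "lightgbm": {"n_estimators": 100, "num_leaves": 31, "learning_rate": 0.1,
                 "n_jobs": 1, "verbose": -1},
}


@dataclass(frozen=True)
class ModelSpec:
    """An algorithm name plus its frozen hyperparameter table and seed."""

    algorithm: str
    hyperparameters: tuple = ()  # overrides of the pinned table, as sorted items
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"unknown algorithm {self.algorithm!r}; expected {ALGORITHMS}")
        if isinstance(self.hyperparameters, dict):
            object.__setattr__(
                self, "hyperparameters", tuple(sorted(self.hyperparameters.items()))
            )

    def resolved(self) -> dict[str, Any]:
        params = dict(DEFAULT_HYPERPARAMETERS[self.algorithm])
        params.update(dict(self.hyperparameters))
        return params


@dataclass
class FittedModel:
    """A fitted estimator, its spec, and the training-time column order."""

    spec: ModelSpec
    estimator: Any
    columns: list[str]
    training_fitted: np.ndarray = field(repr=False, default=None)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return predict_ages(self, X)


def _build_estimator(spec: ModelSpec):
    params = spec.resolved()
    if spec.algorithm == "linear":
        return LinearRegression()
    if spec.algorithm == "lasso":
        if params["alpha"] is not None:
            reg = Lasso(alpha=float(params["alpha"]), max_iter=params["max_iter"])
        else:
            reg = LassoCV(
                alphas=np.logspace(-4, 1, 30),
                cv=KFold(params["cv_folds"], shuffle=True, random_state=spec.seed),
                max_iter=params["max_iter"],
            )
        return Pipeline([("scale", StandardScaler()), ("lasso", reg)])
    if spec.algorithm == "svm":
        svr = SVR(kernel=params["kernel"], C=params["C"],
                  epsilon=params["epsilon"], gamma=params["gamma"])
        pipe = Pipeline([("scale", StandardScaler()), ("svr", svr)])
        if params["standardize_target"]:
            return TransformedTargetRegressor(regressor=pipe, transformer=StandardScaler())
        return pipe
    if spec.algorithm == "xgboost":
        from xgboost import XGBRegressor

        return XGBRegressor(
            n_estimators=params["n_estimators"], max_depth=params["max_depth"],
            learning_rate=params["learning_rate"], tree_method=params["tree_method"],
            n_jobs=params["n_jobs"], random_state=spec.seed, verbosity=0,
        )
    if spec.algorithm == "lightgbm":
        from lightgbm import LGBMRegressor

        return LGBMRegressor(
            n_estimators=params["n_estimators"], num_leaves=params["num_leaves"],
            learning_rate=params["learning_rate"], n_jobs=params["n_jobs"],
            random_state=spec.seed, verbose=params["verbose"],
        )
    raise AssertionError(spec.algorithm)


def _check_full_rank(X: np.ndarray, columns: list[str]) -> None:
    """Raise with the names of the dependent columns if [1, X] is rank deficient."""
    design = np.column_stack([np.ones(len(X)), X])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        _, _, piv = linalg.qr(design, mode="economic", pivoting=True)
        dependent = sorted(
            columns[j - 1] for j in piv[rank:] if j > 0
        )
        raise ValueError(
            f"design matrix is rank deficient (rank {rank} < {design.shape[1]}); "
            f"linearly dependent columns: {dependent}"
        )


def fit_model(spec: ModelSpec, X: pd.DataFrame, y: pd.Series | np.ndarray) -> FittedModel:
    """Fit one model.  Deterministic given ``spec.seed``."""
    if not isinstance(X, pd.DataFrame):
        X = pd.DataFrame(np.asarray(X))
    y = np.asarray(y, dtype=float)
    if len(X) != len(y):
        raise ValueError("X and y have different lengths")
    values = X.to_numpy(dtype=float)
    if np.isnan(values).any() or np.isnan(y).any():
        raise ValueError("missing values in training data")
    if spec.algorithm == "linear":
        if len(X) < X.shape[1] + 1:
            raise ValueError(
                f"linear regression needs at least {X.shape[1] + 1} rows, got {len(X)}"
            )
        _check_full_rank(values, list(X.columns))
    estimator = _build_estimator(spec)
    estimator.fit(values, y)
    fitted = np.asarray(estimator.predict(values), dtype=float)
    return FittedModel(
        spec=spec, estimator=estimator, columns=[str(c) for c in X.columns],
        training_fitted=fitted,
    )


def predict_ages(model: FittedModel, X: pd.DataFrame) -> np.ndarray:
    """Predict ages; refuses matrices whose column order differs from training."""
    if isinstance(X, pd.DataFrame):
        cols = [str(c) for c in X.columns]
        if cols != model.columns:
            raise ValueError("feature columns differ from training order")
        values = X.to_numpy(dtype=float)
    else:
        values = np.asarray(X, dtype=float)
        if values.ndim != 2 or values.shape[1] != len(model.columns):
            raise ValueError("feature matrix width differs from training")
    if np.isnan(values).any():
        raise ValueError("missing values in prediction data")
    pred = np.asarray(model.estimator.predict(values), dtype=float)
    if not np.all(np.isfinite(pred)):
        raise FloatingPointError("non-finite predictions")
    return pred


def save_model(model: FittedModel, path: str | Path) -> None:
    """Persist a fitted model (spec, column order, learned parameters)."""
    with open(path, "wb") as fh:
        pickle.dump(
            {"spec": model.spec, "columns": model.columns,
             "estimator": model.estimator, "training_fitted": model.training_fitted},
            fh,
        )


def load_model(path: str | Path) -> FittedModel:
    with open(path, "rb") as fh:
        payload = pickle.load(fh)
    return FittedModel(
        spec=payload["spec"], estimator=payload["estimator"],
        columns=payload["columns"], training_fitted=payload["training_fitted"],
    )
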