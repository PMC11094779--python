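"""Model building: cross-validated scoring, greedy forward feature
selection, tree-ensemble regression, and mutation ranking.

Feature selection is bottom-up: starting from the empty set, each round
scores every remaining candidate feature joined to the current set by
10-fold cross-validated Pearson correlation of pooled out-of-fold
predictions, fixes the best one, and stops as soon as no candidate
strictly improves the correlation.  The fold partition is drawn once per
run so candidate scores are comparable; MSE is recorded at every step but
never drives selection.

Four tree-ensemble algorithms are supported, each with 300 estimators and
otherwise default hyperparameters: random_forest, extra_trees,
gradient_boosting, extreme_gradient_boosting.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Callable, Sequence

import joblib
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin, TransformerMixin, clone
from sklearn.ensemble import (
    ExtraTreesRegressor,
    GradientBoostingRegressor,
    RandomForestRegressor,
)
from sklearn.model_selection import KFold
from xgboost import XGBRegressor

from .errors import ConfigurationError, SchemaError

DEFAULT_SEED = 42
DEFAULT_N_ESTIMATORS = 300
DEFAULT_FOLDS = 10

ALGORITHMS = (
    "random_forest",
    "extra_trees",
    "gradient_boosting",
    "extreme_gradient_boosting",
)


def _make_estimator(algorithm: str, n_estimators: int, seed: int):
    if algorithm == "random_forest":
        return RandomForestRegressor(n_estimators=n_estimators, random_state=seed)
    if algorithm == "extra_trees":
        return ExtraTreesRegressor(n_estimators=n_estimators, random_state=seed)
    if algorithm == "gradient_boosting":
        return GradientBoostingRegressor(n_estimators=n_estimators, random_state=seed)
    if algorithm == "extreme_gradient_boosting":
        return XGBRegressor(n_estimators=n_estimators, random_state=seed, n_jobs=1)
    raise ConfigurationError(f"unknown algorithm {algorithm!r} (choose from {ALGORITHMS})")


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X
    return pd.DataFrame(np.asarray(X))


def _pooled_oof(X: np.ndarray, y: np.ndarray, folds, estimator) -> np.ndarray:
    pred = np.empty_like(y, dtype=float)
    for train_idx, test_idx in folds:
        est = clone(estimator)
        est.fit(X[train_idx], y[train_idx])
        pred[test_idx] = est.predict(X[test_idx])
    return pred


def _pearson(y: np.ndarray, pred: np.ndarray) -> float:
    # constant predictions leave the correlation undefined: flag with NaN,
    # which every comparison treats as -inf
    if np.std(pred) == 0 or np.std(y) == 0:
        return float("nan")
    return float(stats.pearsonr(y, pred)[0])


def _better(a: float, b: float) -> bool:
    """Is score a strictly better than b, with NaN ranked below everything?"""
    a_ = -np.inf if np.isnan(a) else a
    b_ = -np.inf if np.isnan(b) else b
    return a_ > b_


def cv_score(
    X,
    y,
    features: Sequence[str],
    algorithm: str = "random_forest",
    k: int = DEFAULT_FOLDS,
    seed: int = DEFAULT_SEED,
    n_estimators: int = DEFAULT_N_ESTIMATORS,
) -> tuple[float, float]:
    """Pooled out-of-fold (Pearson r, MSE) of a k-fold cross-validation."""
    Xf = _as_frame(X)
    y = np.asarray(y, dtype=float)
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(y) < k:
        raise ValueError(f"need at least k={k} rows, got {len(y)}")
    folds = list(KFold(n_splits=k, shuffle=True, random_state=seed).split(Xf))
    pred = _pooled_oof(
        Xf.loc[:, list(features)].to_numpy(dtype=float),
        y,
        folds,
        _make_estimator(algorithm, n_estimators, seed),
    )
    return _pearson(y, pred), float(np.mean((y - pred) ** 2))


@dataclasses.dataclass
class SelectionStep:
    feature: str
    cv_pearson: float
    cv_mse: float


@dataclasses.dataclass
class SelectionTrace:
    steps: list[SelectionStep]

    @property
    def selected(self) -> list[str]:
        return [s.feature for s in self.steps]


class GreedyForwardSelector(TransformerMixin, BaseEstimator):
    """Bottom-up greedy feature selector scored by CV Pearson correlation.

    Fitted attributes: ``selected_features_`` (ordered), ``trace_`` (a
    SelectionTrace with the per-step CV Pearson and MSE), ``cv_pearson_``.
    Ties between candidates break by column order.
    """

    def __init__(
        self,
        algorithm: str = "random_forest",
        k: int = DEFAULT_FOLDS,
        seed: int = DEFAULT_SEED,
        n_estimators: int = DEFAULT_N_ESTIMATORS,
        max_features: int | None = None,
    ):
        self.algorithm = algorithm
        self.k = k
        self.seed = seed
        self.n_estimators = n_estimators
        self.max_features = max_features

    def fit(self, X, y):
        Xf = _as_frame(X)
        y = np.asarray(y, dtype=float)
        if Xf.shape[1] < 1:
            raise ConfigurationError("need at least one candidate feature")
        names = list(Xf.columns)
        data = {n: Xf[n].to_numpy(dtype=float) for n in names}
        folds = list(KFold(n_splits=self.k, shuffle=True, random_state=self.seed).split(Xf))
        template = _make_estimator(self.algorithm, self.n_estimators, self.seed)

        selected: list[str] = []
        steps: list[SelectionStep] = []
        best_score = float("nan")  # ranked below any real score
        limit = self.max_features or len(names)
        while len(selected) < limit:
            round_best = None
            for cand in names:
                if cand in selected:
                    continue
                cols = np.column_stack([data[f] for f in selected + [cand]])
                pred = _pooled_oof(cols, y, folds, template)
                r = _pearson(y, pred)
                mse = float(np.mean((y - pred) ** 2))
                if round_best is None or _better(r, round_best[1]):
                    round_best = (cand, r, mse)
            if round_best is None or not _better(round_best[1], best_score):
                break
            selected.append(round_best[0])
            best_score = round_best[1]
            steps.append(SelectionStep(*round_best))
        self.feature_names_in_ = np.asarray(names, dtype=object)
        self.n_features_in_ = len(names)
        self.selected_features_ = selected
        self.trace_ = SelectionTrace(steps)
        self.cv_pearson_ = best_score
        self.cv_mse_ = steps[-1].cv_mse if steps else float("nan")
        return self

    def transform(self, X):
        Xf = _as_frame(X)
        missing = [f for f in self.selected_features_ if f not in Xf.columns]
        if missing:
            raise SchemaError(f"missing selected features: {missing}")
        return Xf.loc[:, self.selected_features_]

    def get_feature_names_out(self, input_features=None):
        return np.asarray(self.selected_features_, dtype=object)


class StabilityRegressor(RegressorMixin, BaseEstimator):
    """Tree-ensemble dTm regressor over a fixed, ordered feature list.

    ``features=None`` uses every column of the training frame.  Predicting
    validates that all stored features are present and reorders columns to
    the training order.
    """

    def __init__(
        self,
        algorithm: str = "random_forest",
        n_estimators: int = DEFAULT_N_ESTIMATORS,
        seed: int = DEFAULT_SEED,
        features: Sequence[str] | None = None,
    ):
        self.algorithm = algorithm
        self.n_estimators = n_estimators
        self.seed = seed
        self.features = features

    def fit(self, X, y):
        Xf = _as_frame(X)
        y = np.asarray(y, dtype=float)
        if len(y) < 2:
            raise ValueError("need at least 2 training rows")
        feats = list(self.features) if self.features is not None else list(Xf.columns)
        if not feats:
            raise ConfigurationError("empty feature list")
        missing = [f for f in feats if f not in Xf.columns]
        if missing:
            raise SchemaError(f"training frame lacks features: {missing}")
        self.selected_features_ = feats
        self.model_ = _make_estimator(self.algorithm, self.n_estimators, self.seed)
        self.model_.fit(Xf.loc[:, feats].to_numpy(dtype=float), y)
        self.n_features_in_ = Xf.shape[1]
        return self

    def predict(self, X) -> np.ndarray:
        Xf = _as_frame(X)
        missing = [f for f in self.selected_features_ if f not in Xf.columns]
        if missing:
            raise SchemaError(f"missing features at prediction time: {missing}")
        return self.model_.predict(
            Xf.loc[:, self.selected_features_].to_numpy(dtype=float)
        )

    # -- persistence -------------------------------------------------------
    def save(self, path: str | Path) -> None:
        """Binary bundle plus a JSON sidecar describing the model."""
        path = Path(path)
        joblib.dump(self, path)
        sidecar = {
            "algorithm": self.algorithm,
            "n_estimators": self.n_estimators,
            "seed": self.seed,
            "selected_features": list(self.selected_features_),
            "format_version": 1,
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))

    @staticmethod
    def load(path: str | Path) -> "StabilityRegressor":
        model = joblib.load(path)
        if not isinstance(model, StabilityRegressor):
            raise ConfigurationError(f"{path} is not a StabilityRegressor bundle")
        return model


def greedy_forward_selection(
    X,
    y,
    algorithm: str = "random_forest",
    k: int = DEFAULT_FOLDS,
    seed: int = DEFAULT_SEED,
    n_estimators: int = DEFAULT_N_ESTIMATORS,
) -> SelectionTrace:
    """Functional wrapper over GreedyForwardSelector; returns the trace."""
    sel = GreedyForwardSelector(
        algorithm=algorithm, k=k, seed=seed, n_estimators=n_estimators
    ).fit(X, y)
    return sel.trace_


def train(
    X,
    y,
    features: Sequence[str] | None = None,
    algorithm: str = "random_forest",
    n_estimators: int = DEFAULT_N_ESTIMATORS,
    seed: int = DEFAULT_SEED,
) -> StabilityRegressor:
    """Fit a tree ensemble on the given features (all columns if None)."""
    return StabilityRegressor(
        algorithm=algorithm, n_estimators=n_estimators, seed=seed, features=features
    ).fit(X, y)


def predict_and_rank(model: StabilityRegressor, X, keys: Sequence | None = None):
    """Predictions sorted by descending dTm; ties keep input order.

    Positive predictions are read as stabilizing.  ``keys`` (e.g.
    MutationSpec objects) ride along with the predictions; row indices are
    used when omitted.
    """
    Xf = _as_frame(X)
    pred = model.predict(Xf)
    if keys is None:
        keys = list(range(len(pred)))
    order = sorted(range(len(pred)), key=lambda i: -pred[i])  # stable
    return [(keys[i], float(pred[i])) for i in order]


def feature_importance(
    model: StabilityRegressor,
    method: str | Callable = "impurity",
    X=None,
    y=None,
    seed: int = DEFAULT_SEED,
) -> pd.Series:
    """Per-feature importance of a trained model.

    ``method`` is pluggable: "impurity" uses the ensemble's own
    impurity-based importances; "permutation" uses permutation importance
    on (X, y); a callable receives (fitted_estimator, X, y) and must return
    an array aligned with the model's feature order — the hook for
    attribution engines such as SHAP-style explainers.
    """
    feats = model.selected_features_
    if callable(method):
        values = np.asarray(method(model.model_, X, y))
    elif method == "impurity":
        values = np.asarray(model.model_.feature_importances_)
    elif method == "permutation":
        if X is None or y is None:
            raise ConfigurationError("permutation importance needs X and y")
        from sklearn.inspection import permutation_importance

        Xf = _as_frame(X)
        res = permutation_importance(
            model.model_,
            Xf.loc[:, feats].to_numpy(dtype=float),
            np.asarray(y, dtype=float),
            random_state=seed,
        )
        values = res.importances_mean
    else:
        raise ConfigurationError(f"unknown importance method {method!r}")
    return pd.Series(values, index=feats).sort_values(ascending=False)
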