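"""Quality-score regression: training, tuning, selection, validation.

The reference protocol is an RBF-kernel support-vector regressor on
z-scored features, tuned by grid search (5-fold CV over C, γ, ε), with
permutation importance ranking the 39 features and the model retrained
on the 25 most important.  Random-forest, MLP and (optional) XGBoost
backends are available for comparison.  Predictions are clamped to the
[0, 4] score range.
"""

from __future__ import annotations

import datetime
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.inspection import permutation_importance as _sk_perm_importance
from sklearn.model_selection import GridSearchCV, KFold, RandomizedSearchCV
from sklearn.neural_network import MLPRegressor
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

from ._errors import ConfigError, FormatError, ValidationError
from .features import FEATURE_NAMES
from .metrics import EvalReport, ScorePair, evaluate_all

__all__ = [
    "SplitSpec",
    "ModelConfig",
    "TrainedModel",
    "ImportanceReport",
    "CVReport",
    "split_dataset",
    "train",
    "predict",
    "permutation_importance",
    "select_top_k",
    "cross_validate",
    "save_model",
    "load_model",
    "DEFAULT_SVR_GRID",
]

SCORE_MIN, SCORE_MAX = 0.0, 4.0
MODEL_FORMAT_VERSION = "ctiqa-model-1"

#: Default RBF-SVR search space; grid search is exhaustive over it,
#: random search draws 25 configurations uniformly.
DEFAULT_SVR_GRID: dict[str, list] = {
    "C": [0.1, 1.0, 10.0, 100.0],
    "gamma": ["scale", 0.001, 0.01, 0.1],
    "epsilon": [0.01, 0.1, 0.2],
}
RANDOM_SEARCH_BUDGET = 25


@dataclass(frozen=True)
class SplitSpec:
    """Train/test partition parameters (default 80/20)."""

    train_fraction: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValidationError(
                f"train_fraction must be in (0,1), got {self.train_fraction}"
            )


@dataclass(frozen=True)
class ModelConfig:
    """Backend and hyperparameter-search configuration."""

    backend: str = "svr"
    search: str = "grid"  # none | random | grid
    search_space: dict | None = None
    cv_folds_for_search: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.backend not in ("svr", "random_forest", "mlp", "xgboost"):
            raise ConfigError(f"unknown backend '{self.backend}'")
        if self.search not in ("none", "random", "grid"):
            raise ConfigError(f"unknown search mode '{self.search}'")
        if self.search != "none" and self.search_space is not None \
                and len(self.search_space) == 0:
            raise ConfigError("empty search space with search enabled")


@dataclass
class TrainedModel:
    """Fitted scaler+regressor pipeline with its feature list and metadata."""

    backend: str
    pipeline: Pipeline
    selected_features: list[str]
    best_hyperparameters: dict
    n_train: int
    seed: int
    timestamp: str = field(default_factory=lambda: datetime.datetime.now().isoformat())
    format_version: str = MODEL_FORMAT_VERSION

    @property
    def scaler(self) -> StandardScaler:
        return self.pipeline.named_steps["scaler"]


@dataclass(frozen=True)
class ImportanceReport:
    """Permutation importances (MSE increase) for every model feature."""

    importances: dict[str, float]
    stds: dict[str, float]
    method: str = "permutation"
    n_repeats: int = 10
    seed: int = 0


@dataclass(frozen=True)
class CVReport:
    """Per-fold and aggregate evaluation over a k-fold partition."""

    folds: int
    per_fold: list[EvalReport]
    aggregate: EvalReport


def _feature_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c != "score"]


def _require_scores(table: pd.DataFrame) -> np.ndarray:
    if "score" not in table.columns:
        raise ValidationError("table has no 'score' column")
    return table["score"].to_numpy(dtype=np.float64)


def split_dataset(table: pd.DataFrame, spec: SplitSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Seed-driven shuffle split into round(n·f) train and n − round(n·f)
    test rows; the partition is disjoint and exhaustive."""
    _require_scores(table)
    n = len(table)
    if n < 10:
        raise ValidationError(f"need ≥ 10 rows to split, got {n}")
    n_train = int(round(n * spec.train_fraction))
    rng = np.random.default_rng(spec.seed)
    order = rng.permutation(n)
    train_idx, test_idx = np.sort(order[:n_train]), np.sort(order[n_train:])
    return table.iloc[train_idx].reset_index(drop=True), \
        table.iloc[test_idx].reset_index(drop=True)


def _make_estimator(config: ModelConfig):
    if config.backend == "svr":
        return SVR(kernel="rbf")
    if config.backend == "random_forest":
        return RandomForestRegressor(n_estimators=200, random_state=config.seed)
    if config.backend == "mlp":
        return MLPRegressor(hidden_layer_sizes=(64, 32), max_iter=2000,
                            random_state=config.seed)
    if config.backend == "xgboost":
        try:
            from xgboost import XGBRegressor
        except ImportError as exc:
            raise ConfigError(
                "backend 'xgboost' requires the xgboost package; "
                "install it or choose another backend"
            ) from exc
        return XGBRegressor(random_state=config.seed, n_estimators=300)
    raise ConfigError(config.backend)


def _search_space(config: ModelConfig) -> dict:
    if config.search_space is not None:
        return config.search_space
    if config.backend == "svr":
        return dict(DEFAULT_SVR_GRID)
    if config.backend == "random_forest":
        return {"max_depth": [None, 5, 10, 20], "min_samples_leaf": [1, 2, 5]}
    if config.backend == "mlp":
        return {"alpha": [1e-4, 1e-3, 1e-2]}
    if config.backend == "xgboost":
        return {"max_depth": [3, 5, 7], "learning_rate": [0.05, 0.1, 0.3]}
    raise ConfigError(config.backend)


def train(table: pd.DataFrame, config: ModelConfig,
          feature_subset: list[str] | None = None) -> TrainedModel:
    """Fit a quality-score regressor on a feature table.

    Features are z-scored with training statistics inside the pipeline.
    With search enabled, hyperparameters minimizing CV MSE over the
    search space are selected (exhaustive for grid, 25 seeded uniform
    draws for random) before the final refit on all rows.
    """
    y = _require_scores(table)
    features = feature_subset if feature_subset is not None else _feature_columns(table)
    missing = [f for f in features if f not in table.columns]
    if missing:
        raise ValidationError(f"table is missing feature columns: {missing}")
    X = table[features].to_numpy(dtype=np.float64)
    if len(X) < 2:
        raise ValidationError("need at least 2 training rows")
    if not np.all(np.isfinite(X)):
        bad = [features[j] for j in np.where(~np.isfinite(X).all(axis=0))[0]]
        raise ValidationError(f"non-finite values in features: {bad}")
    if y.min() < SCORE_MIN or y.max() > SCORE_MAX:
        raise ValidationError("scores outside [0,4]")

    pipe = Pipeline([("scaler", StandardScaler()), ("reg", _make_estimator(config))])
    best_params: dict = {}
    if config.search != "none":
        space = {f"reg__{k}": v for k, v in _search_space(config).items()}
        cv = KFold(n_splits=config.cv_folds_for_search, shuffle=True,
                   random_state=config.seed)
        if config.search == "grid":
            searcher = GridSearchCV(pipe, space, cv=cv,
                                    scoring="neg_mean_squared_error", n_jobs=1)
        else:
            searcher = RandomizedSearchCV(
                pipe, space, n_iter=RANDOM_SEARCH_BUDGET, cv=cv,
                scoring="neg_mean_squared_error",
                random_state=config.seed, n_jobs=1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            searcher.fit(X, y)
        pipe = searcher.best_estimator_
        best_params = {k.removeprefix("reg__"): v
                       for k, v in searcher.best_params_.items()}
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pipe.fit(X, y)

    return TrainedModel(
        backend=config.backend,
        pipeline=pipe,
        selected_features=list(features),
        best_hyperparameters=best_params,
        n_train=len(X),
        seed=config.seed,
    )


def _matrix_from(model: TrainedModel, data) -> np.ndarray:
    """Assemble the model's feature matrix from a table or vector list."""
    if isinstance(data, pd.DataFrame):
        missing = [f for f in model.selected_features if f not in data.columns]
        if missing:
            raise ValidationError(f"input is missing features: {missing}")
        return data[model.selected_features].to_numpy(dtype=np.float64)
    rows = []
    for vec in data:
        missing = [f for f in model.selected_features if f not in vec]
        if missing:
            raise ValidationError(f"feature vector is missing: {missing}")
        rows.append([vec[f] for f in model.selected_features])
    return np.asarray(rows, dtype=np.float64)


def predict(model: TrainedModel, data) -> np.ndarray:
    """Predict quality scores, clamped to [0, 4].

    ``data`` may be a feature table (DataFrame) or a list of feature
    vectors (name→value mappings); order is preserved.
    """
    X = _matrix_from(model, data)
    if X.shape[0] == 0:
        return np.empty(0, dtype=np.float64)
    raw = model.pipeline.predict(X)
    return np.clip(raw, SCORE_MIN, SCORE_MAX)


def permutation_importance(model: TrainedModel, table: pd.DataFrame,
                           n_repeats: int = 10, seed: int = 0) -> ImportanceReport:
    """Permutation importance: mean MSE increase when one feature is
    shuffled, over ``n_repeats`` seeded permutations."""
    if n_repeats < 1:
        raise ConfigError(f"n_repeats must be ≥ 1, got {n_repeats}")
    y = _require_scores(table)
    X = _matrix_from(model, table)
    res = _sk_perm_importance(
        model.pipeline, X, y, n_repeats=n_repeats,
        random_state=seed, scoring="neg_mean_squared_error", n_jobs=1,
    )
    names = model.selected_features
    return ImportanceReport(
        importances={n: float(v) for n, v in zip(names, res.importances_mean)},
        stds={n: float(v) for n, v in zip(names, res.importances_std)},
        n_repeats=n_repeats,
        seed=seed,
    )


def select_top_k(report: ImportanceReport, k: int = 25) -> list[str]:
    """The k most important features, descending; ties break by the
    canonical feature order."""
    names = list(report.importances)
    if k > len(names):
        raise ValidationError(f"k={k} exceeds {len(names)} available features")
    canon = {n: i for i, n in enumerate(FEATURE_NAMES)}
    ranked = sorted(names,
                    key=lambda n: (-report.importances[n],
                                   canon.get(n, len(canon)), n))
    return ranked[:k]


def cross_validate(table: pd.DataFrame, config: ModelConfig,
                   folds: int = 100, seed: int = 0,
                   feature_subset: list[str] | None = None) -> CVReport:
    """k-fold cross-validation with per-fold metric reports.

    Folds are a seeded shuffle partition into near-equal parts.  The
    aggregate is the unweighted mean of each metric over the folds in
    which it is defined; rank metrics are missing for folds of size 1
    (leave-one-out) and excluded from the aggregate.
    """
    y = _require_scores(table)
    n = len(table)
    if folds > n:
        raise ValidationError(f"folds={folds} > n={n}")
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    per_fold: list[EvalReport] = []
    preds = np.empty(n)
    for train_idx, test_idx in kf.split(np.arange(n)):
        m = train(table.iloc[train_idx], config, feature_subset=feature_subset)
        p = predict(m, table.iloc[test_idx])
        preds[test_idx] = p
        if len(test_idx) >= 2:
            per_fold.append(evaluate_all(ScorePair(predicted=p, actual=y[test_idx])))
        else:
            err = float(p[0] - y[test_idx][0])
            per_fold.append(EvalReport(
                mse=err**2, r_squared=None, mae=abs(err), rmse=abs(err),
                explained_variance=None, median_absolute_error=abs(err),
                plcc=None, srocc=None, klcc=None))
    agg = {}
    for name in per_fold[0].as_dict():
        vals = [getattr(r, name) for r in per_fold if getattr(r, name) is not None]
        agg[name] = float(np.mean(vals)) if vals else None
    return CVReport(folds=folds, per_fold=per_fold, aggregate=EvalReport(**agg))


def save_model(model: TrainedModel, path: str | Path) -> None:
    """Serialize a model bundle, with a clear-text JSON sidecar listing
    the selected features and hyperparameters for auditability."""
    path = Path(path)
    joblib.dump({
        "format_version": MODEL_FORMAT_VERSION,
        "backend": model.backend,
        "pipeline": model.pipeline,
        "selected_features": model.selected_features,
        "best_hyperparameters": model.best_hyperparameters,
        "n_train": model.n_train,
        "seed": model.seed,
        "timestamp": model.timestamp,
    }, path)
    sidecar = {
        "format_version": MODEL_FORMAT_VERSION,
        "backend": model.backend,
        "selected_features": model.selected_features,
        "best_hyperparameters": {k: str(v) for k, v in
                                 model.best_hyperparameters.items()},
        "n_train": model.n_train,
        "seed": model.seed,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def load_model(path: str | Path) -> TrainedModel:
    """Load a model bundle saved by :func:`save_model`."""
    try:
        blob = joblib.load(path)
    except Exception as exc:
        raise FormatError(f"cannot read model file {path}: {exc}") from exc
    if not isinstance(blob, dict) or "format_version" not in blob:
        raise FormatError(f"{path} is not a ctiqa model bundle")
    if blob["format_version"] != MODEL_FORMAT_VERSION:
        raise FormatError(
            f"model format {blob['format_version']!r} not supported "
            f"(expected {MODEL_FORMAT_VERSION!r})"
        )
    return TrainedModel(
        backend=blob["backend"],
        pipeline=blob["pipeline"],
        selected_features=blob["selected_features"],
        best_hyperparameters=blob["best_hyperparameters"],
        n_train=blob["n_train"],
        seed=blob["seed"],
        timestamp=blob["timestamp"],
    )
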