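"""Cross-validated brain-age estimation on regional volume features.

A gradient-boosted tree ensemble is trained to predict chronological age
from (any subset of) the regional volumes; out-of-fold predictions give
each participant a brain-age estimate, and the brain-age delta is
predicted minus chronological age.  The boosted-tree engine is pluggable:
``"xgboost"`` is the reference engine (defaults: max depth 6, 140
estimators, learning rate 0.1); ``"hist"`` is scikit-learn's histogram
gradient booster, used as a fast engine for simulation studies.

Fold assignment is seeded and can be shared across feature sets so that
feature-set-specific deltas are computed on identical partitions and stay
comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import HistGradientBoostingRegressor
from sklearn.inspection import permutation_importance as _sk_permutation_importance
from sklearn.model_selection import ParameterSampler


@dataclass
class ModelParams:
    max_depth: int = 6
    n_estimators: int = 140
    learning_rate: float = 0.1
    n_folds: int = 10
    n_search_iterations: int = 10
    seed: int = 0
    engine: str = "xgboost"

    def __post_init__(self):
        if min(self.max_depth, self.n_estimators, self.n_folds, self.n_search_iterations) <= 0:
            raise ValueError("ModelParams integer fields must be positive")
        if not 0.0 < self.learning_rate <= 1.0:
            raise ValueError("learning_rate must lie in (0, 1]")


#: Fast engine configuration for Monte-Carlo studies.
FAST_PARAMS = ModelParams(max_depth=3, n_estimators=60, learning_rate=0.1, engine="hist")

#: Default randomized-search space for hyperparameter tuning.
DEFAULT_SEARCH_SPACE = {
    "max_depth": list(range(3, 13)),
    "n_estimators": list(range(60, 221, 40)),
    "learning_rate": [0.1, 0.01, 0.05],
}


@dataclass
class BrainAgeResult:
    """Out-of-fold predictions for one feature set."""

    table: pd.DataFrame  # participant_id index; predicted_age, delta, fold
    feature_set: str = ""
    params: ModelParams | None = None

    @property
    def delta(self) -> pd.Series:
        return self.table["delta"]

    @property
    def predicted_age(self) -> pd.Series:
        return self.table["predicted_age"]


@dataclass
class PredictionMetrics:
    n_features: int
    r: float
    r_ci: tuple[float, float]
    r2: float
    rmse: float
    mae: float
    n: int

    def as_dict(self) -> dict:
        return {
            "N_feat": self.n_features, "r": self.r,
            "r_ci_low": self.r_ci[0], "r_ci_high": self.r_ci[1],
            "R2": self.r2, "RMSE": self.rmse, "MAE": self.mae, "n": self.n,
        }


@dataclass
class FeatureImportance:
    table: pd.DataFrame  # feature index; importance_mean, importance_sd
    n_repeats: int = 0
    seed: int = 0


def make_estimator(params: ModelParams):
    if params.engine == "xgboost":
        from xgboost import XGBRegressor

        return XGBRegressor(
            max_depth=params.max_depth,
            n_estimators=params.n_estimators,
            learning_rate=params.learning_rate,
            objective="reg:squarederror",
            random_state=params.seed,
            n_jobs=1,
            tree_method="hist",
            verbosity=0,
        )
    if params.engine == "hist":
        return HistGradientBoostingRegressor(
            max_depth=params.max_depth,
            max_iter=params.n_estimators,
            learning_rate=params.learning_rate,
            random_state=params.seed,
        )
    raise ValueError(f"unknown engine {params.engine!r}")


def assign_folds(index: pd.Index, n_folds: int, seed: int) -> pd.Series:
    """Seeded balanced random partition into folds 0..n_folds-1."""
    n = len(index)
    if n < n_folds:
        raise ValueError(f"n={n} participants but {n_folds} folds requested")
    rng = np.random.default_rng(seed)
    folds = np.tile(np.arange(n_folds), n // n_folds + 1)[:n]
    rng.shuffle(folds)
    return pd.Series(folds, index=index, name="fold")


def crossval_predict(
    features: pd.DataFrame,
    age: pd.Series,
    params: ModelParams,
    folds: pd.Series | None = None,
    feature_set: str = "",
) -> BrainAgeResult:
    """Out-of-fold age predictions and deltas under k-fold cross-validation.

    Each participant's prediction comes from a model trained without their
    fold.  ``folds`` may be supplied to share one partition across feature
    sets; otherwise a seeded partition is drawn from ``params.seed``.
    """
    if not features.index.equals(age.index):
        raise ValueError("features and age must share the same participant index")
    if features.shape[1] == 0:
        raise ValueError("empty feature set")
    if folds is None:
        folds = assign_folds(features.index, params.n_folds, params.seed)
    pred = pd.Series(np.nan, index=features.index)
    X = features.to_numpy(dtype=float)
    y = age.to_numpy(dtype=float)
    for f in np.unique(folds.to_numpy()):
        test = (folds == f).to_numpy()
        est = make_estimator(params)
        est.fit(X[~test], y[~test])
        pred[test] = est.predict(X[test])
    table = pd.DataFrame(
        {"predicted_age": pred, "delta": pred - age, "fold": folds},
        index=features.index,
    )
    return BrainAgeResult(table=table, feature_set=feature_set, params=params)


def fit_then_predict(
    train_features: pd.DataFrame,
    train_age: pd.Series,
    test_features: pd.DataFrame,
    params: ModelParams,
):
    """Train on one sample, predict ages for another (no refitting on test).

    Returns ``(predicted, model)`` with one prediction per test row.
    """
    overlap = train_features.index.intersection(test_features.index)
    if len(overlap) > 0:
        raise ValueError(f"train and test ids overlap ({len(overlap)} ids)")
    if list(train_features.columns) != list(test_features.columns):
        raise ValueError("train/test feature columns differ")
    est = make_estimator(params)
    est.fit(train_features.to_numpy(dtype=float), train_age.to_numpy(dtype=float))
    if len(test_features) == 0:
        return pd.Series(dtype=float, index=test_features.index), est
    pred = est.predict(test_features.to_numpy(dtype=float))
    return pd.Series(pred, index=test_features.index, name="predicted_age"), est


def tune_params(
    features: pd.DataFrame,
    age: pd.Series,
    search_space: dict | None = None,
    n_folds: int = 10,
    n_iterations: int = 10,
    seed: int = 0,
    engine: str = "xgboost",
) -> ModelParams:
    """Randomized hyperparameter search scored by cross-validated MAE.

    Samples ``n_iterations`` candidates from ``search_space`` and returns the
    one with the lowest mean out-of-fold absolute error (ties: first seen).
    """
    space = search_space or DEFAULT_SEARCH_SPACE
    if not space or any(len(v) == 0 for v in space.values()):
        raise ValueError("search_space must be non-empty")
    if len(features) < n_folds:
        raise ValueError("fewer participants than folds")
    folds = assign_folds(features.index, n_folds, seed)
    best: tuple[float, ModelParams] | None = None
    for cand in ParameterSampler(space, n_iter=n_iterations, random_state=seed):
        params = ModelParams(
            n_folds=n_folds, n_search_iterations=n_iterations, seed=seed,
            engine=engine, **cand,
        )
        res = crossval_predict(features, age, params, folds=folds)
        mae = float((res.predicted_age - age).abs().mean())
        if best is None or mae < best[0]:
            best = (mae, params)
    return best[1]


def metrics(result: BrainAgeResult, age: pd.Series, n_features: int | None = None) -> PredictionMetrics:
    """Accuracy of predicted vs chronological age.

    Pearson r with a Fisher-z 95% CI, R^2 = 1 - SSres/SStot, RMSE and MAE
    in years.
    """
    pred = result.predicted_age.loc[age.index]
    n = len(pred)
    if n < 3:
        raise ValueError("need at least 3 predictions")
    y = age.to_numpy(dtype=float)
    if np.var(y) == 0:
        raise ValueError("zero variance in chronological age")
    p = pred.to_numpy(dtype=float)
    r = float(np.corrcoef(p, y)[0, 1])
    z = np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15))
    halfwidth = stats.norm.ppf(0.975) / np.sqrt(n - 3)
    ci = (float(np.tanh(z - halfwidth)), float(np.tanh(z + halfwidth)))
    resid = y - p
    r2 = float(1.0 - (resid**2).sum() / ((y - y.mean()) ** 2).sum())
    return PredictionMetrics(
        n_features=n_features if n_features is not None else -1,
        r=r, r_ci=ci, r2=r2,
        rmse=float(np.sqrt((resid**2).mean())),
        mae=float(np.abs(resid).mean()),
        n=n,
    )


def permutation_feature_importance(
    model,
    features: pd.DataFrame,
    age: pd.Series,
    n_repeats: int = 10,
    seed: int = 0,
) -> FeatureImportance:
    """Mean drop in R^2 when each feature column is shuffled in turn."""
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    out = _sk_permutation_importance(
        model,
        features.to_numpy(dtype=float),
        age.to_numpy(dtype=float),
        n_repeats=n_repeats,
        random_state=seed,
        scoring="r2",
    )
    table = pd.DataFrame(
        {"importance_mean": out.importances_mean, "importance_sd": out.importances_std},
        index=pd.Index(features.columns, name="feature"),
    ).sort_values("importance_mean", ascending=False)
    return FeatureImportance(table=table, n_repeats=n_repeats, seed=seed)


def top_features(importance: FeatureImportance, k: int = 4) -> list[str]:
    return list(importance.table.index[:k])
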