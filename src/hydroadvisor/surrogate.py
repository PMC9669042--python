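"""Boosted-tree surrogate for 24 h urine osmolality.

Fits and compares regressors that map easily collectable features (age, sex,
anthropometrics, food and fluid intakes) to 24 h urine osmolality, ranks
candidate features by their share of total split gain, prunes to a
deployable feature policy that excludes urine-derived measurements, and
quantifies error as mean absolute error (MAE) with a repeat-split stability
assessment.

Learner kinds
-------------
``gbt``  extreme gradient boosting (xgboost) — the primary surrogate
``rf``   random forest (scikit-learn) — comparator
``gbm``  gradient boosting machine (scikit-learn) — comparator

All three route missing feature values natively through tree splits, so no
imputation step exists anywhere in the pipeline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import HistGradientBoostingRegressor, RandomForestRegressor
from sklearn.model_selection import GroupKFold
from xgboost import XGBRegressor

__all__ = [
    "RESPONSE",
    "DEFAULT_ALLOWED_FEATURES",
    "FeatureImportanceTable",
    "FeaturePolicy",
    "SurrogateModel",
    "StabilityReport",
    "mae",
    "rank_features",
    "prune_features",
    "fit_surrogate",
    "compare_learners",
    "save_model",
    "load_model",
]

RESPONSE = "urine_osm"
ID_COLUMN = "participant_id"

#: deployable default: information the general population can self-report
DEFAULT_ALLOWED_FEATURES = [
    "age",
    "sex",
    "height",
    "weight",
    "bmi",
    "plain_water",
    "total_fluid_intake",
    "total_water_intake",
    "energy_kcal",
    "protein_g",
    "sodium_mg",
    "food_moisture_mL",
]

LEARNER_KINDS = ("gbt", "rf", "gbm")

#: seeded random-search space per learner (standard boosted/forest practice)
DEFAULT_SEARCH_SPACE: dict[str, dict] = {
    "gbt": {
        "max_depth": (3, 8),
        "learning_rate": (0.03, 0.3),
        "n_estimators": (100, 600),
        "subsample": (0.7, 1.0),
    },
    "gbm": {
        "max_depth": (2, 8),
        "learning_rate": (0.03, 0.3),
        "max_iter": (100, 400),
        "l2_regularization": (0.0, 1.0),
    },
    "rf": {
        "max_depth": (4, 20),
        "n_estimators": (100, 400),
        "max_features": (0.4, 1.0),
    },
}


def mae(actual: Sequence[float], predicted: Sequence[float]) -> float:
    """Mean absolute error (1/N) sum |y_i - yhat_i|, in mOsm/kg."""
    a = np.asarray(actual, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if a.shape != p.shape or a.ndim != 1:
        raise ValueError("actual and predicted must be equal-length 1-D sequences")
    if a.size == 0:
        raise ValueError("MAE of empty sequences is undefined")
    if np.isnan(a).any() or np.isnan(p).any():
        raise ValueError("MAE inputs must not contain missing values")
    return float(np.mean(np.abs(a - p)))


def _design_matrix(rows: pd.DataFrame, features: Sequence[str]) -> np.ndarray:
    """Numeric design matrix; sex encoded female=1/male=0; NaN passes through."""
    cols = []
    for f in features:
        col = rows[f]
        if f == "sex" or col.dtype == object:
            col = col.map({"female": 1.0, "male": 0.0})
        cols.append(pd.to_numeric(col, errors="coerce").to_numpy(dtype=float))
    return np.column_stack(cols)


@dataclass
class FeatureImportanceTable:
    """Per-feature share of the ensemble's total split gain."""

    table: pd.DataFrame  # columns: feature, fractional_gain, max_normalized, rank

    def __post_init__(self) -> None:
        g = self.table["fractional_gain"].to_numpy()
        if (g < 0).any():
            raise ValueError("fractional gains must be non-negative")
        if abs(g.sum() - 1.0) > 1e-9:
            raise ValueError("fractional gains must sum to 1")
        ranks = np.sort(self.table["rank"].to_numpy())
        if not np.array_equal(ranks, np.arange(1, len(ranks) + 1)):
            raise ValueError("ranks must be a permutation of 1..n")

    def top(self, k: int) -> list[str]:
        return self.table.nsmallest(k, "rank")["feature"].tolist()


def rank_features(
    train_rows: pd.DataFrame,
    all_candidate_features: Sequence[str],
    response: str = RESPONSE,
    seed: int = 0,
) -> FeatureImportanceTable:
    """Rank candidate features by fractional total-gain importance.

    A boosted-tree model is fit on all candidates; each feature's importance
    is its accumulated split gain divided by the ensemble total, so the
    column sums to 1 and a never-split feature scores exactly 0. A
    max-normalized column is kept alongside for display parity with
    importance plots scaled to the top feature.
    """
    feats = list(all_candidate_features)
    if len(feats) < 2:
        raise ValueError("need at least 2 candidate features")
    if len(train_rows) < 20:
        raise ValueError("need at least 20 rows to rank features")
    y = train_rows[response].to_numpy(dtype=float)
    if np.nanstd(y) == 0:
        raise ValueError("degenerate response: constant urine osmolality")
    X = _design_matrix(train_rows, feats)
    model = XGBRegressor(
        n_estimators=200,
        max_depth=6,
        learning_rate=0.1,
        subsample=0.9,
        random_state=seed,
        n_jobs=1,
        verbosity=0,
    )
    model.fit(X, y)
    score = model.get_booster().get_score(importance_type="total_gain")
    gains = np.array([score.get(f"f{i}", 0.0) for i in range(len(feats))], dtype=float)
    total = gains.sum()
    if total <= 0:
        raise ValueError("model made no splits; cannot rank features")
    frac = gains / total
    order = np.argsort(-frac, kind="stable")
    rank = np.empty(len(feats), dtype=int)
    rank[order] = np.arange(1, len(feats) + 1)
    table = pd.DataFrame(
        {
            "feature": feats,
            "fractional_gain": frac,
            "max_normalized": frac / frac.max(),
            "rank": rank,
        }
    ).sort_values("rank", ignore_index=True)
    return FeatureImportanceTable(table)


@dataclass(frozen=True)
class FeaturePolicy:
    """Which features may enter the deployed surrogate.

    ``excluded_features`` are measurements the general population cannot
    easily supply (24 h urine volume, micturition counts); ``allowed_features``
    is the final modelling list and must not intersect the exclusions nor
    contain the response or the participant identifier.
    """

    excluded_features: tuple[str, ...] = ("urine_volume", "n_micturitions")
    allowed_features: tuple[str, ...] = tuple(DEFAULT_ALLOWED_FEATURES)

    def __post_init__(self) -> None:
        overlap = set(self.excluded_features) & set(self.allowed_features)
        if overlap:
            raise ValueError(f"features both allowed and excluded: {sorted(overlap)}")
        forbidden = {RESPONSE, ID_COLUMN} & set(self.allowed_features)
        if forbidden:
            raise ValueError(f"allowed list may not contain {sorted(forbidden)}")
        if not self.allowed_features:
            raise ValueError("allowed feature list is empty")


def prune_features(
    importances: FeatureImportanceTable, policy: FeaturePolicy
) -> list[str]:
    """Final modelling feature list: the policy's allowed set, order preserved."""
    final = [f for f in policy.allowed_features if f not in policy.excluded_features]
    if not final:
        raise ValueError("no features remain after applying the policy")
    return final


def _sample_params(kind: str, space: Mapping[str, tuple], rng: np.random.Generator) -> dict:
    params: dict = {}
    for name, (lo, hi) in space.items():
        if name in ("n_estimators", "max_depth", "max_iter"):
            params[name] = int(rng.integers(int(lo), int(hi) + 1))
        elif name == "learning_rate":
            params[name] = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        else:
            params[name] = float(rng.uniform(lo, hi))
    return params


def _make_learner(kind: str, params: Mapping, seed: int):
    if kind == "gbt":
        return XGBRegressor(random_state=seed, n_jobs=1, verbosity=0, **params)
    if kind == "rf":
        return RandomForestRegressor(random_state=seed, n_jobs=1, **params)
    if kind == "gbm":
        return HistGradientBoostingRegressor(random_state=seed, **params)
    raise ValueError(f"unknown learner kind {kind!r}; choose from {LEARNER_KINDS}")


@dataclass
class SurrogateModel:
    """A fitted regressor mapping feature rows to predicted urine osmolality."""

    learner_kind: str
    estimator: object
    features: list[str]
    hyperparameters: dict
    cv_config: dict
    train_mae: float
    handles_missing: bool = True

    def predict(self, rows: pd.DataFrame) -> np.ndarray:
        """Predicted U_Osm (mOsm/kg) per row; finite even with missing entries."""
        X = _design_matrix(rows, self.features)
        yhat = np.asarray(self.estimator.predict(X), dtype=float)
        if not np.all(np.isfinite(yhat)):
            raise RuntimeError("surrogate produced non-finite predictions")
        return yhat


def _group_folds(groups: np.ndarray, n_folds: int) -> list[tuple[np.ndarray, np.ndarray]]:
    """Participant-grouped CV folds: no participant spans a fold boundary."""
    n_groups = len(np.unique(groups))
    k = min(n_folds, n_groups)
    if k < 2:
        raise ValueError("need at least 2 participant groups for grouped CV")
    splitter = GroupKFold(n_splits=k)
    return list(splitter.split(np.zeros(len(groups)), groups=groups))


def fit_surrogate(
    train_rows: pd.DataFrame,
    features: Sequence[str],
    learner_kind: str = "gbt",
    hyperparameter_space: Mapping[str, tuple] | None = None,
    cv_folds: int = 5,
    n_search: int = 50,
    seed: int = 0,
) -> SurrogateModel:
    """Tune and fit one surrogate by seeded random search over grouped CV.

    Hyperparameter draws are scored by mean CV MAE with folds grouped by
    participant (no participant appears in both a training fold and its
    validation fold); the best draw is refit on the full training table.
    Entirely-missing feature columns are dropped with a warning.
    """
    if learner_kind not in LEARNER_KINDS:
        raise ValueError(f"unknown learner kind {learner_kind!r}")
    features = list(features)
    all_missing = [f for f in features if train_rows[f].isna().all()]
    if all_missing:
        warnings.warn(f"dropping all-missing feature columns: {all_missing}", stacklevel=2)
        features = [f for f in features if f not in all_missing]
    if not features:
        raise ValueError("no usable features remain")

    y = train_rows[RESPONSE].to_numpy(dtype=float)
    X = _design_matrix(train_rows, features)
    groups = train_rows[ID_COLUMN].to_numpy()
    folds = _group_folds(groups, cv_folds)
    space = dict(hyperparameter_space or DEFAULT_SEARCH_SPACE[learner_kind])

    rng = np.random.default_rng(seed)
    best_params, best_score = None, np.inf
    for _ in range(max(1, n_search)):
        params = _sample_params(learner_kind, space, rng)
        fold_maes = []
        for tr, va in folds:
            est = _make_learner(learner_kind, params, seed)
            est.fit(X[tr], y[tr])
            fold_maes.append(mae(y[va], est.predict(X[va])))
        score = float(np.mean(fold_maes))
        if score < best_score:
            best_params, best_score = params, score

    final = _make_learner(learner_kind, best_params, seed)
    final.fit(X, y)
    model = SurrogateModel(
        learner_kind=learner_kind,
        estimator=final,
        features=features,
        hyperparameters=dict(best_params),
        cv_config={"folds": len(folds), "n_search": n_search, "seed": seed, "cv_mae": best_score},
        train_mae=mae(y, final.predict(X)),
    )
    return model


def save_model(model: SurrogateModel, directory: str) -> None:
    """Persist estimator (binary) plus a JSON sidecar with fit metadata."""
    import json
    import os

    import joblib

    os.makedirs(directory, exist_ok=True)
    joblib.dump(model.estimator, os.path.join(directory, "estimator.joblib"))
    sidecar = {
        "format_version": "1.0",
        "learner_kind": model.learner_kind,
        "features": model.features,
        "hyperparameters": model.hyperparameters,
        "cv_config": model.cv_config,
        "train_mae": model.train_mae,
        "handles_missing": model.handles_missing,
    }
    with open(os.path.join(directory, "model.json"), "w") as fh:
        json.dump(sidecar, fh, indent=2)


def load_model(directory: str) -> SurrogateModel:
    import json
    import os

    import joblib

    with open(os.path.join(directory, "model.json")) as fh:
        meta = json.load(fh)
    estimator = joblib.load(os.path.join(directory, "estimator.joblib"))
    return SurrogateModel(
        learner_kind=meta["learner_kind"],
        estimator=estimator,
        features=meta["features"],
        hyperparameters=meta["hyperparameters"],
        cv_config=meta["cv_config"],
        train_mae=meta["train_mae"],
        handles_missing=meta["handles_missing"],
    )


@dataclass
class StabilityReport:
    """Test-MAE stability of each learner over repeated full split+fit cycles."""

    maes: dict[str, list[float]]
    n_repeats: int

    @property
    def mean(self) -> dict[str, float]:
        return {k: float(np.mean(v)) for k, v in self.maes.items()}

    @property
    def sd(self) -> dict[str, float]:
        # sd is undefined for a single repeat; reported as NaN with the flag below
        return {
            k: float(np.std(v, ddof=1)) if len(v) > 1 else float("nan")
            for k, v in self.maes.items()
        }

    @property
    def sd_defined(self) -> bool:
        return self.n_repeats > 1


def compare_learners(
    train_rows: pd.DataFrame,
    test_rows: pd.DataFrame,
    learner_kinds: Sequence[str] = LEARNER_KINDS,
    seed: int = 0,
    features: Sequence[str] | None = None,
    n_repeats: int = 5,
    ratio: float = 0.75,
    hyperparameter_space: Mapping[str, Mapping] | None = None,
    cv_folds: int = 5,
    n_search: int = 10,
) -> tuple[dict[str, float], StabilityReport]:
    """Tune each learner identically and compare test MAE, with stability.

    The headline MAE per learner comes from the provided train/test split.
    Stability re-splits the pooled rows by participant ``n_repeats`` times
    with distinct seeds and repeats the whole tune+fit+score cycle, mirroring
    a five-repeat reliability protocol.
    """
    from .preprocess import split_by_participant  # local import avoids a cycle

    if len(learner_kinds) < 1:
        raise ValueError("need at least one learner kind")
    features = list(features or DEFAULT_ALLOWED_FEATURES)
    pooled = pd.concat([train_rows, test_rows], ignore_index=True)

    def _space(kind: str):
        if hyperparameter_space is None:
            return None
        return hyperparameter_space.get(kind)

    def _score(kind: str, tr: pd.DataFrame, te: pd.DataFrame, s: int) -> float:
        model = fit_surrogate(
            tr, features, kind, _space(kind), cv_folds=cv_folds, n_search=n_search, seed=s
        )
        eligible = te[te[RESPONSE].notna()]
        return mae(eligible[RESPONSE].to_numpy(dtype=float), model.predict(eligible))

    headline = {k: _score(k, train_rows, test_rows, seed) for k in learner_kinds}

    maes: dict[str, list[float]] = {k: [] for k in learner_kinds}
    for r in range(n_repeats):
        split = split_by_participant(pooled, ratio=ratio, seed=seed + 1000 + r)
        for kind in learner_kinds:
            maes[kind].append(_score(kind, split.train_rows, split.test_rows, seed + r))
    return headline, StabilityReport(maes=maes, n_repeats=n_repeats)
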