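"""Stacking ensemble for disease-lncRNA pair scoring.

Five tree-based base learners (XGBoost, LightGBM, histogram gradient
boosting, ExtraTrees, RandomForest) are stacked under a logistic-regression
meta-learner. The meta-learner is fit on out-of-fold base probabilities
(5-fold within the 80% model-selection pool) so it never sees in-fold
predictions; the base learners are then refit on the full pool. Training
data are balanced 1:1 — all known positives against an equal number of
negatives sampled from the denoised unknown set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from lightgbm import LGBMClassifier
from sklearn.base import clone
from sklearn.ensemble import (
    ExtraTreesClassifier,
    HistGradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, train_test_split
from xgboost import XGBClassifier

# lightgbm's sklearn wrapper records synthetic feature names at fit time and
# sklearn then warns on every ndarray predict; the names carry no information
warnings.filterwarnings("ignore", message="X does not have valid feature names")

__all__ = [
    "BalancedDataset",
    "StackingModel",
    "default_base_learners",
    "build_training_set",
    "train_stacking",
    "predict_pairs",
]

BASE_LEARNER_NAMES = ("xgboost", "lightgbm", "hist_gbdt", "extra_trees", "random_forest")


def default_base_learners(seed: int = 0, enabled: tuple[str, ...] | None = None) -> dict:
    """The five tree-based base learners at library defaults, seeded.

    ``enabled`` restricts the set (for ablations); order is preserved.
    """
    learners = {
        "xgboost": XGBClassifier(random_state=seed, verbosity=0, eval_metric="logloss",
                                 n_jobs=1),
        "lightgbm": LGBMClassifier(random_state=seed, verbose=-1, n_jobs=1),
        "hist_gbdt": HistGradientBoostingClassifier(random_state=seed),
        "extra_trees": ExtraTreesClassifier(random_state=seed, n_jobs=1),
        "random_forest": RandomForestClassifier(random_state=seed, n_jobs=1),
    }
    if enabled is not None:
        unknown = set(enabled) - set(learners)
        if unknown:
            raise ValueError(f"unknown base learners: {sorted(unknown)}")
        learners = {k: v for k, v in learners.items() if k in enabled}
    return learners


@dataclass
class BalancedDataset:
    """1:1 positive/negative pairs split into a pool and a held-out set."""

    X_pool: np.ndarray
    y_pool: np.ndarray
    X_holdout: np.ndarray
    y_holdout: np.ndarray
    pool_indices: np.ndarray      # sample indices into the originating PairSet
    holdout_indices: np.ndarray
    negative_indices: np.ndarray  # the sampled negatives (subset of U_reliable)
    seed: int = 0


def build_training_set(features: np.ndarray, positive_indices: np.ndarray,
                       reliable_indices: np.ndarray, seed: int = 0,
                       holdout_frac: float = 0.2) -> BalancedDataset:
    """Balance positives with sampled reliable negatives and split 80/20.

    Negatives are drawn uniformly without replacement from the reliable
    unknowns; if fewer than |P| are available, all of them are used and a
    warning is raised. The split is stratified and deterministic per seed.
    """
    positive_indices = np.asarray(positive_indices)
    reliable_indices = np.asarray(reliable_indices)
    if reliable_indices.size == 0:
        raise ValueError("no reliable negatives to sample from")
    rng = np.random.default_rng(seed)
    n_pos = positive_indices.size
    if reliable_indices.size < n_pos:
        warnings.warn(
            f"only {reliable_indices.size} reliable negatives for {n_pos} positives; "
            "using all of them (classes will be imbalanced)"
        )
        negatives = reliable_indices.copy()
    else:
        negatives = rng.choice(reliable_indices, size=n_pos, replace=False)
    idx = np.concatenate([positive_indices, negatives])
    y = np.concatenate([np.ones(n_pos, dtype=int), np.zeros(negatives.size, dtype=int)])
    pool_idx, hold_idx, y_pool, y_hold = train_test_split(
        idx, y, test_size=holdout_frac, stratify=y,
        random_state=int(rng.integers(0, 2**31 - 1)),
    )
    return BalancedDataset(
        X_pool=features[pool_idx], y_pool=y_pool,
        X_holdout=features[hold_idx], y_holdout=y_hold,
        pool_indices=pool_idx, holdout_indices=hold_idx,
        negative_indices=negatives, seed=seed,
    )


@dataclass
class StackingModel:
    """Fitted stacking ensemble: base learners + logistic meta-learner."""

    base_learners: dict
    meta_learner: LogisticRegression
    seed: int
    n_features: int
    oof_scheme: str = "stratified 5-fold out-of-fold probabilities"

    @property
    def meta_feature_width(self) -> int:
        return len(self.base_learners)

    def base_probabilities(self, X: np.ndarray) -> np.ndarray:
        return np.column_stack([m.predict_proba(X)[:, 1]
                                for m in self.base_learners.values()])

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if X.shape[1] != self.n_features:
            raise ValueError(f"expected {self.n_features} features, got {X.shape[1]}")
        return self.meta_learner.predict_proba(self.base_probabilities(X))[:, 1]


def train_stacking(dataset: BalancedDataset, seed: int = 0, folds: int = 5,
                   enabled: tuple[str, ...] | None = None) -> StackingModel:
    """Fit the stacking ensemble on the model-selection pool.

    Out-of-fold base probabilities feed the meta-learner; a fold that ends
    up single-class is retried with a shifted shuffle seed.
    """
    X, y = dataset.X_pool, dataset.y_pool
    if len(np.unique(y)) < 2:
        raise ValueError("pool must contain both classes")
    minority = int(np.bincount(y).min())
    if minority < 2:
        raise ValueError("minority class has fewer than 2 pool samples")
    folds = min(folds, minority)
    learners = default_base_learners(seed, enabled)
    oof = np.zeros((X.shape[0], len(learners)))
    for attempt in range(10):
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed + attempt)
        splits = list(skf.split(X, y))
        if all(len(np.unique(y[tr])) == 2 for tr, _ in splits):
            break
    for tr, te in splits:
        for col, model in enumerate(learners.values()):
            m = clone(model)
            m.fit(X[tr], y[tr])
            oof[te, col] = m.predict_proba(X[te])[:, 1]
    meta = LogisticRegression(max_iter=1000, random_state=seed)
    meta.fit(oof, y)
    fitted = {}
    for name, model in learners.items():
        m = clone(model)
        m.fit(X, y)
        fitted[name] = m
    return StackingModel(base_learners=fitted, meta_learner=meta, seed=seed,
                         n_features=X.shape[1])


def predict_pairs(model: StackingModel, F_disease: np.ndarray, F_lncrna: np.ndarray,
                  pairs: list[tuple[int, int]]) -> np.ndarray:
    """Score (disease index, lncRNA index) pairs with the fitted ensemble."""
    F_disease = np.asarray(F_disease)
    F_lncrna = np.asarray(F_lncrna)
    d = np.array([p[0] for p in pairs])
    l = np.array([p[1] for p in pairs])
    if d.size and (d.max() >= F_disease.shape[0] or l.max() >= F_lncrna.shape[0]):
        from .datatypes import IdentifierError
        raise IdentifierError("pair index outside the embedding matrices")
    X = np.hstack([F_disease[d], F_lncrna[l]])
    return model.predict_proba(X)
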