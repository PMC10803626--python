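"""Classification metrics, cross-validation, ablation and per-disease ranking.

Hard-label metrics (ACC, MCC, F1, precision, recall) are computed from the
confusion matrix with the usual zero-denominator conventions (MCC = 0,
precision/recall/F1 = 0). Ranking metrics (AUC, AUPR) use the midrank ROC
statistic and step-wise precision-recall integration. Cross-validation
reports each metric's per-fold values with mean and population variance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "ConfusionMetrics",
    "confusion_metrics",
    "ranking_metrics",
    "CVReport",
    "cross_validate",
    "select_best_model",
    "leave_disease_out",
    "view_ablation",
]

METRIC_NAMES = ("ACC", "MCC", "F1", "precision", "recall", "AUC", "AUPR")


@dataclass
class ConfusionMetrics:
    TP: int
    TN: int
    FP: int
    FN: int
    ACC: float
    MCC: float
    F1: float
    precision: float
    recall: float

    def as_dict(self) -> dict[str, float]:
        return {"ACC": self.ACC, "MCC": self.MCC, "F1": self.F1,
                "precision": self.precision, "recall": self.recall}


def confusion_metrics(y_true, y_pred) -> ConfusionMetrics:
    """ACC/MCC/F1/precision/recall from binary truth and hard predictions."""
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    if y_true.size == 0:
        raise ValueError("empty input")
    if y_true.shape != y_pred.shape:
        raise ValueError("length mismatch")
    tp = int(((y_true == 1) & (y_pred == 1)).sum())
    tn = int(((y_true == 0) & (y_pred == 0)).sum())
    fp = int(((y_true == 0) & (y_pred == 1)).sum())
    fn = int(((y_true == 1) & (y_pred == 0)).sum())
    acc = (tp + tn) / (tp + tn + fp + fn)
    prec = tp / (tp + fp) if tp + fp else 0.0
    rec = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
    denom = math.sqrt((tp + fn) * (tp + fp) * (tn + fn) * (tn + fp))
    mcc = (tp * tn - fp * fn) / denom if denom else 0.0
    return ConfusionMetrics(tp, tn, fp, fn, acc, mcc, f1, prec, rec)


def ranking_metrics(y_true, scores) -> tuple[float, float]:
    """(AUC, AUPR); raises on single-class truth."""
    y_true = np.asarray(y_true).astype(int)
    scores = np.asarray(scores, dtype=np.float64)
    if len(np.unique(y_true)) < 2:
        raise ValueError("both classes required for ranking metrics")
    return float(roc_auc_score(y_true, scores)), float(average_precision_score(y_true, scores))


def all_metrics(y_true, scores, threshold: float = 0.5) -> dict[str, float]:
    auc, aupr = ranking_metrics(y_true, scores)
    cm = confusion_metrics(y_true, np.asarray(scores) >= threshold)
    out = cm.as_dict()
    out["AUC"] = auc
    out["AUPR"] = aupr
    return out


@dataclass
class CVReport:
    per_fold: dict[str, list[float]]
    mean: dict[str, float]
    variance: dict[str, float]       # population variance over fold values
    seed: int
    threshold: float
    folds: int

    def as_dict(self) -> dict:
        return {"folds": self.folds, "seed": self.seed, "threshold": self.threshold,
                "per_fold": self.per_fold, "mean": self.mean, "variance": self.variance}


def cross_validate(X, y, model_factory, folds: int = 5, threshold: float = 0.5,
                   seed: int = 0) -> CVReport:
    """Stratified k-fold CV of ``model_factory() -> fit/predict_proba`` model.

    Reports mean and population variance of all seven metrics across folds.
    A degenerate single-class fold triggers a re-stratification with the
    next seed.
    """
    X = np.asarray(X)
    y = np.asarray(y).astype(int)
    minority = int(np.bincount(y).min())
    if minority < folds:
        raise ValueError(
            f"minority class has {minority} samples; cannot stratify {folds} folds")
    for attempt in range(10):
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed + attempt)
        splits = list(skf.split(X, y))
        if all(len(np.unique(y[tr])) == 2 and len(np.unique(y[te])) == 2
               for tr, te in splits):
            break
    per_fold: dict[str, list[float]] = {m: [] for m in METRIC_NAMES}
    for tr, te in splits:
        model = model_factory()
        model.fit(X[tr], y[tr])
        proba = model.predict_proba(X[te])
        if proba.ndim == 2:
            proba = proba[:, 1]
        fold_metrics = all_metrics(y[te], proba, threshold)
        for m in METRIC_NAMES:
            per_fold[m].append(fold_metrics[m])
    mean = {m: float(np.mean(v)) for m, v in per_fold.items()}
    var = {m: float(np.var(v)) for m, v in per_fold.items()}
    return CVReport(per_fold=per_fold, mean=mean, variance=var,
                    seed=seed, threshold=threshold, folds=folds)


def select_best_model(stacking_model, dataset) -> tuple[str, dict[str, dict[str, float]]]:
    """Compare the stacked model and each refit base learner on the held-out
    split by AUC (ties broken by AUPR); returns (winner name, scores table)."""
    table: dict[str, dict[str, float]] = {}
    auc, aupr = ranking_metrics(dataset.y_holdout,
                                stacking_model.predict_proba(dataset.X_holdout))
    table["stacking"] = {"AUC": auc, "AUPR": aupr}
    for name, m in stacking_model.base_learners.items():
        auc, aupr = ranking_metrics(dataset.y_holdout,
                                    m.predict_proba(dataset.X_holdout)[:, 1])
        table[name] = {"AUC": auc, "AUPR": aupr}
    winner = max(table, key=lambda k: (table[k]["AUC"], table[k]["AUPR"]))
    return winner, table


@dataclass
class RankedPredictions:
    disease_id: str
    lncrna_ids: list[str]
    scores: list[float]

    def __post_init__(self) -> None:
        if any(a < b for a, b in zip(self.scores, self.scores[1:])):
            raise ValueError("scores must be non-increasing")


def leave_disease_out(disease_id: str, A, F_disease: np.ndarray, F_lncrna: np.ndarray,
                      reliable_indices: np.ndarray, samples, seed: int = 0,
                      top_n: int = 30, enabled: tuple[str, ...] | None = None,
                      return_details: bool = False):
    """Rank all lncRNAs for one disease with its pairs excluded from training.

    The classifier is retrained on a balanced set built from all other
    diseases' pairs (embeddings and denoising are reused); every lncRNA is
    then scored for the target disease and the top ``top_n`` returned.
    """
    from .ensemble import build_training_set, predict_pairs, train_stacking

    d = A.disease_index(disease_id)
    if A.values[d].sum() == 0:
        raise ValueError(f"disease {disease_id!r} has no known associations")
    keep = samples.disease_idx != d
    pos = np.flatnonzero(samples.labels & keep)
    reliable = np.asarray(reliable_indices)
    reliable = reliable[samples.disease_idx[reliable] != d]
    dataset = build_training_set(samples.features, pos, reliable, seed=seed)
    model = train_stacking(dataset, seed=seed, enabled=enabled)
    pairs = [(d, l) for l in range(A.n_lncrnas)]
    scores = predict_pairs(model, F_disease, F_lncrna, pairs)
    order = np.argsort(-scores, kind="stable")[: min(top_n, A.n_lncrnas)]
    ranked = RankedPredictions(disease_id=disease_id,
                               lncrna_ids=[A.lncrna_ids[i] for i in order],
                               scores=[float(scores[i]) for i in order])
    if return_details:
        return ranked, dataset
    return ranked


def view_ablation(run_subset, view_subsets: list[tuple[str, ...]]) -> list[dict]:
    """Run the pipeline per view subset and tabulate held-out AUC/AUPR.

    ``run_subset(views) -> {"AUC": .., "AUPR": ..}`` must use shared seeds
    so rows are comparable; each subset needs at least one disease view and
    one lncRNA view.
    """
    from .datatypes import DISEASE_VIEWS, LNCRNA_VIEWS

    rows = []
    for subset in view_subsets:
        if not subset:
            raise ValueError("empty view subset")
        if not set(subset) & set(DISEASE_VIEWS) or not set(subset) & set(LNCRNA_VIEWS):
            raise ValueError(f"subset {subset} must contain a disease view and a lncRNA view")
        metrics = run_subset(tuple(subset))
        rows.append({"views": "+".join(subset), "AUC": metrics["AUC"], "AUPR": metrics["AUPR"]})
    return rows
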