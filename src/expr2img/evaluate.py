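"""Stratified five-fold cross-validation of the three models on one task.

Every supervised artifact — LASSO selection, Fisher scores, categories and
the LDA gene map — is fitted on the four training folds only; the held-out
fold is pushed through the frozen artifacts.  AUC is computed from the
rank statistic (Mann–Whitney, tie-corrected); thresholded metrics use a
0.5 cut with the task's first-named group as the positive class.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import accuracy_score, f1_score, precision_score, recall_score, roc_curve
from sklearn.model_selection import StratifiedKFold

from .containers import ExpressionMatrix
from .errors import LeakageError
from .genemap import GeneImageMapper
from .ingest import PairTask, make_pair_subset
from .nets import CNNClassifier, FNNClassifier, FusionClassifier
from .select import DEFAULT_LAMBDA, LassoGeneSelector

MODEL_NAMES = ("fnn_only", "cnn_only", "fusion")
METRIC_NAMES = ("accuracy", "auc", "precision", "recall", "f1")


def make_folds(y: np.ndarray, k: int = 5, seed: int = 0) -> np.ndarray:
    """Stratified fold assignment (0..k-1 per sample), deterministic per seed."""
    y = np.asarray(y)
    for cls, count in zip(*np.unique(y, return_counts=True)):
        if count < k:
            raise ValueError(f"class {cls} has {count} samples; need >= {k} for {k} folds")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = np.empty(len(y), dtype=int)
    for f, (_, test_idx) in enumerate(skf.split(np.zeros(len(y)), y)):
        folds[test_idx] = f
    return folds


def auc_rank(y: np.ndarray, scores: np.ndarray) -> float:
    """AUC as the normalized Mann–Whitney rank statistic (tie-corrected)."""
    y = np.asarray(y).astype(int)
    scores = np.asarray(scores, dtype=float)
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n0 == 0 or n1 == 0:
        raise ValueError("AUC needs both classes present")
    ranks = rankdata(scores)
    u = ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n0 * n1))


def binary_metrics(y: np.ndarray, scores: np.ndarray, threshold: float = 0.5) -> dict[str, float]:
    """The full metric suite for one fold's held-out predictions."""
    y = np.asarray(y).astype(int)
    pred = (np.asarray(scores) >= threshold).astype(int)
    return {
        "accuracy": float(accuracy_score(y, pred)),
        "auc": auc_rank(y, scores),
        "precision": float(precision_score(y, pred, zero_division=0)),
        "recall": float(recall_score(y, pred, zero_division=0)),
        "f1": float(f1_score(y, pred, zero_division=0)),
    }


@dataclass
class FoldReport:
    """Per-fold and averaged metrics for one model on one task."""

    model: str
    task: str
    seed: int
    fold_assignment: list[int]
    per_fold: list[dict[str, float]]
    roc_curves: list[dict[str, list[float]]] = field(default_factory=list)
    n_selected_per_fold: list[int] = field(default_factory=list)
    sample_ids: list[str] = field(default_factory=list)
    fitted_on_per_fold: list[list[str]] = field(default_factory=list)  # provenance

    @property
    def means(self) -> dict[str, float]:
        return {
            m: float(np.mean([f[m] for f in self.per_fold])) for m in METRIC_NAMES
        }

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "task": self.task,
            "seed": self.seed,
            "fold_assignment": self.fold_assignment,
            "per_fold": self.per_fold,
            "means": self.means,
            "roc_curves": self.roc_curves,
            "n_selected_per_fold": self.n_selected_per_fold,
            "sample_ids": self.sample_ids,
            "fitted_on_per_fold": self.fitted_on_per_fold,
        }


def reports_to_json(reports: dict[str, FoldReport], path: str | Path) -> None:
    obj = {name: r.to_dict() for name, r in reports.items()}
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True))


def reports_to_csv(reports: dict[str, FoldReport], path: str | Path) -> None:
    rows = []
    for name, r in reports.items():
        for f, metrics in enumerate(r.per_fold):
            for m, v in metrics.items():
                rows.append({"model": name, "fold": f, "metric": m, "value": v})
        for m, v in r.means.items():
            rows.append({"model": name, "fold": "mean", "metric": m, "value": v})
    pd.DataFrame(rows).to_csv(path, index=False)


def _check_no_leakage(fitted_on: list[str], test_ids: list[str]) -> None:
    overlap = set(fitted_on) & set(test_ids)
    if overlap:
        raise LeakageError(f"gene map fitted on held-out samples: {sorted(overlap)[:5]}")


def run_cv(
    matrix: ExpressionMatrix,
    task: PairTask | str,
    lam: float = DEFAULT_LAMBDA,
    n_categories: int = 15,
    resolution: tuple[int, int] = (50, 50),
    k: int = 5,
    seed: int = 0,
    learning_rate: float = 1e-4,
    batch_size: int = 30,
    min_epochs_before_stop: int = 250,
    patience: int = 10,
    max_epochs: int = 2000,
    models: tuple[str, ...] = MODEL_NAMES,
) -> dict[str, FoldReport]:
    """Cross-validate the FNN, CNN and fusion models on one pairwise task.

    Returns one :class:`FoldReport` per requested model.  Per-model,
    per-fold seeds are derived from `seed` so runs are reproducible and the
    three models see independent initializations.
    """
    sub = make_pair_subset(matrix, task)
    task_name = task if isinstance(task, str) else task.name
    y = sub.binary_labels
    X = sub.X  # samples x genes, already in [0, 1]
    folds = make_folds(y, k=k, seed=seed)

    per_model: dict[str, list[dict[str, float]]] = {m: [] for m in models}
    rocs: dict[str, list[dict[str, list[float]]]] = {m: [] for m in models}
    n_selected: list[int] = []
    fitted_on_per_fold: list[list[str]] = []

    for f in range(k):
        test_mask = folds == f
        train_idx = np.flatnonzero(~test_mask)
        test_idx = np.flatnonzero(test_mask)
        y_tr, y_te = y[train_idx], y[test_idx]
        if len(np.unique(y_te)) < 2:
            raise ValueError(f"fold {f} has a single class in its test set")
        train_ids = [sub.sample_ids[i] for i in train_idx]
        test_ids = [sub.sample_ids[i] for i in test_idx]

        # supervised preprocessing on training folds only
        selector = LassoGeneSelector(lam=lam).fit(X[train_idx], y_tr)
        Xtr = selector.transform(X[train_idx])
        Xte = selector.transform(X[test_idx])
        n_selected.append(selector.n_selected_)

        mapper = GeneImageMapper(n_categories=n_categories, resolution=resolution)
        mapper.fit(Xtr, y_tr, sample_ids=train_ids)
        _check_no_leakage(mapper.fitted_on_, test_ids)
        fitted_on_per_fold.append(list(mapper.fitted_on_))
        img_tr = mapper.transform(Xtr)
        img_te = mapper.transform(Xte)

        def _mk(cls, offset: int):
            return cls(
                learning_rate=learning_rate,
                batch_size=batch_size,
                min_epochs_before_stop=min_epochs_before_stop,
                patience=patience,
                max_epochs=max_epochs,
                seed=(seed * 1009 + f * 101 + offset) % (2**31 - 1),
            )

        # the branch models are always trained: they are reported when
        # requested and seed the fusion model's trunks (warm start)
        fitted = {}
        fnn = _mk(FNNClassifier, 1).fit(Xtr, y_tr)
        cnn = _mk(CNNClassifier, 2).fit(img_tr, y_tr)
        if "fnn_only" in models:
            fitted["fnn_only"] = fnn._proba_positive(Xte)
        if "cnn_only" in models:
            fitted["cnn_only"] = cnn._proba_positive(img_te)
        if "fusion" in models:
            fus = _mk(FusionClassifier, 3)
            fus.warm_start_models = (fnn, cnn)
            fitted["fusion"] = fus.fit((Xtr, img_tr), y_tr)._proba_positive((Xte, img_te))
        for name, scores in fitted.items():
            per_model[name].append(binary_metrics(y_te, scores))
            fpr, tpr, _ = roc_curve(y_te, scores)
            rocs[name].append({"fpr": fpr.tolist(), "tpr": tpr.tolist()})

    return {
        m: FoldReport(
            model=m,
            task=task_name,
            seed=seed,
            fold_assignment=folds.tolist(),
            per_fold=per_model[m],
            roc_curves=rocs[m],
            n_selected_per_fold=n_selected,
            sample_ids=list(sub.sample_ids),
            fitted_on_per_fold=fitted_on_per_fold,
        )
        for m in models
    }
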