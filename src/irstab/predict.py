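"""Classifier accuracy and its relation to the Information Ratio.

Intra-study accuracy uses a nested stratified cross-validation with an RBF
SVM: the outer loop selects the top-fraction genes by Welch p-value on the
training folds only (no selection leakage) and measures accuracy on the
untouched test fold; the inner loop grid-searches the SVM cost and gamma.
Inter-study transfer derives a gene list from the full source study, trains a
default-parameter SVM per study on that fixed list, and reports the accuracy
lost in the target.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import GridSearchCV, StratifiedKFold, cross_val_score
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .io_prep import BinaryContrast, ExpressionStudy, ValidationError
from .diffexpr import _welch_p_rows

__all__ = ["COST_GRID", "GAMMA_GRID", "AccuracyResult", "TransferResult",
           "intra_study_accuracy", "transfer_accuracy", "ir_vs_accuracy_report"]

log = logging.getLogger(__name__)

COST_GRID = tuple(2.0 ** k for k in (-2, 0, 2, 4, 6))
GAMMA_GRID = tuple(2.0 ** k for k in range(-8, 3, 2))


@dataclass
class AccuracyResult:
    study_id: str
    contrast_name: str
    accuracy: float
    fold_accuracies: list[float]
    selected_genes_per_fold: list[list[str]]
    tuned_params: list[dict]
    seed: int


@dataclass
class TransferResult:
    source_study: str
    target_study: str
    contrast_name: str
    source_accuracy: float
    target_accuracy: float
    loss: float
    gene_list: list[str]
    seed: int


def _contrast_arrays(study: ExpressionStudy, contrast: BinaryContrast
                     ) -> tuple[np.ndarray, np.ndarray]:
    pos = {s: k for k, s in enumerate(study.sample_ids)}
    try:
        idx = np.array([pos[s] for s in contrast.sample_ids], dtype=int)
    except KeyError as exc:
        raise ValidationError(f"contrast sample {exc.args[0]!r} not in study") from exc
    X = study.expr[:, idx].T  # samples x genes
    y = contrast.label_array()
    return X, y


def _select_top(X: np.ndarray, y: np.ndarray, k: int) -> np.ndarray:
    """Indices of the k genes with smallest Welch p between the classes of (X, y)."""
    p = _welch_p_rows(X[y == 1].T, X[y == 2].T)
    return np.argsort(p, kind="stable")[:k]


def _fold_count(requested: int, y: np.ndarray) -> int:
    minority = int(min(np.sum(y == 1), np.sum(y == 2)))
    if minority < 2:
        raise ValidationError("a class is too small for any cross-validation split")
    folds = min(requested, minority)
    if folds < requested:
        log.info("reducing fold count from %d to minority class size %d",
                 requested, folds)
    return folds


def _svm_pipeline(cost: float = 1.0, gamma="auto") -> Pipeline:
    # features are z-scored within the training data before the RBF kernel
    return Pipeline([
        ("scale", StandardScaler()),
        ("svm", SVC(kernel="rbf", C=cost, gamma=gamma)),
    ])


def intra_study_accuracy(study: ExpressionStudy, contrast: BinaryContrast,
                         fraction: float = 0.05, seed: int = 0,
                         n_outer: int = 10, n_inner: int = 10) -> AccuracyResult:
    """Nested cross-validated RBF-SVM accuracy with in-fold gene selection.

    Outer ``n_outer``-fold stratified CV (folds reduced to the minority class
    size when necessary); inside each outer training set the top-``fraction``
    genes by Welch p are selected and an inner ``n_inner``-fold grid search
    tunes cost and gamma.  Accuracy is the mean over outer test folds.
    """
    X, y = _contrast_arrays(study, contrast)
    k = max(1, int(np.floor(fraction * X.shape[1])))
    outer_folds = _fold_count(n_outer, y)
    outer = StratifiedKFold(n_splits=outer_folds, shuffle=True, random_state=seed)
    fold_acc: list[float] = []
    fold_genes: list[list[str]] = []
    fold_params: list[dict] = []
    grid = {"svm__C": list(COST_GRID), "svm__gamma": list(GAMMA_GRID)}
    for f, (tr, te) in enumerate(outer.split(X, y)):
        sel = _select_top(X[tr], y[tr], k)
        inner_folds = _fold_count(n_inner, y[tr])
        inner = StratifiedKFold(n_splits=inner_folds, shuffle=True,
                                random_state=seed + 1000 + f)
        search = GridSearchCV(_svm_pipeline(), grid, cv=inner, scoring="accuracy",
                              n_jobs=1)
        search.fit(X[np.ix_(tr, sel)], y[tr])
        acc = float(search.best_estimator_.score(X[np.ix_(te, sel)], y[te]))
        fold_acc.append(acc)
        fold_genes.append([study.gene_ids[int(i)] for i in sel])
        fold_params.append({"cost": float(search.best_params_["svm__C"]),
                            "gamma": float(search.best_params_["svm__gamma"])})
    return AccuracyResult(
        study_id=study.study_id,
        contrast_name=contrast.name,
        accuracy=float(np.mean(fold_acc)),
        fold_accuracies=fold_acc,
        selected_genes_per_fold=fold_genes,
        tuned_params=fold_params,
        seed=seed,
    )


def _cv_accuracy_fixed_genes(study: ExpressionStudy, contrast: BinaryContrast,
                             gene_rows: np.ndarray, seed: int, n_folds: int = 10
                             ) -> float:
    X, y = _contrast_arrays(study, contrast)
    folds = _fold_count(n_folds, y)
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    scores = cross_val_score(_svm_pipeline(), X[:, gene_rows], y, cv=cv,
                             scoring="accuracy", n_jobs=1)
    return float(scores.mean())


def transfer_accuracy(source: ExpressionStudy, target: ExpressionStudy,
                      source_contrast: BinaryContrast,
                      target_contrast: BinaryContrast,
                      fraction: float = 0.05, seed: int = 0) -> TransferResult:
    """Accuracy loss when the source study's gene list is reused in the target.

    The list is the top ``fraction`` by Welch p on the source's full contrast
    data (deliberately optimistic for the source); both studies are then
    evaluated by 10-fold CV of a default-parameter RBF SVM (cost 1, gamma =
    1/n_features) restricted to that list.
    """
    if source.gene_ids != target.gene_ids:
        raise ValidationError("source and target must share a gene universe")
    Xs, ys = _contrast_arrays(source, source_contrast)
    k = max(1, int(np.floor(fraction * Xs.shape[1])))
    sel = _select_top(Xs, ys, k)
    src_acc = _cv_accuracy_fixed_genes(source, source_contrast, sel, seed)
    tgt_acc = _cv_accuracy_fixed_genes(target, target_contrast, sel, seed)
    return TransferResult(
        source_study=source.study_id,
        target_study=target.study_id,
        contrast_name=source_contrast.name,
        source_accuracy=src_acc,
        target_accuracy=tgt_acc,
        loss=src_acc - tgt_acc,
        gene_list=[source.gene_ids[int(i)] for i in sel],
        seed=seed,
    )


def ir_vs_accuracy_report(cells: list[dict], ir_threshold: float = 0.25) -> dict:
    """Summarize (study, contrast, ir, accuracy) cells by the IR threshold.

    ``cells`` rows need keys ``study``, ``contrast``, ``ir``, ``accuracy``.
    Returns the table plus group means, a Welch two-sample t-test p-value for
    the group difference, and the Pearson correlation of IR with accuracy
    (reported as missing when undefined).
    """
    if len(cells) < 2:
        raise ValidationError("need at least 2 (study, contrast) cells")
    tbl = pd.DataFrame(cells)
    low = tbl[tbl["ir"] <= ir_threshold]
    high = tbl[tbl["ir"] > ir_threshold]
    summary: dict = {
        "n_cells": int(len(tbl)),
        "mean_accuracy_low_ir": float(low["accuracy"].mean()) if len(low) else None,
        "mean_accuracy_high_ir": float(high["accuracy"].mean()) if len(high) else None,
        "welch_p": None,
        "pearson_r": None,
    }
    if len(low) >= 2 and len(high) >= 2:
        res = stats.ttest_ind(low["accuracy"], high["accuracy"], equal_var=False)
        summary["welch_p"] = float(res.pvalue)
    else:
        log.info("a group has < 2 cells; Welch test skipped")
    if tbl["ir"].nunique() > 1 and tbl["accuracy"].nunique() > 1:
        summary["pearson_r"] = float(np.corrcoef(tbl["ir"], tbl["accuracy"])[0, 1])
    return {"table": tbl, "summary": summary}
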