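"""Cross-validated RBF-SVM evaluation of selected gene subsets.

Small expression studies (tens of samples) cannot spare a held-out test
set, so classification accuracy is estimated with stratified 10-fold
cross-validation: folds preserve the class proportions of the full
sample, and the pooled accuracy is the fraction of all samples classified
correctly by the model trained on the other nine folds.

Two protocol variants matter and both are exposed:

* ``normalize_within_fold`` — recompute z-score statistics on the
  training folds only, so no test-fold statistic leaks into training
  (default off: statistics from the full dataset, the conventional
  whole-matrix preprocessing).
* selection inside vs. outside CV — :func:`benchmark_hybrids` by default
  selects genes once on the full dataset and then cross-validates, the
  conventional two-step protocol; ``select_within_fold=True`` redoes the
  full hybrid selection inside each training fold.  The default is
  optimistically biased (the test folds were seen during selection) and
  the within-fold mode is the honest estimate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .datasets import ExpressionDataset
from .filters import METHODS, rank_features, select_top
from .svm import hybrid_select, train_svm

logger = logging.getLogger("igselect")

__all__ = [
    "CvResult",
    "stratified_kfold",
    "cross_validate",
    "benchmark_hybrids",
    "accuracy_curve",
]


@dataclass(frozen=True)
class CvResult:
    """Fold assignment and per-fold / pooled accuracy for one gene subset."""

    fold_assignment: np.ndarray
    per_fold_correct: tuple  # (correct, total) per fold
    accuracy: float  # pooled, percent in [0, 100]

    @property
    def n_folds(self) -> int:
        return len(self.per_fold_correct)


def stratified_kfold(labels, k: int = 10, seed: int = 0) -> np.ndarray:
    """Stratified fold assignment by per-class round-robin.

    Each class's sample indices are shuffled with the seeded generator and
    dealt round-robin into the k folds, so per-class fold sizes differ by
    at most one and every fold's class proportions stay within one sample
    of the global proportions.  If the smaller class has fewer than k
    members, k is reduced to that size (with a warning).
    """
    labels = np.asarray(labels, dtype=int)
    m = len(labels)
    if m < 2:
        raise ValueError("need at least 2 samples")
    min_class = min(int((labels == c).sum()) for c in (-1, 1))
    if min_class < k:
        logger.warning("reducing k from %d to %d (smallest class size)", k, min_class)
        k = min_class
    if k < 2:
        raise ValueError("cannot build at least 2 folds with a sample per class")
    rng = np.random.default_rng(seed)
    assignment = np.empty(m, dtype=int)
    for cls in (-1, 1):
        idx = np.flatnonzero(labels == cls)
        rng.shuffle(idx)
        assignment[idx] = np.arange(len(idx)) % k
    return assignment


def _fold_accuracy(
    X: np.ndarray,
    y: np.ndarray,
    assignment: np.ndarray,
    C: float,
    gamma,
    normalize_within_fold: bool,
) -> tuple[tuple, float]:
    folds = np.unique(assignment)
    per_fold = []
    correct_total = 0
    for f in folds:
        test = assignment == f
        X_tr, y_tr = X[~test], y[~test]
        X_te, y_te = X[test], y[test]
        if normalize_within_fold:
            mu = X_tr.mean(axis=0)
            sd = X_tr.std(axis=0)
            sd = np.where(sd == 0.0, 1.0, sd)
            X_tr = (X_tr - mu) / sd
            X_te = (X_te - mu) / sd
        model = train_svm(X_tr, y_tr, C=C, kernel="rbf", gamma=gamma)
        pred = model.predict(X_te)
        n_correct = int((pred == y_te).sum())
        per_fold.append((n_correct, int(test.sum())))
        correct_total += n_correct
    accuracy = 100.0 * correct_total / len(y)
    return tuple(per_fold), accuracy


def cross_validate(
    ds: ExpressionDataset,
    genes,
    k: int = 10,
    C: float = 1.0,
    gamma="auto",
    seed: int = 0,
    normalize_within_fold: bool = False,
) -> CvResult:
    """Stratified k-fold accuracy of an RBF SVM on a gene subset.

    ``gamma="auto"`` uses 1/|genes|, the libsvm default.  The fold
    assignment is computed from the label vector and seed before any data
    is touched, so the estimate is invariant to sample order.
    """
    genes = list(genes)
    sub = ds.subset_genes(genes)  # raises on unknown ids
    assignment = stratified_kfold(ds.labels, k=k, seed=seed)
    per_fold, accuracy = _fold_accuracy(
        sub.values, ds.labels, assignment, C, gamma, normalize_within_fold
    )
    return CvResult(
        fold_assignment=assignment,
        per_fold_correct=per_fold,
        accuracy=accuracy,
    )


def benchmark_hybrids(
    ds: ExpressionDataset,
    methods=METHODS,
    n_filter: int = 150,
    k_final: int = 3,
    k_folds: int = 10,
    seed: int = 0,
    select_within_fold: bool = False,
    **filter_params,
) -> dict:
    """Hybrid-select then cross-validate for each filter method.

    Returns ``{method: {"genes": [...], "accuracy": float}}``.  With
    ``select_within_fold=True`` the full selection pipeline is re-run on
    each training fold and the reported genes are those selected on the
    full data (for reference) while the accuracy is the honest
    fold-wise estimate.
    """
    results = {}
    for method in methods:
        params = dict(filter_params)
        if method == "relieff":
            params.setdefault("seed", seed)
        genes = hybrid_select(
            ds, method, n_filter=n_filter, k_final=k_final, **params
        )
        if select_within_fold:
            accuracy = _cv_with_inner_selection(
                ds, method, n_filter, k_final, k_folds, seed, params
            )
            results[method] = {"genes": genes, "accuracy": accuracy}
        else:
            cv = cross_validate(ds, genes, k=k_folds, seed=seed)
            results[method] = {"genes": genes, "accuracy": cv.accuracy}
    return results


def _cv_with_inner_selection(
    ds: ExpressionDataset,
    method: str,
    n_filter: int,
    k_final: int,
    k_folds: int,
    seed: int,
    filter_params: dict,
) -> float:
    from dataclasses import replace

    assignment = stratified_kfold(ds.labels, k=k_folds, seed=seed)
    correct = 0
    for f in np.unique(assignment):
        test = assignment == f
        train_ds = replace(
            ds,
            values=ds.values[~test],
            sample_ids=ds.sample_ids[~test],
            labels=ds.labels[~test],
        )
        genes = hybrid_select(
            train_ds, method, n_filter=n_filter, k_final=k_final, **filter_params
        )
        idx = ds.gene_index(genes)
        model = train_svm(
            ds.values[~test][:, idx], ds.labels[~test], C=1.0, kernel="rbf"
        )
        pred = model.predict(ds.values[test][:, idx])
        correct += int((pred == ds.labels[test]).sum())
    return 100.0 * correct / ds.n_samples


def accuracy_curve(
    ds: ExpressionDataset,
    method: str = "ig",
    n_grid=range(1, 201),
    k_folds: int = 10,
    seed: int = 0,
    **filter_params,
) -> list[tuple[int, float]]:
    """Accuracy as a function of the number of top filter-ranked genes.

    For each n in ``n_grid`` the top-n genes of a single filter ranking
    are cross-validated (filter only — no RFE stage), tracing how accuracy
    saturates as genes are added.
    """
    n_grid = list(n_grid)
    if not n_grid or min(n_grid) < 1 or max(n_grid) > ds.n_genes:
        raise ValueError(f"n_grid must lie within [1, {ds.n_genes}]")
    if method == "relieff":
        filter_params.setdefault("seed", seed)
    ranking = rank_features(ds, method, **filter_params)
    curve = []
    for n in n_grid:
        genes = select_top(ranking, n)
        cv = cross_validate(ds, genes, k=k_folds, seed=seed)
        curve.append((n, cv.accuracy))
    return curve
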