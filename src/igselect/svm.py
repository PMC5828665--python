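"""Soft-margin SVM training and SVM-based wrapper selection (SVM-RFE).

The classifier is the standard soft-margin SVM: minimize
``(1/2)||w||^2 + C sum_i xi_i`` subject to ``y_i (w.x_i + b) >= 1 - xi_i``,
solved in the dual with box constraints ``0 <= alpha_i <= C`` and
``sum_i alpha_i y_i = 0``.  Training is delegated to scikit-learn's
``SVC`` (a libsvm wrapper); :class:`SvmModel` exposes the dual solution
(alpha_i * y_i, bias, support vectors) and, for the linear kernel, the
primal weight vector ``w = sum_i alpha_i y_i x_i`` that drives recursive
feature elimination.

The wrapper stage (``svm_rfe``) takes the filter's candidate genes and
repeatedly drops the gene with the smallest squared linear-SVM weight,
refitting after each drop, until ``k_final`` genes remain — the Guyon
et al. recursive feature elimination scheme.  ``hybrid_select`` composes
filter ranking, top-n truncation and RFE into the two-stage pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.svm import SVC

from .datasets import ExpressionDataset
from .filters import rank_features, select_top

__all__ = [
    "SvmModel",
    "RfeTrace",
    "rbf_kernel",
    "train_svm",
    "svm_rfe",
    "single_pass_select",
    "hybrid_select",
]


@dataclass(frozen=True)
class SvmModel:
    """A trained soft-margin SVM in dual form.

    ``dual_coefs`` holds alpha_i * y_i for every training sample (zero for
    non-support vectors); ``weights`` is the primal w for the linear
    kernel and None otherwise.
    """

    dual_coefs: np.ndarray
    bias: float
    kernel: str
    gamma: float | None
    C: float
    support_idx: np.ndarray
    X: np.ndarray
    y: np.ndarray
    weights: np.ndarray | None = None

    @property
    def alphas(self) -> np.ndarray:
        return self.dual_coefs * self.y

    def decision_function(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if self.kernel == "linear":
            return X @ self.weights + self.bias
        sv = self.X[self.support_idx]
        d2 = ((X[:, None, :] - sv[None, :, :]) ** 2).sum(axis=2)
        K = np.exp(-self.gamma * d2)
        return K @ self.dual_coefs[self.support_idx] + self.bias

    def predict(self, X) -> np.ndarray:
        return np.where(self.decision_function(X) >= 0.0, 1, -1)

    def dual_objective(self) -> float:
        """Value of the dual objective  sum(alpha) - 1/2 a^T Q a  at the
        trained solution (Q_ij = y_i y_j K(x_i, x_j))."""
        a = self.dual_coefs  # alpha_i y_i
        if self.kernel == "linear":
            K = self.X @ self.X.T
        else:
            d2 = ((self.X[:, None, :] - self.X[None, :, :]) ** 2).sum(axis=2)
            K = np.exp(-self.gamma * d2)
        return float(self.alphas.sum() - 0.5 * a @ K @ a)


@dataclass(frozen=True)
class RfeTrace:
    """Record of one recursive-elimination run.

    ``elimination_order`` lists removed genes, first-removed first;
    ``surviving_sets`` holds the gene set after each removal (strictly
    nested); ``criterion_values`` holds the squared weight each removed
    gene had when it was dropped.
    """

    elimination_order: tuple
    surviving_sets: tuple
    criterion_values: tuple


def rbf_kernel(a, b, gamma: float) -> float:
    """Gaussian radial basis kernel K(a, b) = exp(-gamma ||a - b||^2)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("vectors must have equal length")
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    return float(np.exp(-gamma * ((a - b) ** 2).sum()))


def train_svm(
    X,
    y,
    C: float = 1.0,
    kernel: str = "linear",
    gamma: float | str = "auto",
    tol: float = 1e-3,
) -> SvmModel:
    """Train a soft-margin SVM and return its dual solution.

    Parameters
    ----------
    X : (m, p) array
    y : (m,) array of {-1, +1}
    C : float
        Slack penalty; bounds every dual variable, 0 <= alpha_i <= C.
    kernel : {"linear", "rbf"}
    gamma : float or "auto"
        RBF width; "auto" uses 1/p (the libsvm default).
    tol : float
        KKT stopping tolerance of the solver.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.ndim != 2 or X.shape[1] < 1:
        raise ValueError("X must be an m x p matrix with p >= 1")
    if set(np.unique(y)) != {-1, 1}:
        raise ValueError("training labels must contain both classes (-1 and +1)")
    if kernel not in ("linear", "rbf"):
        raise ValueError(f"unsupported kernel {kernel!r}")
    gamma_val = 1.0 / X.shape[1] if gamma == "auto" else float(gamma)
    clf = SVC(C=C, kernel=kernel, gamma=gamma_val, tol=tol, shrinking=True)
    clf.fit(X, y)

    dual = np.zeros(len(y))
    dual[clf.support_] = clf.dual_coef_[0]
    weights = X.T @ dual if kernel == "linear" else None
    return SvmModel(
        dual_coefs=dual,
        bias=float(clf.intercept_[0]),
        kernel=kernel,
        gamma=gamma_val if kernel == "rbf" else None,
        C=C,
        support_idx=np.array(clf.support_, dtype=int),
        X=X,
        y=y,
        weights=weights,
    )


def svm_rfe(
    ds: ExpressionDataset,
    candidate_genes,
    k_final: int = 3,
    C: float | None = None,
    step: int = 1,
) -> tuple[list[str], RfeTrace]:
    """Recursive feature elimination with a linear-kernel SVM.

    Starting from ``candidate_genes``, a linear SVM is trained on the
    surviving genes and the ``step`` genes with the smallest squared
    weights w_j^2 are removed, repeating until ``k_final`` remain.  Weight
    ties are broken toward removing the later gene in canonical order.
    Survivors are returned ordered by their final-model w_j^2, largest
    first (ties again by canonical order).

    The linear kernel is used here even when downstream classification is
    RBF: only the linear kernel yields the per-gene weights the
    elimination criterion needs.

    ``C=None`` (default) scales the slack penalty as 1/m.  With far more
    genes than samples the training data are separable, so any fixed
    C >= 1 leaves the box constraints inactive (an effectively hard
    margin) and the elimination criterion becomes unstable; a penalty
    inversely proportional to the sample count keeps the regularization
    active and the per-gene weights stable across elimination rounds.
    """
    candidates = list(candidate_genes)
    if len(candidates) < k_final or k_final < 1:
        raise ValueError(
            f"need k_final in [1, {len(candidates)}], got {k_final}"
        )
    if C is None:
        C = 1.0 / ds.n_samples
    canon = {g: i for i, g in enumerate(ds.gene_ids)}
    surviving = list(candidates)
    eliminated: list[str] = []
    surviving_sets: list[tuple] = []
    criterion_values: list[float] = []

    idx = ds.gene_index(surviving)
    X_all = ds.values[:, idx]
    col = {g: j for j, g in enumerate(surviving)}

    model = None
    while len(surviving) > k_final:
        cols = [col[g] for g in surviving]
        model = train_svm(X_all[:, cols], ds.labels, C=C, kernel="linear")
        w2 = model.weights**2
        # remove smallest w^2; on ties prefer dropping the later canonical gene
        order = sorted(
            range(len(surviving)),
            key=lambda j: (w2[j], -canon[surviving[j]]),
        )
        n_drop = min(step, len(surviving) - k_final)
        drop = sorted(order[:n_drop], reverse=True)
        for j in drop:
            eliminated.append(surviving[j])
            criterion_values.append(float(w2[j]))
            del surviving[j]
        surviving_sets.append(tuple(surviving))

    final_cols = [col[g] for g in surviving]
    final_model = train_svm(X_all[:, final_cols], ds.labels, C=C, kernel="linear")
    w2 = final_model.weights**2
    final_order = sorted(
        range(len(surviving)), key=lambda j: (-w2[j], canon[surviving[j]])
    )
    selected = [surviving[j] for j in final_order]
    trace = RfeTrace(
        elimination_order=tuple(eliminated),
        surviving_sets=tuple(surviving_sets),
        criterion_values=tuple(criterion_values),
    )
    return selected, trace


def single_pass_select(
    ds: ExpressionDataset, candidate_genes, k_final: int = 3, C: float | None = None
) -> list[str]:
    """Alternative wrapper: one linear SVM fit on all candidates, keep the
    k genes with the largest squared weights (no refitting).  ``C=None``
    scales the penalty as 1/m, as in :func:`svm_rfe`."""
    if C is None:
        C = 1.0 / ds.n_samples
    candidates = list(candidate_genes)
    if len(candidates) < k_final or k_final < 1:
        raise ValueError(f"need k_final in [1, {len(candidates)}], got {k_final}")
    canon = {g: i for i, g in enumerate(ds.gene_ids)}
    sub = ds.subset_genes(candidates)
    model = train_svm(sub.values, sub.labels, C=C, kernel="linear")
    w2 = model.weights**2
    order = sorted(range(len(candidates)), key=lambda j: (-w2[j], canon[candidates[j]]))
    return [candidates[j] for j in order[:k_final]]


def hybrid_select(
    ds: ExpressionDataset,
    filter_method: str = "ig",
    n_filter: int = 150,
    k_final: int = 3,
    C: float | None = None,
    step: int = 1,
    **filter_params,
) -> list[str]:
    """Two-stage hybrid gene selection: filter ranking, then SVM-RFE.

    Equivalent to composing ``rank_features`` -> ``select_top(n_filter)``
    -> ``svm_rfe(k_final)``.  Defaults follow the filter-then-wrapper
    protocol: keep the top 150 filter-ranked genes, then eliminate down to
    3 informative genes.
    """
    if not k_final <= n_filter <= ds.n_genes:
        raise ValueError(
            f"need k_final <= n_filter <= n_genes, got {k_final}, {n_filter}, {ds.n_genes}"
        )
    ranking = rank_features(ds, filter_method, **filter_params)
    top = select_top(ranking, n_filter)
    selected, _ = svm_rfe(ds, top, k_final=k_final, C=C, step=step)
    return selected
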