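"""Independent reference implementations used only to check the package.

Each oracle recomputes a quantity by a different route than the library:
mutual information from the explicit joint distribution, MDLP by literal
recursive enumeration over raw arrays, the SVM dual by a general-purpose
QP solver, and ReliefF by a naive per-instance loop.
"""

import math

import numpy as np
from scipy.optimize import minimize


def joint_mutual_information(codes, labels) -> float:
    """I(X; Y) in bits from the explicit joint probability table."""
    codes = np.asarray(codes)
    labels = np.asarray(labels)
    m = len(labels)
    xs, ys = np.unique(codes), np.unique(labels)
    mi = 0.0
    for x in xs:
        px = (codes == x).sum() / m
        for y in ys:
            pxy = ((codes == x) & (labels == y)).sum() / m
            py = (labels == y).sum() / m
            if pxy > 0:
                mi += pxy * math.log2(pxy / (px * py))
    return mi


def shannon_entropy(labels) -> float:
    labels = np.asarray(labels)
    _, counts = np.unique(labels, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def reference_candidate_cuts(values, labels):
    """Midpoints between adjacent distinct values with differing label
    multisets, by literal grouping."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    order = np.argsort(values, kind="stable")
    v, y = values[order], labels[order]
    groups = []
    for val in sorted(set(v.tolist())):
        groups.append((val, sorted(y[v == val].tolist())))
    cuts = []
    for (v1, g1), (v2, g2) in zip(groups, groups[1:]):
        if g1 != g2:
            cuts.append((v1 + v2) / 2.0)
    return cuts


def reference_mdlp(values, labels):
    """Literal recursive MDLP over raw sub-arrays (exhaustive search over
    every candidate cut at every level)."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    out = []

    def rec(v, y):
        if len(v) < 2:
            return
        best, best_gain, best_mask = None, -np.inf, None
        for cut in reference_candidate_cuts(v, y):
            mask = v < cut
            y1, y2 = y[mask], y[~mask]
            n, n1, n2 = len(y), len(y1), len(y2)
            h, h1, h2 = shannon_entropy(y), shannon_entropy(y1), shannon_entropy(y2)
            gain = h - (n1 * h1 + n2 * h2) / n
            k = len(np.unique(y))
            k1, k2 = len(np.unique(y1)), len(np.unique(y2))
            threshold = (
                math.log2(n - 1) + math.log2(3**k - 2) - (k * h - k1 * h1 - k2 * h2)
            ) / n
            if gain > threshold and gain > best_gain:
                best, best_gain, best_mask = cut, gain, mask
        if best is None:
            return
        out.append(best)
        rec(v[best_mask], y[best_mask])
        rec(v[~best_mask], y[~best_mask])

    rec(values, labels)
    return sorted(out)


def qp_svm_dual(X, y, C, kernel="linear", gamma=1.0):
    """Solve the soft-margin SVM dual with a general QP solver.

    maximize  sum(a) - 1/2 sum_ij a_i a_j y_i y_j K_ij
    s.t.      0 <= a_i <= C,  sum_i a_i y_i = 0

    Returns (alpha, dual objective value).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    m = len(y)
    if kernel == "linear":
        K = X @ X.T
    else:
        d2 = ((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=2)
        K = np.exp(-gamma * d2)
    Q = (y[:, None] * y[None, :]) * K

    def neg_obj(a):
        return -(a.sum() - 0.5 * a @ Q @ a)

    def neg_grad(a):
        return -(np.ones(m) - Q @ a)

    best = None
    for start in (np.zeros(m), np.full(m, min(C, 1.0) / 2)):
        res = minimize(
            neg_obj,
            start,
            jac=neg_grad,
            bounds=[(0.0, C)] * m,
            constraints=[{"type": "eq", "fun": lambda a: a @ y,
                          "jac": lambda a: y}],
            method="SLSQP",
            options={"maxiter": 2000, "ftol": 1e-14},
        )
        if best is None or -res.fun > best[1]:
            best = (res.x, -res.fun)
    return best


def reference_relieff(X, y, k, sample_idx=None):
    """Naive ReliefF for two classes: explicit loops, all-instance default."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    m, n = X.shape
    span = X.max(axis=0) - X.min(axis=0)
    span = np.where(span == 0, 1.0, span)
    if sample_idx is None:
        sample_idx = range(m)
    sample_idx = list(sample_idx)
    w = np.zeros(n)
    for i in sample_idx:
        dists = np.sqrt(((X - X[i]) ** 2).sum(axis=1))
        hits = [j for j in range(m) if j != i and y[j] == y[i]]
        misses = [j for j in range(m) if y[j] != y[i]]
        hits.sort(key=lambda j: (dists[j], j))
        misses.sort(key=lambda j: (dists[j], j))
        kh, km = min(k, len(hits)), min(k, len(misses))
        for j in hits[:kh]:
            w -= np.abs(X[j] - X[i]) / span / (len(sample_idx) * kh)
        for j in misses[:km]:
            w += np.abs(X[j] - X[i]) / span / (len(sample_idx) * km)
    w[X.max(axis=0) - X.min(axis=0) == 0] = 0.0
    return w
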