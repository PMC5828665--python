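"""Supervised discretization of continuous gene expression values.

Entropy-based scores (information gain, gain ratio) are only defined for
discrete variables, so each gene is first cut into bins.  The default is
the Fayyad-Irani minimum-description-length principle (MDLP) method:
recursive binary splitting at class-boundary midpoints, where a split is
kept only if its information gain exceeds an MDL coding cost.  Genes whose
values carry no class signal receive zero cuts, a single bin, and hence an
information gain of exactly 0 downstream.

An unsupervised equal-frequency binning (default 10 bins) is provided as a
configurable fallback.

All entropies here are in bits (log base 2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "Discretization",
    "candidate_cuts",
    "mdl_discretize",
    "equal_frequency_discretize",
    "apply_cuts",
]


@dataclass(frozen=True)
class Discretization:
    """Per-gene cut points and the integer bin code of each sample.

    ``codes[i]`` is the number of cut points strictly below ``values[i]``,
    i.e. bins are half-open intervals ``[c_b, c_{b+1})``.  No cut points
    means every sample falls in bin 0.
    """

    cut_points: tuple
    codes: np.ndarray

    @property
    def n_bins(self) -> int:
        return len(self.cut_points) + 1


def apply_cuts(values, cut_points) -> np.ndarray:
    """Integer bin codes: count of cut points strictly below each value."""
    return np.searchsorted(np.asarray(cut_points, dtype=float),
                           np.asarray(values, dtype=float), side="right")


def _entropy_counts(counts: np.ndarray) -> float:
    n = counts.sum()
    if n == 0:
        return 0.0
    p = counts[counts > 0] / n
    return float(-(p * np.log2(p)).sum())


def candidate_cuts(values, labels) -> list[float]:
    """Class-boundary candidate cut points for one gene.

    Midpoints between consecutive *distinct* sorted values whose label
    multisets differ.  Tied values are grouped before the boundary test, so
    a value shared by both classes creates boundaries on both sides.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(values) < 2:
        raise ValueError("need at least 2 samples")
    order = np.argsort(values, kind="stable")
    v, y = values[order], labels[order]
    distinct, starts = np.unique(v, return_index=True)
    if len(distinct) < 2:
        return []
    cuts = []
    bounds = list(starts) + [len(v)]
    for i in range(len(distinct) - 1):
        left = y[bounds[i]:bounds[i + 1]]
        right = y[bounds[i + 1]:bounds[i + 2]]
        if sorted(left.tolist()) != sorted(right.tolist()):
            cuts.append((distinct[i] + distinct[i + 1]) / 2.0)
    return cuts


_LOG2_3 = np.log2(3.0)
_LOG2_7 = np.log2(7.0)


def _h2(pos: float, n: float) -> float:
    """Binary entropy in bits of a count pair (pos, n - pos)."""
    if n == 0 or pos == 0 or pos == n:
        return 0.0
    p = pos / n
    return -(p * np.log2(p) + (1.0 - p) * np.log2(1.0 - p))


def _mdlp_accepts(n, pos, n1, pos1) -> tuple[bool, float]:
    """Fayyad-Irani MDL test for one binary split of a two-class segment.

    Accept when  gain > ( log2(N-1) + log2(3^k - 2)
                          - [k*H(S) - k1*H(S1) - k2*H(S2)] ) / N
    with k, k1, k2 the numbers of classes present in S, S1, S2.
    Returns (accepted, gain).
    """
    n2, pos2 = n - n1, pos - pos1
    h, h1, h2 = _h2(pos, n), _h2(pos1, n1), _h2(pos2, n2)
    gain = h - (n1 * h1 + n2 * h2) / n
    k = 1 if (pos == 0 or pos == n) else 2
    k1 = 1 if (pos1 == 0 or pos1 == n1) else 2
    k2 = 1 if (pos2 == 0 or pos2 == n2) else 2
    log_3k = _LOG2_7 if k == 2 else 0.0  # log2(3^k - 2)
    delta = log_3k - (k * h - k1 * h1 - k2 * h2)
    threshold = (np.log2(n - 1.0) + delta) / n
    return gain > threshold, gain


def _mdlp_recurse_groups(
    distinct: np.ndarray,
    csize: np.ndarray,
    cpos: np.ndarray,
    a: int,
    b: int,
    out: list[float],
) -> None:
    """Recursive MDLP over value groups [a, b).

    ``distinct`` are the sorted distinct values; ``csize``/``cpos`` are
    cumulative sample and positive-label counts per group, so any
    segment's class composition is an O(1) prefix difference.
    """
    n = int(csize[b] - csize[a])
    pos = int(cpos[b] - cpos[a])
    if b - a < 2 or n < 2:
        return
    best_i, best_gain = -1, -np.inf
    for i in range(a + 1, b):
        # class-boundary candidates only: adjacent groups with equal label
        # multisets (same size and positive count) are skipped
        size_l = csize[i] - csize[i - 1]
        size_r = csize[i + 1] - csize[i]
        pos_l = cpos[i] - cpos[i - 1]
        pos_r = cpos[i + 1] - cpos[i]
        if size_l == size_r and pos_l == pos_r:
            continue
        n1 = int(csize[i] - csize[a])
        pos1 = int(cpos[i] - cpos[a])
        accepted, gain = _mdlp_accepts(n, pos, n1, pos1)
        if accepted and gain > best_gain:  # strict: ties keep the leftmost
            best_i, best_gain = i, gain
    if best_i < 0:
        return
    out.append((distinct[best_i - 1] + distinct[best_i]) / 2.0)
    _mdlp_recurse_groups(distinct, csize, cpos, a, best_i, out)
    _mdlp_recurse_groups(distinct, csize, cpos, best_i, b, out)


def mdl_discretize(values, labels) -> Discretization:
    """Discretize one gene by recursive MDLP splitting.

    At each level the candidate class-boundary cut with the largest class
    information gain is tested against the MDL stopping criterion; if
    accepted, both sub-intervals are split recursively.  Ties between
    equally good cuts go to the leftmost one.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(values) != len(labels):
        raise ValueError("values and labels must have the same length")
    if len(values) < 2:
        raise ValueError("need at least 2 samples")
    uniq = np.unique(labels)
    if len(uniq) > 2:
        raise ValueError("labels must be binary")
    order = np.argsort(values, kind="stable")
    v, y = values[order], labels[order]
    distinct, starts = np.unique(v, return_index=True)
    bounds = np.append(starts, len(v))
    pos01 = (y == uniq[-1]).astype(np.int64)
    cum = np.concatenate([[0], np.cumsum(pos01)])
    csize = bounds.astype(np.int64)
    cpos = cum[bounds]
    cuts: list[float] = []
    _mdlp_recurse_groups(distinct, csize, cpos, 0, len(distinct), cuts)
    cuts.sort()
    return Discretization(cut_points=tuple(cuts), codes=apply_cuts(values, cuts))


def equal_frequency_discretize(values, labels=None, n_bins: int = 10) -> Discretization:
    """Unsupervised equal-frequency binning (fallback to MDLP).

    Cut points are distinct interior quantiles; duplicate quantiles from
    heavily tied data collapse, so fewer than ``n_bins`` bins may result.
    ``labels`` is accepted and ignored for signature compatibility.
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 2:
        raise ValueError("need at least 2 samples")
    qs = np.quantile(values, np.arange(1, n_bins) / n_bins)
    cuts = tuple(sorted(set(float(q) for q in qs if values.min() < q <= values.max())))
    # drop cuts that create empty leading bins on tied minima
    cuts = tuple(c for c in cuts if c > float(values.min()))
    return Discretization(cut_points=cuts, codes=apply_cuts(values, cuts))
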