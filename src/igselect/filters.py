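"""Filter-stage gene scoring and ranking.

Four per-gene relevance scores are implemented, each computed
independently of any classifier:

``ig``
    Information gain: the reduction in class-label entropy obtained by
    observing the (MDLP-discretized) gene,  g(Y, X) = H(Y) - H(Y | X).
``gain_ratio``
    Information gain divided by the split information (the entropy of the
    gene's own bin distribution), the C4.5 correction for IG's bias toward
    many-valued features.
``correlation``
    Absolute Pearson correlation between the continuous gene values and
    the +/-1 labels (the point-biserial correlation).
``relieff``
    ReliefF weights: a gene is rewarded for differing between an instance
    and its nearest other-class neighbours (misses) and penalized for
    differing from its nearest same-class neighbours (hits).

``rank_features`` applies one of these to every gene and orders the genes
by score, breaking ties by the canonical (on-disk) gene order so that
rankings are exactly reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .datasets import ExpressionDataset, RankingRecord
from .discretize import equal_frequency_discretize, mdl_discretize

logger = logging.getLogger("igselect")

METHODS = ("ig", "gain_ratio", "relieff", "correlation")

__all__ = [
    "METHODS",
    "FeatureRanking",
    "entropy",
    "conditional_entropy",
    "info_gain",
    "gain_ratio",
    "pearson_score",
    "relieff_weights",
    "rank_features",
    "select_top",
]


@dataclass(frozen=True)
class FeatureRanking:
    """Complete scored ordering of all genes produced by one filter."""

    method: str
    records: tuple

    @property
    def gene_ids(self) -> list[str]:
        return [r.gene_id for r in self.records]

    @property
    def scores(self) -> np.ndarray:
        return np.array([r.score for r in self.records])


def entropy(labels) -> float:
    """Shannon entropy of a label vector in bits, with 0*log(0) := 0."""
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("empty label vector")
    _, counts = np.unique(labels, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def conditional_entropy(codes, labels) -> float:
    """H(Y | X) = sum_x p(x) H(Y | X = x), in bits."""
    codes = np.asarray(codes)
    labels = np.asarray(labels)
    if codes.shape != labels.shape:
        raise ValueError("codes and labels must have the same length")
    m = len(labels)
    total = 0.0
    for x in np.unique(codes):
        mask = codes == x
        total += (mask.sum() / m) * entropy(labels[mask])
    return total


def info_gain(codes, labels) -> float:
    """Information gain g(Y, X) = H(Y) - H(Y|X) in bits; never negative.

    Tiny negative rounding residues (< 1e-12 in magnitude) are clipped to
    exactly 0.
    """
    gain = entropy(labels) - conditional_entropy(codes, labels)
    if gain < 0:
        if gain < -1e-12:
            raise AssertionError(f"information gain {gain} below rounding floor")
        gain = 0.0
    return gain


def split_information(codes) -> float:
    """Entropy of the bin-code distribution (C4.5 split info)."""
    return entropy(np.asarray(codes))


def gain_ratio(codes, labels) -> float:
    """C4.5 gain ratio: info_gain / split_information, 0 when the split
    information is 0 (constant feature)."""
    si = split_information(codes)
    if si == 0.0:
        return 0.0
    return info_gain(codes, labels) / si


def pearson_score(values, labels) -> float:
    """Absolute point-biserial correlation |r(values, labels)| in [0, 1].

    A constant gene has no defined correlation and scores 0.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=float)
    if len(values) < 2:
        raise ValueError("need at least 2 samples")
    vc = values - values.mean()
    lc = labels - labels.mean()
    denom = np.sqrt((vc**2).sum() * (lc**2).sum())
    if denom == 0.0:
        return 0.0
    return float(abs((vc * lc).sum() / denom))


def relieff_weights(
    ds: ExpressionDataset,
    k: int = 10,
    m_iter: int | None = None,
    seed: int = 0,
) -> np.ndarray:
    """ReliefF feature weights for every gene (two-class specialization).

    For each sampled instance, the k nearest same-class neighbours (hits)
    and the k nearest other-class neighbours (misses) are found by
    Euclidean distance over all genes.  Per-gene differences are scaled to
    [0, 1] by the gene's dataset-wide range, so weights lie in [-1, 1] and
    a constant gene receives weight exactly 0.  In the two-class case the
    miss-class prior factor P(miss)/(1 - P(own)) reduces to 1.

    Parameters
    ----------
    k : int
        Neighbour count; classes with fewer than k+1 members use all
        available neighbours (with a warning).
    m_iter : int or None
        Number of seeded sampled instances; None means all instances in
        order (seed-independent except for distance ties).
    seed : int
        Seed for instance sampling when ``m_iter`` is given.
    """
    X = ds.values
    y = ds.labels
    m, n = X.shape
    rng = np.random.default_rng(seed)

    span = X.max(axis=0) - X.min(axis=0)
    safe_span = np.where(span == 0.0, 1.0, span)

    for cls in (-1, 1):
        if (y == cls).sum() < k + 1:
            logger.warning(
                "class %+d has %d samples < k+1=%d; using all available neighbours",
                cls, int((y == cls).sum()), k + 1,
            )

    if m_iter is None:
        picks = np.arange(m)
    else:
        picks = rng.choice(m, size=min(m_iter, m), replace=False)
    n_iter = len(picks)

    # full pairwise Euclidean distances over all genes
    sq = (X**2).sum(axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * X @ X.T
    np.maximum(d2, 0.0, out=d2)

    weights = np.zeros(n)
    for i in picks:
        same = np.flatnonzero((y == y[i]) & (np.arange(m) != i))
        other = np.flatnonzero(y != y[i])
        k_hit = min(k, len(same))
        k_miss = min(k, len(other))
        if k_hit == 0 or k_miss == 0:
            continue
        hit_order = same[np.lexsort((same, d2[i, same]))][:k_hit]
        miss_order = other[np.lexsort((other, d2[i, other]))][:k_miss]
        diff_hit = np.abs(X[hit_order] - X[i]) / safe_span
        diff_miss = np.abs(X[miss_order] - X[i]) / safe_span
        weights -= diff_hit.sum(axis=0) / (n_iter * k_hit)
        weights += diff_miss.sum(axis=0) / (n_iter * k_miss)
    weights[span == 0.0] = 0.0
    return weights


def _scores_for_method(ds: ExpressionDataset, method: str, params: dict) -> np.ndarray:
    y = ds.labels
    if method in ("ig", "gain_ratio"):
        discretizer = params.get("discretizer", "mdlp")
        if discretizer == "mdlp":
            disc = mdl_discretize
        elif discretizer == "equal_frequency":
            n_bins = params.get("n_bins", 10)
            disc = lambda v, yy: equal_frequency_discretize(v, yy, n_bins=n_bins)
        else:
            raise ValueError(f"unknown discretizer {discretizer!r}")
        score = info_gain if method == "ig" else gain_ratio
        return np.array([
            score(disc(ds.values[:, j], y).codes, y) for j in range(ds.n_genes)
        ])
    if method == "correlation":
        return np.array([
            pearson_score(ds.values[:, j], y) for j in range(ds.n_genes)
        ])
    if method == "relieff":
        return relieff_weights(
            ds,
            k=params.get("k", 10),
            m_iter=params.get("m_iter"),
            seed=params.get("seed", 0),
        )
    raise ValueError(f"unknown filter method {method!r}; choose from {METHODS}")


def rank_features(ds: ExpressionDataset, method: str, **params) -> FeatureRanking:
    """Score every gene with the given filter and rank them.

    Genes are ordered by score descending; exact ties keep the canonical
    gene order.  For ``ig`` and ``gain_ratio`` each gene is MDLP-discretized
    first (``discretizer="equal_frequency"`` switches to quantile binning).
    The ranking is complete — truncation is a separate step
    (:func:`select_top`).
    """
    scores = _scores_for_method(ds, method, params)
    if not np.all(np.isfinite(scores)):
        raise AssertionError("non-finite filter score")
    order = np.lexsort((np.arange(ds.n_genes), -scores))
    records = tuple(
        RankingRecord(gene_id=str(ds.gene_ids[j]), score=float(scores[j]), rank=r + 1)
        for r, j in enumerate(order)
    )
    return FeatureRanking(method=method, records=records)


def select_top(ranking: FeatureRanking, n_keep: int) -> list[str]:
    """The first ``n_keep`` gene ids of a ranking."""
    n = len(ranking.records)
    if not 1 <= n_keep <= n:
        raise ValueError(f"n_keep must be in [1, {n}], got {n_keep}")
    return ranking.gene_ids[:n_keep]
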