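"""Synthetic microarray-like data with planted class-informative genes.

Real two-class expression benchmarks (colon, lung, leukemia) have a few
thousand genes, under about a hundred samples, and an unknown informative
subset.  The generator reproduces that shape with a *known* ground truth:
a small planted set of genes whose class means are separated by a chosen
effect size (in pooled-SD units) against a background of independent
Gaussian noise genes.  An optional correlated block clones one informative
gene with correlation ``rho`` to emulate redundant genes, and a log-normal
toggle emulates the heavy right tail of raw intensities.

Everything is driven by one integer seed and is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datasets import ExpressionDataset

__all__ = ["SyntheticSpec", "generate", "make_fixture", "FIXTURE_SHAPES"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic two-class expression dataset.

    Attributes
    ----------
    m, n : int
        Samples and genes.
    n_informative : int
        Number of planted class-informative genes (placed at random
        positions among the n genes).
    effect : float
        Mean shift between the two classes in pooled-SD units; 0 plants
        no signal.
    class_balance : float in (0, 1)
        Fraction of +1 samples; counts are rounded, both classes kept
        non-empty.
    noise_sd : float
        Within-class standard deviation of every gene.
    correlated_block : (size, rho) or None
        Optional block of ``size`` redundant genes, each correlated with
        the first informative gene at level ``rho``.
    lognormal : bool
        Exponentiate values to emulate heavy-tailed raw intensities.
    seed : int
    """

    m: int
    n: int
    n_informative: int = 3
    effect: float = 2.5
    class_balance: float = 0.5
    noise_sd: float = 1.0
    correlated_block: tuple | None = None
    lognormal: bool = False
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.class_balance < 1:
            raise ValueError("class_balance must be in (0, 1)")
        if self.n_informative > self.n:
            raise ValueError("n_informative must be <= n")
        if self.effect < 0:
            raise ValueError("effect must be >= 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.correlated_block is not None:
            size, rho = self.correlated_block
            if self.n_informative == 0:
                raise ValueError("correlated block requires an informative gene")
            if not -1 <= rho <= 1:
                raise ValueError("rho must be in [-1, 1]")
            if self.n_informative + size > self.n:
                raise ValueError("correlated block does not fit")


def generate(spec: SyntheticSpec) -> tuple[ExpressionDataset, list[str]]:
    """Draw one dataset from the spec; returns (dataset, planted gene ids).

    Labels are +1 with probability ``class_balance`` (counts fixed by
    rounding, then shuffled).  Informative genes are
    Normal(+-effect/2 * noise_sd, noise_sd) by class, noise genes
    Normal(0, noise_sd), so the planted between-class shift equals
    ``effect`` pooled SDs.  Correlated-block genes are built from the
    standardized first informative gene g as
    rho * standardize(g) + sqrt(1-rho^2) * noise, so their overall
    correlation with g is rho and they inherit an attenuated share of its
    class signal (redundant genes).
    """
    rng = np.random.default_rng(spec.seed)
    m, n = spec.m, spec.n

    n_pos = int(round(m * spec.class_balance))
    n_pos = min(max(n_pos, 1), m - 1)
    labels = np.concatenate([np.ones(n_pos, dtype=int), -np.ones(m - n_pos, dtype=int)])
    rng.shuffle(labels)

    values = rng.normal(0.0, spec.noise_sd, size=(m, n))
    positions = rng.choice(n, size=spec.n_informative, replace=False)
    shift = 0.5 * spec.effect * spec.noise_sd
    for j in positions:
        values[:, j] += shift * labels

    if spec.correlated_block is not None:
        size, rho = spec.correlated_block
        anchor = positions[0]
        free = np.setdiff1d(np.arange(n), positions)
        block = rng.choice(free, size=size, replace=False)
        a = values[:, anchor]
        a_std = (a - a.mean()) / a.std()
        for j in block:
            z = rng.normal(size=m)
            values[:, j] = spec.noise_sd * (rho * a_std + np.sqrt(1 - rho**2) * z)

    if spec.lognormal:
        values = np.exp(values)

    width = len(str(n - 1))
    gene_ids = np.array([f"g{j:0{width}d}" for j in range(n)], dtype=object)
    sample_ids = np.array([f"s{i}" for i in range(m)], dtype=object)
    ds = ExpressionDataset(
        values=values,
        gene_ids=gene_ids,
        sample_ids=sample_ids,
        labels=labels,
        label_names={-1: "neg", 1: "pos"},
    )
    planted = sorted(str(gene_ids[j]) for j in positions)
    return ds, planted


#: Benchmark-like preset shapes: (n_genes, m_samples, n_positive).
#: colon-like uses the classic 2,000-gene matrix size.
FIXTURE_SHAPES = {
    "colon-like": (2000, 62, 40),
    "lung-like": (7129, 96, 86),
    "leukemia-like": (7129, 72, 25),
}


def make_fixture(
    name: str,
    seed: int = 0,
    n_informative: int = 3,
    effect: float = 2.5,
) -> tuple[ExpressionDataset, list[str]]:
    """Synthetic dataset shaped like a classic two-class benchmark.

    Presets fix (n, m, class split): colon-like 2000 x 62 (40/22),
    lung-like 7129 x 96 (86/10), leukemia-like 7129 x 72 (25/47).
    Values are synthetic — only the shape imitates the benchmarks.
    """
    if name not in FIXTURE_SHAPES:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(FIXTURE_SHAPES)}")
    n, m, n_pos = FIXTURE_SHAPES[name]
    spec = SyntheticSpec(
        m=m,
        n=n,
        n_informative=n_informative,
        effect=effect,
        class_balance=n_pos / m,
        seed=seed,
    )
    return generate(spec)
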