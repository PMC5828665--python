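"""Expression-table I/O, validation and normalization.

The central container is :class:`ExpressionDataset`: an m-samples x n-genes
matrix of continuous expression values with unique gene and sample
identifiers and a binary class label per sample.  Labels are mapped to
{-1, +1} on load (lexicographically smaller class string -> -1) so that all
downstream scoring and SVM code sees a canonical encoding.

Gene order as found on disk is preserved and acts as the canonical
tie-breaking order for every ranking step in the package.
"""

from __future__ import annotations

import io as _io
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger("igselect")

__all__ = [
    "ExpressionDataset",
    "RankingRecord",
    "read_expression_table",
    "zscore_normalize",
    "write_ranking",
    "read_ranking",
]


@dataclass(frozen=True)
class ExpressionDataset:
    """Samples x genes expression matrix with binary class labels.

    Attributes
    ----------
    values : ndarray, shape (m, n)
        Continuous expression levels, one row per sample.
    gene_ids : ndarray of str, length n
        Unique gene identifiers in canonical (on-disk) order.
    sample_ids : ndarray of str, length m
        Unique sample identifiers.
    labels : ndarray of int, length m
        Class labels in {-1, +1}; exactly two classes are present.
    label_names : dict
        Mapping {-1: original_name, +1: original_name} recording how the
        two class strings were encoded.
    constant_genes : ndarray of str
        Gene ids flagged as constant by :func:`zscore_normalize` (empty
        before normalization).
    """

    values: np.ndarray
    gene_ids: np.ndarray
    sample_ids: np.ndarray
    labels: np.ndarray
    label_names: dict = field(default_factory=dict)
    constant_genes: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=object))

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        gene_ids = np.asarray(self.gene_ids, dtype=object)
        sample_ids = np.asarray(self.sample_ids, dtype=object)
        labels = np.asarray(self.labels, dtype=int)
        if values.ndim != 2:
            raise ValueError("values must be a 2-D samples x genes matrix")
        m, n = values.shape
        if len(gene_ids) != n:
            raise ValueError(f"{len(gene_ids)} gene ids for {n} gene columns")
        if len(sample_ids) != m or len(labels) != m:
            raise ValueError("sample_ids and labels must match the number of rows")
        if len(set(gene_ids)) != n:
            dupes = pd.Index(gene_ids)[pd.Index(gene_ids).duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dupes}")
        if len(set(sample_ids)) != m:
            raise ValueError("duplicate sample ids")
        present = set(np.unique(labels).tolist())
        if present != {-1, 1}:
            raise ValueError(f"labels must be exactly {{-1, +1}}, got {sorted(present)}")
        if not np.all(np.isfinite(values)):
            bad = np.argwhere(~np.isfinite(values))[0]
            raise ValueError(
                f"non-finite value at sample {sample_ids[bad[0]]!r}, gene {gene_ids[bad[1]]!r}"
            )
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "gene_ids", gene_ids)
        object.__setattr__(self, "sample_ids", sample_ids)
        object.__setattr__(self, "labels", labels)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def gene_index(self, gene_ids) -> np.ndarray:
        """Column indices of ``gene_ids``, raising on unknown ids."""
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        try:
            return np.array([lookup[g] for g in gene_ids], dtype=int)
        except KeyError as exc:
            raise KeyError(f"unknown gene id: {exc.args[0]!r}") from None

    def subset_genes(self, gene_ids) -> "ExpressionDataset":
        """Dataset restricted to ``gene_ids`` (kept in the given order)."""
        idx = self.gene_index(gene_ids)
        return replace(
            self,
            values=self.values[:, idx],
            gene_ids=self.gene_ids[idx],
        )


@dataclass(frozen=True)
class RankingRecord:
    """One row of a feature ranking: gene id, filter score, 1-based rank."""

    gene_id: str
    score: float
    rank: int


def _map_labels(raw_labels) -> tuple[np.ndarray, dict]:
    classes = sorted({str(v) for v in raw_labels})
    if len(classes) != 2:
        raise ValueError(
            f"not a binary problem: found {len(classes)} classes {classes}"
        )
    mapping = {classes[0]: -1, classes[1]: 1}
    labels = np.array([mapping[str(v)] for v in raw_labels], dtype=int)
    logger.info("label mapping: %r -> -1, %r -> +1", classes[0], classes[1])
    return labels, {-1: classes[0], 1: classes[1]}


def _validate_numeric(frame: pd.DataFrame, impute_mean: bool = False) -> np.ndarray:
    numeric = frame.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & ~frame.isna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-numeric cell at row {frame.index[r]!r}, column {frame.columns[c]!r}"
        )
    missing = frame.isna()
    if missing.to_numpy().any():
        if not impute_mean:
            r, c = np.argwhere(missing.to_numpy())[0]
            raise ValueError(
                f"missing cell at row {frame.index[r]!r}, column {frame.columns[c]!r}"
                " (pass impute_mean=True to fill with per-gene means)"
            )
        # deliberate opt-in: silent imputation would shift rankings
        numeric = numeric.fillna(numeric.mean(axis=0))
        logger.info("imputed %d missing cells with per-gene means",
                    int(missing.to_numpy().sum()))
    return numeric.to_numpy(dtype=float)


def _read_arff(path) -> tuple[pd.DataFrame, pd.Series]:
    """Minimal dense-ARFF reader for numeric attribute tables with one
    nominal class attribute.  Covers the subset used by two-class
    expression tables; sparse ARFF is not supported."""
    attrs: list[tuple[str, str]] = []
    data_lines: list[str] = []
    in_data = False
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("%"):
                continue
            low = line.lower()
            if in_data:
                data_lines.append(line)
            elif low.startswith("@attribute"):
                rest = line.split(None, 1)[1]
                if rest.startswith(("'", '"')):
                    quote = rest[0]
                    end = rest.index(quote, 1)
                    name, spec = rest[1:end], rest[end + 1:].strip()
                else:
                    name, spec = rest.split(None, 1)
                attrs.append((name, spec.strip()))
            elif low.startswith("@data"):
                in_data = True
    if not attrs or not data_lines:
        raise ValueError(f"{path}: not a dense ARFF attribute table")
    names = [a[0] for a in attrs]
    nominal = [i for i, (_, s) in enumerate(attrs) if s.startswith("{")]
    if len(nominal) != 1:
        raise ValueError("expected exactly one nominal (class) attribute")
    table = pd.read_csv(
        _io.StringIO("\n".join(data_lines)), header=None, names=names,
        skipinitialspace=True, quotechar="'",
    )
    class_col = names[nominal[0]]
    y = table[class_col].astype(str).str.strip()
    return table.drop(columns=[class_col]), y


def read_expression_table(
    path,
    orientation: str = "genes-as-columns",
    label_source: str = "label",
    format: str | None = None,
    impute_mean: bool = False,
) -> ExpressionDataset:
    """Load an expression table with binary labels into an ExpressionDataset.

    Parameters
    ----------
    path : path-like
        TSV/CSV file with a header row, or a dense ARFF file.
    orientation : {"genes-as-columns", "genes-as-rows"}
        Whether genes run across columns (samples as rows) or down rows.
        Ignored for ARFF (attributes are always genes).
    label_source : str
        Name of the label column (genes-as-columns) or label row
        (genes-as-rows).
    format : {"tsv", "csv", "arff"}, optional
        Inferred from the file suffix when omitted.

    The two class strings are mapped lexicographically: smaller -> -1,
    larger -> +1; the mapping is logged and stored on the dataset.
    """
    path = str(path)
    if format is None:
        suffix = path.rsplit(".", 1)[-1].lower()
        format = suffix if suffix in {"tsv", "csv", "arff"} else "tsv"
    if orientation not in {"genes-as-columns", "genes-as-rows"}:
        raise ValueError(f"unknown orientation {orientation!r}")

    if format == "arff":
        frame, raw_labels = _read_arff(path)
        frame.index = [f"s{i}" for i in range(len(frame))]
    else:
        sep = "," if format == "csv" else "\t"
        frame = pd.read_csv(path, sep=sep, index_col=0)
        frame.index = frame.index.astype(str)
        frame.columns = frame.columns.astype(str)
        if orientation == "genes-as-rows":
            if label_source not in frame.index:
                raise ValueError(f"label row {label_source!r} not found")
            raw_labels = frame.loc[label_source]
            frame = frame.drop(index=label_source).T
        else:
            if label_source not in frame.columns:
                raise ValueError(f"label column {label_source!r} not found")
            raw_labels = frame[label_source]
            frame = frame.drop(columns=[label_source])

    labels, label_names = _map_labels(raw_labels)
    values = _validate_numeric(frame, impute_mean=impute_mean)
    return ExpressionDataset(
        values=values,
        gene_ids=np.asarray(frame.columns, dtype=object),
        sample_ids=np.asarray(frame.index, dtype=object),
        labels=labels,
        label_names=label_names,
    )


def zscore_normalize(ds: ExpressionDataset) -> ExpressionDataset:
    """Scale each gene to zero mean and unit population variance.

    Constant genes cannot be scaled; they are mapped to all-zeros and
    recorded in ``constant_genes`` rather than raising.  The operation is
    idempotent and depends only on per-gene statistics, so it is invariant
    to sample order.
    """
    if ds.n_samples < 2:
        raise ValueError("need at least 2 samples to normalize")
    mean = ds.values.mean(axis=0)
    sd = ds.values.std(axis=0)  # population (1/m) form
    constant = sd == 0.0
    safe_sd = np.where(constant, 1.0, sd)
    values = (ds.values - mean) / safe_sd
    values[:, constant] = 0.0
    return replace(ds, values=values, constant_genes=ds.gene_ids[constant])


def write_ranking(records, path) -> None:
    """Write ranking records as TSV (gene_id, score, rank).

    Scores are serialized at 6 significant digits, which the companion
    :func:`read_ranking` round-trips exactly.
    """
    records = list(records)
    ranks = [r.rank for r in records]
    if ranks != list(range(1, len(records) + 1)):
        raise ValueError("ranks must be 1..n with no gaps")
    scores = [r.score for r in records]
    if any(b > a for a, b in zip(scores, scores[1:])):
        raise ValueError("scores must be non-increasing with rank")
    with open(path, "w") as fh:
        fh.write("gene_id\tscore\trank\n")
        for r in records:
            fh.write(f"{r.gene_id}\t{r.score:.6g}\t{r.rank}\n")


def read_ranking(path) -> list[RankingRecord]:
    """Read a ranking TSV written by :func:`write_ranking`."""
    table = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    return [
        RankingRecord(gene_id=row.gene_id, score=float(row.score), rank=int(row.rank))
        for row in table.itertuples(index=False)
    ]
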