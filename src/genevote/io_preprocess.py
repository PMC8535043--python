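"""Expression-matrix I/O, min-max scaling and stratified fold construction.

The in-memory container is :class:`ExpressionMatrix`: a dense samples x genes
float matrix with string gene/sample identifiers and a binary label per
sample (0 = healthy/class A, 1 = cancer/class B).  On-disk formats are
delimited text: CSV/TSV with samples as rows (header of gene ids, first
column the sample id, labels in a named column), the transposed
genes-as-rows layout, and a GCT-like dialect (two header lines, then
NAME/Description columns with genes as rows; labels travel as a pseudo-gene
row named after the label column).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "ExpressionMatrix",
    "FoldSpec",
    "read_matrix",
    "write_matrix",
    "scale_minmax",
    "make_folds",
]


@dataclass
class ExpressionMatrix:
    """Samples x genes expression values with identifiers and binary labels."""

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.validate()

    def validate(self) -> None:
        n, p = self.values.shape
        if len(self.gene_ids) != p:
            raise ValueError(f"{len(self.gene_ids)} gene ids for {p} columns")
        if len(self.sample_ids) != n:
            raise ValueError(f"{len(self.sample_ids)} sample ids for {n} rows")
        if len(self.labels) != n:
            raise ValueError(f"{len(self.labels)} labels for {n} samples")
        _check_unique(self.gene_ids, "gene id")
        _check_unique(self.sample_ids, "sample id")
        if not np.all(np.isfinite(self.values)):
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"non-finite value at sample {self.sample_ids[i]!r}, "
                f"gene {self.gene_ids[j]!r}"
            )
        if len(np.unique(self.labels)) > 2:
            raise ValueError(
                f"labels must take at most two values, got {sorted(set(self.labels))}"
            )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def gene_index(self, gene_ids) -> np.ndarray:
        pos = {g: i for i, g in enumerate(self.gene_ids)}
        try:
            return np.array([pos[g] for g in gene_ids], dtype=int)
        except KeyError as exc:
            raise KeyError(f"gene {exc.args[0]!r} not in matrix") from None

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        idx = self.gene_index(gene_ids)
        return ExpressionMatrix(
            self.values[:, idx], [self.gene_ids[i] for i in idx],
            list(self.sample_ids), self.labels.copy(),
        )

    def subset_samples(self, rows) -> "ExpressionMatrix":
        rows = np.asarray(rows, dtype=int)
        return ExpressionMatrix(
            self.values[rows], list(self.gene_ids),
            [self.sample_ids[i] for i in rows], self.labels[rows],
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, ExpressionMatrix):
            return NotImplemented
        return (
            self.gene_ids == other.gene_ids
            and self.sample_ids == other.sample_ids
            and np.array_equal(self.labels, other.labels)
            and np.allclose(self.values, other.values, rtol=1e-10, atol=0)
        )


@dataclass
class FoldSpec:
    """A stratified k-fold partition: sample index -> fold index in [0, k)."""

    k: int
    assignment: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        self.assignment = np.asarray(self.assignment, dtype=int)
        sizes = np.bincount(self.assignment, minlength=self.k)
        if np.any(sizes == 0):
            raise ValueError("every fold must be non-empty")
        if sizes.max() - sizes.min() > 1:
            raise ValueError("fold sizes must differ by at most 1")

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignment == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignment != fold)

    def to_frame(self, sample_ids) -> pd.DataFrame:
        return pd.DataFrame({"sample_id": sample_ids, "fold": self.assignment})


def _check_unique(ids, what: str) -> None:
    seen, dups = set(), []
    for i in ids:
        if i in seen:
            dups.append(i)
        seen.add(i)
    if dups:
        raise ValueError(f"duplicate {what}(s): {sorted(set(dups))}")


def _encode_labels(raw: pd.Series, positive_label=None) -> np.ndarray:
    values = sorted(raw.unique(), key=str)
    if len(values) > 2:
        raise ValueError(f"label column has more than two values: {values}")
    if positive_label is not None:
        pos = type(values[0])(positive_label) if values else positive_label
        return (raw == pos).astype(int).to_numpy()
    if len(values) == 1:
        return np.zeros(len(raw), dtype=int)
    return (raw == values[1]).astype(int).to_numpy()


def _coerce_numeric(frame: pd.DataFrame) -> pd.DataFrame:
    """Convert all cells to float, reporting the first offending coordinate."""
    out = frame.apply(pd.to_numeric, errors="coerce")
    if out.isna().any().any() and not frame.isna().any().any():
        bad = np.argwhere(out.isna().to_numpy() & ~frame.isna().to_numpy())[0]
        raise ValueError(
            f"non-numeric value {frame.iloc[bad[0], bad[1]]!r} at row "
            f"{frame.index[bad[0]]!r}, column {frame.columns[bad[1]]!r}"
        )
    return out.astype(float)


def _check_header_dups(path: Path, sep: str, skip: int = 0) -> None:
    """pandas mangles duplicate header names (x, x.1), so inspect the raw
    header line before parsing."""
    with open(path) as fh:
        for _ in range(skip):
            fh.readline()
        tokens = fh.readline().rstrip("\n").split(sep)
    _check_unique(tokens[1:], "header id")


def read_matrix(
    path,
    dialect: str = "tsv",
    orientation: str = "samples-as-rows",
    label_column: str = "label",
    positive_label=None,
) -> ExpressionMatrix:
    """Read a delimited expression table into an :class:`ExpressionMatrix`.

    Parameters
    ----------
    dialect : {"csv", "tsv", "gct-like"}
    orientation : {"samples-as-rows", "genes-as-rows"}
        Ignored for gct-like, which is always genes-as-rows.
    label_column : str
        Column (or gene-row, for genes-as-rows layouts) holding the labels.
    positive_label : optional
        The raw label value mapped to 1; by default the larger of the two
        observed values under string sort.
    """
    path = Path(path)
    if dialect == "gct-like":
        _check_header_dups(path, "\t", skip=2)
        with open(path) as fh:
            fh.readline()
            fh.readline()
            body = pd.read_csv(fh, sep="\t", index_col=0)
        body = body.drop(columns=["Description"], errors="ignore")
        frame = body.T  # samples as rows, genes (incl. label row) as columns
    else:
        sep = {"csv": ",", "tsv": "\t"}[dialect]
        _check_header_dups(path, sep)
        frame = pd.read_csv(path, sep=sep, index_col=0)
        if orientation == "genes-as-rows":
            frame = frame.T
        elif orientation != "samples-as-rows":
            raise ValueError(f"unknown orientation {orientation!r}")
    if label_column not in frame.columns:
        raise ValueError(f"label column {label_column!r} not found in {path}")
    labels = _encode_labels(frame[label_column], positive_label)
    data = _coerce_numeric(frame.drop(columns=[label_column]))
    _check_unique(list(data.columns), "gene id")
    _check_unique(list(data.index), "sample id")
    return ExpressionMatrix(
        data.to_numpy(), [str(c) for c in data.columns],
        [str(i) for i in data.index], labels,
    )


def write_matrix(
    matrix: ExpressionMatrix,
    path,
    dialect: str = "tsv",
    label_column: str = "label",
) -> Path:
    """Write ``matrix`` so that :func:`read_matrix` round-trips it.

    Values are printed with 12 significant digits.
    """
    path = Path(path)
    frame = pd.DataFrame(
        matrix.values, index=pd.Index(matrix.sample_ids, name="sample_id"),
        columns=matrix.gene_ids,
    )
    frame.insert(0, label_column, matrix.labels)
    if dialect == "gct-like":
        body = frame.T  # genes (and label row) as rows
        with open(path, "w") as fh:
            fh.write("#1.2\n")
            fh.write(f"{body.shape[0]}\t{body.shape[1]}\n")
            body.index.name = "NAME"
            body.insert(0, "Description", "na")
            body.to_csv(fh, sep="\t", float_format="%.12g")
    else:
        sep = {"csv": ",", "tsv": "\t"}[dialect]
        frame.to_csv(path, sep=sep, float_format="%.12g")
    return path


def scale_minmax(
    train: ExpressionMatrix, apply_to: ExpressionMatrix | None = None
) -> ExpressionMatrix:
    """Per-gene min-max scaling fit on ``train``, applied to ``apply_to``.

    Each gene is mapped to ``(x - min_train) / (max_train - min_train)``;
    constant genes map to 0.  Held-out values are NOT clipped and may fall
    outside [0, 1].
    """
    if apply_to is None:
        apply_to = train
    if apply_to.gene_ids != train.gene_ids:
        raise ValueError("apply_to must have the same gene ids as train")
    lo = train.values.min(axis=0)
    span = train.values.max(axis=0) - lo
    safe = np.where(span == 0, 1.0, span)
    scaled = (apply_to.values - lo) / safe
    scaled[:, span == 0] = 0.0
    return replace(apply_to, values=scaled, labels=apply_to.labels.copy())


def make_folds(labels, k: int, seed: int) -> FoldSpec:
    """Seeded stratified k-fold assignment (fold sizes differ by <= 1)."""
    labels = np.asarray(labels)
    n = len(labels)
    if k > n:
        raise ValueError(f"k={k} exceeds the number of samples ({n})")
    if k < 2:
        raise ValueError("k must be at least 2")
    counts = np.bincount(labels.astype(int))
    if np.any(counts[counts > 0] < k):
        warnings.warn(
            "a class has fewer members than folds; stratification degrades",
            stacklevel=2,
        )
        # fall back to plain seeded round-robin over a shuffle
        rng = np.random.default_rng(seed)
        order = rng.permutation(n)
        assignment = np.empty(n, dtype=int)
        assignment[order] = np.arange(n) % k
        return FoldSpec(k=k, assignment=assignment, seed=seed)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignment = np.empty(n, dtype=int)
    for f, (_, test) in enumerate(skf.split(np.zeros((n, 1)), labels)):
        assignment[test] = f
    return FoldSpec(k=k, assignment=assignment, seed=seed)
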