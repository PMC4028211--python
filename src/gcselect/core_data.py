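"""Labelled expression-matrix container, delimited-text I/O and sample splitting.

On disk the matrix is genes x samples (rows = genes, first column = gene id,
header = sample ids), the dominant microarray convention; the in-memory ``X``
keeps the same genes x samples orientation, and classifier-facing code
transposes once at its own boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split


class FormatError(ValueError):
    """Malformed input files (dimension mismatches, duplicate identifiers)."""


class ValidationError(ValueError):
    """Structurally valid input that violates a dataset precondition."""


@dataclass
class ExpressionDataset:
    """Genes x samples expression matrix with one class label per sample.

    ``y`` holds integer class codes 0..n_classes-1; ``class_names`` maps a code
    back to the original label, in first-appearance order of the labels file.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    X: np.ndarray  # genes x samples
    y: np.ndarray  # int codes, one per sample
    class_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if self.X.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise FormatError(
                f"matrix shape {self.X.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if self.y.shape != (len(self.sample_ids),):
            raise FormatError("one label required per sample")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise FormatError("gene identifiers must be unique")
        if not np.isfinite(self.X).all():
            raise ValidationError("expression matrix contains missing/non-finite values")
        if not self.class_names:
            self.class_names = [str(c) for c in range(int(self.y.max()) + 1 if self.y.size else 0)]
        counts = np.bincount(self.y, minlength=len(self.class_names))
        if len(self.class_names) < 2:
            raise ValidationError("at least two classes are required")
        if (counts < 2).any():
            small = [self.class_names[i] for i in np.flatnonzero(counts < 2)]
            raise ValidationError(f"every class needs >=2 samples; too small: {small}")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    def subset_genes(self, idx: np.ndarray) -> "ExpressionDataset":
        idx = np.asarray(idx, dtype=int)
        return ExpressionDataset(
            [self.gene_ids[i] for i in idx],
            list(self.sample_ids),
            self.X[idx],
            self.y.copy(),
            list(self.class_names),
        )

    def subset_samples(self, idx: np.ndarray) -> "ExpressionDataset":
        idx = np.asarray(idx, dtype=int)
        return ExpressionDataset(
            list(self.gene_ids),
            [self.sample_ids[i] for i in idx],
            self.X[:, idx],
            self.y[idx],
            list(self.class_names),
        )


def read_dataset(expression_path, labels_path, delimiter: str = ",") -> ExpressionDataset:
    """Read an expression matrix plus a two-column (sample id, class) labels file.

    Class labels are mapped to codes 0..c-1 in first-appearance order in the
    labels file.
    """
    expr = pd.read_csv(expression_path, sep=delimiter, index_col=0)
    labels = pd.read_csv(labels_path, sep=delimiter, header=None, dtype=str)
    if labels.shape[1] != 2:
        raise FormatError("labels file must have exactly two columns: sample id, class")
    if expr.index.has_duplicates:
        raise FormatError("duplicate gene ids in expression file")
    if len(labels) != expr.shape[1]:
        raise FormatError(
            f"labels file has {len(labels)} rows but expression file has "
            f"{expr.shape[1]} sample columns"
        )
    label_map = dict(zip(labels.iloc[:, 0], labels.iloc[:, 1]))
    sample_ids = [str(s) for s in expr.columns]
    missing = [s for s in sample_ids if s not in label_map]
    if missing:
        raise FormatError(f"samples missing from labels file: {missing[:5]}")
    class_names: list[str] = []
    for lab in labels.iloc[:, 1]:
        if lab not in class_names:
            class_names.append(lab)
    y = np.array([class_names.index(label_map[s]) for s in sample_ids])
    if expr.isna().any().any():
        raise ValidationError("missing expression values are not supported")
    return ExpressionDataset(
        [str(g) for g in expr.index], sample_ids, expr.to_numpy(dtype=float), y, class_names
    )


def write_dataset(ds: ExpressionDataset, expression_path, labels_path, delimiter: str = ",") -> None:
    """Write the same dialect ``read_dataset`` consumes (lossless round trip)."""
    df = pd.DataFrame(ds.X, index=pd.Index(ds.gene_ids, name="gene_id"), columns=ds.sample_ids)
    df.to_csv(expression_path, sep=delimiter, float_format="%.17g")
    lab = pd.DataFrame({0: ds.sample_ids, 1: [ds.class_names[c] for c in ds.y]})
    lab.to_csv(labels_path, sep=delimiter, header=False, index=False)


def one_hot(y: np.ndarray, n_classes: int) -> np.ndarray:
    """Samples x classes one-hot target matrix."""
    y = np.asarray(y, dtype=int)
    T = np.zeros((y.size, n_classes))
    T[np.arange(y.size), y] = 1.0
    return T


def split_train_test(
    ds: ExpressionDataset, train_fraction: float, seed: int, stratified: bool = True
) -> tuple[ExpressionDataset, ExpressionDataset]:
    """Disjoint train/test sample partition, stratified by class by default."""
    if not 0.0 < train_fraction < 1.0:
        raise ValidationError("train_fraction must lie strictly between 0 and 1")
    idx = np.arange(ds.n_samples)
    stratify = ds.y if stratified else None
    try:
        tr, te = train_test_split(
            idx, train_size=train_fraction, random_state=seed, stratify=stratify
        )
    except ValueError as exc:
        raise ValidationError(f"cannot stratify split: {exc}") from exc
    tr.sort()
    te.sort()
    train, test = ds.subset_samples(tr), ds.subset_samples(te)
    if stratified and (len(set(train.y)) < ds.n_classes or len(set(test.y)) < ds.n_classes):
        raise ValidationError("a class is too small to appear in both split parts")
    return train, test


@dataclass
class Standardizer:
    """Per-gene zero-mean/unit-variance scaling fitted on the training split.

    Constant genes get scale 1 so they map to exactly zero instead of NaN.
    """

    mean_: np.ndarray | None = None
    scale_: np.ndarray | None = None

    def fit(self, ds: ExpressionDataset) -> "Standardizer":
        self.mean_ = ds.X.mean(axis=1)
        sd = ds.X.std(axis=1)
        self.scale_ = np.where(sd > 0, sd, 1.0)
        return self

    def transform(self, ds: ExpressionDataset) -> ExpressionDataset:
        if self.mean_ is None:
            raise ValidationError("Standardizer used before fit")
        Xs = (ds.X - self.mean_[:, None]) / self.scale_[:, None]
        return ExpressionDataset(
            list(ds.gene_ids), list(ds.sample_ids), Xs, ds.y.copy(), list(ds.class_names)
        )

    def fit_transform(self, ds: ExpressionDataset) -> ExpressionDataset:
        return self.fit(ds).transform(ds)
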