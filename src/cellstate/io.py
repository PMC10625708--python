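"""Expression-matrix containers, file I/O, normalization, and train/test splitting.

The on-disk contracts are deliberately simple and text-based:

* dense CSV — first row gene IDs, first column cell barcodes, UTF-8, comma
  separated (the "simple CSV" a web submission form would accept);
* Matrix Market triplets — genes x cells on disk with 1-based indices (the
  CellRanger convention) plus companion ``genes.tsv`` / ``barcodes.tsv``
  one-ID-per-line files; transposed to cells x genes in memory;
* labels — two-column TSV (barcode, class), no header.
"""

from __future__ import annotations

import csv
import enum
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse


class Layer(str, enum.Enum):
    """Which transformation the values of an :class:`ExpressionMatrix` carry."""

    RAW_COUNTS = "raw_counts"
    LOG2P1 = "log2p1"


class DataFormatError(ValueError):
    """Malformed or contract-violating input data."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    dups: list[str] = []
    for i in ids:
        if i in seen:
            dups.append(i)
        seen.add(i)
    if dups:
        raise DataFormatError(f"duplicate {what} IDs: {sorted(set(dups))[:10]}")


@dataclass(frozen=True)
class ExpressionMatrix:
    """A dense cells x genes expression matrix with row/column identifiers.

    Parameters
    ----------
    cell_ids, gene_ids
        Ordered, unique identifiers for rows and columns.
    values
        ``(n_cells, n_genes)`` array of finite, non-negative reals. For the
        ``raw_counts`` layer every value must be an integer.
    layer
        Whether ``values`` are raw counts or log2(count + 1).
    """

    cell_ids: tuple[str, ...]
    gene_ids: tuple[str, ...]
    values: np.ndarray
    layer: Layer = Layer.RAW_COUNTS

    def __post_init__(self) -> None:
        object.__setattr__(self, "cell_ids", tuple(self.cell_ids))
        object.__setattr__(self, "gene_ids", tuple(self.gene_ids))
        values = np.asarray(self.values, dtype=np.float64)
        object.__setattr__(self, "values", values)
        _check_unique(self.cell_ids, "cell")
        _check_unique(self.gene_ids, "gene")
        if values.ndim != 2 or values.shape != (len(self.cell_ids), len(self.gene_ids)):
            raise DataFormatError(
                f"values shape {values.shape} inconsistent with "
                f"{len(self.cell_ids)} cells x {len(self.gene_ids)} genes"
            )
        if not np.all(np.isfinite(values)):
            raise DataFormatError("non-finite expression values")
        if np.any(values < 0):
            raise DataFormatError("negative expression values")
        if self.layer == Layer.RAW_COUNTS and not np.array_equal(values, np.floor(values)):
            raise DataFormatError("raw_counts layer contains non-integer values")

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def gene_index(self, genes: Sequence[str]) -> np.ndarray:
        """Column indices for ``genes``; unknown IDs raise, naming the offender."""
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        try:
            return np.asarray([lookup[g] for g in genes], dtype=np.intp)
        except KeyError as exc:
            raise KeyError(f"unknown gene ID: {exc.args[0]!r}") from None

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        idx = self.gene_index(genes)
        return ExpressionMatrix(self.cell_ids, tuple(genes), self.values[:, idx], self.layer)

    def subset_cells(self, index: np.ndarray) -> "ExpressionMatrix":
        index = np.asarray(index, dtype=np.intp)
        return ExpressionMatrix(
            tuple(self.cell_ids[i] for i in index), self.gene_ids, self.values[index], self.layer
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.cell_ids), columns=list(self.gene_ids))

    def to_anndata(self):
        """Optional adapter to an :class:`anndata.AnnData` (import deferred)."""
        import anndata as ad

        adata = ad.AnnData(X=self.values.copy())
        adata.obs_names = list(self.cell_ids)
        adata.var_names = list(self.gene_ids)
        adata.uns["layer"] = self.layer.value
        return adata


@dataclass(frozen=True)
class LabeledDataset:
    """An :class:`ExpressionMatrix` joined to one categorical label per cell."""

    matrix: ExpressionMatrix
    labels: tuple[str, ...]
    class_names: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "labels", tuple(self.labels))
        object.__setattr__(self, "class_names", tuple(self.class_names))
        if len(self.labels) != self.matrix.n_cells:
            raise DataFormatError("labels not aligned 1:1 with cells")
        _check_unique(self.class_names, "class")
        known = set(self.class_names)
        unknown = sorted({l for l in self.labels if l not in known})
        if unknown:
            raise DataFormatError(f"labels not in class_names: {unknown}")
        present = set(self.labels)
        empty = [c for c in self.class_names if c not in present]
        if empty:
            raise DataFormatError(f"classes with no cells: {empty}")
        if len(self.class_names) < 2:
            raise DataFormatError("need at least 2 classes")

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    def label_codes(self) -> np.ndarray:
        """Labels encoded as integers 0..C-1 in ``class_names`` order."""
        code = {c: i for i, c in enumerate(self.class_names)}
        return np.asarray([code[l] for l in self.labels], dtype=np.int64)

    def class_sizes(self) -> dict[str, int]:
        codes = self.label_codes()
        counts = np.bincount(codes, minlength=self.n_classes)
        return {c: int(n) for c, n in zip(self.class_names, counts)}

    def subset_cells(self, index: np.ndarray) -> "LabeledDataset":
        index = np.asarray(index, dtype=np.intp)
        return LabeledDataset(
            self.matrix.subset_cells(index),
            tuple(self.labels[i] for i in index),
            self.class_names,
        )


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def read_csv_matrix(path: str | Path) -> ExpressionMatrix:
    """Read a dense cells x genes CSV (header = gene IDs, first column = barcodes)."""
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        header = next(csv.reader(fh))
    gene_ids = [g.strip() for g in header[1:]]
    _check_unique(gene_ids, "gene")
    df = pd.read_csv(path, index_col=0)
    cell_ids = [str(c) for c in df.index]
    _check_unique(cell_ids, "cell")
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise DataFormatError(f"non-numeric counts in {path}")
    return ExpressionMatrix(tuple(cell_ids), tuple(gene_ids), values, Layer.RAW_COUNTS)


def write_csv_matrix(m: ExpressionMatrix, path: str | Path) -> None:
    df = m.to_dataframe()
    if m.layer == Layer.RAW_COUNTS:
        df = df.astype(np.int64)
    df.to_csv(path)


def _read_id_column(path: str | Path, what: str) -> list[str]:
    ids = [
        line.split("\t")[0].strip()
        for line in Path(path).read_text(encoding="utf-8").splitlines()
        if line.strip()
    ]
    _check_unique(ids, what)
    return ids


def read_mtx_matrix(
    matrix_path: str | Path, genes_path: str | Path, barcodes_path: str | Path
) -> ExpressionMatrix:
    """Read a Matrix Market triplet file (genes x cells on disk) plus ID files."""
    gene_ids = _read_id_column(genes_path, "gene")
    cell_ids = _read_id_column(barcodes_path, "cell")
    mat = spio.mmread(str(matrix_path))
    if sparse.issparse(mat):
        mat = mat.toarray()
    mat = np.asarray(mat, dtype=np.float64)
    if mat.shape != (len(gene_ids), len(cell_ids)):
        raise DataFormatError(
            f"matrix shape {mat.shape} does not match {len(gene_ids)} genes "
            f"x {len(cell_ids)} barcodes"
        )
    return ExpressionMatrix(tuple(cell_ids), tuple(gene_ids), mat.T, Layer.RAW_COUNTS)


def write_mtx_matrix(
    m: ExpressionMatrix,
    matrix_path: str | Path,
    genes_path: str | Path,
    barcodes_path: str | Path,
) -> None:
    spio.mmwrite(str(matrix_path), sparse.coo_matrix(m.values.T))
    Path(genes_path).write_text("\n".join(m.gene_ids) + "\n", encoding="utf-8")
    Path(barcodes_path).write_text("\n".join(m.cell_ids) + "\n", encoding="utf-8")


def read_labels(path: str | Path) -> dict[str, str]:
    """Read a two-column (barcode, class) TSV into a barcode -> class mapping."""
    mapping: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 2:
            raise DataFormatError(f"{path}:{lineno}: expected 2 tab-separated columns")
        barcode, label = parts[0].strip(), parts[1].strip()
        if barcode in mapping:
            raise DataFormatError(f"duplicate barcode in labels file: {barcode!r}")
        mapping[barcode] = label
    return mapping


def write_labels(d: LabeledDataset, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for barcode, label in zip(d.matrix.cell_ids, d.labels):
            fh.write(f"{barcode}\t{label}\n")


def read_dataset(
    matrix_path: str | Path,
    format: str,
    labels_path: str | Path,
    genes_path: str | Path | None = None,
    barcodes_path: str | Path | None = None,
) -> LabeledDataset:
    """Read a raw-count matrix plus labels and join them by barcode.

    Label order is matched to the matrix barcode order by an ID join, never by
    file order. Cells present in the matrix but absent from the labels file
    are a hard error listing the offending barcodes; extra labelled barcodes
    not in the matrix are ignored. ``class_names`` is the sorted set of
    observed labels (a deterministic, cell-order-invariant convention).
    """
    if format == "csv":
        matrix = read_csv_matrix(matrix_path)
    elif format == "mtx":
        if genes_path is None or barcodes_path is None:
            raise DataFormatError("mtx format requires genes_path and barcodes_path")
        matrix = read_mtx_matrix(matrix_path, genes_path, barcodes_path)
    else:
        raise DataFormatError(f"unknown format {format!r} (expected 'csv' or 'mtx')")
    mapping = read_labels(labels_path)
    missing = [c for c in matrix.cell_ids if c not in mapping]
    if missing:
        raise DataFormatError(f"cells missing from labels file: {missing[:10]}")
    labels = tuple(mapping[c] for c in matrix.cell_ids)
    class_names = tuple(sorted(set(labels)))
    return LabeledDataset(matrix, labels, class_names)


# ---------------------------------------------------------------------------
# normalization and splitting
# ---------------------------------------------------------------------------


def normalize_log2(m: ExpressionMatrix) -> ExpressionMatrix:
    """Replace every count v by log2(v + 1). Re-normalizing is refused."""
    if m.layer != Layer.RAW_COUNTS:
        raise DataFormatError("matrix is already normalized (layer != raw_counts)")
    return ExpressionMatrix(m.cell_ids, m.gene_ids, np.log2(m.values + 1.0), Layer.LOG2P1)


def normalize_dataset(d: LabeledDataset) -> LabeledDataset:
    return LabeledDataset(normalize_log2(d.matrix), d.labels, d.class_names)


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def stratified_split(
    d: LabeledDataset, test_fraction: float, seed: int
) -> tuple[LabeledDataset, LabeledDataset]:
    """Seeded, stratified partition into (train, test).

    Per class the test count is ``round(class_size * test_fraction)`` with
    half-away-from-zero rounding, then repaired into ``[1, class_size - 1]``
    so both splits keep at least one cell of every class. Cells keep their
    original relative order within each split.
    """
    if not 0.0 < test_fraction < 1.0:
        raise ValueError(f"test_fraction must be in (0, 1), got {test_fraction}")
    for cls, n in d.class_sizes().items():
        if n < 2:
            raise DataFormatError(f"class {cls!r} has {n} cell(s); need >= 2 to split")
    rng = np.random.default_rng(seed)
    codes = d.label_codes()
    test_mask = np.zeros(d.matrix.n_cells, dtype=bool)
    for ci in range(d.n_classes):
        idx = np.flatnonzero(codes == ci)
        n_test = min(max(_round_half_away(len(idx) * test_fraction), 1), len(idx) - 1)
        chosen = rng.permutation(idx)[:n_test]
        test_mask[chosen] = True
    train = d.subset_cells(np.flatnonzero(~test_mask))
    test = d.subset_cells(np.flatnonzero(test_mask))
    return train, test
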