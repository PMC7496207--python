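"""Reading, writing and aligning cells × genes expression matrices.

The in-memory container is :class:`ExpressionDataset`: a dense non-negative
matrix with rows = cells and columns = genes, plus gene names, cell barcodes
and (for reference data) one cell-type label per cell. On-disk formats are
dense CSV/TSV (header row + index column, either orientation) and
MatrixMarket coordinate triplets with newline-delimited gene/barcode sidecar
files, as produced by 10x-style exports. All orientations are normalized to
cells × genes at read time.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

#: Reserved output token for cells rejected by every classifier stage.
#: Reference labels may not use it.
UNASSIGNED = "unassigned"


@dataclass
class ExpressionDataset:
    """A cells × genes expression matrix with names and optional labels.

    Parameters
    ----------
    values
        Non-negative, finite matrix of shape ``(n_cells, n_genes)``.
    gene_names
        Unique gene identifiers, one per column.
    cell_ids
        Unique cell barcodes, one per row.
    labels
        Optional cell-type label per cell. ``"unassigned"`` is reserved for
        classifier output and rejected here.
    """

    values: np.ndarray
    gene_names: list[str]
    cell_ids: list[str]
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("expression matrix must be 2-dimensional")
        self.gene_names = [str(g) for g in self.gene_names]
        self.cell_ids = [str(c) for c in self.cell_ids]
        n, p = self.values.shape
        if len(self.gene_names) != p:
            raise ValueError(
                f"{len(self.gene_names)} gene names for {p} matrix columns"
            )
        if len(self.cell_ids) != n:
            raise ValueError(f"{len(self.cell_ids)} cell ids for {n} matrix rows")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite")
        if np.any(self.values < 0):
            raise ValueError("negative expression values are not allowed")
        dup = _duplicates(self.gene_names)
        if dup:
            raise ValueError(f"duplicate gene names: {sorted(dup)}")
        dup = _duplicates(self.cell_ids)
        if dup:
            raise ValueError(f"duplicate cell ids: {sorted(dup)}")
        if self.labels is not None:
            self.labels = [str(l) for l in self.labels]
            if len(self.labels) != n:
                raise ValueError(f"{len(self.labels)} labels for {n} cells")
            if any(l == "" for l in self.labels):
                raise ValueError("empty label strings are not allowed")
            if UNASSIGNED in self.labels:
                raise ValueError(
                    f"label {UNASSIGNED!r} is reserved for classifier output"
                )

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, genes: list[str]) -> "ExpressionDataset":
        """Return a copy restricted to ``genes``, in the given order."""
        index = {g: j for j, g in enumerate(self.gene_names)}
        missing = [g for g in genes if g not in index]
        if missing:
            raise KeyError(f"genes not present in dataset: {missing}")
        cols = [index[g] for g in genes]
        return replace(self, values=self.values[:, cols], gene_names=list(genes))

    def subset_cells(self, rows: np.ndarray) -> "ExpressionDataset":
        """Return a copy restricted to the cell rows in ``rows``."""
        rows = np.asarray(rows)
        return replace(
            self,
            values=self.values[rows],
            cell_ids=[self.cell_ids[i] for i in rows],
            labels=None if self.labels is None else [self.labels[i] for i in rows],
        )


def _duplicates(items: list[str]) -> set[str]:
    seen: set[str] = set()
    dup: set[str] = set()
    for x in items:
        (dup if x in seen else seen).add(x)
    return dup


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","


def _read_labels(label_path: str | Path, cell_ids: list[str]) -> list[str]:
    """Read a two-column cell_id,label file and match by key to cell_ids."""
    label_path = Path(label_path)
    table = pd.read_csv(label_path, sep=_sep_for(label_path), header=0, dtype=str)
    if table.shape[1] < 2:
        raise ValueError("label file must have two columns: cell_id,label")
    mapping = dict(zip(table.iloc[:, 0], table.iloc[:, 1]))
    known = set(cell_ids)
    unknown = [c for c in mapping if c not in known]
    if unknown:
        raise ValueError(f"label file contains unknown cell ids: {sorted(unknown)}")
    missing = [c for c in cell_ids if c not in mapping]
    if missing:
        raise ValueError(f"label file is missing cell ids: {sorted(missing)}")
    return [mapping[c] for c in cell_ids]


def read_dense(
    path: str | Path,
    orientation: str = "cells-by-genes",
    label_path: str | Path | None = None,
    uppercase_genes: bool = False,
) -> ExpressionDataset:
    """Read a dense CSV/TSV expression matrix.

    Parameters
    ----------
    path
        CSV or TSV file with one header row of names and one index column.
    orientation
        ``"cells-by-genes"`` or ``"genes-by-cells"``; the on-disk layout.
        The returned dataset is always cells × genes.
    label_path
        Optional two-column ``cell_id,label`` file; rows are matched to the
        matrix by cell id, not by position.
    uppercase_genes
        Normalize gene names to upper case before uniqueness checks and
        matching.
    """
    path = Path(path)
    if orientation not in {"cells-by-genes", "genes-by-cells"}:
        raise ValueError(f"unknown orientation {orientation!r}")
    frame = pd.read_csv(path, sep=_sep_for(path), header=0, index_col=0)
    if orientation == "genes-by-cells":
        frame = frame.T
    values = frame.to_numpy(dtype=float)
    if np.any(values < 0):
        raise ValueError(f"negative expression values in {path}")
    gene_names = [str(g) for g in frame.columns]
    if uppercase_genes:
        gene_names = [g.upper() for g in gene_names]
    cell_ids = [str(c) for c in frame.index]
    labels = _read_labels(label_path, cell_ids) if label_path is not None else None
    return ExpressionDataset(values, gene_names, cell_ids, labels)


def read_sparse_triplet(
    matrix_path: str | Path,
    genes_path: str | Path,
    barcodes_path: str | Path,
    label_path: str | Path | None = None,
    orientation: str = "genes-by-cells",
    uppercase_genes: bool = False,
) -> ExpressionDataset:
    """Read a MatrixMarket coordinate matrix with gene/barcode sidecars.

    Follows the 10x convention: the matrix is genes × cells on disk (rows
    named by ``genes_path``, columns by ``barcodes_path``) unless
    ``orientation="cells-by-genes"``. Entries absent from the triplet list
    are exact zeros. MatrixMarket coordinate indices are 1-based.
    """
    matrix_path = Path(matrix_path)
    _check_one_based(matrix_path)
    try:
        mat = scipy.io.mmread(matrix_path)
    except ValueError as exc:
        raise ValueError(f"malformed MatrixMarket file {matrix_path}: {exc}") from exc
    mat = scipy.sparse.coo_matrix(mat)
    genes = _read_names(genes_path)
    barcodes = _read_names(barcodes_path)
    if orientation == "genes-by-cells":
        expected = (len(genes), len(barcodes))
    elif orientation == "cells-by-genes":
        expected = (len(barcodes), len(genes))
    else:
        raise ValueError(f"unknown orientation {orientation!r}")
    if mat.shape != expected:
        raise ValueError(
            f"matrix dimensions {mat.shape} inconsistent with sidecar lengths "
            f"{expected} ({len(genes)} genes, {len(barcodes)} barcodes)"
        )
    dense = mat.toarray().astype(float)
    if orientation == "genes-by-cells":
        dense = dense.T
    if uppercase_genes:
        genes = [g.upper() for g in genes]
    labels = _read_labels(label_path, barcodes) if label_path is not None else None
    return ExpressionDataset(dense, genes, barcodes, labels)


def _check_one_based(matrix_path: Path) -> None:
    # MatrixMarket coordinate indices start at 1; an explicit 0 index means
    # the producer wrote 0-based triplets.
    with open(matrix_path) as fh:
        header_seen = False
        for line in fh:
            line = line.strip()
            if not line or line.startswith("%"):
                continue
            if not header_seen:  # dimension line
                header_seen = True
                continue
            parts = line.split()
            if len(parts) >= 2 and (parts[0] == "0" or parts[1] == "0"):
                raise ValueError(
                    f"zero index in {matrix_path}: 1-based indices expected"
                )


def _read_names(path: str | Path) -> list[str]:
    with open(path) as fh:
        names = [line.strip() for line in fh if line.strip()]
    # 10x gene files are often two-column (id, symbol); keep the first field
    return [n.split("\t")[0].split(",")[0] for n in names]


def write_dense(
    dataset: ExpressionDataset,
    path: str | Path,
    label_path: str | Path | None = None,
) -> None:
    """Write cells × genes CSV/TSV (and labels, if present and requested)."""
    path = Path(path)
    frame = pd.DataFrame(
        dataset.values, index=dataset.cell_ids, columns=dataset.gene_names
    )
    frame.to_csv(path, sep=_sep_for(path))
    if label_path is not None:
        if dataset.labels is None:
            raise ValueError("dataset has no labels to write")
        lp = Path(label_path)
        pd.DataFrame(
            {"cell_id": dataset.cell_ids, "label": dataset.labels}
        ).to_csv(lp, sep=_sep_for(lp), index=False)


def write_predictions(
    cell_ids: list[str], predictions: list[str], path: str | Path
) -> None:
    """Write per-cell predictions as CSV ``cell_id,predicted_label``."""
    pd.DataFrame({"cell_id": cell_ids, "predicted_label": predictions}).to_csv(
        Path(path), index=False
    )


def align_common_genes(
    reference: ExpressionDataset, query: ExpressionDataset
) -> tuple[ExpressionDataset, ExpressionDataset, list[str]]:
    """Restrict both datasets to their shared genes, in reference order.

    Returns ``(reference, query, shared)`` where both datasets carry exactly
    the genes in ``shared`` — the intersection ordered by the reference
    dataset's original gene order.
    """
    if reference.n_cells == 0 or query.n_cells == 0:
        raise ValueError("cannot align empty datasets")
    query_genes = set(query.gene_names)
    shared = [g for g in reference.gene_names if g in query_genes]
    if not shared:
        raise ValueError("no shared genes between reference and query")
    return reference.subset_genes(shared), query.subset_genes(shared), shared
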