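"""Count-matrix container, readers/writers, per-cell QC and normalization.

The pipeline works on genes x cells matrices of raw UMI counts. Two on-disk
encodings are supported: the 10x-style Matrix Market triplet
(``matrix.mtx`` + ``features.tsv`` + ``barcodes.tsv``) and a dense CSV with
genes in rows, the gene id in the first column and one column per cell
barcode.

Cell quality control follows the two printed rules used throughout the
analysis: a cell is discarded when it has 1,250 or fewer detected genes, or
when more than 25% of its molecules map to mitochondrial genes. Bursting
inference downstream consumes the *raw* counts of QC-passed cells; the
log-normalized layer produced here feeds only the correlation and
differential-expression stages.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = [
    "CountMatrix",
    "FormatError",
    "compute_cell_qc",
    "filter_cells",
    "normalize",
    "read_count_matrix",
    "write_count_matrix",
]

DEFAULT_MIN_GENES = 1250
DEFAULT_MAX_MITO = 0.25
SCALE_FACTOR = 10_000.0


class FormatError(ValueError):
    """Raised when an on-disk matrix violates the format contract."""


@dataclass
class CountMatrix:
    """Integer UMI counts, genes x cells, with per-cell sample labels.

    Parameters
    ----------
    counts
        Sparse CSR matrix of nonnegative integers, shape (n_genes, n_cells).
    gene_ids
        Gene symbols/ids, length n_genes.
    barcodes
        Unique cell barcodes, length n_cells.
    sample_labels
        One sample (cell line) label per cell.
    tag_genes
        Gene ids treated as exogenous tags (e.g. Dendra2, HaloTag).
    mito_genes
        Explicit mitochondrial gene list; when None, genes whose symbol
        starts with "MT-" (case-insensitive) are flagged.
    """

    counts: sp.csr_matrix
    gene_ids: np.ndarray
    barcodes: np.ndarray
    sample_labels: np.ndarray
    tag_genes: tuple[str, ...] = ()
    mito_genes: tuple[str, ...] | None = None
    is_mito: np.ndarray = field(init=False)
    is_tag: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.barcodes = np.asarray(self.barcodes, dtype=object)
        self.sample_labels = np.asarray(self.sample_labels, dtype=object)
        if self.counts.shape != (len(self.gene_ids), len(self.barcodes)):
            raise FormatError(
                f"counts shape {self.counts.shape} inconsistent with "
                f"{len(self.gene_ids)} genes x {len(self.barcodes)} cells"
            )
        if len(self.sample_labels) != len(self.barcodes):
            raise FormatError("one sample label required per cell")
        dup = pd.Index(self.barcodes).duplicated()
        if dup.any():
            raise FormatError(f"duplicate barcode: {self.barcodes[dup][0]!r}")
        data = self.counts.data
        if data.size and (np.any(data < 0) or np.any(data != np.floor(data))):
            bad = data[(data < 0) | (data != np.floor(data))][0]
            raise FormatError(f"non-integer or negative count entry: {bad!r}")
        self.counts = self.counts.astype(np.int64)
        if self.mito_genes is None:
            self.is_mito = np.array(
                [str(g).upper().startswith("MT-") for g in self.gene_ids]
            )
        else:
            mito = set(self.mito_genes)
            self.is_mito = np.array([g in mito for g in self.gene_ids])
        tags = set(self.tag_genes)
        self.is_tag = np.array([g in tags for g in self.gene_ids])

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.barcodes)

    @property
    def samples(self) -> list[str]:
        """Sample labels in first-appearance order."""
        return list(pd.unique(self.sample_labels))

    def subset_cells(self, mask: np.ndarray) -> "CountMatrix":
        mask = np.asarray(mask)
        if mask.dtype == bool and len(mask) != self.n_cells:
            raise ValueError("cell mask length mismatch")
        return CountMatrix(
            self.counts[:, mask],
            self.gene_ids,
            self.barcodes[mask],
            self.sample_labels[mask],
            tag_genes=self.tag_genes,
            mito_genes=self.mito_genes,
        )

    def subset_genes(self, mask: np.ndarray) -> "CountMatrix":
        mask = np.asarray(mask)
        return CountMatrix(
            self.counts[mask, :],
            self.gene_ids[mask],
            self.barcodes,
            self.sample_labels,
            tag_genes=self.tag_genes,
            mito_genes=self.mito_genes,
        )

    def sample_view(self, sample: str) -> "CountMatrix":
        """Cells of one sample, in their stored order."""
        mask = self.sample_labels == sample
        if not mask.any():
            raise KeyError(f"unknown sample {sample!r}")
        return self.subset_cells(mask)

    def gene_index(self, gene: str) -> int:
        hits = np.flatnonzero(self.gene_ids == gene)
        if hits.size == 0:
            raise KeyError(f"gene {gene!r} not present in matrix")
        return int(hits[0])

    def dense(self) -> np.ndarray:
        return np.asarray(self.counts.todense())


@dataclass(frozen=True)
class NormalizedMatrix:
    """ln(1 + 10,000 * count / cell_total) expression layer, genes x cells."""

    values: sp.csr_matrix
    gene_ids: np.ndarray
    barcodes: np.ndarray
    sample_labels: np.ndarray

    def dense(self) -> np.ndarray:
        return np.asarray(self.values.todense())

    def gene_vector(self, gene: str) -> np.ndarray:
        hits = np.flatnonzero(self.gene_ids == gene)
        if hits.size == 0:
            raise KeyError(f"gene {gene!r} not present in matrix")
        return np.asarray(self.values[int(hits[0])].todense()).ravel()


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

def write_count_matrix(matrix: CountMatrix, path: str | Path, format: str = "mtx-triplet") -> None:
    """Write a CountMatrix as a 10x-style MTX triplet or dense CSV.

    ``mtx-triplet`` writes ``matrix.mtx``, ``features.tsv`` (gene id, gene id,
    "Gene Expression"; tab-separated, no header), ``barcodes.tsv`` and a
    ``samples.tsv`` companion carrying the per-cell sample label. ``dense-csv``
    writes ``counts.csv`` (genes x cells) plus ``samples.tsv``.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    samples = pd.DataFrame(
        {"barcode": matrix.barcodes, "sample": matrix.sample_labels}
    )
    samples.to_csv(path / "samples.tsv", sep="\t", index=False)
    if format == "mtx-triplet":
        scipy.io.mmwrite(str(path / "matrix.mtx"), matrix.counts.tocoo(), field="integer")
        feats = pd.DataFrame(
            {"id": matrix.gene_ids, "name": matrix.gene_ids, "type": "Gene Expression"}
        )
        feats.to_csv(path / "features.tsv", sep="\t", index=False, header=False)
        pd.Series(matrix.barcodes).to_csv(
            path / "barcodes.tsv", sep="\t", index=False, header=False
        )
    elif format == "dense-csv":
        df = pd.DataFrame(matrix.dense(), index=matrix.gene_ids, columns=matrix.barcodes)
        df.index.name = "gene"
        df.to_csv(path / "counts.csv")
    else:
        raise ValueError(f"unknown format {format!r}")


def read_count_matrix(
    path: str | Path,
    format: str = "mtx-triplet",
    tag_genes: tuple[str, ...] = (),
    mito_genes: tuple[str, ...] | None = None,
    default_sample: str = "sample1",
) -> CountMatrix:
    """Read a count matrix written by :func:`write_count_matrix`.

    A ``samples.tsv`` companion (barcode -> sample label) is honoured when
    present; otherwise every cell is assigned ``default_sample``.
    """
    path = Path(path)
    if format == "mtx-triplet":
        mtx_path = path / "matrix.mtx"
        if not mtx_path.exists():
            raise FormatError(f"missing {mtx_path}")
        raw = scipy.io.mmread(str(mtx_path))
        coo = sp.coo_matrix(raw)
        if coo.data.size and np.any(coo.data != np.floor(coo.data)):
            i = int(np.flatnonzero(coo.data != np.floor(coo.data))[0])
            raise FormatError(
                f"non-integer entry {coo.data[i]!r} at (row {coo.row[i] + 1}, "
                f"col {coo.col[i] + 1}) in {mtx_path}"
            )
        counts = coo.tocsr()
        feats = pd.read_csv(path / "features.tsv", sep="\t", header=None)
        gene_ids = feats.iloc[:, 0].astype(str).to_numpy()
        barcodes = (
            pd.read_csv(path / "barcodes.tsv", sep="\t", header=None)
            .iloc[:, 0]
            .astype(str)
            .to_numpy()
        )
    elif format == "dense-csv":
        csv_path = path / "counts.csv"
        if not csv_path.exists():
            raise FormatError(f"missing {csv_path}")
        df = pd.read_csv(csv_path, index_col=0)
        vals = df.to_numpy()
        if np.any(vals != np.floor(vals)):
            r, c = np.argwhere(vals != np.floor(vals))[0]
            raise FormatError(
                f"non-integer entry {vals[r, c]!r} for gene {df.index[r]!r}, "
                f"barcode {df.columns[c]!r} in {csv_path}"
            )
        counts = sp.csr_matrix(vals.astype(np.int64))
        gene_ids = df.index.astype(str).to_numpy()
        barcodes = df.columns.astype(str).to_numpy()
    else:
        raise ValueError(f"unknown format {format!r}")

    samples_path = path / "samples.tsv"
    if samples_path.exists():
        smp = pd.read_csv(samples_path, sep="\t").set_index("barcode")["sample"]
        try:
            sample_labels = smp.loc[barcodes].astype(str).to_numpy()
        except KeyError as exc:
            raise FormatError(f"samples.tsv missing barcode: {exc}") from exc
    else:
        sample_labels = np.repeat(default_sample, len(barcodes))
    return CountMatrix(
        counts, gene_ids, barcodes, sample_labels,
        tag_genes=tag_genes, mito_genes=mito_genes,
    )


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

def compute_cell_qc(matrix: CountMatrix) -> pd.DataFrame:
    """Per-cell QC metrics.

    Returns a DataFrame indexed by barcode with columns ``n_detected``
    (genes with count > 0), ``total_counts``, ``mito_fraction`` and
    ``degenerate`` (True for zero-total cells, whose mitochondrial fraction
    is undefined and stored as NaN — such cells are always removed).
    """
    counts = matrix.counts.tocsc()
    n_detected = np.asarray((counts > 0).sum(axis=0)).ravel()
    total = np.asarray(counts.sum(axis=0)).ravel().astype(float)
    mito_total = np.asarray(counts[matrix.is_mito, :].sum(axis=0)).ravel().astype(float)
    degenerate = total == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_fraction = np.where(degenerate, np.nan, mito_total / np.where(degenerate, 1.0, total))
    return pd.DataFrame(
        {
            "barcode": matrix.barcodes,
            "sample": matrix.sample_labels,
            "n_detected": n_detected,
            "total_counts": total.astype(np.int64),
            "mito_fraction": mito_fraction,
            "degenerate": degenerate,
        }
    ).set_index("barcode")


def filter_cells(
    matrix: CountMatrix,
    qc: pd.DataFrame | None = None,
    min_genes: int = DEFAULT_MIN_GENES,
    max_mito: float = DEFAULT_MAX_MITO,
) -> tuple[CountMatrix, pd.DataFrame]:
    """Apply the cell filters: keep cells with strictly more than
    ``min_genes`` detected genes AND mitochondrial fraction <= ``max_mito``.

    Boundary semantics follow the printed rules: a cell with exactly
    ``min_genes`` detected genes is removed ("1,250 or less"); a cell at
    exactly ``max_mito`` is retained ("more than 25%" is the exclusion).
    Zero-total (degenerate) cells are always removed.

    Returns the filtered matrix and the QC table with a ``kept`` column.
    """
    if qc is None:
        qc = compute_cell_qc(matrix)
    if len(qc) != matrix.n_cells or not np.array_equal(
        qc.index.to_numpy(), matrix.barcodes
    ):
        raise ValueError("QC table not aligned with matrix cells")
    kept = (
        (qc["n_detected"].to_numpy() > min_genes)
        & ~qc["degenerate"].to_numpy()
        & (np.nan_to_num(qc["mito_fraction"].to_numpy(), nan=1.0) <= max_mito)
    )
    report = qc.copy()
    report["kept"] = kept
    return matrix.subset_cells(kept), report


def normalize(matrix: CountMatrix) -> NormalizedMatrix:
    """Library-size normalization: ln(1 + 10,000 * count / cell_total).

    Every cell must have positive total counts (zero-total cells never pass
    the detected-genes filter; reaching this stage with one is a contract
    violation). Zero counts map to exactly 0, so sparsity is preserved.
    """
    totals = np.asarray(matrix.counts.sum(axis=0)).ravel().astype(float)
    if np.any(totals == 0):
        bad = matrix.barcodes[totals == 0][0]
        raise ValueError(f"zero-total cell reached normalization: {bad!r}")
    # scale each column by 1e4 / total, then log1p on the stored nonzeros
    scale = SCALE_FACTOR / totals
    csc = (matrix.counts.tocsc().astype(float) @ sp.diags(scale)).tocsc()
    csc.data = np.log1p(csc.data)
    return NormalizedMatrix(
        csc.tocsr(), matrix.gene_ids, matrix.barcodes, matrix.sample_labels
    )
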