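"""Cell/gene QC filtering, log normalization, and metadata subsetting.

Core matrix containers live here too: :class:`CountMatrix` holds sparse
gene-by-cell integer counts, :class:`NormalizedMatrix` the log-normalized
counterpart, and cell annotations travel as a plain :class:`pandas.DataFrame`
validated by :func:`validate_cell_meta`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

CONDITIONS = ("control", "stressed")
META_COLUMNS = ("barcode", "species", "cell_type", "condition", "sample")


class QcError(ValueError):
    """Raised when QC filtering cannot proceed or empties the dataset."""


def _check_unique(labels: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for lab in labels:
        if lab in seen:
            raise ValueError(f"duplicate {what}: {lab!r}")
        seen.add(lab)


@dataclass
class CountMatrix:
    """Sparse nonnegative-integer counts; genes on rows, cells on columns."""

    genes: list[str]
    barcodes: list[str]
    x: sp.csr_matrix

    def __post_init__(self) -> None:
        self.x = sp.csr_matrix(self.x)
        if self.x.shape != (len(self.genes), len(self.barcodes)):
            raise ValueError(
                f"matrix shape {self.x.shape} does not match "
                f"{len(self.genes)} genes x {len(self.barcodes)} barcodes"
            )
        _check_unique(self.genes, "gene label")
        _check_unique(self.barcodes, "barcode")
        if self.x.nnz and self.x.data.min() < 0:
            raise ValueError("negative count entries are not allowed")
        if not np.issubdtype(self.x.dtype, np.integer):
            data = self.x.data
            if not np.all(data == np.floor(data)):
                raise ValueError("count matrix contains non-integer values")
            self.x = self.x.astype(np.int64)

    @property
    def shape(self) -> tuple[int, int]:
        return self.x.shape

    def gene_index(self, gene: str) -> int:
        try:
            return self.genes.index(gene)
        except ValueError:
            raise KeyError(f"gene {gene!r} not present") from None

    def equals(self, other: "CountMatrix") -> bool:
        return (
            self.genes == other.genes
            and self.barcodes == other.barcodes
            and (self.x != other.x).nnz == 0
        )


@dataclass
class NormalizedMatrix:
    """Log-normalized expression with the same axes as its source counts."""

    genes: list[str]
    barcodes: list[str]
    x: sp.csr_matrix

    def __post_init__(self) -> None:
        self.x = sp.csr_matrix(self.x)
        if self.x.shape != (len(self.genes), len(self.barcodes)):
            raise ValueError("matrix shape does not match axis labels")
        _check_unique(self.genes, "gene label")
        _check_unique(self.barcodes, "barcode")

    @property
    def shape(self) -> tuple[int, int]:
        return self.x.shape

    def gene_index(self, gene: str) -> int:
        try:
            return self.genes.index(gene)
        except ValueError:
            raise KeyError(f"gene {gene!r} not present") from None


@dataclass
class QcThresholds:
    """Per-cell and per-gene QC cutoffs; all default to permissive stand-ins.

    The reanalysed studies applied the filters of their source publications,
    whose exact values are not restated; every threshold here is therefore
    configurable rather than asserted.
    """

    min_counts_per_cell: int = 500
    min_genes_per_cell: int = 200
    max_counts_per_cell: Optional[int] = None
    min_cells_per_gene: int = 3

    def __post_init__(self) -> None:
        for name in ("min_counts_per_cell", "min_genes_per_cell", "min_cells_per_gene"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.max_counts_per_cell is not None and self.max_counts_per_cell < 0:
            raise ValueError("max_counts_per_cell must be >= 0")


def validate_cell_meta(meta: pd.DataFrame) -> pd.DataFrame:
    """Check the per-cell annotation table invariants and return it.

    Requires the columns barcode/species/cell_type/condition/sample, unique
    barcodes, and conditions restricted to the closed control/stressed
    vocabulary.
    """
    missing = [c for c in META_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"cell metadata missing columns: {missing}")
    dup = meta["barcode"][meta["barcode"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate barcode in cell metadata: {dup.iloc[0]!r}")
    bad = set(meta["condition"]) - set(CONDITIONS)
    if bad:
        raise ValueError(
            f"unknown condition labels {sorted(bad)}; allowed: {list(CONDITIONS)}"
        )
    return meta


@dataclass
class QcReport:
    n_cells_in: int = 0
    n_genes_in: int = 0
    removed_low_counts: int = 0
    removed_low_genes: int = 0
    removed_high_counts: int = 0
    removed_genes_low_cells: int = 0
    n_cells_out: int = 0
    n_genes_out: int = 0
    thresholds: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def qc_filter(
    counts: CountMatrix, meta: pd.DataFrame, thr: QcThresholds
) -> tuple[CountMatrix, pd.DataFrame, QcReport]:
    """Remove failing cells, then sparsely-detected genes.

    Order is fixed (cells first, then genes) so the result is deterministic.
    A cell is removed if it fails *any* per-cell rule; gene detection counts
    are computed on the surviving cells only.
    """
    validate_cell_meta(meta)
    if list(meta["barcode"]) != counts.barcodes:
        raise ValueError("metadata barcodes do not match count matrix barcodes")

    x = counts.x.tocsc()
    cell_totals = np.asarray(x.sum(axis=0)).ravel()
    genes_per_cell = np.asarray((x > 0).sum(axis=0)).ravel()

    keep = np.ones(x.shape[1], dtype=bool)
    rep = QcReport(
        n_cells_in=x.shape[1],
        n_genes_in=x.shape[0],
        thresholds={
            "min_counts_per_cell": thr.min_counts_per_cell,
            "min_genes_per_cell": thr.min_genes_per_cell,
            "max_counts_per_cell": thr.max_counts_per_cell,
            "min_cells_per_gene": thr.min_cells_per_gene,
        },
    )

    low_counts = cell_totals < thr.min_counts_per_cell
    low_genes = genes_per_cell < thr.min_genes_per_cell
    rep.removed_low_counts = int(low_counts.sum())
    rep.removed_low_genes = int(low_genes.sum())
    keep &= ~low_counts
    keep &= ~low_genes
    if thr.max_counts_per_cell is not None:
        high = cell_totals > thr.max_counts_per_cell
        rep.removed_high_counts = int(high.sum())
        keep &= ~high

    if not keep.any():
        raise QcError("empty dataset after QC: all cells removed")

    x = x[:, keep]
    kept_barcodes = [b for b, k in zip(counts.barcodes, keep) if k]

    cells_per_gene = np.asarray((x > 0).sum(axis=1)).ravel()
    gene_keep = cells_per_gene >= thr.min_cells_per_gene
    rep.removed_genes_low_cells = int((~gene_keep).sum())
    x = x[gene_keep, :]
    kept_genes = [g for g, k in zip(counts.genes, gene_keep) if k]

    rep.n_cells_out = len(kept_barcodes)
    rep.n_genes_out = len(kept_genes)

    out_counts = CountMatrix(kept_genes, kept_barcodes, x.tocsr())
    out_meta = meta.loc[keep].reset_index(drop=True)
    return out_counts, out_meta, rep


def lognormalize(counts: CountMatrix, scale: float = 1e4) -> NormalizedMatrix:
    """Library-size normalize to ``scale`` counts per cell, then ln(1+x).

    value(g, i) = ln(1 + scale * count(g, i) / total(i)). Zeros stay zero,
    so sparsity is preserved exactly.
    """
    x = counts.x.tocsc().astype(np.float64)
    totals = np.asarray(x.sum(axis=0)).ravel()
    if np.any(totals == 0):
        idx = int(np.flatnonzero(totals == 0)[0])
        raise QcError(
            f"cell {counts.barcodes[idx]!r} has zero total count; "
            "run qc_filter before lognormalize"
        )
    # scale each column by scale/total, then log1p on stored entries only
    x = x @ sp.diags(scale / totals)
    x.data = np.log1p(x.data)
    return NormalizedMatrix(list(counts.genes), list(counts.barcodes), x.tocsr())


def subset_cells(
    meta: pd.DataFrame,
    cell_type: str,
    condition: Optional[str] = None,
    species: Optional[str] = None,
) -> list[str]:
    """Barcodes matching all provided criteria, in stored order.

    ``condition``/``species`` of None mean "any". Unknown labels raise with
    the valid vocabulary; an empty result is legal.
    """
    validate_cell_meta(meta)
    known_types = sorted(set(meta["cell_type"]))
    if cell_type not in known_types:
        raise ValueError(
            f"unknown cell_type {cell_type!r}; valid labels: {known_types}"
        )
    mask = meta["cell_type"] == cell_type
    if condition is not None:
        if condition not in CONDITIONS:
            raise ValueError(
                f"unknown condition {condition!r}; valid labels: {list(CONDITIONS)}"
            )
        mask &= meta["condition"] == condition
    if species is not None:
        known_species = sorted(set(meta["species"]))
        if species not in known_species:
            raise ValueError(
                f"unknown species {species!r}; valid labels: {known_species}"
            )
        mask &= meta["species"] == species
    return list(meta.loc[mask, "barcode"])
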