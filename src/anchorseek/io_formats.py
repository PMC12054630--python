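"""On-disk formats: Matrix-Market count bundles, TSV tables, FASTA, BED, manifests.

All tabular files are TSV (never CSV). Genomic coordinates are stored
internally as :class:`~anchorseek.regulatory.GenomicInterval` (1-based
inclusive in its external string form); BED input/output is converted at the
boundary by the centralized ``GenomicInterval.from_zero_based`` /
``to_zero_based`` pair.
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import scipy
import scipy.io
import scipy.sparse as sp
from Bio import SeqIO

from .preprocess import CountMatrix, validate_cell_meta
from .regulatory import GenomicInterval, Pwm

MTX_FILE = "matrix.mtx"
FEATURES_FILE = "features.tsv"
BARCODES_FILE = "barcodes.tsv"
META_FILE = "cell_meta.tsv"


class FormatError(ValueError):
    """Malformed or inconsistent input file."""


@dataclass
class DatasetBundle:
    counts: CountMatrix
    meta: pd.DataFrame
    species: str
    provenance: str = ""

    def __post_init__(self) -> None:
        validate_cell_meta(self.meta)
        if list(self.meta["barcode"]) != self.counts.barcodes:
            raise FormatError("metadata barcodes do not match count matrix barcodes")


def _read_label_column(path: Path, what: str) -> list[str]:
    labels = [line.rstrip("\n").strip() for line in path.read_text().splitlines()]
    labels = [l for l in labels if l]
    seen: set[str] = set()
    for lab in labels:
        if lab in seen:
            raise FormatError(f"{path.name}: duplicate {what}: {lab!r}")
        seen.add(lab)
    return labels


def write_mtx_bundle(bundle: DatasetBundle, dir_path: str | Path) -> None:
    """Write matrix.mtx + features.tsv + barcodes.tsv + cell_meta.tsv."""
    d = Path(dir_path)
    d.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(d / MTX_FILE, bundle.counts.x.tocoo(), field="integer")
    (d / FEATURES_FILE).write_text("".join(g + "\n" for g in bundle.counts.genes))
    (d / BARCODES_FILE).write_text("".join(b + "\n" for b in bundle.counts.barcodes))
    bundle.meta.to_csv(d / META_FILE, sep="\t", index=False)


def read_mtx_bundle(dir_path: str | Path) -> DatasetBundle:
    """Read a count bundle written by :func:`write_mtx_bundle`.

    Genes are rows, cells are columns. Raises :class:`FormatError` naming any
    missing file, on dimension mismatch, and on non-integer matrix values.
    """
    d = Path(dir_path)
    for fname in (MTX_FILE, FEATURES_FILE, BARCODES_FILE, META_FILE):
        if not (d / fname).is_file():
            raise FormatError(f"missing required file: {d / fname}")

    x = scipy.io.mmread(d / MTX_FILE)
    x = sp.coo_matrix(x)
    if not np.issubdtype(x.dtype, np.integer):
        if not np.all(x.data == np.floor(x.data)):
            raise FormatError(f"{MTX_FILE}: matrix contains non-integer values")
        x = x.astype(np.int64)

    genes = _read_label_column(d / FEATURES_FILE, "gene label")
    barcodes = _read_label_column(d / BARCODES_FILE, "barcode")
    if x.shape != (len(genes), len(barcodes)):
        raise FormatError(
            f"{MTX_FILE} header says {x.shape} but {FEATURES_FILE} has "
            f"{len(genes)} rows and {BARCODES_FILE} has {len(barcodes)} rows"
        )

    meta = pd.read_csv(d / META_FILE, sep="\t", dtype=str)
    validate_cell_meta(meta)
    meta_by_barcode = meta.set_index("barcode", drop=False)
    missing = [b for b in barcodes if b not in meta_by_barcode.index]
    if missing:
        raise FormatError(f"{META_FILE}: no metadata row for barcode {missing[0]!r}")
    meta = meta_by_barcode.loc[barcodes].reset_index(drop=True)

    counts = CountMatrix(genes, barcodes, x.tocsr())
    species = meta["species"].iloc[0] if len(meta) else ""
    return DatasetBundle(counts=counts, meta=meta, species=species, provenance=str(d))


def read_homolog_table(path: str | Path) -> pd.DataFrame:
    """Two-column TSV of (gene_a, gene_b) pairs; many-to-many preserved.

    A first line exactly matching the header names is skipped. Values are
    whitespace-trimmed, case preserved; duplicate identical pairs dropped.
    """
    path = Path(path)
    pairs: list[tuple[str, str]] = []
    seen: set[tuple[str, str]] = set()
    lines = path.read_text().splitlines()
    for lineno, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        fields = [f.strip() for f in line.split("\t")]
        if len(fields) != 2:
            raise FormatError(
                f"{path.name}:{lineno}: expected 2 tab-separated fields, got {len(fields)}"
            )
        if lineno == 1 and [f.lower() for f in fields] == ["gene_a", "gene_b"]:
            continue
        pair = (fields[0], fields[1])
        if pair not in seen:
            seen.add(pair)
            pairs.append(pair)
    return pd.DataFrame(pairs, columns=["gene_a", "gene_b"])


def write_homolog_table(table: pd.DataFrame, path: str | Path) -> None:
    table[["gene_a", "gene_b"]].to_csv(path, sep="\t", index=False)


def read_fasta(path: str | Path) -> list:
    """FASTA records via Biopython; empty files and files not starting with '>' error."""
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            if not line.startswith(">"):
                raise FormatError(
                    f"{path.name}:{lineno}: expected FASTA header line starting with '>'"
                )
            break
        else:
            raise FormatError(f"{path.name}: empty FASTA file")
    return list(SeqIO.parse(str(path), "fasta"))


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """BED3 (0-based half-open) -> internal 1-based inclusive intervals."""
    path = Path(path)
    intervals: list[GenomicInterval] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise FormatError(f"{path.name}:{lineno}: BED line has fewer than 3 fields")
        chrom = fields[0].strip()
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError:
            raise FormatError(
                f"{path.name}:{lineno}: non-integer BED coordinates"
            ) from None
        try:
            intervals.append(GenomicInterval.from_zero_based(chrom, start, end))
        except ValueError as exc:
            raise FormatError(f"{path.name}:{lineno}: {exc}") from None
    return intervals


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            chrom, start, end = iv.to_zero_based()
            fh.write(f"{chrom}\t{start}\t{end}\n")


def read_clinical_table(path: str | Path) -> pd.DataFrame:
    """Subject-level TSV; first column is subject_id, remaining columns numeric."""
    tbl = pd.read_csv(path, sep="\t")
    if tbl.columns[0] != "subject_id":
        raise FormatError(
            f"{Path(path).name}: first column must be 'subject_id', got {tbl.columns[0]!r}"
        )
    if tbl["subject_id"].duplicated().any():
        dup = tbl["subject_id"][tbl["subject_id"].duplicated()].iloc[0]
        raise FormatError(f"{Path(path).name}: duplicate subject_id {dup!r}")
    return tbl


def read_jaspar_pwm(path: str | Path, pseudocount: float = 0.01) -> Pwm:
    """JASPAR-style text matrix: optional '>id' header, then 4 lines A/C/G/T.

    Rows may be 'A [ 1 2 3 ]' or plain whitespace-separated numbers; counts
    are normalized to probabilities per position.
    """
    path = Path(path)
    lines = [l.strip() for l in path.read_text().splitlines() if l.strip()]
    motif_id = path.stem
    if lines and lines[0].startswith(">"):
        motif_id = lines[0][1:].split()[0]
        lines = lines[1:]
    if len(lines) != 4:
        raise FormatError(f"{path.name}: expected 4 matrix rows (A,C,G,T), got {len(lines)}")
    rows = []
    for base, line in zip("ACGT", lines):
        body = line
        if body[:1].upper() == base:
            body = body[1:]
        body = body.replace("[", " ").replace("]", " ")
        try:
            rows.append([float(v) for v in body.split()])
        except ValueError:
            raise FormatError(f"{path.name}: malformed matrix row for base {base}") from None
    if len({len(r) for r in rows}) != 1:
        raise FormatError(f"{path.name}: matrix rows have unequal lengths")
    counts = np.array(rows, dtype=float).T  # -> (length, 4)
    totals = counts.sum(axis=1, keepdims=True)
    if np.any(totals <= 0):
        raise FormatError(f"{path.name}: a matrix position sums to zero")
    return Pwm(motif_id=motif_id, matrix=counts / totals, pseudocount=pseudocount)


def write_manifest(path: str | Path, inputs: dict, parameters: dict, seed=None) -> None:
    """JSON run manifest recording inputs, parameters, seed, and versions."""
    manifest = {
        "inputs": inputs,
        "parameters": parameters,
        "seed": seed,
        "versions": {
            "python": platform.python_version(),
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
        },
    }
    Path(path).write_text(json.dumps(manifest, indent=2, default=str) + "\n")
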