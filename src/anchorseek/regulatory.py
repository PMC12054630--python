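"""Genomic-interval arithmetic and DNA motif scanning (consensus + PWM)."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

IUPAC = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")
_BASES = "ACGT"


@dataclass(frozen=True)
class GenomicInterval:
    """1-based inclusive interval in its user-facing form (e.g. mm39 chr8:46080750-46081200)."""

    chrom: str
    start: int
    end: int
    assembly: str = ""

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < 1:
            raise ValueError("positions must be >= 1 (1-based inclusive)")
        if self.start > self.end:
            raise ValueError(f"start {self.start} > end {self.end}")

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"

    def to_zero_based(self) -> tuple[str, int, int]:
        """(chrom, start, end) in 0-based half-open (BED) convention."""
        return self.chrom, self.start - 1, self.end

    @classmethod
    def from_zero_based(
        cls, chrom: str, start: int, end: int, assembly: str = ""
    ) -> "GenomicInterval":
        if start < 0:
            raise ValueError("0-based start must be >= 0")
        if end <= start:
            raise ValueError(f"zero-length or inverted interval: start={start} end={end}")
        return cls(chrom, start + 1, end, assembly)


def interval_length(iv: GenomicInterval) -> int:
    """Number of base pairs covered: end - start + 1 (1-based inclusive)."""
    return iv.end - iv.start + 1


def revcomp(seq: str) -> str:
    """Reverse complement; case preserved; alphabet ACGTN (either case)."""
    for i, ch in enumerate(seq):
        if ch.upper() not in "ACGTN":
            raise ValueError(f"illegal character {ch!r} at position {i + 1}")
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class Pwm:
    """Position probability matrix over A,C,G,T with background and pseudocount.

    ``matrix`` has shape (motif_length, 4) with rows summing to 1; the
    pseudocount regularizes each row as (p + c) / (1 + 4c) before log-odds.
    """

    motif_id: str
    matrix: np.ndarray
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    pseudocount: float = 0.01

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("PWM matrix must have shape (length, 4)")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("each PWM position must sum to 1")
        if not np.isclose(self.background.sum(), 1.0, atol=1e-9):
            raise ValueError("background must sum to 1")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be >= 0")

    def __len__(self) -> int:
        return self.matrix.shape[0]

    def log_odds(self) -> np.ndarray:
        """log2 odds matrix (length, 4) after pseudocount regularization."""
        p = (self.matrix + self.pseudocount) / (1.0 + 4.0 * self.pseudocount)
        with np.errstate(divide="ignore"):
            return np.log2(p / self.background)


@dataclass(frozen=True)
class MotifHit:
    """A motif occurrence; ``position`` is 1-based on the forward strand.

    For minus-strand hits the coordinates refer to the forward strand but
    ``site`` is the motif-strand sequence (reverse complement of the
    forward-strand window).
    """

    position: int
    strand: str
    site: str
    score: Optional[float] = None


def _matches_consensus(window: str, consensus: str) -> bool:
    return all(base in IUPAC[code] for base, code in zip(window, consensus))


def scan_consensus(
    seq: str, consensus: str = "WGATAA", both_strands: bool = True
) -> list[MotifHit]:
    """All (overlapping) matches of an IUPAC consensus, ordered by position then strand."""
    consensus = consensus.upper()
    for i, code in enumerate(consensus):
        if code not in IUPAC:
            raise ValueError(f"invalid IUPAC code {code!r} at position {i + 1}")
    s = seq.upper()
    m = len(consensus)
    hits: list[MotifHit] = []
    for i in range(len(s) - m + 1):
        window = s[i : i + m]
        if _matches_consensus(window, consensus):
            hits.append(MotifHit(position=i + 1, strand="+", site=window))
        if both_strands:
            rc = revcomp(window)
            if _matches_consensus(rc, consensus):
                hits.append(MotifHit(position=i + 1, strand="-", site=rc))
    return hits


def scan_pwm(
    seq: str,
    pwm: Pwm,
    threshold_bits: float,
    both_strands: bool = True,
) -> tuple[list[MotifHit], list[int]]:
    """Log-odds scan; returns (hits with score >= threshold, skipped positions).

    Windows containing a base outside ACGT (e.g. N) are skipped and their
    1-based start positions collected in the second return value.
    """
    s = seq.upper()
    m = len(pwm)
    if len(s) < m:
        raise ValueError(f"sequence length {len(s)} < motif length {m}")
    lo = pwm.log_odds()
    base_idx = {b: j for j, b in enumerate(_BASES)}
    hits: list[MotifHit] = []
    skipped: list[int] = []
    for i in range(len(s) - m + 1):
        window = s[i : i + m]
        if any(b not in base_idx for b in window):
            skipped.append(i + 1)
            continue
        fwd = float(sum(lo[j, base_idx[b]] for j, b in enumerate(window)))
        if fwd >= threshold_bits:
            hits.append(MotifHit(position=i + 1, strand="+", site=window, score=fwd))
        if both_strands:
            rc = revcomp(window)
            rev = float(sum(lo[j, base_idx[b]] for j, b in enumerate(rc)))
            if rev >= threshold_bits:
                hits.append(MotifHit(position=i + 1, strand="-", site=rc, score=rev))
    return hits, skipped
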