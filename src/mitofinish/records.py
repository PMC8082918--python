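"""Core domain types shared across the toolkit.

Coordinates are 0-based, half-open everywhere; 1-based coordinates appear only
in human-readable report output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

# IUPAC nucleotide alphabet (ambiguity codes accepted and preserved on input;
# k-mer operations skip k-mers containing non-ACGT characters).
IUPAC = set("ACGTNRYSWKMBDHV")

_COMPLEMENT = str.maketrans(
    "ACGTNRYSWKMBDHVacgtnryswkmbdhv",
    "TGCANYRSWMKVHDBtgcanyrswmkvhdb",
)


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC-aware)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class SequenceRecord:
    """A named DNA sequence with optional per-base phred qualities.

    ``circular`` marks sequences that represent a closed molecule; operations
    that need to cross the origin (read simulation, mapping, k-mer counting)
    honour the flag.
    """

    id: str
    seq: str
    quals: list[int] | None = None
    circular: bool = False

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        self.seq = self.seq.upper()
        bad = set(self.seq) - IUPAC
        if bad:
            raise ValueError(f"{self.id}: invalid characters {sorted(bad)!r}")
        if self.quals is not None and len(self.quals) != len(self.seq):
            raise ValueError(
                f"{self.id}: quality length {len(self.quals)} != sequence length {len(self.seq)}"
            )

    def __len__(self) -> int:
        return len(self.seq)

    def reverse_complement(self, new_id: str | None = None) -> "SequenceRecord":
        quals = self.quals[::-1] if self.quals is not None else None
        return SequenceRecord(new_id or self.id, revcomp(self.seq), quals, self.circular)


@dataclass(frozen=True)
class Interval:
    """0-based half-open interval on a named sequence."""

    seq_id: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start <= self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, other: "Interval") -> bool:
        return self.start <= other.start and other.end <= self.end


@dataclass
class AlignmentRecord:
    """PAF-style pairwise alignment.

    Query coordinates always refer to the original (forward) query sequence.
    ``cigar``, when present, is an extended cigar (=, X, I, D; I consumes
    query) describing the alignment of the *oriented* query (reverse
    complemented first when strand is '-') against the forward target.
    """

    query_id: str
    query_len: int
    query_start: int
    query_end: int
    strand: str
    target_id: str
    target_len: int
    target_start: int
    target_end: int
    n_matches: int
    block_len: int
    cigar: list[tuple[str, int]] | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.query_start <= self.query_end <= self.query_len):
            raise ValueError(f"{self.query_id}: bad query coordinates")
        if not (0 <= self.target_start <= self.target_end):
            raise ValueError(f"{self.query_id}: bad target coordinates")
        if not (0 <= self.n_matches <= self.block_len):
            raise ValueError(f"{self.query_id}: matches {self.n_matches} > block {self.block_len}")
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def identity(self) -> float:
        """Fraction of matching bases over the alignment block (PAF convention)."""
        return self.n_matches / self.block_len if self.block_len else 0.0


@dataclass(frozen=True)
class MatchSegment:
    """An exact match between two same-length intervals.

    ``diagonal`` is ``t_start - q_start`` (meaningful on the forward strand);
    for self-matches the trivial identity diagonal is never emitted.
    """

    q_start: int
    q_end: int
    t_start: int
    t_end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.q_end - self.q_start != self.t_end - self.t_start:
            raise ValueError("match intervals must have equal length")

    @property
    def length(self) -> int:
        return self.q_end - self.q_start

    @property
    def diagonal(self) -> int:
        return self.t_start - self.q_start


@dataclass(frozen=True)
class ContingencyTable2x2:
    """2x2 count table: rows = outcome present/absent, cols = factor present/absent."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("table total must be positive")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass
class RepeatAnnotation:
    """A tandem repeat array: interval, unit length, copy number, unit consensus."""

    region: Interval
    unit_len: int
    copy_number: float
    unit_consensus: str = ""

    def __post_init__(self) -> None:
        if self.unit_len < 1:
            raise ValueError("unit_len must be >= 1")


@dataclass
class VariantCall:
    """A haploid consensus edit on a (circular) sequence.

    Normalized form is parsimonious and left-aligned: SNVs share no flanking
    bases; length-changing variants keep exactly one left anchor base.
    """

    pos: int
    ref_allele: str
    alt_allele: str
    depth: int = 0
    alt_support: int = 0

    def __post_init__(self) -> None:
        if not self.ref_allele or not self.alt_allele:
            raise ValueError("alleles must be non-empty")
        if self.alt_support > self.depth:
            raise ValueError("alt_support cannot exceed depth")


@dataclass
class SpanningObservation:
    """Per-read length deviation over a repeat/duplication interval."""

    read_id: str
    observed_len: int
    ref_len: int
    unit_len: int | None = None
    low_confidence: bool = False

    @property
    def deviation_bp(self) -> int:
        return self.observed_len - self.ref_len

    @property
    def deviation_rel(self) -> float:
        return self.deviation_bp / self.ref_len

    @property
    def implied_copies(self) -> int | None:
        if self.unit_len is None:
            return None
        x = self.observed_len / self.unit_len
        # nearest integer, half away from zero
        import math

        return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))
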