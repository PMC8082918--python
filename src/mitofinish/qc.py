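"""Quality and structure analytics.

* k-mer assembly QV in the Merqury style: assembly k-mers absent from the
  (high-frequency-filtered) read k-mer set are counted as erroneous
  positions and converted to a phred-scaled per-base quality. Read k-mers
  below a frequency floor (default 100, presuming deep mitochondrial
  short-read coverage) are removed first so nuclear-genome k-mers do not
  inflate the QV.
* tandem repeat annotation from self maximal exact matches (word size 16),
  and shared-7-mer repeat similarity.
* duplication completeness classification (>= 95% of the source is
  "complete").
* spanning-read heteroplasmy: per-read length deviation over a repeat or
  duplication interval, and the implied copy-number spectrum.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass

import edlib
import numpy as np

from ._encode import canonical_kmer_codes, code_to_kmer, encode
from .matchfinder import ReadMapper, maximal_exact_matches
from .records import (
    AlignmentRecord,
    Interval,
    RepeatAnnotation,
    SequenceRecord,
    SpanningObservation,
    revcomp,
)


# ---------------------------------------------------------------------------
# k-mer counting
# ---------------------------------------------------------------------------

@dataclass
class KmerCounts:
    """Canonical k-mer multiset held as sorted 2-bit codes + counts."""

    k: int
    codes: np.ndarray   # sorted uint64
    counts: np.ndarray  # int64, parallel to codes

    @property
    def n_distinct(self) -> int:
        return int(self.codes.size)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def get(self, kmer: str) -> int:
        code_f, valid = canonical_kmer_codes(encode(kmer), self.k)
        if code_f.size != 1 or not valid[0]:
            return 0
        i = np.searchsorted(self.codes, code_f[0])
        if i < self.codes.size and self.codes[i] == code_f[0]:
            return int(self.counts[i])
        return 0

    def contains(self, codes: np.ndarray) -> np.ndarray:
        idx = np.searchsorted(self.codes, codes)
        idx = np.clip(idx, 0, max(self.codes.size - 1, 0))
        if self.codes.size == 0:
            return np.zeros(codes.size, dtype=bool)
        return self.codes[idx] == codes

    def to_dict(self) -> dict[str, int]:
        return {code_to_kmer(int(c), self.k): int(n) for c, n in zip(self.codes, self.counts)}


def _seq_canonical_codes(rec: SequenceRecord, k: int, circular: bool | None = None) -> np.ndarray:
    seq = rec.seq
    wrap = rec.circular if circular is None else circular
    if wrap and len(seq) >= k:
        seq = seq + seq[: k - 1]
    codes, valid = canonical_kmer_codes(encode(seq), k)
    return codes[valid]


def count_kmers(seqs, k: int) -> KmerCounts:
    """Canonical k-mer counts over a collection of SequenceRecords.

    k must be odd (no self-complementary k-mers) and in [3, 32]. K-mers
    containing non-ACGT characters are skipped; circular sequences are
    counted across the origin.
    """
    if k % 2 == 0 or not (3 <= k <= 32):
        raise ValueError("k must be odd and in [3, 32]")
    if isinstance(seqs, SequenceRecord):
        seqs = [seqs]
    chunks = [_seq_canonical_codes(rec, k) for rec in seqs]
    if not chunks or sum(c.size for c in chunks) == 0:
        return KmerCounts(k, np.empty(0, np.uint64), np.empty(0, np.int64))
    allc = np.concatenate(chunks)
    codes, counts = np.unique(allc, return_counts=True)
    return KmerCounts(k, codes, counts.astype(np.int64))


def filter_high_frequency(read_counts: KmerCounts, min_freq: int = 100) -> KmerCounts:
    """Drop read k-mers with frequency < min_freq (nuclear background guard)."""
    if min_freq < 1:
        raise ValueError("min_freq must be >= 1")
    keep = read_counts.counts >= min_freq
    if read_counts.n_distinct and not keep.any():
        warnings.warn(
            "no read k-mer reaches the frequency floor; coverage is likely too "
            "low for a reliable QV estimate",
            stacklevel=2,
        )
    return KmerCounts(read_counts.k, read_counts.codes[keep], read_counts.counts[keep])


@dataclass
class QVReport:
    k: int
    total_positions: int
    false_positions: int
    error_rate: float
    qv: float  # math.inf when no false k-mers
    note: str = ""


def kmer_qv(assembly, filtered_read_counts: KmerCounts, k: int = 31) -> QVReport:
    """Merqury-style assembly QV.

    error rate E = 1 - (1 - false/total)^(1/k); QV = -10 log10 E. The
    assembly is evaluated as deposited (linearized; L - k + 1 positions per
    sequence), k-mers canonical.
    """
    if isinstance(assembly, SequenceRecord):
        assembly = [assembly]
    chunks = [_seq_canonical_codes(rec, k, circular=False) for rec in assembly]
    total = sum(c.size for c in chunks)
    if total == 0:
        raise ValueError("assembly has no k-mer positions")
    false = 0
    for c in chunks:
        false += int((~filtered_read_counts.contains(c)).sum())
    if false == 0:
        return QVReport(k, total, 0, 0.0, math.inf, "no false k-mers")
    err = 1.0 - (1.0 - false / total) ** (1.0 / k)
    return QVReport(k, total, false, err, -10.0 * math.log10(err))


def shared_kmer_fraction(a: KmerCounts, b: KmerCounts, denominator: str = "union") -> float:
    """Fraction of shared distinct canonical k-mers between two sets.

    ``union`` (default) is the Jaccard index |A n B| / |A u B|; ``total``
    divides by |A| + |B| instead.
    """
    if a.k != b.k:
        raise ValueError("k-mer sizes differ")
    if a.n_distinct == 0 and b.n_distinct == 0:
        raise ValueError("both k-mer sets are empty")
    inter = np.intersect1d(a.codes, b.codes, assume_unique=True).size
    if denominator == "union":
        denom = a.n_distinct + b.n_distinct - inter
    elif denominator == "total":
        denom = a.n_distinct + b.n_distinct
    else:
        raise ValueError("denominator must be 'union' or 'total'")
    return inter / denom


# ---------------------------------------------------------------------------
# repeat annotation
# ---------------------------------------------------------------------------

def annotate_repeats(seq: SequenceRecord, min_match: int = 16) -> list[RepeatAnnotation]:
    """Tandem repeat arrays from forward self maximal exact matches.

    Off-diagonal self-matches whose query and target intervals overlap or
    abut are tandem-periodic; overlapping match footprints are clustered into
    arrays. Per array: unit length = smallest positive diagonal (the array
    period), region = union span, copy number = region length / unit, unit
    consensus = per-column majority over the full copies.
    """
    if len(seq.seq) < 100:
        raise ValueError("sequence too short")
    mems = [
        m
        for m in maximal_exact_matches(seq, seq, min_match, both_strands=False)
        if m.diagonal > 0 and m.t_start <= m.q_end  # tandem: copies adjacent/overlapping
    ]
    if not mems:
        return []
    # cluster by overlapping [q_start, t_end) footprints
    mems.sort(key=lambda m: m.q_start)
    clusters: list[list] = [[mems[0]]]
    for m in mems[1:]:
        if m.q_start < max(x.t_end for x in clusters[-1]):
            clusters[-1].append(m)
        else:
            clusters.append([m])

    out = []
    for cluster in clusters:
        unit = min(m.diagonal for m in cluster)
        start = min(m.q_start for m in cluster)
        end = max(m.t_end for m in cluster)
        region = Interval(seq.id, start, end)
        copy_number = len(region) / unit
        if copy_number < 2:
            continue
        n_full = int(copy_number)
        consensus = []
        for col in range(unit):
            votes = Counter(seq.seq[start + row * unit + col] for row in range(n_full))
            consensus.append(votes.most_common(1)[0][0])
        out.append(RepeatAnnotation(region, unit, copy_number, "".join(consensus)))
    return out


def classify_duplication(dup_len: int, source_len: int) -> str:
    """'complete' iff the duplication covers >= 95% of the source gene."""
    if source_len <= 0:
        raise ValueError("source_len must be positive")
    return "complete" if dup_len / source_len >= 0.95 else "partial"


# ---------------------------------------------------------------------------
# spanning-read heteroplasmy
# ---------------------------------------------------------------------------

def _containment_shift(a: AlignmentRecord, repeat: Interval, margin: float) -> int | None:
    """Offset (0 or L) at which the alignment contains the repeat with margins."""
    for shift in (0, a.target_len):
        if (
            a.target_start <= repeat.start + shift - margin
            and a.target_end >= repeat.end + shift + margin
        ):
            return shift
    return None


def spanning_reads(
    alignments: list[AlignmentRecord],
    repeat: Interval,
    min_identity: float = 0.70,
    min_extra: int = 2000,
) -> list[str]:
    """Reads whose alignments fully contain the repeat with anchoring flanks.

    Filters: identity strictly > min_identity; read length >= repeat length +
    min_extra; an anchor of at least min_extra/2 aligned on each side.
    """
    ids = []
    margin = min_extra / 2
    for a in alignments:
        if a.identity <= min_identity:
            continue
        if a.query_len < len(repeat) + min_extra:
            continue
        if _containment_shift(a, repeat, margin) is None:
            continue
        ids.append(a.query_id)
    return ids


def _project_boundaries(alignment: AlignmentRecord, bounds: tuple[int, int]):
    """Project target positions to oriented-query positions via the cigar.

    Returns ({bound: query_pos}, gap_flag); a boundary inside a deletion
    projects to the gap's query position and sets the flag.
    """
    q = alignment.query_start if alignment.strand == "+" else alignment.query_len - alignment.query_end
    t = alignment.target_start
    q_at: dict[int, int] = {}
    in_gap = False
    for op, ln in alignment.cigar:
        if op in "=XM":
            for bound in bounds:
                if bound not in q_at and t <= bound < t + ln:
                    q_at[bound] = q + (bound - t)
            q += ln
            t += ln
        elif op == "I":
            q += ln
        elif op == "D":
            for bound in bounds:
                if bound not in q_at and t <= bound < t + ln:
                    q_at[bound] = q
                    in_gap = True
            t += ln
    return q_at, in_gap


def length_deviation(
    read: SequenceRecord,
    alignment: AlignmentRecord,
    repeat: Interval,
    reference: SequenceRecord | None = None,
    flank_pad: int = 100,
) -> SpanningObservation:
    """Length of the read segment projecting onto the repeat interval.

    The repeat boundaries are first projected through the alignment cigar.
    When the reference is supplied, the projection is refined by re-locating
    the two ``flank_pad``-long reference flanks directly in the read
    (hard-clip style): among equally optimal global alignment paths the
    placement of gaps around a length polymorphism is arbitrary, so the
    cigar projection alone can smear a large deletion across the boundary.
    A flank that cannot be anchored cleanly marks the observation
    low-confidence. A read from an allele lacking the region entirely yields
    observed length ~0: deviation_rel -1.0, the structural-loss signature.
    """
    if alignment.cigar is None:
        raise ValueError("alignment has no cigar; cannot project boundaries")
    shift = _containment_shift(alignment, repeat, flank_pad)
    if shift is None:
        raise ValueError("read does not span the repeat with the flank pad")
    bounds = (repeat.start + shift, repeat.end + shift)
    q_at, in_gap = _project_boundaries(alignment, bounds)
    if len(q_at) < 2:
        raise ValueError("projection undefined: alignment does not reach a boundary")
    q0, q1 = q_at[bounds[0]], q_at[bounds[1]]
    low_conf = in_gap

    if reference is not None:
        oriented = read.seq if alignment.strand == "+" else revcomp(read.seq)
        ref2 = reference.seq * 2 if reference.circular else reference.seq
        left = ref2[max(0, bounds[0] - flank_pad) : bounds[0]]
        right = ref2[bounds[1] : bounds[1] + flank_pad]
        limit = max(2, int(0.3 * flank_pad))
        low_conf = False
        for flank, guess, is_left in ((left, q0, True), (right, q1, False)):
            res = edlib.align(flank, oriented, mode="HW", task="locations", k=limit)
            if res["editDistance"] < 0 or not res["locations"]:
                low_conf = True
                continue
            # pick the hit nearest the cigar-projected position
            if is_left:
                pos = min((loc[1] + 1 for loc in res["locations"]),
                          key=lambda p: abs(p - guess))
                q0 = pos
            else:
                pos = min((loc[0] for loc in res["locations"]),
                          key=lambda p: abs(p - guess))
                q1 = pos
    observed = max(0, q1 - q0)
    return SpanningObservation(read.id, observed, len(repeat), low_confidence=low_conf)


def spanning_observations(
    reads: list[SequenceRecord],
    reference: SequenceRecord,
    repeat: Interval,
    min_identity: float = 0.70,
    min_extra: int = 2000,
    max_edit_frac: float = 0.30,
) -> list[SpanningObservation]:
    """Map reads to the reference and collect spanning-read deviations."""
    ref = reference if reference.circular else SequenceRecord(
        reference.id, reference.seq, circular=True
    )
    mapper = ReadMapper(ref, max_edit_frac=max_edit_frac)
    out = []
    by_id = {}
    for read in reads:
        a = mapper.map(read)
        if a is None:
            continue
        by_id[read.id] = (read, a)
    keep = spanning_reads([a for _, a in by_id.values()], repeat, min_identity, min_extra)
    for rid in keep:
        read, a = by_id[rid]
        try:
            out.append(length_deviation(read, a, repeat, reference=ref))
        except ValueError:
            continue
    return out


def copy_number_histogram(
    observations: list[SpanningObservation],
    unit_len: int,
    ref_copies: int,
) -> tuple[dict[int, int], float]:
    """Implied copy-number spectrum and the fraction supporting the reference.

    implied copies = observed length / unit length, rounded to the nearest
    integer half away from zero.
    """
    if unit_len <= 0:
        raise ValueError("unit_len must be positive")
    hist: dict[int, int] = {}
    for obs in observations:
        x = obs.observed_len / unit_len
        copies = int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))
        hist[copies] = hist.get(copies, 0) + 1
    majority = hist.get(ref_copies, 0) / len(observations) if observations else 0.0
    return dict(sorted(hist.items())), majority
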