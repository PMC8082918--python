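"""Circularity-aware short-read consensus polishing.

Short reads are mapped to a 2-copy concatemer of the circular assembly so
coverage and pileups have no edge artifact at the origin; depth and pileup
columns are folded back modulo the genome length. Polishing is a haploid
majority consensus: the pileup majority allele replaces the assembly allele
when its support fraction strictly exceeds ``min_frac`` at depth
``min_depth`` or more; exact ties keep the assembly base. Substitutions and
small indels (<= 50 bp) are supported. Variant calls are reported in
parsimonious, left-aligned normalized form.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from ._encode import encode
from .matchfinder import ReadMapper
from .records import Interval, SequenceRecord, VariantCall, revcomp

MAX_INDEL = 50


def circular_coverage(
    reads: list[SequenceRecord],
    circ: SequenceRecord,
    max_edit_frac: float = 0.25,
) -> np.ndarray:
    """Per-base short-read depth over a circular sequence (length L).

    Reads are mapped to the doubled sequence and depth is folded modulo L, so
    reads spanning the origin contribute exactly once per wrapped position.
    """
    if not circ.circular:
        raise ValueError("sequence must be circular")
    L = len(circ.seq)
    depth = np.zeros(L, dtype=np.int32)
    mapper = ReadMapper(circ, max_edit_frac=max_edit_frac)
    for read in reads:
        a = mapper.map(read)
        if a is None:
            continue
        s, e = a.target_start, a.target_end
        if e <= L:
            depth[s:e] += 1
        else:
            depth[s:] += 1
            depth[: e - L] += 1
    return depth


@dataclass
class PolishResult:
    sequence: SequenceRecord
    variants: list[VariantCall]
    low_coverage: list[Interval] = field(default_factory=list)
    depth: np.ndarray | None = None


def _pileup(circ: SequenceRecord, reads, max_edit_frac: float):
    """Column counts over the folded circle.

    Returns (base_counts[L, 5] with columns A,C,G,T,deletion; insertions as
    {pos: Counter(inserted_seq)} attached to the preceding position).
    """
    L = len(circ.seq)
    base_counts = np.zeros((L, 5), dtype=np.int32)
    insertions: dict[int, Counter] = {}
    mapper = ReadMapper(circ, max_edit_frac=max_edit_frac, match_gap=200)
    for read in reads:
        a = mapper.map(read)
        if a is None or a.cigar is None:
            continue
        oriented = read.seq if a.strand == "+" else revcomp(read.seq)
        q = a.query_start if a.strand == "+" else a.query_len - a.query_end
        t = a.target_start
        codes = encode(oriented)
        for op, ln in a.cigar:
            if op in "=XM":
                for i in range(ln):
                    c = codes[q + i]
                    if c >= 0:
                        base_counts[(t + i) % L, c] += 1
                q += ln
                t += ln
            elif op == "I":
                if ln <= MAX_INDEL:
                    ins = oriented[q : q + ln]
                    insertions.setdefault((t - 1) % L, Counter())[ins] += 1
                q += ln
            elif op == "D":
                if ln <= MAX_INDEL:
                    for i in range(ln):
                        base_counts[(t + i) % L, 4] += 1
                t += ln
    return base_counts, insertions


def pileup_polish(
    circ: SequenceRecord,
    short_reads: list[SequenceRecord],
    min_depth: int = 3,
    min_frac: float = 0.5,
    max_edit_frac: float = 0.25,
) -> PolishResult:
    """Haploid majority-consensus polish of a circular assembly.

    Positions below ``min_depth`` are left unchanged and reported as
    low-coverage intervals. Polishing an already-correct sequence with clean
    reads is the identity.
    """
    if not circ.circular:
        raise ValueError("assembly must be circular")
    L = len(circ.seq)
    base_counts, insertions = _pileup(circ, short_reads, max_edit_frac)
    ref_codes = encode(circ.seq)
    depth = base_counts.sum(axis=1)

    out_pieces: list[str] = []
    raw_events: list[tuple[int, str, str]] = []  # (pos, ref, alt) pre-merge
    pos = 0
    while pos < L:
        ref_base = circ.seq[pos]
        col = base_counts[pos]
        d = int(depth[pos])
        chosen = ref_base
        if d >= min_depth:
            best = int(np.argmax(col))
            # strict majority; argmax ties resolve to the lowest code, but a
            # tie with the reference allele never clears the strict threshold
            if col[best] / d > min_frac and best != ref_codes[pos]:
                if best == 4:  # deletion of this base
                    chosen = ""
                    raw_events.append((pos, ref_base, ""))
                else:
                    chosen = "ACGT"[best]
                    raw_events.append((pos, ref_base, chosen))
        out_pieces.append(chosen)
        ins_counter = insertions.get(pos)
        if ins_counter and d >= min_depth:
            ins_seq, n_sup = ins_counter.most_common(1)[0]
            if n_sup / d > min_frac:
                out_pieces.append(ins_seq)
                raw_events.append((pos, "", ins_seq))
        pos += 1

    polished = SequenceRecord(circ.id, "".join(out_pieces), circular=True)

    variants = _events_to_calls(circ.seq, raw_events, base_counts, insertions, depth)
    low_cov = _low_coverage_intervals(circ.id, depth, min_depth)
    return PolishResult(polished, variants, low_cov, depth)


def _low_coverage_intervals(seq_id, depth, min_depth) -> list[Interval]:
    low = depth < min_depth
    out = []
    i = 0
    n = depth.size
    while i < n:
        if low[i]:
            j = i
            while j < n and low[j]:
                j += 1
            out.append(Interval(seq_id, i, j))
            i = j
        else:
            i += 1
    return out


def _events_to_calls(ref_seq, raw_events, base_counts, insertions, depth):
    """Merge per-position events into VariantCalls and normalize them."""
    calls: list[VariantCall] = []
    i = 0
    n = len(raw_events)
    while i < n:
        pos, ref, alt = raw_events[i]
        if ref and not alt:  # deletion: merge an adjacent run
            j = i + 1
            end = pos + 1
            while j < n and raw_events[j][2] == "" and raw_events[j][0] == end and raw_events[j][1]:
                end += 1
                j += 1
            if pos == 0:  # deletion at origin: anchor on the right instead
                call = VariantCall(pos, ref_seq[pos:end] + ref_seq[end], ref_seq[end],
                                   int(depth[pos]), int(base_counts[pos, 4]))
            else:
                call = VariantCall(pos - 1, ref_seq[pos - 1 : end], ref_seq[pos - 1],
                                   int(depth[pos]), int(base_counts[pos, 4]))
            calls.append(normalize_variant(ref_seq, call))
            i = j
        elif not ref:  # insertion after pos
            ins_counter = insertions.get(pos, Counter())
            sup = ins_counter.get(alt, 0)
            call = VariantCall(pos, ref_seq[pos], ref_seq[pos] + alt, int(depth[pos]), int(sup))
            calls.append(normalize_variant(ref_seq, call))
            i += 1
        else:  # substitution
            code = "ACGT".index(alt)
            call = VariantCall(pos, ref, alt, int(depth[pos]), int(base_counts[pos, code]))
            calls.append(normalize_variant(ref_seq, call))
            i += 1
    return calls


def normalize_variant(ref_seq: str, call: VariantCall) -> VariantCall:
    """Unique parsimonious, left-aligned variant representation.

    SNVs end with no shared flanking bases; length-changing variants keep
    exactly one left anchor base. Equal to the brute-force leftmost
    equivalent representation; idempotent.
    """
    pos, ref, alt = call.pos, call.ref_allele, call.alt_allele
    if ref_seq[pos : pos + len(ref)] != ref:
        raise ValueError(f"ref allele {ref!r} inconsistent with sequence at {pos}")
    changed = True
    while changed:
        changed = False
        if ref and alt and ref[-1] == alt[-1] and (len(ref) > 1 or len(alt) > 1):
            ref, alt = ref[:-1], alt[:-1]
            changed = True
        if not ref or not alt:
            if pos == 0:
                # cannot extend further left; re-anchor on the right
                nxt = ref_seq[pos + len(ref)]
                ref, alt = ref + nxt, alt + nxt
                break
            pos -= 1
            b = ref_seq[pos]
            ref, alt = b + ref, b + alt
            changed = True
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return VariantCall(pos, ref, alt, call.depth, call.alt_support)


def apply_variants(seq: str, variants: list[VariantCall]) -> str:
    """Apply normalized variant calls to a sequence (for round-trip checks)."""
    out = seq
    for v in sorted(variants, key=lambda v: -v.pos):
        assert out[v.pos : v.pos + len(v.ref_allele)] == v.ref_allele
        out = out[: v.pos] + v.alt_allele + out[v.pos + len(v.ref_allele) :]
    return out
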