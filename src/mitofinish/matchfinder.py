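"""Exact-match and lightweight alignment engine.

Three layers, all built on a shared 2-bit k-mer seed index:

* :func:`maximal_exact_matches` — complete, both-strand maximal exact match
  enumeration (the self-alignment used for repeat deconvolution and repeat
  boundary annotation; default word size 16).
* :func:`seed_extend_align` — seed-chain-extend local alignment with banded
  edit distance (edlib), reporting alignments above an identity floor.
* :func:`map_reads` — read mapping against a 2-copy concatemer of a circular
  reference, with target coordinates folded back modulo the genome length.

Identity is defined as matches / block_len (PAF convention) throughout.
"""

from __future__ import annotations

import numpy as np
import edlib

from ._encode import encode, kmer_codes
from .records import AlignmentRecord, MatchSegment, SequenceRecord, revcomp

DEFAULT_MIN_SEED = 16  # mirrors the self-alignment word size used for repeat finding


# ---------------------------------------------------------------------------
# seed machinery
# ---------------------------------------------------------------------------

class SeedIndex:
    """Sorted k-mer code index over a target sequence (forward strand)."""

    def __init__(self, seq: str, k: int):
        self.k = k
        self.seq = seq
        self.length = len(seq)
        codes = encode(seq)
        kc, valid = kmer_codes(codes, k)
        pos = np.nonzero(valid)[0]
        kc = kc[valid]
        order = np.argsort(kc, kind="stable")
        self.sorted_codes = kc[order]
        self.sorted_pos = pos[order]

    def seed_pairs(self, query_codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """All (query_pos, target_pos) pairs whose k-mers are identical."""
        kc, valid = kmer_codes(query_codes, self.k)
        qpos = np.nonzero(valid)[0]
        kc = kc[valid]
        left = np.searchsorted(self.sorted_codes, kc, "left")
        right = np.searchsorted(self.sorted_codes, kc, "right")
        cnt = right - left
        total = int(cnt.sum())
        if total == 0:
            return np.empty(0, np.int64), np.empty(0, np.int64)
        i_rep = np.repeat(qpos, cnt)
        starts = np.repeat(left, cnt)
        offs = np.arange(total) - np.repeat(np.cumsum(cnt) - cnt, cnt)
        j_all = self.sorted_pos[starts + offs]
        return i_rep.astype(np.int64), j_all.astype(np.int64)


def _merge_seed_runs(i: np.ndarray, j: np.ndarray, k: int):
    """Merge seed pairs into maximal runs along each diagonal.

    A maximal run of consecutive matching k-mer positions on one diagonal is
    exactly a maximal exact match of length run + k - 1.
    Returns (q_start, q_end, t_start) arrays.
    """
    if i.size == 0:
        z = np.empty(0, np.int64)
        return z, z, z
    diag = j - i
    order = np.lexsort((i, diag))
    d = diag[order]
    ii = i[order]
    new = np.ones(d.size, bool)
    new[1:] = (d[1:] != d[:-1]) | (ii[1:] != ii[:-1] + 1)
    starts = np.nonzero(new)[0]
    ends = np.append(starts[1:], d.size) - 1
    q0 = ii[starts]
    q1 = ii[ends] + k
    t0 = q0 + d[starts]
    return q0, q1, t0


def maximal_exact_matches(
    a: SequenceRecord,
    b: SequenceRecord,
    min_len: int = DEFAULT_MIN_SEED,
    both_strands: bool = True,
) -> list[MatchSegment]:
    """All maximal exact matches of length >= min_len between a and b.

    Every returned segment is exact and not extendable in either direction,
    and every such match is returned (completeness follows from the seed-run
    construction with seed size = min_len). In self mode (a and b identical)
    the trivial full-length identity diagonal is excluded.
    """
    if min_len < 8:
        raise ValueError("min_len must be >= 8")
    self_mode = a is b or (a.id == b.id and a.seq == b.seq)
    a_codes = encode(a.seq)
    out: list[MatchSegment] = []

    idx_f = SeedIndex(b.seq, min_len)
    qi, tj = idx_f.seed_pairs(a_codes)
    q0, q1, t0 = _merge_seed_runs(qi, tj, min_len)
    for s, e, t in zip(q0, q1, t0):
        if self_mode and t == s:
            continue
        out.append(MatchSegment(int(s), int(e), int(t), int(t + e - s), "+"))

    if both_strands:
        brc = revcomp(b.seq)
        idx_r = SeedIndex(brc, min_len)
        qi, tj = idx_r.seed_pairs(a_codes)
        q0, q1, t0 = _merge_seed_runs(qi, tj, min_len)
        n = len(b.seq)
        for s, e, t in zip(q0, q1, t0):
            length = e - s
            # map interval on rc(b) back to forward b coordinates
            out.append(MatchSegment(int(s), int(e), int(n - t - length), int(n - t), "-"))

    out.sort(key=lambda m: (m.strand, m.q_start, m.t_start))
    return out


# ---------------------------------------------------------------------------
# seed-and-extend alignment
# ---------------------------------------------------------------------------

def _parse_cigar(cigar: str) -> list[tuple[str, int]]:
    ops = []
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            ops.append((ch, int(num)))
            num = ""
    return ops


def _cigar_stats(ops) -> tuple[int, int]:
    """(n_matches, block_len) from an extended cigar."""
    matches = sum(n for op, n in ops if op == "=")
    block = sum(n for _, n in ops)
    return matches, block


def _chains(qpos: np.ndarray, tpos: np.ndarray, k: int, band: int, match_gap: int):
    """Group seed pairs into collinear chains.

    Seeds are clustered by diagonal (tolerance ``band``) and split where the
    query-coordinate gap between consecutive seeds exceeds ``match_gap``.
    Yields (q0, q1, t0, t1, support) per chain.
    """
    if qpos.size == 0:
        return
    diag = tpos - qpos
    order = np.lexsort((qpos, diag))
    d = diag[order]
    q = qpos[order]
    t = tpos[order]
    cluster_break = np.ones(d.size, bool)
    cluster_break[1:] = (d[1:] - d[:-1]) > band
    cluster_ids = np.cumsum(cluster_break)
    for cid in np.unique(cluster_ids):
        sel = cluster_ids == cid
        qs, ts = q[sel], t[sel]
        o = np.argsort(qs, kind="stable")
        qs, ts = qs[o], ts[o]
        # split at large query gaps
        brk = np.nonzero(np.diff(qs) > match_gap)[0] + 1
        for part_q, part_t in zip(np.split(qs, brk), np.split(ts, brk)):
            q0, q1 = int(part_q[0]), int(part_q[-1] + k)
            t0, t1 = int(part_t.min()), int(part_t.max() + k)
            # support: number of distinct query positions seeded (collinearity proxy)
            support = int(np.unique(part_q).size)
            yield q0, q1, t0, t1, support


def _extend_chain(
    oriented_query: str,
    target_seq: str,
    chain,
    max_edit_frac: float,
    match_gap: int,
):
    """Banded-edit-distance extension of one seed chain.

    Tries to place the full query in the target window first; falls back to
    the chain's local query segment (partial-overlap case). Returns
    (q0, q1, t0, t1, cigar_ops) in oriented-query coordinates, or None.
    """
    q0, q1, t0, t1, _ = chain
    qlen = len(oriented_query)
    pad = 50 + int(max_edit_frac * qlen)
    # a full-length alignment can only clear the identity floor when the seed
    # chain already spans most of the query (chimeric reads never do)
    try_full = (q1 - q0) >= (1 - 2 * max_edit_frac) * qlen
    for full in (True, False):
        if full:
            if not try_full:
                continue
            seg0, seg1 = 0, qlen
            ws = max(0, t0 - q0 - pad)
            we = min(len(target_seq), t1 + (qlen - q1) + pad)
        else:
            seg0, seg1 = q0, q1  # chain span exactly: seed-bounded, exact ends
            if (seg0, seg1) == (0, qlen):
                break
            pad = 50 + int(max_edit_frac * (seg1 - seg0))
            ws = max(0, t0 - pad)
            we = min(len(target_seq), t1 + pad)
        segment = oriented_query[seg0:seg1]
        if not segment or we <= ws:
            continue
        limit = int(max_edit_frac * len(segment)) + 1
        res = edlib.align(segment, target_seq[ws:we], mode="HW", task="path", k=limit)
        if res["editDistance"] < 0 or not res.get("cigar"):
            continue
        ops = _parse_cigar(res["cigar"])
        matches, block = _cigar_stats(ops)
        if block == 0 or matches / block < 1.0 - max_edit_frac:
            continue
        loc = res["locations"][0]
        return seg0, seg1, ws + loc[0], ws + loc[1] + 1, ops
    return None


def _align_against_index(
    query: SequenceRecord,
    index: SeedIndex,
    target_id: str,
    target_len: int,
    max_edit_frac: float,
    match_gap: int,
    dedup_query: bool = True,
) -> list[AlignmentRecord]:
    """All chain alignments of query (both strands) against an indexed target."""
    k = index.k
    qlen = len(query.seq)
    band = max(2 * k, int(max_edit_frac * qlen))
    results: list[AlignmentRecord] = []
    for strand, oriented in (("+", query.seq), ("-", revcomp(query.seq))):
        qpos, tpos = index.seed_pairs(encode(oriented))
        chains = sorted(
            _chains(qpos, tpos, k, band, match_gap), key=lambda c: -c[4]
        )[:8]  # cap chain candidates per strand
        for chain in chains:
            ext = _extend_chain(oriented, index.seq, chain, max_edit_frac, match_gap)
            if ext is None:
                continue
            seg0, seg1, ts, te, ops = ext
            matches, block = _cigar_stats(ops)
            if strand == "+":
                qs, qe = seg0, seg1
            else:  # report on the original (forward) query
                qs, qe = qlen - seg1, qlen - seg0
            results.append(
                AlignmentRecord(
                    query_id=query.id, query_len=qlen,
                    query_start=qs, query_end=qe, strand=strand,
                    target_id=target_id, target_len=target_len,
                    target_start=ts, target_end=te,
                    n_matches=matches, block_len=block, cigar=ops,
                )
            )
    # best first; deterministic tie-break: smallest target_start, then '+'
    results.sort(key=lambda r: (-r.n_matches, r.target_start, r.strand))
    if not dedup_query:
        return results
    # drop near-duplicate chains covering the same query stretch
    kept: list[AlignmentRecord] = []
    for rec in results:
        dup = False
        for prev in kept:
            ov = min(rec.query_end, prev.query_end) - max(rec.query_start, prev.query_start)
            if ov > 0.5 * (rec.query_end - rec.query_start):
                dup = True
                break
        if not dup:
            kept.append(rec)
    return kept


def seed_extend_align(
    query: SequenceRecord,
    target: SequenceRecord,
    min_seed: int = DEFAULT_MIN_SEED,
    max_edit_frac: float = 0.25,
    match_gap: int = 500,
) -> list[AlignmentRecord]:
    """Chain collinear seeds and extend with banded edit-distance alignment.

    Returns alignments with identity >= 1 - max_edit_frac, best first (the
    first record is the primary alignment). Secondary records cover distinct
    query stretches, supporting fragmented-reference use cases.
    """
    if not (0 < max_edit_frac <= 0.5):
        raise ValueError("max_edit_frac must be in (0, 0.5]")
    index = SeedIndex(target.seq, min_seed)
    return _align_against_index(
        query, index, target.id, len(target.seq), max_edit_frac, match_gap
    )


class LinearMapper:
    """Reusable seed index over one linear target for mapping many queries."""

    def __init__(
        self,
        target: SequenceRecord,
        min_seed: int = DEFAULT_MIN_SEED,
        max_edit_frac: float = 0.25,
        match_gap: int = 500,
    ):
        self.target = target
        self.max_edit_frac = max_edit_frac
        self.match_gap = match_gap
        self._index = SeedIndex(target.seq, min_seed)

    def align(self, query: SequenceRecord, all_placements: bool = False) -> list[AlignmentRecord]:
        """Alignments best-first; with ``all_placements`` alternative
        placements of the same query stretch (multi-mapping) are kept."""
        return _align_against_index(
            query, self._index, self.target.id, len(self.target.seq),
            self.max_edit_frac, self.match_gap, dedup_query=not all_placements,
        )

    def map(self, query: SequenceRecord) -> AlignmentRecord | None:
        recs = self.align(query)
        return recs[0] if recs else None


# ---------------------------------------------------------------------------
# circular read mapping
# ---------------------------------------------------------------------------

class ReadMapper:
    """Maps reads against a 2-copy concatemer of a circular reference.

    Target coordinates in the returned alignments are folded back modulo the
    reference length L: target_start is in [0, L), target_end may exceed L for
    alignments that wrap past the origin.
    """

    def __init__(
        self,
        reference: SequenceRecord,
        min_seed: int = DEFAULT_MIN_SEED,
        max_edit_frac: float = 0.25,
        match_gap: int = 500,
    ):
        if not reference.circular:
            raise ValueError("reference must be circular")
        if len(reference.seq) == 0:
            raise ValueError("reference must be non-empty")
        self.reference = reference
        self.L = len(reference.seq)
        self.max_edit_frac = max_edit_frac
        self.match_gap = match_gap
        self._index = SeedIndex(reference.seq * 2, min_seed)

    def align(self, read: SequenceRecord) -> list[AlignmentRecord]:
        """All chain alignments for one read, folded, best first."""
        recs = _align_against_index(
            read, self._index, self.reference.id, self.L,
            self.max_edit_frac, self.match_gap,
        )
        folded = []
        seen = set()
        for r in recs:
            span = r.target_end - r.target_start
            r.target_start = r.target_start % self.L
            r.target_end = r.target_start + span
            key = (r.strand, r.query_start, r.target_start)
            if key in seen:  # same placement seen in both concatemer copies
                continue
            seen.add(key)
            folded.append(r)
        folded.sort(key=lambda r: (-r.n_matches, r.target_start, r.strand))
        return folded

    def map(self, read: SequenceRecord) -> AlignmentRecord | None:
        """Primary alignment for one read (best score; ties broken by smallest
        folded target_start, then forward strand), or None if unmapped."""
        recs = self.align(read)
        return recs[0] if recs else None


def map_reads(
    reads,
    reference: SequenceRecord,
    min_seed: int = DEFAULT_MIN_SEED,
    max_edit_frac: float = 0.25,
    match_gap: int = 500,
    all_chains: bool = False,
) -> list[AlignmentRecord]:
    """Map reads to a circular reference via its 2-copy concatemer.

    With ``all_chains`` False (default), at most one primary alignment per
    read is returned.
    """
    mapper = ReadMapper(reference, min_seed, max_edit_frac, match_gap)
    out: list[AlignmentRecord] = []
    for read in reads:
        if all_chains:
            out.extend(mapper.align(read))
        else:
            rec = mapper.map(read)
            if rec is not None:
                out.append(rec)
    return out
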