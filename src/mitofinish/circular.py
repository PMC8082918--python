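"""The trimmer: collapse a concatemeric linear contig into one circular unit.

Linear assemblers leave terminal overlaps on contigs built from circular
molecules; when library artifacts let the polymerase read through the circle
repeatedly, a contig can contain the genome several times over. The trimmer

1. restricts analysis to the reliable interval whose ends have short-read
   support (``reliable_ends``),
2. finds the terminal overlap by deconvolving repetitive self-matches: only a
   self-match diagonal whose collinear chain reaches both the contig start
   (query side) and the contig end (target side) can be the circular period;
   chains confined to the interior are tandem repeats and are never trimmed
   (``find_terminal_overlap``),
3. cuts one period out of the contig (``collapse_to_unit``), and
4. rotates/orients the circular unit to a supplied anchor, the conventional
   tRNA-Phe start (``rotate_to_anchor``).

Order is fixed as trim -> detect -> collapse.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import edlib

from .matchfinder import maximal_exact_matches
from .records import AlignmentRecord, Interval, SequenceRecord, revcomp


@dataclass
class OverlapCall:
    """A detected terminal concatemeric overlap."""

    period: int          # candidate circular unit length
    head: Interval       # prefix copy of the duplicated stretch
    tail: Interval       # suffix copy (ends within tolerance of the contig end)
    support: int         # exact-matched bases in the chain
    n_copies: float      # contig_len / period

    def __post_init__(self):
        if self.period <= 0:
            raise ValueError("period must be positive")


def reliable_ends(
    contig: SequenceRecord,
    short_read_alignments: list[AlignmentRecord],
    min_depth: int = 3,
) -> Interval:
    """Maximal interval whose first and last positions have short-read depth
    >= min_depth. Internal coverage dips are reported elsewhere, not trimmed."""
    n = len(contig.seq)
    depth = np.zeros(n, dtype=np.int32)
    for a in short_read_alignments:
        if a.target_id != contig.id:
            continue
        depth[max(0, a.target_start) : min(n, a.target_end)] += 1
    ok = np.nonzero(depth >= min_depth)[0]
    if ok.size == 0:
        raise ValueError("no reliable sequence: whole contig below minimum depth")
    return Interval(contig.id, int(ok[0]), int(ok[-1]) + 1)


def find_terminal_overlap(
    contig: SequenceRecord,
    min_match: int = 16,
    max_edit_frac: float = 0.05,
    match_gap: int = 500,
    max_repeat_period: int = 2500,
) -> OverlapCall | None:
    """Detect the terminal overlap diagonal, deconvolving tandem repeats.

    Forward self-matches are grouped by diagonal (banded by the edit
    tolerance) and chained collinearly with gap tolerance ``match_gap``. A
    chain is a terminal-overlap candidate only if it extends to within
    tolerance of the contig start on the query side and of the contig end on
    the target side; interior chains (tandem repeat arrays, dispersed
    duplications) are never candidates. Candidates whose matched bases lie
    entirely inside short-period self-overlapping regions are also rejected:
    when the contig boundary falls inside a tandem array, the array's own
    periodicity produces end-to-end chains that merely re-express the repeat
    and would shave units off the array if trimmed. The best surviving
    candidate maximises chained support, then closeness of the implied copy
    number to a whole or half pass.
    """
    n = len(contig.seq)
    if contig.circular:
        raise ValueError("contig must be linear")
    if n < 1000:
        raise ValueError("contig too short")
    all_mems = [
        m
        for m in maximal_exact_matches(contig, contig, min_match, both_strands=False)
        if m.diagonal > 0
    ]
    if not all_mems:
        return None
    tol = max(25, 2 * min_match)
    band = max(8, int(max_edit_frac * n))

    # periodic mask: positions inside tandem arrays (short-period self-matches
    # whose query and target footprints overlap or abut). Matches wholly
    # inside the mask re-express array periodicity and cannot evidence a
    # junction duplication; a concatemer junction has period >> any repeat
    # unit, so the mask is capped at max_repeat_period.
    periodic = np.zeros(n, dtype=bool)
    for m in all_mems:
        if m.diagonal <= max_repeat_period and m.t_start <= m.q_end:
            periodic[m.q_start : m.t_end] = True
    mems = all_mems

    # cluster by diagonal
    mems.sort(key=lambda m: m.diagonal)
    clusters: list[list] = [[mems[0]]]
    for m in mems[1:]:
        if m.diagonal - clusters[-1][-1].diagonal <= band:
            clusters[-1].append(m)
        else:
            clusters.append([m])

    candidates = []
    for cluster in clusters:
        cluster.sort(key=lambda m: m.q_start)
        # split into collinear chains at large query gaps
        chains: list[list] = [[cluster[0]]]
        for m in cluster[1:]:
            if m.q_start - chains[-1][-1].q_end <= match_gap:
                chains[-1].append(m)
            else:
                chains.append([m])
        for chain in chains:
            q_min = min(m.q_start for m in chain)
            q_max = max(m.q_end for m in chain)
            t_min = min(m.t_start for m in chain)
            t_max = max(m.t_end for m in chain)
            if q_min > tol or t_max < n - tol:
                continue  # interior chain: repeat/duplication, not the overlap
            unique_support = sum(
                int((~periodic[m.q_start : m.q_end]).sum()) for m in chain
            )
            if unique_support < min_match:
                continue  # deconvolution: chain lives entirely in tandem arrays
            longest = max(chain, key=lambda m: m.length)
            period = longest.diagonal
            if period <= 0:
                continue
            support = sum(m.length for m in chain)
            n_copies = n / period
            # distance to the nearest whole or half pass through the circle
            half_dist = abs(n_copies * 2 - round(n_copies * 2)) / 2
            candidates.append(
                (
                    support,
                    -half_dist,
                    OverlapCall(
                        period=period,
                        head=Interval(contig.id, q_min, q_max),
                        tail=Interval(contig.id, t_min, t_max),
                        support=support,
                        n_copies=n_copies,
                    ),
                )
            )
    if not candidates:
        return None
    candidates.sort(key=lambda c: (-c[0], -c[1]))
    return candidates[0][2]


def collapse_to_unit(
    contig: SequenceRecord,
    call: OverlapCall | None,
    depth: np.ndarray | None = None,
) -> SequenceRecord:
    """Cut a single circular unit of length ``call.period`` out of the contig.

    With no overlap call the contig is returned unchanged (flagged via a
    warning for manual review). When the head and tail copies of the overlap
    disagree (sequencing error) and a short-read depth track is supplied, the
    base with the higher depth wins per disagreeing position.
    """
    if call is None:
        warnings.warn(f"{contig.id}: no overlap found; returning contig unchanged", stacklevel=2)
        return SequenceRecord(contig.id, contig.seq, circular=True)
    if call.period < 1000:
        raise ValueError("implausible mitogenome: period < 1 kb")
    n = len(contig.seq)
    start = call.head.start
    unit = list(contig.seq[start : start + call.period])

    if depth is not None:
        # arbitrate head/tail copy disagreements by short-read support
        m = min(n - call.period - start, call.period)
        head = contig.seq[start : start + m]
        tail = contig.seq[start + call.period : start + call.period + m]
        if head != tail and len(head) == len(tail):
            for i, (hb, tb) in enumerate(zip(head, tail)):
                if hb != tb:
                    d_head = depth[start + i] if start + i < len(depth) else 0
                    j = start + call.period + i
                    d_tail = depth[j] if j < len(depth) else 0
                    if d_tail > d_head:
                        unit[i] = tb
    return SequenceRecord(contig.id, "".join(unit), circular=True)


def rotate_to_anchor(
    circ: SequenceRecord,
    anchor: SequenceRecord,
    min_identity: float = 0.8,
) -> SequenceRecord:
    """Rotate (and orient) a circular sequence to start at the anchor.

    The anchor is located on both strands of the doubled sequence; the output
    is the rotation (reverse-complemented first when the best hit is on the
    minus strand) beginning at the anchor's first base. Idempotent.
    """
    if not circ.circular:
        raise ValueError("sequence must be circular")
    if len(anchor.seq) < 20:
        raise ValueError("anchor must be >= 20 bp")
    L = len(circ.seq)
    limit = int((1 - min_identity) * len(anchor.seq))
    best = None
    for strand_seq in (circ.seq, revcomp(circ.seq)):
        res = edlib.align(anchor.seq, strand_seq * 2, mode="HW", task="locations", k=limit)
        if res["editDistance"] >= 0:
            cand = (res["editDistance"], res["locations"][0][0] % L, strand_seq)
            if best is None or cand[:1] < best[:1]:
                best = cand
    if best is None:
        raise ValueError("anchor not found at the required identity")
    _, start, seq = best
    return SequenceRecord(circ.id, seq[start:] + seq[:start], circular=True)


def is_rotation(a: str, b: str, allow_revcomp: bool = False) -> bool:
    """True iff a is a rotation of b (doubled-string substring criterion)."""
    if len(a) != len(b):
        return False
    if a in b + b:
        return True
    return allow_revcomp and a in revcomp(b) + revcomp(b)
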