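"""Mitochondrial long-read fishing from a WGS read mixture.

A read is a confident mtDNA read when the fraction of its length accounted
for by reference-aligned sequence reaches a threshold (default 70%):

    fraction = reference_len x query_cover / read_len

where query_cover is the fraction of reference positions covered by the
union of the read's alignment segments (multi-segment support handles
fragmented references). An optional maximum read length cutoff (the ``-f``
guard) drops over-long reads, which typically contain NUMTs with flanking
nuclear sequence.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .matchfinder import ReadMapper
from .records import AlignmentRecord, SequenceRecord

DEFAULT_MIN_FRACTION = 0.70


def _covered_reference_bases(alignments: list[AlignmentRecord], reference_len: int) -> int:
    """Union length of folded reference positions covered by the alignments."""
    mask = np.zeros(reference_len, dtype=bool)
    for a in alignments:
        span = a.target_end - a.target_start
        span = min(span, reference_len)
        s = a.target_start % reference_len
        e = s + span
        if e <= reference_len:
            mask[s:e] = True
        else:
            mask[s:] = True
            mask[: e - reference_len] = True
    return int(mask.sum())


def confident_read_fraction(
    alignments: list[AlignmentRecord], reference_len: int, read_len: int
) -> float:
    """reference_len x query_cover / read_len, capped at 1.0.

    query_cover is the union coverage of the reference by this read's
    alignment segments, so the product reduces to covered bases / read length.
    """
    if read_len <= 0 or reference_len <= 0:
        raise ValueError("lengths must be positive")
    covered = _covered_reference_bases(alignments, reference_len)
    return min(1.0, covered / read_len)


def select_mt_reads(
    reads: list[SequenceRecord],
    reference: SequenceRecord,
    min_fraction: float = DEFAULT_MIN_FRACTION,
    max_read_len: int | None = None,
    min_seed: int = 16,
    max_edit_frac: float = 0.25,
) -> tuple[list[SequenceRecord], pd.DataFrame]:
    """Select putative mtDNA reads by the confident-read criterion.

    A read is kept iff it maps, its confident fraction >= min_fraction, and
    (when a cutoff is set) its length <= max_read_len. Returns the selected
    reads and a per-read report (fraction, length, decision).
    """
    if len(reference.seq) == 0:
        raise ValueError("reference must be non-empty")
    ref = reference if reference.circular else SequenceRecord(
        reference.id, reference.seq, circular=True
    )
    mapper = ReadMapper(ref, min_seed=min_seed, max_edit_frac=max_edit_frac)
    rows = []
    selected = []
    for read in reads:
        alns = mapper.align(read)
        frac = confident_read_fraction(alns, len(ref.seq), len(read)) if alns else 0.0
        too_long = max_read_len is not None and len(read) > max_read_len
        keep = bool(alns) and frac >= min_fraction and not too_long
        rows.append(
            {
                "read_id": read.id,
                "read_len": len(read),
                "mapped": bool(alns),
                "fraction": round(frac, 4),
                "too_long": too_long,
                "selected": keep,
            }
        )
        if keep:
            selected.append(read)
    report = pd.DataFrame(rows)
    if not selected:
        warnings.warn(
            "no long mtDNA reads selected; downstream assembly would fail here",
            stacklevel=2,
        )
    return selected, report
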