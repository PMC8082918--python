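"""Putative mitocontig selection from a multi-contig assembly.

Each contig is scored by reference query coverage -- the fraction of
reference positions covered by local alignments to the contig (union over
segments, reference side, matching the BLAST orientation used to screen
contigs). Contigs below a small percentage cutoff (default 5%) are spurious
matches and are discarded; with a complete, closely related reference the
cutoff can safely be raised (e.g., to 70%).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .matchfinder import seed_extend_align
from .records import SequenceRecord


class MitocontigNotFoundError(RuntimeError):
    """All contigs fell below the query-coverage cutoff."""


def contig_query_coverage(
    contig: SequenceRecord,
    reference: SequenceRecord,
    min_seed: int = 16,
    max_edit_frac: float = 0.25,
) -> float:
    """Fraction of reference positions covered by alignments to the contig."""
    if not contig.seq or not reference.seq:
        raise ValueError("sequences must be non-empty")
    alns = seed_extend_align(
        reference, contig, min_seed=min_seed, max_edit_frac=max_edit_frac
    )
    mask = np.zeros(len(reference.seq), dtype=bool)
    for a in alns:  # query side == reference side
        mask[a.query_start : a.query_end] = True
    return float(mask.sum()) / len(reference.seq)


def select_mitocontig(
    contigs: list[SequenceRecord],
    reference: SequenceRecord,
    min_query_cov_pct: float = 5.0,
    min_seed: int = 16,
    max_edit_frac: float = 0.25,
) -> tuple[SequenceRecord, pd.DataFrame]:
    """Pick the contig with the highest reference query coverage.

    Contigs under ``min_query_cov_pct`` percent are reported as filtered.
    Ties: longer contig first, then lexicographically smaller id.
    Raises MitocontigNotFoundError when every contig is filtered.
    """
    if not contigs:
        raise ValueError("need at least one contig")
    rows = []
    for c in contigs:
        cov = contig_query_coverage(c, reference, min_seed, max_edit_frac)
        rows.append({"contig_id": c.id, "length": len(c), "query_cov_pct": round(100 * cov, 2)})
    report = pd.DataFrame(rows)
    report["passed"] = report["query_cov_pct"] >= min_query_cov_pct
    survivors = report[report["passed"]]
    if survivors.empty:
        raise MitocontigNotFoundError(
            f"no contig reaches {min_query_cov_pct}% reference query coverage"
        )
    ranked = survivors.sort_values(
        by=["query_cov_pct", "length", "contig_id"], ascending=[False, False, True]
    )
    best_id = ranked.iloc[0]["contig_id"]
    best = next(c for c in contigs if c.id == best_id)
    return best, report
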