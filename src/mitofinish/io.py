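"""Readers and writers for FASTA, FASTQ, PAF, BED and TSV reports.

FASTA/FASTQ parsing is delegated to Biopython's SeqIO; PAF and BED are simple
tab-separated formats parsed directly. All coordinates stay 0-based half-open
through every parse/write cycle. Files ending in ``.gz`` are transparently
gzip-compressed.
"""

from __future__ import annotations

import gzip
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .records import AlignmentRecord, Interval, SequenceRecord


class ParseError(ValueError):
    """Raised when an input file violates its format."""


def _open(path, mode="rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def parse_sequences(path, format: str) -> list[SequenceRecord]:
    """Parse a FASTA or FASTQ file into SequenceRecords (file order, uppercased).

    FASTQ qualities are decoded as phred+33.
    """
    if format not in ("fasta", "fastq"):
        raise ValueError(f"unsupported format {format!r}")
    records: list[SequenceRecord] = []
    with _open(path) as fh:
        try:
            for rec in SeqIO.parse(fh, format):
                seq = str(rec.seq).upper()
                if not seq:
                    raise ParseError(f"{path}: record {rec.id!r} has empty sequence")
                quals = None
                if format == "fastq":
                    quals = rec.letter_annotations["phred_quality"]
                records.append(SequenceRecord(rec.id, seq, quals))
        except ParseError:
            raise
        except ValueError as exc:  # malformed record (Biopython reports the offence)
            raise ParseError(f"{path}: record {len(records) + 1}: {exc}") from exc
    return records


def write_sequences(records, path, format: str, line_width: int = 60) -> None:
    """Write SequenceRecords as FASTA (wrapped at ``line_width``) or FASTQ (phred+33)."""
    if format not in ("fasta", "fastq"):
        raise ValueError(f"unsupported format {format!r}")
    with _open(path, "wt") as fh:
        for rec in records:
            if format == "fasta":
                fh.write(f">{rec.id}\n")
                for i in range(0, len(rec.seq), line_width):
                    fh.write(rec.seq[i : i + line_width] + "\n")
            else:
                quals = rec.quals if rec.quals is not None else [30] * len(rec.seq)
                qstr = "".join(chr(min(q, 93) + 33) for q in quals)
                fh.write(f"@{rec.id}\n{rec.seq}\n+\n{qstr}\n")


def parse_paf(path) -> list[AlignmentRecord]:
    """Parse a 12+-column PAF file (minimap2 dialect); extra tag columns ignored."""
    out: list[AlignmentRecord] = []
    with _open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) < 12:
                raise ParseError(f"{path}:{lineno}: PAF line has {len(cols)} columns (< 12)")
            try:
                out.append(
                    AlignmentRecord(
                        query_id=cols[0],
                        query_len=int(cols[1]),
                        query_start=int(cols[2]),
                        query_end=int(cols[3]),
                        strand="-" if cols[4] in ("-", "−") else "+",
                        target_id=cols[5],
                        target_len=int(cols[6]),
                        target_start=int(cols[7]),
                        target_end=int(cols[8]),
                        n_matches=int(cols[9]),
                        block_len=int(cols[10]),
                    )
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_paf(alignments, path) -> None:
    with _open(path, "wt") as fh:
        for a in alignments:
            mapq = 60
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        a.query_id, a.query_len, a.query_start, a.query_end,
                        a.strand, a.target_id, a.target_len, a.target_start,
                        a.target_end, a.n_matches, a.block_len, mapq,
                    )
                )
                + "\n"
            )


def parse_bed(path) -> list[Interval]:
    """Parse BED3/BED6 lines into Intervals (0-based half-open, as BED natively is)."""
    out: list[Interval] = []
    with _open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise ParseError(f"{path}:{lineno}: BED line has fewer than 3 columns")
            strand = cols[5] if len(cols) >= 6 and cols[5] in "+-" else "+"
            out.append(Interval(cols[0], int(cols[1]), int(cols[2]), strand))
    return out


def write_bed(intervals, path, names=None) -> None:
    with _open(path, "wt") as fh:
        for i, iv in enumerate(intervals):
            name = names[i] if names else "."
            fh.write(f"{iv.seq_id}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")


def write_tsv(df: pd.DataFrame, path) -> None:
    """Write a report table as TSV with a '#'-prefixed header line."""
    with _open(path, "wt") as fh:
        fh.write("#" + "\t".join(map(str, df.columns)) + "\n")
        df.to_csv(fh, sep="\t", header=False, index=False)


def read_tsv(path) -> pd.DataFrame:
    with _open(path) as fh:
        header = fh.readline().rstrip("\n")
        if not header.startswith("#"):
            raise ParseError(f"{path}: TSV report must start with a '#' header line")
        cols = header[1:].split("\t")
        return pd.read_csv(fh, sep="\t", names=cols)
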