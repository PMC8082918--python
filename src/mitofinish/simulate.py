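"""Seeded generators of synthetic circular mitogenomes and read sets.

The generator emulates the study system: circular vertebrate mitogenomes of
14-22 kbp whose control region can carry tandem repeat arrays (unit 14-100 bp,
array up to ~2 kbp) and gene-region duplications; heteroplasmic mixtures that
differ in repeat copy number or in the presence of a duplication; noisy
insertion-biased long reads; accurate 150 bp short reads; and nuclear
background containing NUMT insertions with flanking nuclear sequence.
Concatemeric contigs mimic the raw output of a linear assembler on a circular
molecule. Every generator is deterministic under a fixed seed.

Read ids carry their true origin (allele, start, strand) so that downstream
selection and mapping can be scored exactly against truth with no alignment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ._encode import decode, encode
from .records import Interval, RepeatAnnotation, SequenceRecord, revcomp

MITO_GC = 0.44  # typical vertebrate mitogenome GC fraction


@dataclass
class RepeatSpec:
    """A tandem repeat array to plant in the control region."""

    unit_len: int
    copies: int
    unit_gc: float = 0.3
    position: int = 0  # offset into the control region

    def __post_init__(self):
        if self.unit_len < 1:
            raise ValueError("unit_len must be >= 1")
        if self.copies < 0:
            raise ValueError("copies must be >= 0")


@dataclass
class DuplicationSpec:
    """A (possibly partial) duplication of a gene-region interval."""

    source: Interval
    insert_at: int
    completeness: float = 1.0

    def __post_init__(self):
        if not (0 < self.completeness <= 1):
            raise ValueError("completeness must be in (0, 1]")


@dataclass
class ErrorProfile:
    """Per-base i.i.d. error rates; the default is insertion-biased as in
    single-molecule CLR data."""

    sub_rate: float = 0.02
    ins_rate: float = 0.06
    del_rate: float = 0.03

    def __post_init__(self):
        if min(self.sub_rate, self.ins_rate, self.del_rate) < 0:
            raise ValueError("rates must be >= 0")
        if self.sub_rate + self.ins_rate + self.del_rate >= 1:
            raise ValueError("total error rate must be < 1")


ERROR_FREE = ErrorProfile(0.0, 0.0, 0.0)


@dataclass
class GenomeTruth:
    """A simulated circular mitogenome plus exact truth annotations."""

    genome: SequenceRecord
    repeats: list[RepeatAnnotation] = field(default_factory=list)
    duplications: list[Interval] = field(default_factory=list)
    anchor: Interval = None

    def __post_init__(self):
        L = len(self.genome)
        for iv in [r.region for r in self.repeats] + list(self.duplications):
            if iv.end > L:
                raise ValueError("truth interval outside genome")
            if self.anchor and iv.start < self.anchor.end:
                raise ValueError("truth annotation overlaps the anchor")

    @property
    def anchor_seq(self) -> str:
        return self.genome.seq[self.anchor.start : self.anchor.end]


def _random_seq(rng: np.random.Generator, n: int, gc: float = MITO_GC) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return decode(rng.choice(4, size=n, p=p).astype(np.int8))


def simulate_mitogenome(
    base_len: int = 16500,
    repeat_specs: list[RepeatSpec] | None = None,
    dup_specs: list[DuplicationSpec] | None = None,
    anchor_len: int = 70,
    seed: int = 0,
    gc: float = MITO_GC,
    cr_len: int = 2500,
) -> GenomeTruth:
    """Generate a circular mitogenome with exact truth annotations.

    The anchor (a tRNA-Phe stand-in) occupies [0, anchor_len) by convention.
    Repeat arrays are inserted into the control region (the last ``cr_len``
    bases of the base genome); duplications at their requested positions.
    Final genome length is base_len plus the summed insert lengths.
    """
    if base_len < 1000:
        raise ValueError("base_len must be >= 1000")
    if anchor_len < 20:
        raise ValueError("anchor_len must be >= 20")
    repeat_specs = repeat_specs or []
    dup_specs = dup_specs or []
    rng = np.random.default_rng(seed)
    cr_len = min(cr_len, base_len // 4)
    cr_start = base_len - cr_len

    for attempt in range(20):
        base = _random_seq(rng, base_len, gc)
        # (position_in_base, inserted_seq, kind, payload)
        events = []
        total_insert = 0
        for spec in repeat_specs:
            unit = _random_seq(rng, spec.unit_len, spec.unit_gc)
            array = unit * spec.copies
            pos = min(cr_start + spec.position, base_len)
            events.append((pos, array, "repeat", (spec, unit)))
            total_insert += len(array)
        for spec in dup_specs:
            src_len = int(round(spec.completeness * len(spec.source)))
            seq = base[spec.source.start : spec.source.start + src_len]
            events.append((spec.insert_at, seq, "dup", spec))
            total_insert += len(seq)
        if total_insert > base_len:
            raise ValueError("inserts exceed base_len (genome would exceed 2x base length)")
        for pos, _, _, _ in events:
            if pos <= anchor_len:
                raise ValueError("insert position overlaps the anchor")

        events.sort(key=lambda e: e[0])
        pieces, repeats, dups = [], [], []
        prev = 0
        offset = 0
        gid = f"mito_sim_{seed}"
        for pos, ins, kind, payload in events:
            pieces.append(base[prev:pos])
            start = pos + offset
            if kind == "repeat":
                spec, unit = payload
                if ins:
                    repeats.append(
                        RepeatAnnotation(
                            Interval(gid, start, start + len(ins)),
                            spec.unit_len, float(spec.copies), unit,
                        )
                    )
            else:
                dups.append(Interval(gid, start, start + len(ins)))
            pieces.append(ins)
            offset += len(ins)
            prev = pos
        pieces.append(base[prev:])
        seq = "".join(pieces)
        assert len(seq) == base_len + total_insert

        anchor_seq = seq[:anchor_len]
        doubled = seq + seq[: anchor_len - 1]
        if doubled.count(anchor_seq) == 1 and anchor_seq not in revcomp(doubled):
            genome = SequenceRecord(gid, seq, circular=True)
            return GenomeTruth(genome, repeats, dups, Interval(gid, 0, anchor_len))
    raise RuntimeError("could not place a unique anchor (pathological parameters)")


# ---------------------------------------------------------------------------
# heteroplasmic allele construction
# ---------------------------------------------------------------------------

def repeat_copy_variant(truth: GenomeTruth, copies: int, repeat_index: int = 0) -> SequenceRecord:
    """Allele that differs from the reference only in repeat copy number."""
    rep = truth.repeats[repeat_index]
    g = truth.genome.seq
    unit = rep.unit_consensus
    seq = g[: rep.region.start] + unit * copies + g[rep.region.end :]
    return SequenceRecord(f"{truth.genome.id}|rep{repeat_index}x{copies}", seq, circular=True)


def drop_duplication_variant(truth: GenomeTruth, dup_index: int = 0) -> SequenceRecord:
    """Allele lacking one of the reference's duplications (structural loss)."""
    dup = truth.duplications[dup_index]
    g = truth.genome.seq
    seq = g[: dup.start] + g[dup.end :]
    return SequenceRecord(f"{truth.genome.id}|nodup{dup_index}", seq, circular=True)


# ---------------------------------------------------------------------------
# error injection
# ---------------------------------------------------------------------------

def apply_errors(seq: str, profile: ErrorProfile, rng: np.random.Generator) -> str:
    """i.i.d. per-base substitutions/insertions/deletions; an insertion emits
    the original base followed by one random base."""
    if profile.sub_rate == profile.ins_rate == profile.del_rate == 0:
        return seq
    codes = encode(seq).astype(np.int8)
    n = codes.size
    r = rng.random(n)
    s, d, i = profile.sub_rate, profile.del_rate, profile.ins_rate
    sub_mask = r < s
    del_mask = (r >= s) & (r < s + d)
    ins_mask = (r >= s + d) & (r < s + d + i)
    if sub_mask.any():
        shifts = rng.integers(1, 4, int(sub_mask.sum()), dtype=np.int8)
        codes[sub_mask] = (codes[sub_mask] + shifts) % 4
    indel_pos = np.nonzero(del_mask | ins_mask)[0]
    if indel_pos.size == 0:
        return decode(codes)
    ins_bases = rng.integers(0, 4, indel_pos.size, dtype=np.int8)
    parts = []
    prev = 0
    for p, ib in zip(indel_pos, ins_bases):
        parts.append(codes[prev:p])
        if ins_mask[p]:
            parts.append(codes[p : p + 1])
            parts.append(np.array([ib], dtype=np.int8))
        prev = p + 1
    parts.append(codes[prev:])
    return decode(np.concatenate(parts))


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------

def _lognormal_lengths(rng, n, mean, sd, lo, hi):
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2
    lens = rng.lognormal(mu, math.sqrt(sigma2), n)
    return np.clip(lens, lo, hi).astype(np.int64)


def simulate_long_reads(
    truth: GenomeTruth,
    alleles: list[tuple[SequenceRecord, float]] | None = None,
    coverage: float = 60.0,
    len_mean: float = 8000.0,
    len_sd: float = 4000.0,
    profile: ErrorProfile = ERROR_FREE,
    seed: int = 0,
) -> list[SequenceRecord]:
    """Noisy long reads from a (possibly heteroplasmic) circular genome.

    ``alleles`` is a list of (genome variant, weight); weights must sum to 1.
    Read starts are uniform on the circle, lengths log-normal truncated to
    [500, 3L]. Total bases land within 10% of coverage x mean allele length.
    Each read id encodes its true (allele, start, strand, length).
    """
    if alleles is None:
        alleles = [(truth.genome, 1.0)]
    weights = np.array([w for _, w in alleles], float)
    if abs(weights.sum() - 1.0) > 1e-9:
        raise ValueError("allele weights must sum to 1")
    if coverage <= 0:
        raise ValueError("coverage must be > 0")
    mean_L = float(np.mean([len(a) for a, _ in alleles]))
    if len_mean > 3 * mean_L:
        raise ValueError("len_mean exceeds 3x genome length")
    rng = np.random.default_rng(seed)
    target = coverage * mean_L
    reads: list[SequenceRecord] = []
    total = 0
    n = 0
    while total < 0.9 * target:
        ai = int(rng.choice(len(alleles), p=weights))
        allele, _ = alleles[ai]
        L = len(allele)
        length = int(_lognormal_lengths(rng, 1, len_mean, len_sd, 500, 3 * L)[0])
        if total + length > 1.1 * target:
            length = max(500, int(target - total))
        start = int(rng.integers(0, L))
        doubled = allele.seq * 3  # supports lengths up to 3L with wrap
        frag = doubled[start : start + length]
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            frag = revcomp(frag)
        frag = apply_errors(frag, profile, rng)
        rid = f"lr{n}|allele={ai}|start={start}|strand={strand}|len={length}"
        reads.append(SequenceRecord(rid, frag, quals=None))
        total += length
        n += 1
    return reads


def simulate_short_reads(
    genome: SequenceRecord,
    coverage: float = 100.0,
    read_len: int = 150,
    sub_rate: float = 0.001,
    seed: int = 0,
) -> list[SequenceRecord]:
    """Accurate single-end short reads, uniform on the circle (wrapping)."""
    if coverage <= 0:
        raise ValueError("coverage must be > 0")
    L = len(genome)
    n_reads = int(round(coverage * L / read_len))
    rng = np.random.default_rng(seed)
    starts = rng.integers(0, L, n_reads)
    strands = rng.random(n_reads) < 0.5
    doubled = genome.seq * 2
    reads = []
    for i in range(n_reads):
        s = int(starts[i])
        frag = doubled[s : s + read_len]
        strand = "+" if strands[i] else "-"
        if strand == "-":
            frag = revcomp(frag)
        if sub_rate > 0:
            codes = encode(frag).astype(np.int8)
            mask = rng.random(len(frag)) < sub_rate
            if mask.any():
                shifts = rng.integers(1, 4, int(mask.sum()), dtype=np.int8)
                codes[mask] = (codes[mask] + shifts) % 4
                frag = decode(codes)
        reads.append(SequenceRecord(f"sr{i}|start={s}|strand={strand}", frag))
    return reads


def simulate_nuclear_background(
    genome: SequenceRecord,
    numt_fragments: list[tuple[Interval, int]] | None = None,
    n_reads: int = 500,
    len_mean: float = 8000.0,
    seed: int = 0,
    n_chimeric_per_fragment: int = 10,
) -> list[SequenceRecord]:
    """Nuclear background reads plus NUMT-chimeric reads.

    Pure nuclear reads are random sequence (sharing no 16-mer with the
    mitogenome, with high probability). Each NUMT fragment (source interval,
    flank length) yields chimeric reads carrying the mtDNA-derived segment
    embedded in random nuclear flanks; chimeric reads are labeled in their id.
    """
    rng = np.random.default_rng(seed)
    reads = []
    lens = _lognormal_lengths(rng, n_reads, len_mean, len_mean / 2, 500, 10 * len_mean)
    for i in range(n_reads):
        reads.append(SequenceRecord(f"nuc{i}", _random_seq(rng, int(lens[i]), 0.41)))
    for fi, (src, flank) in enumerate(numt_fragments or []):
        if flank <= 0:
            raise ValueError("NUMT flank must be > 0")
        insert = genome.seq[src.start : src.end]
        for j in range(n_chimeric_per_fragment):
            left = _random_seq(rng, int(rng.integers(flank // 2, flank + 1)), 0.41)
            right = _random_seq(rng, int(rng.integers(flank // 2, flank + 1)), 0.41)
            reads.append(
                SequenceRecord(f"numt{fi}_{j}|src={src.start}-{src.end}", left + insert + right)
            )
    return reads


def make_concatemer_contig(
    truth: GenomeTruth,
    rotation: int = 0,
    copies: float = 2.0,
    contig_id: str = "tig00000001",
) -> SequenceRecord:
    """A linear Canu-like contig: the rotated genome read through ``copies``
    times (terminal overlap = everything beyond one full unit)."""
    if copies < 1:
        raise ValueError("copies must be >= 1")
    g = truth.genome.seq
    L = len(g)
    rot = g[rotation % L :] + g[: rotation % L]
    n = int(round(copies * L))
    tiled = rot * (n // L + 2)
    return SequenceRecord(contig_id, tiled[:n], circular=False)
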