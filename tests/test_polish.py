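"""Short-read consensus polishing and variant normalization."""

import numpy as np
import pytest

from conftest import random_dna
from mitofinish import polish, simulate
from mitofinish.polish import apply_variants, circular_coverage, normalize_variant, pileup_polish
from mitofinish.records import SequenceRecord, VariantCall


def brute_force_normalize(ref_seq: str, pos: int, ref: str, alt: str):
    """Leftmost parsimonious equivalent representation, by exhaustive search.

    Enumerates every (p, ref', alt') candidate over the edited string,
    keeps those that reproduce the same edit, restricts to minimal total
    allele length, and returns the leftmost. SNVs carry no shared context;
    indels keep one anchor base.
    """
    edited = ref_seq[:pos] + alt + ref_seq[pos + len(ref) :]
    best = None
    for p in range(len(ref_seq)):
        for lr in range(0, len(ref_seq) - p + 1):
            r = ref_seq[p : p + lr]
            for la in range(0, len(edited) + 1):
                for astart in range(0, len(edited) - la + 1):
                    a = edited[astart : astart + la]
                    if not r or not a:
                        continue
                    if ref_seq[:p] + a + ref_seq[p + lr :] == edited:
                        key = (len(r) + len(a), p)
                        if best is None or key < best[0]:
                            best = (key, (p, r, a))
    return best[1]


class TestNormalizeVariant:
    def test_snv_unchanged(self):
        ref = "ACGTACGT"
        call = VariantCall(3, "T", "G")
        out = normalize_variant(ref, call)
        assert (out.pos, out.ref_allele, out.alt_allele) == (3, "T", "G")

    def test_deletion_in_repeat_shifts_left(self):
        #      0123456789
        ref = "GCACACATTT"
        # deletion of "CA" reported at the rightmost unit (pos 4 del "CA")
        call = VariantCall(4, "ACA", "A")
        out = normalize_variant(ref, call)
        assert (out.pos, out.ref_allele, out.alt_allele) == (0, "GCA", "G")

    def test_homopolymer_insertion_left_aligned(self):
        ref = "AGTTTTCA"
        # insertion of T reported at the right end of the run
        call = VariantCall(5, "T", "TT")
        out = normalize_variant(ref, call)
        assert (out.pos, out.ref_allele, out.alt_allele) == (1, "G", "GT")

    def test_inconsistent_ref_allele_rejected(self):
        with pytest.raises(ValueError):
            normalize_variant("ACGT", VariantCall(0, "T", "A"))

    def test_idempotent_and_matches_brute_force_on_random_cases(self):
        rng = np.random.default_rng(77)
        for _ in range(250):
            ref_seq = random_dna(rng, int(rng.integers(10, 25)), "ACG")
            pos = int(rng.integers(1, len(ref_seq) - 3))
            kind = rng.integers(0, 3)
            if kind == 0:  # SNV
                ref = ref_seq[pos]
                alt = "ACGT"[(("ACGT".index(ref)) + 1 + int(rng.integers(0, 3))) % 4]
                if alt == ref:
                    continue
            elif kind == 1:  # deletion
                dlen = int(rng.integers(1, min(4, len(ref_seq) - pos - 1)))
                ref = ref_seq[pos : pos + 1 + dlen]
                alt = ref_seq[pos]
            else:  # insertion
                ins = random_dna(rng, int(rng.integers(1, 4)), "ACG")
                ref = ref_seq[pos]
                alt = ref + ins
            out = normalize_variant(ref_seq, VariantCall(pos, ref, alt))
            again = normalize_variant(ref_seq, out)
            assert (again.pos, again.ref_allele, again.alt_allele) == (
                out.pos, out.ref_allele, out.alt_allele)
            expect = brute_force_normalize(ref_seq, pos, ref, alt)
            assert (out.pos, out.ref_allele, out.alt_allele) == expect


class TestCircularCoverage:
    def test_no_reads_all_zero(self, plain_truth):
        depth = circular_coverage([], plain_truth.genome)
        assert depth.shape == (16000,)
        assert not depth.any()

    def test_origin_spanning_read_folds(self, plain_truth):
        g = plain_truth.genome
        L = len(g.seq)
        read = SequenceRecord("wrap", g.seq[L - 200 :] + g.seq[:300])
        depth = circular_coverage([read], g)
        assert depth[L - 200 :].sum() == 200
        assert depth[:300].sum() == 300
        assert depth[300 : L - 200].sum() == 0

    def test_uniform_simulation_covers_junction(self, plain_truth):
        reads = simulate.simulate_short_reads(plain_truth.genome, coverage=30, seed=51)
        depth = circular_coverage(reads, plain_truth.genome)
        assert depth[0] > 0 and depth[-1] > 0
        assert depth.min() > 0


def _inject(seq, rng, n_sub=0, n_del=0, n_ins=0):
    """Random substitutions/indels, kept away from each other and the origin."""
    seq = list(seq)
    positions = rng.choice(np.arange(200, len(seq) - 200, 60), n_sub + n_del + n_ins,
                           replace=False)
    for i, p in enumerate(sorted(positions, reverse=True)):
        p = int(p)
        if i < n_ins:
            seq.insert(p, "ACGT"[int(rng.integers(0, 4))])
        elif i < n_ins + n_del:
            del seq[p : p + int(rng.integers(1, 4))]
        else:
            seq[p] = "ACGT"[("ACGT".index(seq[p]) + 1 + int(rng.integers(0, 3))) % 4]
    return "".join(seq)


class TestPileupPolish:
    def test_identity_on_correct_assembly(self, plain_truth):
        reads = simulate.simulate_short_reads(plain_truth.genome, coverage=50,
                                              sub_rate=0.0, seed=61)
        result = pileup_polish(plain_truth.genome, reads)
        assert result.sequence.seq == plain_truth.genome.seq
        assert result.variants == []

    def test_recovers_substitutions_and_indels(self, plain_truth):
        g = plain_truth.genome
        rng = np.random.default_rng(62)
        broken = SequenceRecord(g.id, _inject(g.seq, rng, n_sub=4, n_del=2, n_ins=2),
                                circular=True)
        reads = simulate.simulate_short_reads(g, coverage=60, sub_rate=0.0, seed=63)
        result = pileup_polish(broken, reads)
        assert result.sequence.seq == g.seq
        # applying the reported calls to the broken assembly reproduces the fix
        assert apply_variants(broken.seq, result.variants) == g.seq

    def test_tie_keeps_assembly_base(self, plain_truth):
        g = plain_truth.genome
        # half the reads support the reference base, half an alternative
        pos = 5000
        alt = "A" if g.seq[pos] != "A" else "C"
        reads = []
        for i in range(10):
            frag = g.seq[pos - 70 : pos + 70]
            if i % 2:
                frag = frag[:70] + alt + frag[71:]
            reads.append(SequenceRecord(f"t{i}", frag))
        result = pileup_polish(g, reads, min_depth=3)
        assert result.sequence.seq[pos] == g.seq[pos]

    def test_zero_coverage_segment_unchanged_and_flagged(self, plain_truth):
        g = plain_truth.genome
        # reads only from the first half of the circle
        reads = [SequenceRecord(f"r{i}", g.seq[s : s + 150])
                 for i, s in enumerate(range(0, 7850, 30))]
        result = pileup_polish(g, reads)
        assert result.sequence.seq == g.seq
        assert result.low_coverage
        flagged = {(iv.start, iv.end) for iv in result.low_coverage}
        assert any(end - start > 7000 for start, end in flagged)

    @pytest.mark.parametrize("seed", range(4))
    def test_parameter_recovery_across_seeds(self, seed):
        truth = simulate.simulate_mitogenome(14000 + 500 * seed, seed=70 + seed)
        g = truth.genome
        rng = np.random.default_rng(90 + seed)
        broken = SequenceRecord(g.id, _inject(g.seq, rng, n_sub=6, n_del=1, n_ins=1),
                                circular=True)
        reads = simulate.simulate_short_reads(g, coverage=50, sub_rate=0.0,
                                              seed=80 + seed)
        assert pileup_polish(broken, reads).sequence.seq == g.seq
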