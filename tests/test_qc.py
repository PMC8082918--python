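"""k-mer QV, repeat annotation, similarity and heteroplasmy analytics."""

import math

import numpy as np  # noqa: E402
import pytest

from conftest import random_dna
from mitofinish import qc, simulate
from mitofinish.records import Interval, SequenceRecord, revcomp
from mitofinish.simulate import RepeatSpec


def brute_canonical_counts(seqs, k):
    out = {}
    for rec in seqs:
        s = rec.seq + (rec.seq[: k - 1] if rec.circular and len(rec.seq) >= k else "")
        for i in range(len(s) - k + 1):
            kmer = s[i : i + k]
            if set(kmer) - set("ACGT"):
                continue
            canon = min(kmer, revcomp(kmer))
            out[canon] = out.get(canon, 0) + 1
    return out


class TestCountKmers:
    def test_acgt_k3_canonical_merge(self):
        counts = qc.count_kmers(SequenceRecord("s", "ACGT"), 3)
        assert counts.to_dict() == {"ACG": 2}

    def test_empty_input(self):
        counts = qc.count_kmers([], 31)
        assert counts.n_distinct == 0

    def test_circular_genome_has_L_positions(self, plain_truth):
        counts = qc.count_kmers(plain_truth.genome, 31)
        assert counts.total == 16000

    @pytest.mark.parametrize("seed,k", [(1, 3), (2, 5), (3, 7), (4, 31)])
    def test_matches_brute_force_including_n_skipping(self, seed, k):
        rng = np.random.default_rng(seed)
        recs = [
            SequenceRecord("a", random_dna(rng, 200, "ACGTN")),
            SequenceRecord("b", random_dna(rng, 120), circular=True),
        ]
        assert qc.count_kmers(recs, k).to_dict() == brute_canonical_counts(recs, k)

    def test_k_validation(self):
        with pytest.raises(ValueError):
            qc.count_kmers([], 4)


class TestFilterHighFrequency:
    def test_boundary_at_min_freq(self):
        # one k-mer at 99 copies, another at 100
        low = [SequenceRecord(f"l{i}", "AAACCCTTT") for i in range(99)]
        high = [SequenceRecord(f"h{i}", "GGGTTTAAA") for i in range(100)]
        counts = qc.count_kmers(low + high, 7)
        filt = qc.filter_high_frequency(counts, 100)
        assert filt.get("AAACCCT") == 0
        assert filt.get("GGGTTTA") == 100

    def test_min_freq_one_is_identity(self, plain_truth):
        counts = qc.count_kmers(plain_truth.genome, 31)
        filt = qc.filter_high_frequency(counts, 1)
        assert filt.n_distinct == counts.n_distinct

    def test_nuclear_kmers_removed_mito_retained(self, plain_truth, rng):
        mito_reads = simulate.simulate_short_reads(plain_truth.genome, coverage=250,
                                                   sub_rate=0.0, seed=1)
        nuclear = [SequenceRecord(f"n{i}", random_dna(rng, 150)) for i in range(300)]
        counts = qc.count_kmers(mito_reads + nuclear, 31)
        filt = qc.filter_high_frequency(counts, 100)
        genome_kmers = qc.count_kmers(plain_truth.genome, 31)
        assert filt.contains(genome_kmers.codes).mean() > 0.999
        nuc_kmers = qc.count_kmers(nuclear, 31)
        only_nuc = np.setdiff1d(nuc_kmers.codes, genome_kmers.codes)
        assert not filt.contains(only_nuc).any()

    def test_all_below_floor_warns(self, plain_truth):
        counts = qc.count_kmers(plain_truth.genome, 31)
        with pytest.warns(UserWarning, match="coverage"):
            qc.filter_high_frequency(counts, 100)


@pytest.fixture(scope="module")
def assembly_and_reads():
    truth = simulate.simulate_mitogenome(16800, seed=99)
    reads = simulate.simulate_short_reads(truth.genome, coverage=200,
                                          sub_rate=0.0, seed=100)
    counts = qc.filter_high_frequency(qc.count_kmers(reads, 31), 100)
    return truth.genome, counts


class TestKmerQV:
    def test_error_free_assembly_infinite_qv(self, assembly_and_reads):
        genome, counts = assembly_and_reads
        report = qc.kmer_qv(SequenceRecord(genome.id, genome.seq), counts)
        assert report.false_positions == 0
        assert report.qv == math.inf
        assert report.note == "no false k-mers"

    def test_single_substitution_closed_form(self, assembly_and_reads):
        genome, counts = assembly_and_reads
        seq = list(genome.seq)
        seq[8000] = "ACGT"[("ACGT".index(seq[8000]) + 1) % 4]
        report = qc.kmer_qv(SequenceRecord("mut", "".join(seq)), counts)
        assert report.total_positions == 16800 - 30
        assert report.false_positions == 31
        expect = -10 * math.log10(1 - (1 - 31 / 16770) ** (1 / 31))
        assert report.qv == pytest.approx(expect, abs=1e-9)
        assert report.qv == pytest.approx(42.25, abs=0.01)

    def test_more_false_kmers_lower_qv(self, assembly_and_reads):
        genome, counts = assembly_and_reads
        def qv_with(n_subs):
            seq = list(genome.seq)
            for p in range(2000, 2000 + n_subs * 100, 100):
                seq[p] = "ACGT"[("ACGT".index(seq[p]) + 1) % 4]
            return qc.kmer_qv(SequenceRecord("m", "".join(seq)), counts).qv
        assert qv_with(1) > qv_with(2) > qv_with(8)

    def test_empty_assembly_rejected(self, assembly_and_reads):
        _, counts = assembly_and_reads
        with pytest.raises(ValueError):
            qc.kmer_qv([], counts)


class TestSharedKmerFraction:
    def test_identical_sequences(self, rng):
        s = SequenceRecord("s", random_dna(rng, 300))
        c = qc.count_kmers(s, 7)
        assert qc.shared_kmer_fraction(c, c) == 1.0

    def test_disjoint_is_zero(self):
        a = qc.count_kmers(SequenceRecord("a", "A" * 50), 7)
        b = qc.count_kmers(SequenceRecord("b", "ACGGCTA" * 10), 7)
        assert qc.shared_kmer_fraction(a, b) == 0.0

    def test_explicit_set_oracle_on_random_pairs(self, rng):
        from test_qc import brute_canonical_counts

        for _ in range(40):
            x = SequenceRecord("x", random_dna(rng, 60))
            y = SequenceRecord("y", random_dna(rng, 60))
            a, b = qc.count_kmers(x, 7), qc.count_kmers(y, 7)
            sa = set(brute_canonical_counts([x], 7))
            sb = set(brute_canonical_counts([y], 7))
            assert qc.shared_kmer_fraction(a, b) == pytest.approx(
                len(sa & sb) / len(sa | sb))
            assert qc.shared_kmer_fraction(a, b, denominator="total") == pytest.approx(
                len(sa & sb) / (len(sa) + len(sb)))

    def test_both_empty_rejected(self):
        e = qc.count_kmers([], 7)
        with pytest.raises(ValueError):
            qc.shared_kmer_fraction(e, e)


class TestAnnotateRepeats:
    def test_planted_84x11_array(self, kakapo_like_truth):
        anns = qc.annotate_repeats(kakapo_like_truth.genome)
        assert len(anns) == 1
        (a,) = anns
        truth_rep = kakapo_like_truth.repeats[0]
        assert a.unit_len == 84
        assert a.copy_number == pytest.approx(11, abs=0.5)
        assert abs(a.region.start - truth_rep.region.start) <= 84
        assert abs(a.region.end - truth_rep.region.end) <= 84

    def test_random_sequence_empty(self, rng):
        assert qc.annotate_repeats(SequenceRecord("r", random_dna(rng, 8000))) == []

    def test_two_arrays_distinct_units(self):
        truth = simulate.simulate_mitogenome(
            16000,
            [RepeatSpec(36, 8, position=100), RepeatSpec(70, 7, position=1200)],
            seed=111,
        )
        anns = sorted(qc.annotate_repeats(truth.genome), key=lambda a: a.region.start)
        assert [a.unit_len for a in anns] == [36, 70]

    @pytest.mark.parametrize("seed", range(8))
    def test_parameter_recovery(self, seed):
        rng = np.random.default_rng(300 + seed)
        unit_len = int(rng.integers(14, 101))
        copies = int(rng.integers(3, 21))
        truth = simulate.simulate_mitogenome(
            14000, [RepeatSpec(unit_len, copies, position=300)], seed=400 + seed)
        anns = qc.annotate_repeats(truth.genome)
        assert len(anns) == 1
        assert anns[0].unit_len == unit_len
        assert anns[0].copy_number == pytest.approx(copies, abs=0.5)

    def test_consensus_matches_planted_unit(self, kakapo_like_truth):
        (a,) = qc.annotate_repeats(kakapo_like_truth.genome)
        truth_unit = kakapo_like_truth.repeats[0].unit_consensus
        # consensus is some cyclic phase of the planted unit
        assert a.unit_consensus in truth_unit * 2


class TestClassifyDuplication:
    @pytest.mark.parametrize("dup,src,expect", [
        (95, 100, "complete"),
        (94, 100, "partial"),
        (100, 100, "complete"),
        (609, 1140, "partial"),
    ])
    def test_boundaries(self, dup, src, expect):
        assert qc.classify_duplication(dup, src) == expect

    def test_zero_source_rejected(self):
        with pytest.raises(ValueError):
            qc.classify_duplication(10, 0)


def _span_aln(rid, read_len, ts, te, ident=0.9, L=16000):
    from mitofinish.records import AlignmentRecord

    block = te - ts
    return AlignmentRecord(rid, read_len, 0, read_len, "+", "ref", L, ts, te,
                           int(block * ident), block)


class TestSpanningReads:
    REPEAT = Interval("ref", 7000, 7925)  # 925 bp

    def test_read_too_short_for_length_gate(self):
        a = _span_aln("short", 2900, 5000, 7950)
        assert qc.spanning_reads([a], self.REPEAT) == []

    def test_contained_high_identity_kept(self):
        a = _span_aln("good", 10000, 2000, 12000, ident=0.9)
        assert qc.spanning_reads([a], self.REPEAT) == ["good"]

    def test_boundary_overlap_only_excluded(self):
        a = _span_aln("left", 10000, 2000, 7500)
        assert qc.spanning_reads([a], self.REPEAT) == []

    def test_identity_strictly_above_threshold(self):
        a = _span_aln("lowid", 10000, 2000, 12000, ident=0.70)
        assert qc.spanning_reads([a], self.REPEAT) == []

    def test_anchor_margin_required_each_side(self):
        a = _span_aln("thin", 10000, 6500, 12000)  # only 500 bp left anchor
        assert qc.spanning_reads([a], self.REPEAT) == []


class TestLengthDeviation:
    def test_reference_allele_zero_deviation(self, kakapo_like_truth):
        truth = kakapo_like_truth
        reads = simulate.simulate_long_reads(truth, coverage=20, len_mean=8000,
                                             len_sd=2000, seed=500)
        obs = qc.spanning_observations(reads, truth.genome, truth.repeats[0].region)
        assert len(obs) >= 5
        assert all(o.deviation_bp == 0 for o in obs)

    def test_extra_unit_positive_deviation(self, kakapo_like_truth):
        truth = kakapo_like_truth
        twelve = simulate.repeat_copy_variant(truth, 12)
        reads = simulate.simulate_long_reads(truth, [(twelve, 1.0)], coverage=15,
                                             len_mean=8000, len_sd=2000, seed=501)
        obs = qc.spanning_observations(reads, truth.genome, truth.repeats[0].region)
        assert len(obs) >= 3
        assert all(o.deviation_bp == 84 for o in obs)
        assert all(o.deviation_rel == pytest.approx(84 / 924) for o in obs)

    def test_structural_loss_full_negative_deviation(self):
        truth = simulate.simulate_mitogenome(
            16000,
            dup_specs=[simulate.DuplicationSpec(Interval("base", 5000, 5924), 15000)],
            seed=502,
        )
        nodup = simulate.drop_duplication_variant(truth)
        reads = simulate.simulate_long_reads(truth, [(nodup, 1.0)], coverage=15,
                                             len_mean=8000, len_sd=2000, seed=503)
        obs = qc.spanning_observations(reads, truth.genome, truth.duplications[0])
        assert len(obs) >= 3
        assert all(o.deviation_rel == pytest.approx(-1.0, abs=0.02) for o in obs)


class TestCopyNumberHistogram:
    def test_all_reference_single_bin(self):
        from mitofinish.records import SpanningObservation

        obs = [SpanningObservation(f"r{i}", 924, 924) for i in range(20)]
        hist, maj = qc.copy_number_histogram(obs, 84, 11)
        assert hist == {11: 20}
        assert maj == 1.0

    def test_half_unit_rounds_away_from_zero(self):
        from mitofinish.records import SpanningObservation

        obs = [SpanningObservation("r", 84 * 11 + 42, 924)]  # exactly +half unit
        hist, _ = qc.copy_number_histogram(obs, 84, 11)
        assert hist == {12: 1}

    def test_mixture_recovery(self, kakapo_like_truth):
        truth = kakapo_like_truth
        alleles = [(truth.genome, 0.8)] + [
            (simulate.repeat_copy_variant(truth, c), 0.2 / 6)
            for c in (7, 8, 9, 10, 12, 13)
        ]
        reads = simulate.simulate_long_reads(
            truth, alleles, coverage=60, len_mean=7000, len_sd=2000,
            profile=simulate.ErrorProfile(0.01, 0.02, 0.01), seed=504)
        obs = qc.spanning_observations(reads, truth.genome, truth.repeats[0].region)
        hist, maj = qc.copy_number_histogram(obs, 84, 11)
        assert max(hist, key=hist.get) == 11
        # per-read implied copies match their allele labels exactly
        for o in obs:
            allele = int(dict(kv.split("=") for kv in o.read_id.split("|")[1:])["allele"])
            expect = 11 if allele == 0 else (7, 8, 9, 10, 12, 13)[allele - 1]
            x = o.observed_len / 84
            got = int(math.floor(x + 0.5))
            assert got == expect

    def test_insertion_bias_gives_positive_mean_deviation(self, kakapo_like_truth):
        truth = kakapo_like_truth
        profile = simulate.ErrorProfile(0.01, 0.05, 0.02)  # insertions favored
        reads = simulate.simulate_long_reads(truth, coverage=40, len_mean=7000,
                                             len_sd=2000, profile=profile, seed=505)
        obs = qc.spanning_observations(reads, truth.genome, truth.repeats[0].region)
        assert len(obs) >= 10
        assert np.mean([o.deviation_bp for o in obs]) > 0
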