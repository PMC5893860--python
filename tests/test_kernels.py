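import numpy as np
import pytest

import metacov as mc
from metacov.kernels import QueryKmer, reverse_complement

from conftest import brute_force_kmer_counts, random_reads


def make_reads(seqs):
    return [mc.SequenceRead(f"r{i}", s, source_index=i) for i, s in enumerate(seqs)]


def queries_from(reads, indices, k):
    out = []
    for i in indices:
        kmer = mc.extract_query_kmer(reads[i], k)
        assert kmer is not None
        out.append(QueryKmer(kmer=kmer, source_index=i, read=reads[i]))
    return out


class TestExtractQueryKmer:
    def test_prefix(self):
        read = mc.SequenceRead("r", "ACGTACGTAC")
        assert mc.extract_query_kmer(read, 4) == "ACGT"

    def test_short_read_ineligible(self):
        assert mc.extract_query_kmer(mc.SequenceRead("r", "A" * 20), 24) is None

    def test_n_in_window_ineligible(self):
        assert mc.extract_query_kmer(mc.SequenceRead("r", "ANGTACGT"), 4) is None


class TestKernelConfig:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"k": 0},
            {"k": 33},
            {"min_identity": 0.0},
            {"min_overlap": 1.5},
            {"transform_factor": 0.0},
            {"kernel": "blast"},
        ],
    )
    def test_invalid(self, kwargs):
        with pytest.raises(ValueError):
            mc.KernelConfig(**kwargs)


class TestCountKmerMatches:
    def test_forward_and_revcomp_hits(self):
        # query AACC from read 0: self hit at (0,0) excluded; revcomp GGTT
        # occurs at read 1 offset 1
        reads = make_reads(["AACCG", "TGGTT"])
        queries = queries_from(reads, [0], 4)
        profile = mc.count_kmer_matches(reads, queries, 4)
        assert profile.counts.tolist() == [1]
        assert profile.effective_positions == 4.0

    def test_unique_kmer_zero(self):
        reads = make_reads(["ACGTACGTAC", "TTTTTTTTTT"])
        queries = queries_from(reads, [0], 8)
        assert mc.count_kmer_matches(reads, queries, 8).counts.tolist() == [0]

    def test_identical_reads_full_length_kmer(self):
        reads = make_reads(["ACGTACGT"] * 3)
        queries = queries_from(reads, [1], 8)
        assert mc.count_kmer_matches(reads, queries, 8).counts.tolist() == [2]

    def test_k_mismatch_rejected(self):
        reads = make_reads(["ACGTACGT"])
        queries = [QueryKmer(kmer="ACG", source_index=0, read=reads[0])]
        with pytest.raises(ValueError):
            mc.count_kmer_matches(reads, queries, 4)

    @pytest.mark.parametrize("seed", range(30))
    def test_equals_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 50))
        length = int(rng.integers(8, 30))
        k = int(rng.integers(4, min(length, 12)))
        reads = random_reads(n, length, seed + 1000, alphabet="ACGTN" if seed % 3 == 0 else "ACGT")
        queries = []
        for i in rng.choice(n, size=min(10, n), replace=False):
            kmer = mc.extract_query_kmer(reads[int(i)], k)
            if kmer is not None:
                queries.append(QueryKmer(kmer=kmer, source_index=int(i), read=reads[int(i)]))
        if not queries:
            pytest.skip("no eligible queries drawn")
        got = mc.count_kmer_matches(reads, queries, k).counts
        np.testing.assert_array_equal(got, brute_force_kmer_counts(reads, queries, k))

    def test_strand_symmetry(self):
        # external queries (no self occurrence): reverse-complementing every
        # dataset read must leave all match counts unchanged
        reads = random_reads(30, 20, seed=42)
        queries = [
            QueryKmer(kmer=r.bases[:8], source_index=-1, read=r) for r in reads[:8]
        ]
        fwd = mc.count_kmer_matches(reads, queries, 8).counts
        flipped = [
            mc.SequenceRead(r.id, reverse_complement(r.bases), source_index=r.source_index)
            for r in reads
        ]
        rev = mc.count_kmer_matches(flipped, queries, 8).counts
        np.testing.assert_array_equal(fwd, rev)

    def test_monotone_in_dataset(self):
        reads = random_reads(40, 25, seed=3)
        queries = queries_from(reads, range(10), 10)
        small = mc.count_kmer_matches(reads[:20], queries, 10).counts
        large = mc.count_kmer_matches(reads, queries, 10).counts
        assert np.all(large >= small)

    def test_chunked_scan_identical(self):
        reads = random_reads(50, 30, seed=9)
        queries = queries_from(reads, range(12), 10)
        a = mc.count_kmer_matches(reads, queries, 10).counts
        b = mc.count_kmer_matches(reads, queries, 10, chunk_reads=7).counts
        np.testing.assert_array_equal(a, b)


class TestSelectQueryKmers:
    def test_redraw_past_ineligible(self):
        reads = make_reads(["ACGT" * 6, "AC", "N" * 24, "TGCA" * 6])
        queries = mc.select_query_kmers(reads, 2, k=24, seed=0)
        assert len(queries) == 2
        assert {q.source_index for q in queries} == {0, 3}

    def test_deterministic(self):
        reads = random_reads(50, 30, seed=1)
        a = mc.select_query_kmers(reads, 10, 10, seed=4)
        b = mc.select_query_kmers(reads, 10, 10, seed=4)
        assert [q.source_index for q in a] == [q.source_index for q in b]


class TestErrorMass:
    def test_q40_closed_form(self):
        probs = np.full(24, 1e-4)
        read = mc.SequenceRead("r", "A" * 24, error_probs=probs)
        q = QueryKmer(kmer=read.bases, source_index=0, read=read)
        e = mc.expected_error_kmers([q], 24)
        assert e == pytest.approx(1 - (1 - 1e-4) ** 24, rel=1e-12)

    def test_certain_error_contributes_one(self):
        probs = np.zeros(10)
        probs[3] = 1.0
        read = mc.SequenceRead("r", "A" * 10, error_probs=probs)
        q = QueryKmer(kmer=read.bases, source_index=0, read=read)
        assert mc.expected_error_kmers([q], 10) == pytest.approx(1.0)

    def test_fasta_reads_zero(self):
        read = mc.SequenceRead("r", "A" * 10)
        q = QueryKmer(kmer=read.bases, source_index=0, read=read)
        assert mc.expected_error_kmers([q], 10) == 0.0


class TestErrorCorrection:
    def make_profile(self, counts, n_reads=100, total_bp=10100, k=24):
        counts = np.asarray(counts)
        stats = mc.ReadSetStats(n_reads=n_reads, total_bp=total_bp)
        return mc.MatchProfile(
            counts=counts,
            n_queries_effective=float(counts.size),
            n_zero_effective=float((counts == 0).sum()),
            effective_positions=float(n_reads * (total_bp / n_reads - k + 1)),
            error_mass=0.0,
            stats=stats,
        )

    def test_identity_at_zero(self):
        profile = self.make_profile([0, 1, 2, 0])
        out = mc.apply_error_correction(profile, 0.0)
        assert out.n_zero_effective == 2.0
        assert out.n_queries_effective == 4.0
        assert out.effective_positions == profile.effective_positions

    def test_fractional_removal(self):
        counts = np.concatenate([np.zeros(40, dtype=int), np.ones(60, dtype=int)])
        out = mc.apply_error_correction(self.make_profile(counts), 10.0)
        assert out.n_zero_effective == pytest.approx(30.0)
        assert out.n_queries_effective == pytest.approx(90.0)

    def test_clamp_when_e_exceeds_zeros(self, caplog):
        counts = np.concatenate([np.zeros(40, dtype=int), np.ones(60, dtype=int)])
        with caplog.at_level("WARNING"):
            out = mc.apply_error_correction(self.make_profile(counts), 50.0)
        assert out.n_zero_effective == 0.0
        assert out.n_queries_effective == pytest.approx(60.0)
        assert any("clamp" in r.message for r in caplog.records)


class TestAlignUngapped:
    CONFIG = mc.KernelConfig(kernel="alignment")

    def test_identical_match(self):
        seq = random_reads(1, 100, seed=0)[0].bases
        assert mc.align_ungapped(seq, seq, self.CONFIG)

    def test_half_overlap_boundary_inclusive(self):
        rng = np.random.default_rng(1)
        query = "".join(rng.choice(list("ACGT"), size=100))
        tail = "".join(rng.choice(list("ACGT"), size=50))
        subject = query[50:] + tail  # exact 50-column overlap at one offset
        assert mc.align_ungapped(query, subject, self.CONFIG)

    def test_identity_below_threshold(self):
        rng = np.random.default_rng(2)
        query = "".join(rng.choice(list("ACGT"), size=100))
        subject = list(query)
        flipped = 0
        for i in range(0, 100, 17):  # 6 mismatches -> identity 0.94
            subject[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[subject[i]]
            flipped += 1
        assert flipped == 6
        assert not mc.align_ungapped(query, "".join(subject), self.CONFIG)

    def test_revcomp_match(self):
        seq = random_reads(1, 80, seed=3)[0].bases
        assert mc.align_ungapped(seq, reverse_complement(seq), self.CONFIG)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mc.align_ungapped("", "ACGT", self.CONFIG)


class TestCountAlignmentMatches:
    CONFIG = mc.KernelConfig(kernel="alignment")

    def test_identical_copies(self):
        reads = make_reads(["ACGTACGTACGTACGTACGT"] * 5)
        profile = mc.count_alignment_matches(reads, [reads[0]], self.CONFIG)
        assert profile.counts.tolist() == [4]
        assert profile.effective_positions == 100.0

    def test_unique_random_reads_all_zero(self):
        reads = random_reads(50, 100, seed=11)
        profile = mc.count_alignment_matches(reads, reads[:10], self.CONFIG)
        assert np.all(profile.counts == 0)

    @pytest.mark.parametrize("lengths", ["uniform", "mixed"])
    def test_equals_pairwise_oracle(self, lengths):
        rng = np.random.default_rng(23)
        genome = "".join(rng.choice(list("ACGT"), size=400))
        seqs = []
        for i in range(8):
            start = int(rng.integers(0, 300))
            ln = 60 if lengths == "uniform" else int(rng.integers(40, 80))
            frag = genome[start : start + ln]
            if rng.random() < 0.5:
                frag = reverse_complement(frag)
            seqs.append(frag)
        reads = make_reads(seqs)
        profile = mc.count_alignment_matches(reads, reads, self.CONFIG)
        expected = []
        for q in reads:
            m = sum(
                1
                for s in reads
                if s.source_index != q.source_index
                and mc.align_ungapped(q.bases, s.bases, self.CONFIG)
            )
            expected.append(m)
        assert profile.counts.tolist() == expected
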