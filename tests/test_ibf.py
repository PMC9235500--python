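"""The interleaved Bloom filter: hashing, insertion, queries, serialization."""

import numpy as np
import pytest
from scipy.stats import chisquare

from poresieve import (IbfParams, IndexFormatError, InterleavedBloomFilter,
                       default_seeds, hash_kmer)
from poresieve.ibf import Fragment
from poresieve.kmers import (canonical_codes, canonicalize, decode_kmer,
                             encode_kmers, random_kmer_codes,
                             reverse_complement_codes)


class TestKmerEncoding:
    def test_roundtrip(self, rng):
        for code in random_kmer_codes(50, 13, rng):
            assert encode_kmers(decode_kmer(int(code), 13), 13)[0] == code

    def test_ambiguous_windows_skipped(self):
        assert encode_kmers("ACGNACG", 3).size == 2  # 3 of 5 windows hold the N

    def test_palindrome_is_self_canonical(self):
        assert decode_kmer(int(canonical_codes("ACGT", 4)[0]), 4) == "ACGT"

    def test_canonical_of_homopolymer(self):
        assert decode_kmer(int(canonical_codes("TTTT", 4)[0]), 4) == "AAAA"

    def test_revcomp_involution(self, rng):
        codes = random_kmer_codes(100, 21, rng)
        assert (reverse_complement_codes(
            reverse_complement_codes(codes, 21), 21) == codes).all()

    def test_canonical_strand_invariant(self, rng):
        codes = random_kmer_codes(100, 15, rng)
        rc = reverse_complement_codes(codes, 15)
        assert (canonicalize(codes, 15) == canonicalize(rc, 15)).all()


class TestHashing:
    def test_deterministic(self):
        assert hash_kmer(123456, 42, 10_007) == hash_kmer(123456, 42, 10_007)

    def test_range(self, rng):
        codes = random_kmer_codes(100_000, 13, rng)
        idx = hash_kmer(codes, default_seeds(1)[0], 977)
        assert idx.min() >= 0 and idx.max() < 977

    def test_uniformity_chi_square(self, rng):
        codes = random_kmer_codes(1_000_000, 13, rng)
        idx = hash_kmer(codes, default_seeds(3)[2], 1024)
        counts = np.bincount(np.asarray(idx, dtype=np.int64), minlength=1024)
        assert chisquare(counts).pvalue > 1e-4

    def test_seeds_distinct_and_stable(self):
        s4 = default_seeds(4)
        assert len(set(s4)) == 4
        assert default_seeds(2) == s4[:2]  # published prefix property


class TestInsertQuery:
    def test_single_kmer_sets_at_most_h_bits(self, toy_ibf):
        code = canonical_codes("CAGGATT", 7)
        toy_ibf.insert_fragment(code, bin_index=1)
        assert int(np.unpackbits(toy_ibf.bits.view(np.uint8)).sum()) <= toy_ibf.params.h
        assert toy_ibf.query_kmer(int(code[0])).bits.tolist() == [False, True, False]

    def test_no_false_negatives(self, toy_ibf, rng):
        codes = canonicalize(random_kmer_codes(500, 7, rng), 7)
        toy_ibf.insert_fragment(codes, bin_index=2)
        assert toy_ibf.query_kmers(codes)[:, 2].all()

    def test_query_empty_filter_all_zero(self, toy_ibf, rng):
        codes = random_kmer_codes(100, 7, rng)
        assert not toy_ibf.query_kmers(codes).any()

    def test_insertion_never_clears_bits(self, toy_ibf, rng):
        a = canonicalize(random_kmer_codes(200, 7, rng), 7)
        b = canonicalize(random_kmer_codes(200, 7, rng), 7)
        toy_ibf.insert_fragment(a, 0)
        before = toy_ibf.query_kmers(b).copy()
        toy_ibf.insert_fragment(b, 1)
        after = toy_ibf.query_kmers(b)
        assert (after | ~before).all()  # no 1 -> 0 flips anywhere

    def test_bin_index_out_of_range(self, toy_ibf):
        with pytest.raises(IndexError):
            toy_ibf.insert_fragment(np.array([1], dtype=np.uint64), 3)

    def test_padding_bins_stay_zero(self, toy_ibf, rng):
        toy_ibf.insert_fragment(random_kmer_codes(500, 7, rng), 0)
        words = toy_ibf._binning_words(random_kmer_codes(64, 7, rng))
        bits = np.unpackbits(words.view(np.uint8), axis=1, bitorder="little")
        assert not bits[:, toy_ibf.n_frag:].any()

    def test_monte_carlo_fp_on_oversized_filter(self, toy_ibf, rng):
        """At a rated FP of 1e-9, random non-inserted k-mers essentially
        never produce a hit."""
        inserted = canonicalize(random_kmer_codes(58, 7, rng), 7)
        toy_ibf.insert_fragment(inserted, 1)
        probes = random_kmer_codes(100_000, 7, rng)
        # at k=7 the k-mer space is tiny: drop genuine members of the bin
        probes = probes[~np.isin(probes, inserted)]
        hit_rate = toy_ibf.query_kmers(probes).any(axis=1).mean()
        assert probes.size > 90_000
        assert hit_rate <= 1e-3


class TestCountMatches:
    def test_exact_substring_matches_all_kmers(self, small_index, small_reference):
        seq = small_reference[0][1][1000:1360]
        cv = small_index.count_matches(seq)
        assert cv.L_queried == 348
        assert cv.counts[0] == 348

    def test_figure_scenario_three_of_four_7mers(self, toy_ibf):
        """A 10-nt read holds four 7-mers; a fragment sharing its last 9 nt
        holds three of them, so bin 2's counter reads 3 — enough to accept
        the read at a threshold of 3."""
        read = "CAGGATTACG"
        fragment = read[1:]  # drops only the first 7-mer
        toy_ibf.insert_fragment(canonical_codes(fragment, 7), bin_index=1)
        cv = toy_ibf.count_matches(read)
        assert cv.L_queried == 4
        assert cv.counts.tolist() == [0, 3, 0]
        assert cv.counts[1] >= 3  # the acceptance rule of the worked example

    def test_read_shorter_than_k_rejected(self, small_index):
        with pytest.raises(ValueError):
            small_index.count_matches("ACGT")

    def test_counts_match_exact_set_oracle(self, rng):
        """With a filter oversized to FP ~ 1e-9, per-bin counts equal exact
        k-mer-set membership counting; counts never undershoot the oracle."""
        from poresieve import build_index, generate_reference, simulate_reads
        from poresieve.simulate import SimulationConfig
        refs = generate_reference(10, [10_000] * 10, 0.5, seed=21)
        params = IbfParams(k=13, p=1e-9, fragment_size=10_000, overlap=500)
        ibf = build_index([], params, records=refs)
        exact_sets = [frozenset(canonical_codes(seq, 13).tolist())
                      for _, seq in refs]
        cfg = SimulationConfig(substitution_rate=0.1, insertion_rate=0.0,
                               deletion_rate=0.0, median_read_length=500, seed=22)
        for read in simulate_reads(refs, 200, config=cfg, seed=22):
            cv = ibf.count_matches(read.sequence)
            codes = canonical_codes(read.sequence, 13).tolist()
            oracle = [sum(c in s for c in codes) for s in exact_sets]
            assert cv.counts.tolist() == oracle


class TestSerialization:
    def test_roundtrip_bit_exact(self, toy_ibf, tmp_path, rng):
        toy_ibf.insert_fragment(random_kmer_codes(300, 7, rng), 1)
        path = tmp_path / "toy.ibf"
        toy_ibf.write(path)
        again = InterleavedBloomFilter.read(path)
        assert again.to_bytes() == toy_ibf.to_bytes()
        assert again.params == toy_ibf.params
        assert again.fragments == toy_ibf.fragments

    def test_roundtrip_preserves_queries(self, toy_ibf, tmp_path, rng):
        toy_ibf.insert_fragment(random_kmer_codes(300, 7, rng), 2)
        path = tmp_path / "toy.ibf"
        toy_ibf.write(path)
        again = InterleavedBloomFilter.read(path)
        probes = random_kmer_codes(1000, 7, rng)
        assert (again.query_kmers(probes) == toy_ibf.query_kmers(probes)).all()

    def test_empty_file_is_format_error(self, tmp_path):
        path = tmp_path / "empty.ibf"
        path.write_bytes(b"")
        with pytest.raises(IndexFormatError, match="magic|truncated"):
            InterleavedBloomFilter.read(path)

    def test_bad_magic(self, tmp_path):
        path = tmp_path / "bad.ibf"
        path.write_bytes(b"NOPE" + b"\x00" * 64)
        with pytest.raises(IndexFormatError, match="magic"):
            InterleavedBloomFilter.read(path)

    def test_truncated_file(self, toy_ibf, tmp_path):
        path = tmp_path / "trunc.ibf"
        toy_ibf.write(path)
        path.write_bytes(path.read_bytes()[:-100])
        with pytest.raises(IndexFormatError, match="truncated"):
            InterleavedBloomFilter.read(path)

    def test_version_mismatch(self, toy_ibf, tmp_path):
        path = tmp_path / "ver.ibf"
        raw = bytearray(toy_ibf.to_bytes())
        raw[4] = 99
        path.write_bytes(bytes(raw))
        with pytest.raises(IndexFormatError, match="version"):
            InterleavedBloomFilter.read(path)


class TestParams:
    def test_duplicate_seeds_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            IbfParams(h=2, seeds=(7, 7))

    def test_overlap_bounds(self):
        with pytest.raises(ValueError):
            IbfParams(fragment_size=100, overlap=100)

    def test_fragment_must_hold_one_kmer(self):
        with pytest.raises(ValueError):
            IbfParams(k=13, fragment_size=12, overlap=0)
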