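import numpy as np
import pytest

from conftest import random_dna
from minifuge import (
    GenomeRecord,
    KmerSimilarityTable,
    compress_species,
    find_identical_regions,
    merge_pair,
    most_similar_pair,
    sample_kmers,
    simulate_strain,
    simulate_strain_family,
)
from minifuge.compressor import verify_dropped_matches


class TestSampleKmers:
    def test_full_rate_is_exhaustive(self):
        g = GenomeRecord("g", 0, "ACGTA")
        assert sample_kmers(g, k=3, rate=1.0) == {"ACG", "CGT", "GTA"}

    def test_too_short_genome_empty(self):
        assert sample_kmers(GenomeRecord("g", 0, "AC"), k=3, rate=1.0) == set()

    def test_kmers_with_n_skipped(self):
        g = GenomeRecord("g", 0, "ACNTA")
        assert sample_kmers(g, k=3, rate=1.0) == set()

    def test_sampling_rate_binomial(self):
        rng = np.random.default_rng(0)
        g = GenomeRecord("g", 0, random_dna(rng, 100_000))
        kmers = sample_kmers(g, k=53, rate=0.01, seed=5)
        # expected ~1000 sampled positions; nearly all k-mers are distinct
        assert 850 <= len(kmers) <= 1150

    def test_seed_determinism(self):
        rng = np.random.default_rng(1)
        g = GenomeRecord("g", 0, random_dna(rng, 5000))
        assert sample_kmers(g, seed=3) == sample_kmers(g, seed=3)

    def test_invalid_params(self):
        g = GenomeRecord("g", 0, "ACGT")
        with pytest.raises(ValueError):
            sample_kmers(g, k=0)
        with pytest.raises(ValueError):
            sample_kmers(g, rate=0.0)


class TestMostSimilarPair:
    def _table(self, seqs):
        sets = {sid: sample_kmers(GenomeRecord(sid, 0, s), k=5, rate=1.0) for sid, s in seqs.items()}
        return KmerSimilarityTable(k=5, sample_rate=1.0, kmer_sets=sets)

    def test_two_genomes(self):
        rng = np.random.default_rng(2)
        table = self._table({"a": random_dna(rng, 100), "b": random_dna(rng, 100)})
        assert most_similar_pair(table) == ("a", "b")

    def test_identical_twins_found(self):
        rng = np.random.default_rng(3)
        twin = random_dna(rng, 200)
        table = self._table(
            {"x": random_dna(rng, 200), "t1": twin, "t2": twin, "y": random_dna(rng, 200)}
        )
        assert most_similar_pair(table) == ("t1", "t2")

    def test_all_zero_ties_lexicographic(self):
        table = self._table({"c": "A" * 10, "b": "C" * 10, "a": "G" * 10})
        assert most_similar_pair(table) == ("a", "b")

    def test_single_genome_errors(self):
        with pytest.raises(ValueError):
            most_similar_pair(self._table({"a": "ACGTACGT"}))


class TestFindIdenticalRegions:
    def test_identical_query_single_full_match(self):
        rng = np.random.default_rng(4)
        seq = random_dna(rng, 3000)
        ref = [GenomeRecord("r", 0, seq)]
        (m,) = find_identical_regions(ref, GenomeRecord("q", 0, seq))
        assert (m.qry_start, m.qry_end) == (0, 3000)
        assert m.identity == 1.0

    def test_unrelated_query_no_matches(self):
        rng = np.random.default_rng(5)
        ref = [GenomeRecord("r", 0, random_dna(rng, 3000))]
        qry = GenomeRecord("q", 0, random_dna(rng, 3000))
        assert find_identical_regions(ref, qry) == []

    def test_planted_mutations_identity(self):
        # one substitution per 200 bp -> one chained match, identity 0.995
        base = random_dna(np.random.default_rng(60), 4000)
        mutated = list(base)
        for pos in range(100, 4000, 200):
            mutated[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mutated[pos]]
        matches = find_identical_regions(
            [GenomeRecord("r", 0, base)], GenomeRecord("q", 0, "".join(mutated))
        )
        assert len(matches) == 1
        assert matches[0].identity == pytest.approx(1 - 20 / 4000, abs=1e-9)

    def test_matches_non_overlapping_on_query(self):
        rng = np.random.default_rng(8)
        block = random_dna(rng, 500)
        ref = [GenomeRecord("r", 0, block + random_dna(rng, 500) + block)]
        qry = GenomeRecord("q", 0, random_dna(rng, 200) + block + random_dna(rng, 200))
        matches = find_identical_regions(ref, qry)
        spans = sorted((m.qry_start, m.qry_end) for m in matches)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert e1 <= s2


class TestMergePair:
    def test_identical_query_fully_dropped(self):
        rng = np.random.default_rng(9)
        seq = random_dna(rng, 2000)
        merged, dropped = merge_pair(
            [GenomeRecord("r", 7, seq)], GenomeRecord("q", 7, seq)
        )
        assert [g.seq_id for g in merged] == ["r"]
        assert len(dropped) == 1

    def test_unrelated_query_fully_retained(self):
        rng = np.random.default_rng(10)
        ref = [GenomeRecord("r", 7, random_dna(rng, 2000))]
        qry = GenomeRecord("q", 7, random_dna(rng, 2000))
        merged, dropped = merge_pair(ref, qry)
        assert dropped == []
        assert sum(g.length for g in merged) == 4000

    def test_half_copy_retains_novel_half(self):
        rng = np.random.default_rng(11)
        shared = random_dna(rng, 2000)
        novel = random_dna(rng, 2000)
        merged, _ = merge_pair(
            [GenomeRecord("r", 7, shared + random_dna(rng, 1000))],
            GenomeRecord("q", 7, shared + novel),
        )
        retained = sum(g.length for g in merged if g.seq_id.startswith("q|"))
        assert retained == pytest.approx(2000, abs=60)

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            merge_pair([GenomeRecord("r", 0, "ACGT")], GenomeRecord("q", 0, "ACGT"), 0.0)


class TestCompressSpecies:
    def test_single_genome_unchanged(self):
        g = GenomeRecord("g", 5, "ACGT" * 100)
        merged, stats, dropped = compress_species([g])
        assert merged == [g] and stats.ratio == 1.0 and dropped == []

    def test_identical_genomes_collapse_to_one(self):
        rng = np.random.default_rng(12)
        seq = random_dna(rng, 8000)
        genomes = [GenomeRecord(f"g{i}", 5, seq) for i in range(5)]
        merged, stats, _ = compress_species(genomes, seed=1)
        assert stats.compressed_bp == 8000
        assert stats.original_bp == 40000

    def test_mixed_taxa_rejected(self):
        with pytest.raises(ValueError):
            compress_species(
                [GenomeRecord("a", 1, "ACGT" * 50), GenomeRecord("b", 2, "ACGT" * 50)]
            )

    def test_strain_family_compresses_and_stays_lossless(self):
        fam = simulate_strain_family(20_000, 5, 0.005, seed=21, taxon_id=9)
        merged, stats, dropped = compress_species(fam, seed=21)
        assert stats.compressed_bp < 1.3 * 20_000
        identities = verify_dropped_matches({g.seq_id: g for g in fam}, merged, dropped)
        assert identities and min(identities) >= 0.99

    def test_seeded_determinism(self):
        fam = simulate_strain_family(10_000, 4, 0.005, seed=33, taxon_id=9)
        m1, s1, _ = compress_species(fam, seed=2)
        m2, s2, _ = compress_species(fam, seed=2)
        assert [(g.seq_id, g.sequence) for g in m1] == [(g.seq_id, g.sequence) for g in m2]
        assert s1 == s2

    def test_compressed_never_exceeds_input(self):
        rng = np.random.default_rng(13)
        genomes = [GenomeRecord(f"g{i}", 5, random_dna(rng, 3000)) for i in range(4)]
        merged, stats, _ = compress_species(genomes, seed=3)
        assert stats.compressed_bp <= stats.original_bp


def test_strain_divergence_vs_parent():
    parent = GenomeRecord("p", 1, random_dna(np.random.default_rng(14), 100_000))
    strain = simulate_strain(parent, 0.005, seed=15)
    diffs = sum(a != b for a, b in zip(parent.sequence, strain.sequence))
    assert 400 <= diffs <= 600
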