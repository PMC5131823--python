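import numpy as np
import pytest

from conftest import random_dna
from minifuge import (
    FmIndex,
    GenomeRecord,
    build_worked_example,
    classify_pair,
    classify_read,
    revcomp,
    score_taxa,
    segment_strand,
)
from minifuge.classifier import SegmentHit
from minifuge.worked_example import GENUS_I, SPECIES


@pytest.fixture(scope="module")
def example():
    ex = build_worked_example(seed=17)
    return ex, FmIndex.build(ex.records)


def _mutate(base: str) -> str:
    return {"A": "C", "C": "G", "G": "T", "T": "A"}[base]


class TestSegmentStrand:
    def test_exact_substring_single_segment(self, tiny_db):
        records, idx, taxmap = tiny_db
        read = records[0].sequence[200:300]
        (hit,) = segment_strand(idx, read, taxmap)
        assert hit.length == 100 and hit.read_start == 0
        assert hit.taxa == frozenset({101})

    def test_canonical_three_segment_read(self, example):
        # rightmost 40 bp -> six species; 26 bp -> two; 32-bp prefix -> one
        ex, idx = example
        hits = segment_strand(idx, ex.read, ex.taxmap)
        assert [(h.read_start, h.length) for h in hits] == [(0, 32), (33, 26), (60, 40)]
        assert [len(h.taxa) for h in hits] == [1, 2, 6]
        rc_hits = segment_strand(idx, revcomp(ex.read), ex.taxmap)
        assert [h.length for h in rc_hits] == [17, 18, 28, 16, 17]

    def test_all_n_read_no_segments(self, tiny_db):
        _, idx, taxmap = tiny_db
        assert segment_strand(idx, "N" * 80, taxmap) == []

    def test_mismatch_consumes_one_base(self, tiny_db):
        records, idx, taxmap = tiny_db
        read = list(records[1].sequence[100:200])
        read[40] = _mutate(read[40])
        hits = segment_strand(idx, "".join(read), taxmap)
        assert [(h.read_start, h.length) for h in hits] == [(0, 40), (41, 59)]

    def test_short_matches_advance_but_do_not_report(self, tiny_db):
        records, idx, taxmap = tiny_db
        read = list(records[0].sequence[300:340])
        for pos in (10, 25):  # split into runs of 10, 14, 14 -> all under 16
            read[pos] = _mutate(read[pos])
        assert segment_strand(idx, "".join(read), taxmap, min_seed=16) == []


class TestScoreTaxa:
    def test_forty_bp_hit_scores_625(self):
        hits = [SegmentHit("forward", 60, 40, frozenset({1}))]
        assert score_taxa(hits) == {1: 625.0}

    def test_below_report_threshold_absent(self):
        hits = [SegmentHit("forward", 0, 21, frozenset({1}))]
        assert score_taxa(hits, min_report=22) == {}
        assert score_taxa(hits, min_report=21) == {1: 36.0}

    def test_two_hits_sum(self):
        hits = [
            SegmentHit("forward", 0, 26, frozenset({1})),
            SegmentHit("forward", 30, 32, frozenset({1})),
        ]
        assert score_taxa(hits) == {1: 121.0 + 289.0}


class TestClassifyRead:
    def test_canonical_example_classification(self, example):
        ex, idx = example
        res = classify_read(idx, ex.tree, ex.taxmap, ex.read, read_id=ex.read_id)
        assert res.score == 625.0
        assert set(res.labels) == {GENUS_I, SPECIES["D"], SPECIES["E"], SPECIES["F"]}
        assert res.second_best_score == 410.0  # species G: 121 + 289
        assert res.best_hit_length == 40
        assert res.total_match_length == 98
        res1 = classify_read(idx, ex.tree, ex.taxmap, ex.read, cap=1)
        assert res1.labels == (10,)  # the family-level LCA

    def test_unmatched_read_unclassified(self, example, small_tree):
        ex, idx = example
        rng = np.random.default_rng(0)
        res = classify_read(idx, ex.tree, ex.taxmap, random_dna(rng, 100))
        assert not res.classified and res.score == 0.0

    def test_read_shorter_than_report_threshold(self, example):
        ex, idx = example
        res = classify_read(idx, ex.tree, ex.taxmap, ex.read[:21])
        assert not res.classified

    def test_strand_symmetry(self, tiny_db, small_tree):
        records, idx, taxmap = tiny_db
        rng = np.random.default_rng(23)
        for _ in range(50):
            gi = int(rng.integers(0, 3))
            start = int(rng.integers(0, 1900))
            read = list(records[gi].sequence[start : start + 100])
            for pos in rng.integers(0, len(read), size=3):
                read[pos] = _mutate(read[pos])
            read = "".join(read)
            fwd = classify_read(idx, small_tree, taxmap, read, read_id="f")
            rev = classify_read(idx, small_tree, taxmap, revcomp(read), read_id="f")
            assert fwd == rev

    def test_determinism(self, example):
        ex, idx = example
        a = classify_read(idx, ex.tree, ex.taxmap, ex.read)
        b = classify_read(idx, ex.tree, ex.taxmap, ex.read)
        assert a == b

    def test_score_monotone_in_hit_length(self, tiny_db, small_tree):
        records, idx, taxmap = tiny_db
        scores = []
        for k in (30, 31, 32):
            read = records[0].sequence[100 : 100 + k]
            scores.append(classify_read(idx, small_tree, taxmap, read).score)
        assert scores[0] < scores[1] < scores[2]

    def test_self_classification_of_error_free_reads(self, tiny_db, small_tree):
        records, idx, taxmap = tiny_db
        rng = np.random.default_rng(31)
        for _ in range(20):
            gi = int(rng.integers(0, 3))
            start = int(rng.integers(0, 1950))
            read = records[gi].sequence[start : start + 50]
            res = classify_read(idx, small_tree, taxmap, read)
            assert res.labels == (records[gi].taxon_id,)
            assert res.score >= (50 - 15) ** 2


class TestClassifyPair:
    def test_empty_scoring_mate_degenerates_to_single(self, tiny_db, small_tree):
        records, idx, taxmap = tiny_db
        rng = np.random.default_rng(5)
        mate1 = records[0].sequence[400:500]
        mate2 = random_dna(rng, 100)  # matches nothing
        pair = classify_pair(idx, small_tree, taxmap, mate1, mate2, read_id="p")
        single = classify_read(idx, small_tree, taxmap, mate1, read_id="p")
        # identical classification; query_length covers both mates
        assert (pair.labels, pair.score, pair.second_best_score,
                pair.best_hit_length, pair.total_match_length) == (
            single.labels, single.score, single.second_best_score,
            single.best_hit_length, single.total_match_length)
        assert pair.query_length == 200

    def test_consistent_mates_sum_scores(self, tiny_db, small_tree):
        records, idx, taxmap = tiny_db
        mate1 = records[1].sequence[100:200]
        mate2 = revcomp(records[1].sequence[300:400])
        pair = classify_pair(idx, small_tree, taxmap, mate1, mate2)
        s1 = classify_read(idx, small_tree, taxmap, mate1).score
        s2 = classify_read(idx, small_tree, taxmap, mate2).score
        assert pair.labels == (102,)
        assert pair.score == s1 + s2

    def test_conflicting_mates_argmax_of_sums(self, tiny_db, small_tree):
        # mate1 -> species 101 with 100 bp; mate2 -> species 103 with 60 bp
        records, idx, taxmap = tiny_db
        mate1 = records[0].sequence[500:600]
        mate2 = records[2].sequence[500:560]
        pair = classify_pair(idx, small_tree, taxmap, mate1, mate2)
        assert pair.labels == (101,)
        assert pair.score == (100 - 15) ** 2

    def test_empty_mate_errors(self, tiny_db, small_tree):
        _, idx, taxmap = tiny_db
        with pytest.raises(ValueError):
            classify_pair(idx, small_tree, taxmap, "ACGT", "")
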