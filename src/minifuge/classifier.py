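"""Per-read classification by greedy exact-match segmentation.

A read is scanned right to left (3' to 5') on both strands.  From the
current right end the longest exact match against the database is taken; a
mismatch consumes exactly one read base before the search resumes.  Matches
of at least ``min_seed`` (16) bases are resolved to the sequences (hence
taxa) containing them; only segments of at least ``min_report`` (22) bases
contribute to the per-taxon score

    score(taxon) = sum over that taxon's segments of (length - 15)^2,

which weights long matches quadratically; 15 bases is roughly the match
length expected by chance against a large database.  Each taxon's score is
the maximum of its per-strand scores (summing both strands would bias toward
palindromic sequence).  The taxa achieving the global maximum score become
the read's labels and are collapsed to at most ``cap`` (default 5) labels by
taxonomic label reduction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .fmindex import FmIndex
from .taxonomy import TaxonomyTree

MIN_SEED = 16  # shortest match worth a locate query
MIN_REPORT = 22  # shortest match allowed to contribute score
SCORE_OFFSET = 15  # subtracted from match length before squaring
DEFAULT_CAP = 5  # maximum labels per read
DEFAULT_MAX_POSITIONS = 200  # cap on resolved sequences per segment

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

FORWARD = "forward"
REVCOMP = "revcomp"


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SegmentHit:
    """One maximal exact match between a read stretch and the database."""

    strand: str
    read_start: int
    length: int
    taxa: frozenset[int]


@dataclass(frozen=True)
class ReadClassification:
    """Classification outcome for one read (or read pair)."""

    read_id: str
    labels: tuple[int, ...]
    score: float
    second_best_score: float
    best_hit_length: int
    total_match_length: int
    query_length: int

    @property
    def classified(self) -> bool:
        return bool(self.labels)


def segment_strand(
    index: FmIndex,
    read: str,
    taxmap: Mapping[str, int],
    strand: str = FORWARD,
    min_seed: int = MIN_SEED,
    max_positions: int = DEFAULT_MAX_POSITIONS,
) -> list[SegmentHit]:
    """Greedy right-to-left decomposition of one strand into exact matches.

    Matches shorter than ``min_seed`` advance the cursor but are not resolved.
    Each mismatch (or N) consumes one read base before the search resumes.
    """
    hits: list[SegmentHit] = []
    end = len(read)
    while end > 0:
        length, rng = index.extend_left(read, end)
        if length >= min_seed:
            pairs = index.resolve(rng, max_positions=max_positions)
            taxa = frozenset(
                taxmap[sid] for sid, _ in pairs if sid in taxmap
            )
            if taxa:
                hits.append(
                    SegmentHit(strand=strand, read_start=end - length, length=length, taxa=taxa)
                )
        end -= length + 1
    hits.reverse()
    return hits


def score_taxa(
    hits: Iterable[SegmentHit],
    min_report: int = MIN_REPORT,
    offset: int = SCORE_OFFSET,
) -> dict[int, float]:
    """Per-taxon sum of squared (length - offset) over qualifying segments.

    Segments shorter than ``min_report`` contribute nothing; taxa with no
    qualifying segment are absent from the result.
    """
    scores: dict[int, float] = {}
    for hit in hits:
        if hit.length < min_report:
            continue
        weight = float(hit.length - offset) ** 2
        for taxon in hit.taxa:
            scores[taxon] = scores.get(taxon, 0.0) + weight
    return scores


def _strand_scores(
    index: FmIndex,
    read: str,
    taxmap: Mapping[str, int],
    min_seed: int,
    min_report: int,
    max_positions: int,
) -> tuple[dict[str, dict[int, float]], dict[str, list[SegmentHit]]]:
    hits = {
        FORWARD: segment_strand(
            index, read, taxmap, FORWARD, min_seed=min_seed, max_positions=max_positions
        ),
        REVCOMP: segment_strand(
            index, revcomp(read), taxmap, REVCOMP, min_seed=min_seed, max_positions=max_positions
        ),
    }
    scores = {s: score_taxa(h, min_report=min_report) for s, h in hits.items()}
    return scores, hits


def _combine_strands(per_strand: Mapping[str, Mapping[int, float]]) -> dict[int, float]:
    combined: dict[int, float] = {}
    for strand_scores in per_strand.values():
        for taxon, s in strand_scores.items():
            if s > combined.get(taxon, 0.0):
                combined[taxon] = s
    return combined


def _winning_strand(per_strand: Mapping[str, Mapping[int, float]]) -> str:
    best_f = max(per_strand[FORWARD].values(), default=0.0)
    best_r = max(per_strand[REVCOMP].values(), default=0.0)
    return FORWARD if best_f >= best_r else REVCOMP


def _hit_lengths(hits: Sequence[SegmentHit], min_report: int) -> tuple[int, int]:
    qualifying = [h.length for h in hits if h.length >= min_report]
    return (max(qualifying, default=0), sum(qualifying))


def _unclassified(read_id: str, query_length: int) -> ReadClassification:
    return ReadClassification(read_id, (), 0.0, 0.0, 0, 0, query_length)


def classify_read(
    index: FmIndex,
    tree: TaxonomyTree,
    taxmap: Mapping[str, int],
    read: str,
    read_id: str = "read",
    cap: int = DEFAULT_CAP,
    min_report: int = MIN_REPORT,
    min_seed: int = MIN_SEED,
    max_positions: int = DEFAULT_MAX_POSITIONS,
) -> ReadClassification:
    """Classify a single read against the database.

    Both strands are segmented and scored; each taxon takes its best strand
    score; the taxa tied at the global maximum become the labels, reduced to
    at most ``cap`` by ancestor grouping.  Hit lengths are reported for the
    winning strand only.  Reads with no qualifying match are unclassified.
    """
    if cap < 1:
        raise ValueError("cap must be >= 1")
    read = read.upper()
    if len(read) < min_report:
        return _unclassified(read_id, len(read))
    per_strand, hits = _strand_scores(
        index, read, taxmap, min_seed, min_report, max_positions
    )
    combined = _combine_strands(per_strand)
    if not combined:
        return _unclassified(read_id, len(read))
    best = max(combined.values())
    winners = {t for t, s in combined.items() if s == best}
    labels = tree.reduce_labels(winners, cap, scores=combined)
    second = max((s for t, s in combined.items() if t not in winners), default=0.0)
    strand = _winning_strand(per_strand)
    best_hit, total = _hit_lengths(hits[strand], min_report)
    return ReadClassification(
        read_id=read_id,
        labels=tuple(sorted(labels)),
        score=best,
        second_best_score=second,
        best_hit_length=best_hit,
        total_match_length=total,
        query_length=len(read),
    )


def classify_pair(
    index: FmIndex,
    tree: TaxonomyTree,
    taxmap: Mapping[str, int],
    read1: str,
    read2: str,
    read_id: str = "pair",
    cap: int = DEFAULT_CAP,
    min_report: int = MIN_REPORT,
    min_seed: int = MIN_SEED,
    max_positions: int = DEFAULT_MAX_POSITIONS,
) -> ReadClassification:
    """Classify a read pair: per-mate strand selection, then summed scores."""
    if cap < 1:
        raise ValueError("cap must be >= 1")
    if not read1 or not read2:
        raise ValueError("both mates must be nonempty")
    mates = [read1.upper(), read2.upper()]
    combined_per_mate = []
    best_hit = 0
    total = 0
    for mate in mates:
        if len(mate) < min_report:
            combined_per_mate.append({})
            continue
        per_strand, hits = _strand_scores(
            index, mate, taxmap, min_seed, min_report, max_positions
        )
        combined_per_mate.append(_combine_strands(per_strand))
        strand = _winning_strand(per_strand)
        bh, tl = _hit_lengths(hits[strand], min_report)
        best_hit = max(best_hit, bh)
        total += tl
    summed: dict[int, float] = {}
    for mate_scores in combined_per_mate:
        for taxon, s in mate_scores.items():
            summed[taxon] = summed.get(taxon, 0.0) + s
    query_length = sum(len(m) for m in mates)
    if not summed:
        return _unclassified(read_id, query_length)
    best = max(summed.values())
    winners = {t for t, s in summed.items() if s == best}
    labels = tree.reduce_labels(winners, cap, scores=summed)
    second = max((s for t, s in summed.items() if t not in winners), default=0.0)
    return ReadClassification(
        read_id=read_id,
        labels=tuple(sorted(labels)),
        score=best,
        second_best_score=second,
        best_hit_length=best_hit,
        total_match_length=total,
        query_length=query_length,
    )


class Classifier:
    """Convenience wrapper binding an index, taxon map, tree, and parameters."""

    def __init__(
        self,
        index: FmIndex,
        taxmap: Mapping[str, int],
        tree: TaxonomyTree,
        cap: int = DEFAULT_CAP,
        min_seed: int = MIN_SEED,
        min_report: int = MIN_REPORT,
        max_positions: int = DEFAULT_MAX_POSITIONS,
    ):
        self.index = index
        self.taxmap = dict(taxmap)
        self.tree = tree
        self.cap = cap
        self.min_seed = min_seed
        self.min_report = min_report
        self.max_positions = max_positions

    def classify(self, read: str, read_id: str = "read") -> ReadClassification:
        return classify_read(
            self.index,
            self.tree,
            self.taxmap,
            read,
            read_id=read_id,
            cap=self.cap,
            min_report=self.min_report,
            min_seed=self.min_seed,
            max_positions=self.max_positions,
        )

    def classify_pair(self, read1: str, read2: str, read_id: str = "pair") -> ReadClassification:
        return classify_pair(
            self.index,
            self.tree,
            self.taxmap,
            read1,
            read2,
            read_id=read_id,
            cap=self.cap,
            min_report=self.min_report,
            min_seed=self.min_seed,
            max_positions=self.max_positions,
        )

    def classify_reads(self, reads) -> list[ReadClassification]:
        return [self.classify(r.sequence, r.read_id) for r in reads]
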