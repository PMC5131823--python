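"""Similarity-driven compression of same-species genome collections.

Multiple sequenced strains of one species are usually near-identical; storing
each in full wastes index space.  Compression greedily merges the collection:

1. sample k-mers (k = 53 by default) from every genome at a 1% rate and count
   shared sampled k-mers per genome pair;
2. merge the most similar pair — regions of the candidate genome that align
   to the growing merged genome at >= 99% identity are discarded, the rest is
   retained as new sequences;
3. recompute similarity of the remaining genomes against the merged genome
   (using the union of its constituents' sampled k-mer sets) and repeat.

Near-identical regions are found by chaining shared exact ``anchor_k``-mers
that fall on a common diagonal, then measuring column-wise identity over the
chained span.  This targets substitution-level divergence between strains;
it does not model rearrangements or indels between the genomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io_formats import GenomeRecord
from .taxonomy import TaxonomyTree

DEFAULT_K = 53
DEFAULT_SAMPLE_RATE = 0.01
DEFAULT_ANCHOR_K = 21
DEFAULT_IDENTITY = 0.99
MAX_ANCHOR_HITS = 8  # anchors seen more often in the reference are skipped
DEFAULT_MAX_GAP = 500  # max distance between chained anchor starts


@dataclass(frozen=True)
class IdentityMatch:
    """A near-identical region pair between a merged reference and a candidate."""

    ref_id: str
    ref_start: int
    ref_end: int
    qry_id: str
    qry_start: int
    qry_end: int
    identity: float


@dataclass
class KmerSimilarityTable:
    """Symmetric shared-sampled-k-mer counts between genome pairs.

    ``kmer_sets[g]`` holds, for genome g, the sampled k-mers it contains.
    When built with :meth:`from_genomes`, k-mer positions are first sampled
    at ``sample_rate`` from every genome, pooled, and then every genome's
    membership in the pooled k-mers is evaluated exactly — a table of which
    sampled k-mers belong to which genomes.  Pooling matters: it makes the
    shared counts reflect true sequence similarity instead of the tiny
    overlap between two independent 1% position samples.
    """

    k: int
    sample_rate: float
    kmer_sets: dict[str, set[str]]
    shared_counts: dict[tuple[str, str], int] = field(default_factory=dict)

    def __post_init__(self):
        ids = sorted(self.kmer_sets)
        for i, a in enumerate(ids):
            for b in ids[i + 1 :]:
                self.shared_counts[(a, b)] = len(self.kmer_sets[a] & self.kmer_sets[b])

    def shared(self, a: str, b: str) -> int:
        key = (a, b) if a <= b else (b, a)
        return self.shared_counts[key]

    @classmethod
    def from_genomes(
        cls,
        genomes: Sequence[GenomeRecord],
        k: int = DEFAULT_K,
        rate: float = DEFAULT_SAMPLE_RATE,
        seed: int = 0,
    ) -> "KmerSimilarityTable":
        ss = np.random.SeedSequence(seed)
        pool: set[str] = set()
        for g, child in zip(genomes, ss.spawn(len(genomes))):
            pool |= sample_kmers(
                g, k=k, rate=rate, seed=int(child.generate_state(1)[0] % (2**31))
            )
        membership = {
            g.seq_id: genome_membership(g, pool, k) for g in genomes
        }
        return cls(k=k, sample_rate=rate, kmer_sets=membership)


def genome_membership(genome: GenomeRecord, pool: set[str], k: int) -> set[str]:
    """Subset of the pooled k-mers occurring exactly in the genome."""
    seq = genome.sequence
    return {
        kmer
        for pos in range(genome.length - k + 1)
        if (kmer := seq[pos : pos + k]) in pool
    }


@dataclass(frozen=True)
class CompressionStats:
    taxon_id: int
    n_genomes: int
    original_bp: int
    compressed_bp: int

    @property
    def ratio(self) -> float:
        return self.compressed_bp / self.original_bp if self.original_bp else 1.0


def sample_kmers(
    genome: GenomeRecord,
    k: int = DEFAULT_K,
    rate: float = DEFAULT_SAMPLE_RATE,
    seed: int = 0,
) -> set[str]:
    """Randomly sample k-mer start positions at the given rate (seeded).

    Every position is included independently with probability ``rate``;
    k-mers containing N are skipped.  Genomes shorter than ``k`` yield the
    empty set.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if not 0 < rate <= 1:
        raise ValueError("rate must be in (0, 1]")
    n_pos = genome.length - k + 1
    if n_pos <= 0:
        return set()
    rng = np.random.default_rng(seed)
    if rate >= 1.0:
        positions = np.arange(n_pos)
    else:
        positions = np.nonzero(rng.random(n_pos) < rate)[0]
    seq = genome.sequence
    out = set()
    for pos in positions:
        kmer = seq[pos : pos + k]
        if "N" not in kmer:
            out.add(kmer)
    return out


def most_similar_pair(table: KmerSimilarityTable) -> tuple[str, str]:
    """Genome pair with the maximal shared sampled-k-mer count.

    Ties (including the all-zero case) break to the lexicographically first
    pair.  Fewer than two genomes is an error.
    """
    if len(table.kmer_sets) < 2:
        raise ValueError("need at least two genomes to pick a pair")
    best = min(
        table.shared_counts.items(), key=lambda item: (-item[1], item[0])
    )
    return best[0]


def find_identical_regions(
    ref: Sequence[GenomeRecord],
    qry: GenomeRecord,
    anchor_k: int = DEFAULT_ANCHOR_K,
    max_gap: int = DEFAULT_MAX_GAP,
) -> list[IdentityMatch]:
    """Near-identical regions between a (merged) reference and a candidate.

    Shared exact ``anchor_k``-mers on a common (ref_seq, diagonal) are chained
    when consecutive anchor starts are within ``max_gap``; each chain's span
    is scored by column-wise identity.  Returned matches are non-overlapping
    on the query (longest chains win).
    """
    if not ref or not qry.sequence:
        raise ValueError("reference and query must be nonempty")
    anchors: dict[str, list[tuple[int, int]]] = {}
    overflow: set[str] = set()
    for ridx, rec in enumerate(ref):
        seq = rec.sequence
        for pos in range(rec.length - anchor_k + 1):
            kmer = seq[pos : pos + anchor_k]
            if "N" in kmer or kmer in overflow:
                continue
            hits = anchors.setdefault(kmer, [])
            if len(hits) >= MAX_ANCHOR_HITS:
                overflow.add(kmer)
                del anchors[kmer]
                continue
            hits.append((ridx, pos))

    diagonals: dict[tuple[int, int], list[int]] = {}
    qseq = qry.sequence
    for qpos in range(qry.length - anchor_k + 1):
        kmer = qseq[qpos : qpos + anchor_k]
        for ridx, rpos in anchors.get(kmer, ()):
            diagonals.setdefault((ridx, rpos - qpos), []).append(qpos)

    qarr = np.frombuffer(qseq.encode("ascii"), dtype=np.uint8)
    rarrs = [np.frombuffer(r.sequence.encode("ascii"), dtype=np.uint8) for r in ref]

    candidates: list[IdentityMatch] = []
    for (ridx, diag), qpositions in diagonals.items():
        qpositions.sort()
        chain_start = qpositions[0]
        prev = qpositions[0]
        spans = []
        for qp in qpositions[1:]:
            if qp - prev > max_gap:
                spans.append((chain_start, prev + anchor_k))
                chain_start = qp
            prev = qp
        spans.append((chain_start, prev + anchor_k))
        for qs, qe in spans:
            rs, re = qs + diag, qe + diag
            ident = float(np.mean(qarr[qs:qe] == rarrs[ridx][rs:re]))
            candidates.append(
                IdentityMatch(
                    ref_id=ref[ridx].seq_id,
                    ref_start=rs,
                    ref_end=re,
                    qry_id=qry.seq_id,
                    qry_start=qs,
                    qry_end=qe,
                    identity=ident,
                )
            )

    # greedy non-overlapping selection on the query, longest span first
    candidates.sort(key=lambda m: (-(m.qry_end - m.qry_start), m.qry_start))
    chosen: list[IdentityMatch] = []
    taken: list[tuple[int, int]] = []
    for m in candidates:
        if any(m.qry_start < e and s < m.qry_end for s, e in taken):
            continue
        chosen.append(m)
        taken.append((m.qry_start, m.qry_end))
    chosen.sort(key=lambda m: m.qry_start)
    return chosen


def merge_pair(
    ref: Sequence[GenomeRecord],
    qry: GenomeRecord,
    identity_threshold: float = DEFAULT_IDENTITY,
    anchor_k: int = DEFAULT_ANCHOR_K,
    min_retain: int | None = None,
    max_gap: int = DEFAULT_MAX_GAP,
) -> tuple[list[GenomeRecord], list[IdentityMatch]]:
    """Merge a candidate genome into the reference collection.

    Query intervals matched at >= ``identity_threshold`` identity are
    discarded; the remaining intervals, if at least ``min_retain`` bases
    (default ``2 * anchor_k``), are appended as new provenance-tagged
    sequences.  Returns ``(merged records, dropped matches)``.
    """
    if not 0 < identity_threshold <= 1:
        raise ValueError("identity_threshold must be in (0, 1]")
    if min_retain is None:
        min_retain = 2 * anchor_k
    matches = find_identical_regions(ref, qry, anchor_k=anchor_k, max_gap=max_gap)
    dropped = [m for m in matches if m.identity >= identity_threshold]

    covered = sorted((m.qry_start, m.qry_end) for m in dropped)
    merged_cov: list[list[int]] = []
    for s, e in covered:
        if merged_cov and s <= merged_cov[-1][1]:
            merged_cov[-1][1] = max(merged_cov[-1][1], e)
        else:
            merged_cov.append([s, e])

    retained: list[GenomeRecord] = []
    cursor = 0
    for s, e in merged_cov + [[qry.length, qry.length]]:
        if s - cursor >= min_retain:
            retained.append(
                GenomeRecord(
                    seq_id=f"{qry.seq_id}|{cursor}-{s}",
                    taxon_id=qry.taxon_id,
                    sequence=qry.sequence[cursor:s],
                )
            )
        cursor = max(cursor, e)
    return list(ref) + retained, dropped


def compress_species(
    genomes: Sequence[GenomeRecord],
    k: int = DEFAULT_K,
    rate: float = DEFAULT_SAMPLE_RATE,
    anchor_k: int = DEFAULT_ANCHOR_K,
    identity_threshold: float = DEFAULT_IDENTITY,
    seed: int = 0,
    min_retain: int | None = None,
    max_gap: int = DEFAULT_MAX_GAP,
) -> tuple[list[GenomeRecord], CompressionStats, list[IdentityMatch]]:
    """Iteratively merge a same-species genome collection.

    The most similar pair seeds the merged genome (the longer member is the
    reference); each remaining genome is then merged in order of decreasing
    shared sampled k-mers with the merged genome, whose k-mer set is the
    union of its constituents' samples.  Returns the merged records, the
    compression stats, and all dropped near-identical matches (for post-hoc
    verification of the identity guarantee).
    """
    if not genomes:
        raise ValueError("no genomes to compress")
    taxa = {g.taxon_id for g in genomes}
    taxon = genomes[0].taxon_id
    original_bp = sum(g.length for g in genomes)
    if len(genomes) == 1:
        stats = CompressionStats(taxon, 1, original_bp, original_bp)
        return list(genomes), stats, []
    if len(taxa) > 1:
        raise ValueError("compress_species requires genomes sharing one taxon")

    by_id = {g.seq_id: g for g in genomes}
    table = KmerSimilarityTable.from_genomes(genomes, k=k, rate=rate, seed=seed)
    kmer_sets = table.kmer_sets
    a, b = most_similar_pair(table)
    # the longer genome of the seed pair becomes the reference
    if (by_id[b].length, a) > (by_id[a].length, b):
        a, b = b, a
    merged = [by_id[a]]
    merged_kmers = set(kmer_sets[a])
    remaining = sorted(sid for sid in by_id if sid not in (a, b))
    queue = [b] + remaining
    dropped_all: list[IdentityMatch] = []

    while queue:
        nxt = min(queue, key=lambda sid: (-len(kmer_sets[sid] & merged_kmers), sid))
        queue.remove(nxt)
        merged, dropped = merge_pair(
            merged,
            by_id[nxt],
            identity_threshold=identity_threshold,
            anchor_k=anchor_k,
            min_retain=min_retain,
            max_gap=max_gap,
        )
        dropped_all.extend(dropped)
        merged_kmers |= kmer_sets[nxt]

    compressed_bp = sum(g.length for g in merged)
    stats = CompressionStats(taxon, len(genomes), original_bp, compressed_bp)
    return merged, stats, dropped_all


def compress_database(
    genomes: Sequence[GenomeRecord],
    tree: TaxonomyTree | None = None,
    **params,
) -> tuple[list[GenomeRecord], list[CompressionStats]]:
    """Compress a whole database, species group by species group.

    Genomes are grouped by their species-rank ancestor when a taxonomy is
    given (falling back to their own taxon id), compressed per group, and
    concatenated in input group order.
    """
    groups: dict[int, list[GenomeRecord]] = {}
    order: list[int] = []
    for g in genomes:
        key = g.taxon_id
        if tree is not None and g.taxon_id in tree:
            anc = tree.ancestor_at_rank(g.taxon_id, "species")
            if anc is not None:
                key = anc
        if key not in groups:
            order.append(key)
        groups.setdefault(key, []).append(g)

    merged_all: list[GenomeRecord] = []
    stats_all: list[CompressionStats] = []
    for key in order:
        group = groups[key]
        if len({g.taxon_id for g in group}) > 1:
            # same species, different strain taxa: compress under the species id
            group = [
                GenomeRecord(g.seq_id, key, g.sequence) for g in group
            ]
        merged, stats, _ = compress_species(group, **params)
        merged_all.extend(merged)
        stats_all.append(
            CompressionStats(key, stats.n_genomes, stats.original_bp, stats.compressed_bp)
        )
    return merged_all, stats_all


def verify_dropped_matches(
    genomes_by_id: Mapping[str, GenomeRecord],
    merged: Sequence[GenomeRecord],
    dropped: Iterable[IdentityMatch],
) -> list[float]:
    """Realign every dropped query interval to the retained sequence.

    Returns the recomputed identity of each dropped interval against the
    reference interval it was matched to; used to check the guarantee that
    discarded sequence is >= threshold identical to retained sequence.
    """
    merged_by_id = {g.seq_id: g for g in merged}
    identities = []
    for m in dropped:
        qseq = genomes_by_id[m.qry_id].sequence[m.qry_start : m.qry_end]
        rseq = merged_by_id[m.ref_id].sequence[m.ref_start : m.ref_end]
        qa = np.frombuffer(qseq.encode(), dtype=np.uint8)
        ra = np.frombuffer(rseq.encode(), dtype=np.uint8)
        identities.append(float(np.mean(qa == ra)))
    return identities
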