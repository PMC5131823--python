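# Methods

This note documents the models and procedures implemented in `minifuge`,
the parameters that matter, the numerical choices made where the design was
open, and the limits of what the synthetic-data tests demonstrate.

## Index structure

The database is the concatenation of all genome sequences with a `#`
separator after each sequence and a final `$` terminator. Symbols sort as
`$ < # < A < C < G < N < T`; separators never match a query base, so an
exact match can never span two sequences. The suffix array is built by
prefix doubling (numpy `lexsort` rounds, O(n log² n)) — chosen for
correctness and simplicity at the megabase scale this package targets, not
for construction speed. From it the BWT, a cumulative symbol-count table,
an occurrence table checkpointed every 128 symbols, and a stride-sampled
suffix array (default stride 16) are derived. Locate queries walk the LF
mapping to the nearest sample, so locate cost is bounded by the stride.
`N` bases are indexed as a fifth symbol but a query `N` matches nothing,
including a database `N`; consequently normalizing ambiguity codes to `N`
on input loses nothing for exact-match search.

## Read classification

Both the read and its reverse complement are segmented right to left: the
longest exact suffix match at the current position is found by backward
search, one base (the mismatch) is consumed, and the search resumes.
Segments equal the maximal exact matches ending at each resume position;
a run of mismatches degenerates to single-base steps.

* `min_seed = 16` bp: the shortest match for which a locate query is
  issued. Shorter matches still advance the cursor. A terminal fragment
  shorter than 16 bp at the read's 5' end is searched like any other
  segment; it cannot score anyway.
* `min_report = 22` bp: the shortest match allowed to contribute score.
  Only qualifying segments are summed into a taxon's score; sub-22-bp
  segments of a taxon that also has a qualifying segment are excluded (the
  alternative — admitting them once one long match exists — is a one-line
  change in `score_taxa` via `min_report`).
* Score per taxon: Σ (length − 15)² over qualifying segments, computed per
  strand; the taxon's score is the **maximum** over strands, not the sum,
  to avoid favoring palindromic sequence. 15 bp is approximately the match
  length expected by chance against a large database.
* `max_positions = 200`: a segment resolving to more sequences than this
  (low-complexity sequence) has its taxa set truncated after deduplication,
  bounding worst-case work per segment.
* Reported hit lengths (`best_hit_length`, `total_match_length`) refer to
  the winning strand only (ties go to the forward strand) and feed the
  report filters (e.g. "matching length ≥ 60 bp", "drop score ≤ 300 with
  match length ≤ 50 bp" style filters via `filter_report`, which keeps rows
  passing *both* thresholds).
* Reads shorter than `min_report` are reported unclassified, not an error.
* Paired reads: per-mate strand selection, then per-taxon scores summed
  over mates; everything else as for single reads.

Label reduction: if more than `cap` (default 5) taxa tie at the maximum
score, the group of labels sharing the ancestor (genus first, then
ascending ranks) that covers the most current labels is replaced by that
ancestor, recomputing after each replacement. Ties between equally large
groups break by larger summed member score, then smaller ancestor id.
Labels already above genus participate at their own level; `no_rank` nodes
are transparent. `cap = 1` returns the LCA directly — the generic walk is
confined to named ranks and could not land on an unranked LCA.

## Database compression

Same-species genomes are merged greedily. Similarity is measured on a
table of sampled k-mers (k = 53, sample rate 1%): sampled k-mers from all
genomes of the species are pooled, and each genome's exact membership in
the pool is recorded. Pooling is essential — two *independent* 1% position
samples of the same 100 kb genome share only ~10 positions, so comparing
per-genome samples directly would reduce pair selection to noise.

The most similar pair seeds the merged genome (the longer member is the
reference; ties break lexicographically). Near-identical regions between
the merged genome and each candidate are found by chaining shared exact
21-mers (`anchor_k`) lying on a common diagonal, with chains split when
consecutive anchor starts are more than `max_gap = 500` bp apart; each
chain's span is scored by column-wise identity. Candidate intervals
matched at ≥ 99% identity are discarded at sub-sequence granularity
(contigs are split); retained fragments shorter than `2 * anchor_k` are
dropped as unindexable slivers. The merged genome's k-mer set is the union
of its constituents' sets, so similarity recomputation never resamples.
Repetitive anchors (> 8 reference hits) are skipped.

Same-diagonal chaining handles substitution-level divergence, which is
what distinguishes sequenced strains in the simulator; it does not model
indels or rearrangements between genomes. External match lists (e.g. from
a whole-genome aligner) can be substituted for the internal finder at the
`merge_pair` level if that matters. Every dropped interval carries its
coordinates, so the losslessness-at-threshold guarantee — discarded
sequence realigns at ≥ threshold identity to retained sequence — is
directly checkable (`verify_dropped_matches`), and is checked in the tests.

An `--uncompressed` flag skips this stage entirely, preserving strain-level
sequence identity for strain-level classification.

## Abundance estimation

The model and EM update are described in the README. Two implementation
points deserve note:

* The E-step responsibilities are proportional to α_j·l_j, the same weights
  that appear in the likelihood. This makes the iteration a proper EM for
  that likelihood: the log-likelihood is non-decreasing every iteration
  (asserted in tests) and the fixed point is the maximizer (checked against
  a grid search for S = 2). An E-step weighting by α alone, with the
  length division deferred entirely to the M-step, has a different fixed
  point whenever ambiguous reads meet unequal genome lengths, and can
  decrease the likelihood.
* Genome lengths l_j are the average *pre-compression* lengths of the
  genomes of species j, so abundance estimates are not biased by how much
  sequence compression discarded. The CLI `compress` step emits this table
  for `build` to embed.

Reads labeled above species rank are redistributed as C_ij = 1 for every
database species below the labeled node; strain labels map to their
species. Reads whose labels touch no database species are dropped and
counted. Initialization is uniform; `max_iter = 1000` with a convergence
flag rather than an error. With fully ambiguous data the likelihood is
flat and EM correctly stays at its uniform start.

`unique_normalized_counts` provides the simpler heat-map statistic (unique
reads / genome length, rescaled to the column maximum), and
`aggregate_rank` sums α over rank ancestors (mass conserved; species with
no ancestor at the rank pool under `unassigned`).

## Simulator and what the tests show

Genomes are i.i.d. with a GC parameter; strains substitute each base
independently at the divergence rate (a strain family is a founder plus
n − 1 strains diverged *from the founder*, so strain–strain distance is
about twice the nominal divergence); reads pick a genome ∝ length (or by
explicit weights), uniform start and strand, and substitute bases i.i.d.
at the error rate — 3% by default, above Illumina error, standing in for
the mutational distance between sample organisms and their database
relatives. No indels, no quality-correlated errors, no coverage bias, no
chimeras. Evaluation counts a read as a prediction iff it has exactly one
label at or below the evaluation rank; sensitivity = correct / all reads,
precision = correct / predictions (1.0 with an explicit flag when there
are no predictions).

Consequences: passing tests demonstrate the algorithms' correctness and
their behavior under substitution noise, but say nothing about indel-rich
platforms, about databases of real genomes whose species boundaries blur
into each other, or about taxonomies with misplaced nodes. In particular,
sensitivity on simulated communities of unrelated random genomes
(≥ 0.97 species-level in our runs) is far above what real databases full
of near-identical species permit, where many reads are multi-labeled and
count as unclassified under the unique-read evaluation.

Problem sizes used by the test suite: search-oracle checks on 100 random
texts up to 10 kb against brute-force counting; compression on a 10-strain
family of 100 kb genomes at 0.5% divergence; community recovery on
10 species × 100 kb with 20,000 reads; abundance recovery on 5 species ×
50 kb with 4,000 reads at α = (0.40, 0.30, 0.15, 0.10, 0.05); strand
symmetry on 1,000 reads. These sizes exercise every code path at a scale
a laptop handles in seconds to a couple of minutes per test.

## Known limitations

* Suffix-array construction is in-memory and not linear-time; databases
  beyond a few tens of megabases will be slow to build.
* Exact-match-only extension: a single sequencing error always terminates
  a segment; there is no mismatch-tolerant extension.
* The anchor-chaining identity finder assumes collinear, indel-free
  similarity within a chain.
* No confidence intervals on abundance estimates; strain-level resolution
  exists only insofar as unique strain labels survive (uncompressed index).
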