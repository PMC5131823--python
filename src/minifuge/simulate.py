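"""Synthetic genomes, strain families, and error-bearing reads.

The simulator is the test harness for the whole system: it produces genome
databases with known taxonomy, reads with known origin, and the ground truth
needed to score classifications.  Reads follow a simple uniform model: the
source genome is chosen with probability proportional to its length (longer
genomes yield proportionally more reads), the start position and strand are
uniform, and each base is substituted independently at the given error rate
(3% by default, deliberately higher than Illumina error to emulate the
mutation load of real prokaryotic samples).  Indels are not modeled: the
classifier is exact-match based, and substitutions are the dominant effect
at these settings.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .classifier import ReadClassification, revcomp
from .io_formats import GenomeRecord, Read
from .taxonomy import TaxNode, TaxonomyTree

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
DEFAULT_READ_LENGTH = 100
DEFAULT_ERROR_RATE = 0.03


@dataclass(frozen=True)
class ReadTruth:
    """Ground truth for one simulated read."""

    seq_id: str
    taxon_id: int
    start: int
    strand: str  # "forward" or "revcomp"


#: read_id -> ReadTruth
SimulationTruth = dict[str, ReadTruth]


@dataclass(frozen=True)
class EvaluationResult:
    sensitivity: float
    precision: float
    n_reads: int
    n_predictions: int
    n_correct: int
    zero_predictions: bool


def _decode(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


def simulate_genome(
    length: int,
    gc: float = 0.5,
    seed: int = 0,
    seq_id: str = "sim",
    taxon_id: int = 0,
) -> GenomeRecord:
    """I.i.d. random genome with the given GC fraction."""
    if length < 1:
        raise ValueError("length must be >= 1")
    if not 0 <= gc <= 1:
        raise ValueError("gc must be in [0, 1]")
    rng = np.random.default_rng(seed)
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    arr = rng.choice(_BASES, size=length, p=probs)
    return GenomeRecord(seq_id=seq_id, taxon_id=taxon_id, sequence=_decode(arr))


def simulate_strain(
    parent: GenomeRecord,
    divergence: float,
    seed: int = 0,
    seq_id: str | None = None,
    taxon_id: int | None = None,
) -> GenomeRecord:
    """Derive a strain by independent per-base substitution.

    Each base mutates with probability ``divergence`` to one of the three
    other bases, uniformly.  The strain keeps the parent's taxon unless a
    new one is given.
    """
    if not 0 <= divergence < 1:
        raise ValueError("divergence must be in [0, 1)")
    rng = np.random.default_rng(seed)
    arr = np.frombuffer(parent.sequence.encode("ascii"), dtype=np.uint8).copy()
    base_index = np.full(256, -1, dtype=np.int8)
    for i, b in enumerate(_BASES):
        base_index[b] = i
    mask = (rng.random(arr.size) < divergence) & (base_index[arr] >= 0)
    idx = np.nonzero(mask)[0]
    shifts = rng.integers(1, 4, size=idx.size)
    arr[idx] = _BASES[(base_index[arr[idx]] + shifts) % 4]
    return GenomeRecord(
        seq_id=seq_id or f"{parent.seq_id}_mut",
        taxon_id=parent.taxon_id if taxon_id is None else taxon_id,
        sequence=_decode(arr),
    )


def simulate_strain_family(
    length: int,
    n_strains: int,
    divergence: float,
    seed: int = 0,
    gc: float = 0.5,
    taxon_id: int = 0,
    seq_prefix: str = "strain",
) -> list[GenomeRecord]:
    """A founder genome plus ``n_strains - 1`` strains diverged from it.

    All members share one species taxon; divergence is measured against the
    founder, so two derived strains are roughly twice as far from each other
    as from the founder.
    """
    if n_strains < 1:
        raise ValueError("n_strains must be >= 1")
    ss = np.random.SeedSequence(seed)
    seeds = [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(n_strains)]
    founder = simulate_genome(
        length, gc=gc, seed=seeds[0], seq_id=f"{seq_prefix}0", taxon_id=taxon_id
    )
    family = [founder]
    for i in range(1, n_strains):
        family.append(
            simulate_strain(
                founder, divergence, seed=seeds[i], seq_id=f"{seq_prefix}{i}"
            )
        )
    return family


def simulate_community(
    n_species: int,
    genome_length: int,
    seed: int = 0,
    gc: float = 0.5,
) -> tuple[list[GenomeRecord], dict[str, int], TaxonomyTree]:
    """Random community: one genome per species, each species its own genus.

    Taxonomy layout: root (1, no rank) -> superkingdom (2) -> one family
    (10) -> genus (100+i) -> species (1000+i).  Returns the genome records,
    the sequence-to-taxon map, and the tree.
    """
    if n_species < 1:
        raise ValueError("n_species must be >= 1")
    ss = np.random.SeedSequence(seed)
    seeds = [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(n_species)]
    nodes = [
        TaxNode(1, 1, "no_rank", "root"),
        TaxNode(2, 1, "superkingdom", "Bacteria"),
        TaxNode(10, 2, "family", "Simfamily"),
    ]
    records = []
    taxmap = {}
    for i in range(n_species):
        genus_id, species_id = 100 + i, 1000 + i
        nodes.append(TaxNode(genus_id, 10, "genus", f"Simgenus{i}"))
        nodes.append(TaxNode(species_id, genus_id, "species", f"Simspecies{i}"))
        rec = simulate_genome(
            genome_length, gc=gc, seed=seeds[i], seq_id=f"sp{i}", taxon_id=species_id
        )
        records.append(rec)
        taxmap[rec.seq_id] = species_id
    return records, taxmap, TaxonomyTree(nodes)


def _apply_errors(arr: np.ndarray, error_rate: float, rng: np.random.Generator) -> np.ndarray:
    if error_rate <= 0:
        return arr
    base_index = np.full(256, -1, dtype=np.int8)
    for i, b in enumerate(_BASES):
        base_index[b] = i
    mask = (rng.random(arr.size) < error_rate) & (base_index[arr] >= 0)
    idx = np.nonzero(mask)[0]
    shifts = rng.integers(1, 4, size=idx.size)
    out = arr.copy()
    out[idx] = _BASES[(base_index[arr[idx]] + shifts) % 4]
    return out


def simulate_reads(
    genomes: Sequence[GenomeRecord],
    n_reads: int,
    read_length: int = DEFAULT_READ_LENGTH,
    error_rate: float = DEFAULT_ERROR_RATE,
    seed: int = 0,
    paired: bool = False,
    fragment_length: int = 300,
    weights: Sequence[float] | None = None,
) -> tuple[list, SimulationTruth]:
    """Draw reads from a genome collection with substitution errors.

    The source genome is chosen with probability proportional to length
    (override with ``weights``), start positions and strands are uniform,
    and bases are substituted i.i.d. at ``error_rate``.  With ``paired``,
    each item of the returned list is a (mate1, mate2) tuple drawn from the
    two ends of a ``fragment_length`` fragment.
    """
    if n_reads <= 0:
        raise ValueError("n_reads must be positive")
    span = fragment_length if paired else read_length
    if paired and fragment_length < read_length:
        raise ValueError("fragment_length must be >= read_length")
    for g in genomes:
        if g.length < span:
            raise ValueError(f"genome {g.seq_id!r} shorter than {span} bp")
    rng = np.random.default_rng(seed)
    if weights is None:
        p = np.array([g.length for g in genomes], dtype=float)
    else:
        p = np.asarray(weights, dtype=float)
        if p.shape != (len(genomes),) or np.any(p < 0) or p.sum() <= 0:
            raise ValueError("weights must be nonnegative, one per genome")
    p = p / p.sum()

    arrs = [np.frombuffer(g.sequence.encode("ascii"), dtype=np.uint8) for g in genomes]
    choices = rng.choice(len(genomes), size=n_reads, p=p)
    reads: list = []
    truth: SimulationTruth = {}
    width = len(str(n_reads - 1))
    for i in range(n_reads):
        gi = int(choices[i])
        g = genomes[gi]
        start = int(rng.integers(0, g.length - span + 1))
        strand = "forward" if rng.random() < 0.5 else "revcomp"
        read_id = f"r{i:0{width}d}"
        if not paired:
            frag = arrs[gi][start : start + read_length]
            seq = _decode(_apply_errors(frag, error_rate, rng))
            if strand == "revcomp":
                seq = revcomp(seq)
            reads.append(Read(read_id=read_id, sequence=seq))
        else:
            frag = arrs[gi][start : start + fragment_length]
            if strand == "revcomp":
                frag = np.frombuffer(
                    revcomp(_decode(frag)).encode("ascii"), dtype=np.uint8
                )
            m1 = _decode(_apply_errors(frag[:read_length], error_rate, rng))
            m2 = revcomp(_decode(_apply_errors(frag[-read_length:], error_rate, rng)))
            reads.append(
                (
                    Read(read_id=read_id, sequence=m1),
                    Read(read_id=read_id, sequence=m2),
                )
            )
        truth[read_id] = ReadTruth(
            seq_id=g.seq_id, taxon_id=g.taxon_id, start=start, strand=strand
        )
    return reads, truth


def evaluate(
    results: Sequence[ReadClassification],
    truth: Mapping[str, ReadTruth],
    tree: TaxonomyTree,
    rank: str = "species",
) -> EvaluationResult:
    """Sensitivity and precision of uniquely classified reads at a rank.

    A read counts as a prediction iff it carries exactly one label and that
    label sits at the given rank or below it.  The prediction is correct iff
    the label's rank ancestor equals the truth taxon's rank ancestor.
    Sensitivity = correct / all reads; precision = correct / predictions
    (reported as 1.0 with a flag when no predictions were made).
    """
    n_reads = len(results)
    n_predictions = 0
    n_correct = 0
    for res in results:
        if len(res.labels) != 1:
            continue
        label = res.labels[0]
        if label not in tree:
            continue
        predicted = tree.ancestor_at_rank(label, rank)
        if predicted is None:
            continue  # label above the evaluation rank: not a prediction
        n_predictions += 1
        true_taxon = truth[res.read_id].taxon_id
        expected = tree.ancestor_at_rank(true_taxon, rank) if true_taxon in tree else None
        if expected is not None and predicted == expected:
            n_correct += 1
    sensitivity = n_correct / n_reads if n_reads else 0.0
    zero = n_predictions == 0
    precision = 1.0 if zero else n_correct / n_predictions
    return EvaluationResult(
        sensitivity=sensitivity,
        precision=precision,
        n_reads=n_reads,
        n_predictions=n_predictions,
        n_correct=n_correct,
        zero_predictions=zero,
    )
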