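"""A constructed database realizing the canonical segmentation example.

A 100-bp read is planted into an eight-species toy database so that its
greedy right-to-left segmentation is fully determined:

* forward strand: a 40-bp suffix shared by six species (A-F), a mismatch, a
  26-bp segment shared by two species (G, H), a mismatch, and a 32-bp prefix
  unique to species G;
* reverse complement: segments of 17, 16, 28, 18, and 17 bases, of which
  only the 28-bp segment clears the 22-bp reporting threshold (it belongs
  to species H, which therefore has matches on both strands).

With the squared-length scoring rule the six tied species score
(40-15)^2 = 625, species G scores 121 + 289 = 410, and species H scores
max(121, 169) = 169.  Species A, B, C share genus I; D and E share genus J;
F sits alone in genus K; all three genera belong to one family, so label
reduction with a cap of five yields {genus I, D, E, F} and a cap of one
yields the family.

Construction is randomized but self-verifying: every planted segment is
checked to occur exactly the intended number of times with a mismatching
base in front of it, and the build retries with a fresh substream until the
check passes, so any seed yields a valid instance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .classifier import revcomp
from .io_formats import GenomeRecord
from .taxonomy import TaxNode, TaxonomyTree

# taxon ids of the toy taxonomy
ROOT, KINGDOM = 1, 2
FAMILY_ABCDEF, FAMILY_GH = 10, 11
GENUS_I, GENUS_J, GENUS_K, GENUS_M = 20, 21, 22, 23
SPECIES = {name: 101 + i for i, name in enumerate("ABCDEFGH")}

#: (start, end) of the forward-strand segments on the read, right to left
FORWARD_SEGMENTS = [(60, 100), (33, 59), (0, 32)]
#: (start, end) of the reverse-complement segments, right to left
REVCOMP_SEGMENTS = [(83, 100), (66, 82), (37, 65), (18, 36), (0, 17)]


@dataclass(frozen=True)
class WorkedExample:
    records: list[GenomeRecord]
    taxmap: dict[str, int]
    tree: TaxonomyTree
    read: str
    read_id: str


def _toy_tree() -> TaxonomyTree:
    nodes = [
        TaxNode(ROOT, ROOT, "no_rank", "root"),
        TaxNode(KINGDOM, ROOT, "superkingdom", "Bacteria"),
        TaxNode(FAMILY_ABCDEF, KINGDOM, "family", "Family-IJK"),
        TaxNode(FAMILY_GH, KINGDOM, "family", "Family-M"),
        TaxNode(GENUS_I, FAMILY_ABCDEF, "genus", "Genus I"),
        TaxNode(GENUS_J, FAMILY_ABCDEF, "genus", "Genus J"),
        TaxNode(GENUS_K, FAMILY_ABCDEF, "genus", "Genus K"),
        TaxNode(GENUS_M, FAMILY_GH, "genus", "Genus M"),
    ]
    genus_of = {
        "A": GENUS_I, "B": GENUS_I, "C": GENUS_I,
        "D": GENUS_J, "E": GENUS_J, "F": GENUS_K,
        "G": GENUS_M, "H": GENUS_M,
    }
    for name, taxid in SPECIES.items():
        nodes.append(TaxNode(taxid, genus_of[name], "species", f"Species {name}"))
    return TaxonomyTree(nodes)


def _rand_dna(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[c] for c in rng.integers(0, 4, size=n))


def _other_base(rng: np.random.Generator, base: str) -> str:
    choices = [b for b in "ACGT" if b != base]
    return choices[int(rng.integers(0, 3))]


def _try_build(rng: np.random.Generator) -> WorkedExample | None:
    read = _rand_dna(rng, 100)
    rc = revcomp(read)

    f1 = read[60:100]  # 40 bp -> species A-F
    f2 = read[33:59]   # 26 bp -> species G, H
    f3 = read[0:32]    # 32 bp -> species G only
    g1 = rc[83:100]    # 17 bp
    g2 = rc[66:82]     # 16 bp
    g3 = rc[37:65]     # 28 bp -> species H
    g4 = rc[18:36]     # 18 bp
    g5 = rc[0:17]      # 17 bp

    def block(segment: str, stop_base: str | None) -> str:
        guard = (
            _other_base(rng, stop_base) if stop_base is not None else _rand_dna(rng, 1)
        )
        return _rand_dna(rng, 150) + guard + segment

    genomes: dict[str, str] = {}
    for name in "ABCDEF":
        genomes[name] = block(f1, read[59]) + _rand_dna(rng, 150)
    genomes["G"] = block(f2, read[32]) + block(f3, None) + _rand_dna(rng, 150)
    genomes["H"] = (
        block(f2, read[32])
        + block(g3, rc[36])
        + block(g1, rc[82])
        + block(g2, rc[65])
        + block(g4, rc[17])
        + block(g5, None)
        + _rand_dna(rng, 150)
    )

    # self-check: each planted pattern occurs exactly as intended, and the
    # one-base extension of each segment occurs nowhere in the database
    all_text = "#".join(genomes.values())

    def occurrences(pattern: str) -> int:
        count = 0
        pos = all_text.find(pattern)
        while pos != -1:
            count += 1
            pos = all_text.find(pattern, pos + 1)
        return count

    expected = [
        (f1, 6, read[59]),
        (f2, 2, read[32]),
        (f3, 1, None),
        (g3, 1, rc[36]),
        (g1, 1, rc[82]),
        (g2, 1, rc[65]),
        (g4, 1, rc[17]),
        (g5, 1, None),
    ]
    for segment, n_expected, stop_base in expected:
        if occurrences(segment) != n_expected:
            return None
        if stop_base is not None and occurrences(stop_base + segment) != 0:
            return None

    records = [
        GenomeRecord(seq_id=f"gnm{name}", taxon_id=SPECIES[name], sequence=seq)
        for name, seq in genomes.items()
    ]
    taxmap = {rec.seq_id: rec.taxon_id for rec in records}
    return WorkedExample(
        records=records,
        taxmap=taxmap,
        tree=_toy_tree(),
        read=read,
        read_id="example-read",
    )


def build_worked_example(seed: int = 0) -> WorkedExample:
    """Build a verified instance of the toy database (any seed works)."""
    root = np.random.SeedSequence(seed & 0x7FFFFFFF)
    for child in root.spawn(50):
        example = _try_build(np.random.default_rng(child))
        if example is not None:
            return example
    raise RuntimeError("could not construct a collision-free toy database")
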