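import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from minifuge import FmIndex, GenomeRecord, TaxNode, TaxonomyTree

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[c] for c in rng.integers(0, 4, size=n))


def naive_count(text: str, pattern: str) -> int:
    """Overlapping substring occurrence count (brute-force oracle)."""
    if not pattern:
        return len(text) + 1
    count = 0
    pos = text.find(pattern)
    while pos != -1:
        count += 1
        pos = text.find(pattern, pos + 1)
    return count


@pytest.fixture(scope="session")
def small_tree() -> TaxonomyTree:
    """root -> superkingdom -> family(10) -> genera(20, 21) -> species/strains."""
    return TaxonomyTree(
        [
            TaxNode(1, 1, "no_rank", "root"),
            TaxNode(2, 1, "superkingdom", "Bacteria"),
            TaxNode(10, 2, "family", "Fam"),
            TaxNode(20, 10, "genus", "GenA"),
            TaxNode(21, 10, "genus", "GenB"),
            TaxNode(101, 20, "species", "SpA1"),
            TaxNode(102, 20, "species", "SpA2"),
            TaxNode(103, 21, "species", "SpB1"),
            TaxNode(1001, 101, "strain", "SpA1-s1"),
            TaxNode(1002, 101, "strain", "SpA1-s2"),
        ]
    )


@pytest.fixture(scope="session")
def tiny_db():
    """Three unrelated 2-kb genomes with an index, map, and tree."""
    rng = np.random.default_rng(42)
    records = [
        GenomeRecord("g1", 101, random_dna(rng, 2000)),
        GenomeRecord("g2", 102, random_dna(rng, 2000)),
        GenomeRecord("g3", 103, random_dna(rng, 2000)),
    ]
    index = FmIndex.build(records)
    taxmap = {r.seq_id: r.taxon_id for r in records}
    return records, index, taxmap
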