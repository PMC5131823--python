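"""Single-file reference database: FM-index + taxon map + taxonomy + lengths.

The bundle is what the command-line ``build`` step produces and the
``classify``/``report`` steps consume.  Species genome lengths are stored at
build time (pass pre-compression lengths when the input FASTA was
compressed, so abundance estimation is not biased by discarded sequence).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .classifier import Classifier
from .fmindex import FORMAT_VERSION, FmIndex
from .io_formats import GenomeRecord
from .taxonomy import TaxNode, TaxonomyTree


def species_lengths(
    records: Sequence[GenomeRecord], tree: TaxonomyTree | None = None
) -> dict[int, float]:
    """Average genome length per species taxon.

    Each record contributes its length to its species-rank ancestor (or its
    own taxon when no taxonomy or no species ancestor is available); the
    species value is the mean over its genomes.
    """
    sums: dict[int, float] = {}
    counts: dict[int, int] = {}
    for rec in records:
        key = rec.taxon_id
        if tree is not None and rec.taxon_id in tree:
            anc = tree.ancestor_at_rank(rec.taxon_id, "species")
            if anc is not None:
                key = anc
        sums[key] = sums.get(key, 0.0) + rec.length
        counts[key] = counts.get(key, 0) + 1
    return {k: sums[k] / counts[k] for k in sums}


class ReferenceDB:
    """An FM-index bound to its taxon map, taxonomy tree, and genome lengths."""

    def __init__(
        self,
        index: FmIndex,
        taxmap: Mapping[str, int],
        tree: TaxonomyTree,
        lengths: Mapping[int, float],
    ):
        self.index = index
        self.taxmap = dict(taxmap)
        self.tree = tree
        self.lengths = {int(k): float(v) for k, v in lengths.items()}

    @classmethod
    def build(
        cls,
        records: Sequence[GenomeRecord],
        tree: TaxonomyTree,
        sa_stride: int = 16,
        lengths: Mapping[int, float] | None = None,
    ) -> "ReferenceDB":
        index = FmIndex.build(records, sa_stride=sa_stride)
        taxmap = {r.seq_id: r.taxon_id for r in records}
        if lengths is None:
            lengths = species_lengths(records, tree)
        return cls(index, taxmap, tree, lengths)

    def classifier(self, **params) -> Classifier:
        return Classifier(self.index, self.taxmap, self.tree, **params)

    def save(self, path: str | Path) -> None:
        idx = self.index
        nodes = [
            [n.taxon_id, n.parent_id, n.rank, n.name] for n in self.tree.nodes()
        ]
        meta = json.dumps(
            {
                "version": FORMAT_VERSION,
                "sa_stride": idx.sa_stride,
                "seq_ids": idx.seq_ids,
                "taxmap": self.taxmap,
                "nodes": nodes,
                "lengths": {str(k): v for k, v in self.lengths.items()},
            }
        )
        with open(path, "wb") as fh:
            np.savez(
                fh,
                meta=np.array(meta),
                bwt=idx.bwt,
                counts=idx.counts,
                occ=idx._occ,
                samples=idx._samples,
                starts=idx._starts,
                lengths=idx._lengths,
            )

    @classmethod
    def load(cls, path: str | Path) -> "ReferenceDB":
        with np.load(path, allow_pickle=False) as data:
            meta = json.loads(str(data["meta"]))
            if meta.get("version") != FORMAT_VERSION:
                raise ValueError(f"unsupported database version {meta.get('version')}")
            index = FmIndex(
                data["bwt"],
                data["counts"],
                data["occ"],
                data["samples"],
                meta["sa_stride"],
                meta["seq_ids"],
                data["starts"],
                data["lengths"],
            )
        tree = TaxonomyTree(
            TaxNode(int(t), int(p), rank, name) for t, p, rank, name in meta["nodes"]
        )
        lengths = {int(k): float(v) for k, v in meta["lengths"].items()}
        return cls(index, meta["taxmap"], tree, lengths)
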