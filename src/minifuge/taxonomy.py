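"""Rank-labeled taxonomic tree with LCA, rank-ancestor, and label-reduction queries.

The tree is a parent-pointer structure in the style of the NCBI taxonomy:
every node carries a parent id and a rank name, the root points to itself,
and ``no_rank`` nodes are allowed anywhere.  Three queries matter for
classification:

* :meth:`TaxonomyTree.lca` — the deepest node ancestral to a set of taxa,
  used when a single label per read is requested.
* :meth:`TaxonomyTree.ancestor_at_rank` — nearest ancestor-or-self at a named
  rank, used for rank-level evaluation and abundance aggregation.
* :meth:`TaxonomyTree.reduce_labels` — collapse a set of tied labels into at
  most ``cap`` labels by repeatedly replacing the group of labels sharing the
  lowest-rank ancestor that covers the most labels (genus groups first, then
  ascending ranks) with that single ancestor.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping

#: Named ranks in ascending order.  ``no_rank`` nodes are transparent: they
#: never host a grouping level and are skipped when walking to the "next
#: higher taxonomic unit".
RANKS = (
    "strain",
    "species",
    "genus",
    "family",
    "order",
    "class",
    "phylum",
    "superkingdom",
)

NO_RANK = "no_rank"

VALID_RANKS = frozenset(RANKS) | {NO_RANK}


@dataclass(frozen=True)
class TaxNode:
    """One taxonomy node: integer id, parent pointer, rank, display name."""

    taxon_id: int
    parent_id: int
    rank: str = NO_RANK
    name: str = ""

    @property
    def is_root(self) -> bool:
        return self.taxon_id == self.parent_id


class TaxonomyTree:
    """Parent-pointer taxonomy supporting LCA and rank queries.

    Parameters
    ----------
    nodes:
        Iterable of :class:`TaxNode`.  Exactly one node must be its own
        parent (the root); every other node's parent must be present, and
        parent chains must be acyclic.
    """

    def __init__(self, nodes: Iterable[TaxNode]):
        self._nodes: dict[int, TaxNode] = {}
        for node in nodes:
            if node.taxon_id in self._nodes:
                raise ValueError(f"duplicate taxon id {node.taxon_id}")
            self._nodes[node.taxon_id] = node
        if not self._nodes:
            raise ValueError("taxonomy has no nodes")

        roots = [n.taxon_id for n in self._nodes.values() if n.is_root]
        if len(roots) != 1:
            raise ValueError(f"taxonomy must have exactly one root, found {len(roots)}")
        self.root_id: int = roots[0]

        self._children: dict[int, list[int]] = {t: [] for t in self._nodes}
        for node in self._nodes.values():
            if node.parent_id not in self._nodes:
                raise ValueError(
                    f"orphan node {node.taxon_id}: parent {node.parent_id} undefined"
                )
            if not node.is_root:
                self._children[node.parent_id].append(node.taxon_id)
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        state: dict[int, int] = {}  # 0 in progress, 1 done
        for start in self._nodes:
            chain = []
            t = start
            while t not in state:
                state[t] = 0
                chain.append(t)
                node = self._nodes[t]
                if node.is_root:
                    break
                t = node.parent_id
            if state.get(t) == 0 and not self._nodes[t].is_root:
                raise ValueError(f"cycle in taxonomy involving node {t}")
            for c in chain:
                state[c] = 1

    # -- basic accessors ---------------------------------------------------
    def __contains__(self, taxon_id: int) -> bool:
        return taxon_id in self._nodes

    def __len__(self) -> int:
        return len(self._nodes)

    def __iter__(self) -> Iterator[int]:
        return iter(self._nodes)

    def node(self, taxon_id: int) -> TaxNode:
        try:
            return self._nodes[taxon_id]
        except KeyError:
            raise KeyError(f"unknown taxon {taxon_id}") from None

    def nodes(self) -> Iterator[TaxNode]:
        return iter(self._nodes.values())

    def parent(self, taxon_id: int) -> int:
        return self.node(taxon_id).parent_id

    def rank(self, taxon_id: int) -> str:
        return self.node(taxon_id).rank

    def name(self, taxon_id: int) -> str:
        return self.node(taxon_id).name

    def children(self, taxon_id: int) -> list[int]:
        self.node(taxon_id)
        return list(self._children[taxon_id])

    def path_to_root(self, taxon_id: int) -> list[int]:
        """Node ids from ``taxon_id`` (inclusive) up to and including the root."""
        path = [taxon_id]
        node = self.node(taxon_id)
        while not node.is_root:
            node = self.node(node.parent_id)
            path.append(node.taxon_id)
        return path

    def descendants(self, taxon_id: int) -> Iterator[int]:
        """All strict descendants of ``taxon_id`` (preorder)."""
        stack = list(self._children[self.node(taxon_id).taxon_id])
        while stack:
            t = stack.pop()
            yield t
            stack.extend(self._children[t])

    def species_under(self, taxon_id: int) -> set[int]:
        """Species-rank nodes at or below ``taxon_id``."""
        if self.rank(taxon_id) == "species":
            return {taxon_id}
        return {t for t in self.descendants(taxon_id) if self.rank(t) == "species"}

    # -- queries -----------------------------------------------------------
    def lca(self, taxa: Iterable[int]) -> int:
        """Lowest common ancestor of a nonempty set of taxa."""
        taxa = list(taxa)
        if not taxa:
            raise ValueError("lca of an empty taxon set is undefined")
        path = self.path_to_root(taxa[0])
        common = set(path)
        for t in taxa[1:]:
            anc = t
            self.node(anc)
            while anc not in common:
                anc = self.parent(anc)
            # trim everything below anc from the common path
            idx = path.index(anc)
            path = path[idx:]
            common = set(path)
        return path[0]

    def ancestor_at_rank(self, taxon_id: int, rank: str) -> int | None:
        """Nearest ancestor-or-self with the given rank, or ``None``."""
        if rank not in RANKS:
            raise ValueError(f"unknown rank {rank!r}")
        node = self.node(taxon_id)
        while True:
            if node.rank == rank:
                return node.taxon_id
            if node.is_root:
                return None
            node = self.node(node.parent_id)

    def reduce_labels(
        self,
        taxa: Iterable[int],
        cap: int,
        scores: Mapping[int, float] | None = None,
    ) -> set[int]:
        """Collapse a label set to at most ``cap`` labels by ancestor grouping.

        Starting from the lowest named rank and ascending, labels sharing an
        ancestor at the current rank are grouped; the group covering the most
        labels is replaced by that single ancestor, and grouping is recomputed
        against the updated label set.  Ties between equally large groups are
        broken by the larger summed member score, then by the smaller ancestor
        id.  ``cap == 1`` degenerates to the LCA of the input set.
        """
        labels = set(taxa)
        if not labels:
            raise ValueError("cannot reduce an empty label set")
        if cap < 1:
            raise ValueError("cap must be >= 1")
        for t in labels:
            self.node(t)
        if cap == 1:
            return {self.lca(labels)}
        if len(labels) <= cap:
            return labels

        def group_score(members: list[int]) -> float:
            if scores is None:
                return 0.0
            return float(sum(scores.get(m, 0.0) for m in members))

        for rank in RANKS:
            while len(labels) > cap:
                groups: dict[int, list[int]] = {}
                for t in labels:
                    anc = self.ancestor_at_rank(t, rank)
                    if anc is not None:
                        groups.setdefault(anc, []).append(t)
                candidates = [
                    (len(members), group_score(members), -anc, anc, members)
                    for anc, members in groups.items()
                    if len(members) >= 2
                ]
                if not candidates:
                    break
                _, _, _, anc, members = max(candidates, key=lambda c: c[:3])
                labels.difference_update(members)
                labels.add(anc)
            if len(labels) <= cap:
                return labels
        # Mixed-superkingdom (or rank-free) leftovers: collapse to the LCA.
        return {self.lca(labels)}


def lca(tree: TaxonomyTree, taxa: Iterable[int]) -> int:
    return tree.lca(taxa)


def ancestor_at_rank(tree: TaxonomyTree, taxon_id: int, rank: str) -> int | None:
    return tree.ancestor_at_rank(taxon_id, rank)


def reduce_labels(
    tree: TaxonomyTree,
    taxa: Iterable[int],
    cap: int,
    scores: Mapping[int, float] | None = None,
) -> set[int]:
    return tree.reduce_labels(taxa, cap, scores)
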