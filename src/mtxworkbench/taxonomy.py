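"""Rank-annotated taxonomy tree: LCA queries, ascent, genus aggregation support.

The tree is small (tens of nodes in the toy references) but the classifier
touches it for millions of k-mers, so :meth:`TaxonomyTree.linearize` exposes a
dense integer view (parent indices, depths, ancestor matrix) that the
vectorized classification code consumes.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ParameterError

RANKS = ("root", "domain", "phylum", "genus", "species")
_RANK_LEVEL = {r: i for i, r in enumerate(RANKS)}


@dataclass(frozen=True)
class TaxonNode:
    taxon_id: str
    parent_id: Optional[str]
    rank: str
    name: str

    def __post_init__(self):
        if self.rank not in _RANK_LEVEL:
            raise ParameterError(f"unknown rank {self.rank!r}")
        if (self.parent_id is None) != (self.rank == "root"):
            raise ParameterError("exactly the root node may lack a parent")


@dataclass(frozen=True)
class Linearized:
    """Dense integer view of the tree for vectorized classification."""

    ids: tuple[str, ...]            # position -> taxon_id
    index: dict                     # taxon_id -> position
    parent: np.ndarray              # int32, parent position (root points to itself)
    depth: np.ndarray               # int32, root = 0
    ancestor: np.ndarray            # bool (n, n): ancestor[a, d] = a is ancestor-or-self of d


class TaxonomyTree:
    """Rooted tree over :class:`TaxonNode` with strict rank ordering."""

    def __init__(self, nodes: Iterable[TaxonNode]):
        nodes = list(nodes)
        self.index: dict[str, TaxonNode] = {}
        for n in nodes:
            if n.taxon_id in self.index:
                raise ParameterError(f"duplicate taxon_id {n.taxon_id!r}")
            self.index[n.taxon_id] = n
        roots = [n for n in nodes if n.parent_id is None]
        if len(roots) != 1:
            raise ParameterError(f"expected exactly one root, found {len(roots)}")
        self.root = roots[0]
        self._children: dict[str, list[str]] = {n.taxon_id: [] for n in nodes}
        for n in nodes:
            if n.parent_id is None:
                continue
            parent = self.index.get(n.parent_id)
            if parent is None:
                raise ParameterError(f"{n.taxon_id}: parent {n.parent_id!r} not in tree")
            if _RANK_LEVEL[parent.rank] >= _RANK_LEVEL[n.rank]:
                raise ParameterError(
                    f"{n.taxon_id}: rank {n.rank} not below parent rank {parent.rank}"
                )
            self._children[n.parent_id].append(n.taxon_id)
        for n in nodes:  # acyclicity + reachability
            self.ancestors(n.taxon_id)
        for n in nodes:
            if n.rank == "species" and self._children[n.taxon_id]:
                raise ParameterError(f"species {n.taxon_id} must be a leaf")

    def __len__(self) -> int:
        return len(self.index)

    def __contains__(self, taxon_id: str) -> bool:
        return taxon_id in self.index

    def node(self, taxon_id: str) -> TaxonNode:
        return self.index[taxon_id]

    def children(self, taxon_id: str) -> list[str]:
        return list(self._children[taxon_id])

    def ancestors(self, taxon_id: str) -> list[str]:
        """Taxon ids from the node itself up to and including the root."""
        chain = [taxon_id]
        seen = {taxon_id}
        node = self.index[taxon_id]
        while node.parent_id is not None:
            if node.parent_id in seen:
                raise ParameterError(f"cycle through {node.parent_id!r}")
            chain.append(node.parent_id)
            seen.add(node.parent_id)
            node = self.index[node.parent_id]
        return chain

    def depth(self, taxon_id: str) -> int:
        return len(self.ancestors(taxon_id)) - 1

    def lca(self, a: str, b: str) -> str:
        """Lowest common ancestor; lca(a, a) == a."""
        anc_a = self.ancestors(a)
        anc_b = set(self.ancestors(b))
        for t in anc_a:
            if t in anc_b:
                return t
        raise ParameterError("nodes share no ancestor")  # unreachable in a tree

    def lca_many(self, taxa: Sequence[str]) -> str:
        out = taxa[0]
        for t in taxa[1:]:
            out = self.lca(out, t)
        return out

    def subtree(self, taxon_id: str) -> list[str]:
        """All taxa in the clade rooted at ``taxon_id`` (inclusive, preorder)."""
        out, stack = [], [taxon_id]
        while stack:
            t = stack.pop()
            out.append(t)
            stack.extend(reversed(self._children[t]))
        return out

    def subtree_species(self, taxon_id: str) -> list[str]:
        return [t for t in self.subtree(taxon_id) if self.index[t].rank == "species"]

    def species_ids(self) -> list[str]:
        return [t for t, n in self.index.items() if n.rank == "species"]

    def ancestor_at_rank(self, taxon_id: str, rank: str) -> Optional[str]:
        for t in self.ancestors(taxon_id):
            if self.index[t].rank == rank:
                return t
        return None

    def genus_of(self, species_id: str) -> str:
        g = self.ancestor_at_rank(species_id, "genus")
        if g is None:
            raise ParameterError(f"species {species_id} has no genus ancestor")
        return g

    @functools.cache
    def linearize(self) -> Linearized:
        ids = tuple(sorted(self.index))
        pos = {t: i for i, t in enumerate(ids)}
        n = len(ids)
        parent = np.empty(n, dtype=np.int32)
        depth = np.empty(n, dtype=np.int32)
        anc = np.zeros((n, n), dtype=bool)
        for t, i in pos.items():
            chain = self.ancestors(t)
            depth[i] = len(chain) - 1
            parent[i] = pos[chain[1]] if len(chain) > 1 else i
            for a in chain:
                anc[pos[a], i] = True
        return Linearized(ids=ids, index=pos, parent=parent, depth=depth, ancestor=anc)

    # -- TSV round trip (taxon_id, parent_id, rank, name) ---------------------

    def to_tsv(self, path) -> None:
        rows = [
            (n.taxon_id, n.parent_id if n.parent_id is not None else "", n.rank, n.name)
            for n in self.index.values()
        ]
        pd.DataFrame(rows, columns=["taxon_id", "parent_id", "rank", "name"]).to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def from_tsv(cls, path) -> "TaxonomyTree":
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        nodes = [
            TaxonNode(r.taxon_id, r.parent_id or None, r.rank, r.name)
            for r in df.itertuples()
        ]
        return cls(nodes)
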