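"""Four-rank taxonomy (root / phylum / genus / species) with LCA queries.

The classifier and the signature builder both operate on this tree: k-mers
shared by several genomes are mapped to the lowest common ancestor of their
species, and contig-level calls are lifted to the genus or species rank when
signature pairs are assembled.
"""

from __future__ import annotations

from dataclasses import dataclass

RANKS = ("root", "phylum", "genus", "species")
RANK_DEPTH = {r: i for i, r in enumerate(RANKS)}


@dataclass(frozen=True)
class TaxonNode:
    taxon_id: str
    name: str
    rank: str
    parent: str | None  # None only for the root


class TaxonomyTree:
    """Immutable rooted tree over :class:`TaxonNode` records."""

    def __init__(self, nodes: list[TaxonNode]):
        self._nodes: dict[str, TaxonNode] = {}
        roots = []
        for node in nodes:
            if node.rank not in RANK_DEPTH:
                raise ValueError(f"unknown rank {node.rank!r} for {node.taxon_id}")
            if node.taxon_id in self._nodes:
                raise ValueError(f"duplicate taxon_id {node.taxon_id!r}")
            self._nodes[node.taxon_id] = node
            if node.parent is None:
                roots.append(node.taxon_id)
        if len(roots) != 1:
            raise ValueError(f"expected exactly one root, found {len(roots)}")
        self.root = roots[0]
        self._children: dict[str, list[str]] = {tid: [] for tid in self._nodes}
        for node in nodes:
            if node.parent is not None:
                if node.parent not in self._nodes:
                    raise ValueError(f"parent {node.parent!r} of {node.taxon_id!r} missing")
                parent = self._nodes[node.parent]
                if RANK_DEPTH[parent.rank] >= RANK_DEPTH[node.rank]:
                    raise ValueError(
                        f"parent rank {parent.rank} not above child rank {node.rank}"
                        f" ({node.taxon_id})"
                    )
                self._children[node.parent].append(node.taxon_id)
        # cache root-to-node paths: LCA and ancestor queries dominate classify()
        self._path: dict[str, tuple[str, ...]] = {}
        for tid in self._nodes:
            chain = []
            cur: str | None = tid
            while cur is not None:
                chain.append(cur)
                cur = self._nodes[cur].parent
            self._path[tid] = tuple(reversed(chain))

    def __contains__(self, taxon_id: str) -> bool:
        return taxon_id in self._nodes

    def __len__(self) -> int:
        return len(self._nodes)

    def node(self, taxon_id: str) -> TaxonNode:
        return self._nodes[taxon_id]

    def rank(self, taxon_id: str) -> str:
        return self._nodes[taxon_id].rank

    def children(self, taxon_id: str) -> list[str]:
        return list(self._children[taxon_id])

    def ancestors(self, taxon_id: str) -> tuple[str, ...]:
        """Root-to-node path, inclusive of both ends."""
        return self._path[taxon_id]

    def ancestor_at(self, taxon_id: str, rank: str) -> str | None:
        """The ancestor of ``taxon_id`` at ``rank``, or None if the node is above it."""
        if rank not in RANK_DEPTH:
            raise ValueError(f"unknown rank {rank!r}")
        for tid in self._path[taxon_id]:
            if self._nodes[tid].rank == rank:
                return tid
        return None

    def lca(self, taxon_ids) -> str:
        ids = list(taxon_ids)
        if not ids:
            raise ValueError("lca of empty set")
        common = self._path[ids[0]]
        for tid in ids[1:]:
            other = self._path[tid]
            n = 0
            for a, b in zip(common, other):
                if a != b:
                    break
                n += 1
            common = common[:n]
        return common[-1]

    def subtree(self, taxon_id: str) -> list[str]:
        out = [taxon_id]
        stack = list(self._children[taxon_id])
        while stack:
            tid = stack.pop()
            out.append(tid)
            stack.extend(self._children[tid])
        return out

    def species_under(self, taxon_id: str) -> list[str]:
        return sorted(t for t in self.subtree(taxon_id) if self._nodes[t].rank == "species")

    def all_at_rank(self, rank: str) -> list[str]:
        return sorted(t for t, n in self._nodes.items() if n.rank == rank)

    @classmethod
    def from_lineages(
        cls,
        species_to_genus: dict[str, str],
        genus_to_phylum: dict[str, str] | None = None,
        root_id: str = "root",
    ) -> "TaxonomyTree":
        """Build a tree from species→genus (and optional genus→phylum) maps.

        Genera with no phylum entry are attached to a single default phylum.
        """
        genus_to_phylum = dict(genus_to_phylum or {})
        nodes = [TaxonNode(root_id, root_id, "root", None)]
        phyla = {}
        for genus in sorted(set(species_to_genus.values())):
            phylum = genus_to_phylum.get(genus, "p__default")
            if phylum not in phyla:
                phyla[phylum] = True
                nodes.append(TaxonNode(phylum, phylum, "phylum", root_id))
            nodes.append(TaxonNode(genus, genus, "genus", phylum))
        for species in sorted(species_to_genus):
            nodes.append(TaxonNode(species, species, "species", species_to_genus[species]))
        return cls(nodes)

    def to_records(self) -> list[dict]:
        return [
            {"taxon_id": n.taxon_id, "name": n.name, "rank": n.rank,
             "parent": "" if n.parent is None else n.parent}
            for n in self._nodes.values()
        ]

    @classmethod
    def from_records(cls, records) -> "TaxonomyTree":
        nodes = [
            TaxonNode(r["taxon_id"], r["name"], r["rank"], r["parent"] or None)
            for r in records
        ]
        return cls(nodes)
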