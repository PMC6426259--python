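"""Six-rank bacterial taxonomy scaffold (phylum .. species).

The study screens 168 taxa spread over six nested ranks (6 phyla, 12 classes,
17 orders, 36 families, 63 genera, 34 species); this module generates a random
but reproducible hierarchy with those counts so abundance tables with the same
nesting structure can be simulated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

RANKS = ("phylum", "class", "order", "family", "genus", "species")
RANK_PREFIX = {"phylum": "p", "class": "c", "order": "o",
               "family": "f", "genus": "g", "species": "s"}
DEFAULT_LEVEL_COUNTS = (6, 12, 17, 36, 63, 34)


@dataclass(frozen=True)
class TaxonNode:
    taxon_id: str
    rank: str
    parent: Optional[str]
    name: str


class Taxonomy:
    """Rooted six-rank hierarchy: every non-phylum node has exactly one parent
    of the immediately higher rank."""

    def __init__(self, nodes: dict[str, TaxonNode]):
        self.nodes = dict(nodes)
        self._children: dict[str, list[str]] = {tid: [] for tid in self.nodes}
        for tid, node in self.nodes.items():
            if node.parent is not None:
                if node.parent not in self.nodes:
                    raise ValueError(f"{tid} has unknown parent {node.parent}")
                parent = self.nodes[node.parent]
                if RANKS.index(parent.rank) != RANKS.index(node.rank) - 1:
                    raise ValueError(
                        f"{tid} ({node.rank}) must attach to a "
                        f"{RANKS[RANKS.index(node.rank) - 1]}")
                self._children[node.parent].append(tid)
            elif node.rank != "phylum":
                raise ValueError(f"non-phylum node {tid} lacks a parent")

    def __len__(self) -> int:
        return len(self.nodes)

    def ids_at_rank(self, rank: str) -> list[str]:
        return [tid for tid, n in self.nodes.items() if n.rank == rank]

    def children(self, taxon_id: str) -> list[str]:
        return list(self._children[taxon_id])

    def parent(self, taxon_id: str) -> Optional[str]:
        return self.nodes[taxon_id].parent

    def lineage(self, taxon_id: str) -> list[str]:
        """Path of ids from phylum down to the node."""
        path = [taxon_id]
        while self.nodes[path[0]].parent is not None:
            path.insert(0, self.nodes[path[0]].parent)
        return path

    def lineage_string(self, taxon_id: str) -> str:
        return "|".join(self.lineage(taxon_id))

    def leaves(self) -> list[str]:
        """Nodes without children, at any rank."""
        return [tid for tid, kids in self._children.items() if not kids]


def build_taxonomy(level_counts=DEFAULT_LEVEL_COUNTS, seed: int = 0) -> Taxonomy:
    """Random reproducible taxonomy with the requested nodes per rank.

    Each node below the phylum rank is attached to a uniformly drawn parent of
    the rank above (so ranks with fewer nodes than the rank above leave some
    lineages unresolved below a given depth, as in real annotations).
    """
    counts = list(level_counts)
    if len(counts) != len(RANKS):
        raise ValueError(f"need exactly {len(RANKS)} level counts, got {len(counts)}")
    if any(int(c) != c or c < 1 for c in counts):
        raise ValueError("all level counts must be positive integers")
    rng = np.random.default_rng(seed)
    nodes: dict[str, TaxonNode] = {}
    previous: list[str] = []
    for rank, count in zip(RANKS, counts):
        prefix = RANK_PREFIX[rank]
        current = []
        for i in range(int(count)):
            tid = f"{prefix}__{i + 1:03d}"
            parent = None if rank == "phylum" else str(rng.choice(previous))
            nodes[tid] = TaxonNode(taxon_id=tid, rank=rank, parent=parent,
                                   name=f"{rank.capitalize()}{i + 1:03d}")
            current.append(tid)
        previous = current
    return Taxonomy(nodes)
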