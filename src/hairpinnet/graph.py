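"""Network representation of a stem-loop secondary structure.

Every nucleotide becomes a node (1-based, following CT-file and biological
numbering) and every bond becomes an edge: the sugar-phosphate backbone
contributes the path ``1-2-...-n`` and each base pair contributes one extra
edge.  The result is a simple, connected, undirected graph of maximum
degree 3 in which base identity plays no role — all downstream features
are purely structural.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import igraph as ig

from .records import RnaRecord, StructureError, check_balanced

BACKBONE = "backbone"
PAIR = "pair"


def pair_table(structure: str) -> dict[int, int]:
    """Map each 1-based position to its pairing partner (0 = unpaired).

    Stack matching of the brackets; raises :class:`StructureError` on an
    unbalanced structure.  The mapping is symmetric: if ``t[i] == j`` then
    ``t[j] == i``, with ``(`` at the smaller position.
    """
    check_balanced(structure)
    table = {i: 0 for i in range(1, len(structure) + 1)}
    stack: list[int] = []
    for i, ch in enumerate(structure, start=1):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            j = stack.pop()
            table[j] = i
            table[i] = j
    return table


def pairs_from_structure(structure: str) -> list[tuple[int, int]]:
    """Base pairs ``(i, j)`` with ``i < j``, sorted by opening position."""
    table = pair_table(structure)
    return sorted((i, j) for i, j in table.items() if j > i)


@dataclass(frozen=True)
class StructureGraph:
    """Undirected simple graph of a secondary structure.

    Attributes
    ----------
    n : int
        Number of nodes (== sequence length).
    pairs : tuple of (int, int)
        Base-pair edges, 1-based, ``i < j``.
    graph : igraph.Graph
        Backing graph with 0-based vertex ids (vertex ``k`` is nucleotide
        ``k+1``) and an edge attribute ``kind`` in {backbone, pair}.
    """

    n: int
    pairs: tuple[tuple[int, int], ...]
    graph: ig.Graph = field(compare=False, repr=False)

    @property
    def n_edges(self) -> int:
        return self.graph.ecount()

    def degrees(self) -> list[int]:
        return self.graph.degree()


def build_graph(record_or_structure: RnaRecord | str) -> StructureGraph:
    """Build the structure graph of a record (or bare dot-bracket string)."""
    if isinstance(record_or_structure, RnaRecord):
        structure = record_or_structure.structure
    else:
        structure = record_or_structure
    n = len(structure)
    pairs = tuple(pairs_from_structure(structure))
    edges = [(i, i + 1) for i in range(n - 1)]
    kinds = [BACKBONE] * (n - 1)
    for i, j in pairs:
        if j == i + 1:
            # a pair between adjacent nucleotides would duplicate a backbone
            # edge; folding programs never emit it (hairpin loops >= 3 nt)
            raise StructureError(
                f"adjacent base pair ({i},{j}) duplicates a backbone edge")
        edges.append((i - 1, j - 1))
        kinds.append(PAIR)
    g = ig.Graph(n=n, edges=edges, edge_attrs={"kind": kinds})
    return StructureGraph(n=n, pairs=pairs, graph=g)


def edge_table(sg: StructureGraph) -> list[tuple[int, int, str]]:
    """Edge list ``(node_i, node_j, kind)`` with 1-based nodes, for export."""
    out = []
    for e in sg.graph.es:
        a, b = sorted(e.tuple)
        out.append((a + 1, b + 1, e["kind"]))
    return sorted(out)
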