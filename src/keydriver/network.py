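"""Directed gene-network container, edge-list / gene-set I/O, and downstream queries.

The central object is :class:`GeneNetwork`, a thin wrapper around a
:class:`networkx.DiGraph` whose edges carry a ``confidence`` in ``[0, 1]``
(the fraction of consensus iterations supporting the edge).  Every other
module — structure learning, topology diagnostics, key-driver analysis —
speaks this type.

Edge lists are the canonical interchange format: whitespace- or
tab-delimited lines ``parent child [confidence]``, ``#`` comments and blank
lines ignored.  Gene sets are one identifier per line.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import networkx as nx

__all__ = [
    "GeneNetwork",
    "GeneSet",
    "read_edge_list",
    "write_edge_list",
    "read_gene_set",
    "write_gene_set",
]


@dataclass(frozen=True)
class GeneSet:
    """A named collection of gene identifiers (GWAS candidates, eGenes, ...)."""

    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "members", frozenset(self.members))

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, gene: str) -> bool:
        return gene in self.members

    def __iter__(self) -> Iterator[str]:
        return iter(self.members)


class GeneNetwork:
    """Directed network over gene identifiers with per-edge confidence.

    Parameters
    ----------
    edges
        Iterable of ``(parent, child)`` or ``(parent, child, confidence)``
        tuples.  Missing confidence defaults to 1.0.  Duplicate edges
        collapse to a single edge keeping the maximum confidence (the
        conservative merge used by the consensus machinery).
    nodes
        Optional extra (possibly isolated) nodes; the node set is always at
        least the union of edge endpoints.

    Raises
    ------
    ValueError
        On self-edges or confidences outside ``[0, 1]``.
    """

    def __init__(
        self,
        edges: Iterable[tuple] = (),
        nodes: Iterable[str] = (),
    ) -> None:
        g = nx.DiGraph()
        g.add_nodes_from(nodes)
        for edge in edges:
            if len(edge) == 2:
                parent, child = edge
                confidence = 1.0
            else:
                parent, child, confidence = edge
                confidence = float(confidence)
            if parent == child:
                raise ValueError(f"self-edge forbidden: {parent!r} -> {child!r}")
            if not 0.0 <= confidence <= 1.0:
                raise ValueError(
                    f"confidence {confidence} outside [0, 1] on edge {parent!r} -> {child!r}"
                )
            if g.has_edge(parent, child):
                confidence = max(confidence, g[parent][child]["confidence"])
            g.add_edge(parent, child, confidence=confidence)
        self._graph = g
        #: edges removed by cycle breaking, populated by bayesnet.break_cycles
        self.removed_edges: list[tuple[str, str, float]] = []

    # -- basic accessors ---------------------------------------------------

    @property
    def graph(self) -> nx.DiGraph:
        """The underlying networkx DiGraph (shared, not copied)."""
        return self._graph

    @property
    def nodes(self) -> set[str]:
        return set(self._graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self._graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self._graph.number_of_edges()

    def edges(self) -> set[tuple[str, str]]:
        return set(self._graph.edges)

    def confidence(self, parent: str, child: str) -> float:
        return self._graph[parent][child]["confidence"]

    def edges_with_confidence(self) -> list[tuple[str, str, float]]:
        return [(u, v, d["confidence"]) for u, v, d in self._graph.edges(data=True)]

    @property
    def is_dag(self) -> bool:
        return nx.is_directed_acyclic_graph(self._graph)

    def connected_nodes(self) -> set[str]:
        """Genes with at least one incident edge (the paper-style 'connected genes')."""
        return {n for n in self._graph.nodes if self._graph.degree(n) > 0}

    def subgraph(self, nodes: Iterable[str]) -> "GeneNetwork":
        keep = set(nodes)
        sub = GeneNetwork(
            ((u, v, d["confidence"]) for u, v, d in self._graph.edges(data=True)
             if u in keep and v in keep),
            nodes=keep & self.nodes,
        )
        return sub

    def copy(self) -> "GeneNetwork":
        return GeneNetwork(self.edges_with_confidence(), nodes=self.nodes)

    def __contains__(self, gene: str) -> bool:
        return gene in self._graph

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneNetwork):
            return NotImplemented
        return self.nodes == other.nodes and set(
            self.edges_with_confidence()
        ) == set(other.edges_with_confidence())

    def __repr__(self) -> str:
        return f"GeneNetwork(n_nodes={self.n_nodes}, n_edges={self.n_edges})"

    # -- downstream queries ------------------------------------------------

    def distances_from(self, gene: str, max_distance: int | None = None) -> Mapping[str, int]:
        """Directed shortest-path (BFS) distance from ``gene`` to every reachable node."""
        if gene not in self._graph:
            raise KeyError(f"unknown gene: {gene!r}")
        return nx.single_source_shortest_path_length(
            self._graph, gene, cutoff=max_distance
        )

    def downstream_at_distance(self, gene: str, d: int) -> set[str]:
        """Genes whose directed shortest-path distance from ``gene`` is exactly ``d``.

        The focal gene itself is excluded (its distance is 0).
        """
        if d < 1:
            raise ValueError(f"distance must be >= 1, got {d}")
        dist = self.distances_from(gene, max_distance=d)
        return {node for node, k in dist.items() if k == d}

    def downstream_within(self, gene: str, radius: int) -> set[str]:
        """Union of downstream genes at distances ``1..radius`` (the 'neighborhood')."""
        if radius < 1:
            raise ValueError(f"radius must be >= 1, got {radius}")
        dist = self.distances_from(gene, max_distance=radius)
        return {node for node, k in dist.items() if 1 <= k <= radius}


# -- I/O -------------------------------------------------------------------


def read_edge_list(path: str | Path, directed: bool = True) -> GeneNetwork:
    """Parse a ``parent child [confidence]`` edge-list file into a GeneNetwork.

    Lines starting with ``#`` and blank lines are skipped; an optional header
    line ``parent child [confidence]`` is recognised and skipped.  Duplicate
    edges keep the maximum confidence.  ``directed=False`` adds both
    orientations of every edge.
    """
    path = Path(path)
    edges: list[tuple[str, str, float]] = []
    seen_data = False
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if not seen_data and fields[0].lower() == "parent":
                continue
            seen_data = True
            if len(fields) not in (2, 3):
                raise ValueError(
                    f"{path}:{lineno}: expected 2 or 3 columns, got {len(fields)}"
                )
            if len(fields) == 3:
                try:
                    conf = float(fields[2])
                except ValueError as exc:
                    raise ValueError(
                        f"{path}:{lineno}: bad confidence {fields[2]!r}"
                    ) from exc
            else:
                conf = 1.0
            parent, child = fields[0], fields[1]
            if parent == child:
                raise ValueError(f"{path}:{lineno}: self-edge {parent!r}")
            edges.append((parent, child, conf))
            if not directed:
                edges.append((child, parent, conf))
    return GeneNetwork(edges)


def write_edge_list(net: GeneNetwork, path: str | Path, header: bool = True) -> None:
    """Write a network as a sorted tab-delimited edge list with confidence."""
    path = Path(path)
    with path.open("w") as fh:
        if header:
            fh.write("parent\tchild\tconfidence\n")
        for parent, child, conf in sorted(net.edges_with_confidence()):
            fh.write(f"{parent}\t{child}\t{conf:.6g}\n")


def read_gene_set(path: str | Path, name: str | None = None) -> GeneSet:
    """Read a one-identifier-per-line gene-set file ('#' comments ignored)."""
    path = Path(path)
    members = []
    with path.open() as fh:
        for raw in fh:
            line = raw.strip()
            if line and not line.startswith("#"):
                members.append(line.split()[0])
    return GeneSet(name=name or path.stem, members=frozenset(members))


def write_gene_set(genes: Iterable[str], path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for gene in sorted(set(genes)):
            fh.write(f"{gene}\n")
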