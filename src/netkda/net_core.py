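"""Directed gene-network data model, I/O, and neighborhood primitives.

The network is the substrate for every downstream stage: layered signature
overlap, key-driver enrichment, and bridge-subnetwork extraction.  Nodes are
gene identifiers (non-empty strings, compared case-sensitively after trimming
surrounding whitespace); edges are ordered regulator -> target pairs.
Self-loops and duplicate edges are dropped on construction with a logged
count, so a :class:`GeneNetwork` always satisfies its invariants.
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import networkx as nx

logger = logging.getLogger(__name__)

Direction = str
_DIRECTIONS = ("downstream", "upstream", "undirected")


class NetworkFormatError(ValueError):
    """A network or signature file does not parse in the named format."""


def _clean_gene(g: str) -> str:
    g = g.strip()
    if not g:
        raise ValueError("gene identifiers must be non-empty strings")
    return g


class GeneNetwork:
    """Directed graph over gene identifiers.

    Parameters
    ----------
    edges
        Iterable of (regulator, target) pairs.  Self-loops and duplicates
        are dropped (counted and logged).
    nodes
        Optional extra nodes with no incident edges.
    name
        Free-text label carried through outputs.
    """

    def __init__(
        self,
        edges: Iterable[tuple[str, str]] = (),
        nodes: Iterable[str] = (),
        name: str = "",
    ) -> None:
        g = nx.DiGraph()
        n_self, n_dup = 0, 0
        for u, v in edges:
            u, v = _clean_gene(u), _clean_gene(v)
            if u == v:
                n_self += 1
                continue
            if g.has_edge(u, v):
                n_dup += 1
                continue
            g.add_edge(u, v)
        for n in nodes:
            g.add_node(_clean_gene(n))
        if n_self or n_dup:
            logger.info(
                "dropped %d self-loop(s) and %d duplicate edge(s) building %r",
                n_self, n_dup, name,
            )
        self._g = g
        self.name = name
        self.dropped_self_loops = n_self
        self.dropped_duplicates = n_dup

    # -- basic views -------------------------------------------------------
    @property
    def nodes(self) -> frozenset[str]:
        return frozenset(self._g.nodes)

    @property
    def edges(self) -> frozenset[tuple[str, str]]:
        return frozenset(self._g.edges)

    @property
    def graph(self) -> nx.DiGraph:
        """The underlying networkx DiGraph (treat as read-only)."""
        return self._g

    def __len__(self) -> int:
        return self._g.number_of_nodes()

    def n_edges(self) -> int:
        return self._g.number_of_edges()

    def __contains__(self, gene: str) -> bool:
        return gene in self._g

    def __repr__(self) -> str:
        return (
            f"GeneNetwork(name={self.name!r}, nodes={len(self)}, "
            f"edges={self.n_edges()})"
        )

    def successors(self, gene: str) -> set[str]:
        return set(self._g.successors(gene)) if gene in self._g else set()

    def predecessors(self, gene: str) -> set[str]:
        return set(self._g.predecessors(gene)) if gene in self._g else set()

    def subnetwork(self, genes: Iterable[str], name: str = "") -> "GeneNetwork":
        """Subgraph induced by ``genes`` (members absent from the network ignored)."""
        keep = set(genes) & set(self._g.nodes)
        sub = self._g.subgraph(keep)
        return GeneNetwork(edges=sub.edges, nodes=sub.nodes, name=name or self.name)


@dataclass(frozen=True)
class GeneSignature:
    """Named gene set with a provenance label (e.g. an EP-res resistance list)."""

    name: str
    genes: frozenset[str]
    source: str = ""

    def __post_init__(self) -> None:
        cleaned = frozenset(_clean_gene(g) for g in self.genes)
        if not cleaned:
            raise ValueError(f"signature {self.name!r} has an empty gene set")
        object.__setattr__(self, "genes", cleaned)

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self) -> Iterator[str]:
        return iter(self.genes)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_network(
    path: str | Path,
    format: str = "edgelist",
    header: bool = False,
    name: str | None = None,
) -> GeneNetwork:
    """Read a directed gene network.

    ``format`` is ``"edgelist"`` (two tab-separated columns,
    regulator<TAB>target, optional header row skipped when ``header=True``)
    or ``"graphml"``.  Invariant violations (self-loops, duplicate edges)
    are dropped with a logged count.
    """
    path = Path(path)
    if name is None:
        name = path.stem
    if format == "graphml":
        g = nx.read_graphml(path)
        return GeneNetwork(edges=((str(u), str(v)) for u, v in g.edges),
                           nodes=(str(n) for n in g.nodes), name=name)
    if format != "edgelist":
        raise ValueError(f"unknown network format {format!r}")
    edges = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            if header and lineno == 1:
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 2:
                raise NetworkFormatError(
                    f"{path}:{lineno}: expected 2 tab-separated fields, "
                    f"got {len(parts)}"
                )
            edges.append((parts[0], parts[1]))
    return GeneNetwork(edges=edges, name=name)


def write_network(net: GeneNetwork, path: str | Path, format: str = "edgelist") -> None:
    """Write a network as edge-list TSV or GraphML (deterministic row order)."""
    path = Path(path)
    if format == "graphml":
        nx.write_graphml(net.graph, path)
        return
    if format != "edgelist":
        raise ValueError(f"unknown network format {format!r}")
    with open(path, "w") as fh:
        # edge-list TSV carries edges only; isolated nodes need GraphML
        for u, v in sorted(net.edges):
            fh.write(f"{u}\t{v}\n")


def read_signature(path: str | Path, name: str | None = None,
                   source: str = "") -> GeneSignature:
    """Read a gene signature: one gene per line, optional ``# name:`` header."""
    path = Path(path)
    genes: list[str] = []
    sig_name = name
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if body.lower().startswith("name:") and sig_name is None:
                    sig_name = body[5:].strip()
                continue
            genes.append(line)
    return GeneSignature(name=sig_name or path.stem, genes=frozenset(genes),
                         source=source or str(path))


def write_signature(sig: GeneSignature, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# name: {sig.name}\n")
        for g in sorted(sig.genes):
            fh.write(g + "\n")


# ---------------------------------------------------------------------------
# Neighborhood primitives
# ---------------------------------------------------------------------------

def neighborhood(
    net: GeneNetwork,
    seeds: Iterable[str],
    layers: int,
    direction: Direction = "undirected",
) -> set[str]:
    """Seeds plus all nodes within ``layers`` edge traversals.

    ``direction`` chooses the traversal: ``downstream`` follows
    regulator -> target edges, ``upstream`` the reverse, ``undirected``
    ignores orientation.  Seeds absent from the network are retained in the
    result but not expanded.  Monotone in ``layers``.
    """
    if layers < 0:
        raise ValueError(f"layers must be non-negative, got {layers}")
    if direction not in _DIRECTIONS:
        raise ValueError(f"direction must be one of {_DIRECTIONS}, got {direction!r}")
    seeds = {_clean_gene(s) for s in seeds}
    result = set(seeds)
    frontier = deque(s for s in seeds if s in net)
    g = net.graph
    depth = {s: 0 for s in frontier}
    while frontier:
        u = frontier.popleft()
        d = depth[u]
        if d == layers:
            continue
        if direction == "downstream":
            nbrs: Iterable[str] = g.successors(u)
        elif direction == "upstream":
            nbrs = g.predecessors(u)
        else:
            nbrs = set(g.successors(u)) | set(g.predecessors(u))
        for v in nbrs:
            if v not in depth or depth[v] > d + 1:
                depth[v] = d + 1
                result.add(v)
                frontier.append(v)
    return result


def largest_connected_subnetwork(net: GeneNetwork, nodes: Iterable[str]) -> set[str]:
    """Node set of the largest weakly connected component of the induced subgraph.

    Members of ``nodes`` absent from the network are ignored (logged count).
    Size ties are broken by the component containing the lexicographically
    smallest gene.  Empty intersection yields the empty set.
    """
    nodes = set(nodes)
    present = nodes & set(net.graph.nodes)
    if len(present) < len(nodes):
        logger.info("largest_connected_subnetwork: %d node(s) absent from network ignored",
                    len(nodes) - len(present))
    if not present:
        return set()
    sub = net.graph.subgraph(present)
    comps = list(nx.weakly_connected_components(sub))
    max_size = max(len(c) for c in comps)
    tied = [c for c in comps if len(c) == max_size]
    return set(min(tied, key=lambda c: min(c)))
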