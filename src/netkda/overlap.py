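"""Layered signature-overlap analysis on a gene network.

Two resistance signatures that barely intersect as raw gene lists can still
converge on the same network neighborhood.  This module quantifies that:
each signature is expanded to its n-layer network neighborhood and the
expansion-level overlap is scored with a one-sided Fisher exact test
(hypergeometric upper tail), including the "2c" variant in which each
two-layer neighborhood is first reduced to its largest connected induced
subnetwork.  The intersection of the two connected subnetworks is the
bridge subnetwork, the candidate region where a shared regulator lives.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from scipy.stats import hypergeom

from .net_core import (
    Direction,
    GeneNetwork,
    GeneSignature,
    largest_connected_subnetwork,
    neighborhood,
)

logger = logging.getLogger(__name__)

#: cap for -log10(p) in output tables (avoids inf in TSVs)
NEG_LOG10_CAP = 300.0


@dataclass(frozen=True)
class OverlapCell:
    """One 2x2 overlap test: counts, cross-product odds ratio, upper-tail p."""

    layer_label: str
    set_a_size: int
    set_b_size: int
    overlap: int
    universe: int
    odds_ratio: float
    p_value: float
    degenerate: bool = False

    @property
    def neg_log10_p(self) -> float:
        if self.p_value <= 0.0:
            return NEG_LOG10_CAP
        return min(-math.log10(self.p_value), NEG_LOG10_CAP)


@dataclass(frozen=True)
class OverlapGrid:
    """Ordered per-layer overlap cells for a pair of signatures (heatmap form)."""

    cells: tuple[OverlapCell, ...]
    signature_a: str
    signature_b: str
    direction: Direction

    def __post_init__(self) -> None:
        labels = [c.layer_label for c in self.cells]
        if len(set(labels)) != len(labels):
            raise ValueError(f"duplicate layer labels: {labels}")
        if "Gene" not in labels:
            raise ValueError("grid must contain the 'Gene' cell")

    def cell(self, label: str) -> OverlapCell:
        for c in self.cells:
            if c.layer_label == label:
                return c
        raise KeyError(label)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "layer": [c.layer_label for c in self.cells],
                "set_a_size": [c.set_a_size for c in self.cells],
                "set_b_size": [c.set_b_size for c in self.cells],
                "overlap": [c.overlap for c in self.cells],
                "universe": [c.universe for c in self.cells],
                "odds_ratio": [c.odds_ratio for c in self.cells],
                "p_value": [c.p_value for c in self.cells],
                "neg_log10_p": [c.neg_log10_p for c in self.cells],
            }
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def fisher_overlap(
    set_a: Iterable[str],
    set_b: Iterable[str],
    universe: Iterable[str] | int,
    layer_label: str = "",
) -> OverlapCell:
    """One-sided Fisher exact overlap of two gene sets against a universe.

    Builds the 2x2 table (k, |A|-k, |B|-k, U-|A|-|B|+k) with k = |A n B|.
    The odds ratio is the cross-product ratio (+inf when a zero denominator
    meets k > 0, 0 when k = 0); the p-value is the hypergeometric upper
    tail P(X >= k).  ``universe`` may be a gene set (A and B must be subsets)
    or a plain count >= |A u B|.
    """
    a, b = set(set_a), set(set_b)
    if not a or not b:
        raise ValueError("fisher_overlap requires two non-empty gene sets")
    k = len(a & b)
    if isinstance(universe, int):
        u = universe
        if u < len(a | b):
            raise ValueError(
                f"universe count {u} smaller than |A u B| = {len(a | b)}")
    else:
        uset = set(universe)
        if not (a <= uset and b <= uset):
            raise ValueError("set_a and set_b must be subsets of the universe")
        u = len(uset)
    rest = u - len(a) - len(b) + k
    denom = (len(a) - k) * (len(b) - k)
    if k == 0:
        odds = 0.0
    elif denom == 0:
        odds = math.inf
    else:
        odds = k * rest / denom
    p = float(hypergeom.sf(k - 1, u, len(a), len(b)))
    return OverlapCell(
        layer_label=layer_label,
        set_a_size=len(a),
        set_b_size=len(b),
        overlap=k,
        universe=u,
        odds_ratio=odds,
        p_value=min(max(p, 0.0), 1.0),
    )


def _degenerate_cell(label: str, a: int, b: int, u: int) -> OverlapCell:
    return OverlapCell(layer_label=label, set_a_size=a, set_b_size=b,
                       overlap=0, universe=u, odds_ratio=0.0, p_value=1.0,
                       degenerate=True)


def layered_overlap_grid(
    net: GeneNetwork,
    sig_a: GeneSignature,
    sig_b: GeneSignature,
    max_layers: int = 3,
    direction: Direction = "undirected",
) -> OverlapGrid:
    """Per-layer Fisher overlap grid for two signatures.

    Emits the "Gene" cell (raw signatures; universe = network nodes plus
    both signatures), one cell per expansion layer 1..max_layers (expanded
    sets restricted to the network; universe = network nodes), and — when
    max_layers >= 2 — the "2c" cell computed on the largest connected
    subnetwork of each signature's two-layer neighborhood.  A signature
    with no genes in the network yields degenerate layer cells (warned).
    """
    if max_layers < 1:
        raise ValueError("max_layers must be >= 1")
    net_nodes = net.nodes
    gene_universe = net_nodes | sig_a.genes | sig_b.genes
    cells = [fisher_overlap(sig_a.genes, sig_b.genes, gene_universe, "Gene")]

    a_in = sig_a.genes & net_nodes
    b_in = sig_b.genes & net_nodes
    for layer in range(1, max_layers + 1):
        label = str(layer)
        if not a_in or not b_in:
            logger.warning("layer %s degenerate: a signature has no genes in the network",
                           label)
            cells.append(_degenerate_cell(label, len(a_in), len(b_in), len(net_nodes)))
        else:
            ea = neighborhood(net, a_in, layer, direction) & net_nodes
            eb = neighborhood(net, b_in, layer, direction) & net_nodes
            cells.append(fisher_overlap(ea, eb, net_nodes, label))
        if layer == 2:
            if not a_in or not b_in:
                cells.append(_degenerate_cell("2c", len(a_in), len(b_in),
                                              len(net_nodes)))
                continue
            ca = largest_connected_subnetwork(net, ea)
            cb = largest_connected_subnetwork(net, eb)
            if not ca or not cb:
                cells.append(_degenerate_cell("2c", len(ca), len(cb), len(net_nodes)))
            else:
                cells.append(fisher_overlap(ca, cb, net_nodes, "2c"))
    return OverlapGrid(cells=tuple(cells), signature_a=sig_a.name,
                       signature_b=sig_b.name, direction=direction)


@dataclass(frozen=True)
class BridgeResult:
    """Bridge subnetwork plus per-node signature membership annotation."""

    network: GeneNetwork
    membership: pd.DataFrame  # columns: gene, in_a, in_b

    def write(self, edge_path: str | Path, node_path: str | Path) -> None:
        from .net_core import write_network

        write_network(self.network, edge_path)
        self.membership.to_csv(node_path, sep="\t", index=False)


def bridge_subnetwork(
    net: GeneNetwork,
    sig_a: GeneSignature,
    sig_b: GeneSignature,
    layers: int = 2,
    direction: Direction = "undirected",
) -> BridgeResult:
    """Intersection of the two signatures' largest connected layer-L subnetworks.

    Each signature is expanded ``layers`` steps, reduced to the largest
    weakly connected induced component, and the two components are
    intersected; the induced subgraph on the intersection is returned with
    per-node annotation of raw signature membership.  An empty intersection
    yields an empty network (warned), not an error.
    """
    if layers < 1:
        raise ValueError("layers must be >= 1")
    comp_a = largest_connected_subnetwork(
        net, neighborhood(net, sig_a.genes & net.nodes, layers, direction))
    comp_b = largest_connected_subnetwork(
        net, neighborhood(net, sig_b.genes & net.nodes, layers, direction))
    shared = comp_a & comp_b
    if not shared:
        logger.warning("bridge_subnetwork: empty intersection between %s and %s",
                       sig_a.name, sig_b.name)
    bridge = net.subnetwork(shared, name=f"bridge[{sig_a.name}&{sig_b.name}]")
    genes = sorted(shared)
    membership = pd.DataFrame(
        {
            "gene": genes,
            "in_a": [g in sig_a.genes for g in genes],
            "in_b": [g in sig_b.genes for g in genes],
        }
    )
    return BridgeResult(network=bridge, membership=membership)
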