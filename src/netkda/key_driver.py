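"""Key-driver analysis: hypergeometric enrichment of signatures in node neighborhoods.

A key driver is a node whose h-layer (by default downstream) neighborhood is
significantly enriched for a signature's genes; a *bridging* driver is
enriched for two signatures at once, scored by the max of the two enrichment
p-values (an intersection-union test: the bridge score is small only when
both are).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .net_core import Direction, GeneNetwork, GeneSignature, neighborhood

logger = logging.getLogger(__name__)

DEFAULT_MIN_NEIGHBORHOOD = 5
DEFAULT_ALPHA = 0.05

KD_COLUMNS = ["gene", "neighborhood_size", "overlap", "p", "q", "rank"]


def _node_neighborhoods(
    net: GeneNetwork, h: int, direction: Direction, min_size: int
) -> dict[str, set[str]]:
    """h-layer neighborhood (node itself excluded) for every node passing min_size."""
    out = {}
    for node in net.nodes:
        nb = neighborhood(net, {node}, h, direction) - {node}
        if len(nb) >= min_size:
            out[node] = nb
    return out


def key_driver_analysis(
    net: GeneNetwork,
    signature: GeneSignature,
    h: int = 2,
    direction: Direction = "downstream",
    min_neighborhood: int = DEFAULT_MIN_NEIGHBORHOOD,
    _neighborhoods: dict[str, set[str]] | None = None,
) -> pd.DataFrame:
    """Rank nodes by signature enrichment of their h-layer neighborhoods.

    For each node with at least ``min_neighborhood`` neighbors, the overlap
    of the neighborhood (node excluded) with the signature is scored against
    the hypergeometric null on a universe of all other network nodes;
    Benjamini-Hochberg adjustment is applied across tested nodes.  Nodes are
    ranked by p ascending, then neighborhood size descending, then gene id.

    Returns a DataFrame with columns ``gene, neighborhood_size, overlap, p,
    q, rank`` sorted by rank.  ``_neighborhoods`` lets callers reuse
    precomputed neighborhoods (bridging analysis runs two signatures on the
    same graph).
    """
    if h < 1:
        raise ValueError("h must be >= 1")
    sig_in_net = signature.genes & net.nodes
    if not sig_in_net:
        logger.warning("signature %s shares no genes with the network", signature.name)
        return pd.DataFrame(columns=KD_COLUMNS)
    nbhd = _neighborhoods
    if nbhd is None:
        nbhd = _node_neighborhoods(net, h, direction, min_neighborhood)
    genes = sorted(nbhd)
    u = len(net.nodes) - 1
    sizes = np.array([len(nbhd[g]) for g in genes], dtype=np.int64)
    big_k = np.array([len(sig_in_net - {g}) for g in genes], dtype=np.int64)
    k = np.array([len(nbhd[g] & sig_in_net) for g in genes], dtype=np.int64)
    p = hypergeom.sf(k - 1, u, big_k, sizes)
    p = np.clip(p, 0.0, 1.0)
    q = multipletests(p, method="fdr_bh")[1] if len(p) else p
    df = pd.DataFrame(
        {"gene": genes, "neighborhood_size": sizes, "overlap": k, "p": p, "q": q}
    )
    df = df.sort_values(
        ["p", "neighborhood_size", "gene"], ascending=[True, False, True]
    ).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df


def bridging_driver_rank(
    net: GeneNetwork,
    sig_a: GeneSignature,
    sig_b: GeneSignature,
    h: int = 2,
    direction: Direction = "downstream",
    min_neighborhood: int = DEFAULT_MIN_NEIGHBORHOOD,
    alpha: float = DEFAULT_ALPHA,
) -> pd.DataFrame:
    """Rank nodes as bridging drivers of two signatures.

    Runs :func:`key_driver_analysis` for each signature on shared
    neighborhoods; a node's ``bridge_p`` is max(p_A, p_B) and nodes are
    ranked ascending by it (ties: neighborhood size descending, then gene
    id).  A node is ``flagged`` as a bridging driver when both BH-adjusted
    values pass ``alpha``.

    Returns columns ``gene, neighborhood_size, overlap_a, p_a, q_a,
    overlap_b, p_b, q_b, bridge_p, rank, flagged``.
    """
    nbhd = _node_neighborhoods(net, h, direction, min_neighborhood)
    res_a = key_driver_analysis(net, sig_a, h, direction, min_neighborhood,
                                _neighborhoods=nbhd)
    res_b = key_driver_analysis(net, sig_b, h, direction, min_neighborhood,
                                _neighborhoods=nbhd)
    if res_a.empty or res_b.empty:
        logger.warning("bridging analysis degenerate: a signature is disjoint "
                       "from the network")
        return pd.DataFrame(columns=[
            "gene", "neighborhood_size", "overlap_a", "p_a", "q_a",
            "overlap_b", "p_b", "q_b", "bridge_p", "rank", "flagged"])
    a = res_a.drop(columns="rank").rename(
        columns={"overlap": "overlap_a", "p": "p_a", "q": "q_a"})
    b = res_b.drop(columns=["rank", "neighborhood_size"]).rename(
        columns={"overlap": "overlap_b", "p": "p_b", "q": "q_b"})
    df = a.merge(b, on="gene", how="inner")
    df["bridge_p"] = np.maximum(df["p_a"], df["p_b"])
    df = df.sort_values(
        ["bridge_p", "neighborhood_size", "gene"], ascending=[True, False, True]
    ).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    df["flagged"] = (df["q_a"] <= alpha) & (df["q_b"] <= alpha)
    return df
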