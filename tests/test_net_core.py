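"""Graph model, I/O round-trips, and neighborhood primitives vs brute-force oracles."""

import numpy as np
import pytest

from netkda import (
    GeneNetwork,
    GeneSignature,
    largest_connected_subnetwork,
    neighborhood,
    read_network,
    read_signature,
    write_network,
    write_signature,
)
from netkda.net_core import NetworkFormatError

from conftest import random_network


# ---------------------------------------------------------------------------
# construction and I/O
# ---------------------------------------------------------------------------

class TestGeneNetwork:
    def test_basic_construction(self):
        net = GeneNetwork(edges=[("a", "b"), ("b", "c"), ("a", "c")])
        assert net.nodes == {"a", "b", "c"}
        assert net.edges == {("a", "b"), ("b", "c"), ("a", "c")}

    def test_self_loops_and_duplicates_dropped_with_counts(self):
        net = GeneNetwork(edges=[("a", "a"), ("a", "b"), ("a", "b")])
        assert net.nodes == {"a", "b"}
        assert net.edges == {("a", "b")}
        assert net.dropped_self_loops == 1
        assert net.dropped_duplicates == 1

    def test_whitespace_trimmed_and_empty_rejected(self):
        net = GeneNetwork(edges=[(" a ", "b\t")])
        assert net.edges == {("a", "b")}
        with pytest.raises(ValueError):
            GeneNetwork(edges=[("", "b")])

    def test_signature_rejects_empty(self):
        with pytest.raises(ValueError):
            GeneSignature(name="x", genes=frozenset())


class TestIO:
    def test_edgelist_read(self, tmp_path):
        p = tmp_path / "net.tsv"
        p.write_text("a\tb\nb\tc\na\tc\n")
        net = read_network(p)
        assert len(net) == 3 and net.n_edges() == 3

    def test_invariant_enforcement_on_read(self, tmp_path):
        p = tmp_path / "net.tsv"
        p.write_text("a\ta\na\tb\na\tb\n")
        net = read_network(p)
        assert net.nodes == {"a", "b"} and net.edges == {("a", "b")}
        assert net.dropped_self_loops + net.dropped_duplicates == 2

    def test_bad_row_names_line(self, tmp_path):
        p = tmp_path / "net.tsv"
        p.write_text("a\tb\nonlyonefield\n")
        with pytest.raises(NetworkFormatError, match=":2"):
            read_network(p)

    @pytest.mark.parametrize("fmt", ["edgelist", "graphml"])
    def test_round_trip(self, tmp_path, fmt):
        net = random_network(3, n=40, p=0.05)
        p = tmp_path / f"net.{fmt}"
        write_network(net, p, format=fmt)
        back = read_network(p, format=fmt)
        assert back.edges == net.edges
        if fmt == "graphml":  # edge-list TSV cannot carry isolated nodes
            assert back.nodes == net.nodes

    def test_signature_round_trip(self, tmp_path):
        sig = GeneSignature(name="EP-res", genes=frozenset({"a", "b", "c"}),
                            source="unit")
        p = tmp_path / "sig.txt"
        write_signature(sig, p)
        back = read_signature(p)
        assert back.genes == sig.genes and back.name == "EP-res"


# ---------------------------------------------------------------------------
# neighborhood
# ---------------------------------------------------------------------------

def bfs_oracle(net: GeneNetwork, seeds, layers, direction):
    """Plain breadth-first search truncated at depth, written independently."""
    adj = {n: set() for n in net.nodes}
    for u, v in net.edges:
        if direction in ("downstream", "undirected"):
            adj[u].add(v)
        if direction in ("upstream", "undirected"):
            adj[v].add(u)
    seen = set(seeds)
    frontier = {s for s in seeds if s in adj}
    for _ in range(layers):
        frontier = {v for u in frontier for v in adj[u]} - seen
        seen |= frontier
    return seen


class TestNeighborhood:
    def test_zero_layers_is_identity(self, chain_net):
        assert neighborhood(chain_net, {"a", "zzz"}, 0) == {"a", "zzz"}

    def test_chain_downstream_two_layers(self, chain_net):
        assert neighborhood(chain_net, {"a"}, 2, "downstream") == {"a", "b", "c"}

    def test_absent_seeds_retained_not_expanded(self, chain_net):
        out = neighborhood(chain_net, {"ghost"}, 3, "downstream")
        assert out == {"ghost"}

    def test_negative_layers_rejected(self, chain_net):
        with pytest.raises(ValueError):
            neighborhood(chain_net, {"a"}, -1)

    @pytest.mark.parametrize("direction", ["downstream", "upstream", "undirected"])
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_bfs_oracle_on_random_graphs(self, seed, direction):
        net = random_network(seed)
        rng = np.random.default_rng(100 + seed)
        seeds = set(rng.choice(sorted(net.nodes), size=5, replace=False))
        for layers in (0, 1, 2, 3):
            assert neighborhood(net, seeds, layers, direction) == \
                bfs_oracle(net, seeds, layers, direction)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_monotone_in_layers_and_direction(self, seed):
        net = random_network(seed)
        seeds = {"g0", "g10"}
        prev = None
        for layers in range(4):
            cur = neighborhood(net, seeds, layers, "undirected")
            down = neighborhood(net, seeds, layers, "downstream")
            up = neighborhood(net, seeds, layers, "upstream")
            assert down <= cur and up <= cur
            if prev is not None:
                assert prev <= cur
            prev = cur


# ---------------------------------------------------------------------------
# largest connected subnetwork
# ---------------------------------------------------------------------------

def union_find_components(nodes, edges):
    """Weakly connected components by union-find, independent of networkx."""
    parent = {n: n for n in nodes}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for u, v in edges:
        if u in parent and v in parent:
            ru, rv = find(u), find(v)
            if ru != rv:
                parent[ru] = rv
    comps = {}
    for n in nodes:
        comps.setdefault(find(n), set()).add(n)
    return list(comps.values())


class TestLargestConnectedSubnetwork:
    def test_size_comparison(self):
        net = GeneNetwork(edges=[("a", "b"), ("b", "c"), ("d", "e")])
        assert largest_connected_subnetwork(net, net.nodes) == {"a", "b", "c"}

    def test_tie_broken_by_smallest_gene(self):
        net = GeneNetwork(edges=[("c", "d"), ("a", "b")])
        assert largest_connected_subnetwork(net, net.nodes) == {"a", "b"}

    def test_absent_members_ignored_and_empty_ok(self, chain_net):
        assert largest_connected_subnetwork(chain_net, {"x", "y"}) == set()
        assert largest_connected_subnetwork(chain_net, {"a", "b", "zz"}) == {"a", "b"}

    @pytest.mark.parametrize("seed", range(10))
    def test_agrees_with_union_find_oracle(self, seed):
        net = random_network(seed, n=60, p=0.03)
        rng = np.random.default_rng(200 + seed)
        subset = set(rng.choice(sorted(net.nodes), size=35, replace=False))
        got = largest_connected_subnetwork(net, subset)
        sub_edges = [(u, v) for u, v in net.edges if u in subset and v in subset]
        comps = union_find_components(subset, sub_edges)
        max_size = max(len(c) for c in comps)
        expected = min((c for c in comps if len(c) == max_size),
                       key=lambda c: min(c))
        assert got == expected
        # output really is weakly connected
        assert len(union_find_components(got, sub_edges)) == 1
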