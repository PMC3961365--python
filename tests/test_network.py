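"""Module construction and centrality conventions."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

from seednet.network import (
    InteractionNetwork,
    build_network,
    compute_centralities,
    degree_sequence,
    read_interactions,
    read_seeds,
    write_network,
)


@pytest.mark.parametrize(
    "seeds, interactions, exp_proteins, exp_edges",
    [
        # C is a partner of a non-seed only, so (B,C) loses an endpoint
        (["A"], [("A", "B"), ("B", "C"), ("C", "D")], {"A", "B"}, {("A", "B")}),
        (["A"], [], {"A"}, set()),
        # B partners both seeds; C partners only the non-seed B
        (
            ["A", "D"],
            [("A", "B"), ("B", "D"), ("B", "C")],
            {"A", "B", "D"},
            {("A", "B"), ("B", "D")},
        ),
    ],
)
def test_seed_extension_rule(seeds, interactions, exp_proteins, exp_edges):
    if interactions:
        net = build_network(seeds, interactions)
    else:
        with pytest.warns(UserWarning, match="isolated"):
            net = build_network(seeds, interactions)
    assert set(net.proteins) == exp_proteins
    assert set(net.edges) == exp_edges
    assert set(net.seeds) == set(seeds)


def test_empty_seed_list_rejected():
    with pytest.raises(ValueError):
        build_network([], [("A", "B")])


def test_build_is_idempotent():
    net = build_network(["A", "D"], [("A", "B"), ("B", "D"), ("B", "C"), ("D", "E")])
    again = build_network(sorted(net.seeds), sorted(net.edges))
    assert again.proteins == net.proteins
    assert again.edges == net.edges


def test_network_invariants_enforced():
    with pytest.raises(ValueError):
        InteractionNetwork(frozenset({"A"}), frozenset({("A", "A")}), frozenset())
    with pytest.raises(ValueError):
        InteractionNetwork(frozenset({"A"}), frozenset({("A", "B")}), frozenset())
    with pytest.raises(ValueError):
        InteractionNetwork(frozenset({"A"}), frozenset(), frozenset({"Z"}))


def test_triangle_centralities(triangle):
    prof = compute_centralities(triangle)
    assert prof.density == 1.0
    assert all(c == 1.0 for c in prof.clustering.values())
    assert degree_sequence(triangle) == [2, 2, 2]


def test_path_centralities(path_abc):
    prof = compute_centralities(path_abc)
    assert prof.betweenness["B"] == 1.0  # unnormalized pair count
    assert prof.eccentricity == {"A": 2, "B": 1, "C": 2}
    assert prof.closeness["B"] == 1.0
    assert prof.closeness["A"] == pytest.approx(2 / 3)
    assert degree_sequence(path_abc) == [1, 2, 1]


def test_star_center_clustering():
    star = InteractionNetwork.from_edges([("Z", "A"), ("Z", "B"), ("Z", "C")])
    prof = compute_centralities(star)
    assert prof.degree["Z"] == 3
    assert prof.clustering["Z"] == 0.0


def test_isolated_vertex_conventions():
    net = InteractionNetwork.from_edges([("A", "B")], extra_proteins=["X"])
    prof = compute_centralities(net)
    assert prof.closeness["X"] == 0.0
    assert prof.eccentricity["X"] == 0


def _brute_force_shortest_paths(nodes, edges):
    """BFS-free oracle: repeated edge relaxation (Bellman-Ford style)."""
    inf = float("inf")
    dist = {(u, v): (0 if u == v else inf) for u in nodes for v in nodes}
    adj = {u: set() for u in nodes}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
    for _ in range(len(nodes)):
        for u in nodes:
            for v in nodes:
                for w in adj[v]:
                    if dist[(u, w)] + 1 < dist[(u, v)]:
                        dist[(u, v)] = dist[(u, w)] + 1
    return dist


def _count_shortest_paths(nodes, adj, s, t, dist):
    """Enumerate shortest s-t paths by DFS along distance-decreasing edges."""
    if s == t:
        return [[s]]
    paths = []
    for w in adj[s]:
        if dist[(w, t)] == dist[(s, t)] - 1:
            paths.extend([[s] + p for p in _count_shortest_paths(nodes, adj, w, t, dist)])
    return paths


@settings(max_examples=40, deadline=None, derandomize=True)
@given(
    n=st.integers(min_value=2, max_value=7),
    edge_bits=st.integers(min_value=0, max_value=2**21 - 1),
)
def test_centralities_match_brute_force_oracle(n, edge_bits):
    """All five measures agree with exhaustive shortest-path enumeration on
    graphs with at most 7 vertices."""
    nodes = [chr(ord("a") + i) for i in range(n)]
    pairs = list(itertools.combinations(nodes, 2))
    edges = [p for i, p in enumerate(pairs) if edge_bits >> i & 1]
    net = InteractionNetwork.from_edges(edges, extra_proteins=nodes)
    prof = compute_centralities(net)

    dist = _brute_force_shortest_paths(nodes, edges)
    adj = {u: set() for u in nodes}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
    inf = float("inf")
    for u in nodes:
        reach = [v for v in nodes if v != u and dist[(u, v)] < inf]
        # degree
        assert prof.degree[u] == len(adj[u])
        # closeness: per-component normalized
        expected_clo = (
            len(reach) / sum(dist[(u, v)] for v in reach) if reach else 0.0
        )
        assert prof.closeness[u] == pytest.approx(expected_clo)
        # eccentricity within the component
        assert prof.eccentricity[u] == (max((dist[(u, v)] for v in reach), default=0))
        # clustering
        nbrs = sorted(adj[u])
        possible = len(nbrs) * (len(nbrs) - 1) / 2
        closed = sum(
            1 for a, b in itertools.combinations(nbrs, 2) if b in adj[a]
        )
        assert prof.clustering[u] == pytest.approx(
            closed / possible if possible else 0.0
        )
    # betweenness: fraction of shortest paths through each vertex, summed
    for w in nodes:
        expected = 0.0
        for s, t in itertools.combinations([x for x in nodes if x != w], 2):
            if dist[(s, t)] == inf:
                continue
            paths = _count_shortest_paths(nodes, adj, s, t, dist)
            through = sum(1 for p in paths if w in p[1:-1])
            expected += through / len(paths)
        assert prof.betweenness[w] == pytest.approx(expected)
    # handshake lemma
    assert sum(degree_sequence(net)) == 2 * net.n_edges


def test_io_roundtrip(tmp_path):
    tsv = tmp_path / "edges.tsv"
    tsv.write_text("# comment\nB\tA\tsrc\nA\tB\nC\tD\nC\tC\n")
    edges = read_interactions(tsv)
    assert edges == [("A", "B"), ("C", "D")]  # dedup of reversed pair, no loop

    seeds = tmp_path / "seeds.txt"
    seeds.write_text("# s\nA\n\nC\n")
    assert read_seeds(seeds) == ["A", "C"]

    net = build_network(["A", "C"], edges)
    paths = write_network(net, tmp_path / "module")
    assert read_interactions(paths["edges"]) == sorted(net.edges)
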