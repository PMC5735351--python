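import json

import networkx as nx
import numpy as np
import pytest

from agingnet import (
    SeedMode,
    SeedSpec,
    degree_ranking,
    expand_second_neighbors,
    extract_subnetwork,
    find_singletons,
    first_neighbor_subnetwork,
)
from agingnet import io as fio
from conftest import YWHAE_PARTNERS


def star_network():
    g = nx.Graph()
    for partner in YWHAE_PARTNERS:
        g.add_edge(fio.canonical_symbol("Ywhae"), fio.canonical_symbol(partner))
    return g


def test_hub_star_expansion_from_partner_seeds():
    """Seeding with the ten immune genes recovers the hub adjacent to all."""
    net = star_network()
    spec = SeedSpec(seed_genes=frozenset(YWHAE_PARTNERS))
    sub = first_neighbor_subnetwork(net, spec)
    assert sub.graph.nodes["YWHAE"]["role"] == "NEIGHBOR"
    assert set(sub.graph.neighbors("YWHAE")) == spec.seed_genes
    assert degree_ranking(sub, k=1).top() == "YWHAE"
    assert sub.graph.nodes["YWHAE"]["degree"] == len(YWHAE_PARTNERS)


def test_seed_without_edges_is_singleton():
    net = star_network()
    spec = SeedSpec(seed_genes=frozenset({"Cd74", "Nothere"}))
    sub = first_neighbor_subnetwork(net, spec)
    assert sub.graph.nodes["NOTHERE"]["role"] == "SINGLETON"
    assert sub.graph.nodes["NOTHERE"]["degree"] == 0
    assert find_singletons(net, spec) == frozenset({"NOTHERE"})


def test_neighbors_must_be_degs_mode_restricts_partners():
    net = star_network()
    net.add_edge("CD74", "OFFLIST")
    spec = SeedSpec(
        seed_genes=frozenset({"Cd74"}),
        mode=SeedMode.NEIGHBORS_MUST_BE_DEGS,
        deg_universe=frozenset({"Ywhae"}),
    )
    sub = first_neighbor_subnetwork(net, spec)
    assert "OFFLIST" not in sub.graph
    assert "YWHAE" in sub.graph


def test_mode_requires_universe_and_empty_seeds_rejected():
    with pytest.raises(ValueError):
        SeedSpec(seed_genes=frozenset({"A"}), mode=SeedMode.NEIGHBORS_MUST_BE_DEGS)
    with pytest.raises(ValueError):
        SeedSpec(seed_genes=frozenset())


def test_star_center_depth2_is_fixed_point():
    net = star_network()
    d1 = first_neighbor_subnetwork(net, SeedSpec(seed_genes=frozenset({"Ywhae"})))
    d2 = expand_second_neighbors(
        net, SeedSpec(seed_genes=frozenset({"Ywhae"}), depth=2)
    )
    assert set(d1.graph.nodes) == set(d2.graph.nodes)


def test_path_depth2_stops_at_two_steps():
    net = nx.path_graph(["A", "B", "C", "D"])
    sub = expand_second_neighbors(net, SeedSpec(seed_genes=frozenset({"A"}), depth=2))
    assert set(sub.graph.nodes) == {"A", "B", "C"}


def test_depth2_induced_edges_included():
    net = nx.Graph([("A", "B"), ("B", "C"), ("C", "D"), ("B", "D")])
    sub = expand_second_neighbors(net, SeedSpec(seed_genes=frozenset({"A"}), depth=2))
    # C-D and B-D are parent edges among included nodes, kept by induction
    assert ("B", "D") in sub.graph.edges and ("C", "D") in sub.graph.edges


def test_degree_ranking_tie_break_and_k():
    g = nx.Graph()
    g.add_nodes_from(["B", "A", "C"])
    ranking = degree_ranking(g, k=10)
    assert [n for n, _ in ranking.entries] == ["A", "B", "C"]
    assert all(d == 0 for _, d in ranking.entries)
    with pytest.raises(ValueError):
        degree_ranking(g, k=0)


def test_role_partition_is_exhaustive_and_disjoint():
    rng = np.random.default_rng(0)
    net = nx.gnp_random_graph(30, 0.1, seed=4)
    net = nx.relabel_nodes(net, {i: f"N{i}" for i in net.nodes})
    seeds = frozenset(f"N{i}" for i in rng.choice(30, size=6, replace=False))
    spec = SeedSpec(seed_genes=seeds)
    sub = first_neighbor_subnetwork(net, spec)
    singles = sub.nodes_with_role("SINGLETON")
    connected = sub.nodes_with_role("SEED")
    assert singles | connected == spec.seed_genes
    assert not singles & connected
    assert singles == find_singletons(net, spec)


@pytest.mark.parametrize("trial", range(20))
def test_extraction_matches_brute_force_bfs(trial):
    """Node/edge sets equal an explicit breadth-first oracle on random graphs."""
    rng = np.random.default_rng(100 + trial)
    n = int(rng.integers(5, 50))
    net = nx.gnp_random_graph(n, float(rng.uniform(0.05, 0.3)), seed=int(rng.integers(1e6)))
    net = nx.relabel_nodes(net, {i: f"N{i}" for i in net.nodes})
    seeds = frozenset(
        f"N{i}" for i in rng.choice(n, size=int(rng.integers(1, max(2, n // 4))), replace=False)
    )
    spec1 = SeedSpec(seed_genes=seeds, depth=1)

    # oracle: one BFS step
    level1 = {p for s in seeds if s in net for p in net.neighbors(s)}
    sub1 = first_neighbor_subnetwork(net, spec1)
    assert set(sub1.graph.nodes) == seeds | level1
    expected_edges = {
        frozenset((s, p)) for s in seeds if s in net for p in net.neighbors(s)
        if p in level1 | seeds
    }
    assert {frozenset(e) for e in sub1.graph.edges} == expected_edges

    # oracle: two BFS steps, induced edges
    level2 = {q for p in level1 for q in net.neighbors(p)}
    members = seeds | level1 | level2
    sub2 = expand_second_neighbors(net, SeedSpec(seed_genes=seeds, depth=2))
    assert set(sub2.graph.nodes) == members
    induced = {
        frozenset(e) for e in net.subgraph(members & set(net.nodes)).edges()
    }
    assert {frozenset(e) for e in sub2.graph.edges} == induced
    assert set(sub1.graph.nodes) <= set(sub2.graph.nodes)

    # oracle: degree ranking by explicit count
    ranking = degree_ranking(sub2, k=sub2.graph.number_of_nodes())
    degrees = {node: sub2.graph.degree(node) for node in sub2.graph.nodes}
    assert all(degrees[node] == d for node, d in ranking.entries)
    ds = [d for _, d in ranking.entries]
    assert ds == sorted(ds, reverse=True)


def test_planted_singletons_recovered_from_bundle(bundle):
    directory, _ = bundle
    truth = json.loads((directory / "truth.json").read_text())
    records = fio.read_biogrid_tab(directory / "interactions_biogrid.txt")
    records += fio.read_mitab(directory / "interactions_intact.mitab")[0]
    from agingnet import filter_species, merge_interactomes

    records, _ = filter_species(records)
    net = merge_interactomes(records, "10090")
    term = json.loads((directory / "truth.json").read_text())["annotation_membership"][
        "immune_response"
    ]
    spec = SeedSpec(seed_genes=frozenset(term))
    singles = find_singletons(net, spec)
    assert frozenset(truth["singleton_genes"]) <= singles
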