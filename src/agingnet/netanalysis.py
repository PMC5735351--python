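"""Seeded subnetwork extraction, singleton detection, and hub ranking.

Two seeding modes mirror the two ways a differential-expression list can
meet an interactome:

* ``SEEDS_ARE_DEGS`` — the seeds themselves are the genes of interest
  (e.g. up-regulated immune-response genes) and every direct interaction
  partner is admitted;
* ``NEIGHBORS_MUST_BE_DEGS`` — the seeds are an annotation set (e.g.
  hippocampal-development genes) and only partners inside a supplied DEG
  universe are admitted.

Depth-1 subnetworks keep seed-incident edges only by default (a star
expansion, matching how such networks are usually displayed); depth-2
subnetworks default to the induced edge policy, keeping every parent edge
among included nodes. Seeds with no admitted partner — including seeds
absent from the interactome — are reported as singletons, not errors.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable

import networkx as nx

from .io import canonical_symbol

SEED = "SEED"
NEIGHBOR = "NEIGHBOR"
SINGLETON = "SINGLETON"


class SeedMode(str, Enum):
    SEEDS_ARE_DEGS = "SEEDS_ARE_DEGS"
    NEIGHBORS_MUST_BE_DEGS = "NEIGHBORS_MUST_BE_DEGS"


@dataclass
class SeedSpec:
    """How to seed a subnetwork extraction."""

    seed_genes: frozenset[str]
    mode: SeedMode = SeedMode.SEEDS_ARE_DEGS
    deg_universe: frozenset[str] | None = None
    depth: int = 1

    def __post_init__(self) -> None:
        self.seed_genes = frozenset(canonical_symbol(g) for g in self.seed_genes)
        if not self.seed_genes:
            raise ValueError("seed set must be non-empty")
        if self.depth not in (1, 2):
            raise ValueError("depth must be 1 or 2")
        if self.mode == SeedMode.NEIGHBORS_MUST_BE_DEGS:
            if self.deg_universe is None:
                raise ValueError("NEIGHBORS_MUST_BE_DEGS requires deg_universe")
            self.deg_universe = frozenset(
                canonical_symbol(g) for g in self.deg_universe
            )


@dataclass
class Subnetwork:
    """A seeded neighborhood graph with node roles and within-degree."""

    graph: nx.Graph  # node attrs: role, degree
    spec: SeedSpec
    parent_id: str | None = None

    def nodes_with_role(self, role: str) -> frozenset[str]:
        return frozenset(
            n for n, data in self.graph.nodes(data=True) if data["role"] == role
        )

    @property
    def singletons(self) -> frozenset[str]:
        return self.nodes_with_role(SINGLETON)


def _admitted(net: nx.Graph, node: str, spec: SeedSpec) -> set[str]:
    """Partners of ``node`` admitted under the seeding mode."""
    if node not in net:
        return set()
    partners = set(net.neighbors(node))
    if spec.mode == SeedMode.NEIGHBORS_MUST_BE_DEGS:
        partners &= spec.deg_universe | spec.seed_genes
    return partners


def first_neighbor_subnetwork(
    net: nx.Graph, spec: SeedSpec, induced: bool = False
) -> Subnetwork:
    """Extract the depth-1 neighborhood of the seeds.

    Node set = seeds plus admitted partners. Edge policy: seed-incident
    edges only unless ``induced`` is set. Seeds with no admitted partner
    keep role SINGLETON and degree 0.
    """
    sub = nx.Graph()
    neighbors: set[str] = set()
    for seed in sorted(spec.seed_genes):
        partners = _admitted(net, seed, spec)
        neighbors |= partners
        sub.add_node(seed)
        for p in sorted(partners):
            sub.add_edge(seed, p)
    neighbors -= spec.seed_genes

    if induced:
        members = set(sub.nodes)
        for a, b in net.subgraph(members & set(net.nodes)).edges():
            sub.add_edge(a, b)

    _assign_roles(sub, spec.seed_genes, neighbors)
    return Subnetwork(graph=sub, spec=spec)


def expand_second_neighbors(
    net: nx.Graph, spec: SeedSpec, induced: bool = True
) -> Subnetwork:
    """Depth-2 breadth-first closure of the seeds.

    The node set is every gene within two admitted steps of a seed; by
    default the subnetwork is induced — it keeps all parent-network edges
    among included nodes, so its edge count can exceed its node count.
    """
    first: set[str] = set()
    for seed in spec.seed_genes:
        first |= _admitted(net, seed, spec)
    second: set[str] = set()
    for node in first:
        second |= _admitted(net, node, spec)
    members = set(spec.seed_genes) | first | second

    sub = nx.Graph()
    sub.add_nodes_from(members)
    if induced:
        sub.add_edges_from(net.subgraph(members & set(net.nodes)).edges())
    else:
        for node in spec.seed_genes | first:
            for p in _admitted(net, node, spec):
                sub.add_edge(node, p)

    neighbors = members - spec.seed_genes
    _assign_roles(sub, spec.seed_genes, neighbors)
    return Subnetwork(graph=sub, spec=spec)


def extract_subnetwork(net: nx.Graph, spec: SeedSpec, induced: bool | None = None) -> Subnetwork:
    """Dispatch on spec.depth with each depth's default edge policy."""
    if spec.depth == 1:
        return first_neighbor_subnetwork(net, spec, induced=bool(induced))
    return expand_second_neighbors(net, spec, induced=True if induced is None else induced)


def _assign_roles(sub: nx.Graph, seeds: frozenset[str], neighbors: set[str]) -> None:
    for node in sub.nodes:
        if node in seeds:
            role = SEED if sub.degree(node) > 0 else SINGLETON
        else:
            role = NEIGHBOR
        sub.nodes[node]["role"] = role
        sub.nodes[node]["degree"] = sub.degree(node)


def find_singletons(net: nx.Graph, spec: SeedSpec) -> frozenset[str]:
    """Seeds whose admitted-partner set is empty (absent seeds included)."""
    return frozenset(
        seed for seed in spec.seed_genes if not _admitted(net, seed, spec)
    )


@dataclass
class DegreeRanking:
    """Top-k nodes of a (sub)network by link degree, ties by symbol."""

    entries: list[tuple[str, int]]
    k: int

    def top(self) -> str:
        return self.entries[0][0]


def degree_ranking(graph: nx.Graph | Subnetwork, k: int = 10) -> DegreeRanking:
    """Rank nodes by within-network degree, descending; ties break by
    ascending symbol for determinism. k beyond the node count returns all."""
    if k <= 0:
        raise ValueError("k must be positive")
    g = graph.graph if isinstance(graph, Subnetwork) else graph
    if g.number_of_nodes() == 0:
        raise ValueError("cannot rank an empty network")
    ranked = sorted(g.nodes, key=lambda n: (-g.degree(n), n))
    return DegreeRanking(entries=[(n, g.degree(n)) for n in ranked[:k]], k=k)
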