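"""Merge multi-source interaction records into one simple graph per species.

Records from different databases are keyed by their unordered canonical
gene-symbol pair; duplicate pairs collapse to a single edge whose
``sources`` attribute is the union of contributing databases. Only
intra-species records survive the species filter, and self-loops are
dropped (and counted) by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx

from .io import InteractionRecord, canonical_pair, canonical_symbol

HUMAN_TAXID = "9606"
MOUSE_TAXID = "10090"


@dataclass
class SpeciesFilterReport:
    kept: int = 0
    dropped_cross_species: int = 0
    dropped_other_taxa: int = 0


def filter_species(
    records: Iterable[InteractionRecord],
    taxids: Sequence[str] = (HUMAN_TAXID, MOUSE_TAXID),
) -> tuple[list[InteractionRecord], SpeciesFilterReport]:
    """Keep only within-species records for the requested taxa.

    Cross-species records (human-mouse and the like) are dropped, as are
    within-species records for taxa outside the requested set.
    """
    wanted = {str(t) for t in taxids}
    report = SpeciesFilterReport()
    kept: list[InteractionRecord] = []
    for rec in records:
        if not rec.intra_species:
            report.dropped_cross_species += 1
        elif rec.taxid_a not in wanted:
            report.dropped_other_taxa += 1
        else:
            kept.append(rec)
            report.kept += 1
    return kept, report


def merge_interactomes(
    records: Iterable[InteractionRecord],
    taxid: str,
    drop_self_loops: bool = True,
    evidence_filter=None,
) -> nx.Graph:
    """Merge records of one species into an undirected simple graph.

    Nodes are canonical (uppercase) gene symbols carrying their first-seen
    display form; edges carry the union of source databases, the evidence
    strings and pubmed ids of every contributing record. ``evidence_filter``
    is an optional predicate on records applied before merging.
    """
    net = nx.Graph(taxid=str(taxid), self_loops_removed=0, records_merged=0)
    for rec in records:
        if rec.taxid_a != str(taxid) or not rec.intra_species:
            continue
        if evidence_filter is not None and not evidence_filter(rec):
            continue
        a, b = canonical_pair(rec.symbol_a, rec.symbol_b)
        if a == b:
            if drop_self_loops:
                net.graph["self_loops_removed"] += 1
                continue
        for sym, display in ((a, rec.symbol_a), (b, rec.symbol_b)):
            if sym not in net:
                net.add_node(sym, display=display)
        if net.has_edge(a, b):
            data = net.edges[a, b]
            data["sources"].add(rec.source_db)
            if rec.evidence:
                data["evidence"].add(rec.evidence)
            if rec.pubmed_id:
                data["pubmed_ids"].add(rec.pubmed_id)
        else:
            net.add_edge(
                a,
                b,
                sources={rec.source_db},
                evidence={rec.evidence} if rec.evidence else set(),
                pubmed_ids={rec.pubmed_id} if rec.pubmed_id else set(),
            )
        net.graph["records_merged"] += 1
    return net


def merge_report(net: nx.Graph) -> dict:
    """Summary counts for a merged network, suitable for JSON export."""
    by_source: dict[str, int] = {}
    for _, _, data in net.edges(data=True):
        for src in data.get("sources", ()):
            by_source[src] = by_source.get(src, 0) + 1
    return {
        "taxid": net.graph.get("taxid"),
        "nodes": net.number_of_nodes(),
        "edges": net.number_of_edges(),
        "records_merged": net.graph.get("records_merged", 0),
        "self_loops_removed": net.graph.get("self_loops_removed", 0),
        "edges_by_source": by_source,
    }
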