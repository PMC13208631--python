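"""Age-filtered bipartite mineral-element networks.

Mineral nodes carry the locality count (node weight) and wMEE_CV (node
colour value); element nodes may be split by redox state ("Fe2+", "Fe3+",
"Fe0", or an "unknown" suffix when the state is unrecorded).  Edges are
unweighted mineral↔element incidences.  Community structure is found with
Louvain modularity maximisation, which treats mineral and element nodes
alike; layouts use the force-directed Fruchterman-Reingold algorithm.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx

from geocofactor.mineral_chem import MineralRecord

__all__ = [
    "CommunityPartition",
    "build_bipartite",
    "export_edge_list",
    "export_graphml",
    "filter_by_age",
    "layout_fr",
    "louvain_communities",
]


@dataclass(frozen=True)
class CommunityPartition:
    """Node→community assignment with its modularity score."""

    assignment: Mapping[str, int]
    modularity: float
    seed: int
    resolution: float


def filter_by_age(
    records: Sequence[MineralRecord], min_age_ga: float
) -> list[MineralRecord]:
    """Keep minerals whose maximum known age is strictly above the threshold.

    The strict inequality mirrors the ">2.5 Ga" / ">3.5 Ga" deep-time
    windows used to bracket the Archean record.
    """
    if min_age_ga < 0:
        raise ValueError("min_age_ga must be >= 0")
    return [r for r in records if r.max_age_ga > min_age_ga]


def _element_label(
    record: MineralRecord,
    element: str,
    split_by_redox: bool,
    redox_table: Mapping[tuple[str, str], str] | None,
) -> str:
    if not split_by_redox:
        return element
    state = "unknown"
    if redox_table is not None:
        state = redox_table.get((record.formula.name, element), "unknown")
    return f"{element}{state}" if state != "unknown" else f"{element}_unknown"


def build_bipartite(
    records: Iterable[MineralRecord],
    split_by_redox: bool = False,
    redox_table: Mapping[tuple[str, str], str] | None = None,
) -> nx.Graph:
    """Build the bipartite mineral-element incidence graph.

    One node per mineral species (attributes: ``type="mineral"``,
    ``weight`` = locality count, ``wmee_cv``) and one per element or
    element-redox label (``type="element"``).  A mineral node's degree is
    the number of distinct element(-redox) labels in its formula.

    ``redox_table`` maps ``(mineral_name, element)`` to a redox suffix such
    as ``"2+"``; missing pairs fall back to ``"unknown"``.
    """
    graph = nx.Graph()
    for rec in records:
        mineral = rec.formula.name
        graph.add_node(
            mineral,
            type="mineral",
            weight=rec.locality_count,
            wmee_cv=rec.wmee_cv,
            bipartite=0,
        )
        for element in rec.formula.counts:
            label = _element_label(rec, element, split_by_redox, redox_table)
            if label not in graph:
                graph.add_node(label, type="element", bipartite=1)
            graph.add_edge(mineral, label)
    return graph


def louvain_communities(
    graph: nx.Graph, seed: int = 1, resolution: float = 1.0
) -> CommunityPartition:
    """Louvain community detection over the full bipartite graph.

    Minerals and elements are partitioned together; no node-type
    distinction is made during modularity maximisation.  Deterministic for
    a fixed seed.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("graph is empty")
    communities = nx.community.louvain_communities(
        graph, seed=seed, resolution=resolution
    )
    assignment = {
        node: idx for idx, comm in enumerate(communities) for node in comm
    }
    mod = nx.community.modularity(graph, communities, resolution=resolution)
    return CommunityPartition(
        assignment=assignment, modularity=mod, seed=seed, resolution=resolution
    )


def layout_fr(graph: nx.Graph, seed: int = 1) -> dict[str, tuple[float, float]]:
    """Fruchterman-Reingold force-directed 2D layout (plotting only)."""
    if graph.number_of_nodes() == 0:
        raise ValueError("graph is empty")
    pos = nx.spring_layout(graph, seed=seed)
    return {node: (float(xy[0]), float(xy[1])) for node, xy in pos.items()}


def export_graphml(
    graph: nx.Graph,
    path,
    partition: CommunityPartition | None = None,
    positions: Mapping[str, tuple[float, float]] | None = None,
) -> None:
    """Write the graph (with optional community and layout attributes)."""
    out = graph.copy()
    if partition is not None:
        nx.set_node_attributes(out, dict(partition.assignment), "community")
    if positions is not None:
        nx.set_node_attributes(out, {n: p[0] for n, p in positions.items()}, "x")
        nx.set_node_attributes(out, {n: p[1] for n, p in positions.items()}, "y")
    nx.write_graphml(out, path)


def export_edge_list(graph: nx.Graph, path) -> None:
    """Write a TSV edge list with node-type annotation columns."""
    with open(path, "w") as fh:
        fh.write("source\ttarget\tsource_type\ttarget_type\n")
        for u, v in sorted(graph.edges()):
            fh.write(
                f"{u}\t{v}\t{graph.nodes[u]['type']}\t{graph.nodes[v]['type']}\n"
            )
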