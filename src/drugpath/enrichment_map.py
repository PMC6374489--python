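"""Pathway-interactome networks from enriched gene sets.

Nodes are FDR-passing gene sets (node size = member count after universe
intersection, attribution by the sign of the enrichment: positive NES ->
first group of the comparison, negative -> second).  An edge connects two
sets whose overlap coefficient |A n B| / min(|A|, |B|) reaches the cutoff
(default 0.05).  An "interactome" is a connected component of this graph;
it is *universal* when it mixes nodes attributed to different groups and
*group-specific* otherwise.  The headline summary is the fraction of
pathways (nodes) residing in universal interactomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import pandas as pd

DEFAULT_OVERLAP_CUTOFF = 0.05


def overlap_coefficient(a, b) -> float:
    """|A n B| / min(|A|, |B|); both sets must be non-empty."""
    sa, sb = set(a), set(b)
    if not sa or not sb:
        raise ValueError("overlap coefficient undefined for empty sets")
    return len(sa & sb) / min(len(sa), len(sb))


@dataclass
class InteractomeSummary:
    components: list[dict] = field(default_factory=list)
    universal_fraction: float = 0.0
    n_nodes: int = 0
    n_edges: int = 0


def build_network(
    results: pd.DataFrame,
    cutoff: float = DEFAULT_OVERLAP_CUTOFF,
    positive_group: str = "ESC/IPSC",
    negative_group: str = "AFSC",
) -> nx.Graph:
    """Threshold the all-pairs overlap-coefficient graph of enriched sets.

    ``results`` is an enrichment table (FDR-passing rows) carrying
    ``name``, ``size``, ``nes``, ``fdr_q`` and a comma-joined ``members``
    column holding each set's universe-intersected genes — the genes the
    enrichment was actually scored on.
    """
    g = nx.Graph()
    members: dict[str, set[str]] = {}
    for row in results.itertuples(index=False):
        mem = set(str(row.members).split(",")) if row.members else set()
        members[row.name] = mem
        group = positive_group if row.nes > 0 else negative_group
        g.add_node(
            row.name,
            size=int(row.size),
            nes=float(row.nes),
            fdr_q=float(row.fdr_q),
            group=group,
        )
    for a, b in combinations(sorted(members), 2):
        coeff = overlap_coefficient(members[a], members[b])
        if coeff >= cutoff:
            g.add_edge(a, b, overlap=coeff, shared_genes=len(members[a] & members[b]))
    return g


def classify_interactomes(g: nx.Graph) -> InteractomeSummary:
    """Label connected components universal vs group-specific.

    A component is universal iff it contains nodes attributed to at least
    two distinct groups.  The universal fraction counts nodes (pathways)
    in universal components over all nodes.
    """
    comps = []
    universal_nodes = 0
    for nodes in nx.connected_components(g):
        groups = set()
        for n in nodes:
            grp = g.nodes[n].get("group")
            if grp is None:
                raise ValueError(f"node {n!r} has no group attribution")
            groups.add(grp)
        label = "universal" if len(groups) >= 2 else f"group_specific:{next(iter(groups))}"
        if len(groups) >= 2:
            universal_nodes += len(nodes)
        comps.append(
            {"nodes": sorted(nodes), "label": label, "groups": sorted(groups)}
        )
    n = g.number_of_nodes()
    comps.sort(key=lambda c: (-len(c["nodes"]), c["nodes"]))
    return InteractomeSummary(
        components=comps,
        universal_fraction=universal_nodes / n if n else 0.0,
        n_nodes=n,
        n_edges=g.number_of_edges(),
    )


def write_graphml(g: nx.Graph, path) -> None:
    nx.write_graphml(g, path)


def write_sif(g: nx.Graph, path) -> None:
    """Simple interaction format: 'A overlaps B'; singletons on their own line."""
    with open(path, "w", encoding="utf-8") as fh:
        for a, b in sorted(g.edges):
            fh.write(f"{a}\toverlaps\t{b}\n")
        for n in sorted(g.nodes):
            if g.degree[n] == 0:
                fh.write(f"{n}\n")
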