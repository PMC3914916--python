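"""Assembly and export of the fungus-nifH association network.

Significant pair scores become a simple undirected graph in which every
edge involves at least one nifH MOTU (fungus-fungus pairs are dropped).
Nodes carry their kingdom and a substrate affiliation: a taxon is assigned
to the tree species carrying at least 75 % of its occurrences, otherwise it
is a substrate generalist.  Hubs are nodes of degree strictly greater than
10.  Edge widths encode the significance level, growing as p falls across
the displayed range 0.049 (thinnest) to 0.0017 (thickest).
"""

from __future__ import annotations

from io import StringIO

import networkx as nx
import pandas as pd

from .nullmodel import PairScore

__all__ = [
    "affiliation",
    "build_network",
    "annotate_affiliations",
    "hubs_and_degree",
    "subnetwork_summary",
    "export_network",
    "import_edge_tsv",
    "edge_width",
    "AFFILIATION_THRESHOLD",
    "HUB_THRESHOLD",
]

AFFILIATION_THRESHOLD = 0.75
HUB_THRESHOLD = 10

#: Significance range displayed by edge widths (thinnest, thickest).
WIDTH_P_RANGE = (0.049, 0.0017)
WIDTH_RANGE = (1.0, 5.0)


def affiliation(
    occurrences_by_species: dict[str, int],
    threshold: float = AFFILIATION_THRESHOLD,
) -> str:
    """Substrate affiliation of one taxon from its per-tree-species counts.

    Returns the species holding a share >= ``threshold`` of the taxon's
    occurrences (the exact threshold counts as affiliated), else
    ``"generalist"``.
    """
    total = sum(occurrences_by_species.values())
    if total <= 0:
        raise ValueError("taxon has zero occurrences; affiliation undefined")
    for species, count in occurrences_by_species.items():
        if count / total >= threshold:
            return species
    return "generalist"


def build_network(pair_scores: list[PairScore]) -> nx.Graph:
    """Graph of significant associations with at least one nifH endpoint.

    Keeps pairs classified co-occurrence or avoidance; fungus-fungus pairs
    are discarded.  An input without significant pairs yields an empty
    graph.  Edges carry ``sign``, ``z`` and ``p`` attributes; nodes carry
    ``kingdom``.
    """
    graph = nx.Graph()
    for score in pair_scores:
        if score.classification not in ("co-occurrence", "avoidance"):
            continue
        if "nifH" not in (score.kingdom_a, score.kingdom_b):
            continue
        graph.add_node(score.taxon_a, kingdom=score.kingdom_a)
        graph.add_node(score.taxon_b, kingdom=score.kingdom_b)
        graph.add_edge(
            score.taxon_a,
            score.taxon_b,
            sign=score.classification,
            z=score.z,
            p=score.p_two_sided,
        )
    return graph


def annotate_affiliations(
    graph: nx.Graph,
    counts_by_species: dict[str, dict[str, int]],
    threshold: float = AFFILIATION_THRESHOLD,
) -> nx.Graph:
    """Attach the substrate-affiliation label to every node in place."""
    for node in graph.nodes:
        counts = counts_by_species.get(node)
        if counts is None:
            raise KeyError(f"no occurrence counts for network node {node!r}")
        graph.nodes[node]["affiliation"] = affiliation(counts, threshold)
    return graph


def hubs_and_degree(
    graph: nx.Graph, hub_threshold: int = HUB_THRESHOLD
) -> tuple[list[str], float]:
    """Hub nodes (degree strictly greater than the threshold) and mean degree."""
    if graph.number_of_nodes() == 0:
        raise ValueError("network is empty")
    hubs = sorted(n for n, d in graph.degree if d > hub_threshold)
    mean_degree = 2 * graph.number_of_edges() / graph.number_of_nodes()
    return hubs, mean_degree


def subnetwork_summary(graph: nx.Graph) -> dict:
    """Edge counts within and between affiliation subnetworks.

    Returns per-(affiliation pair) positive (co-occurrence) and negative
    (avoidance) counts plus a flag for positive edges bridging the two
    tree-species subnetworks.
    """
    within: dict[tuple[str, str], dict[str, int]] = {}
    for u, v, attrs in graph.edges(data=True):
        a = graph.nodes[u].get("affiliation", "unannotated")
        b = graph.nodes[v].get("affiliation", "unannotated")
        key = tuple(sorted((a, b)))
        rec = within.setdefault(key, {"positive": 0, "negative": 0})
        rec["positive" if attrs["sign"] == "co-occurrence" else "negative"] += 1
    species_pairs = [
        key for key in within
        if key[0] != key[1] and "generalist" not in key and "unannotated" not in key
    ]
    bridges_positive = sum(within[k]["positive"] for k in species_pairs)
    return {
        "by_affiliation_pair": {f"{a}|{b}": v for (a, b), v in sorted(within.items())},
        "species_bridging_positive_edges": bridges_positive,
        "total_edges": graph.number_of_edges(),
    }


def edge_width(p: float) -> float:
    """Display width for significance ``p``: monotone decreasing in p.

    p at or above 0.049 maps to the minimum width, p at or below 0.0017 to
    the maximum.
    """
    p_thin, p_thick = WIDTH_P_RANGE
    w_min, w_max = WIDTH_RANGE
    p = min(max(p, p_thick), p_thin)
    return w_min + (w_max - w_min) * (p_thin - p) / (p_thin - p_thick)


def _node_table(graph: nx.Graph) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "taxon": n,
                "kingdom": graph.nodes[n].get("kingdom", ""),
                "affiliation": graph.nodes[n].get("affiliation", ""),
                "degree": graph.degree[n],
            }
            for n in sorted(graph.nodes)
        ],
        columns=["taxon", "kingdom", "affiliation", "degree"],
    )


def _edge_table(graph: nx.Graph) -> pd.DataFrame:
    rows = []
    for u, v, attrs in graph.edges(data=True):
        a, b = sorted((u, v))
        rows.append(
            {
                "taxon_a": a,
                "taxon_b": b,
                "sign": attrs["sign"],
                "z": attrs.get("z", float("nan")),
                "p": attrs.get("p", float("nan")),
                "width": edge_width(min(attrs.get("p", 0.05), 0.05)),
            }
        )
    return pd.DataFrame(
        sorted(rows, key=lambda r: (r["taxon_a"], r["taxon_b"])),
        columns=["taxon_a", "taxon_b", "sign", "z", "p", "width"],
    )


def export_network(graph: nx.Graph, path, fmt: str = "tsv") -> None:
    """Write the network as ``tsv`` (node+edge blocks), ``sif`` or ``graphml``.

    The TSV dialect round-trips losslessly through :func:`import_edge_tsv`.
    """
    path = str(path)
    if fmt == "tsv":
        nodes, edges = _node_table(graph), _edge_table(graph)
        with open(path, "w") as fh:
            fh.write("# nifhnet network v1\n# nodes\n")
            nodes.to_csv(fh, sep="\t", index=False)
            fh.write("# edges\n")
            edges.to_csv(fh, sep="\t", index=False)
    elif fmt == "sif":
        with open(path, "w") as fh:
            for _, row in _edge_table(graph).iterrows():
                fh.write(f"{row.taxon_a}\t{row.sign}\t{row.taxon_b}\n")
            for n in sorted(nx.isolates(graph)):
                fh.write(f"{n}\n")
    elif fmt == "graphml":
        annotated = graph.copy()
        for u, v in annotated.edges:
            annotated.edges[u, v]["width"] = edge_width(
                min(annotated.edges[u, v].get("p", 0.05), 0.05)
            )
        nx.write_graphml(annotated, path)
    else:
        raise ValueError(f"unsupported network format {fmt!r}")


def import_edge_tsv(path) -> nx.Graph:
    """Read a network written by :func:`export_network(..., fmt='tsv')`."""
    with open(path) as fh:
        text = fh.read()
    try:
        _, node_part = text.split("# nodes\n", 1)
        node_text, edge_text = node_part.split("# edges\n", 1)
    except ValueError as exc:
        raise ValueError(f"{path} is not a nifhnet network TSV") from exc
    graph = nx.Graph()
    nodes = pd.read_csv(StringIO(node_text), sep="\t")
    for _, row in nodes.iterrows():
        graph.add_node(
            row["taxon"],
            kingdom=row["kingdom"] if pd.notna(row["kingdom"]) else "",
            affiliation=row["affiliation"] if pd.notna(row["affiliation"]) else "",
        )
    edges = pd.read_csv(StringIO(edge_text), sep="\t")
    for _, row in edges.iterrows():
        graph.add_edge(
            row["taxon_a"], row["taxon_b"],
            sign=row["sign"], z=float(row["z"]), p=float(row["p"]),
        )
    return graph
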