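"""Gene-regulatory-network assembly and hub/bottleneck reduction.

The GRN merges three evidence layers over the DEG set: undirected
interactions (kept only between DEGs), directed TF->target regulon edges for
selected TFs, and directed oncogene ChIP edges for high-confidence
(-log10 p >= 300) promoter-bound targets.  The network is then reduced to
the induced subgraph on the union of top-ranked nodes by three topological
metrics computed on the undirected skeleton:

* MNC  - size of the largest connected component among a node's neighbors;
* DMNC - edge count of that component divided by its node count to the
  power epsilon (1.7);
* BottleNeck - the number of rooted shortest-path trees in which the node's
  subtree holds more than a quarter of the tree.
"""

from __future__ import annotations

import logging
from collections import deque

import networkx as nx
import numpy as np
import pandas as pd

from .config import NO_PATHWAY, ConfigurationError

log = logging.getLogger("stepgrn.network")

PROVENANCES = ("interaction", "regulon", "oncogene_chip")


# ---------------------------------------------------------------------------
# oncogene ChIP targets


def filter_oncogene_targets(
    peaks: pd.DataFrame,
    tss: pd.DataFrame,
    promoter_window: int = 1000,
    minlogp: float = 300.0,
) -> list[str]:
    """Genes whose TSS lies within ``promoter_window`` bp of a high-confidence
    oncogene ChIP peak summit (-log10 p >= minlogp), deduplicated."""
    if "neglog10_p" not in peaks.columns or peaks["neglog10_p"].isna().all():
        raise ConfigurationError("oncogene peak file lacks a -log10(p) column")
    confident = peaks[peaks["neglog10_p"] >= minlogp]
    if len(confident) == 0:
        return []
    summits = np.sort(confident["summit"].to_numpy(np.int64))
    positions = tss["tss"].to_numpy(np.int64)
    lo = np.searchsorted(summits, positions - promoter_window, side="left")
    hi = np.searchsorted(summits, positions + promoter_window, side="right")
    return sorted(tss.index[hi > lo])


# ---------------------------------------------------------------------------
# assembly


def assemble_grn(
    degs: pd.DataFrame,
    interactions,
    regulons: dict[str, list[str]],
    selected_tfs,
    oncogene: str | None = None,
    oncogene_targets=(),
    crm_catalog: pd.DataFrame | None = None,
) -> nx.MultiDiGraph:
    """Provenance-tagged multigraph over DEGs and selected TFs.

    Interaction edges (undirected, ``directed=False``) are kept only when
    both endpoints are DEGs; regulon edges are kept when the TF passed
    selection and the target is a DEG; oncogene edges run from the oncogene
    node to each in-network target.  Self-loops are dropped, duplicates
    within a provenance collapse, and the same pair may carry one edge per
    provenance.
    """
    deg_set = set(degs.index[degs["pathway"] != NO_PATHWAY])
    if not deg_set:
        log.warning("empty DEG set: assembling an empty network")
    tf_set = set(selected_tfs)
    graph = nx.MultiDiGraph()

    def add_node(node: str) -> None:
        if node in graph:
            return
        role = "gene"
        if crm_catalog is not None and node in crm_catalog.index:
            role = "CRM"
        if node in tf_set or node == oncogene:
            role = "TF"
        pathway = NO_PATHWAY
        r1 = r2 = np.nan
        if node in degs.index:
            pathway = degs.loc[node, "pathway"]
            r1 = float(degs.loc[node, "ratio_step1"])
            r2 = float(degs.loc[node, "ratio_step2"])
        graph.add_node(node, role=role, pathway=pathway,
                       ratio_step1=r1, ratio_step2=r2)

    seen: set[tuple] = set()

    for a, _rel, b in interactions:
        if a == b or a not in deg_set or b not in deg_set:
            continue
        key = ("interaction",) + tuple(sorted((a, b)))
        if key in seen:
            continue
        seen.add(key)
        add_node(a)
        add_node(b)
        graph.add_edge(key[1], key[2], provenance="interaction", directed=False)

    for tf in sorted(tf_set):
        for target in regulons.get(tf, []):
            if target == tf or target not in deg_set:
                continue
            key = ("regulon", tf, target)
            if key in seen:
                continue
            seen.add(key)
            add_node(tf)
            add_node(target)
            graph.add_edge(tf, target, provenance="regulon", directed=True)

    if oncogene:
        allowed = deg_set | tf_set
        for target in sorted(set(oncogene_targets)):
            if target == oncogene or target not in allowed:
                continue
            key = ("oncogene_chip", oncogene, target)
            if key in seen:
                continue
            seen.add(key)
            add_node(oncogene)
            add_node(target)
            graph.add_edge(oncogene, target, provenance="oncogene_chip", directed=True)

    return graph


def undirected_skeleton(graph: nx.MultiDiGraph) -> nx.Graph:
    """Simple undirected graph underlying the mixed multigraph (metrics are
    direction-blind)."""
    skeleton = nx.Graph()
    skeleton.add_nodes_from(graph.nodes)
    skeleton.add_edges_from((u, v) for u, v, _ in graph.edges(keys=True) if u != v)
    return skeleton


# ---------------------------------------------------------------------------
# topological metrics


def _neighborhood_components(graph: nx.Graph, node) -> list[set]:
    neighbors = set(graph.neighbors(node)) - {node}
    if not neighbors:
        return []
    induced = graph.subgraph(neighbors)
    return [set(c) for c in nx.connected_components(induced)]


def mnc(graph: nx.Graph, node) -> int:
    """Maximum Neighborhood Component: size of the largest connected
    component of the subgraph induced by the node's neighbors."""
    components = _neighborhood_components(graph, node)
    if not components:
        return 0
    return max(len(c) for c in components)


def dmnc(graph: nx.Graph, node, epsilon: float = 1.7) -> float:
    """Density of the Maximum Neighborhood Component: |E| / |V|**epsilon of
    the largest neighborhood component (ties broken by edge count); 0 when
    MNC <= 1."""
    components = _neighborhood_components(graph, node)
    if not components:
        return 0.0
    best = max(
        components,
        key=lambda c: (len(c), graph.subgraph(c).number_of_edges()),
    )
    if len(best) <= 1:
        return 0.0
    edges = graph.subgraph(best).number_of_edges()
    return edges / len(best) ** epsilon


def bottleneck_scores(graph: nx.Graph) -> dict:
    """BottleNeck score for every node.

    For each root of each connected component a breadth-first shortest-path
    tree is grown with deterministic sorted-neighbor ordering; a non-root
    node is a bottleneck of that tree when its subtree holds strictly more
    than a quarter of the tree's nodes.  A node's score is the number of
    roots for which it is a bottleneck.
    """
    adjacency = {node: sorted(graph.neighbors(node)) for node in graph.nodes}
    scores = {node: 0 for node in graph.nodes}
    for component in nx.connected_components(graph):
        nodes = sorted(component)
        threshold = len(nodes) / 4.0
        for root in nodes:
            parent = {root: None}
            order = [root]
            queue = deque([root])
            while queue:
                u = queue.popleft()
                for v in adjacency[u]:
                    if v not in parent:
                        parent[v] = u
                        order.append(v)
                        queue.append(v)
            subtree = {v: 1 for v in order}
            for v in reversed(order):
                if parent[v] is not None:
                    subtree[parent[v]] += subtree[v]
            for v in order:
                if v != root and subtree[v] > threshold:
                    scores[v] += 1
    return scores


def bottleneck_score(graph: nx.Graph, node) -> int:
    return bottleneck_scores(graph)[node]


def node_metrics(graph: nx.MultiDiGraph, epsilon: float = 1.7) -> pd.DataFrame:
    """MNC, DMNC, BottleNeck, and degree for every node (on the undirected
    skeleton)."""
    skeleton = undirected_skeleton(graph)
    bn = bottleneck_scores(skeleton)
    rows = []
    for node in sorted(skeleton.nodes):
        rows.append(
            (
                node,
                mnc(skeleton, node),
                dmnc(skeleton, node, epsilon),
                bn[node],
                skeleton.degree(node),
            )
        )
    out = pd.DataFrame(rows, columns=["node", "mnc", "dmnc", "bottleneck", "degree"])
    return out.set_index("node")


# ---------------------------------------------------------------------------
# reduction


def _top_k(metrics: pd.DataFrame, column: str, k: int) -> list:
    ranked = sorted(
        metrics.index,
        key=lambda node: (-metrics.at[node, column], -metrics.at[node, "degree"], node),
    )
    return ranked[:k]


def reduce_network(
    graph: nx.MultiDiGraph,
    metrics: pd.DataFrame,
    k_hubs: int = 8,
    k_bottlenecks: int = 6,
) -> nx.MultiDiGraph:
    """Induced subgraph on the union of top-k_hubs by MNC, top-k_hubs by
    DMNC, and top-k_bottlenecks by BottleNeck score.

    Ties break by degree then lexicographic node id.  Provenance-tagged
    edges between retained nodes are preserved.  A ``k`` exceeding the node
    count returns the full graph with a warning.
    """
    n = graph.number_of_nodes()
    if k_hubs >= n or k_bottlenecks >= n:
        log.warning("reduction k exceeds node count; returning full graph")
        return graph.copy()
    keep = set(_top_k(metrics, "mnc", k_hubs))
    keep |= set(_top_k(metrics, "dmnc", k_hubs))
    keep |= set(_top_k(metrics, "bottleneck", k_bottlenecks))
    return graph.subgraph(keep).copy()


# ---------------------------------------------------------------------------
# export


def export_grn(graph: nx.MultiDiGraph, sif_path, nodes_path, edges_path=None) -> None:
    """SIF edge file plus node (and optional edge) attribute tables.

    Nodes carry their pathway segment, per-step expression ratios, and role,
    so the export loads directly into standard graph-visualization tools.
    """
    edges = sorted(
        (u, data["provenance"], v, data["directed"])
        for u, v, data in graph.edges(data=True)
    )
    with open(sif_path, "w") as fh:
        for u, provenance, v, _directed in edges:
            fh.write(f"{u}\t{provenance}\t{v}\n")
    rows = []
    for node in sorted(graph.nodes):
        data = graph.nodes[node]
        rows.append(
            (node, data.get("role", "gene"), data.get("pathway", NO_PATHWAY),
             data.get("ratio_step1", np.nan), data.get("ratio_step2", np.nan))
        )
    pd.DataFrame(
        rows, columns=["node", "role", "segment", "ratio_step1", "ratio_step2"]
    ).to_csv(nodes_path, sep="\t", index=False, float_format="%.6g")
    if edges_path is not None:
        pd.DataFrame(
            edges, columns=["source", "provenance", "target", "directed"]
        ).to_csv(edges_path, sep="\t", index=False)
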