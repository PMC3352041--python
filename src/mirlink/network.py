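"""Multipartite regulatory graph, degree-constrained subnetwork selection,
and viewer-oriented helpers.

The graph is r-partite over three vertex classes — miRNAs, genes (mRNAs)
and an optional disease vertex — with edges only between classes.  Only
deregulated miRNAs that have at least one deregulated predicted target are
admitted, and only those deregulated targets: the joint-deregulation core of
the data.  Node attributes carry what a viewer needs to reproduce the usual
drawing conventions (shape by ``node_class``, colour by ``regulation``,
size by ``degree``).
"""

from __future__ import annotations

import logging
import urllib.parse
from dataclasses import dataclass

import networkx as nx

from .io_formats import GENE, MIRNA, DeregulationSet, InteractionTable

logger = logging.getLogger(__name__)

NODE_CLASS_MIRNA = "miRNA"
NODE_CLASS_GENE = "gene"
NODE_CLASS_DISEASE = "disease"

PUBMED_BASE = "https://pubmed.ncbi.nlm.nih.gov/?term="


def _recompute_degrees(graph: nx.Graph) -> None:
    """Set each node's ``degree`` attribute to its count of miRNA-gene edges."""
    for node in graph.nodes:
        deg = 0
        for nbr in graph.neighbors(node):
            classes = {graph.nodes[node]["node_class"], graph.nodes[nbr]["node_class"]}
            if classes == {NODE_CLASS_MIRNA, NODE_CLASS_GENE}:
                deg += 1
        graph.nodes[node]["degree"] = deg


def assert_multipartite(graph: nx.Graph) -> None:
    """Raise if any edge joins two vertices of the same class."""
    for u, v in graph.edges:
        if graph.nodes[u]["node_class"] == graph.nodes[v]["node_class"]:
            raise AssertionError(
                f"edge ({u}, {v}) joins two {graph.nodes[u]['node_class']} vertices"
            )


def build_graph(
    mir_dereg: DeregulationSet,
    gene_dereg: DeregulationSet,
    interactions: InteractionTable,
    disease: str | None = None,
) -> nx.Graph:
    """Build the regulatory graph over the jointly deregulated core.

    miRNA vertices are the deregulated miRNAs with at least one deregulated
    target; gene vertices are those deregulated targets; edges are the
    corresponding interaction pairs.  When ``disease`` is given, one disease
    vertex is connected to every miRNA and gene vertex.  The empty graph is
    valid (e.g. no deregulated genes).
    """
    if mir_dereg.entity_class != MIRNA or gene_dereg.entity_class != GENE:
        raise TypeError("expected a miRNA deregulation set and a gene deregulation set")
    graph = nx.Graph()
    dereg_mirs = mir_dereg.ids()
    dereg_genes = gene_dereg.ids()
    edges = [
        (m, g)
        for m, g in interactions.pair_keys()
        if m in dereg_mirs and g in dereg_genes
    ]
    for m, g in edges:
        if m not in graph:
            graph.add_node(
                m, node_class=NODE_CLASS_MIRNA, regulation=mir_dereg.direction_of(m)
            )
        if g not in graph:
            graph.add_node(
                g, node_class=NODE_CLASS_GENE, regulation=gene_dereg.direction_of(g)
            )
        graph.add_edge(m, g, interaction="targets")
    if disease is not None:
        if not disease.strip():
            raise ValueError("disease label must be non-empty when given")
        if disease in graph:
            raise ValueError(f"disease label {disease!r} collides with a node id")
        partners = list(graph.nodes)
        graph.add_node(disease, node_class=NODE_CLASS_DISEASE, regulation=0)
        for node in partners:
            graph.add_edge(disease, node, interaction="associated_with")
    _recompute_degrees(graph)
    assert_multipartite(graph)
    return graph


def mirna_nodes(graph: nx.Graph) -> frozenset[str]:
    return frozenset(
        n for n, d in graph.nodes(data=True) if d["node_class"] == NODE_CLASS_MIRNA
    )


def gene_nodes(graph: nx.Graph) -> frozenset[str]:
    return frozenset(
        n for n, d in graph.nodes(data=True) if d["node_class"] == NODE_CLASS_GENE
    )


@dataclass(frozen=True)
class SubnetworkSelection:
    """Result of choosing miRNAs and applying the degree constraint ``k``.

    ``genes`` are the gene vertices adjacent to at least ``k`` of the chosen
    miRNAs; chosen miRNAs none of whose targets survive are dropped from
    ``retained_mirnas`` (and from the drawing).  ``graph`` is the induced
    subgraph with degrees recomputed; ``selection_degree`` on gene nodes
    counts adjacency to the chosen miRNAs only.
    """

    chosen_mirnas: frozenset[str]
    degree_constraint: int
    genes: frozenset[str]
    retained_mirnas: frozenset[str]
    graph: nx.Graph


def select_subnetwork(
    graph: nx.Graph, chosen_mirnas: set[str] | frozenset[str], k: int = 1
) -> SubnetworkSelection:
    """Keep genes targeted by >= k of the chosen miRNAs, plus those miRNAs.

    The degree used for the constraint is counted over the chosen miRNAs
    only, not over all miRNAs in the graph.
    """
    if k < 1:
        raise ValueError("degree constraint k must be >= 1")
    chosen = frozenset(m.lower() for m in chosen_mirnas)
    known = mirna_nodes(graph)
    unknown = sorted(chosen - known)
    if unknown:
        raise KeyError(f"unknown miRNA ids in selection: {unknown}")
    genes: set[str] = set()
    selection_degree: dict[str, int] = {}
    for g in gene_nodes(graph):
        deg = sum(1 for nbr in graph.neighbors(g) if nbr in chosen)
        if deg >= k:
            genes.add(g)
            selection_degree[g] = deg
    retained = frozenset(
        m for m in chosen if any(nbr in genes for nbr in graph.neighbors(m))
    )
    keep = retained | genes
    disease = [
        n for n, d in graph.nodes(data=True) if d["node_class"] == NODE_CLASS_DISEASE
    ]
    sub = graph.subgraph(keep | set(disease)).copy()
    _recompute_degrees(sub)
    for g, deg in selection_degree.items():
        sub.nodes[g]["selection_degree"] = deg
    assert_multipartite(sub)
    return SubnetworkSelection(
        chosen_mirnas=chosen,
        degree_constraint=k,
        genes=frozenset(genes),
        retained_mirnas=retained,
        graph=sub,
    )


def rank_mirnas_by_dereg_targets(graph: nx.Graph) -> list[tuple[str, int]]:
    """miRNAs with their deregulated-target counts, most targets first;
    ties break lexicographically by id."""
    genes = gene_nodes(graph)
    counts = [
        (m, sum(1 for nbr in graph.neighbors(m) if nbr in genes))
        for m in mirna_nodes(graph)
    ]
    counts.sort(key=lambda item: (-item[1], item[0]))
    return counts


def subnetwork_gene_list(selection: SubnetworkSelection) -> list[str]:
    """Sorted gene list of the selection, ready for the focused ORA."""
    if not selection.genes:
        logger.warning("subnetwork selection contains no genes")
    return sorted(selection.genes)


def write_gene_list(genes: list[str], path) -> None:
    with open(path, "w") as handle:
        for gene in genes:
            handle.write(gene + "\n")


def pubmed_query(
    entities: list[str], disease: str, mode: str = "inclusive"
) -> str:
    """Build a PubMed search URL for the selected entities and the disease.

    ``inclusive`` joins entity terms with OR (papers mentioning any of them),
    ``exclusive`` with AND (papers mentioning all); either clause is then
    AND-combined with the disease term.  No network call is made.
    """
    if not disease or not disease.strip():
        raise ValueError("disease must be non-empty")
    if not entities:
        raise ValueError("need at least one entity")
    if mode not in ("inclusive", "exclusive"):
        raise ValueError(f"mode must be 'inclusive' or 'exclusive', got {mode!r}")
    joiner = " OR " if mode == "inclusive" else " AND "
    term = "(" + joiner.join(entities) + ") AND " + disease.strip()
    return PUBMED_BASE + urllib.parse.quote_plus(term)
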