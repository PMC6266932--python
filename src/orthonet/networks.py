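"""Ortholog/paralog gene networks and species-specific gene classification.

Genes of the two species become nodes of one undirected graph whose edges
are orthology relationships (cross-species) and stringent paralogy edges
(within-species).  Connected components of this graph are the gene
networks: each one groups a putative gene family across the two genomes.
Components are binned by size — two-gene networks (one ortholog pair
without retained duplicates), small (3-9 genes) and large (>= 10).

Genes outside every network and without even loose similarity to an
ortholog are species-specific; among those, genes sharing stringent edges
form species-specific families, the rest are singletons.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .orthology import OrthologyRelation
from .paralogy import ParalogEdge, ThresholdClass, filter_edges

__all__ = [
    "GeneNetwork",
    "SpecificityClass",
    "build_network",
    "connected_components",
    "network_stats",
    "classify_species_specific",
    "specific_family_networks",
    "write_networks",
    "write_specificity",
]

Node = tuple[str, str]  # (species label, gene id)


class SpecificityClass(enum.Enum):
    """Mutually exclusive classes partitioning a species' gene universe."""

    ORTHOLOG = "ortholog"
    PARALOG_OF_ORTHOLOG = "paralog_of_ortholog"
    LOOSE_SIMILAR_TO_ORTHOLOG = "loose_similar_to_ortholog"
    SPECIFIC_FAMILY_MEMBER = "specific_family_member"
    SPECIFIC_SINGLETON = "specific_singleton"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass
class GeneNetwork:
    """One connected component of the ortholog/paralog graph."""

    network_id: int
    nodes: frozenset[Node]
    orthology_edges: list[OrthologyRelation] = field(default_factory=list)
    paralogy_edges: list[ParalogEdge] = field(default_factory=list)

    @property
    def size_class(self) -> str:
        n = len(self.nodes)
        if n == 2:
            return "TWO_GENE"
        if n <= 9:
            return "SMALL"
        return "LARGE"

    def species_count(self, species: str) -> int:
        return sum(1 for sp, _ in self.nodes if sp == species)


def build_network(
    relations: Iterable[OrthologyRelation],
    paralog_edges: Iterable[ParalogEdge],
    species_a: str,
    species_b: str,
    threshold_class: ThresholdClass = ThresholdClass.STRINGENT,
) -> nx.Graph:
    """Assemble the typed graph from orthology and paralogy edges.

    One edge per gene pair; the edge attribute ``edge_type`` is
    ``"orthology"`` or ``"paralogy"`` and ``levels`` carries the confirming
    sequence levels.  Paralogy edges are filtered to the requested threshold
    class first.  Orthology edges must span the two species.
    """
    if species_a == species_b:
        raise ValueError("orthology edges require two distinct species labels")
    graph = nx.Graph()
    for rel in relations:
        u: Node = (species_a, rel.gene_a)
        v: Node = (species_b, rel.gene_b)
        graph.add_edge(u, v, edge_type="orthology", levels=rel.levels, relation=rel)
    for edge in filter_edges(paralog_edges, threshold_class):
        u = (edge.species, edge.gene_a)
        v = (edge.species, edge.gene_b)
        if graph.has_edge(u, v):
            continue  # orthology typing wins; cannot occur across species
        graph.add_edge(u, v, edge_type="paralogy", levels=edge.levels, edge=edge)
    return graph


def connected_components(graph: nx.Graph) -> list[GeneNetwork]:
    """Partition the graph into gene networks with stable, deterministic ids.

    Components are numbered by (size descending, smallest gene id) so that
    repeated runs on the same input produce identical network ids.
    """
    comps = sorted(
        (sorted(c) for c in nx.connected_components(graph)),
        key=lambda nodes: (-len(nodes), min(g for _, g in nodes)),
    )
    networks: list[GeneNetwork] = []
    for idx, nodes in enumerate(comps, start=1):
        sub = graph.subgraph(nodes)
        orth = [
            d["relation"]
            for _, _, d in sub.edges(data=True)
            if d["edge_type"] == "orthology"
        ]
        para = [
            d["edge"]
            for _, _, d in sub.edges(data=True)
            if d["edge_type"] == "paralogy"
        ]
        networks.append(
            GeneNetwork(
                network_id=idx,
                nodes=frozenset(nodes),
                orthology_edges=orth,
                paralogy_edges=para,
            )
        )
    return networks


def network_stats(
    networks: Sequence[GeneNetwork], species_a: str, species_b: str
) -> dict:
    """Summary statistics of a network collection.

    Reports node/edge totals split by species and edge type, component
    counts per size class, and the largest component's ("big network")
    breakdown, plus per-network BBH counts for size-vs-content plots.
    """
    totals = {
        "total_networks": len(networks),
        "total_nodes": sum(len(n.nodes) for n in networks),
        "total_edges": sum(
            len(n.orthology_edges) + len(n.paralogy_edges) for n in networks
        ),
        "orthology_edges": sum(len(n.orthology_edges) for n in networks),
        "paralogy_edges": sum(len(n.paralogy_edges) for n in networks),
        f"{species_a}_nodes": sum(n.species_count(species_a) for n in networks),
        f"{species_b}_nodes": sum(n.species_count(species_b) for n in networks),
        "two_gene_networks": sum(1 for n in networks if n.size_class == "TWO_GENE"),
        "small_networks": sum(1 for n in networks if n.size_class == "SMALL"),
        "large_networks": sum(1 for n in networks if n.size_class == "LARGE"),
        "bbh_per_network": {
            n.network_id: len(n.orthology_edges) for n in networks
        },
    }
    if networks:
        big = max(networks, key=lambda n: len(n.nodes))
        totals["big_network"] = {
            "network_id": big.network_id,
            "nodes": len(big.nodes),
            "edges": len(big.orthology_edges) + len(big.paralogy_edges),
            f"{species_a}_nodes": big.species_count(species_a),
            f"{species_b}_nodes": big.species_count(species_b),
        }
    else:
        totals["big_network"] = None
    return totals


def _components_map(genes: set[str], edges: Iterable[ParalogEdge]) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(genes)
    for e in edges:
        g.add_edge(e.gene_a, e.gene_b)
    return g


def classify_species_specific(
    universe: set[str],
    relations: Iterable[OrthologyRelation],
    species_side: str,
    loose_edges: Iterable[ParalogEdge],
    stringent_edges: Iterable[ParalogEdge] | None = None,
) -> dict[str, SpecificityClass]:
    """Assign every gene of one species to exactly one specificity class.

    Order of precedence per gene:

    1. ORTHOLOG — takes part in >= 1 orthology relation;
    2. PARALOG_OF_ORTHOLOG — connected to an ortholog through stringent
       (1e-50) paralogy edges, directly or transitively;
    3. LOOSE_SIMILAR_TO_ORTHOLOG — connected to an ortholog through loose
       (1e-3) edges;
    4. species-specific otherwise: SPECIFIC_FAMILY_MEMBER when it shares a
       stringent edge with another species-specific gene, else
       SPECIFIC_SINGLETON.

    ``species_side`` is "a" or "b": which end of the relations belongs to
    this species.  Both closures are transitive so the specific set is
    exactly the complement of the loose graph's ortholog-containing
    components.
    """
    if species_side not in ("a", "b"):
        raise ValueError("species_side must be 'a' or 'b'")
    loose_edges = set(loose_edges)
    stringent_edges = (
        set(stringent_edges)
        if stringent_edges is not None
        else filter_edges(loose_edges, ThresholdClass.STRINGENT)
    )
    orthologs = {
        (rel.gene_a if species_side == "a" else rel.gene_b) for rel in relations
    }
    stale = orthologs - universe
    edge_genes = {g for e in loose_edges for g in e.pair()}
    stale |= edge_genes - universe
    if stale:
        raise ValueError(
            f"genes in relations/edges missing from universe (stale locus map): "
            + ", ".join(sorted(stale)[:10])
        )

    stringent_graph = _components_map(universe, stringent_edges)
    loose_graph = _components_map(universe, loose_edges)

    stringent_linked: set[str] = set()
    for comp in nx.connected_components(stringent_graph):
        if comp & orthologs:
            stringent_linked |= comp
    loose_linked: set[str] = set()
    for comp in nx.connected_components(loose_graph):
        if comp & orthologs:
            loose_linked |= comp

    specific = universe - loose_linked - orthologs
    specific_family: set[str] = set()
    for e in stringent_edges:
        if e.gene_a in specific and e.gene_b in specific:
            specific_family.update(e.pair())

    out: dict[str, SpecificityClass] = {}
    for gene in universe:
        if gene in orthologs:
            out[gene] = SpecificityClass.ORTHOLOG
        elif gene in stringent_linked:
            out[gene] = SpecificityClass.PARALOG_OF_ORTHOLOG
        elif gene in loose_linked:
            out[gene] = SpecificityClass.LOOSE_SIMILAR_TO_ORTHOLOG
        elif gene in specific_family:
            out[gene] = SpecificityClass.SPECIFIC_FAMILY_MEMBER
        else:
            out[gene] = SpecificityClass.SPECIFIC_SINGLETON
    return out


def specific_family_networks(
    classes: Mapping[str, SpecificityClass],
    edges: Iterable[ParalogEdge],
    threshold_class: ThresholdClass = ThresholdClass.STRINGENT,
) -> list[set[str]]:
    """Connected families among species-specific genes at the given threshold.

    Family membership at 1e-50 vs 1e-3 gives different counts; both
    conventions are reachable through ``threshold_class``.
    """
    specific = {
        g
        for g, c in classes.items()
        if c
        in (
            SpecificityClass.SPECIFIC_FAMILY_MEMBER,
            SpecificityClass.SPECIFIC_SINGLETON,
        )
    }
    g = nx.Graph()
    for e in filter_edges(edges, threshold_class):
        if e.gene_a in specific and e.gene_b in specific:
            g.add_edge(e.gene_a, e.gene_b)
    return [set(c) for c in nx.connected_components(g)]


def write_networks(
    networks: Sequence[GeneNetwork],
    nodes_path: str | Path,
    edges_path: str | Path,
    tool_version: str = "orthonet",
) -> None:
    with open(nodes_path, "w") as handle:
        handle.write(f"# gene\tnetwork_id\tspecies\t[{tool_version}]\n")
        for net in networks:
            for species, gene in sorted(net.nodes, key=lambda n: n[1]):
                handle.write(f"{gene}\t{net.network_id}\t{species}\n")
    lvl_order = ("gene", "transcript", "protein")
    with open(edges_path, "w") as handle:
        handle.write(f"# gene_a\tgene_b\tedge_type\tlevels\t[{tool_version}]\n")
        for net in networks:
            rows = [
                (r.gene_a, r.gene_b, "orthology", r.levels)
                for r in net.orthology_edges
            ] + [
                (e.gene_a, e.gene_b, "paralogy", e.levels)
                for e in net.paralogy_edges
            ]
            for a, b, etype, levels in sorted(rows):
                lv = ",".join(l for l in lvl_order if any(x.value == l for x in levels))
                handle.write(f"{a}\t{b}\t{etype}\t{lv}\n")


def write_specificity(
    classes_by_species: Mapping[str, Mapping[str, SpecificityClass]],
    path: str | Path,
    tool_version: str = "orthonet",
) -> None:
    with open(path, "w") as handle:
        handle.write(f"# gene\tspecies\tclass\t[{tool_version}]\n")
        for species in sorted(classes_by_species):
            for gene in sorted(classes_by_species[species]):
                handle.write(
                    f"{gene}\t{species}\t{classes_by_species[species][gene].value}\n"
                )
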