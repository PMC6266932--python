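"""Within-species paralogy edges at stringent and loose e-value thresholds.

Paralogs are genes of one species related by duplication; they are detected
from all-against-all similarity searches within the species, again at the
gene, transcript and protein level.  A stringent 1e-50 threshold defines
the paralog families used in network construction (it maximises the number
of distinct families); the loose 1e-3 threshold catches any residual
similarity and is used to veto species specificity.  An edge confirmed by
any single level counts (union semantics across levels).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .io import SequenceLevel, SimilarityHit

__all__ = [
    "ThresholdClass",
    "ParalogEdge",
    "within_species_edges",
    "filter_edges",
    "paralogs_of_orthologs",
    "write_paralogs",
]


class ThresholdClass(enum.Enum):
    STRINGENT = "stringent"
    LOOSE = "loose"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class ParalogEdge:
    """An undirected within-species similarity edge between two gene loci.

    ``threshold_class`` is the tightest class the edge passes: STRINGENT
    edges (best e-value <= stringent cut-off) are by construction a subset
    of the loose edge set.  ``levels`` records every sequence level with a
    qualifying hit.
    """

    species: str
    gene_a: str
    gene_b: str
    levels: frozenset[SequenceLevel]
    threshold_class: ThresholdClass
    best_score: float

    def __post_init__(self) -> None:
        if self.gene_a >= self.gene_b:
            raise ValueError("edges are canonical: gene_a < gene_b required")
        if not self.levels:
            raise ValueError("edge must be confirmed at >= 1 level")

    def pair(self) -> tuple[str, str]:
        return (self.gene_a, self.gene_b)


def within_species_edges(
    hits_by_level: Mapping[SequenceLevel, Sequence[SimilarityHit]],
    species: str,
    stringent_evalue: float = 1e-50,
    loose_evalue: float = 1e-3,
) -> set[ParalogEdge]:
    """Build the paralogy edge set of one species in a single pass.

    Hits must be gene-collapsed and within one species; self-pairs are
    dropped.  Every gene pair with a hit at e-value <= loose cut-off gets an
    edge; its class is STRINGENT when some hit also passes the stringent
    cut-off.  Both directions of the all-vs-all search fold onto one
    canonical (lexicographically ordered) edge, so the result is independent
    of input row order.
    """
    if stringent_evalue > loose_evalue:
        raise ValueError("stringent threshold must be <= loose threshold")
    acc: dict[tuple[str, str], dict] = {}
    for level, hits in hits_by_level.items():
        for hit in hits:
            if hit.query_id == hit.subject_id:
                continue
            if hit.e_value > loose_evalue:
                continue
            a, b = sorted((hit.query_id, hit.subject_id))
            rec = acc.setdefault(
                (a, b), {"levels": set(), "score": hit.bit_score, "stringent": False}
            )
            rec["levels"].add(level)
            rec["score"] = max(rec["score"], hit.bit_score)
            if hit.e_value <= stringent_evalue:
                rec["stringent"] = True
    return {
        ParalogEdge(
            species=species,
            gene_a=a,
            gene_b=b,
            levels=frozenset(rec["levels"]),
            threshold_class=(
                ThresholdClass.STRINGENT if rec["stringent"] else ThresholdClass.LOOSE
            ),
            best_score=rec["score"],
        )
        for (a, b), rec in acc.items()
    }


def filter_edges(
    edges: Iterable[ParalogEdge], threshold_class: ThresholdClass
) -> set[ParalogEdge]:
    """Edges usable at the requested class (STRINGENT keeps only stringent;
    LOOSE keeps all, since stringent edges also pass the loose threshold)."""
    if threshold_class is ThresholdClass.LOOSE:
        return set(edges)
    return {e for e in edges if e.threshold_class is ThresholdClass.STRINGENT}


def paralogs_of_orthologs(
    edges: Iterable[ParalogEdge], ortholog_genes: set[str]
) -> set[str]:
    """Genes outside the ortholog set sharing a direct edge with an ortholog.

    Only direct neighbours; genes reached transitively join the family via
    the network module's connected components.
    """
    out: set[str] = set()
    for edge in edges:
        if edge.gene_a in ortholog_genes and edge.gene_b not in ortholog_genes:
            out.add(edge.gene_b)
        elif edge.gene_b in ortholog_genes and edge.gene_a not in ortholog_genes:
            out.add(edge.gene_a)
    return out


def write_paralogs(
    edges: Iterable[ParalogEdge], path: str | Path, tool_version: str = "orthonet"
) -> None:
    with open(path, "w") as handle:
        handle.write(
            f"# gene_a\tgene_b\tlevels\tthreshold_class\tbest_score\t[{tool_version}]\n"
        )
        for e in sorted(edges, key=lambda e: e.pair()):
            levels = ",".join(
                lvl.value
                for lvl in (
                    SequenceLevel.GENE,
                    SequenceLevel.TRANSCRIPT,
                    SequenceLevel.PROTEIN,
                )
                if lvl in e.levels
            )
            handle.write(
                f"{e.gene_a}\t{e.gene_b}\t{levels}\t"
                f"{e.threshold_class.value}\t{e.best_score:g}\n"
            )
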