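"""Bidirectional best hits and the multilevel consensus of ortholog pairs.

Orthologs between two species are called as Bidirectional Best Hits (BBH):
gene ``a`` of species A and gene ``b`` of species B are putative orthologs
when ``b`` attains the highest alignment score among all of ``a``'s hits in
B, and reciprocally ``a`` is the best hit of ``b`` in A.  Score ties are
kept: if several subjects attain a query's maximal score, every reciprocal
pair enters the ortholog list, so a single gene can take part in several
relationships.

The comparison is run independently at the gene (genomic locus), transcript
and protein level; a relationship confirmed by all three is a *consensus*
ortholog, the most reliable class.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .io import SequenceLevel, SimilarityHit

__all__ = [
    "OrthologyRelation",
    "best_hits",
    "bidirectional_best_hits",
    "multilevel_consensus",
    "locus_participation",
    "venn_regions",
    "write_orthologs",
]

LEVELS = (SequenceLevel.GENE, SequenceLevel.TRANSCRIPT, SequenceLevel.PROTEIN)


@dataclass(frozen=True)
class OrthologyRelation:
    """A cross-species gene pair with the levels confirming it as a BBH.

    ``gene_a`` belongs to species A (the query side of the forward search),
    ``gene_b`` to species B.  ``per_level_score`` holds the forward-direction
    best bit score at each confirming level.
    """

    gene_a: str
    gene_b: str
    levels: frozenset[SequenceLevel]
    per_level_score: Mapping[SequenceLevel, float]

    def __post_init__(self) -> None:
        if not self.levels:
            raise ValueError("relation must be confirmed at >= 1 level")

    @property
    def consensus(self) -> bool:
        """True when confirmed independently at gene, transcript and protein level."""
        return len(self.levels) == 3

    def pair(self) -> tuple[str, str]:
        return (self.gene_a, self.gene_b)


def pair_scores(hits: Sequence[SimilarityHit]) -> dict[tuple[str, str], float]:
    """Best bit score per (query gene, subject gene) pair.

    Multiple HSPs and multiple isoform combinations of the same locus pair
    are reduced to the maximum single-hit bit score, the ranking key for
    best-hit selection.
    """
    scores: dict[tuple[str, str], float] = {}
    for hit in hits:
        key = hit.pair()
        if key not in scores or hit.bit_score > scores[key]:
            scores[key] = hit.bit_score
    return scores


def best_hits(hits: Sequence[SimilarityHit]) -> dict[str, set[str]]:
    """Per query gene, every subject gene attaining the maximal pair score.

    Ties are all retained.  Queries without hits are absent from the map.
    Input must already be e-value filtered and collapsed to gene loci.
    """
    scores = pair_scores(hits)
    best: dict[str, tuple[float, set[str]]] = {}
    for (query, subject), score in scores.items():
        cur = best.get(query)
        if cur is None or score > cur[0]:
            best[query] = (score, {subject})
        elif score == cur[0]:
            cur[1].add(subject)
    return {q: subs for q, (_, subs) in best.items()}


def bidirectional_best_hits(
    forward: Mapping[str, set[str]], reverse: Mapping[str, set[str]]
) -> set[tuple[str, str]]:
    """Reciprocal pairs: (a, b) with b a best hit of a and a a best hit of b."""
    pairs: set[tuple[str, str]] = set()
    for a, subjects in forward.items():
        for b in subjects:
            if a in reverse.get(b, ()):
                pairs.add((a, b))
    return pairs


def multilevel_consensus(
    bbh_by_level: Mapping[SequenceLevel, set[tuple[str, str]]],
    scores_by_level: Mapping[SequenceLevel, Mapping[tuple[str, str], float]] | None = None,
) -> list[OrthologyRelation]:
    """Union the per-level BBH sets, annotating each pair with its levels.

    The consensus subset is the pairs present at all three levels.  Output is
    sorted by (gene_a, gene_b) for reproducible files.
    """
    scores_by_level = scores_by_level or {}
    all_pairs: set[tuple[str, str]] = set()
    for pairs in bbh_by_level.values():
        all_pairs |= pairs
    relations = []
    for a, b in sorted(all_pairs):
        levels = frozenset(
            lvl for lvl, pairs in bbh_by_level.items() if (a, b) in pairs
        )
        per_level = {
            lvl: scores_by_level[lvl][(a, b)]
            for lvl in levels
            if lvl in scores_by_level and (a, b) in scores_by_level[lvl]
        }
        relations.append(OrthologyRelation(a, b, levels, per_level))
    return relations


def venn_regions(
    sets: Mapping[SequenceLevel, set],
) -> dict[frozenset[SequenceLevel], int]:
    """Counts of the 7 exclusive regions of a three-set Venn diagram.

    Keys are the non-empty level subsets; a member counts in the region of
    exactly the levels containing it.
    """
    regions: dict[frozenset[SequenceLevel], int] = {
        frozenset(combo): 0
        for r in (1, 2, 3)
        for combo in combinations(LEVELS, r)
    }
    universe = set().union(*sets.values()) if sets else set()
    for item in universe:
        membership = frozenset(lvl for lvl, s in sets.items() if item in s)
        if membership:
            regions[membership] += 1
    return regions


def locus_participation(
    relations: Iterable[OrthologyRelation], species: str
) -> dict:
    """Per-level gene sets for one species and their Venn-region counts.

    ``species`` selects the side: ``"a"`` counts gene_a (species A loci with
    a counterpart in B), ``"b"`` the reverse.  A locus can appear in several
    relations; it is counted once per level it touches.  The union count is
    the species' loci with a BBH confirmed at >= 1 level.
    """
    if species not in ("a", "b"):
        raise ValueError("species must be 'a' or 'b'")
    level_sets: dict[SequenceLevel, set[str]] = {lvl: set() for lvl in LEVELS}
    for rel in relations:
        gene = rel.gene_a if species == "a" else rel.gene_b
        for lvl in rel.levels:
            level_sets[lvl].add(gene)
    union = set().union(*level_sets.values())
    return {
        "level_sets": level_sets,
        "venn": venn_regions(level_sets),
        "union_count": len(union),
    }


def write_orthologs(
    relations: Sequence[OrthologyRelation],
    path: str | Path,
    tool_version: str = "orthonet",
) -> None:
    """Write one row per relation: pair, levels, consensus flag, scores."""
    with open(path, "w") as handle:
        handle.write(
            "# gene_a\tgene_b\tlevels\tconsensus\t"
            f"score_gene\tscore_transcript\tscore_protein\t[{tool_version}]\n"
        )
        for rel in sorted(relations, key=lambda r: r.pair()):
            levels = ",".join(
                lvl.value for lvl in LEVELS if lvl in rel.levels
            )
            scores = "\t".join(
                f"{rel.per_level_score[lvl]:g}" if lvl in rel.per_level_score else "NA"
                for lvl in LEVELS
            )
            handle.write(
                f"{rel.gene_a}\t{rel.gene_b}\t{levels}\t"
                f"{int(rel.consensus)}\t{scores}\n"
            )
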