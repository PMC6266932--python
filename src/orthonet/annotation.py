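"""Functional-annotation transfer and reconciliation between two species.

Transcript collections of both species are searched against a reference
protein database (Swiss-Prot style); an alignment must reach at least 90%
identity and 90% query coverage before its description and EC numbers are
transferred.  Transcript-vs-protein search direction is deliberate: it
rescues loci whose protein-coding region is mis-annotated in a draft gene
build.

Reconciled descriptions of ortholog partners are compared character-wise
(longest common subsequence over mean description length) and histogrammed
into the six identity bins; protein-domain profiles are compared as sets.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .io import SequenceLevel, SimilarityHit, ThresholdConfig, coverage, group_hsps
from .orthology import OrthologyRelation

__all__ = [
    "FunctionalAssignment",
    "DomainProfile",
    "DESCRIPTION_BINS",
    "transfer_annotation",
    "description_similarity",
    "description_bin",
    "compare_domains",
    "summarize_description_bins",
    "read_reference_metadata",
    "read_domain_profiles",
]

#: Description-identity bins: (label, inclusive lower bound, upper bound).
#: 100 is its own bin; the rest partition [0, 100).
DESCRIPTION_BINS = (
    ("100", 100.0, 100.0),
    ("80-99", 80.0, 100.0),
    ("60-79", 60.0, 80.0),
    ("40-59", 40.0, 60.0),
    ("20-39", 20.0, 40.0),
    ("0-19", 0.0, 20.0),
)


@dataclass(frozen=True)
class FunctionalAssignment:
    """A description/EC transfer from the best qualifying reference hit."""

    gene_id: str
    description: str
    source_accession: str
    ec_numbers: tuple[str, ...]
    percent_identity: float
    percent_coverage: float

    def __post_init__(self) -> None:
        if self.percent_identity < 90.0 or self.percent_coverage < 90.0:
            raise ValueError(
                "assignments require >= 90% identity and >= 90% coverage; got "
                f"{self.percent_identity:.1f}/{self.percent_coverage:.1f}"
            )


@dataclass(frozen=True)
class DomainProfile:
    """The set of domain accessions predicted on one gene's protein."""

    gene_id: str
    domains: frozenset[str]


def transfer_annotation(
    hits: Sequence[SimilarityHit],
    reference_metadata: Mapping[str, tuple[str, Sequence[str]]],
    config: ThresholdConfig | None = None,
    gene_of_query: Mapping[str, str] | None = None,
) -> dict[str, FunctionalAssignment]:
    """Assign each gene the best reference hit passing the 90/90 gate.

    ``hits`` are transcript-vs-reference-protein alignments; HSPs of one
    (transcript, accession) pair are unioned first so coverage reflects the
    whole alignment.  Among passing hits per gene the winner has the highest
    bit score, ties broken by lower e-value then accession order.
    ``gene_of_query`` maps transcript ids to gene loci (identity if absent).
    The coverage gate applies to the query (transcript) side, matching the
    search direction.
    """
    config = config or ThresholdConfig()
    missing = sorted(
        {h.subject_id for h in hits} - set(reference_metadata)
    )
    if missing:
        raise KeyError(
            "accessions missing from reference metadata: " + ", ".join(missing[:10])
        )
    best: dict[str, tuple[tuple, SimilarityHit]] = {}
    for hit in group_hsps(hits):
        if hit.percent_identity < config.annotation_min_identity:
            continue
        cov = coverage(hit, "query")
        if cov < config.annotation_min_coverage:
            continue
        gene = (gene_of_query or {}).get(hit.query_id, hit.query_id)
        rank = (-hit.bit_score, hit.e_value, hit.subject_id)
        if gene not in best or rank < best[gene][0]:
            best[gene] = (rank, hit)
    out: dict[str, FunctionalAssignment] = {}
    for gene, (_, hit) in best.items():
        description, ecs = reference_metadata[hit.subject_id]
        out[gene] = FunctionalAssignment(
            gene_id=gene,
            description=description,
            source_accession=hit.subject_id,
            ec_numbers=tuple(ecs),
            percent_identity=hit.percent_identity,
            percent_coverage=coverage(hit, "query"),
        )
    return out


def _fold(text: str) -> str:
    return re.sub(r"\s+", " ", text.strip()).casefold()


def _lcs_length(a: str, b: str) -> int:
    # single-row DP; descriptions are short strings
    if len(a) < len(b):
        a, b = b, a
    prev = [0] * (len(b) + 1)
    for ca in a:
        cur = [0]
        for j, cb in enumerate(b, start=1):
            cur.append(
                prev[j - 1] + 1 if ca == cb else max(prev[j], cur[j - 1])
            )
        prev = cur
    return prev[-1]


def description_similarity(desc_a: str, desc_b: str) -> float:
    """Character-level similarity of two functional descriptions, in percent.

    Both descriptions are case-folded and whitespace-collapsed; similarity is
    100 x LCS(a, b) / mean(len(a), len(b)) with a character-level longest
    common subsequence.  Symmetric; 100 iff the folded strings are equal.
    """
    a, b = _fold(desc_a), _fold(desc_b)
    if not a or not b:
        raise ValueError("descriptions must be non-empty")
    return 100.0 * _lcs_length(a, b) / ((len(a) + len(b)) / 2.0)


def description_bin(similarity: float) -> str:
    """Bin label for a similarity percentage (100 is its own bin)."""
    if not 0.0 <= similarity <= 100.0:
        raise ValueError(f"similarity {similarity} outside [0, 100]")
    if similarity == 100.0:
        return "100"
    for label, lo, hi in DESCRIPTION_BINS[1:]:
        if lo <= similarity < hi:
            return label
    raise AssertionError("unreachable")  # pragma: no cover


def compare_domains(profile_a: DomainProfile, profile_b: DomainProfile) -> str:
    """ALL_SHARED / SOME_SHARED / NONE_SHARED agreement of two domain sets."""
    a, b = profile_a.domains, profile_b.domains
    if not a and not b:
        raise ValueError(
            f"both domain sets empty for {profile_a.gene_id}/{profile_b.gene_id}; "
            "pair must be skipped"
        )
    if a == b:
        return "ALL_SHARED"
    if not a & b:
        return "NONE_SHARED"
    return "SOME_SHARED"


def summarize_description_bins(
    relations: Iterable[OrthologyRelation],
    assignments_a: Mapping[str, FunctionalAssignment],
    assignments_b: Mapping[str, FunctionalAssignment],
) -> dict:
    """Histogram ortholog pairs over the six description-identity bins.

    Pairs where either side lacks an assignment are counted as skipped;
    binned + skipped = number of relations.
    """
    histogram = {label: 0 for label, _, _ in DESCRIPTION_BINS}
    skipped = 0
    for rel in relations:
        fa = assignments_a.get(rel.gene_a)
        fb = assignments_b.get(rel.gene_b)
        if fa is None or fb is None:
            skipped += 1
            continue
        sim = description_similarity(fa.description, fb.description)
        histogram[description_bin(sim)] += 1
    return {"histogram": histogram, "skipped": skipped}


def read_reference_metadata(
    path: str | Path,
) -> dict[str, tuple[str, tuple[str, ...]]]:
    """Read ``accession  description  ec_numbers`` (ECs ;-joined, optional)."""
    out: dict[str, tuple[str, tuple[str, ...]]] = {}
    with open(path) as handle:
        for line in handle:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            accession, description = fields[0], fields[1]
            ecs = tuple(
                ec for ec in (fields[2].split(";") if len(fields) > 2 else []) if ec
            )
            out[accession] = (description, ecs)
    return out


def read_domain_profiles(
    path: str | Path, protein_to_gene: Mapping[str, str] | None = None
) -> dict[str, DomainProfile]:
    """Read InterProScan-style TSV into per-gene domain-accession sets.

    Column 12 (InterPro accession) is used when present and non-empty;
    otherwise the member-database signature accession in column 5.  Rows
    are aggregated per gene; set semantics (a domain counts once).
    """
    domains: dict[str, set[str]] = {}
    with open(path) as handle:
        for line in handle:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            protein = fields[0]
            accession = ""
            if len(fields) > 11 and fields[11] and fields[11] != "-":
                accession = fields[11]
            elif len(fields) > 4 and fields[4] and fields[4] != "-":
                accession = fields[4]
            if not accession:
                continue
            gene = (protein_to_gene or {}).get(protein, protein)
            domains.setdefault(gene, set()).add(accession)
    return {
        gene: DomainProfile(gene_id=gene, domains=frozenset(accs))
        for gene, accs in domains.items()
    }
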