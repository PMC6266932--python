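"""Readers, writers and core records for tabular similarity data.

The pipeline consumes all-vs-all similarity searches in extended BLAST
tabular form (``-outfmt "6 std qlen slen"``): the 12 standard columns plus
query and subject sequence lengths.  Lengths are required because the
downstream annotation-transfer filter and coverage statistics need them.
Coordinates are 1-based closed intervals; minus-strand subject coordinates
(sstart > send) are normalised by swapping on read.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "SequenceLevel",
    "SimilarityHit",
    "LocusMap",
    "ThresholdConfig",
    "SimilarityParseError",
    "LocusMapError",
    "SIMILARITY_COLUMNS",
    "read_similarity_table",
    "write_similarity_table",
    "read_locus_map",
    "collapse_to_loci",
    "coverage",
    "merge_intervals",
]

#: Column order of the consumed dialect (BLAST ``-outfmt "6 std qlen slen"``).
SIMILARITY_COLUMNS = (
    "qseqid sseqid pident length mismatch gapopen "
    "qstart qend sstart send evalue bitscore qlen slen"
).split()


class SequenceLevel(enum.Enum):
    """The three levels at which loci are compared.

    GENE is the full genomic locus (exons plus introns), TRANSCRIPT the
    spliced mRNA, PROTEIN the translated product.  Comparisons at the three
    levels are fully independent; agreement across all three defines the
    consensus ortholog set.
    """

    GENE = "gene"
    TRANSCRIPT = "transcript"
    PROTEIN = "protein"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class SimilarityParseError(ValueError):
    """A malformed row in a similarity table (carries the 1-based line number)."""


class LocusMapError(KeyError):
    """An identifier could not be resolved to a gene locus."""

    def __init__(self, missing: Sequence[str], level: "SequenceLevel"):
        self.missing = list(missing)
        self.level = level
        super().__init__(
            f"{len(self.missing)} unmappable {level.value} identifier(s): "
            + ", ".join(self.missing[:10])
            + ("..." if len(self.missing) > 10 else "")
        )


@dataclass(frozen=True)
class SimilarityHit:
    """One pairwise alignment (one HSP) at a declared sequence level."""

    query_id: str
    subject_id: str
    level: SequenceLevel
    percent_identity: float
    alignment_length: int
    bit_score: float
    e_value: float
    query_length: int
    subject_length: int
    query_intervals: tuple[tuple[int, int], ...] = ()
    subject_intervals: tuple[tuple[int, int], ...] = ()
    mismatch: int = 0
    gap_open: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.percent_identity <= 100.0:
            raise ValueError(
                f"percent_identity {self.percent_identity} outside [0, 100]"
            )
        if self.e_value < 0:
            raise ValueError(f"negative e-value {self.e_value}")
        if self.query_length < 1 or self.subject_length < 1:
            raise ValueError("sequence lengths must be >= 1")
        for ivals, length, side in (
            (self.query_intervals, self.query_length, "query"),
            (self.subject_intervals, self.subject_length, "subject"),
        ):
            for lo, hi in ivals:
                if lo > hi:
                    raise ValueError(f"{side} interval [{lo}, {hi}] reversed")
                if lo < 1 or hi > length:
                    raise ValueError(
                        f"{side} interval [{lo}, {hi}] outside [1, {length}]"
                    )

    def pair(self) -> tuple[str, str]:
        return (self.query_id, self.subject_id)


@dataclass(frozen=True)
class LocusMap:
    """Many-to-one maps from transcript and protein identifiers to gene loci."""

    species_label: str
    transcript_to_gene: Mapping[str, str] = field(default_factory=dict)
    protein_to_gene: Mapping[str, str] = field(default_factory=dict)

    @property
    def gene_universe(self) -> frozenset[str]:
        """All gene loci named by the map (the species' annotated gene set)."""
        return frozenset(self.transcript_to_gene.values()) | frozenset(
            self.protein_to_gene.values()
        )

    def resolve(self, identifier: str, level: SequenceLevel) -> str | None:
        if level is SequenceLevel.GENE:
            return identifier
        table = (
            self.transcript_to_gene
            if level is SequenceLevel.TRANSCRIPT
            else self.protein_to_gene
        )
        return table.get(identifier)


@dataclass(frozen=True)
class ThresholdConfig:
    """E-value and annotation-filter thresholds used across the pipeline.

    Orthologs are searched at a permissive 1e-3 cut-off so that no candidate
    relationship is lost before the reciprocal-best selection.  Paralogy uses
    two classes: a stringent 1e-50 threshold that maximises the number of
    distinct families, and the same loose 1e-3 used to veto species
    specificity.  Annotation transfer requires >= 90% identity and >= 90%
    coverage.
    """

    ortholog_evalue: float = 1e-3
    stringent_paralog_evalue: float = 1e-50
    loose_paralog_evalue: float = 1e-3
    annotation_min_identity: float = 90.0
    annotation_min_coverage: float = 90.0

    def __post_init__(self) -> None:
        for name in (
            "ortholog_evalue",
            "stringent_paralog_evalue",
            "loose_paralog_evalue",
            "annotation_min_identity",
            "annotation_min_coverage",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.stringent_paralog_evalue > self.loose_paralog_evalue:
            raise ValueError("stringent threshold must be <= loose threshold")


def _parse_row(fields: list[str], lineno: int, level: SequenceLevel) -> SimilarityHit:
    if len(fields) != len(SIMILARITY_COLUMNS):
        raise SimilarityParseError(
            f"line {lineno}: expected {len(SIMILARITY_COLUMNS)} columns, "
            f"got {len(fields)}"
        )
    try:
        pident = float(fields[2])
        length = int(fields[3])
        mismatch = int(fields[4])
        gapopen = int(fields[5])
        qstart, qend = int(fields[6]), int(fields[7])
        sstart, send = int(fields[8]), int(fields[9])
        evalue = float(fields[10])
        bitscore = float(fields[11])
        qlen = int(fields[12])
        slen = int(fields[13])
    except ValueError as exc:
        raise SimilarityParseError(f"line {lineno}: non-numeric field ({exc})") from exc
    # minus-strand subject hits arrive with sstart > send
    if sstart > send:
        sstart, send = send, sstart
    if qstart > qend:
        qstart, qend = qend, qstart
    try:
        return SimilarityHit(
            query_id=fields[0],
            subject_id=fields[1],
            level=level,
            percent_identity=pident,
            alignment_length=length,
            bit_score=bitscore,
            e_value=evalue,
            query_length=qlen,
            subject_length=slen,
            query_intervals=((qstart, qend),),
            subject_intervals=((sstart, send),),
            mismatch=mismatch,
            gap_open=gapopen,
        )
    except ValueError as exc:
        raise SimilarityParseError(f"line {lineno}: {exc}") from exc


def read_similarity_table(
    path: str | Path,
    level: SequenceLevel,
    evalue_cutoff: float = 1e-3,
) -> list[SimilarityHit]:
    """Read an extended BLAST tabular file, keeping rows with e-value <= cutoff.

    Multiple rows for the same (query, subject) pair — multiple HSPs — are
    preserved as separate hits; best-hit selection happens downstream.  Row
    order is preserved.  An empty file yields an empty list.
    """
    if evalue_cutoff <= 0:
        raise ValueError("evalue_cutoff must be positive")
    hits: list[SimilarityHit] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            hit = _parse_row(line.split("\t"), lineno, level)
            if hit.e_value <= evalue_cutoff:
                hits.append(hit)
    return hits


def write_similarity_table(
    hits: Iterable[SimilarityHit], path: str | Path, tool_version: str = "orthonet"
) -> None:
    """Write hits back in the 14-column dialect (single-interval hits only)."""
    with open(path, "w") as handle:
        handle.write("# " + "\t".join(SIMILARITY_COLUMNS) + f"\t[{tool_version}]\n")
        for h in hits:
            (qs, qe), (ss, se) = h.query_intervals[0], h.subject_intervals[0]
            handle.write(
                "\t".join(
                    str(x)
                    for x in (
                        h.query_id,
                        h.subject_id,
                        f"{h.percent_identity:g}",
                        h.alignment_length,
                        h.mismatch,
                        h.gap_open,
                        qs,
                        qe,
                        ss,
                        se,
                        f"{h.e_value:g}",
                        f"{h.bit_score:g}",
                        h.query_length,
                        h.subject_length,
                    )
                )
                + "\n"
            )


def read_locus_map(path: str | Path, species_label: str) -> LocusMap:
    """Read a 3-column TSV ``gene_id  transcript_id  protein_id``.

    The protein column may be empty (non-coding loci).  A gene may appear on
    several rows (multiple isoforms).
    """
    t2g: dict[str, str] = {}
    p2g: dict[str, str] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise SimilarityParseError(
                    f"line {lineno}: locus map needs >= 2 columns"
                )
            gene, transcript = fields[0], fields[1]
            protein = fields[2] if len(fields) > 2 and fields[2] else None
            if transcript:
                if t2g.get(transcript, gene) != gene:
                    raise LocusMapError([transcript], SequenceLevel.TRANSCRIPT)
                t2g[transcript] = gene
            if protein:
                if p2g.get(protein, gene) != gene:
                    raise LocusMapError([protein], SequenceLevel.PROTEIN)
                p2g[protein] = gene
    return LocusMap(species_label, t2g, p2g)


def collapse_to_loci(
    hits: Sequence[SimilarityHit],
    query_map: LocusMap,
    subject_map: LocusMap,
) -> list[SimilarityHit]:
    """Relabel transcript/protein hits with their gene-locus identifiers.

    Gene-level identifiers pass through unchanged.  Hits from several
    isoforms of the same locus pair are all retained — per-pair best scores
    are taken downstream, so no information is lost here.  The number of
    hits never changes, only identifiers.
    """
    out: list[SimilarityHit] = []
    missing: list[str] = []
    level = None
    for hit in hits:
        level = hit.level
        q = query_map.resolve(hit.query_id, hit.level)
        s = subject_map.resolve(hit.subject_id, hit.level)
        if q is None:
            missing.append(hit.query_id)
        if s is None:
            missing.append(hit.subject_id)
        if q is None or s is None:
            continue
        out.append(replace(hit, query_id=q, subject_id=s))
    if missing:
        raise LocusMapError(sorted(set(missing)), level or SequenceLevel.GENE)
    return out


def merge_intervals(
    intervals: Iterable[tuple[int, int]]
) -> list[tuple[int, int]]:
    """Merge overlapping/adjacent 1-based closed intervals."""
    ivals = sorted(intervals)
    merged: list[tuple[int, int]] = []
    for lo, hi in ivals:
        if merged and lo <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(merged[-1][1], hi))
        else:
            merged.append((lo, hi))
    return merged


def coverage(hit: SimilarityHit, side: str = "query") -> float:
    """Percent of the chosen side covered by the union of aligned intervals.

    Callers wanting multi-HSP coverage pre-group the HSPs of one
    (query, subject, level) pair into a single hit whose interval tuple
    carries every HSP's interval; the union is taken after merging overlaps,
    so coverage is invariant to interval order and to splitting an interval
    into adjacent pieces.
    """
    if side == "query":
        intervals, length = hit.query_intervals, hit.query_length
    elif side == "subject":
        intervals, length = hit.subject_intervals, hit.subject_length
    else:
        raise ValueError(f"side must be 'query' or 'subject', got {side!r}")
    if not intervals:
        raise ValueError(f"no {side} intervals on hit {hit.pair()}")
    covered = sum(hi - lo + 1 for lo, hi in merge_intervals(intervals))
    return 100.0 * covered / length


def group_hsps(hits: Sequence[SimilarityHit]) -> list[SimilarityHit]:
    """Collapse multiple HSPs of one (query, subject) pair into one record.

    The grouped record unions both sides' intervals (for multi-HSP coverage)
    and keeps the best single-HSP bit score as its score, which is the
    ranking key for best-hit selection.
    """
    by_pair: dict[tuple[str, str], list[SimilarityHit]] = {}
    order: list[tuple[str, str]] = []
    for hit in hits:
        key = hit.pair()
        if key not in by_pair:
            by_pair[key] = []
            order.append(key)
        by_pair[key].append(hit)
    grouped: list[SimilarityHit] = []
    for key in order:
        group = sorted(by_pair[key], key=lambda h: (-h.bit_score, h.e_value))
        best = group[0]
        q_iv = tuple(
            merge_intervals(iv for h in group for iv in h.query_intervals)
        )
        s_iv = tuple(
            merge_intervals(iv for h in group for iv in h.subject_intervals)
        )
        grouped.append(replace(best, query_intervals=q_iv, subject_intervals=s_iv))
    return grouped
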