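"""Two-species synthetic datasets with planted ground truth.

The generator emits every input the pipeline consumes — similarity tables
at three sequence levels (cross-species in both directions and within each
species), locus maps, reference-protein metadata and hits, domain tables,
GO maps and per-stage read counts — together with a truth manifest
recording exactly what was planted.  Planted structure:

* ortholog pairs whose cross-species scores dominate all decoy scores, so
  the reciprocal-best stage must recover exactly them;
* within-species paralogs attached to orthologs at the stringent e-value,
  plus loosely similar genes attached only at the loose e-value;
* species-specific families (stringent internal edges, no cross-species
  similarity) and singletons (no hits at all);
* per-ortholog-pair expression profiles drawn from a small set of
  well-separated template shapes plus Gaussian noise on the log2 scale, so
  clustering at the template count must recover the planted partition;
* reference descriptions/EC numbers/domain sets engineered to known
  description-identity bins and domain-agreement classes.

Scores are drawn so planted relations beat decoys by a wide margin;
emission order is sorted and all randomness flows from one seed, so a given
(config, seed) reproduces byte-identical files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .io import SequenceLevel

__all__ = ["FixtureConfig", "FixtureTruth", "generate_fixture", "corrupt_level"]

LEVELS = (SequenceLevel.GENE, SequenceLevel.TRANSCRIPT, SequenceLevel.PROTEIN)

# log2-RPKM template shapes for planted co-expression clusters; pairwise
# Pearson correlation is low on the full profile and on any 5-stage subset.
_TEMPLATES = (
    (6.0, 5.0, 4.0, 3.0, 2.0, 1.0),
    (1.0, 2.0, 3.0, 4.0, 5.0, 6.0),
    (1.0, 6.0, 1.0, 6.0, 1.0, 6.0),
    (6.0, 1.0, 6.0, 1.0, 6.0, 1.0),
)


@dataclass(frozen=True)
class FixtureConfig:
    """Sizes and noise levels of the planted dataset."""

    species_a: str = "tomato"
    species_b: str = "grape"
    n_ortholog_pairs: int = 20
    n_paralogs_a: int = 8
    n_paralogs_b: int = 4
    n_loose_similar_a: int = 3
    n_loose_similar_b: int = 2
    specific_family_sizes_a: tuple[int, ...] = (4, 3)
    specific_family_sizes_b: tuple[int, ...] = (3,)
    n_singletons_a: int = 6
    n_singletons_b: int = 4
    n_expression_clusters: int = 4
    n_unexpressed_pairs: int = 2
    expression_noise_sd: float = 0.15
    n_multi_isoform: int = 3  # leading species-A orthologs get two isoforms
    # description-bin plan per ortholog pair, cycled: identical / -like
    # variant / unrelated; plus a share of unannotated genes
    n_unannotated_pairs: int = 3
    # domain agreement plan: counts of SOME_SHARED and NONE_SHARED pairs,
    # the rest share all domains
    n_some_shared: int = 3
    n_none_shared: int = 2

    def __post_init__(self) -> None:
        if self.n_ortholog_pairs < 1:
            raise ValueError("need >= 1 ortholog pair")
        for sizes in (self.specific_family_sizes_a, self.specific_family_sizes_b):
            if any(s < 2 for s in sizes):
                raise ValueError("specific family sizes must be >= 2")
        if not 1 <= self.n_expression_clusters <= len(_TEMPLATES):
            raise ValueError(
                f"n_expression_clusters must be in [1, {len(_TEMPLATES)}]"
            )
        if self.n_unexpressed_pairs + self.n_unannotated_pairs > self.n_ortholog_pairs:
            raise ValueError("unexpressed + unannotated pairs exceed ortholog pairs")
        if self.n_some_shared + self.n_none_shared > self.n_ortholog_pairs:
            raise ValueError("domain-plan pairs exceed ortholog pairs")


@dataclass
class FixtureTruth:
    """Manifest of everything planted; the reference for end-to-end tests."""

    species_a: str
    species_b: str
    ortholog_pairs: list[tuple[str, str]]
    pair_levels: dict[str, list[str]]  # "geneA|geneB" -> confirming levels
    paralogs: dict[str, dict[str, str]]  # species -> paralog gene -> host ortholog
    loose_similar: dict[str, dict[str, str]]
    specific_families: dict[str, list[list[str]]]
    singletons: dict[str, list[str]]
    gene_universe: dict[str, list[str]]
    classes: dict[str, dict[str, str]]  # species -> gene -> specificity class
    descriptions: dict[str, str]  # gene -> planted description ("" = none)
    ec_numbers: dict[str, list[str]]
    description_bin_by_pair: dict[str, str]  # annotated pairs only
    domain_agreement_by_pair: dict[str, str]
    domains: dict[str, list[str]]
    go_terms: dict[str, list[str]]  # gene -> terms (species A only)
    enriched_term: str
    cluster_of_pair: dict[str, int]  # expressed pairs -> planted cluster (1-based)
    unexpressed_pairs: list[str]
    stages: dict[str, list[str]]
    seed: int = 0

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as handle:
            json.dump(asdict(self), handle, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "FixtureTruth":
        with open(path) as handle:
            data = json.load(handle)
        data["ortholog_pairs"] = [tuple(p) for p in data["ortholog_pairs"]]
        return cls(**data)


def _gene_ids(prefix: str, n: int, start: int = 1) -> list[str]:
    return [f"{prefix}{i:04d}g" for i in range(start, start + n)]


def _length(gene: str, level: SequenceLevel) -> int:
    # deterministic pseudo-lengths per gene and level
    base = 1200 + 10 * (sum(gene.encode()) % 97)
    if level is SequenceLevel.GENE:
        return base * 2  # locus includes introns
    if level is SequenceLevel.TRANSCRIPT:
        return base
    return base // 3  # amino acids


def _row(
    qid: str,
    sid: str,
    level: SequenceLevel,
    score: float,
    evalue: float,
    pident: float,
    qlen: int,
    slen: int,
    cover: float = 0.95,
) -> str:
    alen = max(1, int(min(qlen, slen) * cover))
    qend = min(qlen, alen)
    send = min(slen, alen)
    mism = int(alen * (100.0 - pident) / 100.0)
    return "\t".join(
        str(x)
        for x in (
            qid, sid, f"{pident:.2f}", alen, mism, 0,
            1, qend, 1, send, f"{evalue:g}", f"{score:.1f}", qlen, slen,
        )
    )


class _SpeciesPlan:
    """Identifier bookkeeping for one species."""

    def __init__(self, label: str, prefix: str, cfg: FixtureConfig, is_a: bool):
        self.label = label
        n_orth = cfg.n_ortholog_pairs
        n_par = cfg.n_paralogs_a if is_a else cfg.n_paralogs_b
        n_loose = cfg.n_loose_similar_a if is_a else cfg.n_loose_similar_b
        fam_sizes = (
            cfg.specific_family_sizes_a if is_a else cfg.specific_family_sizes_b
        )
        n_single = cfg.n_singletons_a if is_a else cfg.n_singletons_b
        start = 1
        self.orthologs = _gene_ids(prefix, n_orth, start); start += n_orth
        self.paralogs = _gene_ids(prefix, n_par, start); start += n_par
        self.loose = _gene_ids(prefix, n_loose, start); start += n_loose
        self.families: list[list[str]] = []
        for size in fam_sizes:
            self.families.append(_gene_ids(prefix, size, start))
            start += size
        self.singletons = _gene_ids(prefix, n_single, start)
        self.n_multi = cfg.n_multi_isoform if is_a else 0

    @property
    def universe(self) -> list[str]:
        return (
            self.orthologs
            + self.paralogs
            + self.loose
            + [g for fam in self.families for g in fam]
            + self.singletons
        )

    def transcripts(self, gene: str) -> list[str]:
        k = 2 if gene in self.orthologs[: self.n_multi] else 1
        return [f"{gene}.{i}" for i in range(1, k + 1)]

    def proteins(self, gene: str) -> list[str]:
        # a couple of singletons are non-coding (no protein)
        if gene in self.singletons[:2]:
            return []
        return [f"{t}.p" for t in self.transcripts(gene)]

    def seq_ids(self, gene: str, level: SequenceLevel) -> list[str]:
        if level is SequenceLevel.GENE:
            return [gene]
        if level is SequenceLevel.TRANSCRIPT:
            return self.transcripts(gene)
        return self.proteins(gene)


def _cross_rows(
    plan_q: _SpeciesPlan,
    plan_s: _SpeciesPlan,
    level: SequenceLevel,
    pair_score: Mapping[int, float],
) -> list[str]:
    """One direction of the cross-species all-vs-all at one level."""
    rows: list[str] = []
    n = len(plan_q.orthologs)
    for i in range(n):
        gq, gs = plan_q.orthologs[i], plan_s.orthologs[i]
        for qid in plan_q.seq_ids(gq, level):
            for k, sid in enumerate(plan_s.seq_ids(gs, level)):
                # secondary isoforms score slightly lower
                penalty = 3.0 * (qid.count(".2") + k)
                rows.append(
                    _row(
                        qid, sid, level,
                        score=pair_score[i] - penalty,
                        evalue=1e-180,
                        pident=92.0,
                        qlen=_length(gq, level),
                        slen=_length(gs, level),
                    )
                )
        # decoy hit to the next ortholog's partner: passes the loose filter
        # but never wins best-hit selection
        gs_decoy = plan_s.orthologs[(i + 1) % n]
        if gs_decoy != gs:
            qid = plan_q.seq_ids(gq, level)[0]
            sids = plan_s.seq_ids(gs_decoy, level)
            if sids:
                rows.append(
                    _row(
                        qid, sids[0], level,
                        score=55.0 + (i % 7),
                        evalue=1e-12,
                        pident=41.0,
                        qlen=_length(gq, level),
                        slen=_length(gs_decoy, level),
                        cover=0.2,
                    )
                )
    return sorted(rows)


def _within_rows(plan: _SpeciesPlan, level: SequenceLevel) -> list[str]:
    rows: list[str] = []

    def both_directions(g1: str, g2: str, score: float, evalue: float, pident: float):
        for qg, sg in ((g1, g2), (g2, g1)):
            for qid in plan.seq_ids(qg, level):
                for sid in plan.seq_ids(sg, level):
                    rows.append(
                        _row(
                            qid, sid, level, score, evalue, pident,
                            _length(qg, level), _length(sg, level),
                        )
                    )

    # self-hits, as a real all-vs-all search reports
    for gene in plan.universe:
        for qid in plan.seq_ids(gene, level):
            rows.append(
                _row(
                    qid, qid, level, 2000.0, 0.0, 100.0,
                    _length(gene, level), _length(gene, level), cover=1.0,
                )
            )
    # paralogs: stringent edge to their host ortholog
    for j, gene in enumerate(plan.paralogs):
        host = plan.orthologs[j % len(plan.orthologs)]
        both_directions(gene, host, score=310.0 + j, evalue=1e-80, pident=78.0)
    # loose associates: sub-stringent edge to an ortholog
    for j, gene in enumerate(plan.loose):
        host = plan.orthologs[j % len(plan.orthologs)]
        both_directions(gene, host, score=58.0 + j, evalue=1e-5, pident=38.0)
    # species-specific families: stringent internal edges only
    for fam in plan.families:
        for g1, g2 in zip(fam, fam[1:]):
            both_directions(g1, g2, score=280.0, evalue=1e-75, pident=74.0)
    return sorted(rows)


def _write(path: Path, lines: Sequence[str], header: str | None = None) -> None:
    with open(path, "w") as handle:
        if header:
            handle.write(header + "\n")
        for line in lines:
            handle.write(line + "\n")


def generate_fixture(
    out_dir: str | Path,
    config: FixtureConfig | None = None,
    seed: int = 0,
) -> tuple[FixtureTruth, dict[str, Path]]:
    """Emit a complete planted dataset under ``out_dir``.

    Returns the truth manifest and a name -> path map of every file
    written.  Regenerating with the same config and seed produces
    byte-identical output.
    """
    cfg = config or FixtureConfig()
    rng = np.random.default_rng(seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    plan_a = _SpeciesPlan(cfg.species_a, "SLY_", cfg, is_a=True)
    plan_b = _SpeciesPlan(cfg.species_b, "VIT_", cfg, is_a=False)
    paths: dict[str, Path] = {}

    n = cfg.n_ortholog_pairs
    pair_score = {i: 800.0 + 5.0 * i for i in range(n)}

    # similarity tables
    for level in LEVELS:
        lv = level.value
        for name, rows in (
            (f"cross_{lv}_a2b", _cross_rows(plan_a, plan_b, level, pair_score)),
            (f"cross_{lv}_b2a", _cross_rows(plan_b, plan_a, level, pair_score)),
            (f"within_{cfg.species_a}_{lv}", _within_rows(plan_a, level)),
            (f"within_{cfg.species_b}_{lv}", _within_rows(plan_b, level)),
        ):
            paths[name] = out / f"{name}.tsv"
            _write(paths[name], rows)

    # locus maps
    for plan, key in ((plan_a, cfg.species_a), (plan_b, cfg.species_b)):
        lines = []
        for gene in plan.universe:
            prots = plan.proteins(gene)
            for idx, t in enumerate(plan.transcripts(gene)):
                p = prots[idx] if idx < len(prots) else ""
                lines.append(f"{gene}\t{t}\t{p}")
        paths[f"locus_map_{key}"] = out / f"locus_map_{key}.tsv"
        _write(paths[f"locus_map_{key}"], lines)

    # --- annotation plan ------------------------------------------------
    # cycle: identical description / "-like" variant / unrelated text
    base_descriptions = [
        "Photosystem II D2 protein",
        "E3 ubiquitin-protein ligase RING1",
        "Pectate lyase",
        "Germin-like protein subfamily 1 member 14",
        "Heat shock cognate 70 kDa protein",
        "Cellulose synthase A catalytic subunit 3",
        "Expansin-A4",
        "Metal transporter Nramp6",
    ]
    unrelated = "Cinnamoyl-CoA reductase 1"
    descriptions: dict[str, str] = {}
    ec_numbers: dict[str, list[str]] = {}
    bin_by_pair: dict[str, str] = {}
    ref_meta_lines: list[str] = []
    ref_hits = {cfg.species_a: [], cfg.species_b: []}
    ref_idx = 0

    from .annotation import description_bin, description_similarity

    # decoy reference entry picked up only by sub-gate alignments
    ref_meta_lines.append("REF_0000\tUncharacterized protein\t")
    for i in range(n):
        ga, gb = plan_a.orthologs[i], plan_b.orthologs[i]
        key = f"{ga}|{gb}"
        if i < cfg.n_unannotated_pairs:
            descriptions[ga] = ""
            descriptions[gb] = ""
            continue
        desc_a = base_descriptions[i % len(base_descriptions)]
        mode = i % 3
        if mode == 0:
            desc_b = desc_a
        elif mode == 1:
            desc_b = desc_a + "-like"
        else:
            desc_b = unrelated
        for gene, desc, plan, species in (
            (ga, desc_a, plan_a, cfg.species_a),
            (gb, desc_b, plan_b, cfg.species_b),
        ):
            ref_idx += 1
            acc = f"REF_{ref_idx:04d}"
            ecs = [f"3.2.1.{i + 1}"] if i % 4 == 0 else []
            ec_numbers[gene] = ecs
            descriptions[gene] = desc
            ref_meta_lines.append(f"{acc}\t{desc}\t{';'.join(ecs)}")
            t = plan.transcripts(gene)[0]
            qlen = _length(gene, SequenceLevel.TRANSCRIPT)
            # subject length kept equal to the query so the declared cover
            # fraction is the query coverage the 90/90 gate sees
            ref_hits[species].append(
                _row(
                    t, acc, SequenceLevel.TRANSCRIPT,
                    score=450.0 + i, evalue=1e-120, pident=95.0,
                    qlen=qlen, slen=qlen, cover=0.93,
                )
            )
            # a low-coverage hit to the decoy entry: must not be transferred
            ref_hits[species].append(
                _row(
                    t, "REF_0000", SequenceLevel.TRANSCRIPT,
                    score=90.0, evalue=1e-20, pident=95.0,
                    qlen=qlen, slen=qlen, cover=0.40,
                )
            )
        bin_by_pair[key] = description_bin(description_similarity(desc_a, desc_b))

    paths["reference_metadata"] = out / "reference_metadata.tsv"
    _write(paths["reference_metadata"], sorted(ref_meta_lines))
    for species in (cfg.species_a, cfg.species_b):
        paths[f"ref_hits_{species}"] = out / f"ref_hits_{species}.tsv"
        _write(paths[f"ref_hits_{species}"], sorted(ref_hits[species]))

    # --- domains ---------------------------------------------------------
    domains: dict[str, list[str]] = {}
    agreement: dict[str, str] = {}
    for i in range(n):
        ga, gb = plan_a.orthologs[i], plan_b.orthologs[i]
        key = f"{ga}|{gb}"
        d1, d2 = f"IPR{i:05d}", f"IPR{i + 1000:05d}"
        if i < cfg.n_some_shared:
            domains[ga] = [d1, d2]
            domains[gb] = [d1, f"IPR{i + 2000:05d}"]
            agreement[key] = "SOME_SHARED"
        elif i < cfg.n_some_shared + cfg.n_none_shared:
            domains[ga] = [d1]
            domains[gb] = [f"IPR{i + 3000:05d}"]
            agreement[key] = "NONE_SHARED"
        else:
            domains[ga] = [d1, d2]
            domains[gb] = [d1, d2]
            agreement[key] = "ALL_SHARED"
    for plan, species in ((plan_a, cfg.species_a), (plan_b, cfg.species_b)):
        lines = []
        for gene in plan.universe:
            prots = plan.proteins(gene)
            if not prots or gene not in domains:
                continue
            for acc in domains[gene]:
                md5 = "0" * 32
                plen = _length(gene, SequenceLevel.PROTEIN)
                lines.append(
                    "\t".join(
                        [
                            prots[0], md5, str(plen), "Pfam", f"PF{acc[-5:]}",
                            "planted domain", "1", str(plen), "1e-30", "T",
                            "01-01-2020", acc, "planted InterPro entry",
                            "-", "-",
                        ]
                    )
                )
        paths[f"domains_{species}"] = out / f"domains_{species}.tsv"
        _write(paths[f"domains_{species}"], sorted(lines))

    # --- GO terms (species A) -------------------------------------------
    enriched_term = "GO:0009999"
    go_terms: dict[str, list[str]] = {}
    for i, gene in enumerate(plan_a.orthologs):
        terms = [f"GO:{1000 + i % 5:07d}"]
        if i % cfg.n_expression_clusters == 0:  # cluster-1 pairs share a term
            terms.append(enriched_term)
        go_terms[gene] = terms
    go_lines = sorted(
        f"{gene}\t{term}" for gene, terms in go_terms.items() for term in terms
    )
    paths[f"go_{cfg.species_a}"] = out / f"go_{cfg.species_a}.tsv"
    _write(paths[f"go_{cfg.species_a}"], go_lines)

    # --- expression ------------------------------------------------------
    stages = {
        cfg.species_a: ["T1", "T2", "T3"],
        cfg.species_b: ["G1", "G2", "G3"],
    }
    cluster_of_pair: dict[str, int] = {}
    unexpressed: list[str] = []
    log2_profiles: dict[str, np.ndarray] = {}  # per pair
    expressed_idx = 0
    for i in range(n):
        ga, gb = plan_a.orthologs[i], plan_b.orthologs[i]
        key = f"{ga}|{gb}"
        if i >= n - cfg.n_unexpressed_pairs:
            unexpressed.append(key)
            log2_profiles[key] = np.full(6, np.log2(1.3))  # ~0.3 RPKM
            continue
        c = expressed_idx % cfg.n_expression_clusters
        expressed_idx += 1
        cluster_of_pair[key] = c + 1
        noise = rng.normal(0.0, cfg.expression_noise_sd, size=6)
        log2_profiles[key] = np.asarray(_TEMPLATES[c]) + noise

    lib_size = 2_000_000.0
    for plan, species, offset in (
        (plan_a, cfg.species_a, 0),
        (plan_b, cfg.species_b, 3),
    ):
        st = stages[species]
        count_lines = []
        length_lines = []
        for gene in plan.universe:
            L = _length(gene, SequenceLevel.TRANSCRIPT)
            length_lines.append(f"{gene}\t{L}")
            if gene in plan.orthologs:
                i = plan.orthologs.index(gene)
                other = (plan_b if plan is plan_a else plan_a).orthologs[i]
                key = (
                    f"{gene}|{other}" if plan is plan_a else f"{other}|{gene}"
                )
                prof = log2_profiles[key][offset : offset + 3]
                rpkm_vals = np.exp2(prof) - 1.0
            else:
                rpkm_vals = np.full(3, 2.0)  # flat background expression
            counts = np.rint(rpkm_vals * lib_size * L / 1e9).astype(int)
            count_lines.append(gene + "\t" + "\t".join(map(str, counts)))
        paths[f"counts_{species}"] = out / f"counts_{species}.tsv"
        _write(
            paths[f"counts_{species}"], count_lines,
            header="gene\t" + "\t".join(st),
        )
        paths[f"gene_lengths_{species}"] = out / f"gene_lengths_{species}.tsv"
        _write(paths[f"gene_lengths_{species}"], length_lines)
        paths[f"library_sizes_{species}"] = out / f"library_sizes_{species}.tsv"
        _write(
            paths[f"library_sizes_{species}"],
            [f"{s}\t{int(lib_size)}" for s in st],
        )

    # --- truth manifest --------------------------------------------------
    classes: dict[str, dict[str, str]] = {}
    for plan, species in ((plan_a, cfg.species_a), (plan_b, cfg.species_b)):
        cls: dict[str, str] = {}
        for g in plan.orthologs:
            cls[g] = "ortholog"
        for g in plan.paralogs:
            cls[g] = "paralog_of_ortholog"
        for g in plan.loose:
            cls[g] = "loose_similar_to_ortholog"
        for fam in plan.families:
            for g in fam:
                cls[g] = "specific_family_member"
        for g in plan.singletons:
            cls[g] = "specific_singleton"
        classes[species] = cls

    truth = FixtureTruth(
        species_a=cfg.species_a,
        species_b=cfg.species_b,
        ortholog_pairs=list(zip(plan_a.orthologs, plan_b.orthologs)),
        pair_levels={
            f"{a}|{b}": [lv.value for lv in LEVELS]
            for a, b in zip(plan_a.orthologs, plan_b.orthologs)
        },
        paralogs={
            cfg.species_a: {
                g: plan_a.orthologs[j % n] for j, g in enumerate(plan_a.paralogs)
            },
            cfg.species_b: {
                g: plan_b.orthologs[j % n] for j, g in enumerate(plan_b.paralogs)
            },
        },
        loose_similar={
            cfg.species_a: {
                g: plan_a.orthologs[j % n] for j, g in enumerate(plan_a.loose)
            },
            cfg.species_b: {
                g: plan_b.orthologs[j % n] for j, g in enumerate(plan_b.loose)
            },
        },
        specific_families={
            cfg.species_a: [list(f) for f in plan_a.families],
            cfg.species_b: [list(f) for f in plan_b.families],
        },
        singletons={
            cfg.species_a: list(plan_a.singletons),
            cfg.species_b: list(plan_b.singletons),
        },
        gene_universe={
            cfg.species_a: list(plan_a.universe),
            cfg.species_b: list(plan_b.universe),
        },
        classes=classes,
        descriptions=descriptions,
        ec_numbers=ec_numbers,
        description_bin_by_pair=bin_by_pair,
        domain_agreement_by_pair=agreement,
        domains=domains,
        go_terms=go_terms,
        enriched_term=enriched_term,
        cluster_of_pair=cluster_of_pair,
        unexpressed_pairs=unexpressed,
        stages=stages,
        seed=seed,
    )
    paths["truth"] = out / "truth.json"
    truth.to_json(paths["truth"])
    return truth, paths


def corrupt_level(
    fixture_dir: str | Path,
    level: SequenceLevel,
    fraction: float,
    seed: int = 0,
) -> FixtureTruth:
    """Strip a fraction of planted pairs from one level's cross tables.

    The chosen pairs lose their rows (all isoforms, both directions) in the
    level's cross-species tables, so downstream they are confirmed only at
    the remaining levels; the truth manifest is rewritten accordingly.
    Fraction 0 is the identity.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    out = Path(fixture_dir)
    truth = FixtureTruth.from_json(out / "truth.json")
    pairs = truth.ortholog_pairs
    n_strip = int(round(fraction * len(pairs)))
    rng = np.random.default_rng(seed)
    strip_idx = sorted(rng.choice(len(pairs), size=n_strip, replace=False))
    stripped = [pairs[i] for i in strip_idx]
    strip_genes: set[str] = {g for p in stripped for g in p}

    lv = level.value
    for name in (f"cross_{lv}_a2b.tsv", f"cross_{lv}_b2a.tsv"):
        path = out / name
        kept = []
        for line in path.read_text().splitlines():
            fields = line.split("\t")
            qg = fields[0].split(".")[0]
            sg = fields[1].split(".")[0]
            qs = {qg, sg}
            if any(set(p) <= qs for p in stripped):
                continue
            kept.append(line)
        _write(path, kept)

    for a, b in stripped:
        key = f"{a}|{b}"
        truth.pair_levels[key] = [x for x in truth.pair_levels[key] if x != lv]
    truth.to_json(out / "truth.json")
    return truth
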