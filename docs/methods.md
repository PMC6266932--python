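# Methods

This note records the models and procedures implemented, the defaults and
why, the numerical choices, and what the synthetic datasets do and do not
exercise.

## Multilevel orthology

Orthology is called per sequence level from all-vs-all similarity tables
in extended BLAST tabular form (`-outfmt "6 std qlen slen"`; the two
length columns are required because coverage and the 90/90 annotation gate
cannot be computed without them). Rows are filtered at the ortholog e-value
cut-off (default 1e-3, permissive on purpose: the selectivity comes from
the reciprocal-best step, not from the filter), transcript and protein
identifiers are collapsed to gene loci through the locus map, and each
gene pair is reduced to its maximum single-HSP bit score. The bit score,
not the e-value, is the ranking key; e-values saturate at zero for strong
alignments and cannot discriminate among them.

Multi-isoform loci are handled by scoring every isoform pair and taking
the per-gene-pair maximum. The alternative — picking one representative
isoform (e.g. the longest) before searching — discards signal and can flip
best hits when the longest isoform is not the most conserved; the maximum
is the least lossy reduction and needs no arbitrary representative choice.

Best hits retain **all** subjects tied at the query's maximal score, and
the BBH set is the reciprocal closure of the two directions' best-hit
maps; no secondary criterion (e-value, alignment length) breaks ties, so a
gene may legitimately appear in several relationships. The three levels
are computed fully independently — no score is ever mixed across levels —
and the union of the three BBH sets, each pair labelled with its
confirming levels, is the relationship collection. Pairs confirmed at all
three levels form the consensus subset, the most reliable class; pairs
confirmed at one or two levels are retained and flagged, because
single-level relationships frequently reflect annotation artefacts
(mis-predicted coding regions produce gene/transcript-only pairs) rather
than absent homology.

Multi-HSP coverage is the union of aligned intervals per (query, subject)
pair after merging overlaps, so it is invariant to interval order and to
splitting an alignment into adjacent pieces; minus-strand subject
coordinates are normalised by swapping on read.

## Paralogy

Within-species edges use the same gene-collapsed tables. Both threshold
classes are computed in one pass: every pair with a hit at e-value ≤ 1e-3
gets an edge, flagged stringent when some hit reaches ≤ 1e-50. The
stringent threshold is the family-defining one — it maximises the number
of distinct components (too loose a cut-off collapses most duplicated
genes into one giant family; too strict a one fragments families) — while
the loose threshold exists only to veto species specificity. An edge
confirmed by any single level counts (union semantics); requiring
per-level consensus for paralogs would conflate annotation quality with
duplication history, and the within-species searches are run at the same
three levels precisely to be robust to it.

## Networks and specificity classes

The graph unions orthology edges (cross-species) with paralogy edges of
the requested threshold class; one edge per gene pair, typed, with its
confirming levels. Connected components are extracted with networkx and
numbered deterministically by (size descending, smallest gene id), then
binned 2 / 3–9 / ≥ 10. Component count is non-increasing under edge
addition on a fixed node set, which is the internal consistency check
between the stringent and loose graphs.

Specificity classification is a strict precedence partition per species:

1. **ortholog** — takes part in ≥ 1 orthology relation;
2. **paralog of ortholog** — reaches an ortholog through stringent edges,
   directly or transitively (component membership, matching the network
   construction);
3. **loosely similar to ortholog** — reaches an ortholog through loose
   edges. Transitive closure is used here too: the specific set must be
   the exact complement of the loose graph's ortholog-containing
   components, otherwise specific counts and network statistics would
   disagree;
4. **specific family member / specific singleton** — the remainder, split
   by whether the gene shares a stringent edge with another specific gene.
   (Since stringent ⊆ loose, a specific gene's stringent neighbours are
   necessarily specific themselves.) Families can also be counted at the
   loose threshold via `specific_family_networks`, since both counting
   conventions are defensible and yield different totals.

## Annotation reconciliation

Transfer is transcript-vs-reference-protein by design: it rescues loci
whose protein prediction is wrong in a draft annotation. HSPs of one
(transcript, accession) pair are unioned before gating, so fragmented
alignments are not unfairly rejected. The 90/90 gate applies identity and
**query** (transcript) coverage; the subject side is not gated because the
reference protein may be a multi-domain fusion legitimately longer than
the transcript. Among passing hits the winner is the highest bit score,
ties broken by lower e-value then accession order, giving deterministic
output.

Description similarity is 100 × LCS(a, b) / mean(len(a), len(b)) with a
character-level longest common subsequence after case-folding and
whitespace collapsing. Character (not token) matching is deliberate: it
places suffix variants ("RING1" vs "RING1-like", ≈ 93%) and qualifier
losses ("Probable pectate lyase P59" vs "Pectate lyase", ≈ 66.7%) into the
intuitively right identity bins where token-level Jaccard would not.
Qualifiers such as "putative" are **not** stripped before matching; the
metric is a single pluggable function should a different convention be
wanted. The six bins treat 100% as its own bin and partition [0, 100)
into five 20-point ranges. Domain profiles are sets of InterPro accessions
(member-database accessions where no InterPro integration exists);
agreement is equality / non-empty intersection / disjoint, and pairs where
both sets are empty are skipped as uninformative.

## Expression

RPKM = 10⁹·C/(N·L) per gene and stage; the 1-RPKM floor marks
non-expression, and an ortholog pair is analysed when **either** gene
passes the floor in ≥ 1 stage (the asymmetric cases — one side silent —
are exactly the interesting divergent-regulation candidates). Profiles are
log₂(RPKM + 1): the +1 pseudocount keeps non-expressed values at exactly 0
and is the standard display transform for RPKM; no further row scaling is
applied, because the Pearson distance used downstream is already
location/scale invariant. The two species' three stages are concatenated
into one 6-component profile per pair — co-expression across the species
boundary is the object of interest, so the pair, not the gene, is the
clustered unit.

**K-means with correlation distance.** distance(p, c) = 1 − r(p, c) ∈
[0, 2]; centroids are arithmetic means of member profiles; initial
centroids are k distinct profiles sampled with the run's seed; default 10
restarts keep the lowest final objective (sum of distances to assigned
centroids). Empty clusters are re-seeded with the profile farthest from
its current centroid. Because the arithmetic-mean update is not exactly
the minimiser of the correlation objective, a rare update could raise it;
the loop therefore tracks the objective and halts on the previous state if
an increase is detected, making the objective provably non-increasing over
iterations. Zero-variance profiles have no defined correlation and are
excluded with a warning (or raise, by option) before clustering.

**Figure of Merit.** For each candidate k and each left-out stage s, the
profiles are clustered on the remaining stages and
FOM(k, s) = √( (1/n) Σ_g (x[g,s] − mean over g's cluster)² ); FOM(k) sums
over stages. The suggested elbow is the last k before the relative
decrease first drops below 5% (exposed as a flag); in the original
workflow the cluster count was chosen by visual inspection of this curve,
so the automated rule is a convenience, not a claim, and the full curve is
always written out for plotting.

Hierarchical sub-clustering of one cluster's members is scipy average
linkage on Euclidean distance. Enrichment per term is the upper-tail
hypergeometric probability of the observed overlap given the term's
frequency in the reference universe (unannotated genes stay in the
universe), Hochberg step-up adjusted across the tested terms at α = 0.05;
terms are processed in sorted order so results are independent of input
order.

## Synthetic data

The generator emulates the complete input surface — cross-species and
within-species similarity tables at three levels, locus maps with
multi-isoform and non-coding entries, reference metadata and
transcript-vs-reference hits, InterProScan-style domain tables, GO maps,
and per-stage counts with lengths and library sizes — with a planted truth
manifest. Default sizes (20 ortholog pairs; 8/4 attached paralogs; 3/2
loose associates; specific families of 4+3 / 3 genes; 6/4 singletons)
keep every class populated at desk scale while making tomato the more
duplicated genome. Planted ortholog scores (≈ 800+) dominate decoy
cross-hits (≈ 55–62) by a wide margin, so recovery failures indicate
implementation defects, not borderline scoring. Expression profiles come
from four template shapes with pairwise low or negative correlation on
any 5-of-6 stage subset, plus Gaussian noise (σ = 0.15 on the log₂ scale)
— separation comfortably above what K-means needs for exact recovery.
`corrupt_level` strips chosen pairs from one level's tables to plant
partial-confirmation classes.

What the generator does **not** emulate: realistic score/e-value joint
distributions, sequence evolution (no indels, no rate variation),
many-to-many orthology beyond score ties, overlapping paralog families,
biological count overdispersion (counts are rounded deterministic RPKM
inversions), or GO term correlation structure. Passing the planted-truth
suite therefore demonstrates algorithmic correctness on unambiguous
signal, not robustness to the noise patterns of real genome annotations.

## Problem sizes and determinism

Tests and the acceptance script run the full pipeline on the default
fixture (~80 genes per species, ≤ a few thousand similarity rows), random
oracle comparisons up to 200 hits / 500 nodes, exhaustive partition search
up to 12 profiles, and enrichment enumeration on universes ≤ 14 — sizes
chosen so every check is exact or exhaustive. All randomness flows from
explicit seeds; file emission is sorted, so identical inputs give
byte-identical outputs, which the pipeline verifies via input checksums in
its run manifest (re-runs over unchanged inputs are skipped).

## Known limitations

- BBH-with-ties is the only orthology model; tree-based one-to-many and
  many-to-many calls are out of scope by design.
- The external aligner is not driven; the package consumes its tabular
  output. Coverage semantics assume BLAST-style 1-based closed intervals.
- In-paralog/out-paralog distinction and duplication ordering are not
  inferred.
- The FOM elbow rule is a heuristic over a curve meant for visual
  inspection; on plateaued curves it can stop before a later large drop,
  so the curve itself is the primary output.
- GO terms are used as given (no DAG propagation), matching the upstream
  enrichment tool's behaviour on flat term lists.
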