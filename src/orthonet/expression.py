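"""Expression normalisation and co-expression clustering of ortholog pairs.

Raw per-stage read counts are normalised to RPKM (reads per kilobase of
transcript per million mapped reads, ``1e9 * C / (N * L)``).  Genes below
1 RPKM everywhere are treated as not expressed; an ortholog pair enters the
co-expression analysis when at least one of its two genes is expressed in
at least one stage.  Each retained pair contributes one 6-component
profile: ``log2(RPKM + 1)`` over the three fruit stages of each species,
concatenated in a fixed stage order.

Profiles are partitioned by K-means with Pearson-correlation distance
(``1 - r``); the number of clusters is guided by the leave-one-stage-out
Figure of Merit.  Clusters can be refined by hierarchical sub-clustering
(Euclidean distance, average linkage), and gene sets are tested for GO-term
enrichment with an upper-tail hypergeometric test and Hochberg step-up
adjustment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .orthology import OrthologyRelation

__all__ = [
    "ClusterResult",
    "rpkm",
    "expressed_mask",
    "filter_expressed_relations",
    "log2_profile",
    "relation_profiles",
    "pearson_distance",
    "kmeans_pearson",
    "figure_of_merit",
    "hierarchical_subcluster",
    "hypergeometric_enrichment",
]


def rpkm(
    counts: pd.DataFrame,
    gene_lengths: Mapping[str, float] | pd.Series,
    library_sizes: Mapping[str, float] | pd.Series,
) -> pd.DataFrame:
    """RPKM-normalise a genes x stages count matrix.

    ``value[g, s] = 1e9 * C[g, s] / (N[s] * L[g])`` with L in bp and N the
    stage's mapped-read total.  Doubling every count together with every
    library size leaves the result unchanged.
    """
    lengths = pd.Series(gene_lengths, dtype=float)
    sizes = pd.Series(library_sizes, dtype=float)
    missing_genes = counts.index.difference(lengths.index)
    if len(missing_genes):
        raise KeyError(f"no gene length for: {', '.join(map(str, missing_genes[:10]))}")
    missing_stages = counts.columns.difference(sizes.index)
    if len(missing_stages):
        raise KeyError(
            f"no library size for stage(s): {', '.join(map(str, missing_stages))}"
        )
    if (lengths.loc[counts.index] < 1).any() or (sizes.loc[counts.columns] < 1).any():
        raise ValueError("gene lengths and library sizes must be >= 1")
    denom = np.outer(lengths.loc[counts.index], sizes.loc[counts.columns])
    return counts.astype(float) * 1e9 / denom


def expressed_mask(rpkm_matrix: pd.DataFrame, threshold: float = 1.0) -> pd.DataFrame:
    """Boolean genes x stages mask: expressed iff RPKM >= threshold."""
    return rpkm_matrix >= threshold


def filter_expressed_relations(
    relations: Sequence[OrthologyRelation],
    rpkm_a: pd.DataFrame,
    rpkm_b: pd.DataFrame,
    threshold: float = 1.0,
) -> list[OrthologyRelation]:
    """Keep relations where either gene reaches the threshold in >= 1 stage."""
    mask_a = expressed_mask(rpkm_a, threshold).any(axis=1)
    mask_b = expressed_mask(rpkm_b, threshold).any(axis=1)
    out = []
    for rel in relations:
        if rel.gene_a not in mask_a.index or rel.gene_b not in mask_b.index:
            raise KeyError(
                f"relation ({rel.gene_a}, {rel.gene_b}) references a gene "
                "absent from the expression matrix"
            )
        if mask_a[rel.gene_a] or mask_b[rel.gene_b]:
            out.append(rel)
    return out


def log2_profile(values: Sequence[float]) -> np.ndarray:
    """``log2(RPKM + 1)`` of a profile; 0 RPKM maps to 0."""
    arr = np.asarray(values, dtype=float)
    if (arr < 0).any():
        raise ValueError("negative RPKM value")
    return np.log2(arr + 1.0)


def relation_profiles(
    relations: Sequence[OrthologyRelation],
    rpkm_a: pd.DataFrame,
    rpkm_b: pd.DataFrame,
    stages_a: Sequence[str] | None = None,
    stages_b: Sequence[str] | None = None,
) -> pd.DataFrame:
    """6-component log2 profiles of ortholog pairs, species A stages first."""
    stages_a = list(stages_a or rpkm_a.columns)
    stages_b = list(stages_b or rpkm_b.columns)
    rows = {}
    for rel in relations:
        vals = np.concatenate(
            [
                rpkm_a.loc[rel.gene_a, stages_a].to_numpy(dtype=float),
                rpkm_b.loc[rel.gene_b, stages_b].to_numpy(dtype=float),
            ]
        )
        rows[f"{rel.gene_a}|{rel.gene_b}"] = log2_profile(vals)
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=list(stages_a) + list(stages_b)
    )


# ---------------------------------------------------------------------------
# K-means with Pearson-correlation distance


@dataclass
class ClusterResult:
    """Outcome of a K-means run: partition, centroids and diagnostics."""

    k: int
    assignments: pd.Series  # profile id -> cluster id in 1..k
    centroids: pd.DataFrame  # k x n_stages
    seed: int
    objective: float
    n_iter: int
    fom_curve: dict[int, float] = field(default_factory=dict)

    def members(self, cluster_id: int) -> list:
        return list(self.assignments.index[self.assignments == cluster_id])


def pearson_distance(profiles: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    """Pairwise ``1 - r`` between profile rows and centroid rows, in [0, 2].

    A zero-variance centroid has no defined correlation; its distance is
    taken as 1 (the uncorrelated value) so the iteration stays total.
    """
    p = profiles - profiles.mean(axis=1, keepdims=True)
    c = centroids - centroids.mean(axis=1, keepdims=True)
    p_norm = np.linalg.norm(p, axis=1)
    c_norm = np.linalg.norm(c, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (p @ c.T) / np.outer(p_norm, c_norm)
    corr = np.nan_to_num(corr, nan=0.0)
    return np.clip(1.0 - corr, 0.0, 2.0)


def _objective(profiles: np.ndarray, centroids: np.ndarray, labels: np.ndarray) -> float:
    d = pearson_distance(profiles, centroids)
    return float(d[np.arange(len(labels)), labels].sum())


def _kmeans_once(
    x: np.ndarray, k: int, rng: np.random.Generator, max_iter: int
) -> tuple[np.ndarray, np.ndarray, float, int]:
    n = x.shape[0]
    centroids = x[rng.choice(n, size=k, replace=False)].copy()
    labels = pearson_distance(x, centroids).argmin(axis=1)
    prev_obj = None
    it = 0
    for it in range(1, max_iter + 1):
        new_centroids = centroids.copy()
        for j in range(k):
            members = x[labels == j]
            if len(members):
                new_centroids[j] = members.mean(axis=0)
        # re-seed empty clusters with the profile farthest from its centroid
        d = pearson_distance(x, new_centroids)
        for j in range(k):
            if not (labels == j).any():
                farthest = d[np.arange(n), labels].argmax()
                new_centroids[j] = x[farthest]
                d = pearson_distance(x, new_centroids)
        new_labels = d.argmin(axis=1)
        new_obj = _objective(x, new_centroids, new_labels)
        if prev_obj is not None and new_obj > prev_obj + 1e-12:
            break  # mean update is not exactly optimal under 1-r; keep best state
        changed = (new_labels != labels).any()
        centroids, labels, prev_obj = new_centroids, new_labels, new_obj
        if not changed:
            break
    if prev_obj is None:
        prev_obj = _objective(x, centroids, labels)
    return labels, centroids, prev_obj, it


def kmeans_pearson(
    profiles: pd.DataFrame,
    k: int,
    seed: int = 0,
    max_iter: int = 100,
    restarts: int = 10,
    constant_profiles: str = "drop",
) -> ClusterResult:
    """K-means under Pearson-correlation distance with restarts.

    Each restart samples k distinct profiles as initial centroids; the run
    with the lowest final objective (sum of ``1 - r`` to the assigned
    centroid) wins.  Centroids are arithmetic means of member profiles;
    empty clusters are re-seeded with the farthest profile.  The objective
    is non-increasing over iterations (a rare mean-update that would raise
    it halts the run on the previous state).  Zero-variance profiles have no
    defined correlation; by default they are excluded with a warning
    (``constant_profiles="error"`` raises instead).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    x_all = profiles.to_numpy(dtype=float)
    variances = x_all.var(axis=1)
    constant = variances == 0.0
    if constant.any():
        if constant_profiles == "error":
            raise ValueError(
                f"{int(constant.sum())} zero-variance profile(s) under "
                "correlation distance"
            )
        warnings.warn(
            f"dropping {int(constant.sum())} zero-variance profile(s) "
            "from correlation-distance clustering",
            stacklevel=2,
        )
    keep = profiles.index[~constant]
    x = x_all[~constant]
    if k > len(x):
        raise ValueError(f"k={k} exceeds {len(x)} usable profiles")
    rng = np.random.default_rng(seed)
    best: tuple | None = None
    for _ in range(max(1, restarts)):
        labels, centroids, obj, n_iter = _kmeans_once(x, k, rng, max_iter)
        if best is None or obj < best[2] - 1e-12:
            best = (labels, centroids, obj, n_iter)
    labels, centroids, obj, n_iter = best
    return ClusterResult(
        k=k,
        assignments=pd.Series(labels + 1, index=keep, name="cluster"),
        centroids=pd.DataFrame(
            centroids, index=range(1, k + 1), columns=profiles.columns
        ),
        seed=seed,
        objective=obj,
        n_iter=n_iter,
    )


def figure_of_merit(
    profiles: pd.DataFrame,
    k_range: Sequence[int],
    seed: int = 0,
    restarts: int = 5,
    max_iter: int = 100,
    elbow_tolerance: float = 0.05,
) -> dict:
    """Leave-one-stage-out Figure of Merit over a range of cluster counts.

    For each k and each left-out stage s, the profiles are clustered on the
    remaining stages; FOM(k, s) is the root mean squared deviation of the
    held-out stage's values from their cluster means, and FOM(k) sums over
    stages.  Low FOM at small k indicates well-supported structure.  The
    suggested elbow is the largest k reached before the relative decrease
    first falls below ``elbow_tolerance`` (clusters beyond it gain little);
    the full curve is returned for plotting.
    """
    n, m = profiles.shape
    ks = sorted(set(int(k) for k in k_range))
    if not ks or ks[0] < 2 or ks[-1] > n - 1:
        raise ValueError(f"k_range must lie within [2, {n - 1}]")
    x = profiles.to_numpy(dtype=float)
    curve: dict[int, float] = {}
    for k in ks:
        total = 0.0
        for s in range(m):
            rest = profiles.drop(columns=profiles.columns[s])
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                result = kmeans_pearson(
                    rest, k, seed=seed + s, restarts=restarts, max_iter=max_iter
                )
            held = pd.Series(x[:, s], index=profiles.index)
            sq = 0.0
            for cluster_id in range(1, k + 1):
                members = result.members(cluster_id)
                if not members:
                    continue
                vals = held.loc[members].to_numpy()
                sq += ((vals - vals.mean()) ** 2).sum()
            dropped = held.index.difference(result.assignments.index)
            # zero-variance profiles dropped by clustering count as their own mean
            total += float(np.sqrt(sq / (n - len(dropped)))) if n > len(dropped) else 0.0
        curve[k] = total
    elbow = ks[-1]
    for prev, k in zip(ks, ks[1:]):
        if curve[prev] <= 0:
            elbow = prev
            break
        if (curve[prev] - curve[k]) / curve[prev] < elbow_tolerance:
            elbow = prev
            break
    else:
        elbow = ks[-1]
    return {"fom": curve, "elbow": elbow}


def hierarchical_subcluster(member_profiles: pd.DataFrame) -> np.ndarray:
    """Average-linkage Euclidean agglomeration of one cluster's members.

    Returns the scipy linkage matrix; merge heights are non-decreasing
    (average linkage is monotone).
    """
    if len(member_profiles) < 2:
        raise ValueError("sub-clustering needs >= 2 member profiles")
    return linkage(
        member_profiles.to_numpy(dtype=float), method="average", metric="euclidean"
    )


def hypergeometric_enrichment(
    test_genes: set[str],
    reference_genes: set[str],
    term_map: Mapping[str, Iterable[str]],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Term enrichment of a test list against a reference universe.

    For each term occurring in the test list, the raw p-value is the
    upper-tail hypergeometric probability of drawing at least the observed
    number of term members in ``len(test_genes)`` draws from the reference.
    P-values are adjusted with the Hochberg step-up procedure; rows with
    ``adjusted_p <= alpha`` are flagged enriched.  Output is sorted by term,
    so it is invariant to input order.
    """
    if not test_genes <= reference_genes:
        raise ValueError("test genes must be a subset of the reference universe")
    term_genes: dict[str, set[str]] = {}
    for gene in reference_genes:
        for term in term_map.get(gene, ()):  # unannotated genes stay in the universe
            term_genes.setdefault(term, set()).add(gene)
    terms = sorted(t for t, genes in term_genes.items() if genes & test_genes)
    m_total = len(reference_genes)
    n_draws = len(test_genes)
    records = []
    for term in terms:
        k_term = len(term_genes[term])
        x = len(term_genes[term] & test_genes)
        p = float(hypergeom.sf(x - 1, m_total, k_term, n_draws))
        records.append((term, x, k_term, p))
    if not records:
        return pd.DataFrame(
            columns=["term", "test_count", "reference_count", "p_value",
                     "adjusted_p", "enriched"]
        ).set_index("term")
    df = pd.DataFrame(
        records, columns=["term", "test_count", "reference_count", "p_value"]
    ).set_index("term")
    _, adjusted, _, _ = multipletests(
        df["p_value"].to_numpy(), alpha=alpha, method="simes-hochberg"
    )
    df["adjusted_p"] = adjusted
    df["enriched"] = df["adjusted_p"] <= alpha
    return df
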