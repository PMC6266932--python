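"""RPKM normalisation, Pearson K-means, FOM, HCL and enrichment."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from orthonet.expression import (
    figure_of_merit,
    filter_expressed_relations,
    hierarchical_subcluster,
    hypergeometric_enrichment,
    kmeans_pearson,
    log2_profile,
    pearson_distance,
    relation_profiles,
    rpkm,
)
from orthonet.io import SequenceLevel
from orthonet.orthology import OrthologyRelation

G = frozenset({SequenceLevel.GENE})
STAGES = ["s1", "s2", "s3"]


def rel(a, b):
    return OrthologyRelation(a, b, G, {})


class TestRpkm:
    def test_closed_form(self):
        counts = pd.DataFrame({"s1": [1000]}, index=["g1"])
        out = rpkm(counts, {"g1": 1000}, {"s1": 1_000_000})
        assert out.loc["g1", "s1"] == 1000.0

    def test_zero_counts_give_zero(self):
        counts = pd.DataFrame({"s1": [0]}, index=["g1"])
        assert rpkm(counts, {"g1": 500}, {"s1": 10}).loc["g1", "s1"] == 0.0

    def test_scale_invariance_doubling_counts_and_libraries(self):
        counts = pd.DataFrame({"s1": [10, 20], "s2": [5, 0]}, index=["g1", "g2"])
        lengths = {"g1": 1500, "g2": 800}
        sizes = {"s1": 1e6, "s2": 2e6}
        base = rpkm(counts, lengths, sizes)
        doubled = rpkm(counts * 2, lengths, {k: 2 * v for k, v in sizes.items()})
        pd.testing.assert_frame_equal(base, doubled)

    def test_missing_length_names_gene(self):
        counts = pd.DataFrame({"s1": [1]}, index=["g1"])
        with pytest.raises(KeyError, match="g1"):
            rpkm(counts, {}, {"s1": 10})

    def test_missing_library_size_names_stage(self):
        counts = pd.DataFrame({"s1": [1]}, index=["g1"])
        with pytest.raises(KeyError, match="s1"):
            rpkm(counts, {"g1": 100}, {})


class TestExpressedFilter:
    def _matrices(self):
        a = pd.DataFrame(
            {"s1": [0.9, 1.0], "s2": [0.9, 0.2]}, index=["a1", "a2"]
        )
        b = pd.DataFrame({"u1": [0.5, 0.5], "u2": [0.5, 0.5]}, index=["b1", "b2"])
        return a, b

    def test_gene_below_threshold_everywhere_is_unexpressed(self):
        a, b = self._matrices()
        assert filter_expressed_relations([rel("a1", "b1")], a, b) == []

    def test_boundary_value_is_inclusive(self):
        a, b = self._matrices()
        kept = filter_expressed_relations([rel("a2", "b2")], a, b)
        assert [r.gene_a for r in kept] == ["a2"]

    def test_unknown_gene_is_an_error(self):
        a, b = self._matrices()
        with pytest.raises(KeyError, match="zz"):
            filter_expressed_relations([rel("zz", "b1")], a, b)

    def test_random_matrices_match_any_over_six_values_oracle(self):
        rng = np.random.default_rng(2)
        a = pd.DataFrame(
            rng.uniform(0, 3, (20, 3)), index=[f"a{i}" for i in range(20)],
            columns=STAGES,
        )
        b = pd.DataFrame(
            rng.uniform(0, 3, (20, 3)), index=[f"b{i}" for i in range(20)],
            columns=["u1", "u2", "u3"],
        )
        rels = [rel(f"a{i}", f"b{i}") for i in range(20)]
        kept = filter_expressed_relations(rels, a, b)
        oracle = [
            r for r in rels
            if (a.loc[r.gene_a] >= 1).any() or (b.loc[r.gene_b] >= 1).any()
        ]
        assert kept == oracle


@pytest.mark.parametrize("value,expected", [(0, 0.0), (1, 1.0), (7, 3.0)])
def test_log2_profile_closed_form(value, expected):
    assert log2_profile([value])[0] == expected


def test_log2_profile_rejects_negative():
    with pytest.raises(ValueError):
        log2_profile([-0.1])


def _profiles(rows, index=None):
    arr = np.asarray(rows, dtype=float)
    idx = index or [f"r{i}" for i in range(len(arr))]
    return pd.DataFrame(arr, index=idx, columns=[f"c{j}" for j in range(arr.shape[1])])


class TestKmeansPearson:
    def test_two_groups_of_identical_profiles_perfectly_separated(self):
        profiles = _profiles([[1, 2, 3, 4]] * 4 + [[4, 3, 2, 1]] * 4)
        result = kmeans_pearson(profiles, 2, seed=0)
        labels = result.assignments
        assert result.objective == pytest.approx(0.0, abs=1e-12)
        assert len(set(labels.iloc[:4])) == 1 and len(set(labels.iloc[4:])) == 1
        assert labels.iloc[0] != labels.iloc[-1]

    def test_k1_centroid_is_global_mean(self):
        profiles = _profiles([[1, 2, 3], [3, 2, 1], [2, 2, 3]])
        result = kmeans_pearson(profiles, 1, seed=0)
        np.testing.assert_allclose(
            result.centroids.iloc[0].to_numpy(),
            profiles.to_numpy().mean(axis=0),
        )

    def test_k_larger_than_profile_count_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            kmeans_pearson(_profiles([[1, 2, 3]]), 2)

    def test_zero_variance_profiles_dropped_with_warning_or_error(self):
        profiles = _profiles([[1, 1, 1], [1, 2, 3], [3, 2, 1]])
        with pytest.warns(UserWarning, match="zero-variance"):
            result = kmeans_pearson(profiles, 2, seed=0)
        assert "r0" not in result.assignments.index
        with pytest.raises(ValueError, match="zero-variance"):
            kmeans_pearson(profiles, 2, seed=0, constant_profiles="error")

    def test_reproducible_given_seed(self):
        rng = np.random.default_rng(3)
        profiles = _profiles(rng.normal(size=(30, 6)))
        r1 = kmeans_pearson(profiles, 4, seed=9)
        r2 = kmeans_pearson(profiles, 4, seed=9)
        pd.testing.assert_series_equal(r1.assignments, r2.assignments)
        assert r1.objective == r2.objective

    def test_objective_non_increasing_across_iterations(self):
        """Each Lloyd iteration (assignment + mean update) may not raise the
        sum of correlation distances to the assigned centroid."""
        from orthonet.expression import _objective, _kmeans_once

        rng = np.random.default_rng(5)
        x = rng.normal(size=(40, 6))
        # instrument a manual loop mirroring the implementation
        centroids = x[rng.choice(40, size=4, replace=False)].copy()
        labels = pearson_distance(x, centroids).argmin(axis=1)
        objectives = [_objective(x, centroids, labels)]
        for _ in range(25):
            new_centroids = centroids.copy()
            for j in range(4):
                members = x[labels == j]
                if len(members):
                    new_centroids[j] = members.mean(axis=0)
            new_labels = pearson_distance(x, new_centroids).argmin(axis=1)
            obj = _objective(x, new_centroids, new_labels)
            if obj > objectives[-1] + 1e-12:
                break
            objectives.append(obj)
            if (new_labels == labels).all():
                break
            centroids, labels = new_centroids, new_labels
        assert all(b <= a + 1e-12 for a, b in zip(objectives, objectives[1:]))
        # and the packaged implementation reports a final objective no worse
        # than its first-iteration state
        labels2, centroids2, obj2, _ = _kmeans_once(
            x, 4, np.random.default_rng(5), 100
        )
        assert obj2 <= objectives[0] + 1e-9

    def test_small_instance_matches_exhaustive_partition_oracle(self):
        """On <= 12 profiles with k=2, the best K-means objective over many
        restarts equals the optimum over all 2-partitions."""
        rng = np.random.default_rng(11)
        base = np.array([[1, 2, 3, 4, 5, 6], [6, 5, 4, 3, 2, 1]], dtype=float)
        rows = [base[i % 2] + rng.normal(0, 0.2, 6) for i in range(10)]
        profiles = _profiles(rows)
        x = profiles.to_numpy()

        def objective_of(partition):
            total = 0.0
            for side in (partition, [not p for p in partition]):
                members = x[np.asarray(side, dtype=bool)]
                if len(members) == 0:
                    return math.inf
                centroid = members.mean(axis=0, keepdims=True)
                total += pearson_distance(members, centroid)[:, 0].sum()
            return total

        best_exhaustive = min(
            objective_of([bool(int(b)) for b in f"{mask:010b}"])
            for mask in range(1, 2 ** 9)  # fix profile 0's side; skip empty
        )
        result = kmeans_pearson(profiles, 2, seed=0, restarts=40)
        assert result.objective == pytest.approx(best_exhaustive, abs=1e-9)

    def test_planted_partition_recovered_at_low_noise(self):
        from sklearn.metrics import adjusted_rand_score

        rng = np.random.default_rng(21)
        templates = np.array(
            [[1, 2, 3, 4, 5, 6], [6, 5, 4, 3, 2, 1], [1, 6, 1, 6, 1, 6]],
            dtype=float,
        )
        truth, rows = [], []
        for i in range(30):
            c = i % 3
            truth.append(c)
            rows.append(templates[c] + rng.normal(0, 0.15, 6))
        result = kmeans_pearson(_profiles(rows), 3, seed=1, restarts=10)
        assert adjusted_rand_score(truth, result.assignments.to_numpy()) == 1.0

    def test_distance_in_unit_interval_and_centroids_in_hull(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=(20, 5))
        d = pearson_distance(x, x)
        assert (d >= 0).all() and (d <= 2).all()
        result = kmeans_pearson(_profiles(x), 3, seed=2)
        for j in range(1, 4):
            members = x[(result.assignments == j).to_numpy()]
            if len(members):
                np.testing.assert_allclose(
                    result.centroids.loc[j].to_numpy(), members.mean(axis=0)
                )


class TestFigureOfMerit:
    def test_zero_at_true_k_on_noiseless_data(self):
        templates = np.array(
            [[1, 2, 3, 4, 5, 6], [6, 5, 4, 3, 2, 1], [1, 6, 1, 6, 1, 6]],
            dtype=float,
        )
        rows = [templates[i % 3] for i in range(15)]
        out = figure_of_merit(_profiles(rows), [3], seed=0, restarts=10)
        assert out["fom"][3] == pytest.approx(0.0, abs=1e-9)

    def test_matches_independent_oracle(self):
        """FOM recomputed from the clustering labels by an independent
        per-stage RMS-deviation summation."""
        rng = np.random.default_rng(4)
        profiles = _profiles(rng.normal(size=(12, 4)))
        k = 3
        out = figure_of_merit(profiles, [k], seed=5, restarts=4)
        total = 0.0
        for s in range(4):
            rest = profiles.drop(columns=profiles.columns[s])
            result = kmeans_pearson(rest, k, seed=5 + s, restarts=4)
            held = profiles.iloc[:, s]
            sq = 0.0
            for cid in range(1, k + 1):
                vals = held.loc[result.members(cid)].to_numpy()
                if len(vals):
                    sq += ((vals - vals.mean()) ** 2).sum()
            total += math.sqrt(sq / len(profiles))
        assert out["fom"][k] == pytest.approx(total)

    def test_k_range_bounds_enforced(self):
        profiles = _profiles(np.arange(12.0).reshape(4, 3))
        with pytest.raises(ValueError, match="k_range"):
            figure_of_merit(profiles, [1], seed=0)
        with pytest.raises(ValueError, match="k_range"):
            figure_of_merit(profiles, [4], seed=0)


class TestHierarchicalSubcluster:
    def test_identical_profiles_merge_at_height_zero(self):
        z = hierarchical_subcluster(_profiles([[1, 2, 3], [1, 2, 3]]))
        assert z.shape == (1, 4)
        assert z[0, 2] == 0.0

    def test_outlier_merges_last(self):
        z = hierarchical_subcluster(
            _profiles([[0, 0, 0], [0.1, 0, 0], [9, 9, 9]])
        )
        # final merge joins the outlier singleton (leaf index 2)
        assert 2 in (int(z[-1, 0]), int(z[-1, 1]))
        assert np.all(np.diff(z[:, 2]) >= 0)

    def test_matches_naive_agglomeration_oracle(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=(8, 4))
        z = hierarchical_subcluster(_profiles(x))
        # naive average-linkage agglomeration over all pairs
        clusters = {i: [i] for i in range(8)}
        heights = []
        next_id = 8
        while len(clusters) > 1:
            best = None
            for a, b in itertools.combinations(sorted(clusters), 2):
                d = np.mean(
                    [
                        np.linalg.norm(x[i] - x[j])
                        for i in clusters[a]
                        for j in clusters[b]
                    ]
                )
                if best is None or d < best[0]:
                    best = (d, a, b)
            d, a, b = best
            heights.append(d)
            clusters[next_id] = clusters.pop(a) + clusters.pop(b)
            next_id += 1
        np.testing.assert_allclose(z[:, 2], heights, rtol=1e-10)

    def test_single_member_rejected(self):
        with pytest.raises(ValueError):
            hierarchical_subcluster(_profiles([[1, 2, 3]]))


class TestHypergeometricEnrichment:
    REFERENCE = {f"g{i}" for i in range(20)}

    def test_term_covering_whole_reference_never_enriched(self):
        term_map = {g: ["T_all"] for g in self.REFERENCE}
        table = hypergeometric_enrichment(
            {"g0", "g1"}, self.REFERENCE, term_map
        )
        assert table.loc["T_all", "p_value"] == pytest.approx(1.0)
        assert not table.loc["T_all", "enriched"]

    def test_matches_enumeration_oracle_on_small_universe(self):
        """Upper-tail probability equals exhaustive enumeration of draws."""
        universe = {f"g{i}" for i in range(12)}
        term_members = {"g0", "g1", "g2", "g3"}
        test = {"g0", "g1", "g2", "g4", "g5"}
        term_map = {g: ["T"] for g in term_members}
        table = hypergeometric_enrichment(test, universe, term_map)
        n = len(test)
        seen = len(term_members & test)
        favourable = total = 0
        for draw in itertools.combinations(sorted(universe), n):
            total += 1
            if len(set(draw) & term_members) >= seen:
                favourable += 1
        assert table.loc["T", "p_value"] == pytest.approx(favourable / total)

    def test_adjusted_p_never_below_raw_and_in_unit_interval(self):
        rng = np.random.default_rng(14)
        term_map = {
            f"g{i}": [f"T{rng.integers(0, 6)}" for _ in range(2)]
            for i in range(20)
        }
        test = {f"g{i}" for i in range(6)}
        table = hypergeometric_enrichment(test, self.REFERENCE, term_map)
        assert (table["adjusted_p"] >= table["p_value"] - 1e-12).all()
        assert table["p_value"].between(0, 1).all()
        assert table["adjusted_p"].between(0, 1).all()

    def test_invariant_to_term_input_order(self):
        term_map_1 = {"g0": ["A", "B"], "g1": ["B"], "g2": ["A"]}
        term_map_2 = {"g2": ["A"], "g0": ["B", "A"], "g1": ["B"]}
        t1 = hypergeometric_enrichment({"g0", "g1"}, self.REFERENCE, term_map_1)
        t2 = hypergeometric_enrichment({"g0", "g1"}, self.REFERENCE, term_map_2)
        pd.testing.assert_frame_equal(t1, t2)

    def test_test_outside_reference_rejected(self):
        with pytest.raises(ValueError, match="subset"):
            hypergeometric_enrichment({"zz"}, self.REFERENCE, {})


def test_relation_profiles_concatenate_species_stages():
    a = pd.DataFrame({"T1": [3.0], "T2": [0.0], "T3": [1.0]}, index=["a1"])
    b = pd.DataFrame({"G1": [7.0], "G2": [0.0], "G3": [15.0]}, index=["b1"])
    profiles = relation_profiles([rel("a1", "b1")], a, b)
    np.testing.assert_allclose(
        profiles.loc["a1|b1"].to_numpy(), [2.0, 0.0, 1.0, 3.0, 0.0, 4.0]
    )
    assert list(profiles.columns) == ["T1", "T2", "T3", "G1", "G2", "G3"]
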