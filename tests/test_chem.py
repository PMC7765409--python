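"""Fingerprint distances, Ward agglomeration, activity profiling."""

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import linkage as scipy_linkage
from scipy.spatial.distance import pdist, squareform

from steatoscreen.chem import (
    FingerprintSet,
    build_activity_matrix,
    cut_clusters,
    linkage_to_newick,
    pairwise_tanimoto,
    rank_target_classes,
    tanimoto_distance,
    ward_cluster,
)
from steatoscreen.synthetic import generate_compound_set


def bits(*on, n=16):
    v = np.zeros(n, dtype=bool)
    v[list(on)] = True
    return v


def greedy_ward_oracle(d: np.ndarray) -> np.ndarray:
    """Independent greedy-Ward oracle.

    Recomputes every candidate merge cost from the ORIGINAL squared
    dissimilarities via the centroid identity (no Lance-Williams recursion):
    for clusters A, B,

        cost(A,B) = 2|A||B|/(|A|+|B|) * ||c_A - c_B||^2,

    with the centroid gap expanded in pairwise distances. Ties resolve to
    the lexicographically smallest cluster-id pair.
    """
    n = d.shape[0]
    d2 = d ** 2
    members = {i: [i] for i in range(n)}
    merges = np.zeros((n - 1, 4))
    next_id = n
    for step in range(n - 1):
        best = None
        ids = sorted(members)
        for ai in range(len(ids)):
            for bi in range(ai + 1, len(ids)):
                a, b = ids[ai], ids[bi]
                ma, mb = members[a], members[b]
                na, nb = len(ma), len(mb)
                cross = sum(d2[i, j] for i in ma for j in mb) / (na * nb)
                within_a = sum(d2[i, j] for i in ma for j in ma) / (2 * na * na)
                within_b = sum(d2[i, j] for i in mb for j in mb) / (2 * nb * nb)
                gap = cross - within_a - within_b  # ||c_A - c_B||^2
                cost = 2.0 * na * nb / (na + nb) * gap
                if best is None or cost < best[0] - 1e-12 or (
                    abs(cost - best[0]) <= 1e-12 and (a, b) < best[1:]
                ):
                    best = (cost, a, b)
        cost, a, b = best
        merges[step] = (a, b, np.sqrt(max(cost, 0.0)), len(members[a]) + len(members[b]))
        members[next_id] = members.pop(a) + members.pop(b)
        next_id += 1
    return merges


class TestTanimoto:
    def test_identical_fingerprints_have_zero_distance(self):
        assert tanimoto_distance(bits(1, 2, 3), bits(1, 2, 3)) == 0.0

    def test_disjoint_fingerprints_have_unit_distance(self):
        assert tanimoto_distance(bits(0, 1), bits(2, 3)) == 1.0

    def test_half_overlap(self):
        # bits {1,2,3} vs {2,3,4}: 1 - 2/4
        assert tanimoto_distance(bits(1, 2, 3), bits(2, 3, 4)) == 0.5

    def test_two_empty_fingerprints_defined_as_zero(self):
        assert tanimoto_distance(bits(), bits()) == 0.0

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError, match="mismatch"):
            tanimoto_distance(bits(1, n=16), bits(1, n=32))


class TestWardCluster:
    def test_two_points_merge_at_their_distance(self):
        d = np.array([[0.0, 0.8], [0.8, 0.0]])
        link = ward_cluster(d)
        assert link.merges.shape == (1, 4)
        assert link.heights[0] == pytest.approx(0.8)

    def test_duplicated_point_merges_first_at_zero(self):
        d = squareform(pdist([[0.0], [0.0], [5.0]]))
        link = ward_cluster(d)
        assert link.heights[0] == 0.0
        assert set(link.merges[0, :2]) == {0.0, 1.0}

    def test_non_symmetric_matrix_rejected(self):
        d = np.array([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            ward_cluster(d)

    @pytest.mark.parametrize("seed", range(50))
    def test_matches_exhaustive_oracle_up_to_size_8(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 9))
        pts = rng.normal(size=(n, 3))
        d = squareform(pdist(pts))
        link = ward_cluster(d)
        oracle = greedy_ward_oracle(d)
        assert np.allclose(link.merges, oracle, atol=1e-8)
        assert np.all(np.diff(link.heights) >= -1e-12)  # no inversions

    def test_heights_match_scipy_ward(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(10, 4))
        mine = ward_cluster(squareform(pdist(pts)))
        ref = scipy_linkage(pdist(pts), method="ward")
        assert np.allclose(np.sort(mine.heights), np.sort(ref[:, 2]))

    def test_permutation_changes_only_labels(self):
        rng = np.random.default_rng(7)
        pts = rng.normal(size=(9, 3))
        d = squareform(pdist(pts))
        perm = rng.permutation(9)
        link_a = ward_cluster(d)
        link_b = ward_cluster(d[np.ix_(perm, perm)])
        assert np.allclose(np.sort(link_a.heights), np.sort(link_b.heights))


class TestCutClusters:
    def _link(self, n=6, seed=0):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(n, 2))
        return ward_cluster(squareform(pdist(pts)))

    def test_k_equals_n_gives_singletons(self):
        link = self._link(6)
        assert len(set(cut_clusters(link, k=6))) == 6

    def test_k_one_gives_single_cluster(self):
        link = self._link(6)
        assert set(cut_clusters(link, k=1)) == {0}

    def test_k_beyond_n_raises(self):
        with pytest.raises(ValueError):
            cut_clusters(self._link(6), k=7)

    def test_planted_families_recovered_at_k3(self):
        fps, _, families, _ = generate_compound_set(21, seed=11, n_families=3)
        link = ward_cluster(pairwise_tanimoto(fps), labels=fps.ids)
        labels = cut_clusters(link, k=3)
        # one-to-one mapping between cut labels and planted families
        assert len(set(zip(families.tolist(), labels.tolist()))) == 3

    def test_labels_stable_across_runs(self):
        link = self._link(8, seed=2)
        assert np.array_equal(cut_clusters(link, k=3), cut_clusters(link, k=3))


class TestNewick:
    def test_dendrogram_round_trips_through_newick(self):
        import dendropy

        fps, _, _, _ = generate_compound_set(7, seed=0)
        link = ward_cluster(pairwise_tanimoto(fps), labels=fps.ids)
        tree = dendropy.Tree.get(data=linkage_to_newick(link), schema="newick")
        leaves = {t.label for t in tree.taxon_namespace}
        assert leaves == set(fps.ids)


class TestActivityMatrix:
    def test_single_record_unmasked(self):
        m = build_activity_matrix(
            pd.DataFrame({"compound": ["c"], "target": ["t"], "value": [7.5]})
        )
        assert m.values.loc["c", "t"] == 7.5
        assert m.masked.loc["c", "t"] == 7.5

    def test_max_rule_over_repeated_measurements(self):
        records = pd.DataFrame(
            {
                "compound": ["c", "c"],
                "target": ["t", "t"],
                "source": ["a", "b"],
                "value": [6.5, 7.5],
            }
        )
        m = build_activity_matrix(records)
        assert m.values.loc["c", "t"] == 7.5

    def test_median_within_source_then_max_across(self):
        records = pd.DataFrame(
            {
                "compound": ["c"] * 4,
                "target": ["t"] * 4,
                "source": ["a", "a", "a", "b"],
                "value": [6.0, 6.4, 6.2, 7.0],
            }
        )
        assert build_activity_matrix(records).values.loc["c", "t"] == 7.0
        assert (
            build_activity_matrix(records, aggregation="median").values.loc["c", "t"]
            == pytest.approx(6.6)
        )

    def test_subcutoff_entry_present_but_masked(self):
        m = build_activity_matrix(
            pd.DataFrame({"compound": ["c"], "target": ["t"], "value": [6.9]})
        )
        assert m.values.loc["c", "t"] == 6.9
        assert np.isnan(m.masked.loc["c", "t"])

    def test_non_numeric_value_names_the_record(self):
        records = pd.DataFrame(
            {"compound": ["c1"], "target": ["t9"], "value": ["potent"]}
        )
        with pytest.raises(ValueError, match="c1.*t9"):
            build_activity_matrix(records)


class TestRankTargetClasses:
    def test_empty_matrix_gives_empty_summary(self):
        m = build_activity_matrix(
            pd.DataFrame({"compound": [], "target": [], "value": []})
        )
        assert rank_target_classes(m, {}).empty

    def test_ordering_by_active_pair_count(self):
        records = pd.DataFrame(
            {
                "compound": ["a", "b", "c", "d"],
                "target": ["t1", "t1", "t1", "t2"],
                "value": [7.5, 8.0, 7.2, 9.0],
            }
        )
        ranked = rank_target_classes(
            build_activity_matrix(records), {"t1": "kinase", "t2": "receptor"}
        )
        assert ranked.iloc[0]["target_class"] == "kinase"
        assert ranked.iloc[0]["n_active_pairs"] == 3

    def test_all_below_cutoff_yields_no_counts(self):
        records = pd.DataFrame(
            {"compound": ["a", "b"], "target": ["t", "t"], "value": [5.0, 6.0]}
        )
        assert rank_target_classes(build_activity_matrix(records), {}).empty

    def test_unmapped_targets_fall_into_unclassified(self):
        records = pd.DataFrame({"compound": ["a"], "target": ["t"], "value": [8.0]})
        ranked = rank_target_classes(build_activity_matrix(records), {})
        assert ranked.iloc[0]["target_class"] == "unclassified"


class TestFingerprintIO:
    def test_csv_round_trip(self, tmp_path):
        fps, _, _, _ = generate_compound_set(5, seed=1, n_bits=64)
        path = tmp_path / "fps.csv"
        fps.to_csv(path)
        back = FingerprintSet.from_csv(path)
        assert back.ids == fps.ids
        assert np.array_equal(back.bits, fps.bits)

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError, match="unique"):
            FingerprintSet(ids=["a", "a"], bits=np.zeros((2, 8), dtype=bool))
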