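"""Profile matrices: averaging, clustering, comparison, K-S, dendrograms."""

import numpy as np
import pytest

from motifshape.profile_analysis import (
    ProfileMatrix,
    aggregate_linkage,
    average_profile,
    cluster_rows,
    compare_profiles,
    dataset_profiles,
    ks_differential,
    read_matrix_tsv,
    shape_dendrogram,
    write_matrix_tsv,
)
from motifshape.tfbs_assembly import TFBSDataset


def _matrix(values, feature="MGW", positions=None):
    values = np.asarray(values, dtype=float)
    if positions is None:
        positions = np.arange(values.shape[1])
    return ProfileMatrix(
        feature=feature,
        seq_ids=[f"s{i}" for i in range(values.shape[0])],
        positions=positions,
        values=values,
    )


def _dataset(seqs, flank_width=0):
    core = len(seqs[0]) - 2 * flank_width
    return TFBSDataset(
        sequences=seqs,
        seq_ids=[f"s{i}" for i in range(len(seqs))],
        core_length=core,
        flank_width=flank_width,
    )


def brute_force_agglomerate(dist, method="average"):
    """Naive agglomeration recomputing cluster distances from members.

    Independent of the Lance-Williams update: average linkage is the
    mean over all cross-pairs of original distances.  Tie-break: first
    minimum over pairs in cluster-id creation order.
    """
    n = dist.shape[0]
    clusters = {i: [i] for i in range(n)}
    order = list(range(n))
    Z = []
    next_id = n
    while len(order) > 1:
        best = None
        for ai in range(len(order)):
            for bi in range(ai + 1, len(order)):
                a, b = order[ai], order[bi]
                pairs = [dist[x, y] for x in clusters[a] for y in clusters[b]]
                if method == "average":
                    d = float(np.mean(pairs))
                elif method == "single":
                    d = float(np.min(pairs))
                else:
                    d = float(np.max(pairs))
                if best is None or d < best[0]:
                    best = (d, a, b)
        d, a, b = best
        clusters[next_id] = clusters.pop(a) + clusters.pop(b)
        Z.append((min(a, b), max(a, b), d, len(clusters[next_id])))
        order = [c for c in order if c not in (a, b)] + [next_id]
        next_id += 1
    return np.array(Z)


class TestClusterOracle:
    @pytest.mark.parametrize("method", ["average", "single", "complete"])
    def test_merge_tree_equals_brute_force(self, method):
        rng = np.random.default_rng(101)
        for _ in range(20):
            n = int(rng.integers(3, 13))
            pts = rng.normal(size=(n, 4))
            dist = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
            Z = aggregate_linkage(dist, method=method)
            Zb = brute_force_agglomerate(dist, method=method)
            assert np.allclose(Z, Zb), (method, n)

    def test_identical_pair_merges_first(self):
        m = _matrix([[1.0, 2, 3], [1.0, 2, 3], [9, 9, 9]])
        order, Z = cluster_rows(m)
        assert set(Z[0, :2].astype(int)) == {0, 1} and Z[0, 2] == 0.0

    def test_row_cap_returns_input_order(self):
        m = _matrix(np.zeros((3001, 2)))
        order, Z = cluster_rows(m, max_rows=3000)
        assert Z is None and np.array_equal(order, np.arange(3001))

    def test_all_missing_row_excluded(self):
        vals = np.array([[1.0, 2], [np.nan, np.nan], [1.1, 2.1], [5, 6]])
        order, Z = cluster_rows(_matrix(vals))
        assert order[-1] == 1  # all-missing row pushed to the end
        assert Z.shape == (2, 4)

    def test_large_matrix_same_leaf_partition_as_small_path(self):
        # both code paths (own agglomeration vs C linkage) order two
        # well-separated blobs contiguously
        rng = np.random.default_rng(5)
        a = rng.normal(0, 0.1, size=(40, 3))
        b = rng.normal(10, 0.1, size=(40, 3))
        m = _matrix(np.vstack([a, b]))
        order, _ = cluster_rows(m)
        groups = (order < 40).astype(int)
        assert np.abs(np.diff(groups)).sum() == 1  # one switch point


class TestAverageProfile:
    def test_identical_rows(self):
        m = _matrix([[4.0, 5, 6]] * 3)
        assert np.allclose(average_profile(m), [4, 5, 6])

    def test_mean_of_two_rows(self):
        m = _matrix([[4.0, 6], [6.0, 4]])
        assert np.allclose(average_profile(m), [5, 5])

    def test_missing_values_ignored(self):
        m = _matrix([[1.0, np.nan], [3.0, 4.0], [5.0, 6.0]])
        assert np.allclose(average_profile(m), [3.0, 5.0])

    def test_all_missing_column_stays_missing(self):
        m = _matrix([[1.0, np.nan], [2.0, np.nan]])
        avg = average_profile(m)
        assert avg[0] == 1.5 and np.isnan(avg[1])


class TestDatasetProfiles(object):
    def test_flanked_core_fully_defined(self, table):
        ds = _dataset(["ATCACGTGAT", "GGCACGTGCC"], flank_width=2)
        mats = dataset_profiles(ds, table)
        core_cols = (mats["MGW"].positions >= 0) & (
            mats["MGW"].positions < ds.core_length
        )
        assert not np.isnan(mats["MGW"].values[:, core_cols]).any()
        assert set(mats) == {"MGW", "ProT", "Roll", "HelT"}

    def test_unflanked_core_missing_margins(self, table):
        ds = _dataset(["CACGTG", "CAAGTG"])
        mats = dataset_profiles(ds, table)
        v = mats["ProT"].values
        assert np.isnan(v[:, [0, 1, -2, -1]]).all()
        assert not np.isnan(v[:, 2:-2]).any()

    def test_single_sequence_matches_direct_prediction(self, table):
        from motifshape.shape_engine import predict_shape

        ds = _dataset(["ATCACGTGAT"], flank_width=2)
        mats = dataset_profiles(ds, table)
        prof = predict_shape("ATCACGTGAT", table)
        assert np.array_equal(mats["Roll"].values[0], prof.roll, equal_nan=True)

    def test_step_positions_are_midpoints(self, table):
        ds = _dataset(["ATCACGTGAT"], flank_width=2)
        mats = dataset_profiles(ds, table)
        assert mats["HelT"].positions[0] == -1.5
        assert mats["MGW"].positions[0] == -2.0


class TestCompareProfiles:
    def test_self_comparison(self):
        avg = {"MGW": np.array([4.0, 5, 6, 5]), "Roll": np.array([1.0, 2, 1])}
        res = compare_profiles(avg, avg, offset=0)
        for f in avg:
            assert res.per_feature[f]["pcc"] == pytest.approx(1.0)
            assert res.per_feature[f]["ed"] == 0.0

    def test_constant_shift_closed_form(self):
        a = {"MGW": np.array([4.0, 5, 6, 7])}
        b = {"MGW": a["MGW"] + 2.0}
        res = compare_profiles(a, b, offset=0)
        assert res.per_feature["MGW"]["pcc"] == pytest.approx(1.0)
        assert res.per_feature["MGW"]["ed"] == pytest.approx(2.0 * np.sqrt(4))

    def test_anticorrelated(self):
        res = compare_profiles(
            {"MGW": np.array([1.0, 2, 3])}, {"MGW": np.array([3.0, 2, 1])}, 0
        )
        assert res.per_feature["MGW"]["pcc"] == pytest.approx(-1.0)

    def test_offset_alignment(self):
        a = {"MGW": np.array([0.0, 1, 2, 3, 4])}
        b = {"MGW": np.array([1.0, 2, 3, 4, 5])}
        # b shifted by +1 aligns b[0] with a[1]: values equal
        res = compare_profiles(a, b, offset=1)
        assert res.per_feature["MGW"]["ed"] == 0.0
        assert res.per_feature["MGW"]["n_positions"] == 4

    def test_insufficient_overlap(self):
        a = {"MGW": np.array([1.0, 2, 3])}
        with pytest.raises(ValueError, match="overlap"):
            compare_profiles(a, a, offset=2)


class TestKsDifferential:
    def test_self_is_null(self):
        rng = np.random.default_rng(0)
        m = _matrix(rng.normal(size=(30, 4)))
        res = ks_differential(m, m)
        assert (res.table["D"] == 0).all()
        assert (res.table["category"] == "none").all()

    def test_disjoint_supports(self):
        m1 = _matrix([[1.0], [2], [3]] * 3)
        m2 = _matrix([[4.0], [5], [6]] * 3)
        res = ks_differential(m1, m2, min_n=3)
        assert res.table.loc[0, "D"] == 1.0

    def test_shifted_distributions_strong(self):
        rng = np.random.default_rng(1)
        m1 = _matrix(rng.normal(0, 1, size=(100, 3)))
        m2 = _matrix(rng.normal(5, 1, size=(100, 3)))
        res = ks_differential(m1, m2)
        assert (res.table["category"] == "strong").all()

    def test_small_groups_untested(self):
        m1 = _matrix(np.ones((4, 2)))
        m2 = _matrix(np.zeros((20, 2)))
        res = ks_differential(m1, m2)
        assert (res.table["category"] == "untested").all()

    def test_no_shared_columns(self):
        m1 = _matrix(np.ones((10, 2)), positions=[0, 1])
        m2 = _matrix(np.ones((10, 2)), positions=[5, 6])
        with pytest.raises(ValueError, match="share no position"):
            ks_differential(m1, m2)

    def test_null_rejection_rate_calibrated(self):
        """Under the null, p < 0.05 in about 5% of replicates."""
        rng = np.random.default_rng(99)
        n_rej = 0
        reps = 400
        for _ in range(reps):
            x = rng.normal(size=(60, 1))
            y = rng.normal(size=(60, 1))
            res = ks_differential(_matrix(x), _matrix(y))
            n_rej += res.table.loc[0, "p_value"] < 0.05
        assert 0.03 <= n_rej / reps <= 0.07


class TestDendrogram:
    def test_identical_profiles_are_siblings(self):
        prof = {
            "a": np.array([1.0, 2, 3]),
            "b": np.array([1.0, 2, 3]),
            "c": np.array([9.0, 9, 9]),
        }
        nwk, Z, labels = shape_dendrogram(prof)
        assert set(Z[0, :2].astype(int)) == {0, 1} and Z[0, 2] == 0.0
        assert "(a:0,b:0)" in nwk

    def test_two_planted_groups_form_two_clades(self):
        rng = np.random.default_rng(3)
        base1 = rng.normal(0, 1, size=6)
        base2 = base1 + 20
        prof = {
            "g1x": base1 + rng.normal(0, 0.01, 6),
            "g1y": base1 + rng.normal(0, 0.01, 6),
            "g2x": base2 + rng.normal(0, 0.01, 6),
            "g2y": base2 + rng.normal(0, 0.01, 6),
        }
        nwk, Z, labels = shape_dendrogram(prof)
        # first two merges are within-group; the last joins the clades
        merged = {frozenset(Z[0, :2].astype(int)), frozenset(Z[1, :2].astype(int))}
        assert merged == {frozenset({0, 1}), frozenset({2, 3})}

    def test_two_profiles_join_at_their_distance(self):
        a = np.array([0.0, 0, 0])
        b = np.array([3.0, 4, 0])
        nwk, Z, labels = shape_dendrogram({"a": a, "b": b})
        assert Z[0, 2] == pytest.approx(5.0)
        assert nwk == "(a:5,b:5);"

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError, match="equal length"):
            shape_dendrogram({"a": np.ones(3), "b": np.ones(4)})


class TestMatrixIO:
    def test_round_trip_bit_exact(self, table, tmp_path):
        ds = _dataset(["ATCACGTGAT", "GGCACGTGCC"], flank_width=2)
        mats = dataset_profiles(ds, table)
        for f, m in mats.items():
            path = tmp_path / f"{f}.tsv"
            write_matrix_tsv(m, path)
            loaded = read_matrix_tsv(path)
            assert loaded.feature == f
            assert np.array_equal(loaded.values, m.values, equal_nan=True)
            assert np.array_equal(loaded.positions, m.positions)
            assert loaded.seq_ids == m.seq_ids
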