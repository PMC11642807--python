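"""Atlas loading, hierarchy aggregation, region filters and adjacency views."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tauspread import (Connectome, SchemaError, ValidationError,
                       aggregate_hierarchy, build_euclidean_connectome,
                       directional_view, filter_regions, load_connectome,
                       oriented_views)
from tauspread.atlas import (RegionAtlas, load_atlas, regional_means,
                             save_atlas, validate_cohort)

from conftest import make_group_cohort


def _frame(rows):
    return pd.DataFrame(rows, columns=["region_id", "acronym", "hemisphere",
                                       "parent_id", "x", "y", "z"])


class TestAtlasValidation:
    def test_chain_levels(self, tmp_path):
        df = _frame([("a", "a", "ipsi", None, 0, 0, 0),
                     ("b", "b", "ipsi", "a", 1, 0, 0),
                     ("c", "c", "ipsi", "b", 2, 0, 0)])
        path = tmp_path / "atlas.csv"
        df.to_csv(path, index=False)
        atlas = load_atlas(path)
        assert atlas.table.loc[["a", "b", "c"], "level"].tolist() == [0, 1, 2]

    def test_roundtrip(self, toy_atlas, tmp_path):
        save_atlas(toy_atlas, tmp_path / "atlas.csv")
        again = load_atlas(tmp_path / "atlas.csv")
        assert again.region_ids == toy_atlas.region_ids
        assert again.table["level"].tolist() == toy_atlas.table["level"].tolist()

    def test_self_parent_is_cycle(self):
        with pytest.raises(ValidationError, match="cyclic"):
            RegionAtlas.from_frame(_frame([("a", "a", "ipsi", "a", 0, 0, 0)]))

    def test_two_cycle_names_offenders(self):
        with pytest.raises(ValidationError, match="a.*b|b.*a"):
            RegionAtlas.from_frame(_frame([("a", "a", "ipsi", "b", 0, 0, 0),
                                           ("b", "b", "ipsi", "a", 1, 0, 0)]))

    def test_duplicate_region_id(self):
        with pytest.raises(ValidationError, match="duplicate"):
            RegionAtlas.from_frame(_frame([("a", "a", "ipsi", None, 0, 0, 0),
                                           ("a", "a2", "ipsi", None, 1, 0, 0)]))

    def test_missing_column_is_schema_error(self):
        with pytest.raises(SchemaError, match="hemisphere"):
            RegionAtlas.from_frame(pd.DataFrame({"region_id": ["a"]}))

    def test_unknown_parent(self):
        with pytest.raises(ValidationError, match="unknown parent"):
            RegionAtlas.from_frame(_frame([("a", "a", "ipsi", "zz", 0, 0, 0)]))

    def test_nonfinite_centroid(self):
        with pytest.raises(ValidationError, match="centroid"):
            RegionAtlas.from_frame(_frame([("a", "a", "ipsi", None, np.nan, 0, 0)]))


class TestAggregateHierarchy:
    def test_children_sum_to_parent(self, toy_atlas):
        totals = aggregate_hierarchy({"DG": 5, "CA1": 3}, toy_atlas)
        assert totals["HIP"] == 8
        assert totals["DG"] == 5 and totals["CA1"] == 3

    def test_empty_counts_all_zero(self, toy_atlas):
        totals = aggregate_hierarchy({}, toy_atlas)
        assert all(v == 0 for v in totals.values())

    def test_three_level_chain(self, toy_atlas):
        # 1 at each of A -> B -> C accumulates to 3 at the root
        totals = aggregate_hierarchy({"A": 1, "B": 1, "C": 1}, toy_atlas)
        assert totals["C"] == 1 and totals["B"] == 2 and totals["A"] == 3

    def test_unknown_region_named(self, toy_atlas):
        with pytest.raises(ValidationError, match="XYZ"):
            aggregate_hierarchy({"XYZ": 1}, toy_atlas)

    def test_total_count_conserved(self, gt_small):
        rng = np.random.default_rng(0)
        leaves = list(gt_small.regions)
        counts = {r: float(rng.integers(0, 20)) for r in leaves}
        totals = aggregate_hierarchy(counts, gt_small.atlas)
        assert totals["root"] == pytest.approx(sum(counts.values()))


class TestFilterRegions:
    def _cohort(self, per_group, region="R1"):
        sizes = dict(zip([("WT", "Sal"), ("WT", "PTZ"), ("5X", "Sal"),
                          ("5X", "PTZ")], per_group))
        return make_group_cohort(sizes, regions=(region,))

    def test_six_per_group_retained(self):
        kept, excluded = filter_regions(self._cohort([6, 6, 6, 6]), 6)
        assert excluded == [] and kept["region_id"].nunique() == 1

    def test_one_group_below_threshold_excluded(self):
        df = pd.concat([self._cohort([6, 6, 6, 6], "R1"),
                        self._cohort([6, 6, 5, 6], "R2")], ignore_index=True)
        kept, excluded = filter_regions(df, 6)
        assert excluded == ["R2"]
        assert set(kept["region_id"]) == {"R1"}

    def test_threshold_one_is_identity(self):
        df = self._cohort([2, 1, 3, 1])
        kept, excluded = filter_regions(df, 1)
        assert excluded == []
        assert set(kept["region_id"]) == set(df["region_id"])

    def test_monotone_in_threshold(self, cohort_small):
        prev = None
        for thr in (1, 4, 7, 9):
            kept, _ = filter_regions(cohort_small, thr)
            regions = set(kept["region_id"])
            if prev is not None:
                assert regions <= prev
            prev = regions

    def test_missing_pathology_not_counted(self):
        df = self._cohort([6, 6, 6, 6])
        df.loc[df.index[:1], "pathology"] = np.nan
        _, excluded = filter_regions(df, 6)
        assert excluded == ["R1"]


class TestEuclideanConnectome:
    def test_inverse_distance(self):
        atlas = RegionAtlas.from_frame(_frame([
            ("a", "a", "ipsi", None, 0, 0, 0), ("b", "b", "ipsi", None, 2, 0, 0)]))
        conn = build_euclidean_connectome(atlas, ["a", "b"])
        assert conn.A[0, 1] == pytest.approx(0.5)
        assert conn.A[1, 0] == pytest.approx(0.5)
        assert conn.mode == "euclidean"

    def test_collinear_middle_has_largest_weights(self):
        atlas = RegionAtlas.from_frame(_frame([
            ("a", "a", "ipsi", None, 0, 0, 0), ("m", "m", "ipsi", None, 1, 0, 0),
            ("b", "b", "ipsi", None, 2, 0, 0)]))
        conn = build_euclidean_connectome(atlas, ["a", "m", "b"])
        # hand-enumerated: d(a,m)=d(m,b)=1 -> weight 1; d(a,b)=2 -> weight 0.5
        off = conn.A[~np.eye(3, dtype=bool)]
        assert sorted(off) == pytest.approx([0.5, 0.5, 1, 1, 1, 1])
        assert conn.A[1, 0] == conn.A[1, 2] == off.max()

    def test_symmetric_and_rigid_motion_invariant(self, gt_small):
        regions = list(gt_small.regions)[:12]
        conn = build_euclidean_connectome(gt_small.atlas, regions)
        assert np.array_equal(conn.A, conn.A.T)
        # rotate + translate every centroid; weights must not change
        rng = np.random.default_rng(1)
        Q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        table = gt_small.atlas.table.copy()
        table[["x", "y", "z"]] = table[["x", "y", "z"]].to_numpy() @ Q.T + 123.0
        moved = RegionAtlas.from_frame(table.reset_index(drop=True))
        conn2 = build_euclidean_connectome(moved, regions)
        np.testing.assert_allclose(conn2.A, conn.A, rtol=1e-9)

    def test_coincident_centroids_rejected(self):
        atlas = RegionAtlas.from_frame(_frame([
            ("a", "a", "ipsi", None, 0, 0, 0), ("b", "b", "ipsi", None, 0, 0, 0)]))
        with pytest.raises(ValidationError, match="coincident"):
            build_euclidean_connectome(atlas, ["a", "b"])

    def test_exponential_kernel(self):
        atlas = RegionAtlas.from_frame(_frame([
            ("a", "a", "ipsi", None, 0, 0, 0), ("b", "b", "ipsi", None, 2, 0, 0)]))
        conn = build_euclidean_connectome(atlas, ["a", "b"],
                                          kernel="exponential", length_scale=2.0)
        assert conn.A[0, 1] == pytest.approx(np.exp(-1.0))


class TestDirectionalView:
    def test_transpose(self, tiny_conn):
        retro = directional_view(tiny_conn, "retrograde")
        assert retro.A[0, 1] == 0 and retro.A[1, 0] == 1
        assert retro.mode == "retrograde"

    def test_involution(self, gt_small):
        conn = gt_small.connectomes["anterograde"]
        back = directional_view(directional_view(conn, "retrograde"), "anterograde")
        np.testing.assert_array_equal(back.A, conn.A)

    def test_symmetric_matrix_views_identical(self):
        A = np.array([[0.0, 2.0], [2.0, 0.0]])
        conn = Connectome(regions=("a", "b"), A=A)
        retro = directional_view(conn, "retrograde")
        np.testing.assert_array_equal(retro.A, conn.A)

    def test_euclidean_rejected(self, gt_small):
        with pytest.raises(ValidationError, match="euclidean"):
            directional_view(gt_small.connectomes["euclidean"], "anterograde")

    def test_convention_switch(self, tiny_conn):
        flipped = oriented_views(tiny_conn.A, tiny_conn.regions,
                                 direction_convention="retrograde")
        np.testing.assert_array_equal(flipped["retrograde"].A, tiny_conn.A)
        np.testing.assert_array_equal(flipped["anterograde"].A, tiny_conn.A.T)


class TestConnectomeIO:
    def test_rejects_nan(self, tmp_path):
        pd.DataFrame([[0.0, np.nan], [1.0, 0.0]], index=["a", "b"],
                     columns=["a", "b"]).to_csv(tmp_path / "A.csv")
        with pytest.raises(ValidationError, match="NaN"):
            load_connectome(tmp_path / "A.csv")

    def test_rejects_negative(self):
        with pytest.raises(ValidationError, match="negative"):
            Connectome(regions=("a", "b"), A=np.array([[0.0, -1.0], [0.0, 0.0]]))

    def test_rejects_nonzero_diagonal(self):
        with pytest.raises(ValidationError, match="diagonal"):
            Connectome(regions=("a", "b"), A=np.array([[1.0, 1.0], [0.0, 0.0]]))


class TestCohortValidation:
    def test_negative_density_rejected(self):
        df = make_group_cohort({("WT", "Sal"): 3})
        df.loc[df.index[0], "pathology"] = -1.0
        with pytest.raises(ValidationError, match="negative"):
            validate_cohort(df)

    def test_duplicate_mouse_region_rejected(self):
        df = make_group_cohort({("WT", "Sal"): 3})
        df = pd.concat([df, df.iloc[[0]]], ignore_index=True)
        with pytest.raises(ValidationError, match="duplicate"):
            validate_cohort(df)

    def test_unknown_region_rejected(self, toy_atlas):
        df = make_group_cohort({("WT", "Sal"): 3}, regions=("nowhere",))
        with pytest.raises(ValidationError, match="nowhere"):
            validate_cohort(df, atlas=toy_atlas)

    def test_regional_means_alignment(self):
        df = make_group_cohort({("WT", "Sal"): 4}, regions=("R1", "R2"), value=2.0)
        means = regional_means(df, ["R2", "R1", "R9"])
        assert means[0] == 2.0 and means[1] == 2.0 and np.isnan(means[2])


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=2 ** 31 - 1))
def test_oriented_views_are_mutual_transposes(seed):
    rng = np.random.default_rng(seed)
    A = rng.random((4, 4)) * (rng.random((4, 4)) < 0.7)
    np.fill_diagonal(A, 0.0)
    views = oriented_views(A, [f"r{i}" for i in range(4)])
    np.testing.assert_array_equal(views["anterograde"].A, views["retrograde"].A.T)
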