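"""Seed partition, walk-count maps, normalization, argmax and reduction."""

import numpy as np
import pandas as pd
import pytest

from conftest import exhaustive_walk_counts
from sfc_aging.connectome import BinaryGraph
from sfc_aging.io import build_node_table
from sfc_aging.sfc import (
    SeedSet,
    SFCMapSet,
    average_maps,
    combined_map,
    partition_caudate,
    region_reduce,
    sfc_maps,
    zscore_maps,
)


def _graph(edges, n):
    adj = np.zeros((n, n))
    for i, j in edges:
        adj[i, j] = adj[j, i] = 1
    return BinaryGraph(adj)


class TestPartition:
    def test_row_atlas(self, row_atlas):
        medial, lateral = partition_caudate(row_atlas, 6)
        # nodes are the caudate voxels in array order: (1,0,0),(2,0,0),(3,0,0)
        assert medial.nodes.tolist() == [0]
        assert lateral.nodes.tolist() == [1, 2]
        assert medial.name == "medial_caudate"
        assert lateral.name == "lateral_caudate"

    def test_face_layer_exactly(self):
        # 3D block: ventricle slab at x=0, caudate at x in {1, 2}
        from sfc_aging.io import LabelEntry, LabelVolume

        labels = np.zeros((3, 3, 3), dtype=np.int32)
        labels[0] = 1
        labels[1:] = 2
        atlas = LabelVolume(
            labels,
            {1: LabelEntry("ventricle", "ventricle"), 2: LabelEntry("caudate_left", "caudate_left")},
        )
        nt = build_node_table(atlas)
        medial, lateral = partition_caudate(atlas, 6, nt)
        medial_coords = {tuple(nt.coords[i]) for i in medial.nodes}
        assert medial_coords == {(1, y, z) for y in range(3) for z in range(3)}
        assert len(lateral) == 9

    def test_corner_case_26_vs_6(self, corner_atlas):
        nt = build_node_table(corner_atlas)
        coords = {i: tuple(nt.coords[i]) for i in range(nt.n_nodes)}
        med6, lat6 = partition_caudate(corner_atlas, 6, nt)
        assert {coords[i] for i in med6.nodes} == {(1, 0, 0)}
        assert {coords[i] for i in lat6.nodes} == {(1, 1, 1), (2, 1, 1)}
        med26, lat26 = partition_caudate(corner_atlas, 26, nt)
        assert {coords[i] for i in med26.nodes} == {(1, 0, 0), (1, 1, 1)}
        assert {coords[i] for i in lat26.nodes} == {(2, 1, 1)}

    def test_degenerate_geometries(self):
        from sfc_aging.io import LabelEntry, LabelVolume

        d = {1: LabelEntry("ventricle", "ventricle"), 2: LabelEntry("caudate_left", "caudate_left")}
        all_medial = np.zeros((2, 1, 1), dtype=np.int32)
        all_medial[0], all_medial[1] = 1, 2
        with pytest.raises(ValueError, match="every caudate voxel"):
            partition_caudate(LabelVolume(all_medial, d), 6)
        none_medial = np.zeros((3, 1, 1), dtype=np.int32)
        none_medial[0], none_medial[2] = 1, 2
        with pytest.raises(ValueError, match="no caudate voxel"):
            partition_caudate(LabelVolume(none_medial, d), 6)
        with pytest.raises(ValueError, match="no ventricle"):
            only_caud = np.full((2, 1, 1), 2, dtype=np.int32)
            partition_caudate(LabelVolume(only_caud, {2: d[2]}), 6)


class TestWalkCounts:
    def test_path_graph_examples(self):
        g = _graph([(0, 1), (1, 2)], 3)  # s - b - c
        maps = sfc_maps(g, SeedSet(np.array([0]), "custom"))
        assert maps.steps[1].tolist() == [0, 1, 0]
        assert maps.steps[2].tolist() == [1, 0, 1]
        assert maps.steps[3].tolist() == [0, 2, 0]

    def test_triangle_step3(self):
        g = _graph([(0, 1), (1, 2), (0, 2)], 3)
        maps = sfc_maps(g, SeedSet(np.array([0]), "custom"))
        assert maps.steps[3][1] == 3  # (A^3)_ab = 3 on K3

    def test_degree_toward_seed_identity(self, rng):
        adj = (rng.random((12, 12)) < 0.3).astype(float)
        adj = np.triu(adj, 1)
        adj = adj + adj.T
        g = BinaryGraph(adj)
        seed = SeedSet(rng.choice(12, size=4, replace=False))
        maps = sfc_maps(g, seed)
        expected = adj[seed.nodes].sum(axis=0)
        np.testing.assert_array_equal(maps.steps[1], expected)

    def test_oracle_small_graphs(self, rng):
        for _ in range(10):
            n = int(rng.integers(3, 9))
            adj = np.triu((rng.random((n, n)) < 0.45).astype(float), 1)
            adj = adj + adj.T
            g = BinaryGraph(adj)
            n_seed = int(rng.integers(1, n))
            seed = SeedSet(rng.choice(n, size=n_seed, replace=False))
            maps = sfc_maps(g, seed)
            oracle = exhaustive_walk_counts(adj, seed.nodes, 4)
            for k in range(1, 5):
                np.testing.assert_array_equal(maps.steps[k], oracle[k])

    def test_permutation_equivariance(self, rng):
        adj = np.triu((rng.random((8, 8)) < 0.4).astype(float), 1)
        adj = adj + adj.T
        perm = rng.permutation(8)
        seed = np.array([0, 3])
        m1 = sfc_maps(BinaryGraph(adj), SeedSet(seed))
        padj = adj[np.ix_(perm, perm)]
        inv = np.argsort(perm)
        m2 = sfc_maps(BinaryGraph(padj), SeedSet(inv[seed]))
        for k in range(1, 5):
            np.testing.assert_array_equal(m2.steps[k], m1.steps[k][perm])

    def test_disconnected_node_zero(self):
        g = _graph([(0, 1)], 3)  # node 2 isolated
        maps = sfc_maps(g, SeedSet(np.array([0])))
        assert all(maps.steps[k][2] == 0 for k in range(1, 5))

    def test_parameter_errors(self):
        g = _graph([(0, 1)], 2)
        with pytest.raises(ValueError, match="max_step"):
            sfc_maps(g, SeedSet(np.array([0])), max_step=0)
        with pytest.raises(ValueError, match="outside"):
            sfc_maps(g, SeedSet(np.array([5])))
        with pytest.raises(ValueError, match="nonempty"):
            SeedSet(np.array([], dtype=int))
        with pytest.raises(ValueError, match="duplicate"):
            SeedSet(np.array([1, 1]))


class TestNormalization:
    def test_zscore_mean_sd_and_seed_nan(self, rng):
        adj = np.triu((rng.random((20, 20)) < 0.4).astype(float), 1)
        adj = adj + adj.T
        seed = SeedSet(np.array([0, 1]))
        z = zscore_maps(sfc_maps(BinaryGraph(adj), seed))
        for k in range(1, 5):
            vals = z.steps[k]
            assert np.isnan(vals[0]) and np.isnan(vals[1])
            rest = vals[2:]
            assert rest.mean() == pytest.approx(0.0, abs=1e-12)
            assert rest.std() == pytest.approx(1.0, abs=1e-12)

    def test_constant_step_zscores_to_zero(self):
        g = _graph([], 4)  # empty graph: every step map is all-zero (constant)
        maps = sfc_maps(g, SeedSet(np.array([0])))
        z = zscore_maps(maps)
        assert np.all(z.steps[1][1:] == 0.0)

    def test_idempotent(self, rng):
        adj = np.triu((rng.random((6, 6)) < 0.5).astype(float), 1)
        adj = adj + adj.T
        z = zscore_maps(sfc_maps(BinaryGraph(adj), SeedSet(np.array([0]))))
        assert zscore_maps(z) is z


class TestAverageAndCombined:
    def _mapset(self, arrays, normalization="zscore"):
        return SFCMapSet(
            {k + 1: np.asarray(a, dtype=float) for k, a in enumerate(arrays)},
            SeedSet(np.array([9]), "whole_caudate"),
            normalization,
        )

    def test_average_identity_and_mean(self):
        m = self._mapset([[1.0, 2.0], [0.0, 1.0], [0.0, 0.0], [0.0, 0.0]])
        assert average_maps([m, m]).steps[1].tolist() == [1.0, 2.0]
        m2 = self._mapset([[3.0, 2.0], [0.0, 1.0], [0.0, 0.0], [0.0, 0.0]])
        assert average_maps([m, m2]).steps[1].tolist() == [2.0, 2.0]

    def test_average_oracle(self, rng):
        sets = [self._mapset(rng.normal(size=(4, 7))) for _ in range(5)]
        avg = average_maps(sets)
        for k in range(1, 5):
            np.testing.assert_allclose(avg.steps[k], np.mean([s.steps[k] for s in sets], axis=0))

    def test_average_mixed_normalization_error(self):
        a = self._mapset(np.ones((4, 2)), "zscore")
        b = self._mapset(np.ones((4, 2)), "raw_counts")
        with pytest.raises(ValueError, match="mixed normalizations"):
            average_maps([a, b])

    def test_combined_argmax_tie_and_sentinel(self):
        m = self._mapset(
            [[0.9, 0.5, 0.0], [0.4, 0.5, 0.0], [0.1, 0.1, 0.0], [0.0, 0.0, 0.0]]
        )
        assert combined_map(m).tolist() == [1, 1, 0]

    def test_combined_needs_four_steps(self):
        m = SFCMapSet({1: np.zeros(2)}, SeedSet(np.array([0])), "zscore")
        with pytest.raises(ValueError, match="steps 1-4"):
            combined_map(m)

    def test_combined_handles_nan_seed_entries(self):
        arrays = np.zeros((4, 3))
        arrays[:, 0] = np.nan
        arrays[2, 1] = 1.5
        m = self._mapset(arrays)
        out = combined_map(m)
        assert out[0] == 0 and out[1] == 3 and out[2] == 0


class TestRegionReduce:
    def test_group_by_oracle(self, small_config, rng):
        from sfc_aging.cohort import build_phantom_atlas

        atlas = build_phantom_atlas(small_config.grid_dims, small_config.n_parcels, small_config.seed)
        nt = build_node_table(atlas)
        values = rng.normal(size=nt.n_nodes)
        got = region_reduce(values, nt)
        labels = atlas.labels_of_class("cortical_parcel", "subcortical_parcel")
        expected = pd.Series(
            {atlas.dictionary[l].name: values[nt.nodes_with_label(l)].mean() for l in labels}
        )
        pd.testing.assert_series_equal(got, expected[got.index], check_names=False)

    def test_constant_map(self, row_atlas):
        nt = build_node_table(row_atlas)
        got = region_reduce(np.full(nt.n_nodes, 2.5), nt, region_labels=[2])
        assert got.tolist() == [2.5]

    def test_nan_dropped_and_all_nan_raises(self, row_atlas):
        nt = build_node_table(row_atlas)
        vals = np.array([np.nan, 1.0, 3.0])
        assert region_reduce(vals, nt, region_labels=[2]).tolist() == [2.0]
        with pytest.raises(ValueError, match="no finite"):
            region_reduce(np.full(3, np.nan), nt, region_labels=[2])
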