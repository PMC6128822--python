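import numpy as np
import pytest
from scipy import stats

import cuetopo as ct
from cuetopo.clusters import connectivity_structure


def _statmap(tvals, df=100, voxel_mm=3.0):
    affine = np.diag([voxel_mm] * 3 + [1.0])
    return ct.StatMap(ct.VolumeGrid(np.asarray(tvals, dtype=float), affine), df=df)


def _mask_like(smap):
    return ct.MaskVolume(ct.VolumeGrid(np.ones(smap.grid.shape), smap.grid.affine))


def flood_fill_components(binary, connectivity):
    """Brute-force connected components by BFS (independent oracle)."""
    offsets = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if (dx, dy, dz) == (0, 0, 0):
                    continue
                order = abs(dx) + abs(dy) + abs(dz)
                if (connectivity == 6 and order == 1) or \
                   (connectivity == 18 and order <= 2) or connectivity == 26:
                    offsets.append((dx, dy, dz))
    seen = np.zeros_like(binary, dtype=bool)
    comps = []
    for start in map(tuple, np.argwhere(binary)):
        if seen[start]:
            continue
        stack, comp = [start], []
        seen[start] = True
        while stack:
            v = stack.pop()
            comp.append(v)
            for off in offsets:
                w = tuple(np.add(v, off))
                if all(0 <= w[i] < binary.shape[i] for i in range(3)) \
                        and binary[w] and not seen[w]:
                    seen[w] = True
                    stack.append(w)
        comps.append(sorted(comp))
    return comps


class TestLabelClusters:
    def test_single_suprathreshold_voxel(self):
        t = np.zeros((5, 5, 5))
        t[2, 2, 2] = 10.0
        records = ct.label_clusters(_statmap(t), 0.005, _mask_like(_statmap(t)))
        assert len(records) == 1
        assert records[0].size_voxels == 1
        assert records[0].peak_voxel_index == (2, 2, 2)

    def test_corner_touch_connectivity_semantics(self):
        t = np.zeros((4, 4, 4))
        t[0, 0, 0] = 10.0
        t[1, 1, 1] = 10.0  # shares only a corner
        smap = _statmap(t)
        assert len(ct.label_clusters(smap, 0.005, _mask_like(smap), connectivity=6)) == 2
        assert len(ct.label_clusters(smap, 0.005, _mask_like(smap), connectivity=26)) == 1

    @pytest.mark.parametrize("connectivity", [6, 18, 26])
    def test_matches_flood_fill_oracle(self, connectivity):
        rng = np.random.default_rng(5)
        t = np.where(rng.random((12, 12, 12)) < 0.2, 10.0, 0.0)
        smap = _statmap(t)
        records = ct.label_clusters(smap, 0.005, _mask_like(smap), connectivity)
        oracle = flood_fill_components(t > 0, connectivity)
        assert len(records) == len(oracle)
        got = sorted(sorted(map(tuple, r.member_voxel_indices)) for r in records)
        expected = sorted([[tuple(v) for v in comp] for comp in oracle])
        assert got == expected

    def test_partition_property(self):
        """Members are disjoint and their union is the suprathreshold set."""
        rng = np.random.default_rng(9)
        t = rng.normal(size=(10, 10, 10)) * 3
        smap = _statmap(t)
        records = ct.label_clusters(smap, 0.01, _mask_like(smap))
        t_thr = stats.t.isf(0.01, smap.df)
        supra = set(map(tuple, np.argwhere(t > t_thr)))
        all_members = [tuple(v) for r in records for v in r.member_voxel_indices]
        assert len(all_members) == len(set(all_members))
        assert set(all_members) == supra

    def test_sorted_by_size_then_peak(self):
        t = np.zeros((8, 8, 8))
        t[0, 0, 0:3] = 5.0
        t[4, 4, 0:3] = 4.0
        t[7, 7, 0] = 9.0
        smap = _statmap(t)
        records = ct.label_clusters(smap, 0.005, _mask_like(smap))
        sizes = [r.size_voxels for r in records]
        assert sizes == sorted(sizes, reverse=True)
        assert records[0].peak_t == 5.0  # equal sizes: higher peak first
        assert records[1].peak_t == 4.0


class TestMonteCarloExtent:
    def test_vacuous_alpha_gives_one(self, unit_mask):
        thr = ct.monte_carlo_extent_threshold(unit_mask((8, 8, 8)), 0.0,
                                              cluster_alpha=1.0, n_iterations=100, seed=0)
        assert thr.min_cluster_size_voxels == 1

    def test_unsmoothed_matches_independence_oracle(self, unit_mask):
        """FWHM=0: threshold agrees with direct simulation of iid fields."""
        mask = unit_mask((20, 20, 20))
        thr = ct.monte_carlo_extent_threshold(mask, 0.0, voxel_p=0.005,
                                              cluster_alpha=0.05,
                                              n_iterations=1000, seed=1)
        # independent oracle: fresh iid normal fields, same rule
        rng = np.random.default_rng(99)
        z = stats.norm.isf(0.005)
        from scipy import ndimage
        maxes = []
        for _ in range(1000):
            supra = rng.standard_normal((20, 20, 20)) > z
            labels, n = ndimage.label(supra, structure=connectivity_structure(6))
            maxes.append(np.bincount(labels.ravel())[1:].max() if n else 0)
        maxes = np.array(maxes)
        oracle = next(k for k in range(1, 50) if np.mean(maxes >= k) <= 0.05)
        assert abs(thr.min_cluster_size_voxels - oracle) <= 1

    def test_monotone_in_voxel_p(self, unit_mask):
        mask = unit_mask((16, 16, 16))
        thr_strict = ct.monte_carlo_extent_threshold(mask, 6.0, voxel_p=0.005,
                                                     n_iterations=300, seed=2)
        thr_loose = ct.monte_carlo_extent_threshold(mask, 6.0, voxel_p=0.01,
                                                    n_iterations=300, seed=2)
        assert thr_strict.min_cluster_size_voxels <= thr_loose.min_cluster_size_voxels

    def test_monotone_in_smoothness(self, unit_mask):
        mask = unit_mask((16, 16, 16))
        sizes = [ct.monte_carlo_extent_threshold(mask, fwhm, n_iterations=300,
                                                 seed=3).min_cluster_size_voxels
                 for fwhm in (0.0, 4.0, 8.0)]
        assert sizes == sorted(sizes)

    def test_kernel_larger_than_mask_rejected(self, unit_mask):
        with pytest.raises(ValueError, match="kernel larger"):
            ct.monte_carlo_extent_threshold(unit_mask((4, 4, 4)), 100.0,
                                            n_iterations=100, seed=0)


class TestApplyExtentThreshold:
    def _threshold(self, min_size, null_sizes):
        return ct.ExtentThreshold(voxel_p=0.005, cluster_alpha=0.05,
                                  min_cluster_size_voxels=min_size,
                                  smoothness_fwhm_mm=8.0, n_iterations=len(null_sizes),
                                  connectivity=6, seed=0,
                                  null_max_sizes=np.asarray(null_sizes))

    def _cluster(self, size):
        members = np.array([[0, 0, k] for k in range(size)])
        return ct.ClusterRecord(label_id=1, size_voxels=size, peak_t=5.0,
                                peak_voxel_index=(0, 0, 0), peak_mm=(0, 0, 0),
                                member_voxel_indices=members, voxel_p=0.005,
                                connectivity=6)

    def test_48_voxel_rule(self):
        thr = self._threshold(48, np.arange(100))
        assert ct.apply_extent_threshold([self._cluster(47)], thr) == []
        kept = ct.apply_extent_threshold([self._cluster(48)], thr)
        assert len(kept) == 1

    def test_empty_input(self):
        assert ct.apply_extent_threshold([], self._threshold(10, [1, 2, 3] * 40)) == []

    def test_cluster_p_below_alpha_for_kept(self):
        null = np.concatenate([np.full(96, 5), np.full(4, 60)])
        thr = self._threshold(50, null)
        kept = ct.apply_extent_threshold([self._cluster(55)], thr)
        assert kept[0].cluster_p == pytest.approx(0.04)
        assert kept[0].cluster_p <= thr.cluster_alpha

    def test_parameter_mismatch_rejected(self):
        thr = self._threshold(10, np.arange(100))
        bad = self._cluster(20)
        bad.voxel_p = 0.01
        with pytest.raises(ValueError, match="do not match"):
            ct.apply_extent_threshold([bad], thr)


class TestDilateMask:
    def _point_mask(self):
        data = np.zeros((7, 7, 7))
        data[3, 3, 3] = 1.0
        return ct.MaskVolume(ct.VolumeGrid(data, np.diag([3, 3, 3, 1.0])))

    def test_zero_iterations_is_identity(self):
        mask = self._point_mask()
        out = ct.dilate_mask(mask, 0)
        np.testing.assert_array_equal(out.grid.data, mask.grid.data)

    def test_single_voxel_six_connected_grows_to_seven(self):
        out = ct.dilate_mask(self._point_mask(), 1, connectivity=6)
        assert out.n_voxels == 7

    def test_dilation_is_superset_and_monotone(self):
        mask = self._point_mask()
        prev = mask.bool_array
        for it in (1, 2, 3):
            cur = ct.dilate_mask(mask, it).bool_array
            assert np.all(cur[prev])  # superset
            prev = cur
        assert ct.dilate_mask(mask, 3).n_voxels > ct.dilate_mask(mask, 1).n_voxels
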