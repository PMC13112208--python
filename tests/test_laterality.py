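"""Lateralization indices: Eq-style identity, bootstrap, ROI selection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from facedcm.cohort import generate_stat_map_pair
from facedcm.laterality import (ROIMask, StatMap, UndefinedLIError,
                                bootstrap_li, bootstrap_li_samples,
                                classify_dominance, compute_li,
                                conjunction_map, select_subject_roi,
                                trimmed_mean, weighted_li)


class TestComputeLI:
    @pytest.mark.parametrize("a_l,a_r,expected", [
        (1.0, 1.0, 0.0),
        (2.0, 1.0, 1.0 / 3.0),
        (0.0, 5.0, -1.0),
        (5.0, 0.0, 1.0),
    ])
    def test_values(self, a_l, a_r, expected):
        assert compute_li(a_l, a_r) == pytest.approx(expected)

    def test_zero_denominator_rejected(self):
        with pytest.raises(UndefinedLIError):
            compute_li(0.0, 0.0)

    def test_negative_mass_rejected(self):
        with pytest.raises(ValueError):
            compute_li(-1.0, 2.0)

    @settings(max_examples=50, deadline=None)
    @given(a=st.floats(0, 1e6), b=st.floats(0, 1e6))
    def test_range_and_antisymmetry(self, a, b):
        if a + b == 0:
            return
        li = compute_li(a, b)
        assert -1.0 <= li <= 1.0
        assert compute_li(b, a) == pytest.approx(-li)


class TestDominance:
    @pytest.mark.parametrize("li,expected", [
        (0.3, "left"), (-0.3, "right"), (0.1, "bilateral"),
        (0.2, "bilateral"), (-0.2, "bilateral"),  # boundaries are bilateral
    ])
    def test_rule(self, li, expected):
        assert classify_dominance(li) == expected


class TestConjunction:
    def test_identity_and_dominance(self):
        rng = np.random.default_rng(0)
        m1 = StatMap(rng.normal(size=(5, 5, 5)))
        same = conjunction_map(m1, m1)
        assert np.array_equal(same.data, m1.data)
        lower = StatMap(m1.data - 1.0)
        assert np.array_equal(conjunction_map(m1, lower).data, lower.data)

    def test_matches_voxel_loop_oracle(self):
        rng = np.random.default_rng(1)
        a = StatMap(rng.normal(size=(4, 3, 2)))
        b = StatMap(rng.normal(size=(4, 3, 2)))
        got = conjunction_map(a, b).data
        for idx in np.ndindex(a.data.shape):
            assert got[idx] == min(a.data[idx], b.data[idx])

    def test_grid_mismatch_rejected(self):
        a = StatMap(np.zeros((4, 4, 4)))
        b = StatMap(np.zeros((5, 4, 4)))
        with pytest.raises(ValueError):
            conjunction_map(a, b)


class TestBootstrap:
    def test_pair_count_is_samples_squared(self):
        v = np.random.default_rng(0).uniform(2, 8, 40)
        assert bootstrap_li_samples(v, v, n_samples=100, rng=1).size == 10_000

    def test_identical_multisets_give_zero(self):
        # content-seeded resampling: identical sides draw identical sums
        v = np.random.default_rng(0).uniform(2, 8, 30)
        assert bootstrap_li(v, v, rng=5) == pytest.approx(0.0, abs=1e-12)

    def test_three_to_one_mass_ratio(self):
        """Planted 3:1 left:right t-mass recovers LI about 0.5."""
        rng = np.random.default_rng(2)
        lis = []
        for seed in range(100):
            base = rng.uniform(3, 5, 160)
            left, right = base[:120], base[120:]
            lis.append(bootstrap_li(left, right, rng=seed))
        assert np.mean(lis) == pytest.approx(0.5, abs=0.05)

    def test_empty_side_signals(self):
        with pytest.raises(UndefinedLIError):
            bootstrap_li(np.array([]), np.ones(5), rng=0)

    def test_trim_one_equals_plain_mean(self):
        v1 = np.random.default_rng(3).uniform(2, 6, 25)
        v2 = np.random.default_rng(4).uniform(2, 6, 30)
        samples = bootstrap_li_samples(v1, v2, rng=9)
        assert trimmed_mean(samples, 1.0) == pytest.approx(samples.mean())


class TestWeightedLI:
    def test_mirrored_map_is_bilateral(self):
        """A perfectly mirrored map scores LI = 0 and classifies
        bilateral."""
        smap, left, right = generate_stat_map_pair(0.0, rng=8)
        nx = smap.data.shape[0]
        sym = smap.data.copy()
        sym[: nx // 2] = np.flip(smap.data, axis=0)[: nx // 2]
        mirrored = StatMap(sym, smap.affine)
        res = weighted_li(mirrored, left, right, rng=8)
        assert res.li == pytest.approx(0.0, abs=1e-12)
        assert res.dominance == "bilateral"

    def test_symmetric_target_stays_near_zero(self):
        lis = [weighted_li(*generate_stat_map_pair(0.0, rng=s)[:3], rng=s).li
               for s in range(30)]
        assert abs(np.mean(lis)) <= 0.05

    def test_one_sided_mass_saturates(self):
        smap, left, right = generate_stat_map_pair(1.0, rng=2)
        res = weighted_li(smap, left, right, rng=2)
        assert res.li > 0.9
        assert res.dominance == "left"

    def test_hemisphere_swap_negates_exactly(self):
        smap, left, right = generate_stat_map_pair(0.4, rng=3)
        res = weighted_li(smap, left, right, rng=11)
        swapped = weighted_li(smap, right, left, rng=11)
        assert np.allclose(res.li_per_threshold, -swapped.li_per_threshold)
        assert res.li == pytest.approx(-swapped.li, abs=1e-12)

    def test_common_scaling_invariance(self):
        """Scaling all t-values (and hence the threshold grid) by a common
        factor leaves every per-threshold LI unchanged."""
        smap, left, right = generate_stat_map_pair(-0.4, rng=4)
        res1 = weighted_li(smap, left, right, rng=13)
        scaled = StatMap(smap.data * 2.5, smap.affine)
        res2 = weighted_li(scaled, left, right, rng=13)
        assert np.allclose(res1.li_per_threshold, res2.li_per_threshold)
        assert res1.li == pytest.approx(res2.li)

    def test_all_lis_in_unit_interval(self):
        for seed in range(5):
            smap, left, right = generate_stat_map_pair(0.7, rng=seed)
            res = weighted_li(smap, left, right, rng=seed)
            assert np.all(np.abs(res.li_per_threshold) <= 1.0)
            assert -1.0 <= res.li <= 1.0

    def test_overlapping_rois_rejected(self):
        smap, left, right = generate_stat_map_pair(0.0, rng=0)
        with pytest.raises(ValueError):
            weighted_li(smap, left, ROIMask(left.mask, "left",
                                            left.center_mm), rng=0)


class TestGeneratorCalibration:
    def test_target_recovered_within_tenth(self):
        """The generator's target LI is recovered by the full estimator."""
        for target in (-0.6, 0.5):
            lis = [weighted_li(*generate_stat_map_pair(target, rng=s)[:3],
                               rng=s).li for s in range(40)]
            assert np.mean(lis) == pytest.approx(target, abs=0.1)

    def test_target_minus_point_six_classifies_right(self):
        hits = 0
        for seed in range(40):
            smap, left, right = generate_stat_map_pair(-0.6, rng=seed)
            res = weighted_li(smap, left, right, rng=seed)
            hits += -0.7 <= res.li <= -0.5 and res.dominance == "right"
        assert hits >= 38  # at least 95 percent of seeds

    def test_target_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            generate_stat_map_pair(1.5, rng=0)

    def test_seed_reproducibility(self):
        a = generate_stat_map_pair(-0.3, rng=7)
        b = generate_stat_map_pair(-0.3, rng=7)
        assert np.array_equal(a[0].data, b[0].data)
        assert np.array_equal(a[1].mask, b[1].mask)


class TestSubjectROISelection:
    def _box(self, shape=(20, 20, 10)):
        mask = np.zeros(shape, dtype=bool)
        mask[2:9, 6:14, 3:8] = True  # left-hemisphere box (low x indices)
        affine = np.diag([2.0, 2.0, 2.0, 1.0])
        affine[:3, 3] = [-19.0, -19.0, -9.0]
        return mask, affine

    def test_planted_peak_found(self):
        mask, affine = self._box()
        data = np.zeros((20, 20, 10))
        data[5, 10, 5] = 6.0  # a clear peak inside the box
        smap = StatMap(data, affine)
        group_peak = smap.world_coords(np.array([3, 8, 4]))[0]
        got = select_subject_roi(smap, ROIMask(mask, "left", None), group_peak)
        assert np.allclose(got, smap.world_coords(np.array([5, 10, 5]))[0])

    def test_fallback_to_group_peak(self):
        mask, affine = self._box()
        smap = StatMap(np.full((20, 20, 10), 1.0), affine)  # nothing >= 3.1
        group_peak = smap.world_coords(np.array([4, 9, 5]))[0]
        got = select_subject_roi(smap, ROIMask(mask, "left", None), group_peak)
        assert np.allclose(got, group_peak)

    def test_nearest_of_two_qualifying_maxima(self):
        mask, affine = self._box()
        data = np.zeros((20, 20, 10))
        data[4, 8, 4] = 5.0   # 4 mm-ish from the group peak
        data[8, 12, 6] = 7.0  # farther away, higher
        smap = StatMap(data, affine)
        group_peak = smap.world_coords(np.array([3, 8, 4]))[0]
        got = select_subject_roi(smap, ROIMask(mask, "left", None), group_peak,
                                 group_peak_t=3.1)
        assert np.allclose(got, smap.world_coords(np.array([4, 8, 4]))[0])


def test_roimask_hemisphere_consistency():
    mask = np.zeros((4, 4, 4), dtype=bool)
    mask[0, 0, 0] = True
    with pytest.raises(ValueError):
        ROIMask(mask, "left", center_mm=[10.0, 0.0, 0.0])  # positive x


def test_statmap_nifti_roundtrip(tmp_path):
    rng = np.random.default_rng(0)
    smap = StatMap(rng.normal(size=(6, 6, 6)), np.diag([2.0, 2, 2, 1]))
    path = tmp_path / "t.nii.gz"
    smap.to_nifti(path)
    back = StatMap.from_nifti(path)
    assert np.allclose(back.data, smap.data, atol=1e-6)
    assert np.allclose(back.affine, smap.affine)
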