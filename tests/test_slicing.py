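"""Oblique-slice lesion load: hand-derived cases and a brute-force oracle."""

import math

import numpy as np
import pytest

from cms_lesionmap import (SlicingSpec, outflow_lesion_load, slice_index,
                           slice_profile)
from conftest import make_mask


def brute_force_profile(roi, lesion, spec):
    """Independent per-voxel enumeration of slice counts and overlaps."""
    theta = math.radians(spec.angle_deg)
    roi_counts, overlap = {}, {}
    for idx in np.ndindex(roi.shape):
        if not roi.data[idx]:
            continue
        world = roi.affine[:3, :3] @ np.asarray(idx, float) + roi.affine[:3, 3]
        u = world[1] * math.cos(theta) - spec.tilt_sign * world[2] * math.sin(theta)
        k = math.floor(u / spec.thickness_mm)
        roi_counts[k] = roi_counts.get(k, 0) + 1
        overlap[k] = overlap.get(k, 0) + int(lesion.data[idx])
    return roi_counts, overlap


class TestSliceIndex:
    def test_zero_tilt_reduces_to_floor_of_y(self):
        spec = SlicingSpec(angle_deg=0)
        assert slice_index((5.0, 2.4, -30.0), spec) == 2

    def test_zero_tilt_is_z_invariant(self):
        spec = SlicingSpec(angle_deg=0)
        assert slice_index((0, 7.2, -5), spec) == slice_index((0, 7.2, 40), spec)

    def test_17_degree_hand_value(self):
        # u = 10*cos(17 deg) = 9.563 -> slice 9
        assert slice_index((0.0, 10.0, 0.0), SlicingSpec(angle_deg=17)) == 9

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            slice_index((0.0, np.nan, 0.0), SlicingSpec())


class TestSliceProfile:
    def test_lesion_covering_roi_gives_100_everywhere(self):
        roi = make_mask((4, 4, 4), [(i, j, 0) for i in range(2) for j in range(3)])
        lesion = make_mask((4, 4, 4), np.argwhere(np.ones((4, 4, 4))))
        prof = slice_profile(roi, lesion, SlicingSpec(angle_deg=0))
        assert np.allclose(prof.percents[prof.eligible], 100.0)

    def test_disjoint_lesion_gives_0_everywhere(self):
        roi = make_mask((4, 4, 4), [(0, j, 0) for j in range(3)])
        lesion = make_mask((4, 4, 4), [(3, 3, 3)])
        prof = slice_profile(roi, lesion, SlicingSpec())
        assert np.allclose(prof.percents[prof.eligible], 0.0)

    def test_hand_enumerated_quarters(self):
        # ROI: 4 voxels at y=0 and 4 at y=1; lesion hits 1 of the first, 3 of the second
        roi_voxels = [(i, y, z) for y in (0, 1) for i in (0, 1) for z in (0, 1)]
        roi = make_mask((3, 3, 3), roi_voxels)
        lesion = make_mask((3, 3, 3), [(0, 0, 0), (0, 1, 0), (0, 1, 1), (1, 1, 0)])
        prof = slice_profile(roi, lesion, SlicingSpec(angle_deg=0))
        assert prof.roi_counts.tolist() == [4, 4]
        assert prof.percents.tolist() == [25.0, 75.0]
        result = outflow_lesion_load(prof)
        assert result.load_percent == 75.0 and result.argmax_slice == 1

    def test_partition_sums_to_roi_count(self, toy_space):
        _, roi, _ = toy_space
        prof = slice_profile(roi, roi, SlicingSpec())
        assert prof.roi_counts.sum() == roi.n_voxels

    def test_empty_roi_rejected(self):
        roi = make_mask((3, 3, 3), [])
        lesion = make_mask((3, 3, 3), [(0, 0, 0)])
        with pytest.raises(ValueError, match="empty"):
            slice_profile(roi, lesion, SlicingSpec())

    def test_grid_mismatch_rejected(self):
        roi = make_mask((3, 3, 3), [(0, 0, 0)])
        lesion = make_mask((4, 4, 4), [(0, 0, 0)])
        with pytest.raises(ValueError):
            slice_profile(roi, lesion, SlicingSpec())


class TestLesionLoad:
    def test_all_zero_percents_gives_load_0(self):
        roi = make_mask((4, 4, 4), [(0, j, 0) for j in range(4)])
        lesion = make_mask((4, 4, 4), [])
        assert outflow_lesion_load(slice_profile(roi, lesion, SlicingSpec())).load_percent == 0.0

    def test_full_slice_gives_load_100(self):
        roi = make_mask((4, 4, 4), [(i, 0, 0) for i in range(4)]
                        + [(i, 2, 0) for i in range(4)])
        lesion = make_mask((4, 4, 4), [(i, 0, 0) for i in range(4)])
        res = outflow_lesion_load(slice_profile(roi, lesion, SlicingSpec(angle_deg=0)))
        assert res.load_percent == 100.0 and res.argmax_slice == 0

    def test_tie_broken_to_smallest_slice_index(self):
        roi = make_mask((4, 4, 4), [(0, 0, 0), (1, 0, 0), (0, 2, 0), (1, 2, 0)])
        lesion = make_mask((4, 4, 4), [(0, 0, 0), (0, 2, 0)])
        res = outflow_lesion_load(slice_profile(roi, lesion, SlicingSpec(angle_deg=0)))
        assert res.load_percent == 50.0 and res.argmax_slice == 0


def _random_case(rng, shape=12):
    n = int(rng.integers(6, 16))
    roi = make_mask((shape,) * 3, rng.integers(0, shape, size=(n, 3)))
    m = int(rng.integers(0, 40))
    lesion = make_mask((shape,) * 3, rng.integers(0, shape, size=(m, 3)))
    aff = np.eye(4)
    aff[:3, 3] = rng.uniform(-6, 0, 3).round(1)
    roi.affine = lesion.affine = aff
    spec = SlicingSpec(angle_deg=float(rng.uniform(0, 45)),
                       thickness_mm=float(rng.choice([0.5, 1.0, 2.0])),
                       tilt_sign=int(rng.choice([-1, 1])))
    return roi, lesion, spec


@pytest.mark.parametrize("seed", range(50))
def test_profile_matches_brute_force_enumeration(seed):
    rng = np.random.default_rng(seed)
    roi, lesion, spec = _random_case(rng)
    prof = slice_profile(roi, lesion, spec)
    roi_counts, overlap = brute_force_profile(roi, lesion, spec)
    assert dict(zip(prof.slice_indices.tolist(), prof.roi_counts.tolist())) == roi_counts
    assert dict(zip(prof.slice_indices.tolist(), prof.overlap_counts.tolist())) == overlap
    # max-slice statistic agrees with the enumerated maximum
    expected = max(100.0 * overlap[k] / roi_counts[k] for k in roi_counts)
    assert outflow_lesion_load(prof).load_percent == pytest.approx(expected)


class TestProperties:
    def test_adding_lesion_voxels_never_decreases_load(self, rng):
        roi, lesion, spec = _random_case(rng)
        base = outflow_lesion_load(slice_profile(roi, lesion, spec)).load_percent
        grown = lesion.data | roi.data  # add all ROI voxels
        grown_mask = make_mask(roi.shape, np.argwhere(grown), affine=roi.affine)
        assert outflow_lesion_load(slice_profile(roi, grown_mask, spec)).load_percent >= base

    def test_lesion_outside_roi_changes_nothing(self, rng):
        roi, lesion, spec = _random_case(rng)
        inside = lesion.data & roi.data
        only_inside = make_mask(roi.shape, np.argwhere(inside), affine=roi.affine)
        a = slice_profile(roi, lesion, spec)
        b = slice_profile(roi, only_inside, spec)
        assert np.array_equal(a.overlap_counts, b.overlap_counts)

    def test_zero_tilt_equals_axis_aligned_coronal(self, rng):
        roi, lesion, _ = _random_case(rng)
        spec = SlicingSpec(angle_deg=0.0, thickness_mm=1.0)
        prof = slice_profile(roi, lesion, spec)
        ys = roi.world_coords(roi.voxel_indices())[:, 1]
        expected = np.unique(np.floor(ys).astype(int))
        assert np.array_equal(prof.slice_indices, expected)

    def test_loads_bounded_0_100(self):
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            roi, lesion, spec = _random_case(rng)
            load = outflow_lesion_load(slice_profile(roi, lesion, spec)).load_percent
            assert 0.0 <= load <= 100.0
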