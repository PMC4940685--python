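"""The four ROI procedures, rater models, truncation and sectioning rules."""

import numpy as np
import pytest

from tractroi.roi_methods import (
    RaterModel,
    Roi,
    find_anterior_limit,
    roi_from_skeleton,
    roi_from_tracking,
    roi_manual,
    truncate_and_section,
)
from tractroi.skeleton import SkeletonMask
from tractroi.tracking import VisitationMap


class TestAnteriorLimit:
    def test_zero_jitter_returns_chiasm(self, noiseless_analysis, exact_rater):
        truth = noiseless_analysis["truth"]
        assert find_anterior_limit(truth, exact_rater) == truth.chiasm_slice

    def test_deterministic_per_key_tuple(self, noiseless_analysis):
        truth = noiseless_analysis["truth"]
        rater = RaterModel("A", start_slice_jitter_sd=1.5, seed=3)
        a = find_anterior_limit(truth, rater, subject_key=4, repeat_key=1)
        b = find_anterior_limit(truth, rater, subject_key=4, repeat_key=1)
        assert a == b

    def test_rounded_gaussian_spread(self, noiseless_analysis):
        """1000 start-slice draws at sd = 1 have an empirical sd near 1
        (the rounded-Gaussian model barely changes the dispersion)."""
        truth = noiseless_analysis["truth"]
        rater = RaterModel("A", start_slice_jitter_sd=1.0, seed=3)
        draws = [
            find_anterior_limit(truth, rater, subject_key=i) for i in range(1000)
        ]
        assert 0.8 <= np.std(draws) <= 1.2


def _single_voxel_image(shape=(12, 24, 10), x=2, z=5, slices=range(5, 21)):
    img = np.full(shape, 100.0)
    for y in slices:
        img[x, y, z] = 1000.0
    return img


class TestManualRoi:
    def test_zero_jitter_tracks_centerline(self, noiseless_analysis, exact_rater):
        """On a noiseless b0 map with no rater jitter the chosen voxels hug
        the true centerline."""
        truth = noiseless_analysis["truth"]
        roi = roi_manual(
            noiseless_analysis["b0_map"], noiseless_analysis["tensors"].fa_map,
            truth.chiasm_slice + 1, exact_rater, "right",
        )
        cl = {v[1]: np.asarray(v) for v in truth.centerline_voxels["right"]}
        for sel in roi.selections[:15]:
            for v in sel:
                assert np.abs(np.asarray(v) - cl[v[1]]).max() <= 1

    def test_t1w_offset_lowers_roi_fa(self, noiseless_analysis, exact_rater):
        """A 2 mm perpendicular misregistration makes the T1W ROI select
        border voxels whose partial-volume FA is depressed."""
        truth = noiseless_analysis["truth"]
        fa = noiseless_analysis["tensors"].fa_map
        start = truth.chiasm_slice + 1
        roi_b0 = roi_manual(noiseless_analysis["b0_map"], fa, start,
                            exact_rater, "right")
        roi_t1 = roi_manual(noiseless_analysis["t1w"].volume, fa, start,
                            exact_rater, "right", method="manual_t1w")
        mean = lambda r: np.mean([fa[v] for sel in r.selections[:15] for v in sel])
        assert mean(roi_t1) < mean(roi_b0)

    def test_single_voxel_cross_section(self, exact_rater):
        img = _single_voxel_image()
        roi = roi_manual(img, np.zeros_like(img), 5, exact_rater, "right")
        assert roi.n_slices >= 10
        assert all(len(sel) == 1 for sel in roi.selections)

    def test_empty_start_rejected(self, exact_rater):
        img = np.full((12, 24, 10), 100.0)
        with pytest.raises(ValueError, match="start slice"):
            roi_manual(img, np.zeros_like(img), 5, exact_rater, "right")


class TestSkeletonRoi:
    def _make(self, fa_by_voxel, shape=(12, 10, 10)):
        fa = np.zeros(shape)
        voxels = np.zeros(shape, dtype=bool)
        for v, f in fa_by_voxel.items():
            fa[v] = f
            voxels[v] = True
        sk = SkeletonMask(voxels=voxels,
                          perpendicular_direction=np.zeros(shape + (3,)),
                          fa_threshold=0.2)
        return sk, fa

    def test_top_two_fa_kept(self, exact_rater):
        """Three candidates with FA 0.5/0.7/0.6: the two highest survive."""
        cands = {(6, 3, 5): 0.5, (7, 3, 5): 0.7, (8, 3, 5): 0.6}
        sk, fa = self._make(cands)
        neigh = np.ones(fa.shape, dtype=bool)
        roi = roi_from_skeleton(sk, fa, 3, neigh, exact_rater, "left")
        chosen = {v: fa[v] for v in roi.selections[0]}
        assert sorted(chosen.values(), reverse=True) == [0.7, 0.6]

    def test_single_candidate_kept(self, exact_rater):
        sk, fa = self._make({(7, 3, 5): 0.55})
        neigh = np.ones(fa.shape, dtype=bool)
        neigh[:, 5:, :] = False
        roi = roi_from_skeleton(sk, fa, 3, neigh, exact_rater, "left")
        assert roi.selections[0] == [(7, 3, 5)]

    def test_gap_slice_recorded(self, exact_rater):
        sk, fa = self._make({(7, 3, 5): 0.55, (7, 5, 5): 0.6})
        neigh = np.ones(fa.shape, dtype=bool)
        neigh[:, 6:, :] = False
        roi = roi_from_skeleton(sk, fa, 3, neigh, exact_rater, "left")
        assert roi.gap_slices == [4]

    def test_empty_everywhere_rejected(self, exact_rater):
        sk, fa = self._make({})
        with pytest.raises(ValueError, match="skeleton"):
            roi_from_skeleton(sk, fa, 3, np.ones(fa.shape, bool),
                              exact_rater, "left")


class TestTrackingRoi:
    def _vismap(self, counts_by_voxel, shape=(12, 10, 10)):
        counts = np.zeros(shape, dtype=int)
        for v, c in counts_by_voxel.items():
            counts[v] = c
        return VisitationMap(counts=counts, n_launched=100, n_accepted=100)

    def test_top_two_fa(self):
        fa = np.zeros((12, 10, 10))
        fa[6, 3, 5], fa[7, 3, 5], fa[8, 3, 5] = 0.41, 0.63, 0.62
        vm = self._vismap({(6, 3, 5): 5, (7, 3, 5): 5, (8, 3, 5): 5})
        roi = roi_from_tracking(vm, fa, 3, "left")
        got = sorted(fa[v] for v in roi.selections[0])
        assert got == [0.62, 0.63]

    def test_single_candidate(self):
        fa = np.zeros((12, 10, 10))
        fa[7, 3, 5] = 0.5
        vm = self._vismap({(7, 3, 5): 9})
        roi = roi_from_tracking(vm, fa, 3, "left")
        assert roi.selections[0] == [(7, 3, 5)]

    def test_fa_tie_broken_by_count(self):
        fa = np.zeros((12, 10, 10))
        fa[6, 3, 5] = fa[8, 3, 5] = 0.60
        fa[7, 3, 5] = 0.1
        vm = self._vismap({(6, 3, 5): 3, (8, 3, 5): 12, (7, 3, 5): 1})
        roi = roi_from_tracking(vm, fa, 3, "left")
        assert roi.selections[0][0] == (8, 3, 5)  # higher count first

    def test_empty_first_slice_rejected(self):
        vm = self._vismap({})
        with pytest.raises(ValueError, match="visited"):
            roi_from_tracking(vm, np.zeros((12, 10, 10)), 3, "left")


def _roi_of_length(n, start=4):
    sels = [[(6, start + i, 5)] for i in range(n)]
    return Roi("manual_b0", "left", start, sels)


class TestTruncateAndSection:
    @pytest.mark.parametrize(
        "length,n_kept,section3,incomplete",
        [(20, 15, 5, False), (15, 15, 5, False), (12, 15, 2, True)],
    )
    def test_sectioning(self, length, n_kept, section3, incomplete):
        sect = truncate_and_section(_roi_of_length(length))
        assert sect.n_slices == n_kept
        assert sect.sections == [1] * 5 + [2] * 5 + [3] * 5
        present = [
            p for p in range(10, 15)
            if p < sect.roi.n_slices and sect.roi.selections[p]
        ]
        assert len(present) == section3
        assert sect.incomplete is incomplete

    def test_rows_carry_sections_and_fa(self):
        fa = np.zeros((12, 30, 10))
        fa[6, :, 5] = 0.5
        rows = truncate_and_section(_roi_of_length(20)).rows(fa)
        assert len(rows) == 15
        assert [r["section"] for r in rows] == [1] * 5 + [2] * 5 + [3] * 5
        assert all(r["fa"] == 0.5 for r in rows)


def test_roi_two_voxel_invariant_enforced():
    bad = Roi("manual_b0", "left", 4, [[(6, 4, 5), (7, 4, 5), (8, 4, 5)]])
    with pytest.raises(ValueError, match="maximum is two"):
        bad.validate()


def test_mirrored_image_gives_mirrored_roi(noiseless_analysis, exact_rater):
    """No left/right asymmetry in the code paths: on the voxel-mirrored image
    the opposite side's ROI is the mirror of the original ROI."""
    truth = noiseless_analysis["truth"]
    fa = noiseless_analysis["tensors"].fa_map
    b0 = noiseless_analysis["b0_map"]
    start = truth.chiasm_slice + 1
    nx = truth.grid_shape[0]
    r = roi_manual(b0, fa, start, exact_rater, "right")
    l = roi_manual(np.flip(b0, 0).copy(), np.flip(fa, 0).copy(), start,
                   exact_rater, "left")
    assert l.n_slices == r.n_slices
    from tractroi.phantom import hemifield_mask
    from tractroi.roi_methods import _segment_cross_section

    b0f = np.flip(b0, 0)
    hemi_r = hemifield_mask(b0.shape, "right")
    hemi_l = hemifield_mask(b0.shape, "left")
    for i, (sr, sl) in enumerate(zip(r.selections[:15], l.selections[:15])):
        y = start + i
        seg_r, _ = _segment_cross_section(b0[:, y, :], hemi_r[:, y, :])
        seg_l, _ = _segment_cross_section(b0f[:, y, :], hemi_l[:, y, :])
        cen_r, cen_l = seg_r.mean(axis=0), seg_l.mean(axis=0)
        # mirrored segmentations and centroids; equidistant candidates may
        # tie-break in either order, so compare the distance multisets
        d_r = sorted(np.hypot(x - cen_r[0], z - cen_r[1]) for x, _, z in sr)
        d_l = sorted(np.hypot(x - cen_l[0], z - cen_l[1]) for x, _, z in sl)
        assert np.allclose(d_r, d_l, atol=1e-9)
        mirrored_seg = sorted((nx - 1 - x, z) for x, z in seg_l)
        assert mirrored_seg == sorted(map(tuple, seg_r))
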