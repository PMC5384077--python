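"""Segmentation, centerline extraction, splitting rules, FWHM diametry."""

import numpy as np
import pytest

from conjflow.config import DiametryConfig, SegmentationConfig
from conjflow.morphology import (DiametryError, VesselSegment,
                                 extract_centerlines, filter_by_variance,
                                 find_bifurcations, find_bifurcations_and_split,
                                 label_vessel_type, measure_diameter,
                                 neighbor_counts, segment_vessels)
from conjflow.registration import register, register_sequence
from conjflow.synthetic import SceneSpec, VesselSpec, render_sequence

from conftest import FIELD, MAIN_POINTS, make_flow_scene

PX = 1.25


def _true_tube_mask(shape, p0, p1, d_um, px=PX):
    """Analytic half-max footprint of a straight rendered vessel."""
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    (x0, y0), (x1, y1) = p0, p1
    t = np.clip(((xx - x0) * (x1 - x0) + (yy - y0) * (y1 - y0))
                / ((x1 - x0) ** 2 + (y1 - y0) ** 2), 0, 1)
    r = np.hypot(xx - (x0 + t * (x1 - x0)), yy - (y0 + t * (y1 - y0)))
    return r <= d_um / 2 / px


class TestSegmentVessels:
    def test_blank_image_gives_empty_mask(self):
        assert not segment_vessels(np.full((128, 128), 150.0)).any()

    def test_single_vessel_footprint_covered(self):
        scene = make_flow_scene(noise_sd=0.0, with_anchor=False)
        seq, _ = render_sequence(scene, seed=1)
        reg = register(seq, (0, 49))
        mask = segment_vessels(reg.time_averaged)
        inside = _true_tube_mask(FIELD, *MAIN_POINTS, 20.0)
        coverage = (mask & inside).sum() / inside.sum()
        spill = (mask & ~inside).sum() / (~inside).sum()
        assert coverage >= 0.95
        assert spill <= 0.05

    def test_crossing_vessels_both_covered(self):
        a = VesselSpec(points=[(15, 100), (340, 110)], diameter_um=18.0,
                       velocity_mm_s=0.4)
        b = VesselSpec(points=[(170, 30), (190, 200)], diameter_um=14.0,
                       velocity_mm_s=0.3)
        scene = SceneSpec(shape=FIELD, vessels=[a, b], noise_sd=0.0)
        seq, _ = render_sequence(scene, seed=2)
        reg = register(seq, (0, 49))
        mask = segment_vessels(reg.time_averaged)
        for spec in (a, b):
            inside = _true_tube_mask(FIELD, spec.points[0], spec.points[-1],
                                     spec.diameter_um)
            assert (mask & inside).sum() / inside.sum() >= 0.90


class TestCenterlines:
    def test_straight_bar_skeleton_is_middle_row(self):
        mask = np.zeros((64, 200), dtype=bool)
        mask[24:40, 10:190] = True          # 16 px wide horizontal bar
        skel = extract_centerlines(mask)
        ys, xs = np.nonzero(skel)
        interior = (xs > 25) & (xs < 175)
        assert np.abs(ys[interior] - 31.5).max() <= 1.0

    def test_empty_mask_empty_skeleton(self):
        assert not extract_centerlines(np.zeros((32, 32), bool)).any()

    def test_y_mask_has_single_branch_cluster(self):
        from scipy import ndimage
        from skimage.morphology import disk
        sk = np.zeros((128, 128), bool)
        sk[64, 10:65] = True                 # stem
        arm = np.arange(1, 41)
        sk[64 - arm, 64 + arm] = True        # upper branch
        sk[64 + arm, 64 + arm] = True        # lower branch
        mask = ndimage.binary_dilation(sk, structure=disk(5))
        skel = extract_centerlines(mask)
        branch = neighbor_counts(skel) >= 3
        _, n_clusters = ndimage.label(branch, structure=np.ones((3, 3)))
        assert n_clusters == 1

    def test_branch_points_match_brute_force_on_random_masks(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            skel = rng.random((24, 24)) < 0.25
            counts = neighbor_counts(skel)
            brute = np.zeros_like(counts)
            for y in range(24):
                for x in range(24):
                    if not skel[y, x]:
                        continue
                    brute[y, x] = sum(
                        skel[y + dy, x + dx]
                        for dy in (-1, 0, 1) for dx in (-1, 0, 1)
                        if (dy or dx) and 0 <= y + dy < 24 and 0 <= x + dx < 24)
            assert np.array_equal(counts, brute)
            ys, xs = np.nonzero((brute >= 3) & skel)
            expected = np.column_stack([xs, ys])
            got = find_bifurcations(skel)
            order = lambda a: a[np.lexsort((a[:, 1], a[:, 0]))] if len(a) else a
            assert np.array_equal(order(got), order(expected))


class TestSplit:
    def test_straight_100px_skeleton_retained(self):
        skel = np.zeros((32, 128), bool)
        skel[16, 10:110] = True              # 100 px -> 99 steps
        segs, discarded = find_bifurcations_and_split(skel, PX)
        assert len(segs) == 1 and discarded == 0
        assert segs[0].length_um == pytest.approx(123.75)

    def test_straight_30px_skeleton_discarded(self):
        skel = np.zeros((32, 64), bool)
        skel[16, 10:40] = True               # 30 px -> 36.25 um <= 50
        segs, discarded = find_bifurcations_and_split(skel, PX)
        assert segs == [] and discarded == 1

    def test_y_skeleton_splits_into_three_segments(self):
        skel = np.zeros((200, 200), bool)
        skel[100, 20:101] = True             # left arm, 80 px + center
        skel[100, 101:181] = True            # right arm, 80 px
        arm = np.arange(1, 81)
        skel[100 + arm, 100 + arm] = True    # diagonal arm, 80 px
        segs, discarded = find_bifurcations_and_split(skel, PX, prune_px=0)
        assert len(segs) == 3
        assert discarded == 0
        assert all(s.length_um > 50 for s in segs)
        parents = {s.parent_vessel_id for s in segs}
        assert len(parents) == 1             # one connected skeleton

    def test_arc_length_invariant_under_translation(self):
        scene = make_flow_scene(noise_sd=0.0)
        seq, _ = render_sequence(scene, seed=1)
        reg = register(seq, (0, 49))
        mask = segment_vessels(reg.time_averaged)
        skel = extract_centerlines(mask)
        segs, _ = find_bifurcations_and_split(skel, PX, prune_px=30)
        shifted = np.roll(np.roll(skel, 4, axis=0), -6, axis=1)
        shifted[:, -6:] = False
        segs2, _ = find_bifurcations_and_split(shifted, PX, prune_px=30)
        a = max(s.length_um for s in segs)
        b = max(s.length_um for s in segs2)
        assert abs(a - b) / a < 0.02


class TestDiametry:
    @pytest.mark.parametrize("d_true", [6.0, 20.0])
    def test_fwhm_within_one_pixel(self, d_true):
        scene = make_flow_scene(diameter_um=d_true, noise_sd=0.0,
                                with_anchor=False)
        seq, _ = render_sequence(scene, seed=4)
        reg = register(seq, (0, 49))
        mask = segment_vessels(reg.time_averaged)
        skel = extract_centerlines(mask)
        segs, _ = find_bifurcations_and_split(skel, PX, prune_px=30)
        seg = max(segs, key=lambda s: s.length_um)
        measure_diameter(seg, reg.time_averaged, PX)
        assert seg.mean_diameter_um == pytest.approx(d_true, abs=PX)
        assert seg.n_stations >= 3
        # stations spaced 5 px of arc length apart
        gaps = np.hypot(*np.diff(seg.stations, axis=0).T)
        assert np.all(gaps >= 4.9)

    def test_constant_image_rejects_segment(self):
        seg = VesselSegment(segment_id=0,
                            points=np.column_stack([np.arange(10, 110),
                                                    np.full(100, 64.0)]),
                            length_um=123.75)
        img = np.full((128, 160), 140.0)
        with pytest.raises(DiametryError, match="diameter stations"):
            measure_diameter(seg, img, PX)
        assert seg.rejection_reason == "diametry failed"


class TestVarianceFilter:
    def test_static_scene_not_flow_detected(self, static_sequence):
        seq, _ = static_sequence
        reg = register(seq, (0, seq.n_frames - 1))
        mask = segment_vessels(reg.time_averaged)
        skel = extract_centerlines(mask)
        segs, _ = find_bifurcations_and_split(skel, PX, prune_px=30)
        filter_by_variance(segs, reg, mask)
        assert all(not s.flow_detected for s in segs)

    def test_advected_texture_flow_detected(self, registered_flow):
        reg, _, _ = registered_flow
        mask = segment_vessels(reg.time_averaged)
        skel = extract_centerlines(mask)
        segs, _ = find_bifurcations_and_split(skel, PX, prune_px=30)
        filter_by_variance(segs, reg, mask)
        main = max(segs, key=lambda s: s.length_um)
        assert main.flow_detected

    def test_false_detection_rate_on_pure_noise(self):
        # a stagnant vessel in a noisy sequence should rarely be called flowing
        false_positives = 0
        n_seeds = 25
        for seed in range(n_seeds):
            scene = make_flow_scene(velocity_mm_s=0.0, noise_sd=3.0,
                                    with_anchor=False, n_frames=20)
            seq, _ = render_sequence(scene, seed=seed)
            reg = register(seq, (0, seq.n_frames - 1))
            mask = segment_vessels(reg.time_averaged)
            skel = extract_centerlines(mask)
            segs, _ = find_bifurcations_and_split(skel, PX, prune_px=30)
            filter_by_variance(segs, reg, mask)
            false_positives += sum(s.flow_detected for s in segs)
        assert false_positives / max(n_seeds, 1) <= 0.05


class TestVesselTypeLabels:
    def _segment(self):
        return VesselSegment(segment_id=3, points=np.zeros((2, 2)),
                             length_um=100.0, parent_vessel_id=7)

    def test_annotation_passthrough(self):
        seg = label_vessel_type(self._segment(), {3: "arteriole"})
        assert seg.vessel_type == "arteriole"

    def test_parent_fallback_and_missing(self):
        seg = label_vessel_type(self._segment(), {7: "venule"})
        assert seg.vessel_type == "venule"
        seg = label_vessel_type(self._segment(), {})
        assert seg.vessel_type == "unlabeled"

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="unknown vessel type"):
            label_vessel_type(self._segment(), {3: "capillary"})
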