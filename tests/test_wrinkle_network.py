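"""Binarize/clean/skeletonize pipeline, stage segmentation, and thickness maps."""

import numpy as np
import pytest

from wrinklekit.io import ImageStack
from wrinklekit import wrinkle_network as wn
from wrinklekit.synthetic import generate_stage_curves

from _oracles import brute_force_otsu


class TestOtsu:
    def test_constant_frame_is_degenerate(self):
        with pytest.raises(ValueError, match="degenerate histogram"):
            wn.otsu_threshold(np.full((10, 10), 7, np.uint8))

    def test_bimodal_threshold_separates_modes(self):
        rng = np.random.default_rng(0)
        frame = np.where(rng.random((64, 64)) < 0.4, 10, 200).astype(np.uint8)
        thr = wn.otsu_threshold(frame)
        assert 10 < thr < 200

    @pytest.mark.parametrize("seed", range(4))
    def test_equals_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        # mixture of two noisy modes with random weights
        w = rng.uniform(0.1, 0.9)
        n = 64 * 64
        frame = np.concatenate(
            [
                rng.normal(60, 10, int(w * n)),
                rng.normal(170, 12, n - int(w * n)),
            ]
        ).reshape(64, 64)
        frame = np.clip(frame, 0, 255).astype(np.uint8)
        bin_width = (frame.max() - frame.min()) / 256
        # agreement up to the one-bin tie-degeneracy of plateau maximizers
        assert wn.otsu_threshold(frame) == pytest.approx(brute_force_otsu(frame), abs=bin_width)

    def test_binary_image_class_assignment(self):
        frame = np.zeros((8, 8), np.uint8)
        frame[:, 4:] = 255
        thr = wn.otsu_threshold(frame)
        assert ((frame < thr) == (frame == 0)).all()


class TestBinarize:
    def test_blank_stack_is_all_background(self):
        rng = np.random.default_rng(1)
        frames = (200 + rng.normal(0, 3, (4, 32, 32))).astype(np.uint8)
        # threshold from a frame with real contrast; the blank frames stay empty
        frames[-1, 10:20, 10:20] = 40
        stack = ImageStack(frames, pixel_size_um=1.0, frame_interval_s=1.0)
        binary = wn.binarize_stack(stack)
        assert binary[:-1].sum() == 0

    def test_reference_frame_out_of_range(self):
        stack = ImageStack(np.zeros((3, 8, 8), np.uint8), 1.0, 1.0)
        with pytest.raises(IndexError):
            wn.binarize_stack(stack, reference=5)

    def test_foreground_matches_generator_mask(self, small_wrinkle_data):
        stack, truth = small_wrinkle_data
        binary = wn.binarize_stack(stack)
        for f in (0, truth.stage2_start, stack.n_frames - 1):
            diff = binary[f] ^ truth.masks[f]
            # agreement up to a 1-px boundary band
            from skimage.morphology import dilation

            boundary = dilation(truth.masks[f], np.ones((3, 3), bool)) & ~truth.masks[f]
            boundary |= truth.masks[f] & ~wn.morphology.erosion(truth.masks[f], np.ones((3, 3), bool))
            assert not (diff & ~boundary).any()

    def test_fixed_reference_convention(self):
        """Thresholding from frame 0 vs the last frame differs on a drifting background."""
        rng = np.random.default_rng(2)
        frames = np.empty((2, 64, 64))
        frames[0] = 100 + rng.normal(0, 2, (64, 64))
        frames[0, 20:40, 20:40] = 30
        frames[1] = frames[0] + 80  # background drift
        stack = ImageStack(np.clip(frames, 0, 255).astype(np.uint8), 1.0, 1.0)
        first = wn.binarize_stack(stack, reference=0)
        last = wn.binarize_stack(stack, reference=-1)
        assert (first != last).any()


class TestCleanBinary:
    def test_size_filter_keeps_only_large_objects(self):
        mask = np.zeros((32, 32), bool)
        mask[2:4, 2:4] = True  # 4 px, removed
        mask[10:15, 10:20] = True  # 50 px, kept
        out = wn.clean_binary(mask)
        assert not out[2:4, 2:4].any()
        assert out[11:14, 11:19].all()

    def test_empty_mask_passthrough(self):
        assert wn.clean_binary(np.zeros((16, 16), bool)).sum() == 0

    def test_opening_removes_isolated_pixels_even_without_size_filter(self):
        mask = np.zeros((16, 16), bool)
        mask[3, 3] = mask[8, 12] = True
        assert wn.clean_binary(mask, min_size=1).sum() == 0


class TestSkeletonize:
    @staticmethod
    def _bar(canvas, r, c, height, width):
        canvas[r : r + height, c : c + width] = True

    def test_two_bars_counted_and_measured(self):
        mask = np.zeros((40, 40), bool)
        self._bar(mask, 5, 5, 3, 10)
        self._bar(mask, 20, 5, 3, 20)
        g = wn.skeletonize_and_label(mask)
        assert g.n_components == 2
        assert abs(int(g.pixel_counts.max()) - 20) <= 2

    def test_empty_mask(self):
        g = wn.skeletonize_and_label(np.zeros((8, 8), bool))
        assert g.n_components == 0

    def test_y_ribbon_is_one_component_with_summed_arms(self):
        from skimage.draw import line
        from skimage.morphology import dilation

        cl = np.zeros((64, 64), bool)
        for end in [(5, 30), (60, 10), (60, 50)]:
            rr, cc = line(32, 30, *end)
            cl[rr, cc] = True
        mask = dilation(cl, np.ones((3, 3), bool))
        g = wn.skeletonize_and_label(mask)
        assert g.n_components == 1
        assert g.pixel_counts[0] == pytest.approx(cl.sum(), rel=0.12)

    def test_skeleton_subset_of_mask(self):
        rng = np.random.default_rng(3)
        mask = rng.random((64, 64)) < 0.4
        mask = wn.clean_binary(mask)
        g = wn.skeletonize_and_label(mask)
        assert not (g.skeleton & ~mask).any()

    def test_geodesic_diameter_on_straight_bar(self):
        mask = np.zeros((20, 40), bool)
        self._bar(mask, 8, 5, 3, 30)
        g = wn.skeletonize_and_label(mask)
        d = wn.geodesic_diameter_px(g, 1)
        assert abs(d - 30) <= 3


class TestWrinkleMetrics:
    def test_blank_stack_raises_no_wrinkles_on_segmentation(self):
        rng = np.random.default_rng(4)
        frames = (200 + rng.normal(0, 2, (5, 32, 32))).astype(np.uint8)
        frames[-1, 5:15, 5:8] = 40  # contrast for the threshold only
        stack = ImageStack(frames, pixel_size_um=1.0, frame_interval_s=60.0)
        metrics = wn.wrinkle_metrics(stack)
        assert (metrics.table["N"].iloc[:-1] == 0).all()
        assert (metrics.table["L_mm"].iloc[:-1] == 0).all()

    def test_merging_components_decreases_n_and_grows_l(self):
        frames = np.full((2, 40, 40), 200, np.uint8)
        frames[0, 10:13, 5:15] = 40
        frames[0, 10:13, 25:35] = 40
        frames[1, 10:13, 5:35] = 40  # the two bars have connected
        stack = ImageStack(frames, pixel_size_um=1000.0, frame_interval_s=1.0)
        metrics = wn.wrinkle_metrics(stack)
        n, l_mm = metrics.table["N"], metrics.table["L_mm"]
        assert n[1] == n[0] - 1
        assert l_mm[1] >= l_mm[0]

    def test_missing_pixel_size_reports_px_with_warning(self):
        frames = np.full((1, 20, 20), 200, np.uint8)
        frames[0, 5:8, 2:18] = 40
        stack = ImageStack(frames, pixel_size_um=None, frame_interval_s=1.0)
        with pytest.warns(UserWarning, match="pixel"):
            metrics = wn.wrinkle_metrics(stack)
        assert metrics.length_unit == "px"

    def test_deterministic(self, small_wrinkle_data):
        stack, _ = small_wrinkle_data
        a = wn.wrinkle_metrics(stack).table
        b = wn.wrinkle_metrics(stack).table
        assert a.equals(b)


class TestStageSegmentation:
    def test_constructed_curves_recovered_within_2_frames(self):
        table, (t1, t2) = generate_stage_curves(seed=3)
        metrics = wn.WrinkleMetrics(table=table, length_unit="mm")
        seg = wn.segment_stages(metrics)
        assert abs(seg.stage2_start - t1) <= 2
        assert seg.stage3_start is not None and abs(seg.stage3_start - t2) <= 2

    def test_stages_are_contiguous_and_ordered(self):
        table, _ = generate_stage_curves(seed=4)
        seg = wn.segment_stages(wn.WrinkleMetrics(table=table, length_unit="mm"))
        labels = seg.labels
        assert (np.diff(labels) >= 0).all()
        assert set(labels) <= {0, 1, 2, 3}

    def test_rising_l_without_plateau_flags_empty_stage3(self):
        import pandas as pd

        n = np.concatenate([np.arange(1, 21), np.full(20, 20)])
        length = np.linspace(0.1, 5.0, 40)  # still rising steeply at the end
        table = pd.DataFrame({"frame": range(40), "time_s": range(40), "N": n, "L_mm": length})
        seg = wn.segment_stages(wn.WrinkleMetrics(table=table, length_unit="mm"))
        assert seg.no_plateau
        assert seg.stage3_start is None

    def test_no_wrinkles_detected(self):
        import pandas as pd

        table = pd.DataFrame({"frame": range(5), "time_s": range(5), "N": 0, "L_mm": 0.0})
        with pytest.raises(ValueError, match="no wrinkles"):
            wn.segment_stages(wn.WrinkleMetrics(table=table, length_unit="mm"))


class TestEffectiveThickness:
    def test_uniform_slab(self):
        slab = np.zeros((20, 8, 8))
        slab[:20] = 100.0  # fills z in (0, 40 um] at 2 um steps
        mean, tmap = wn.effective_thickness(wn.ZStack(slab, z_step_um=2.0), 50.0)
        assert mean == pytest.approx(40.0)
        assert (tmap == 40.0).all()

    def test_buckled_phantom_area_weighted_mean(self):
        """Flat 15 um film with hollow ridges reaching 60 um over 30% of the area."""
        z_step = 1.0
        nz, h, w = 70, 10, 10
        vol = np.zeros((nz, h, w))
        vol[:15] = 100.0  # flat film everywhere
        ridge = np.zeros((h, w), bool)
        ridge[:, :3] = True  # exactly 30% of columns
        vol[59:60, ridge] = 100.0  # ridge apex shell at 60 um
        mean, tmap = wn.effective_thickness(wn.ZStack(vol, z_step), 50.0)
        assert mean == pytest.approx(0.7 * 15 + 0.3 * 60, abs=z_step)

    def test_all_dark_stack_warns_zero(self):
        with pytest.warns(UserWarning, match="threshold"):
            mean, tmap = wn.effective_thickness(wn.ZStack(np.zeros((5, 4, 4)), 1.0), 10.0)
        assert mean == 0.0
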