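"""Registration-propagated doublet segmentation."""

import numpy as np
import pytest

from spherofuse import microwell as mw
from spherofuse import phantom as ph
from spherofuse import segment as sg
from spherofuse.metrics import segmentation_scores

from conftest import KINETICS, R_UM


def _crop_truth(gt, pair):
    x0, y0 = pair.crop_origin
    h, w = pair.binary_mask.shape
    return gt.masks[pair.frame_index][y0:y0 + h, x0:x0 + w]


class TestInitializeMask:
    def test_noiseless_doublet_segmented_accurately(self, clean_sequence,
                                                    clean_well):
        stack, gt = clean_sequence
        pair = sg.initialize_mask(stack[0], clean_well)
        tpr, ppv = segmentation_scores(pair.binary_mask, _crop_truth(gt, pair))
        assert tpr >= 0.98 and ppv >= 0.98

    def test_gray_ref_supported_exactly_on_mask(self, clean_sequence,
                                                clean_well):
        stack, _ = clean_sequence
        pair = sg.initialize_mask(stack[0], clean_well)
        assert np.array_equal(pair.gray_ref > 0, pair.binary_mask)

    def test_debris_only_well_raises_empty(self):
        cfg = ph.PhantomConfig.test_preset(rng_seed=9)
        img, (cx, cy, R) = ph.render_single_well(cfg, disks=[], n_debris=6)
        with pytest.raises(sg.EmptyWellError):
            sg.initialize_mask(img, mw.WellCircle(cx, cy, R))

    def test_single_cell_specks_do_not_perturb_mask(self):
        cfg = ph.PhantomConfig.test_preset(rng_seed=21)
        r_px = 45.0 / cfg.pixel_size
        disks = [(-r_px, 0.0, r_px), (r_px, 0.0, r_px)]
        img0, (cx, cy, R) = ph.render_single_well(cfg, disks=disks)
        img1, _ = ph.render_single_well(cfg, disks=disks, n_cells=10)
        well = mw.WellCircle(cx, cy, R)
        m0 = sg.initialize_mask(img0, well).binary_mask
        m1 = sg.initialize_mask(img1, well).binary_mask
        assert abs(int(m1.sum()) - int(m0.sum())) / m0.sum() < 0.01


class TestRegistration:
    @pytest.fixture(scope="class")
    def ref_pair(self, clean_sequence, clean_well):
        stack, _ = clean_sequence
        return sg.initialize_mask(stack[0], clean_well)

    def test_identity(self, clean_sequence, clean_well, ref_pair):
        stack, _ = clean_sequence
        half = ref_pair.binary_mask.shape[0] // 2
        crop, _ = sg._crop_with_origin(stack[0], clean_well.x, clean_well.y,
                                       half)
        t = sg.register_reference(ref_pair.gray_ref, crop)
        assert abs(t.dx) <= 0.5 and abs(t.dy) <= 0.5 and abs(t.dtheta) <= 0.5

    def test_pure_translation_recovered(self, clean_sequence, clean_well,
                                        ref_pair):
        stack, _ = clean_sequence
        half = ref_pair.binary_mask.shape[0] // 2
        crop, _ = sg._crop_with_origin(stack[0], clean_well.x - 3,
                                       clean_well.y + 2, half)
        t = sg.register_reference(ref_pair.gray_ref, crop)
        assert t.dx == pytest.approx(3.0, abs=0.5)
        assert t.dy == pytest.approx(-2.0, abs=0.5)
        assert abs(t.dtheta) <= 0.5

    def test_pure_rotation_recovered(self, clean_well):
        cfg = ph.PhantomConfig.test_preset(n_frames=1)
        st0, _ = ph.render_doublet_sequence(cfg, KINETICS, 50, 40)
        st4, _ = ph.render_doublet_sequence(cfg, KINETICS, 50, 40,
                                            orientation_deg=4.0)
        pair = sg.initialize_mask(st0[0], clean_well)
        half = pair.binary_mask.shape[0] // 2
        crop, _ = sg._crop_with_origin(st4[0], clean_well.x, clean_well.y,
                                       half)
        t = sg.register_reference(pair.gray_ref, crop)
        assert t.dtheta == pytest.approx(4.0, abs=0.5)

    def test_transform_inverse_composes_to_identity(self):
        t = sg.RigidTransform(dx=3.2, dy=-1.5, dtheta=4.0)
        inv = t.inverse()
        # compose forward then inverse on a test point about the origin
        import math
        p = np.array([10.0, 5.0])
        th = math.radians(t.dtheta)
        R = np.array([[math.cos(th), -math.sin(th)],
                      [math.sin(th), math.cos(th)]])
        p1 = R @ p + np.array([t.dx, t.dy])
        th_i = math.radians(inv.dtheta)
        Ri = np.array([[math.cos(th_i), -math.sin(th_i)],
                       [math.sin(th_i), math.cos(th_i)]])
        p2 = Ri @ p1 + np.array([inv.dx, inv.dy])
        assert np.allclose(p2, p, atol=1e-9)


class TestRefineMask:
    def test_idempotent_when_masks_agree(self):
        m = np.zeros((50, 50), dtype=bool)
        m[10:40, 15:35] = True
        out, fallback = sg.refine_mask(m, m)
        assert np.array_equal(out, m) and not fallback

    def test_disjoint_debris_removed(self):
        ref = np.zeros((60, 60), dtype=bool)
        ref[20:40, 20:40] = True
        fine = ref.copy()
        fine[2:6, 2:6] = True  # blob with zero reference overlap
        out, fallback = sg.refine_mask(fine, ref)
        assert np.array_equal(out, ref) and not fallback

    def test_empty_fine_mask_falls_back_to_reference(self):
        ref = np.zeros((40, 40), dtype=bool)
        ref[10:30, 10:30] = True
        out, fallback = sg.refine_mask(np.zeros_like(ref), ref)
        assert np.array_equal(out, ref) and fallback

    def test_area_jump_falls_back(self):
        ref = np.zeros((60, 60), dtype=bool)
        ref[20:40, 20:40] = True
        fine = np.zeros_like(ref)
        fine[15:45, 15:45] = True  # 2.25x area of the previous frame
        out, fallback = sg.refine_mask(fine, ref, prev_area=float(ref.sum()))
        assert fallback and np.array_equal(out, ref)

    def test_both_empty_raises(self):
        e = np.zeros((10, 10), dtype=bool)
        with pytest.raises(sg.EmptyWellError):
            sg.refine_mask(e, e)


class TestSegmentSequence:
    def test_noiseless_sequence_quality(self, clean_sequence,
                                        clean_segmentation):
        _, gt = clean_sequence
        res = clean_segmentation
        assert res.n_frames == 30 and res.drop_reason is None
        scores = [segmentation_scores(p.binary_mask, _crop_truth(gt, p))
                  for p in res.masks]
        tpr = np.mean([s[0] for s in scores])
        ppv = np.mean([s[1] for s in scores])
        assert tpr >= 0.97 and ppv >= 0.97

    def test_noisy_sequence_quality(self, noisy_sequence, noisy_segmentation):
        _, gt = noisy_sequence
        res = noisy_segmentation
        scores = [segmentation_scores(p.binary_mask, _crop_truth(gt, p))
                  for p in res.masks]
        assert np.mean([s[0] for s in scores]) >= 0.95
        assert np.mean([s[1] for s in scores]) >= 0.95

    def test_rolling_reference_invariant(self, clean_segmentation):
        for pair in clean_segmentation.masks:
            assert np.array_equal(pair.gray_ref > 0, pair.binary_mask)

    def test_cumulative_rotation_recovered(self, clean_well):
        cfg = ph.PhantomConfig.test_preset(n_frames=30)
        stack, _ = ph.render_doublet_sequence(cfg, (0.9, -0.3, 6.0), 50, 40,
                                              rotation_per_frame=0.5)
        res = sg.segment_sequence(stack, clean_well)
        assert res.drop_reason is None
        assert sum(res.rotations) == pytest.approx(0.5 * (res.n_frames - 1),
                                                   abs=2.0)

    def test_well_leaving_fov_drops_sample(self, clean_well):
        cfg = ph.PhantomConfig.test_preset(n_frames=30,
                                           drift_per_frame=(6.0, 0.0))
        stack, gt = ph.render_doublet_sequence(cfg, KINETICS, R_UM, R_UM)
        well = mw.WellCircle(*gt.well_center[0], gt.well_radius_px)
        res = sg.segment_sequence(stack, well)
        assert res.drop_reason is not None
        assert res.drop_frame == res.n_frames
        assert res.n_frames < 30

    def test_area_tracks_analytic_union(self, clean_sequence,
                                        clean_segmentation):
        _, gt = clean_sequence
        for pair in clean_segmentation.masks:
            area_px = pair.binary_mask.sum()
            true_px = gt.union_area_um2[pair.frame_index] / 1.6 ** 2
            assert abs(area_px - true_px) / true_px < 0.02
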