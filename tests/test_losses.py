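"""Loss terms: printed-formula arithmetic, EDT+logistic oracle, topology
properties of the centerline term, and gradient correctness."""

import numpy as np
import pytest
from scipy import ndimage

from angiolume.segmentation import (
    LossParams,
    cldice_loss,
    dice_loss,
    lumen_loss,
    lumen_weight_map,
    sigma_shifted,
    soft_skeleton_np,
    total_loss,
)
from angiolume.segmentation.losses import bce_loss


def brute_force_lumen_weights(gt, r):
    """Exhaustive nearest-background scan → clip → logistic (the oracle)."""
    gt = np.asarray(gt) > 0
    bg = np.argwhere(~gt)
    w = np.zeros(gt.shape)
    for v in np.argwhere(np.ones_like(gt)):
        if not gt[tuple(v)]:
            d = 0.0
        elif len(bg) == 0:
            d = float(max(gt.shape))
        else:
            d = np.sqrt(((bg - v) ** 2).sum(axis=1)).min()
        w[tuple(v)] = 1.0 / (1.0 + np.exp(-(min(d, r) - (r - 5.0))))
    return w


class TestDice:
    def test_perfect_overlap_zero(self):
        g = (np.random.default_rng(0).uniform(size=(6, 6, 6)) > 0.5).astype(float)
        assert dice_loss(g, g).item() == pytest.approx(0.0, abs=1e-2)

    def test_disjoint_near_one(self):
        a = np.zeros((4, 4, 8))
        b = np.zeros((4, 4, 8))
        a[:, :, :3] = 1.0
        b[:, :, 5:] = 1.0
        assert dice_loss(a, b).item() == pytest.approx(1.0, abs=0.02)

    def test_half_overlap(self):
        # |P| = |G| = 100, overlap 50 → loss 0.5 (up to smoothing)
        p = np.zeros((1, 10, 20))
        g = np.zeros((1, 10, 20))
        p[0, :, :10] = 1.0
        g[0, :, 5:15] = 1.0
        assert dice_loss(p, g).item() == pytest.approx(0.5, abs=0.01)

    def test_both_empty_is_zero(self):
        z = np.zeros((4, 4, 4))
        assert dice_loss(z, z).item() == 0.0


class TestSigmaShifted:
    def test_at_r(self):
        assert sigma_shifted(10.0, 10.0) == pytest.approx(0.993307149, abs=1e-8)

    def test_background(self):
        assert sigma_shifted(0.0, 10.0) == pytest.approx(0.006692851, abs=1e-8)


class TestLumenWeights:
    def test_background_and_deep_weights(self):
        gt = np.zeros((24, 24, 24), bool)
        gt[2:22, 2:22, 2:22] = True
        w = lumen_weight_map(gt, r=10.0)
        assert w[0, 0, 0] == pytest.approx(sigma_shifted(0, 10), abs=1e-12)
        assert w[12, 12, 12] == pytest.approx(sigma_shifted(10, 10), abs=1e-12)

    def test_cube_center_weight(self):
        # 7³ solid cube in a 9³ grid: center voxel EDT = 4
        gt = np.zeros((9, 9, 9), bool)
        gt[1:8, 1:8, 1:8] = True
        w = lumen_weight_map(gt, r=10.0)
        expected = 1.0 / (1.0 + np.exp(-(4.0 - 5.0)))
        assert w[4, 4, 4] == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        shape = tuple(rng.integers(4, 9, size=3))
        gt = rng.uniform(size=shape) > 0.6
        r = float(rng.uniform(3, 12))
        assert np.allclose(lumen_weight_map(gt, r), brute_force_lumen_weights(gt, r), atol=1e-12)


class TestSoftSkeleton:
    def test_empty_volume(self):
        assert soft_skeleton_np(np.zeros((8, 8, 8)), 4).sum() == 0

    def test_thin_line_fixed_point(self):
        line = np.zeros((5, 5, 20))
        line[2, 2, 2:18] = 1.0
        skel = soft_skeleton_np(line, 5)
        # a 1-voxel line is already its own skeleton (interior preserved)
        assert np.array_equal(skel[2, 2, 3:17], line[2, 2, 3:17])

    def test_tube_skeleton_near_centerline(self, straight_tube):
        mask, cl = straight_tube
        skel = soft_skeleton_np(mask.astype(float), 6)
        pts = np.argwhere(skel > 0.5)
        pts = pts[(pts[:, 2] > 15) & (pts[:, 2] < 95)]  # away from end caps
        assert len(pts)
        dist_to_axis = np.sqrt((pts[:, 0] - 20) ** 2 + (pts[:, 1] - 20) ** 2)
        assert dist_to_axis.max() <= 1.5


class TestClDice:
    def test_perfect_prediction_zero(self, y_tree):
        assert cldice_loss(y_tree.astype(float), y_tree, iters=6).item() == pytest.approx(0.0, abs=0.02)

    def test_dilation_near_invariance(self, straight_tube):
        mask, _ = straight_tube
        dilated = ndimage.binary_dilation(mask)
        loss = cldice_loss(dilated.astype(float), mask, iters=6).item()
        assert loss < 0.1

    def test_missing_branch_costs_more_than_missing_wall(self, y_tree):
        gt = y_tree
        # drop one entire branch (z > 55, y > 24)
        missing_branch = gt.copy()
        branch_sel = np.zeros_like(gt)
        branch_sel[:, 24:, 60:] = True
        removed = gt & branch_sel
        missing_branch[removed] = False
        n_removed = removed.sum()
        # erode walls by the same voxel count
        eroded = ndimage.binary_erosion(gt)
        wall = gt & ~eroded
        wall_idx = np.argwhere(wall)
        missing_wall = gt.copy()
        missing_wall[tuple(wall_idx[:n_removed].T)] = False
        l_branch = cldice_loss(missing_branch.astype(float), gt, iters=6).item()
        l_wall = cldice_loss(missing_wall.astype(float), gt, iters=6).item()
        assert l_branch > l_wall


class TestLumenLoss:
    def test_perfect_zero(self, straight_tube):
        mask, _ = straight_tube
        assert lumen_loss(mask.astype(float), mask, r=8).item() == pytest.approx(0.0, abs=0.01)

    def test_empty_gt_zero(self):
        z = np.zeros((8, 8, 8))
        assert lumen_loss(z, z, r=10).item() == 0.0

    def test_missing_lumen_costs_more_than_missing_wall(self):
        # thick tube radius 8: removing the innermost core hurts more than
        # removing an equal count of wall voxels
        zz, yy, xx = np.mgrid[:24, :24, :40]
        gt = (zz - 12) ** 2 + (yy - 12) ** 2 <= 64
        edt = ndimage.distance_transform_edt(gt)
        core = edt > 5
        n = core.sum()
        wall_idx = np.argwhere((edt > 0) & (edt <= 2))
        pred_no_lumen = gt & ~core
        pred_no_wall = gt.copy()
        pred_no_wall[tuple(wall_idx[:n].T)] = False
        l_lumen = lumen_loss(pred_no_lumen.astype(float), gt, r=8).item()
        l_wall = lumen_loss(pred_no_wall.astype(float), gt, r=8).item()
        assert l_lumen > l_wall


class TestTotalLoss:
    def test_printed_combination(self):
        # component values 0.4 / 0.2 / 0.1 at α = β = 0.5 → 0.2
        alpha = beta = 0.5
        val = (1 - beta) * ((1 - alpha) * 0.4 + alpha * 0.2) + beta * 0.1
        assert val == pytest.approx(0.2, abs=1e-12)

    def test_zero_when_components_zero(self, straight_tube):
        mask, _ = straight_tube
        lp = LossParams(skel_iters=6, r=8)
        assert total_loss(mask.astype(float), mask, lp).item() == pytest.approx(0.0, abs=0.03)

    def test_beta_zero_reduces_to_dice_cldice(self):
        rng = np.random.default_rng(7)
        pred = rng.uniform(size=(12, 12, 12))
        gt = rng.uniform(size=(12, 12, 12)) > 0.7
        lp = LossParams(alpha=0.3, beta=0.0, skel_iters=3)
        combined = total_loss(pred, gt, lp).item()
        expected = 0.7 * dice_loss(pred, gt.astype(float)).item() + 0.3 * cldice_loss(pred, gt, 3).item()
        assert combined == pytest.approx(expected, abs=1e-10)

    @pytest.mark.parametrize("seed", range(3))
    def test_in_unit_interval(self, seed):
        rng = np.random.default_rng(seed)
        pred = rng.uniform(size=(10, 10, 10))
        gt = rng.uniform(size=(10, 10, 10)) > 0.5
        val = total_loss(pred, gt, LossParams(skel_iters=3)).item()
        assert 0.0 <= val <= 1.0

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            LossParams(alpha=1.5)
        with pytest.raises(ValueError):
            LossParams(r=0)


class TestGradients:
    def test_total_loss_gradient_matches_finite_difference(self):
        from angiolume.segmentation.autograd import Tensor

        rng = np.random.default_rng(1)
        x = rng.uniform(0.2, 0.8, size=(8, 8, 8))
        gt = rng.uniform(size=(8, 8, 8)) > 0.6
        lp = LossParams(skel_iters=2, r=4)
        t = Tensor(x, requires_grad=True)
        loss = total_loss(t, gt, lp)
        loss.backward()
        eps = 1e-6
        for idx in [(0, 0, 0), (4, 4, 4), (7, 3, 2)]:
            orig = x[idx]
            x[idx] = orig + eps
            lp1 = total_loss(Tensor(x), gt, lp).item()
            x[idx] = orig - eps
            lp2 = total_loss(Tensor(x), gt, lp).item()
            x[idx] = orig
            num = (lp1 - lp2) / (2 * eps)
            assert t.grad[idx] == pytest.approx(num, abs=1e-6)

    def test_bce_matches_closed_form(self):
        p = np.array([[[0.8]]])
        g = np.array([[[1.0]]])
        assert bce_loss(p, g).item() == pytest.approx(-np.log(0.8), rel=1e-6)
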