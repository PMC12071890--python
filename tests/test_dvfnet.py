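"""Network construction, the warp operator, SSIM, and the training loss."""

import numpy as np
import pytest

from sctselect import phantom
from sctselect.dvfnet import (
    DVFNet,
    NetworkSpec,
    build_network,
    normalize_hu,
    registration_loss,
    ssim_volumes,
)
from sctselect.dvfnet import autodiff as ad
from sctselect.dvfnet.losses import ssim
from sctselect.grids import DisplacementField, ImageVolume, StructureMask
from sctselect.warping import warp


class TestNetwork:
    def test_zero_init_predicts_zero_field(self, clean_phantom):
        vol, _ = clean_phantom
        model = build_network(NetworkSpec(levels=2, init_channels=8), seed=0)
        dvf = model.predict_dvf(vol)
        assert np.all(dvf.data == 0.0)
        warped = warp(vol, dvf)
        assert np.allclose(warped.data, vol.data, atol=1e-6)

    @pytest.mark.parametrize("shape", [(32, 32, 32), (32, 32, 16)])
    def test_output_shape_matches_input(self, shape):
        model = build_network(NetworkSpec(levels=2, init_channels=4), seed=0)
        x = ad.Tensor(np.random.default_rng(0).random((1, 1, *shape)))
        out = model.forward(x)
        assert out.shape == (1, 3, *shape)

    def test_parameter_count_grows_with_width(self):
        counts = [
            build_network(NetworkSpec(levels=2, init_channels=c)).n_parameters
            for c in (8, 16, 32)
        ]
        assert counts[0] < counts[1] < counts[2]

    def test_indivisible_axis_rejected_by_name(self):
        model = build_network(NetworkSpec(levels=3, init_channels=4))
        x = ad.Tensor(np.zeros((1, 1, 32, 32, 12)))
        with pytest.raises(ValueError, match="axis z"):
            model.forward(x)

    def test_checkpoint_roundtrip(self, tmp_path, clean_phantom):
        vol, _ = clean_phantom
        model = build_network(NetworkSpec(levels=2, init_channels=4), seed=3)
        # make the prediction nontrivial
        model.params["head.w"].data += 0.01
        model.save(tmp_path / "model")
        loaded = DVFNet.load(tmp_path / "model")
        a = model.predict_dvf(vol)
        b = loaded.predict_dvf(vol)
        assert np.array_equal(a.data, b.data)


class TestWarp:
    def test_zero_field_identity(self, clean_phantom):
        vol, masks = clean_phantom
        zero = DisplacementField(
            np.zeros((3, *vol.shape)), vol.spacing, vol.origin
        )
        assert np.array_equal(
            warp(masks["body"], zero, "nearest").data, masks["body"].data
        )
        assert np.allclose(warp(vol, zero, "trilinear").data, vol.data, atol=1e-6)

    def test_integer_shift_matches_index_oracle(self, clean_phantom):
        vol, _ = clean_phantom
        sx, sy, sz = vol.spacing
        # displacement of exactly one voxel along each axis
        disp = np.zeros((3, *vol.shape))
        disp[0] = sx
        disp[1] = -sy
        disp[2] = sz
        out = warp(vol, DisplacementField(disp, vol.spacing, vol.origin), "nearest")
        # backward warp: out[i,j,k] = vol[i+1, j-1, k+1] on the interior
        oracle = vol.data[1:, :-1, 1:]
        assert np.array_equal(out.data[:-1, 1:, :-1], oracle)

    def test_nearest_keeps_masks_binary(self, clean_phantom):
        vol, masks = clean_phantom
        f = phantom.make_smooth_dvf(phantom.DeformationSpec(random_seed=3), vol)
        out = warp(masks["ctv"], f, "nearest")
        assert out.data.dtype == bool

    def test_small_smooth_warp_keeps_ctv_connected(self, clean_phantom):
        from scipy import ndimage

        vol, masks = clean_phantom
        f = phantom.make_smooth_dvf(
            phantom.DeformationSpec(amplitude_mm=(2.0, 5.0), random_seed=6), vol
        )
        out = warp(masks["ctv"], f, "nearest")
        _, n = ndimage.label(out.data)
        assert n == 1

    def test_grid_mismatch_rejected(self, clean_phantom):
        vol, _ = clean_phantom
        bad = DisplacementField(np.zeros((3, 8, 8, 8)), vol.spacing)
        with pytest.raises(ValueError):
            warp(vol, bad)


class TestSSIM:
    def test_self_similarity_is_one(self, clean_phantom):
        vol, _ = clean_phantom
        assert ssim_volumes(vol, vol) == pytest.approx(1.0)

    def test_inverted_contrast_is_negative(self):
        rng = np.random.default_rng(0)
        a = (rng.random((12, 12, 12)) > 0.5).astype(float) * 1000.0 - 500.0
        b = ImageVolume(-a, (1, 1, 1))
        a = ImageVolume(a, (1, 1, 1))
        assert ssim_volumes(a, b) < 0.0

    def test_noise_monotonicity(self, clean_phantom):
        vol, _ = clean_phantom
        vals = []
        for sigma in (0.0, 0.05, 0.1):
            rng = np.random.default_rng(7)
            noisy = vol.with_data(vol.data + rng.normal(0, sigma * 2000.0, vol.shape))
            vals.append(ssim_volumes(vol, noisy))
        assert vals[0] > vals[1] > vals[2]

    def test_window_larger_than_volume_rejected(self):
        a = ad.Tensor(np.zeros((1, 1, 4, 4, 4)))
        with pytest.raises(ValueError, match="window"):
            ssim(a, a, window=7)


class TestLoss:
    def _norm_pair(self, vol):
        x = normalize_hu(vol.data)[None, None]
        return x

    def test_zero_for_identical_pair_and_zero_field(self, clean_phantom):
        vol, _ = clean_phantom
        x = self._norm_pair(vol)
        dvf = ad.Tensor(np.zeros((1, 3, *vol.shape)))
        loss = registration_loss(x, x, dvf, vol.spacing, lam=0.01)
        assert float(loss.data) == pytest.approx(0.0, abs=1e-12)

    def test_zero_field_reduces_to_image_term(self, registration_pair):
        dct, pct, _, _ = registration_pair
        xd, xp = self._norm_pair(dct), self._norm_pair(pct)
        dvf = ad.Tensor(np.zeros((1, 3, *dct.shape)))
        with_reg = float(registration_loss(xd, xp, dvf, dct.spacing, lam=0.5).data)
        image_only = 1.0 - ssim_volumes(dct, pct)
        assert with_reg == pytest.approx(image_only, abs=1e-12)

    def test_regularizer_is_quadratic_in_field(self, clean_phantom):
        vol, _ = clean_phantom
        rng = np.random.default_rng(1)
        u = ad.Tensor(rng.normal(size=(1, 3, *vol.shape)))
        u2 = ad.Tensor(2.0 * u.data)
        r1 = float(ad.grad_penalty(u, vol.spacing).data)
        r2 = float(ad.grad_penalty(u2, vol.spacing).data)
        assert r2 == pytest.approx(4.0 * r1)

    def test_negative_weight_rejected(self, clean_phantom):
        vol, _ = clean_phantom
        x = self._norm_pair(vol)
        dvf = ad.Tensor(np.zeros((1, 3, *vol.shape)))
        with pytest.raises(ValueError):
            registration_loss(x, x, dvf, vol.spacing, lam=-1.0)


class TestGradients:
    """Spot finite-difference checks of the custom backward passes."""

    def _gradcheck(self, fn, t, eps=1e-5, tol=2e-4):
        t.grad = None
        fn(t).backward()
        rng = np.random.default_rng(0)
        flat_idx = rng.choice(t.data.size, size=min(12, t.data.size), replace=False)
        for fi in flat_idx:
            i = np.unravel_index(fi, t.data.shape)
            orig = t.data[i]
            t.data[i] = orig + eps
            lp = float(fn(t).data)
            t.data[i] = orig - eps
            lm = float(fn(t).data)
            t.data[i] = orig
            num = (lp - lm) / (2 * eps)
            assert num == pytest.approx(t.grad[i], abs=max(1e-7, 5e-4 * abs(num)))

    def test_conv3d_input_gradient(self):
        rng = np.random.default_rng(0)
        w = ad.Tensor(rng.normal(size=(2, 2, 3, 3, 3)) * 0.1)
        b = ad.Tensor(np.zeros(2))
        x = ad.Tensor(rng.normal(size=(1, 2, 4, 4, 4)), requires_grad=True)
        self._gradcheck(lambda t: ad.conv3d(t, w, b).square().mean(), x)

    def test_warp_displacement_gradient(self):
        rng = np.random.default_rng(1)
        img = rng.normal(size=(1, 1, 6, 6, 6))
        d = ad.Tensor(rng.uniform(-0.4, 0.4, size=(1, 3, 6, 6, 6)), requires_grad=True)
        self._gradcheck(lambda t: ad.warp3d(img, t).square().mean(), d)

    def test_full_loss_gradient(self):
        rng = np.random.default_rng(2)
        a = rng.uniform(0, 1, size=(1, 1, 8, 8, 8))
        b = rng.uniform(0, 1, size=(1, 1, 8, 8, 8))
        d = ad.Tensor(rng.uniform(-1, 1, size=(1, 3, 8, 8, 8)), requires_grad=True)
        self._gradcheck(
            lambda t: registration_loss(a, b, t, (2.0, 2.0, 2.0), lam=0.01, window=5),
            d,
            tol=1e-3,
        )
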