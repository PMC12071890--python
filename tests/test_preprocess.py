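"""Couch removal, HU histogram matching, rigid alignment, resampling."""

import numpy as np
import pytest

from sctselect import phantom, preprocess
from sctselect.grids import ImageVolume
from sctselect.metrics import mae

from conftest import desk_spec


def dice(a, b) -> float:
    return 2.0 * (a & b).sum() / (a.sum() + b.sum())


class TestRemoveCouch:
    def test_recovers_body_mask_on_couch_phantoms(self):
        for kind, seed in (("flat", 1), ("curved", 2)):
            vol, masks = phantom.make_thorax_phantom(
                desk_spec(couch_kind=kind, noise_sigma=5.0, random_seed=seed)
            )
            cleaned, body, flags = preprocess.remove_couch(vol)
            assert dice(body.data, masks["body"].data) >= 0.99
            assert not flags.truncation

    def test_couch_roundtrip_preserves_body(self, clean_phantom):
        vol, masks = clean_phantom
        with_couch, _ = phantom.add_couch(vol, masks["body"], kind="flat")
        cleaned, _, _ = preprocess.remove_couch(with_couch)
        assert mae(cleaned, vol, mask=masks["body"]) < 2.0

    def test_idempotent_on_clean_volume(self, clean_phantom):
        vol, masks = clean_phantom
        once, body1, _ = preprocess.remove_couch(vol)
        twice, body2, _ = preprocess.remove_couch(once)
        assert np.array_equal(once.data, twice.data)
        assert np.array_equal(body1.data, body2.data)
        # inside body untouched, outside forced to air
        assert np.array_equal(once.data[body1.data], vol.data[body1.data])
        assert np.all(once.data[~body1.data] == -1000.0)

    def test_truncation_raises_qa_flag(self):
        spec = phantom.PhantomSpec.scaled_to((32, 32, 16), (8.0, 8.0, 10.0))
        case = phantom.synthesize_case(spec=spec, seed=11)
        truncated = phantom.truncate_fov(case.dct, 0.2)
        _, _, flags = preprocess.remove_couch(truncated)
        assert flags.truncation
        assert any("truncation" in n.lower() for n in flags.notes)

    def test_all_air_rejected(self):
        vol = ImageVolume(np.full((8, 8, 8), -1000.0), (5, 5, 5))
        with pytest.raises(ValueError):
            preprocess.remove_couch(vol)


class TestHistogramLUT:
    def test_identity_when_source_equals_reference(self, noisy_couch_phantom):
        vol, masks = noisy_couch_phantom
        lut = preprocess.build_hu_lut(vol, vol, masks["body"], masks["body"])
        hs = np.linspace(-800, 400, 25)
        assert np.allclose(np.interp(hs, lut.source_hu, lut.mapped_hu), hs, atol=lut.bin_width)

    def test_recovers_constant_shift(self, noisy_couch_phantom):
        vol, masks = noisy_couch_phantom
        body = masks["body"]
        ref = vol.with_data(np.where(body.data, vol.data + 50.0, -1000.0))
        lut = preprocess.build_hu_lut(vol, ref, body, body)
        occupied = np.linspace(
            vol.data[body.data].min() + 1, vol.data[body.data].max() - 1, 40
        )
        mapped = np.interp(occupied, lut.source_hu, lut.mapped_hu)
        # one (occupied-range) bin width of slack
        occupied_bw = (occupied[-1] - occupied[0]) / 256
        assert np.all(np.abs(mapped - (occupied + 50.0)) <= max(occupied_bw, 1.0))

    def test_deciles_match_after_application(self, noisy_couch_phantom):
        vol, masks = noisy_couch_phantom
        body = masks["body"]
        rng = np.random.default_rng(8)
        ref = vol.with_data(np.where(body.data, vol.data * 1.1 + 20.0, -1000.0))
        lut = preprocess.build_hu_lut(vol, ref, body, body)
        out = preprocess.apply_lut(vol, lut)
        q = np.linspace(0.1, 0.9, 9)
        got = np.quantile(out.data[body.data], q)
        want = np.quantile(ref.data[body.data], q)
        span = want.max() - want.min()
        assert np.all(np.abs(got - want) <= span / 256 + 1.0)

    def test_lut_is_monotone_and_apply_preserves_order(self, noisy_couch_phantom):
        vol, masks = noisy_couch_phantom
        body = masks["body"]
        ref = vol.with_data(np.where(body.data, vol.data * 0.8 - 30.0, -1000.0))
        lut = preprocess.build_hu_lut(vol, ref, body, body)
        assert np.all(np.diff(lut.mapped_hu) >= 0)
        hs = np.sort(np.random.default_rng(0).uniform(-1000, 1000, 64))
        mapped = np.interp(hs, lut.source_hu, lut.mapped_hu)
        assert np.all(np.diff(mapped) >= 0)

    def test_identity_lut_and_constant_volume(self, clean_phantom):
        vol, _ = clean_phantom
        ident = preprocess.HistogramLUT.identity()
        assert np.allclose(preprocess.apply_lut(vol, ident).data, vol.data)
        const = vol.with_data(np.full(vol.shape, 123.0))
        out = preprocess.apply_lut(const, ident)
        assert np.all(out.data == 123.0)

    def test_shift_lut_reduces_mae(self, noisy_couch_phantom):
        vol, masks = noisy_couch_phantom
        body = masks["body"]
        ref = vol.with_data(np.where(body.data, vol.data + 50.0, -1000.0))
        lut = preprocess.build_hu_lut(vol, ref, body, body)
        corrected = preprocess.apply_lut(vol, lut)
        assert mae(corrected, ref, mask=body) < mae(vol, ref, mask=body)


@pytest.fixture(scope="module")
def fine_phantom():
    """2 mm-spacing phantom where small mm shifts are exact voxel shifts."""
    spec = phantom.PhantomSpec.scaled_to(
        (64, 64, 32), (2.0, 2.0, 2.0), noise_sigma=5.0, random_seed=1
    )
    vol, masks = phantom.make_thorax_phantom(spec)
    cleaned, body, _ = preprocess.remove_couch(vol)
    return cleaned, body


class TestRigidAlign:
    def test_identity_pair(self, fine_phantom):
        vol, body = fine_phantom
        _, t = preprocess.rigid_align(vol, vol, body, body)
        assert np.all(np.abs(t) <= 0.5)

    def test_recovers_constructed_shift(self, fine_phantom):
        vol, body = fine_phantom
        sv = (3, -2, 1)  # voxels = (6, -4, 2) mm at 2 mm spacing
        moved = np.full_like(vol.data, -1000.0)
        moved[3:, :-2, 1:] = vol.data[:-3, 2:, :-1]
        mb = np.zeros_like(body.data)
        mb[3:, :-2, 1:] = body.data[:-3, 2:, :-1]
        aligned, t = preprocess.rigid_align(
            vol.with_data(moved), vol, body.with_data(mb), body
        )
        assert np.all(np.abs(np.asarray(t) - (-6.0, 4.0, -2.0)) <= 0.5)

    def test_ncc_never_decreases(self, fine_phantom):
        vol, body = fine_phantom
        rng = np.random.default_rng(2)
        jittered = vol.with_data(
            np.roll(vol.data, (2, -1, 1), axis=(0, 1, 2))
        )
        jb = body.with_data(np.roll(body.data, (2, -1, 1), axis=(0, 1, 2)))
        region = body.data | jb.data
        aligned, _ = preprocess.rigid_align(jittered, vol, jb, body)
        assert preprocess._ncc(aligned.data, vol.data, region) >= preprocess._ncc(
            jittered.data, vol.data, region
        )


class TestResample:
    def test_identity_when_shape_matches(self, clean_phantom):
        vol, _ = clean_phantom
        assert preprocess.resample(vol, vol.shape) is vol

    def test_constant_volume_stays_constant(self):
        vol = ImageVolume(np.full((16, 16, 8), 55.0), (4, 4, 4))
        out = preprocess.resample(vol, (8, 8, 4))
        assert np.allclose(out.data, 55.0)

    def test_extent_preserved_and_spacing_scaled(self):
        vol = ImageVolume(np.zeros((64, 64, 16)), (2.0, 2.0, 5.0))
        out = preprocess.resample(vol, (16, 16, 8))
        assert out.spacing == pytest.approx((8.0, 8.0, 10.0))
        extent_in = [n * s for n, s in zip(vol.shape, vol.spacing)]
        extent_out = [n * s for n, s in zip(out.shape, out.spacing)]
        assert extent_in == pytest.approx(extent_out)

    def test_roundtrip_mean_hu_stable(self, noisy_couch_phantom):
        vol, _ = noisy_couch_phantom
        down = preprocess.resample(vol, (16, 16, 8))
        back = preprocess.resample(down, vol.shape)
        assert abs(back.data.mean() - vol.data.mean()) < 1.0

    def test_mask_resampling_stays_binary(self, clean_phantom):
        _, masks = clean_phantom
        out = preprocess.resample(masks["body"], (16, 16, 8))
        assert out.data.dtype == bool


class TestAugment:
    def test_hflip_is_involution(self, noisy_couch_phantom):
        vol, _ = noisy_couch_phantom
        twice = preprocess.augment(preprocess.augment(vol, "hflip"), "hflip")
        assert np.array_equal(twice.data, vol.data)

    def test_rot45_conserves_body_volume(self):
        # finer grid: the check measures interpolation loss, not voxelization
        spec = phantom.PhantomSpec.scaled_to(
            (64, 64, 16), (5.0, 5.0, 10.0), noise_sigma=0.0, couch_kind="none"
        )
        _, masks = phantom.make_thorax_phantom(spec)
        rot = preprocess.augment(masks["body"], "rot45cw")
        ratio = rot.voxel_count / masks["body"].voxel_count
        assert abs(ratio - 1.0) < 0.01

    def test_rotated_mask_stays_binary(self, clean_phantom):
        _, masks = clean_phantom
        rot = preprocess.augment(masks["ctv"], "rot45cw")
        assert rot.data.dtype == bool

    def test_unknown_op_rejected(self, clean_phantom):
        vol, _ = clean_phantom
        with pytest.raises(ValueError):
            preprocess.augment(vol, "rot90")
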