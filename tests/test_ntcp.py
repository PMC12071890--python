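"""gEUD/LKB model values, the relevance filter, and the modality verdict."""

import numpy as np
import pytest

from sctselect import ntcp
from sctselect.dosimetry import DVHCurve, compute_dvh
from sctselect.grids import DoseVolume, StructureMask
from sctselect.ntcp import (
    EndpointCaseNTCP,
    LKBParams,
    delta_ntcp,
    geud,
    lkb_ntcp,
    load_lkb_params,
    modality_verdict,
    relevance_filter,
)


def uniform_curve(dose_gy, bin_width=1e-4):
    data = np.full((3, 3, 3), float(dose_gy))
    mask = StructureMask(np.ones((3, 3, 3), bool), (2, 2, 2), name="m")
    return compute_dvh(DoseVolume(data, (2, 2, 2)), mask, bin_width=bin_width)


def two_level_curve(lo, hi, bin_width=1e-3):
    data = np.array([lo, hi], float).reshape(2, 1, 1)
    mask = StructureMask(np.ones((2, 1, 1), bool), (10, 10, 10), name="m")
    return compute_dvh(DoseVolume(data, (10, 10, 10)), mask, bin_width=bin_width)


class TestGEUD:
    def test_n_one_is_mean_dose(self):
        c = two_level_curve(20.0, 60.0)
        assert geud(c, 1.0) == pytest.approx(40.0, abs=1e-2)

    def test_uniform_dose_for_any_n(self):
        c = uniform_curve(35.0)
        for n in (0.05, 0.3, 0.5, 1.0):
            assert geud(c, n) == pytest.approx(35.0, rel=1e-4)

    def test_half_half_hand_value(self):
        # v=(0.5, 0.5), d=(0, 60), n=0.5: (0.5 * 60^2)^0.5 = 42.43 Gy
        c = two_level_curve(0.0, 60.0)
        assert geud(c, 0.5) == pytest.approx(42.43, abs=0.01)

    def test_power_mean_bounds_and_small_n_limit(self):
        c = two_level_curve(10.0, 60.0)
        for n in (0.01, 0.1, 0.5, 1.0):
            assert 10.0 - 1e-6 <= geud(c, n) <= 60.0 + 1e-6
        assert geud(c, 0.01) == pytest.approx(60.0, rel=0.01)  # n->0: max dose

    def test_binned_curve_matches_voxel_brute_force(self):
        rng = np.random.default_rng(3)
        for seed in range(5):
            data = np.random.default_rng(seed).uniform(0, 70, (8, 8, 8))
            mask = StructureMask(rng.random((8, 8, 8)) < 0.5, (2, 2, 2), name="m")
            c = compute_dvh(DoseVolume(data, (2, 2, 2)), mask, bin_width=0.1)
            vox = data[mask.data]
            for n in (0.06, 0.35, 0.87, 1.0):
                brute = float(np.mean(vox ** (1.0 / n)) ** n)
                assert geud(c, n) == pytest.approx(brute, rel=0.005)

    def test_invalid_n_rejected(self):
        with pytest.raises(ValueError):
            geud(uniform_curve(10.0), 0.0)


class TestLKB:
    P = LKBParams("test", td50_gy=50.0, m=0.1, n=0.5)

    def test_half_probability_at_td50(self):
        assert lkb_ntcp(uniform_curve(50.0), self.P) == pytest.approx(0.5, abs=1e-4)

    def test_one_sigma_above_td50(self):
        # Deff = TD50 (1 + m): t = 1, Phi(1) = 0.8413
        assert lkb_ntcp(uniform_curve(55.0), self.P) == pytest.approx(0.8413, abs=1e-4)

    def test_zero_dose_tail(self):
        assert lkb_ntcp(uniform_curve(0.0), self.P) < 1e-15

    def test_strictly_increasing_in_dose(self):
        vals = [lkb_ntcp(uniform_curve(d), self.P) for d in (20, 35, 50, 65)]
        assert np.all(np.diff(vals) > 0)

    def test_larger_m_flattens_response(self):
        steep = LKBParams("s", 50.0, 0.05, 0.5)
        flat = LKBParams("f", 50.0, 0.3, 0.5)
        c = uniform_curve(60.0)
        assert abs(lkb_ntcp(c, flat) - 0.5) < abs(lkb_ntcp(c, steep) - 0.5)

    def test_parameter_validation(self):
        for kwargs in (
            dict(td50_gy=-1.0, m=0.1, n=0.5),
            dict(td50_gy=50.0, m=0.0, n=0.5),
            dict(td50_gy=50.0, m=0.1, n=1.5),
        ):
            with pytest.raises(ValueError):
                LKBParams("bad", **kwargs)

    def test_default_parameter_file_covers_all_endpoints(self):
        params = load_lkb_params()
        assert set(params) == set(ntcp.ENDPOINT_STRUCTURES)
        for p in params.values():
            assert p.td50_gy > 0 and p.m > 0 and 0 < p.n <= 1


def result(endpoint, modality, ct, ntcp_value):
    return ntcp.NTCPResult(endpoint, modality, ct, deff_gy=0.0, ntcp=ntcp_value)


class TestDeltaNTCP:
    def test_equal_inputs_give_zero(self):
        a = result("heart_pericarditis", "proton", "sCT", 0.1)
        b = result("heart_pericarditis", "photon", "sCT", 0.1)
        assert delta_ntcp(a, b) == 0.0

    def test_antisymmetry_of_the_difference(self):
        a = result("lung_pneumonitis", "proton", "pCT", 0.02)
        b = result("lung_pneumonitis", "photon", "pCT", 0.05)
        assert delta_ntcp(a, b) == pytest.approx(-0.03)

    def test_endpoint_mismatch_rejected(self):
        a = result("heart_pericarditis", "proton", "sCT", 0.1)
        b = result("lung_pneumonitis", "photon", "sCT", 0.1)
        with pytest.raises(ValueError):
            delta_ntcp(a, b)


def case(name, endpoint, ph_s, pr_s, ph_p, pr_p):
    return EndpointCaseNTCP(
        case=name,
        endpoint=endpoint,
        values={
            ("photon", "sCT"): ph_s,
            ("proton", "sCT"): pr_s,
            ("photon", "pCT"): ph_p,
            ("proton", "pCT"): pr_p,
        },
    )


class TestRelevanceFilter:
    def test_all_below_threshold_excluded(self):
        r = case("c", "heart_pericarditis", 4e-4, 4e-4, 4e-4, 4e-4)
        inc, exc = relevance_filter([r], threshold_pct=0.05)
        assert inc == [] and exc == [r]

    def test_any_value_above_threshold_includes(self):
        r = case("c", "heart_pericarditis", 1e-4, 1e-4, 6e-4, 1e-4)
        inc, exc = relevance_filter([r], threshold_pct=0.05)
        assert inc == [r] and exc == []

    def test_cohort_shaped_19_of_45(self):
        # 15 cases x 3 endpoints; engineer 19 relevant, 26 negligible
        results = []
        k = 0
        for i in range(15):
            for ep in ntcp.ENDPOINT_STRUCTURES:
                k += 1
                peak = 0.02 if k <= 19 else 1e-4  # 2% vs 0.01%
                results.append(case(f"c{i}", ep, peak / 2, peak, peak / 2, peak))
        inc, exc = relevance_filter(results, threshold_pct=0.05)
        assert len(inc) == 19 and len(exc) == 26


class TestModalityVerdict:
    def test_all_sign_matched_gives_100(self):
        rs = [
            case("a", "lung_pneumonitis", 0.02, 0.01, 0.02, 0.015),  # both neg
            case("b", "lung_pneumonitis", 0.01, 0.04, 0.02, 0.03),  # both pos
            case("c", "heart_pericarditis", 0.05, 0.01, 0.02, 0.01),  # both neg
        ]
        d = modality_verdict(rs).to_dict()
        assert d["trend_accuracy_pct"] == 100.0
        assert d["n_included"] == 3

    def test_sign_flip_gives_zero(self):
        rs = [case("a", "lung_pneumonitis", 0.02, 0.01, 0.01, 0.03)]
        d = modality_verdict(rs).to_dict()
        assert d["trend_accuracy_pct"] == 0.0
        assert not d["pairs"][0]["concordant"]

    def test_preferred_modality_follows_sign(self):
        r = case("a", "lung_pneumonitis", 0.04, 0.01, 0.05, 0.02)
        d = modality_verdict([r]).to_dict()
        assert d["pairs"][0]["preferred_sct"] == "proton"
        assert d["pairs"][0]["preferred_pct"] == "proton"
        assert d["endpoint_summary"]["lung_pneumonitis"]["verdict"] == "proton preferred"

    def test_eq2_identity_recomputed_exactly(self):
        r = case("a", "lung_pneumonitis", 0.031, 0.007, 0.028, 0.011)
        d = modality_verdict([r]).to_dict()["pairs"][0]
        assert d["delta_sct_minus_pct_pct"] == (
            d["delta_ntcp_sct_pct"] - d["delta_ntcp_pct_pct"]
        )

    def test_empty_after_filter_reports_status(self):
        r = case("a", "lung_pneumonitis", 1e-4, 1e-4, 1e-4, 1e-4)
        d = modality_verdict([r]).to_dict()
        assert d["status"] == "no relevant endpoints"
        assert d["n_included"] == 0
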