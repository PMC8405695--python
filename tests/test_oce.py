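"""Phase-difference strain estimation, segmentation, modulus recovery."""

import numpy as np
import pytest

import corneamech as cm
from corneamech.oce import SegmentationError, strain_scale_limit

from conftest import OPTICS, uniform_phase_pair


class TestComplexCrossCorrelation:
    def test_identical_scans_give_zero_phase(self):
        pair = uniform_phase_pair(0.0)
        corr = cm.complex_cross_correlation(pair, (5, 5))
        assert np.allclose(np.angle(corr.r_s), 0.0, atol=1e-12)

    def test_constant_phase_offset_appears_negated(self):
        phi0 = 0.7
        pair = uniform_phase_pair(0.0)
        pair.b_def = pair.b_ref * np.exp(1j * phi0)
        corr = cm.complex_cross_correlation(pair, (5, 5))
        assert np.allclose(np.angle(corr.r_s), -phi0, atol=1e-10)

    def test_unit_window_returns_raw_conjugate_product(self):
        pair = uniform_phase_pair(0.05)
        corr = cm.complex_cross_correlation(pair, (1, 1))
        assert np.allclose(corr.r_s, pair.b_ref * np.conj(pair.b_def))

    def test_shape_mismatch_rejected(self):
        pair = uniform_phase_pair(0.0)
        with pytest.raises(ValueError):
            cm.OCEScanPair(pair.b_ref, pair.b_def[:-1, :], pair.meta)


class TestAxialStrain:
    def test_zero_phase_gives_zero_strain(self):
        pair = uniform_phase_pair(0.0)
        sm = cm.axial_strain(cm.complex_cross_correlation(pair, (5, 5)), pair.meta)
        assert np.allclose(sm.eps[sm.mask], 0.0, atol=1e-12)

    def test_pi_phase_step_saturates_at_scale_limit(self):
        # a depth-linear phase of pi per pixel sits exactly at the
        # phase-ambiguity ceiling lambda/(4 n asu) ~ 35.6 permil
        limit = strain_scale_limit(OPTICS)
        assert limit == pytest.approx(35.63e-3, rel=1e-3)
        pair = uniform_phase_pair(-np.pi * 0.98)
        sm = cm.axial_strain(cm.complex_cross_correlation(pair, (1, 1)), pair.meta)
        assert np.median(sm.eps[:-1, :]) == pytest.approx(-0.98 * limit, rel=1e-6)

    def test_sign_convention_compression_is_negative(self):
        # a pressure drop compresses the tissue: phase grows with depth
        # for negative strain, and the estimate keeps the negative sign
        eps = -4.0e-3
        step = 4 * np.pi * OPTICS["refractive_index"] * OPTICS["asu_um"] * eps / (
            OPTICS["wavelength_nm"] * 1e-3
        )
        pair = uniform_phase_pair(step)
        sm = cm.axial_strain(cm.complex_cross_correlation(pair, (1, 1)), pair.meta)
        assert np.median(sm.eps[:-1, :]) == pytest.approx(eps, rel=1e-9)

    def test_global_phase_invariance(self):
        pair = uniform_phase_pair(0.1, seed=3)
        sm1 = cm.axial_strain(cm.complex_cross_correlation(pair, (3, 3)), pair.meta)
        pair.b_def = pair.b_def * np.exp(1j * 1.234)
        sm2 = cm.axial_strain(cm.complex_cross_correlation(pair, (3, 3)), pair.meta)
        assert np.allclose(sm1.eps[:-1], sm2.eps[:-1], atol=1e-10)

    def test_matches_unwrapped_phase_oracle_on_noiseless_phantom(
        self, noiseless_wt_pair
    ):
        """Eq-form strain equals the brute-force unwrap finite difference."""
        pair = noiseless_wt_pair
        corr = cm.complex_cross_correlation(pair, (6, 9))
        sm = cm.axial_strain(corr, pair.meta)
        lam_um = pair.meta["wavelength_nm"] * 1e-3
        scale = lam_um / (
            4 * np.pi * pair.meta["refractive_index"] * pair.meta["asu_um"]
        )
        phi = np.unwrap(np.angle(corr.r_s), axis=0)
        oracle = scale * -np.diff(phi, axis=0)
        inner = pair.truth["tissue_mask"][:-1] & pair.truth["tissue_mask"][1:]
        inner &= sm.mask[:-1]
        assert np.allclose(sm.eps[:-1][inner], oracle[inner], atol=1e-12)

    def test_window_monotonicity_on_white_noise(self):
        # strain-map variance must not increase with smoothing window area
        rng = np.random.default_rng(7)
        shape = (96, 96)
        b_ref = rng.standard_normal(shape) + 1j * rng.standard_normal(shape)
        b_def = rng.standard_normal(shape) + 1j * rng.standard_normal(shape)
        pair = cm.OCEScanPair(b_ref, b_def, dict(OPTICS))
        variances = []
        for window in [(1, 1), (3, 3), (5, 5), (9, 9)]:
            sm = cm.axial_strain(
                cm.complex_cross_correlation(pair, window), pair.meta
            )
            variances.append(np.var(sm.eps[:-1, :]))
        assert np.all(np.diff(variances) <= 0)


class TestSegmentCornea:
    @pytest.mark.parametrize("cct_true", [148.0, 125.0])
    def test_phantom_thickness_within_one_pixel(self, cct_true):
        spec = cm.PhantomSpec(cct_um=cct_true, imposed_strain=-4.9e-3, seed=2)
        pair = cm.gen_oct_pair(spec)
        _, _, cct = cm.segment_cornea(np.abs(pair.b_ref) ** 2, pair.meta)
        assert abs(cct - cct_true) <= spec.asu_um

    def test_uniform_image_rejected(self):
        with pytest.raises(SegmentationError):
            cm.segment_cornea(np.ones((64, 64)), dict(OPTICS))

    def test_boundaries_ordered(self):
        spec = cm.PhantomSpec(cct_um=148.0, imposed_strain=-4.9e-3,
                              snr_db=30.0, seed=4)
        pair = cm.gen_oct_pair(spec)
        ant, post, _ = cm.segment_cornea(np.abs(pair.b_ref) ** 2, pair.meta)
        ok = np.isfinite(ant)
        assert np.all(ant[ok] < post[ok])


class TestMeanCentralStrain:
    def _map(self, eps):
        return cm.StrainMap(eps=eps, mask=np.ones_like(eps, dtype=bool))

    @pytest.mark.parametrize("mode", ["physical_0.5mm", "pixels_21x21"])
    def test_uniform_field_returns_the_constant(self, mode):
        sm = self._map(np.full((60, 80), -3.3e-3))
        val = cm.mean_central_strain(sm, mode, dict(OPTICS), center=(30, 40))
        assert val == pytest.approx(-3.3e-3, rel=1e-12)
        assert sm.roi["mode"] == mode

    def test_half_field_averages_to_half(self):
        eps = np.zeros((60, 80))
        eps[:30, :] = 2.0e-3
        sm = self._map(eps)
        val = cm.mean_central_strain(
            sm, "pixels_21x21", dict(OPTICS), center=(30, 40)
        )
        # 21-row block centred on the boundary: 10 rows at eps0, 11 at 0
        assert val == pytest.approx(2.0e-3 * 10 / 21, rel=1e-12)

    def test_empty_roi_rejected(self):
        sm = cm.StrainMap(eps=np.zeros((10, 10)),
                          mask=np.zeros((10, 10), dtype=bool))
        with pytest.raises(ValueError):
            cm.mean_central_strain(sm, "physical_0.5mm", dict(OPTICS))


class TestEstimateModulus:
    @pytest.mark.parametrize(
        "sigma, eps, expected_kpa",
        [(2027.0, 4.93e-3, 411.2), (2400.0, 4.84e-3, 495.9)],
    )
    def test_direct_ratio(self, sigma, eps, expected_kpa):
        res = cm.estimate_modulus(sigma, eps)
        assert res.e_modulus_pa * 1e-3 == pytest.approx(expected_kpa, rel=1e-3)

    def test_unit_strain_returns_stress(self):
        assert cm.estimate_modulus(1234.0, 1.0).e_modulus_pa == 1234.0

    def test_compression_under_suction_gives_positive_modulus(self):
        res = cm.estimate_modulus(-2027.0, -4.93e-3)
        assert res.e_modulus_pa > 0

    def test_zero_strain_rejected(self):
        with pytest.raises(ValueError):
            cm.estimate_modulus(2027.0, 0.0)


class TestFullPipeline:
    @pytest.mark.parametrize(
        "pair_fixture, imposed_permil",
        [("noiseless_wt_pair", -4.93), ("noiseless_col5a1_pair", -4.84)],
    )
    def test_noiseless_strain_recovery_within_1pct(
        self, pair_fixture, imposed_permil, request
    ):
        pair = request.getfixturevalue(pair_fixture)
        res = cm.PhaseDifferenceOCE(pair).fit()
        assert res.mean_strain_permil == pytest.approx(imposed_permil, rel=0.01)

    def test_modulus_recovery_within_5pct_at_30db_over_seeds(self):
        """Phantom (cct, E, dp) -> recovered E within 5% at SNR 30 dB."""
        cct, e_true = 140.0, 450e3
        g = cm.LoadingGeometry(cct_um=cct, delta_p_mmhg=-3.0)
        eps = cm.laplace_stress(g) / e_true
        for seed in range(20):
            spec = cm.PhantomSpec(cct_um=cct, imposed_strain=eps,
                                  snr_db=30.0, seed=seed)
            res = cm.PhaseDifferenceOCE(cm.gen_oct_pair(spec)).fit()
            assert res.e_modulus_pa == pytest.approx(e_true, rel=0.05)

    def test_summary_reports_key_quantities(self, noiseless_wt_pair):
        res = cm.PhaseDifferenceOCE(noiseless_wt_pair).fit()
        text = res.summary()
        assert "elastic modulus" in text
        assert f"{res.e_modulus_kpa:8.1f}" in text
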