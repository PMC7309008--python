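"""Beer-Lambert SpO2, the linear approximation, PPG simulation, errors."""

import numpy as np
import pytest

import oxishift as ox
from oxishift.chromophores import ChannelExtinction
from oxishift.errors import (
    DegenerateInputError,
    InputError,
    SingularityError,
)
from oxishift.oximetry import (
    count_cycles,
    default_r_grid,
    segment_cycles,
)


def channel_extinction(table, lam):
    o, h = ox.interpolate_extinction(table, lam)
    return ChannelExtinction(o, h)


class TestAbsorbance:
    def test_full_transmission_is_zero(self):
        assert ox.absorbance(1.0, 1.0) == 0.0

    def test_one_neper_attenuation_is_unit_absorbance(self):
        assert ox.absorbance(1.0 / np.e, 1.0) == pytest.approx(1.0)

    def test_single_chromophore_forward_inverse(self):
        # A = eps * c * d = 1 * 2 * 3
        i = 1.0 * np.exp(-1.0 * 2.0 * 3.0)
        assert ox.absorbance(i, 1.0) == pytest.approx(6.0)

    def test_nonpositive_intensity_rejected(self):
        with pytest.raises(InputError):
            ox.absorbance(0.0, 1.0)


class TestSpo2Bll:
    def test_zero_saturation_at_hb_ratio(self, monochromatic_coefficients):
        eps = monochromatic_coefficients
        r0 = eps.red.eps_hb / eps.ir.eps_hb
        assert ox.spo2_bll(eps, r0) == pytest.approx(0.0, abs=1e-9)

    def test_toy_coefficients_give_fifty_percent(self, toy_coefficients):
        assert ox.spo2_bll(toy_coefficients, 1.0) == pytest.approx(50.0)

    def test_strictly_decreasing_in_r_for_physiological_ordering(
            self, monochromatic_coefficients):
        r = np.linspace(0.2, 3.0, 200)
        s = ox.spo2_bll(monochromatic_coefficients, r)
        assert np.all(np.diff(s) < 0)

    def test_singularity_raises_for_scalar(self):
        eps = ox.EffectiveCoefficients(red=ChannelExtinction(1.0, 2.0),
                                       ir=ChannelExtinction(1.0, 2.0))
        # denominator (h1-o1) + (o2-h2) R = 1 - R vanishes at R = 1
        with pytest.raises(SingularityError):
            ox.spo2_bll(eps, 1.0)

    def test_inverse_round_trip(self, monochromatic_coefficients):
        for s in (70.0, 90.0, 97.0, 100.0):
            r = ox.invert_spo2_bll(monochromatic_coefficients, s)
            assert ox.spo2_bll(monochromatic_coefficients, r) == \
                pytest.approx(s, abs=1e-9)


class TestSpo2Linear:
    @pytest.mark.parametrize("r, expected", [(0.0, 110.0), (1.0, 85.0),
                                             (0.4, 100.0)])
    def test_classic_line_substitutions(self, r, expected):
        assert ox.spo2_linear(ox.DEFAULT_CALIBRATION, r) == expected

    def test_clamp_caps_at_100(self):
        assert ox.spo2_linear(ox.DEFAULT_CALIBRATION, 0.0, clamp=True) == 100.0


class TestFitLinearCalibration:
    def test_exactly_linear_relation_recovered(self):
        # coefficients chosen so the BLL formula is itself linear in R:
        # equal denominators make SpO2 = 100 (h1 - h2 R) / const
        eps = ox.EffectiveCoefficients(red=ChannelExtinction(1.0, 3.0),
                                       ir=ChannelExtinction(2.0, 2.0))
        # denominator: (3-1) + (2-2) R = 2 -> SpO2 = 150 - 100 R
        line = ox.fit_linear_calibration(eps, r_range=(0.3, 1.0))
        assert line.a == pytest.approx(-100.0, abs=1e-8)
        assert line.b == pytest.approx(150.0, abs=1e-8)

    def test_narrow_range_approximates_tangent(self,
                                               monochromatic_coefficients):
        eps = monochromatic_coefficients
        r0 = 0.5
        line = ox.fit_linear_calibration(eps, r_range=(r0 - 1e-4, r0 + 1e-4))
        h = 1e-6
        slope = (ox.spo2_bll(eps, r0 + h) - ox.spo2_bll(eps, r0 - h)) / (2 * h)
        assert line.a == pytest.approx(slope, rel=1e-4)

    def test_fixture_calibration_shape(self, monochromatic_coefficients):
        line = ox.fit_linear_calibration(monochromatic_coefficients)
        assert line.a < 0
        assert line.b > 100.0


class TestPpgSimulation:
    def test_no_pulsatile_path_means_zero_perfusion(self, extinction_table):
        eps = channel_extinction(extinction_table, 660.0)
        params = ox.ForwardModelParams(sao2_true=0.97, delta_d_amp=0.0)
        trace = ox.synth_ppg(params, eps)
        assert trace.perfusion_index() == pytest.approx(0.0, abs=1e-12)

    def test_cycle_count_matches_heart_rate(self, extinction_table):
        eps = channel_extinction(extinction_table, 940.0)
        params = ox.ForwardModelParams(sao2_true=0.97, heart_rate_bpm=72.0)
        trace = ox.synth_ppg(params, eps, duration=10.0)
        assert count_cycles(trace) == round(10.0 * 72.0 / 60.0)

    def test_seeded_noise_reproducible(self, extinction_table):
        eps = channel_extinction(extinction_table, 660.0)
        params = ox.ForwardModelParams(sao2_true=0.9, noise_sd=0.01, seed=11)
        a = ox.synth_ppg(params, eps)
        b = ox.synth_ppg(params, eps)
        np.testing.assert_array_equal(a.intensity, b.intensity)

    def test_segmentation_covers_full_cycles(self, extinction_table):
        eps = channel_extinction(extinction_table, 940.0)
        params = ox.ForwardModelParams(sao2_true=0.97)
        trace = ox.synth_ppg(params, eps, duration=5.0)
        cycles = segment_cycles(trace)
        assert len(cycles) == 4  # 5 minima -> 4 full min-to-min windows
        for window in cycles:
            seg = trace.intensity[window]
            assert np.ptp(seg) > 0


class TestRatioOfRatios:
    def test_identical_traces_give_unity(self, extinction_table):
        eps = channel_extinction(extinction_table, 940.0)
        params = ox.ForwardModelParams(sao2_true=0.97)
        trace = ox.synth_ppg(params, eps)
        assert ox.ratio_of_ratios(trace, trace) == pytest.approx(1.0)

    def test_linear_in_red_ac(self, extinction_table):
        eps = channel_extinction(extinction_table, 940.0)
        params = ox.ForwardModelParams(sao2_true=0.97)
        ir = ox.synth_ppg(params, eps)
        dc = ir.intensity.mean()
        red_doubled = ox.PPGTrace(ir.time, dc + 2.0 * (ir.intensity - dc),
                                  ir.sampling_rate)
        # per-cycle DC differs from the global mean by the sampling of
        # the min-to-min window, so linearity holds to ~1e-3
        assert ox.ratio_of_ratios(red_doubled, ir) == pytest.approx(2.0,
                                                                    rel=1e-3)

    def test_matches_small_signal_absorbance_ratio(self, extinction_table):
        eps_red = channel_extinction(extinction_table, 660.0)
        eps_ir = channel_extinction(extinction_table, 940.0)
        sao2 = 0.95
        params = ox.ForwardModelParams(sao2_true=sao2, delta_d_amp=0.005)
        red = ox.synth_ppg(params, eps_red)
        ir = ox.synth_ppg(params, eps_ir)
        r = ox.ratio_of_ratios(red, ir)
        tot = lambda e: e.eps_hbo2 * sao2 + e.eps_hb * (1.0 - sao2)
        analytic = tot(eps_red) / tot(eps_ir)
        assert r == pytest.approx(analytic, rel=0.01)

    def test_zero_ir_perfusion_rejected(self, extinction_table):
        eps = channel_extinction(extinction_table, 940.0)
        params = ox.ForwardModelParams(sao2_true=0.97)
        pulsatile = ox.synth_ppg(params, eps)
        flat = ox.PPGTrace(pulsatile.time,
                           np.full_like(pulsatile.intensity, 0.5),
                           pulsatile.sampling_rate)
        with pytest.raises(DegenerateInputError):
            ox.ratio_of_ratios(pulsatile, flat)

    @pytest.mark.parametrize("sao2", [0.80, 0.90, 0.97, 1.00])
    def test_end_to_end_saturation_recovery(self, extinction_table, sao2):
        eps_red = channel_extinction(extinction_table, 660.0)
        eps_ir = channel_extinction(extinction_table, 940.0)
        params = ox.ForwardModelParams(sao2_true=sao2)
        red = ox.synth_ppg(params, eps_red)
        ir = ox.synth_ppg(params, eps_ir)
        coeffs = ox.EffectiveCoefficients(red=eps_red, ir=eps_ir)
        recovered = ox.spo2_bll(coeffs, ox.ratio_of_ratios(red, ir))
        assert recovered == pytest.approx(100.0 * sao2, abs=0.5)


class TestErrorProfile:
    def test_exactly_linear_bll_gives_zero_error(self):
        eps = ox.EffectiveCoefficients(red=ChannelExtinction(1.0, 3.0),
                                       ir=ChannelExtinction(2.0, 2.0))
        line = ox.fit_linear_calibration(eps, r_range=(0.3, 1.0))
        profile = ox.error_profile(eps, line,
                                   r_grid=np.linspace(0.3, 1.0, 50),
                                   window=(0.0, 200.0))
        np.testing.assert_allclose(profile.delta_spo2, 0.0, atol=1e-9)

    def test_sign_convention_linear_overestimate_is_negative(
            self, monochromatic_coefficients):
        profile = ox.error_profile(monochromatic_coefficients)
        over = profile.spo2_linear > profile.spo2_bll
        assert np.all(profile.delta_spo2[over] < 0)

    def test_hand_computed_profile_values(self, toy_coefficients):
        # BLL: SpO2 = 100 (2 - R) / (1 + R); line: 110 - 25 R
        r = np.array([0.5, 1.0, 2.0])
        profile = ox.error_profile(toy_coefficients, r_grid=r,
                                   window=(0.0, 200.0))
        bll = np.array([100.0, 50.0, 0.0])
        bll[2] = 100.0 * (2 - 2) / (1 + 2)  # 0 -> dropped as singular value
        expected_bll = np.array([100.0, 50.0])
        lin = np.array([97.5, 85.0])
        np.testing.assert_allclose(profile.spo2_bll[:2], expected_bll)
        np.testing.assert_allclose(
            profile.delta_spo2[:2], (expected_bll - lin) / expected_bll * 100)

    def test_monochromatic_consistency_with_narrow_sources(
            self, extinction_table, flat_detector, monochromatic_coefficients):
        red = ox.LightSource("r", ox.GaussianBand(660, 1.0))
        ir = ox.LightSource("i", ox.GaussianBand(940, 1.0))
        pair = ox.SourceDetectorPair(red, ir, flat_detector)
        eff = ox.effective_coefficients(extinction_table, pair)
        r = np.linspace(0.3, 1.0, 30)
        a = ox.error_profile(eff, r_grid=r)
        b = ox.error_profile(monochromatic_coefficients, r_grid=r)
        np.testing.assert_allclose(a.delta_spo2, b.delta_spo2, atol=0.05)

    def test_model_swap_antisymmetry(self, monochromatic_coefficients):
        r = np.linspace(0.4, 0.6, 20)
        profile = ox.error_profile(monochromatic_coefficients, r_grid=r,
                                   window=(0.0, 200.0))
        lin = profile.spo2_linear
        bll = profile.spo2_bll
        swapped = (lin - bll) / lin * 100.0
        np.testing.assert_allclose(swapped, -profile.delta_spo2 * bll / lin)

    def test_wider_source_grows_pairing_deviation(self, extinction_table,
                                                  flat_detector,
                                                  monochromatic_coefficients):
        # the spectral-pairing effect itself -- the gap between the BLL
        # curve with effective coefficients and with the nominal
        # monochromatic ones -- grows monotonically with source FWHM.
        # (The gap to the fixed classic line need not: widening can move
        # the BLL curve toward or away from that line.)
        r = np.linspace(0.3, 0.6, 60)
        nominal = ox.spo2_bll(monochromatic_coefficients, r)
        deviations = []
        for fwhm_red, fwhm_ir in ((1.0, 1.0), (10.0, 25.0), (20.0, 50.0),
                                  (30.0, 75.0)):
            red = ox.LightSource("r", ox.GaussianBand(660, fwhm_red))
            ir = ox.LightSource("i", ox.GaussianBand(940, fwhm_ir))
            pair = ox.SourceDetectorPair(red, ir, flat_detector)
            eff = ox.effective_coefficients(extinction_table, pair)
            deviations.append(np.abs(ox.spo2_bll(eff, r) - nominal).max())
        assert all(b > a for a, b in zip(deviations, deviations[1:]))


class TestMaxAbsErrorInWindow:
    def _profile(self, bll, delta):
        bll = np.asarray(bll, dtype=float)
        delta = np.asarray(delta, dtype=float)
        return ox.ErrorProfile(r_grid=np.arange(bll.size, dtype=float),
                               spo2_bll=bll, spo2_linear=bll,
                               delta_spo2=delta,
                               window=(bll >= 90) & (bll <= 100))

    def test_constant_error(self):
        p = self._profile([92.0, 95.0, 99.0], [3.0, 3.0, 3.0])
        assert ox.max_abs_error_in_window(p) == 3.0

    def test_spike_outside_window_ignored(self):
        p = self._profile([80.0, 95.0], [50.0, 2.0])
        assert ox.max_abs_error_in_window(p) == 2.0

    def test_single_point_window(self):
        p = self._profile([95.0], [-4.5])
        assert ox.max_abs_error_in_window(p) == 4.5

    def test_empty_window_rejected(self):
        p = self._profile([80.0, 85.0], [1.0, 2.0])
        with pytest.raises(DegenerateInputError):
            ox.max_abs_error_in_window(p)

    def test_default_grid_covers_window(self, monochromatic_coefficients):
        profile = ox.error_profile(monochromatic_coefficients,
                                   r_grid=default_r_grid())
        assert profile.window.sum() > 10
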