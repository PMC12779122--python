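import numpy as np
import pytest

import gelqc as g
from tests.conftest import truth_calibration, truth_laneset


def gaussian(x, mu, sd, amp=1.0):
    return amp * np.exp(-0.5 * ((x - mu) / sd) ** 2)


class TestSampleProfile:
    def test_constant_lane(self, calibrated_gel):
        cfg, den, truth, ls, ml, cal = calibrated_gel
        img = g.GelImage(np.full(den.shape, 0.3), stage="denoised")
        p = g.sample_profile(img, ls, 1, cal)
        np.testing.assert_allclose(p.raw_intensity, 0.3, atol=1e-12)
        assert p.baseline == pytest.approx(0.3, abs=1e-12)

    def test_single_band_argmax_at_center(self, calibrated_gel):
        cfg, den, truth, ls, ml, cal = calibrated_gel
        pix = np.full(den.shape, 0.05)
        left, right = ls.lanes[2]
        band = np.array([0.5, 0.8, 0.9, 0.8, 0.5])  # centered at row 120
        pix[118:123, left : right + 1] = band[:, None]
        p = g.sample_profile(g.GelImage(pix, stage="denoised"), ls, 2, cal)
        assert abs(int(np.argmax(p.raw_intensity)) - 120) <= 1

    def test_smear_profile_correlates_with_truth(self, denoised_gel):
        cfg, den, truth = denoised_gel
        ls = truth_laneset(cfg, truth)
        cal = truth_calibration(cfg, truth, den.shape[0])
        for lane in (1, 5):
            p = g.sample_profile(den, ls, lane, cal)
            r = np.corrcoef(p.raw_intensity, truth.true_profile(lane))[0, 1]
            assert r > 0.95

    def test_invalid_lane_index(self, calibrated_gel):
        cfg, den, truth, ls, ml, cal = calibrated_gel
        with pytest.raises(g.ValidationError, match="lane index"):
            g.sample_profile(den, ls, cfg.k, cal)


class TestSmooth:
    def test_blend_contract(self, linear_profile_factory):
        rng = np.random.default_rng(3)
        raw = np.clip(gaussian(np.arange(200.0), 100, 15, 0.5)
                      + rng.normal(0, 0.02, 200) + 0.1, 0, 1)
        p0 = linear_profile_factory(raw, s=0.0)
        p1 = linear_profile_factory(raw, s=1.0)
        ph = linear_profile_factory(raw, s=0.5)
        np.testing.assert_array_equal(p0.final_intensity, p0.raw_intensity)
        np.testing.assert_array_equal(p1.final_intensity, p1.smoothed_intensity)
        # affine in s: the half-way blend is the mean of the endpoints
        np.testing.assert_allclose(
            ph.final_intensity,
            0.5 * (p0.final_intensity + p1.final_intensity), atol=1e-15)

    def test_constant_profile_preserved_for_any_s(self, linear_profile_factory):
        for s in (0.0, 0.3, 1.0):
            p = linear_profile_factory(np.full(150, 0.42), s=s)
            np.testing.assert_allclose(p.final_intensity, 0.42, atol=1e-12)

    def test_invalid_s_and_window(self, linear_profile_factory):
        with pytest.raises(g.ValidationError, match="smoothing factor"):
            linear_profile_factory(np.zeros(50), s=1.5)
        with pytest.raises(g.ValidationError, match="window"):
            linear_profile_factory(np.zeros(50), s=0.5, window=4)


class TestCallPeaks:
    def test_triangular_peak_at_300bp(self, linear_profile_factory):
        raw = np.zeros(181)
        raw[120:161] = np.concatenate([np.linspace(0, 1, 21)[:-1],
                                       np.linspace(1, 0, 21)])
        # bp linear 1000 -> 100 in steps of 5: row 140 maps to 300 bp exactly
        p = linear_profile_factory(raw, bp_top=1000.0, bp_bottom=100.0, s=0.0)
        peaks = g.call_peaks(p)
        assert len(peaks) == 1
        assert peaks[0].peak_bp == pytest.approx(300.0)

    def test_flat_profile_warns_and_returns_empty(self, linear_profile_factory):
        p = linear_profile_factory(np.full(100, 0.2), s=0.0)
        with pytest.warns(UserWarning, match="flat"):
            assert g.call_peaks(p) == []

    def test_two_separated_smears_recovered(self):
        two = (g.SmearSample(300.0, 0.25), g.SmearSample(1500.0, 0.25, amplitude=0.5))
        cfg2 = g.GelSimConfig(seed=21, k=2, samples=(two,))
        img, truth = g.render_gel(cfg2)
        den = g.denoise(img)
        ls = truth_laneset(cfg2, truth)
        cal = truth_calibration(cfg2, truth, den.shape[0])
        p = g.smooth(g.sample_profile(den, ls, 1, cal), 0.5)
        peaks = g.call_peaks(p, min_distance_bp=100.0)
        got = sorted(pk.peak_bp for pk in peaks)
        assert len(peaks) == 2
        assert got[0] == pytest.approx(300.0, rel=0.05)
        assert got[1] == pytest.approx(1500.0, rel=0.05)

    def test_requires_final_intensity(self):
        p = g.IntensityProfile(bp=np.linspace(500, 100, 50),
                               raw_intensity=np.zeros(50), baseline=0.0)
        with pytest.raises(g.ValidationError, match="smooth"):
            g.call_peaks(p)


class TestPeakAreas:
    def test_single_peak_is_exactly_100(self, linear_profile_factory):
        x = np.arange(300.0)
        p = linear_profile_factory(gaussian(x, 150, 12), s=0.0)
        peaks = g.peak_areas(p, g.call_peaks(p))
        assert len(peaks) == 1
        assert peaks[0].relative_area_pct == 100.0

    @pytest.mark.parametrize("ratio,expected", [(1.0, 50.0), (2.0, 200.0 / 3.0),
                                                (9.0, 90.0)])
    def test_two_gaussians_match_analytic_ratio(self, linear_profile_factory,
                                                ratio, expected):
        x = np.arange(400.0)
        raw = gaussian(x, 120, 10, ratio) + gaussian(x, 280, 10, 1.0)
        p = linear_profile_factory(raw, s=0.0)
        peaks = g.peak_areas(p, g.call_peaks(p))
        assert len(peaks) == 2
        big = max(pk.relative_area_pct for pk in peaks)
        assert big == pytest.approx(expected, abs=1.5)

    def test_relative_areas_partition_to_100(self, linear_profile_factory):
        rng = np.random.default_rng(5)
        x = np.arange(500.0)
        raw = sum(gaussian(x, mu, 8, a) for mu, a in
                  zip((60, 150, 260, 400), (0.9, 0.4, 0.7, 0.5)))
        p = linear_profile_factory(np.clip(raw + rng.normal(0, 0.005, 500) + 0.05,
                                           0, 1), s=1.0)
        peaks = g.peak_areas(p, g.call_peaks(p, min_prominence=0.1))
        assert len(peaks) >= 2
        assert sum(pk.relative_area_pct for pk in peaks) == pytest.approx(100.0,
                                                                          abs=1e-9)

    def test_bounds_bracket_each_peak(self, linear_profile_factory):
        x = np.arange(400.0)
        raw = gaussian(x, 120, 10) + gaussian(x, 280, 10, 0.5)
        p = linear_profile_factory(raw, s=0.0)
        for pk in g.peak_areas(p, g.call_peaks(p)):
            assert pk.left_bound_bp >= pk.peak_bp >= pk.right_bound_bp

    def test_zero_area_warns(self, linear_profile_factory):
        p = linear_profile_factory(np.zeros(60), s=0.0)
        peaks = [g.PeakCall(peak_bp=500.0, peak_intensity=0.0, row=30)]
        with pytest.warns(UserWarning, match="zero total"):
            out = g.peak_areas(p, peaks)
        assert out[0].relative_area_pct == 0.0

    def test_area_filter_drops_noise_peaks(self, linear_profile_factory):
        x = np.arange(400.0)
        raw = gaussian(x, 120, 10) + gaussian(x, 300, 4, 0.08)
        p = linear_profile_factory(raw, s=0.0)
        peaks = g.peak_areas(p, g.call_peaks(p, min_prominence=0.03))
        assert len(peaks) == 2
        kept = g.filter_peaks_by_area(peaks, min_area_pct=10.0)
        assert len(kept) == 1 and kept[0].peak_bp == max(pk.peak_bp for pk in peaks)


class TestPctInRange:
    def test_full_span_is_100(self, linear_profile_factory):
        x = np.arange(200.0)
        p = linear_profile_factory(gaussian(x, 100, 10), s=0.0)
        assert g.pct_in_range(p, p.bp[-1], p.bp[0]) == pytest.approx(100.0)

    def test_uniform_block_proportional_to_width(self, linear_profile_factory):
        # uniform intensity over bp [100, 600], zero elsewhere; range [100, 350]
        n = 501
        bp = np.linspace(700.0, 50.0, n)
        raw = np.where((bp >= 100) & (bp <= 600), 0.8, 0.0)
        p = g.IntensityProfile(bp=bp, raw_intensity=raw, baseline=0.0)
        p = g.smooth(p, 0.0)
        assert g.pct_in_range(p, 100.0, 350.0) == pytest.approx(50.0, abs=1.0)

    def test_monotone_in_range_widening(self, linear_profile_factory):
        x = np.arange(300.0)
        p = linear_profile_factory(gaussian(x, 150, 30), s=0.0)
        widths = [(400, 500), (350, 550), (300, 600), (150, 800)]
        vals = [g.pct_in_range(p, lo, hi) for lo, hi in widths]
        assert all(b >= a - 1e-12 for a, b in zip(vals, vals[1:]))

    def test_lognormal_smear_matches_cdf_oracle(self, denoised_gel):
        cfg, den, truth = denoised_gel
        ls = truth_laneset(cfg, truth)
        cal = truth_calibration(cfg, truth, den.shape[0])
        p = g.smooth(g.sample_profile(den, ls, 3, cal), 0.5)
        measured = g.pct_in_range(p, 150.0, 600.0)
        assert measured == pytest.approx(100.0 * truth.true_mass(3, 150.0, 600.0),
                                         abs=2.0)

    def test_range_outside_span_warns_zero(self, linear_profile_factory):
        x = np.arange(200.0)
        p = linear_profile_factory(gaussian(x, 100, 10), s=0.0)
        with pytest.warns(UserWarning, match="outside"):
            assert g.pct_in_range(p, 5000.0, 6000.0) == 0.0

    def test_invalid_range_rejected(self, linear_profile_factory):
        p = linear_profile_factory(np.zeros(50), s=0.0)
        with pytest.raises(g.ValidationError):
            g.pct_in_range(p, 600.0, 150.0)


class TestTrapezoidOracle:
    def test_segment_integration_exact_for_piecewise_linear(self,
                                                            linear_profile_factory):
        # triangle of height h and base 2w has area h*w exactly under the
        # trapezoidal rule on integer rows
        h, w = 0.8, 40
        raw = np.zeros(201)
        raw[100 - w : 100 + w + 1] = h * (1 - np.abs(np.arange(-w, w + 1)) / w)
        p = linear_profile_factory(raw, s=0.0, baseline=0.0)
        peaks = g.peak_areas(p, g.call_peaks(p))
        assert peaks[0].relative_area_pct == pytest.approx(100.0)
        y = np.clip(p.final_intensity - p.baseline, 0, None)
        assert np.trapezoid(y) == pytest.approx(h * w, rel=1e-12)


class TestPercentError:
    @pytest.mark.parametrize("measured,reference,expected",
                             [(110.0, 100.0, 10.0), (100.0, 100.0, 0.0),
                              (90.0, 100.0, 10.0)])
    def test_direct_substitution(self, measured, reference, expected):
        assert g.percent_error(measured, reference) == pytest.approx(expected)

    def test_non_positive_reference_rejected(self):
        with pytest.raises(g.ValidationError):
            g.percent_error(100.0, 0.0)
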