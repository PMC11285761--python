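import dataclasses

import numpy as np
import pytest
from scipy.integrate import quad

from colhier import presets, synthetic, xrd
from colhier.geometry import MASKED
from colhier.synthetic import ScanPattern, ScatterScene


def make_profile(q, intensity):
    return xrd.RadialProfile(np.asarray(q, float), np.asarray(intensity, float))


class TestAzimuthalIntegrate:
    def test_isotropic_image_gives_constant_profile(self, geometry):
        img = np.full(geometry.detector_shape, 5.0)
        prof = xrd.azimuthal_integrate(img, geometry,
                                       azimuth_window=(10.0, 200.0))
        good = np.isfinite(prof.intensity)
        assert good.any()
        assert np.allclose(prof.intensity[good], 5.0, rtol=1e-2)

    def test_porod_image_recovered_within_binning_error(self, geometry):
        q = geometry.q_map()
        with np.errstate(divide="ignore"):
            img = 2.0 * np.where(q > 0, q, np.inf) ** -4.0
        img[geometry.beamstop_mask()] = MASKED
        prof = xrd.azimuthal_integrate(img, geometry)
        good = np.isfinite(prof.intensity)
        expected = 2.0 * prof.q[good] ** -4.0
        assert np.allclose(prof.intensity[good], expected, rtol=1e-2)

    def test_full_circle_equals_mean_of_half_circles(self, nm_pattern, geometry):
        full = xrd.azimuthal_integrate(nm_pattern, geometry)
        upper = xrd.azimuthal_integrate(nm_pattern, geometry,
                                        azimuth_window=(0.0, 180.0))
        lower = xrd.azimuthal_integrate(nm_pattern, geometry,
                                        azimuth_window=(180.0, 360.0))
        combined = 0.5 * (upper.intensity + lower.intensity)
        good = np.isfinite(full.intensity)
        assert np.allclose(full.intensity[good], combined[good], rtol=1e-9)

    def test_window_inside_beamstop_rejected(self, geometry):
        img = np.full(geometry.detector_shape, MASKED)
        with pytest.raises(ValueError, match="no usable pixels"):
            xrd.azimuthal_integrate(img, geometry)


class TestPorodSubtract:
    q = np.arange(0.21, 0.4, 0.002) + 0.001

    def test_pure_porod_slope_and_flat_residual(self):
        prof = make_profile(self.q, 7.0 * self.q**-4.0)
        sub = xrd.porod_subtract(prof, (0.24, 0.32))
        assert sub.slope == pytest.approx(-4.0, abs=1e-3)
        assert np.allclose(sub.ratio, 1.0, atol=1e-6)
        # net peak signal vanishes relative to the background level
        assert np.all(np.abs(sub.signal) <= 1e-6 * sub.background)

    def test_gaussian_peak_position_recovered(self):
        peak = 50.0 * np.exp(-0.5 * ((self.q - 0.2814) / 0.01) ** 2)
        prof = make_profile(self.q, 7.0 * self.q**-4.0 + peak)
        sub = xrd.porod_subtract(prof, (0.24, 0.32))
        imax = np.argmax(sub.signal)
        assert sub.q[imax] == pytest.approx(0.2814, abs=0.002)  # one bin

    def test_log_and_linear_modes_agree_in_intensity_units(self):
        peak = 50.0 * np.exp(-0.5 * ((self.q - 0.28) / 0.01) ** 2)
        prof = make_profile(self.q, 7.0 * self.q**-4.0 + peak)
        a = xrd.porod_subtract(prof, (0.24, 0.32), mode="log")
        b = xrd.porod_subtract(prof, (0.24, 0.32), mode="linear")
        assert np.allclose(a.signal, b.signal, rtol=1e-12)

    def test_nonpositive_flank_rejected_by_name(self):
        bad = 7.0 * self.q**-4.0
        bad[self.q < 0.24] = 0.0
        with pytest.raises(ValueError, match="lower flank"):
            xrd.porod_subtract(make_profile(self.q, bad), (0.24, 0.32))


class TestDPeriodCentroid:
    def test_uniform_signal_centroid_is_window_center(self):
        q = np.arange(0.24, 0.3201, 0.004)
        sub = xrd.SubtractedProfile(
            q, np.ones_like(q), np.ones_like(q), np.ones_like(q),
            -4.0, 0.0, np.ones_like(q, dtype=bool))
        fit, d = xrd.d_period_from_profile(sub)
        assert fit.center_q == pytest.approx(0.28, abs=1e-12)

    def test_symmetric_peak_gives_67nm(self):
        q = np.arange(0.24, 0.3201, 0.0005)
        s = np.exp(-0.5 * ((q - 0.2813) / 0.008) ** 2)
        sub = xrd.SubtractedProfile(q, s, s, s, -4.0, 0.0,
                                    np.ones_like(q, dtype=bool))
        _, d = xrd.d_period_from_profile(sub)
        assert d == pytest.approx(67.0, abs=0.1)

    def test_skewed_triangle_matches_quadrature_oracle(self):
        # fine grid so midpoint binning error is below the comparison level
        q = np.arange(0.24, 0.32, 1e-5) + 5e-6

        def tri(x):
            up = np.clip((x - 0.26) / 0.015, 0, None)
            down = np.clip((0.30 - x) / 0.025, 0, None)
            return np.minimum(up, down).clip(0)

        sub = xrd.SubtractedProfile(q, tri(q), tri(q), tri(q), -4.0, 0.0,
                                    np.ones_like(q, dtype=bool))
        fit, _ = xrd.d_period_from_profile(sub)
        num = quad(lambda x: x * tri(np.array([x]))[0], 0.26, 0.30, limit=200)[0]
        den = quad(lambda x: tri(np.array([x]))[0], 0.26, 0.30, limit=200)[0]
        assert fit.center_q == pytest.approx(num / den, rel=1e-6)

    def test_nonpositive_total_reports_missing(self):
        q = np.arange(0.24, 0.3201, 0.004)
        s = -np.ones_like(q)
        sub = xrd.SubtractedProfile(q, s, s, s, -4.0, 0.0,
                                    np.ones_like(q, dtype=bool))
        fit, d = xrd.d_period_from_profile(sub)
        assert fit is None and np.isnan(d)


class TestIntermolecularFit:
    def test_noiseless_gaussian_at_2p7(self):
        q = np.arange(1.9, 3.5, 0.004)
        s = 40.0 * np.exp(-0.5 * ((q - 2.7) / 0.25) ** 2)
        sub = xrd.SubtractedProfile(q, s, s, s, -4.0, 0.0,
                                    np.ones_like(q, dtype=bool))
        fit = xrd.fit_intermolecular_peak(sub)
        assert fit.center_q == pytest.approx(2.7, abs=1e-6)
        assert 2 * np.pi / fit.center_q == pytest.approx(2.327, abs=1e-3)

    def test_symmetric_peak_center_matches_argmax_bin(self):
        q = np.arange(1.9, 3.5, 0.02)
        s = 40.0 * np.exp(-0.5 * ((q - 2.68) / 0.3) ** 2)
        sub = xrd.SubtractedProfile(q, s, s, s, -4.0, 0.0,
                                    np.ones_like(q, dtype=bool))
        fit = xrd.fit_intermolecular_peak(sub)
        assert abs(fit.center_q - q[np.argmax(s)]) <= 0.01  # half a bin

    def test_degenerate_signal_returns_missing(self):
        q = np.arange(1.9, 3.5, 0.1)
        s = -np.ones_like(q)
        sub = xrd.SubtractedProfile(q, s, s, s, -4.0, 0.0,
                                    np.ones_like(q, dtype=bool))
        assert xrd.fit_intermolecular_peak(sub) is None


class TestAzimuthalPeakProfile:
    def test_isotropic_ring_gives_flat_profile(self, geometry):
        q = geometry.q_map()
        with np.errstate(divide="ignore"):
            img = 2.0 * np.where(q > 0, q, np.inf) ** -4.0
        img += 30.0 * np.exp(-0.5 * ((q - 0.28) / 0.01) ** 2)
        img[geometry.beamstop_mask()] = MASKED
        prof = xrd.azimuthal_peak_profile(img, geometry, (0.24, 0.32))
        s = prof.signal[np.isfinite(prof.signal)]
        assert s.std() / s.mean() < 0.02

    def test_pure_porod_net_signal_zero_everywhere(self, geometry):
        q = geometry.q_map()
        with np.errstate(divide="ignore"):
            img = 2.0 * np.where(q > 0, q, np.inf) ** -4.0
        img[geometry.beamstop_mask()] = MASKED
        prof = xrd.azimuthal_peak_profile(img, geometry, (0.24, 0.32))
        # reference scale: background summed over the window per segment
        ref = 2.0 * (xrd.ReductionConfig().q_centers() ** -4.0)
        ref = ref[(xrd.ReductionConfig().q_centers() >= 0.24)
                  & (xrd.ReductionConfig().q_centers() <= 0.32)].sum()
        good = np.isfinite(prof.signal)
        assert np.all(np.abs(prof.signal[good]) <= 1e-6 * ref)

    def test_partition_additivity(self, geometry):
        q = geometry.q_map()
        with np.errstate(divide="ignore"):
            img = 2.0 * np.where(q > 0, q, np.inf) ** -4.0
        img += 30.0 * np.exp(-0.5 * ((q - 0.28) / 0.01) ** 2)
        img[geometry.beamstop_mask()] = MASKED
        cfg = xrd.ReductionConfig()
        tr = xrd.get_transformer(geometry, cfg)
        polar = tr(img)
        prof = xrd.azimuthal_peak_profile_from_polar(
            polar, tr.q_centers, tr.az_centers, (0.24, 0.32))
        with np.errstate(invalid="ignore"):
            full = xrd.RadialProfile(tr.q_centers, np.nanmean(polar, axis=0))
        sub = xrd.porod_subtract(full, (0.24, 0.32))
        full_total = np.nansum(sub.signal) * 720
        assert np.nansum(prof.signal) == pytest.approx(full_total, rel=1e-6)

    def test_generator_arc_recovers_sigma_10(self, geometry):
        scene = ScatterScene(
            fibril_sigma_deg=10.0, preferred_orientation_deg=37.0,
            intermolecular_amplitude=0.0, mineral_fraction=0.0,
            poisson_noise=False,
        )
        img = synthetic.noiseless_scatter_pattern(scene, geometry)
        prof = xrd.azimuthal_peak_profile(img, geometry, (0.24, 0.32))
        res = xrd.profile_fwhm(prof)
        assert res.fwhm_deg == pytest.approx(23.55, abs=0.5)
        assert res.orientation_deg == pytest.approx(37.0, abs=0.5)


class TestProfileFWHM:
    az = (np.arange(720) + 0.5) * 0.5

    def wrapped_gaussian(self, center, sigma):
        d = ((self.az - center + 90.0) % 180.0) - 90.0
        return np.exp(-0.5 * (d / sigma) ** 2)

    def test_wrapped_gaussian_sigma10(self):
        res = xrd.profile_fwhm(
            xrd.AzimuthalProfile(self.az, self.wrapped_gaussian(40.0, 10.0)))
        assert res.fwhm_deg == pytest.approx(2.3548 * 10.0, abs=0.5)
        assert res.orientation_deg == pytest.approx(40.0, abs=0.3)

    def test_delta_lobe_narrow_limit(self):
        s = np.zeros(720)
        s[100] = s[460] = 1.0
        res = xrd.profile_fwhm(xrd.AzimuthalProfile(self.az, s))
        assert res.fwhm_deg <= 1.0

    def test_flat_profile_flagged(self):
        res = xrd.profile_fwhm(xrd.AzimuthalProfile(self.az, np.ones(720)))
        assert res.flagged and res.fwhm_deg == 180.0

    def test_smoothing_correction_preserves_width(self):
        prof = xrd.AzimuthalProfile(self.az, self.wrapped_gaussian(90.0, 8.0))
        raw = xrd.profile_fwhm(prof)
        smoothed = xrd.profile_fwhm(prof, smooth_sigma_deg=2.0)
        assert smoothed.fwhm_deg == pytest.approx(raw.fwhm_deg, abs=0.3)

    def test_missing_segments_interpolated(self):
        s = self.wrapped_gaussian(120.0, 12.0)
        s[3:40] = np.nan
        res = xrd.profile_fwhm(xrd.AzimuthalProfile(self.az, s))
        assert res.fwhm_deg == pytest.approx(2.3548 * 12.0, abs=1.0)


class TestTwist:
    def test_equal_dispersions_give_zero(self):
        t, clamped = xrd.raw_twist(20.0, 20.0)
        assert t == 0.0 and not clamped

    def test_narrower_molecular_clamped(self):
        t, clamped = xrd.raw_twist(20.0, 15.0)
        assert t == 0.0 and clamped

    def test_quadrature_forward_inverse(self):
        sf, st_ = 6.5, 8.0
        fw_f = 2.3548 * sf
        fw_m = 2.3548 * np.hypot(sf, st_)
        t, _ = xrd.raw_twist(fw_f, fw_m)
        assert t == pytest.approx(st_, rel=1e-3)

    def test_normalization_reference(self):
        t, _ = xrd.estimate_relative_twist(15.0, 25.0, nm_reference=2.0)
        raw, _ = xrd.raw_twist(15.0, 25.0)
        assert t == pytest.approx(raw / 2.0)
        with pytest.raises(ValueError):
            xrd.estimate_relative_twist(15.0, 25.0, nm_reference=0.0)


class TestReducePattern:
    def test_region_round_trip_within_tolerances(self, region_patterns, geometry):
        recovered = {}
        for region, (scene, img) in region_patterns.items():
            m = xrd.reduce_pattern(img, geometry)
            assert m is not None
            p = presets.XRD_REGION_PARAMS[region]
            assert m.d_period_nm == pytest.approx(p["d_period_nm"], abs=0.2)
            assert m.intermolecular_spacing_nm == pytest.approx(
                p["intermolecular_spacing_nm"], abs=0.02)
            assert m.fibril_dispersion_fwhm_deg == pytest.approx(
                p["fibril_fwhm_deg"], abs=1.0)
            assert m.molecular_dispersion_fwhm_deg == pytest.approx(
                p["molecular_fwhm_deg"], abs=1.0)
            assert m.raw_twist_deg == pytest.approx(
                scene.twist_sigma_deg, rel=0.05)
            recovered[region] = m
        # orderings reported for the tissue zones
        assert (recovered["NM"].intermolecular_spacing_nm
                > recovered["EM"].intermolecular_spacing_nm
                > recovered["LM"].intermolecular_spacing_nm)
        assert (recovered["NM"].fibril_dispersion_fwhm_deg
                > max(recovered["EM"].fibril_dispersion_fwhm_deg,
                      recovered["LM"].fibril_dispersion_fwhm_deg))
        assert (recovered["NM"].raw_twist_deg
                > max(recovered["EM"].raw_twist_deg,
                      recovered["LM"].raw_twist_deg))

    def test_all_masked_pattern_skipped(self, geometry):
        img = np.full(geometry.detector_shape, MASKED)
        assert xrd.reduce_pattern(img, geometry) is None

    def test_monotone_in_twist_sigma(self, geometry):
        fwhms, twists = [], []
        for tw in (4.0, 8.0, 12.0):
            scene = ScatterScene(fibril_sigma_deg=8.0, twist_sigma_deg=tw,
                                 poisson_noise=False)
            img = synthetic.noiseless_scatter_pattern(scene, geometry)
            m = xrd.reduce_pattern(img, geometry)
            fwhms.append(m.molecular_dispersion_fwhm_deg)
            twists.append(m.raw_twist_deg)
        assert fwhms[0] < fwhms[1] < fwhms[2]
        assert twists[0] < twists[1] < twists[2]

    def test_orientation_equivariance(self, geometry):
        delta = 40.0
        base = presets.scatter_scene_for_region("EM", poisson_noise=False)
        rotated = dataclasses.replace(
            base, preferred_orientation_deg=base.preferred_orientation_deg + delta)
        m0 = xrd.reduce_pattern(
            synthetic.noiseless_scatter_pattern(base, geometry), geometry)
        m1 = xrd.reduce_pattern(
            synthetic.noiseless_scatter_pattern(rotated, geometry), geometry)
        shift = (m1.preferred_orientation_deg - m0.preferred_orientation_deg) % 180.0
        assert shift == pytest.approx(delta, abs=1.0)
        assert m1.d_period_nm == pytest.approx(m0.d_period_nm, abs=0.1)
        assert m1.intermolecular_spacing_nm == pytest.approx(
            m0.intermolecular_spacing_nm, abs=0.01)
        assert m1.fibril_dispersion_fwhm_deg == pytest.approx(
            m0.fibril_dispersion_fwhm_deg, abs=1.0)
        assert m1.molecular_dispersion_fwhm_deg == pytest.approx(
            m0.molecular_dispersion_fwhm_deg, abs=1.0)


class TestScanBinning:
    def fake_patterns(self, n_rows, n_cols):
        pats = []
        for r in range(n_rows):
            for c in range(n_cols):
                img = np.full((4, 4), float(10 * r + c))
                img[0, 0] = MASKED
                pats.append(ScanPattern(r, c, 20.0 * c, 100.0 * r, "NM", img))
        return pats

    def test_stated_scan_bookkeeping(self):
        # 522,500 patterns in 209 rows of 2,500 at 20 um pitch, factor 5
        total, pitch = xrd.plan_horizontal_binning(209, 2500, 5)
        assert 209 * 2500 == 522500
        assert total == 104500
        assert pitch == 100.0

    def test_factor_one_is_identity(self):
        pats = self.fake_patterns(2, 4)
        assert xrd.bin_scan_horizontal(pats, 1) == pats

    def test_counts_conserved_and_remainder_dropped(self):
        pats = self.fake_patterns(2, 5)
        out = xrd.bin_scan_horizontal(pats, 2)
        assert len(out) == 4  # floor(5/2) per row
        chunk = [p for p in pats if p.row == 0 and p.col < 2]
        expected = sum(p.image[p.image != MASKED].sum() for p in chunk)
        got = out[0].image[out[0].image != MASKED].sum()
        assert got == pytest.approx(expected)
        assert out[0].image[0, 0] == MASKED
        assert out[0].x_um == pytest.approx(10.0)

    def test_invalid_factor_rejected(self):
        with pytest.raises(ValueError):
            xrd.bin_scan_horizontal([], 0)
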