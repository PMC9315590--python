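"""TDC quality control and phase landmark detection, checked against
exhaustive scans over the sampled frames."""

import numpy as np
import pytest

from collateral4d import (
    GammaVariateParams,
    TimeDensityCurve,
    extract_tdc,
    find_av_intersection,
    find_late_venous,
    find_peak,
    gamma_variate,
    landmarks,
    make_protocol,
    qc_curve,
)


def _curve(times, values, site="artery"):
    return TimeDensityCurve(np.asarray(times, float), np.asarray(values, float), site)


def _gamma_curve(params, site, protocol=None):
    t = (protocol or make_protocol()).contrast_times
    return _curve(t, gamma_variate(t, params), site)


ART = GammaVariateParams(t0=9.5, alpha=3.0, beta=3.3, amplitude=220.0)
VEN = GammaVariateParams(t0=28.0, alpha=3.0, beta=4.5, amplitude=130.0)


# ---------------------------------------------------------------------------
# brute-force oracles over the sampled frames
# ---------------------------------------------------------------------------

def brute_peak(curve):
    best = 0
    for i in range(len(curve.values)):
        if curve.values[i] > curve.values[best]:
            best = i
    return best


def brute_intersection(arterial, venous):
    """Scan every inter-sample interval after the arterial peak for the
    first >=0 -> <0 sign change of the interpolated difference."""
    i_a, i_v = brute_peak(arterial), brute_peak(venous)
    d = arterial.values - venous.values
    for i in range(i_a, i_v):
        if d[i] >= 0 > d[i + 1]:
            t = arterial.times[i] + (arterial.times[i + 1] - arterial.times[i]) * d[i] / (
                d[i] - d[i + 1]
            )
            cand = sorted(
                range(len(arterial.times)), key=lambda j: (abs(arterial.times[j] - t), j)
            )[0]
            return t, max(cand, i_a + 1)
    return None


def brute_late_venous(venous, plateau_frac=0.5, slope_tol=5.0):
    i_v = brute_peak(venous)
    peak = venous.values[i_v]
    for i in range(i_v + 1, len(venous.values) - 1):
        slope = (venous.values[i + 1] - venous.values[i]) / (
            venous.times[i + 1] - venous.times[i]
        )
        if venous.values[i] <= plateau_frac * peak and abs(slope) <= slope_tol:
            return i
    return len(venous.values) - 1


# ---------------------------------------------------------------------------


class TestExtractTDC:
    def test_parenchyma_roi_is_flat(self, noiseless_study):
        # parenchyma voxels picked by their NCCT value and one mid-scan
        # frame; the assertion then covers all remaining 17 frames
        s = noiseless_study
        mid = s.contrast_frames[8][1].values
        cand = np.argwhere((s.ncct.values == 30.0) & (mid == s.ncct.values))
        roi = cand[:5]
        curve = extract_tdc(s, roi, "artery")
        assert np.allclose(curve.values, 0.0, atol=1e-3)

    def test_artery_roi_recovers_generating_curve(self, noiseless_study):
        gt = noiseless_study.ground_truth
        curve = extract_tdc(noiseless_study, gt.arterial_roi, "artery")
        expected = gamma_variate(curve.times, gt.arterial_tdc_params)
        assert np.allclose(curve.values, expected, atol=1e-3)

    def test_single_voxel_roi_equals_voxel_series(self, noiseless_study):
        vox = noiseless_study.ground_truth.arterial_roi[:1]
        curve = extract_tdc(noiseless_study, vox, "artery")
        z, y, x = vox[0]
        base = noiseless_study.ncct.values[z, y, x]
        series = [v.values[z, y, x] - base for _, v in noiseless_study.contrast_frames]
        assert np.allclose(curve.values, series)

    def test_empty_and_out_of_bounds_roi_rejected(self, noiseless_study):
        with pytest.raises(ValueError):
            extract_tdc(noiseless_study, np.empty((0, 3), int), "artery")
        with pytest.raises(ValueError):
            extract_tdc(noiseless_study, np.array([[99, 0, 0]]), "artery")


class TestQC:
    def test_clean_gamma_is_bell_shaped(self):
        report = qc_curve(_gamma_curve(ART, "artery"))
        assert report.n_peaks == 1 and report.is_bell_shaped

    def test_double_bolus_fails_qc(self):
        t = make_protocol().contrast_times
        second = GammaVariateParams(t0=30.0, alpha=3.0, beta=3.0, amplitude=150.0)
        v = gamma_variate(t, ART) + gamma_variate(t, second)
        # brute-force count of prominent interior maxima
        n_brute = sum(
            1 for i in range(1, len(v) - 1) if v[i] > v[i - 1] and v[i] >= v[i + 1]
        )
        report = qc_curve(_curve(t, v))
        assert n_brute == 2
        assert report.n_peaks == 2 and not report.is_bell_shaped

    def test_monotone_curve_not_bell_shaped(self):
        report = qc_curve(_curve([11, 13, 15, 17], [0, 1, 2, 3]))
        assert not report.is_bell_shaped

    def test_all_zero_curve(self):
        report = qc_curve(_curve([11, 13, 15], [0, 0, 0]))
        assert report.n_peaks == 0 and not report.is_bell_shaped


class TestFindPeak:
    def test_argmax_example(self):
        assert find_peak(_curve([11, 13, 15, 17, 19], [0, 1, 5, 2, 0])) == (15.0, 2)

    def test_plateau_tie_breaks_earlier(self):
        t, i = find_peak(_curve([11, 13, 15, 17, 19], [0, 4, 5, 5, 0]))
        assert (t, i) == (15.0, 2)

    def test_rejects_non_bell_curve(self):
        with pytest.raises(ValueError):
            find_peak(_curve([11, 13, 15], [0, 1, 2]))

    def test_matches_brute_force_on_random_bell_curves(self, rng):
        for _ in range(20):
            p = GammaVariateParams(
                t0=rng.uniform(6, 11), alpha=3.0, beta=rng.uniform(2.5, 4),
                amplitude=rng.uniform(100, 300),
            )
            c = _gamma_curve(p, "artery")
            _, idx = find_peak(c)
            assert idx == brute_peak(c)


class TestIntersection:
    def test_interpolated_crossing_bumped_past_arterial_peak(self):
        times = [17, 19, 21, 23, 25]
        arterial = _curve(times, [2, 6, 10, 4, 1], "artery")
        venous = _curve(times, [0, 3, 6, 8, 7], "vein")
        t_star, frame, flagged = find_av_intersection(arterial, venous)
        # difference 4 -> -4 over [21, 23] crosses zero at 22; the nearest
        # frame (21) is the arterial peak itself, so the next frame is used
        assert t_star == pytest.approx(22.0)
        assert frame == 3 and not flagged

    def test_crossing_at_sample_time(self):
        times = [11, 13, 15, 17, 19]
        arterial = _curve(times, [1, 8, 4, 2, 1], "artery")
        venous = _curve(times, [0, 2, 4, 6, 5], "vein")
        t_star, frame, flagged = find_av_intersection(arterial, venous)
        assert t_star == pytest.approx(15.0) and frame == 2 and not flagged

    def test_no_crossing_falls_back_flagged(self):
        times = [11, 13, 15, 17, 19]
        arterial = _curve(times, [1, 9, 5, 3, 2], "artery")
        venous = _curve(times, [0, 1, 2, 2.5, 2], "vein")
        t_star, frame, flagged = find_av_intersection(arterial, venous)
        assert flagged
        window = [2, 3]  # frames strictly after the arterial peak, up to the venous peak
        diffs = [abs(arterial.values[i] - venous.values[i]) for i in window]
        assert frame == window[int(np.argmin(diffs))]

    def test_identical_curves_rejected(self):
        c = _curve([11, 13, 15, 17], [1, 5, 3, 1], "artery")
        d = _curve([11, 13, 15, 17], [1, 5, 3, 1], "vein")
        with pytest.raises(ValueError):
            find_av_intersection(c, d)

    def test_matches_brute_force_on_synthetic_pairs(self, rng):
        protocol = make_protocol()
        for _ in range(20):
            art = GammaVariateParams(
                t0=rng.uniform(8, 10.5), alpha=3.0, beta=rng.uniform(3.0, 3.8),
                amplitude=rng.uniform(180, 260),
            )
            ven = GammaVariateParams(
                t0=rng.uniform(27.5, 29), alpha=3.0, beta=rng.uniform(4.2, 4.8),
                amplitude=rng.uniform(110, 150),
            )
            a = _gamma_curve(art, "artery", protocol)
            v = _gamma_curve(ven, "vein", protocol)
            t_star, frame, flagged = find_av_intersection(a, v)
            oracle = brute_intersection(a, v)
            assert oracle is not None and not flagged
            assert t_star == pytest.approx(oracle[0])
            assert frame == oracle[1]


class TestLateVenous:
    def test_plateau_example(self):
        times = [40, 45, 50, 55, 60, 65]
        venous = _curve(times, [0, 8, 10, 6, 4.8, 4.6], "vein")
        t, i, flagged = find_late_venous(venous, plateau_frac=0.5, slope_tol=0.2)
        assert (t, i) == (60.0, 4) and not flagged

    def test_never_descending_returns_last_flagged(self):
        venous = _curve([40, 45, 50, 55, 60], [0, 8, 10, 9, 8.5], "vein")
        t, i, flagged = find_late_venous(venous)
        assert i == 4 and flagged

    def test_peak_at_last_frame_rejected(self):
        venous = _curve([40, 45, 50, 55], [0, 2, 5, 10], "vein")
        with pytest.raises(ValueError):
            find_late_venous(venous)

    def test_matches_brute_force_scan(self, rng):
        protocol = make_protocol()
        for _ in range(20):
            ven = GammaVariateParams(
                t0=rng.uniform(27.5, 29), alpha=3.0, beta=rng.uniform(4.2, 4.8),
                amplitude=rng.uniform(110, 150),
            )
            v = _gamma_curve(ven, "vein", protocol)
            _, i, _ = find_late_venous(v)
            assert i == brute_late_venous(v)


class TestLandmarks:
    def test_phase_windows_on_synthetic_curves(self):
        a = _gamma_curve(ART, "artery")
        v = _gamma_curve(VEN, "vein")
        lm = landmarks(a, v)
        assert 11 <= lm.t_arterial_peak <= 36
        assert lm.t_venous_peak >= 40
        assert lm.t_arterial_peak < lm.t_av_intersection <= lm.t_venous_peak
        assert lm.t_late_venous > lm.t_venous_peak
        assert lm.frame_arterial != lm.frame_venous

    def test_reversed_peaks_rejected(self):
        a = _gamma_curve(ART, "artery")
        v = _gamma_curve(VEN, "vein")
        with pytest.raises(ValueError):
            landmarks(v, a)  # venous peak handed over as "arterial"

    def test_time_translation_equivariance(self):
        """Shifting both generating curves by +2 s on the same grid
        shifts every landmark time by one grid notion of +2 s."""
        protocol = make_protocol()
        t = protocol.contrast_times
        art2 = GammaVariateParams(ART.t0 + 2, ART.alpha, ART.beta, ART.amplitude)
        ven2 = GammaVariateParams(VEN.t0 + 2, VEN.alpha, VEN.beta, VEN.amplitude)
        # evaluate the shifted curves on a shifted grid: identical samples
        a1 = _curve(t, gamma_variate(t, ART), "artery")
        v1 = _curve(t, gamma_variate(t, VEN), "vein")
        a2 = _curve(t + 2, gamma_variate(t + 2, art2), "artery")
        v2 = _curve(t + 2, gamma_variate(t + 2, ven2), "vein")
        lm1, lm2 = landmarks(a1, v1), landmarks(a2, v2)
        assert np.allclose(np.asarray(lm2.times) - np.asarray(lm1.times), 2.0)
        assert lm1.frame_indices == lm2.frame_indices
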