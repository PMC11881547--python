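"""Peak-model fitting, detection thresholds, and feature tracking."""

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad

from lidpipe import nbg
from lidpipe.spectral import Spectrogram

F_NBG = np.arange(65.0, 110.01, 0.5)


def model_spectrogram(params_per_window, freqs=F_NBG, noise=0.5, seed=0):
    """Spectrogram whose windows are drawn from the peak model + noise."""
    rng = np.random.default_rng(seed)
    rows = [nbg.peak_model(freqs, *p) + rng.normal(0, noise, len(freqs))
            for p in params_per_window]
    return Spectrogram(times=np.arange(len(rows)) * 4.0, freqs=freqs,
                       power_db=np.asarray(rows))


class TestPeakFit:
    def test_parameter_recovery(self, rng):
        errs_b, rel_a, rel_c = [], [], []
        for _ in range(30):
            y = nbg.peak_model(F_NBG, 10, 80, 5, 0, 0) + rng.normal(0, 0.5, len(F_NBG))
            fit = nbg.fit_peak_model(F_NBG, y, (65, 110))
            errs_b.append(abs(fit.B - 80))
            rel_a.append(abs(fit.A - 10) / 10)
            rel_c.append(abs(fit.C - 5) / 5)
        assert np.median(errs_b) < 1.0
        assert np.median(rel_a) < 0.10
        assert np.median(rel_c) < 0.20

    def test_flat_spectrum_not_detected(self):
        fit = nbg.fit_peak_model(F_NBG, np.zeros_like(F_NBG), (65, 110))
        nbg.classify_detection(fit, band_classes={"nbg": (65, 110)})
        assert not fit.detected
        assert fit.A < 2.0

    def test_band_not_covered_flagged(self):
        fit = nbg.fit_peak_model(np.arange(0, 30.0), np.zeros(30), (65, 110))
        assert not fit.detected
        assert fit.diagnostic is not None

    def test_invalid_band_rejected(self):
        with pytest.raises(ValueError):
            nbg.fit_peak_model(F_NBG, np.zeros_like(F_NBG), (110, 65))


class TestDetectionThresholds:
    """Boundary truth table for the printed detection conditions."""

    CASES = [
        # (A, B, C, D, E, r2) -> (detected with gamma+hfo, class)
        ((10, 80, 5, 0, 0, 0.9), False, None),      # B between gamma and HFO
        ((5, 140, 8, 0.2, 1, 0.5), True, "hfo"),
        ((10, 50, 5, 0, 0, 0.9), True, "gamma"),
        ((150, 50, 5, 0, 0, 0.9), False, None),     # A >= 100
        ((10, 50, 5, 0, 0, 0.15), False, None),     # r2 <= 0.2
        ((2, 50, 5, 0, 0, 0.9), False, None),       # A at lower bound (strict)
        ((10, 70, 5, 0, 0, 0.9), False, None),      # B at gamma edge (strict)
        ((10, 50, 20, 0, 0, 0.9), False, None),     # C at upper bound
        ((10, 50, 0.5, 0, 0, 0.9), False, None),    # C below lower bound
        ((10, 50, 5, 1.0, 0, 0.9), False, None),    # D at bound
        ((10, 50, 5, 0, -10.0, 0.9), False, None),  # E at bound
        ((10, 50, 5, 0, 0, 0.2), False, None),      # r2 at bound (strict)
    ]

    @pytest.mark.parametrize("params,expect,cls", CASES)
    def test_truth_table(self, params, expect, cls):
        A, B, C, D, E, r2 = params
        fit = nbg.PeakFit(A=A, B=B, C=C, D=D, E=E, r2=r2)
        det, got = nbg.classify_detection(
            fit, band_classes={"gamma": (30, 70), "hfo": (115, 170)})
        assert det is expect
        assert got == cls

    def test_nbg_custom_band(self):
        fit = nbg.PeakFit(A=10, B=80, C=5, D=0, E=0, r2=0.9)
        det, cls = nbg.classify_detection(fit, band_classes={"nbg": (65, 110)})
        assert det and cls == "nbg"


class TestBandPower:
    def test_constant_spectrum(self):
        f = np.arange(0, 300.5, 0.5)
        assert nbg.band_power(f, np.full_like(f, 7.5), 80.0) == pytest.approx(7.5)

    def test_model_spectrum_matches_quadrature(self):
        f = np.arange(0, 300.5, 0.5)
        y = nbg.peak_model(f, 10, 80, 5, 0, 0)
        expected = quad(lambda g: nbg.peak_model(g, 10, 80, 5, 0, 0), 70, 90)[0] / 20
        assert nbg.band_power(f, y, 80.0) == pytest.approx(expected, rel=0.01)

    def test_band_outside_range_rejected(self):
        f = np.arange(0, 100.5, 0.5)
        with pytest.raises(ValueError):
            nbg.band_power(f, np.zeros_like(f), 95.0)


class TestTrack:
    def test_zero_amplitude_session_rate_zero(self, rng):
        sp = model_spectrogram([(0, 80, 5, 0, 0)] * 20, noise=0.5, seed=1)
        tr = nbg.track_nbg(sp, "M1")
        assert tr.detection_rate == 0.0
        assert np.isnan(tr.median_peak_hz)

    def test_half_on_session(self):
        params = [(10, 80, 5, 0, 0)] * 10 + [(0, 80, 5, 0, 0)] * 10
        tr = nbg.track_nbg(model_spectrogram(params, seed=2), "M1")
        assert tr.detection_rate == pytest.approx(0.5, abs=0.05)

    def test_drifting_peak_median(self):
        centers = np.linspace(75, 85, 21)
        params = [(10, b, 5, 0, 0) for b in centers]
        tr = nbg.track_nbg(model_spectrogram(params, seed=3), "M1")
        assert tr.median_peak_hz == pytest.approx(80.0, abs=1.0)

    def test_frame_export_schema(self):
        tr = nbg.track_nbg(model_spectrogram([(10, 80, 5, 0, 0)] * 3, seed=4), "M1")
        df = tr.to_frame()
        assert {"structure", "window_start_s", "detected", "A", "B", "C",
                "D", "E", "r2", "band_power"} <= set(df.columns)


def make_track(structure, series, rate=0.5):
    n = len(series)
    fits = [nbg.PeakFit(A=10, B=v, C=5, D=0, E=0, r2=0.9, detected=np.isfinite(v))
            for v in series]
    det = np.array([f.detected for f in fits])
    return nbg.NbgTrack(structure=structure, times=np.arange(n) * 4.0,
                        fits=fits, band=(65, 110),
                        detection_rate=float(det.mean()),
                        median_peak_hz=80.0,
                        band_power_series=np.where(np.isfinite(series), series, 0.0))


class TestFeatureDistance:
    def test_identical_tracks_distance_zero(self, rng):
        s = 80 + rng.normal(0, 2, 50)
        fd = nbg.feature_distance([make_track("M1", s), make_track("dStr", s)])
        assert fd.distance[0, 1] == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(fd.distance, fd.distance.T)
        assert np.allclose(np.diag(fd.distance), 0.0)

    def test_anticorrelated_distance_two(self, rng):
        s = 80 + rng.normal(0, 2, 50)
        anti = 160 - s   # mean-centered negation around 80
        fd = nbg.feature_distance([make_track("M1", s), make_track("vHipp", anti)])
        assert fd.distance[0, 1] == pytest.approx(2.0, abs=1e-9)

    def test_gate_excludes_low_rate_structures(self, rng):
        s = 80 + rng.normal(0, 2, 50)
        sparse = np.full(50, np.nan)
        sparse[0] = 80.0     # 2% detection rate
        tracks = [make_track("M1", s), make_track("dStr", s),
                  make_track("OFC", sparse)]
        fd = nbg.feature_distance(tracks)
        assert fd.structures == ["M1", "dStr"]

    def test_fewer_than_two_gated_raises(self, rng):
        sparse = np.full(50, np.nan)
        with pytest.raises(ValueError):
            nbg.feature_distance([make_track("M1", sparse),
                                  make_track("dStr", sparse)])


class TestAimsCorrelation:
    def _aims(self, levels):
        rows = []
        for t, lv in zip(range(10, 10 * len(levels) + 1, 10), levels):
            for sub in ("axial", "limb", "orolingual"):
                rows.append({"t_min": float(t), "subtype": sub,
                             "severity": lv, "amplitude": 2})
        return pd.DataFrame(rows)

    def _track_with_power(self, power_per_bin):
        n = len(power_per_bin) * 150   # 150 windows of 4 s per 10-min bin
        series = np.repeat(power_per_bin, 150)
        fits = [nbg.PeakFit(detected=False) for _ in range(n)]
        return nbg.NbgTrack(structure="M1", times=np.arange(n) * 4.0, fits=fits,
                            band=(65, 110), band_power_series=series)

    def test_slaved_power_correlates(self):
        levels = [0, 0, 1, 2, 2.5, 2, 1, 0, 0]
        tr = self._track_with_power(np.array(levels, dtype=float) * 4.0)
        res = nbg.aims_gamma_correlation(tr, self._aims(levels))
        assert res.defined and res.r > 0.8

    def test_constant_aims_flagged_undefined(self):
        tr = self._track_with_power(np.arange(6, dtype=float))
        res = nbg.aims_gamma_correlation(tr, self._aims([1] * 6))
        assert not res.defined
        assert res.note == "zero variance"

    def test_permuted_aims_decorrelates(self, rng):
        levels = np.array([0, 0, 1, 2, 2.5, 2, 1, 0, 0], dtype=float)
        tr = self._track_with_power(levels * 4.0)
        rs = []
        for _ in range(100):
            perm = rng.permutation(levels)
            if perm.std() == 0:
                continue
            res = nbg.aims_gamma_correlation(tr, self._aims(perm.tolist()))
            if res.defined:
                rs.append(abs(res.r))
        assert np.median(rs) < 0.3

    def test_too_few_bins_flagged(self):
        tr = self._track_with_power(np.array([1.0, 2.0]))
        res = nbg.aims_gamma_correlation(tr, self._aims([1, 2]))
        assert not res.defined
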