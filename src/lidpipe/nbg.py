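"""Parametric narrowband-peak detection and feature tracking.

A Gaussian peak on a linear background,

    y(f) = A * exp(-((f - B) / C)**2) + D*f + E,

is fitted by bounded nonlinear least squares to fractal-normalized spectra
(dB_fractal) restricted to a frequency band.  A window counts as a positive
detection when the goodness of fit and every fitted parameter fall inside
configurable thresholds (defaults: R^2 > 0.2, 2 < A < 100 dB, 1 < C < 20 Hz,
-1 < D < 1, -10 < E < 10, and B inside the band class).  Three band classes
are provided: gamma 30-70 Hz, HFO 115-170 Hz, and the narrowband-gamma (NBG)
dyskinesia band 65-110 Hz.

Session-level readouts per structure are the detection rate (fraction of
analysis windows with a positive detection), the median fitted peak frequency
B, and the band power (mean dB_fractal over a 20-Hz band centered on the
session's median peak frequency).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.stats import pearsonr

__all__ = [
    "BAND_CLASSES",
    "DetectionThresholds",
    "PeakFit",
    "NbgTrack",
    "FeatureDistanceMatrix",
    "peak_model",
    "fit_peak_model",
    "classify_detection",
    "band_power",
    "track_nbg",
    "feature_distance",
    "aims_gamma_correlation",
]

BAND_CLASSES = {
    "gamma": (30.0, 70.0),
    "hfo": (115.0, 170.0),
    "nbg": (65.0, 110.0),
}


@dataclass(frozen=True)
class DetectionThresholds:
    r2_min: float = 0.2
    a_min: float = 2.0
    a_max: float = 100.0
    c_min: float = 1.0
    c_max: float = 20.0
    d_abs_max: float = 1.0
    e_abs_max: float = 10.0


@dataclass
class PeakFit:
    A: float = np.nan     # peak height, dB
    B: float = np.nan     # peak frequency, Hz
    C: float = np.nan     # peak width, Hz
    D: float = np.nan     # background inclination, dB/Hz
    E: float = np.nan     # background offset, dB
    r2: float = 0.0
    detected: bool = False
    band_class: str | None = None
    diagnostic: str | None = None


def peak_model(f, A, B, C, D, E):
    return A * np.exp(-((f - B) / C) ** 2) + D * f + E


def fit_peak_model(freqs, spectrum_db, band, n_starts=5) -> PeakFit:
    """Bounded least-squares fit of the peak model within `band`.

    The Gaussian-peak objective is multimodal in B, so the optimizer is
    restarted from a grid of `n_starts` peak-frequency values across the band
    and the best solution kept.  Optimizer failure is reported through the
    `diagnostic` field of an undetected fit, never as an exception.
    """
    lo, hi = band
    if not lo < hi:
        raise ValueError("band must satisfy lo < hi")
    freqs = np.asarray(freqs, dtype=float)
    y = np.asarray(spectrum_db, dtype=float)
    keep = (freqs >= lo) & (freqs <= hi) & np.isfinite(y)
    f, y = freqs[keep], y[keep]
    if len(f) < 8:
        return PeakFit(diagnostic="band not covered by spectrum")

    lower = np.array([0.0, lo, 0.5, -5.0, -30.0])
    upper = np.array([200.0, hi, 40.0, 5.0, 30.0])

    def resid(p):
        return peak_model(f, *p) - y

    best = None
    for b0 in np.linspace(lo + 0.1 * (hi - lo), hi - 0.1 * (hi - lo), n_starts):
        a0 = max(float(y.max() - np.median(y)), 0.1)
        p0 = np.clip([a0, b0, 5.0, 0.0, float(np.median(y))], lower, upper)
        try:
            sol = least_squares(resid, p0, bounds=(lower, upper), max_nfev=400)
        except Exception as exc:   # pragma: no cover - scipy failures are rare
            return PeakFit(diagnostic=f"optimizer failure: {exc}")
        if best is None or sol.cost < best.cost:
            best = sol
    ss_res = 2.0 * best.cost
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    A, B, C, D, E = best.x
    return PeakFit(A=float(A), B=float(B), C=float(C), D=float(D), E=float(E),
                   r2=float(max(r2, 0.0)))


def classify_detection(fit: PeakFit, thresholds=DetectionThresholds(),
                       band_classes=BAND_CLASSES):
    """Apply the printed detection conditions; assign the class by B interval.

    Returns ``(detected, band_class)`` and mutates the fit in place.  All
    bounds are strict inequalities.
    """
    t = thresholds
    ok = (fit.r2 > t.r2_min
          and t.a_min < fit.A < t.a_max
          and t.c_min < fit.C < t.c_max
          and -t.d_abs_max < fit.D < t.d_abs_max
          and -t.e_abs_max < fit.E < t.e_abs_max)
    cls = None
    if ok:
        for name, (lo, hi) in band_classes.items():
            if lo < fit.B < hi:
                cls = name
                break
    fit.detected = ok and cls is not None
    fit.band_class = cls if fit.detected else None
    return fit.detected, fit.band_class


def band_power(freqs, spectrum_db, center, width=20.0):
    """Mean normalized power (dB_fractal) over a `width`-Hz band at `center`.

    The mean is the integral average over the band (trapezoid rule on the
    frequency grid), so it is consistent with the continuous definition.
    """
    freqs = np.asarray(freqs, dtype=float)
    lo, hi = center - width / 2.0, center + width / 2.0
    if lo < freqs.min() - 1e-9 or hi > freqs.max() + 1e-9:
        raise ValueError("band extends outside the spectrum range")
    keep = (freqs >= lo) & (freqs <= hi)
    f, y = freqs[keep], np.asarray(spectrum_db)[keep]
    return float(np.trapezoid(y, f) / (f[-1] - f[0]))


@dataclass
class NbgTrack:
    """Per-window peak fits and session summaries for one structure."""

    structure: str
    times: np.ndarray
    fits: list
    band: tuple
    detection_rate: float = 0.0
    median_peak_hz: float = np.nan      # undefined (NaN) when nothing detected
    band_power_series: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def detected(self):
        return np.array([f.detected for f in self.fits], dtype=bool)

    def feature_series(self, feature):
        key = {"peak": "B", "height": "A", "width": "C"}[feature]
        vals = np.array([getattr(f, key) for f in self.fits], dtype=float)
        vals[~self.detected] = np.nan
        return vals

    def to_frame(self):
        rows = [{"structure": self.structure, "window_start_s": t,
                 "detected": f.detected, "band_class": f.band_class,
                 "A": f.A, "B": f.B, "C": f.C, "D": f.D, "E": f.E,
                 "r2": f.r2, "band_power": bp}
                for t, f, bp in zip(self.times, self.fits, self.band_power_series)]
        return pd.DataFrame(rows)


def track_nbg(spectrogram, structure, band_class="nbg",
              thresholds=DetectionThresholds(), band_classes=None) -> NbgTrack:
    """Fit + classify every window of a normalized spectrogram.

    `spectrogram.power_db` must hold dB_fractal values (structure-averaged
    normalized spectra).  The band-power series uses a 20-Hz band centered on
    the session median peak frequency; when nothing is detected the band
    midpoint is used so the series remains defined.
    """
    if band_classes is None:
        band_classes = {band_class: BAND_CLASSES[band_class]}
    band = band_classes[band_class]
    fits = []
    for row in spectrogram.power_db:
        fit = fit_peak_model(spectrogram.freqs, row, band)
        classify_detection(fit, thresholds, band_classes)
        fits.append(fit)
    det = np.array([f.detected for f in fits], dtype=bool)
    rate = float(det.mean()) if len(fits) else 0.0
    med = float(np.median([f.B for f in fits if f.detected])) if det.any() else np.nan
    center = med if np.isfinite(med) else 0.5 * (band[0] + band[1])
    bp = np.array([band_power(spectrogram.freqs, row, center)
                   for row in spectrogram.power_db])
    return NbgTrack(structure=structure, times=spectrogram.times, fits=fits,
                    band=band, detection_rate=rate, median_peak_hz=med,
                    band_power_series=bp)


@dataclass
class FeatureDistanceMatrix:
    structures: list
    r: np.ndarray          # pairwise temporal Pearson correlation
    distance: np.ndarray   # 1 - r
    feature: str


def feature_distance(tracks, feature="peak", min_rate=0.05,
                     min_overlap=3) -> FeatureDistanceMatrix:
    """1 - r distances between structures' per-window feature series.

    Structures with a detection rate below `min_rate` are excluded before any
    comparison.  Correlations use only windows where both series are defined
    (both detected); pairs with fewer than `min_overlap` such windows, or a
    constant series, are flagged undefined (NaN).
    """
    gated = [t for t in tracks if t.detection_rate >= min_rate]
    if len(gated) < 2:
        raise ValueError("fewer than two structures pass the detection-rate gate")
    names = [t.structure for t in gated]
    series = [t.feature_series(feature) for t in gated]
    m = len(gated)
    r = np.full((m, m), np.nan)
    np.fill_diagonal(r, 1.0)
    for i in range(m):
        for j in range(i + 1, m):
            both = np.isfinite(series[i]) & np.isfinite(series[j])
            if both.sum() < min_overlap:
                continue
            a, b = series[i][both], series[j][both]
            if a.std() == 0 or b.std() == 0:
                continue
            r[i, j] = r[j, i] = float(pearsonr(a, b)[0])
    return FeatureDistanceMatrix(structures=names, r=r, distance=1.0 - r,
                                 feature=feature)


@dataclass
class CorrelationResult:
    r: float
    n_bins: int
    defined: bool
    note: str | None = None


def aims_gamma_correlation(track: NbgTrack, aims, bin_min=10.0) -> CorrelationResult:
    """Pearson correlation of per-bin NBG band power with the global AIMs score.

    The band-power series is averaged within the AIMs observation bins
    (nearest `bin_min`-minute interval).  Fewer than three overlapping bins or
    zero variance on either side yields a flagged undefined result rather
    than NaN propagation.
    """
    from .behavior import global_aims

    scores = global_aims(aims).set_index("t_min")["global"]
    bins = scores.index.to_numpy(dtype=float)
    power = np.full(len(bins), np.nan)
    t_min = track.times / 60.0
    for k, tb in enumerate(bins):
        inb = (t_min >= tb - bin_min) & (t_min < tb)
        if inb.any():
            power[k] = np.nanmean(track.band_power_series[inb])
    ok = np.isfinite(power)
    if ok.sum() < 3:
        return CorrelationResult(np.nan, int(ok.sum()), False, "fewer than 3 bins")
    x, y = power[ok], scores.to_numpy(dtype=float)[ok]
    if x.std() == 0 or y.std() == 0:
        return CorrelationResult(np.nan, int(ok.sum()), False, "zero variance")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        r = float(pearsonr(x, y)[0])
    return CorrelationResult(r, int(ok.sum()), True)
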