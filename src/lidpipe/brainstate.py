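"""Whole-spectrum brain-state comparison across treatments.

Treatment brain states are summarized per structure as the aperiodic-
normalized power spectrum over 1-200 Hz, computed from monopolar electrodes
in 4-s windows restricted to the peak (40-80 min) or late (120-160 min)
period after levodopa, averaged over windows and recording sites.  Two
treatments are compared by the Pearson correlation between one session's
state spectrum and the average spectrum of each reference condition; a
two-sided rank-sum annotation on the two correlation samples is provided as
reporting plumbing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import pearsonr, ranksums

from .spectral import IRASA_FACTORS, _sliding_windows, db, irasa_windows

__all__ = ["StateSpectrum", "SimilarityResult", "state_spectrum",
           "treatment_similarity", "average_state_spectra"]


@dataclass
class StateSpectrum:
    structure: str
    period_min: tuple            # (t0, t1) minutes post levodopa
    freqs: np.ndarray            # 1-200 Hz on the native 4-s grid (0.25 Hz)
    normalized_db: np.ndarray
    n_windows: int
    source: str = "single session"


def state_spectrum(rec, structure, period_min=(40.0, 80.0), window_s=4.0,
                   hemisphere="lesioned", factors=IRASA_FACTORS,
                   f_lo=1.0, f_hi=200.0) -> StateSpectrum:
    """Fractal-normalized 1-200 Hz spectrum of one structure in one period.

    Monopolar electrodes (per-site signals, not bipolar pairs) are cut into
    non-overlapping `window_s` windows inside the period; total and fractal
    spectra are averaged over windows and sites in linear power before
    normalization, and the result restricted to the 1-200 Hz grid.
    """
    chans = rec.channels_of(structure, hemisphere)
    if len(chans) == 0:
        raise ValueError(f"no electrodes in structure {structure!r}")
    t0 = period_min[0] * 60.0 + rec.meta.get("injection_time_s", 0.0)
    t1 = period_min[1] * 60.0 + rec.meta.get("injection_time_s", 0.0)
    i0 = max(0, int(round(t0 * rec.fs)))
    i1 = min(rec.data.shape[1], int(round(t1 * rec.fs)))
    nperseg = int(round(window_s * rec.fs))
    if i1 - i0 < nperseg:
        raise ValueError("recording does not cover the requested period")
    tot_acc = None
    fra_acc = None
    n_win = 0
    for c in chans:
        wins = _sliding_windows(rec.data[int(c), i0:i1], nperseg, nperseg)
        freqs, total, fractal = irasa_windows(wins, rec.fs, factors, average=True)
        n_win += wins.shape[0]
        tot_acc = total if tot_acc is None else tot_acc + total
        fra_acc = fractal if fra_acc is None else fra_acc + fractal
    keep = (freqs >= f_lo) & (freqs <= f_hi)
    norm = db(tot_acc[keep]) - db(fra_acc[keep])
    return StateSpectrum(structure=structure, period_min=tuple(period_min),
                         freqs=freqs[keep], normalized_db=norm,
                         n_windows=n_win)


def average_state_spectra(spectra) -> StateSpectrum:
    """Condition-average state spectrum (mean in the dB domain)."""
    spectra = list(spectra)
    if not spectra:
        raise ValueError("no spectra to average")
    f0 = spectra[0].freqs
    for s in spectra[1:]:
        if not np.array_equal(s.freqs, f0):
            raise ValueError("state spectra are not on a common grid")
    return StateSpectrum(
        structure=spectra[0].structure, period_min=spectra[0].period_min,
        freqs=f0, normalized_db=np.mean([s.normalized_db for s in spectra], axis=0),
        n_windows=sum(s.n_windows for s in spectra), source="condition average")


@dataclass
class SimilarityResult:
    structure: str
    r_a: list = field(default_factory=list)   # test sessions vs reference A
    r_b: list = field(default_factory=list)   # test sessions vs reference B
    p_value: float = np.nan                   # two-sided rank-sum annotation
    note: str | None = None

    @property
    def median_r_a(self):
        return float(np.median(self.r_a)) if self.r_a else np.nan

    @property
    def median_r_b(self):
        return float(np.median(self.r_b)) if self.r_b else np.nan


def treatment_similarity(test_spectra, reference_a: StateSpectrum,
                         reference_b: StateSpectrum) -> SimilarityResult:
    """Pearson r of each test-session spectrum against two reference averages.

    All spectra must share one frequency grid.  One r per test session per
    reference; the paired r samples are annotated with a two-sided Wilcoxon
    rank-sum p value (reporting plumbing, not an acceptance quantity).
    """
    test_spectra = list(test_spectra)
    if not test_spectra:
        raise ValueError("no test sessions")
    f0 = reference_a.freqs
    if not np.array_equal(reference_b.freqs, f0):
        raise ValueError("reference spectra on different grids")
    res = SimilarityResult(structure=test_spectra[0].structure)
    for s in test_spectra:
        if not np.array_equal(s.freqs, f0):
            raise ValueError("test spectrum grid mismatch")
        res.r_a.append(float(pearsonr(s.normalized_db, reference_a.normalized_db)[0]))
        res.r_b.append(float(pearsonr(s.normalized_db, reference_b.normalized_db)[0]))
    if len(test_spectra) >= 2:
        res.p_value = float(ranksums(res.r_a, res.r_b).pvalue)
    else:
        res.note = "single test session: comparison underpowered"
    return res
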