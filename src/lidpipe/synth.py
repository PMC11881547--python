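"""Synthetic LFP sessions, trajectories and AIMs schedules with known ground truth.

This module emulates the statistical structure that the analysis chain assumes:

* a 1/f^chi aperiodic ("fractal") background per wire,
* transient narrowband oscillations (narrowband gamma 65-110 Hz, low gamma,
  HFO, theta) shared by the wires of one or several structures,
* controlled phase coupling between wires, parameterised by the von Mises
  concentration kappa of the pairwise phase differences,
* a drug-response time course (onset ~20-40 min, peak 40-80 min, decay),
* open-field trajectories containing a known number of complete rotations,
* AIMs rating schedules correlated with the oscillation epochs.

Every generated quantity is recorded in :class:`GroundTruth` so downstream
stages can be scored without re-deriving anything from the signals.

Phase-coupling calibration
--------------------------
Each wire of a coupled group receives the group's shared narrowband analytic
signal rotated by a smooth, band-limited Gaussian phase process ``theta_w(t)``
(wrapped-normal jitter).  For two wires with independent jitter of variance
``sigma**2`` the pairwise phase difference has mean resultant length
``R = exp(-sigma**2)``.  The downstream estimator maps resultant length to
concentration through the von Mises link ``A(kappa) = I1(kappa)/I0(kappa)``,
so choosing ``sigma**2 = -log(A(kappa_target))`` makes the recovered
concentration equal ``kappa_target`` in expectation.  The wrapped-normal
family is closed under differences, which makes this calibration exact at the
level of resultant lengths; the residual von-Mises/wrapped-normal shape
mismatch is absorbed by the link function and verified numerically in the
test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal
from scipy.optimize import brentq
from scipy.special import i0e, i1e

__all__ = [
    "DrugProfile",
    "OscillationSpec",
    "SessionConfig",
    "GroundTruth",
    "Recording",
    "SessionBundle",
    "generate_aperiodic",
    "generate_oscillation",
    "generate_session",
    "generate_trajectory",
    "generate_aims_schedule",
    "simulate_session",
    "vm_resultant",
    "vm_kappa_from_resultant",
    "jitter_sigma_for_kappa",
    "schedule_from_profile",
]

KAPPA_MAX = 1000.0

# the 11 structure groups analysed in the study (lesioned hemisphere)
DEFAULT_STRUCTURES = (
    "M1", "S1", "dStr", "vStr", "thal",
    "dHipp", "vHipp", "OFC", "mPFC", "amyg", "OC",
)


def vm_resultant(kappa: float) -> float:
    """Mean resultant length A(kappa) = I1(kappa)/I0(kappa) of a von Mises law."""
    if kappa < 0:
        raise ValueError("kappa must be >= 0")
    return float(i1e(kappa) / i0e(kappa))


def vm_kappa_from_resultant(rbar: float) -> float:
    """Invert A(kappa) numerically; saturates at KAPPA_MAX near rbar = 1."""
    if rbar <= 0.0:
        return 0.0
    if rbar >= vm_resultant(KAPPA_MAX):
        return KAPPA_MAX
    return brentq(lambda k: vm_resultant(k) - rbar, 1e-12, KAPPA_MAX)


def jitter_sigma_for_kappa(kappa: float) -> float:
    """Per-wire jitter s.d. so pairwise phase-difference concentration is kappa.

    Pairwise resultant length exp(-sigma^2) must equal A(kappa); see module
    docstring for the derivation.
    """
    r = vm_resultant(kappa)
    if r <= 0:
        raise ValueError("kappa too small for jitter calibration; use kappa=0 "
                         "(independent oscillations) instead")
    return float(np.sqrt(-np.log(r)))


# --------------------------------------------------------------------------
# configuration dataclasses
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class DrugProfile:
    """Piecewise-linear drug-response level in [0, 1] versus minutes post injection.

    Zero before `onset_min`, ramps to 1 at `peak_start_min`, holds through
    `peak_end_min`, decays linearly to 0 at `decay_end_min`.
    """

    onset_min: float = 20.0
    peak_start_min: float = 40.0
    peak_end_min: float = 80.0
    decay_end_min: float = 160.0

    def __post_init__(self):
        ts = (self.onset_min, self.peak_start_min, self.peak_end_min, self.decay_end_min)
        if any(b < a for a, b in zip(ts, ts[1:])):
            raise ValueError("drug profile times must be non-decreasing")

    def level(self, t_min):
        t = np.asarray(t_min, dtype=float)
        out = np.zeros_like(t)
        rise = self.peak_start_min - self.onset_min
        if rise > 0:
            m = (t >= self.onset_min) & (t < self.peak_start_min)
            out[m] = (t[m] - self.onset_min) / rise
        out[(t >= self.peak_start_min) & (t <= self.peak_end_min)] = 1.0
        fall = self.decay_end_min - self.peak_end_min
        if fall > 0:
            m = (t > self.peak_end_min) & (t < self.decay_end_min)
            out[m] = 1.0 - (t[m] - self.peak_end_min) / fall
        return out if out.ndim else float(out)


def schedule_from_profile(profile: DrugProfile, threshold: float = 0.5):
    """On-epochs (seconds) where the drug level is at or above `threshold`."""
    # piecewise linear => at most one contiguous epoch
    ts = np.linspace(0.0, profile.decay_end_min + 30.0, 20000)
    lv = profile.level(ts) >= threshold
    if not lv.any():
        return []
    t0 = ts[lv][0] * 60.0
    t1 = ts[lv][-1] * 60.0
    return [(float(t0), float(t1))]


@dataclass(frozen=True)
class OscillationSpec:
    """One transient narrowband oscillatory component shared by a structure group.

    amplitude is the RMS of the oscillation (same units as the aperiodic
    background, nominally microvolts) while the schedule is "on".  kappa is
    the target von Mises concentration of pairwise phase differences between
    any two wires carrying this component; kappa=0 requests independent
    oscillations per wire (uniform phase relation) and kappa=None perfectly
    identical ones.
    """

    name: str
    center_hz: float
    bandwidth_hz: float
    amplitude: float
    structures: tuple = ()
    schedule: tuple = ()           # ((t0_s, t1_s), ...); empty = always on
    kappa: float | None = 8.0
    center_end_hz: float | None = None   # linear drift target, None = constant

    def band_limits(self):
        lo = self.center_hz - self.bandwidth_hz / 2.0
        c1 = self.center_end_hz if self.center_end_hz is not None else self.center_hz
        hi = max(self.center_hz, c1) + self.bandwidth_hz / 2.0
        return lo, hi


@dataclass(frozen=True)
class SessionConfig:
    duration_s: float = 600.0
    fs: float = 2000.0
    structures: tuple = ("M1", "dStr", "thal")
    wires_per_structure: int = 2
    aperiodic_exponent: float = 1.5      # scalar or mapping structure -> chi
    aperiodic_scale: float = 50.0        # background RMS, microvolts
    oscillations: tuple = ()
    drug_profile: DrugProfile | None = None
    treatment: str = "L-DOPA + vehicle"
    injection_time_s: float = 0.0
    hemisphere: str = "lesioned"
    window_s: float = 8.0                # analysis windowing for ground-truth flags
    window_overlap: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.duration_s <= 0 or self.fs <= 0:
            raise ValueError("duration_s and fs must be positive")
        for osc in self.oscillations:
            lo, hi = osc.band_limits()
            if hi >= self.fs / 2.0:
                raise ValueError(f"oscillation {osc.name!r} exceeds Nyquist")
            if osc.kappa is not None and osc.kappa < 0:
                raise ValueError("coupling kappa must be >= 0")
            for (t0, t1) in osc.schedule:
                if not (0 <= t0 <= t1 <= self.duration_s):
                    raise ValueError(f"schedule of {osc.name!r} outside session")
        if self.wires_per_structure < 1:
            raise ValueError("need at least one wire per structure")

    def exponent_for(self, structure: str) -> float:
        chi = self.aperiodic_exponent
        if isinstance(chi, dict):
            return float(chi[structure])
        return float(chi)

    @staticmethod
    def desk_scale(**over) -> "SessionConfig":
        """The full desk-scale session: 11 structures, 4 wires, 30 min."""
        kw = dict(duration_s=1800.0, structures=DEFAULT_STRUCTURES,
                  wires_per_structure=4)
        kw.update(over)
        return SessionConfig(**kw)

    @staticmethod
    def long_session(**over) -> "SessionConfig":
        """180-min end-to-end configuration."""
        kw = dict(duration_s=10800.0, structures=DEFAULT_STRUCTURES,
                  wires_per_structure=4)
        kw.update(over)
        return SessionConfig(**kw)


# --------------------------------------------------------------------------
# output containers
# --------------------------------------------------------------------------

@dataclass
class Recording:
    """Multichannel recording: channels x samples plus a channel map and metadata."""

    data: np.ndarray                 # (n_channels, n_samples), microvolts
    fs: float
    channel_map: pd.DataFrame        # columns: channel, structure, hemisphere
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.data.ndim != 2:
            raise ValueError("data must be channels x samples")
        if len(self.channel_map) != self.data.shape[0]:
            raise ValueError("channel map does not cover every channel")
        bad = set(self.channel_map["hemisphere"]) - {"lesioned", "intact"}
        if bad:
            raise ValueError(f"invalid hemisphere labels: {bad}")

    @property
    def n_channels(self):
        return self.data.shape[0]

    @property
    def duration_s(self):
        return self.data.shape[1] / self.fs

    def channels_of(self, structure, hemisphere="lesioned"):
        cm = self.channel_map
        sel = (cm["structure"] == structure) & (cm["hemisphere"] == hemisphere)
        return cm.loc[sel, "channel"].to_numpy()

    def structures(self, hemisphere="lesioned"):
        cm = self.channel_map
        return list(dict.fromkeys(cm.loc[cm["hemisphere"] == hemisphere, "structure"]))


@dataclass
class GroundTruth:
    """Everything needed to score the downstream stages without touching signals."""

    window_starts_s: np.ndarray          # analysis-window grid (8 s, 50% overlap)
    nbg_window_flags: np.ndarray         # bool per window: NBG on >= half the window
    true_peak_freq: np.ndarray           # Hz per window, NaN where flag is False
    true_kappa: dict                     # frozenset({a, b}) -> kappa
    true_rotations: list = field(default_factory=list)   # (t_s, 'contra'|'ipsi')
    true_aims: pd.DataFrame | None = None

    @property
    def nbg_fraction(self) -> float:
        return float(np.mean(self.nbg_window_flags)) if len(self.nbg_window_flags) else 0.0


@dataclass
class SessionBundle:
    config: SessionConfig
    recording: Recording
    ground_truth: GroundTruth
    trajectory: pd.DataFrame | None = None
    aims: pd.DataFrame | None = None


# --------------------------------------------------------------------------
# signal generators
# --------------------------------------------------------------------------

def generate_aperiodic(exponent, duration_s, fs, seed=None, scale=1.0,
                       flatten_below_hz=0.5):
    """Zero-mean noise whose power spectrum follows f**(-exponent).

    Synthesised by spectral shaping of complex white noise (amplitude
    proportional to f**(-exponent/2), random phases), which gives the target
    spectrum exactly in expectation.  Below `flatten_below_hz` the amplitude
    is held constant to keep very-low-frequency power finite; the 1-200 Hz
    range is an exact power law.  Output is rescaled to RMS `scale`.
    """
    if duration_s <= 0 or fs <= 0:
        raise ValueError("duration_s and fs must be positive")
    if not 0 <= exponent <= 3:
        raise ValueError("exponent outside the supported range [0, 3]")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    amp = np.ones_like(freqs)
    f_eff = np.maximum(freqs, flatten_below_hz)
    amp[1:] = f_eff[1:] ** (-exponent / 2.0)
    amp[0] = 0.0
    spec = amp * (rng.standard_normal(len(freqs)) + 1j * rng.standard_normal(len(freqs)))
    x = np.fft.irfft(spec, n)
    sd = x.std()
    if sd > 0:
        x *= scale / sd
    return x


def _schedule_envelope(schedule, n, fs, ramp_s=0.1):
    """0/1 gate with raised-cosine ramps at epoch edges (avoids spectral clicks)."""
    if not schedule:
        return np.ones(n)
    env = np.zeros(n)
    t = np.arange(n) / fs
    for (t0, t1) in schedule:
        ramp = min(ramp_s, (t1 - t0) / 2.0)
        seg = np.zeros(n)
        inside = (t >= t0) & (t < t1)
        seg[inside] = 1.0
        if ramp > 0:
            up = inside & (t < t0 + ramp)
            seg[up] = 0.5 * (1 - np.cos(np.pi * (t[up] - t0) / ramp))
            dn = inside & (t >= t1 - ramp)
            seg[dn] = 0.5 * (1 - np.cos(np.pi * (t1 - t[dn]) / ramp))
        env = np.maximum(env, seg)
    return env


def _oscillation_analytic(spec: OscillationSpec, duration_s, fs, rng):
    """Complex analytic narrowband process for one oscillation component.

    Complex Gaussian baseband noise rotated to the (possibly drifting) center
    frequency, so the real part is narrowband Gaussian noise rather than a
    pure sinusoid -- peak width is then a meaningful recovery target for the
    parametric fit.
    """
    n = int(round(duration_s * fs))
    if spec.amplitude == 0:
        return np.zeros(n, dtype=complex)
    lo, _ = spec.band_limits()
    if lo <= 0:
        raise ValueError("bandwidth must be smaller than the center frequency")
    # complex Gaussian baseband with a Gaussian-shaped PSD (s.d. bandwidth/2),
    # so the real signal's spectrum peaks exactly at the center frequency and
    # the parametric peak-width parameter has a well-defined target
    sigma_f = spec.bandwidth_hz / 2.0
    f2 = np.fft.fftfreq(n, 1.0 / fs)
    shape = np.exp(-f2 ** 2 / (2.0 * sigma_f ** 2))
    wn = rng.standard_normal(n) + 1j * rng.standard_normal(n)
    base = np.fft.ifft(np.fft.fft(wn) * shape)
    c0 = spec.center_hz
    c1 = spec.center_end_hz if spec.center_end_hz is not None else c0
    f_inst = np.linspace(c0, c1, n)
    phase = 2.0 * np.pi * np.cumsum(f_inst) / fs
    z = base * np.exp(1j * phase)
    rms = np.sqrt(np.mean(z.real ** 2))
    if rms > 0:
        z *= spec.amplitude / rms
    env = _schedule_envelope(spec.schedule, n, fs)
    return z * env


def generate_oscillation(center_hz, bandwidth_hz, amplitude, schedule,
                         duration_s, fs, seed=None, center_end_hz=None):
    """Real band-limited oscillatory series, nonzero only inside schedule epochs."""
    if center_hz >= fs / 2.0:
        raise ValueError("center frequency at or above Nyquist")
    if not 0 < bandwidth_hz < center_hz:
        raise ValueError("need 0 < bandwidth < center frequency")
    spec = OscillationSpec("osc", center_hz, bandwidth_hz, amplitude,
                           schedule=tuple(tuple(e) for e in schedule),
                           center_end_hz=center_end_hz)
    rng = np.random.default_rng(seed)
    return _oscillation_analytic(spec, duration_s, fs, rng).real


def _smooth_phase_jitter(sigma, n, fs, rng, cutoff_hz=2.0):
    """Band-limited Gaussian phase process with marginal s.d. `sigma` (radians)."""
    if sigma == 0:
        return np.zeros(n)
    sos = signal.butter(4, cutoff_hz, btype="low", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, rng.standard_normal(n))
    sd = x.std()
    return x * (sigma / sd) if sd > 0 else x


def _window_grid(duration_s, window_s, overlap):
    step = window_s * (1.0 - overlap)
    starts = []
    t = 0.0
    while t + window_s <= duration_s + 1e-9:
        starts.append(t)
        t += step
    return np.asarray(starts)


def _epoch_coverage(starts, window_s, schedule):
    """Fraction of each window covered by the union of schedule epochs."""
    cov = np.zeros(len(starts))
    for (t0, t1) in schedule:
        a = np.maximum(starts, t0)
        b = np.minimum(starts + window_s, t1)
        cov += np.maximum(0.0, b - a)
    return cov / window_s


def generate_session(cfg: SessionConfig):
    """Generate a multichannel recording plus its ground truth.

    Each wire receives an independent aperiodic background at the structure's
    exponent; wires of structures listed in an :class:`OscillationSpec` share
    that component's narrowband analytic signal, rotated by per-wire phase
    jitter calibrated to the requested pairwise concentration (see module
    docstring).  kappa=0 draws an independent component per wire instead.
    """
    ss = np.random.SeedSequence(cfg.seed)
    n = int(round(cfg.duration_s * cfg.fs))
    n_ch = len(cfg.structures) * cfg.wires_per_structure

    rows = []
    ch = 0
    wires = {}      # structure -> list of channel indices
    for s in cfg.structures:
        wires[s] = []
        for _ in range(cfg.wires_per_structure):
            rows.append({"channel": ch, "structure": s, "hemisphere": cfg.hemisphere})
            wires[s].append(ch)
            ch += 1
    channel_map = pd.DataFrame(rows)

    # independent child streams: one per channel background, one per oscillation
    child = ss.spawn(n_ch + len(cfg.oscillations))
    data = np.empty((n_ch, n), dtype=np.float64)
    for s in cfg.structures:
        chi = cfg.exponent_for(s)
        for c in wires[s]:
            data[c] = generate_aperiodic(chi, cfg.duration_s, cfg.fs,
                                         seed=child[c], scale=cfg.aperiodic_scale)

    for k, osc in enumerate(cfg.oscillations):
        orng = np.random.default_rng(child[n_ch + k])
        members = [c for s in osc.structures for c in wires.get(s, [])]
        if not members:
            continue
        if osc.kappa == 0:
            for c in members:
                z = _oscillation_analytic(osc, cfg.duration_s, cfg.fs, orng)
                data[c] += z.real
            continue
        z = _oscillation_analytic(osc, cfg.duration_s, cfg.fs, orng)
        if osc.kappa is None:
            for c in members:
                data[c] += z.real
            continue
        sigma = jitter_sigma_for_kappa(osc.kappa)
        for c in members:
            theta = _smooth_phase_jitter(sigma, n, cfg.fs, orng)
            data[c] += (z * np.exp(1j * theta)).real

    # ---- ground truth -----------------------------------------------------
    starts = _window_grid(cfg.duration_s, cfg.window_s, cfg.window_overlap)
    flags = np.zeros(len(starts), dtype=bool)
    peak = np.full(len(starts), np.nan)
    for osc in cfg.oscillations:
        lo, hi = osc.band_limits()
        if not (lo < 110 and hi > 65) or osc.amplitude == 0:
            continue  # only NBG-band components set the flags
        sched = osc.schedule if osc.schedule else ((0.0, cfg.duration_s),)
        cov = _epoch_coverage(starts, cfg.window_s, sched)
        on = cov >= 0.5
        flags |= on
        c0 = osc.center_hz
        c1 = osc.center_end_hz if osc.center_end_hz is not None else c0
        mid = (starts + cfg.window_s / 2.0) / cfg.duration_s
        peak[on] = c0 + (c1 - c0) * mid[on]

    true_kappa = {}
    for osc in cfg.oscillations:
        if osc.kappa is None:
            k = KAPPA_MAX
        else:
            k = osc.kappa
        for a in osc.structures:
            for b in osc.structures:
                if a < b:
                    key = frozenset({a, b})
                    true_kappa[key] = max(true_kappa.get(key, 0.0), k)

    meta = {"treatment": cfg.treatment, "injection_time_s": cfg.injection_time_s,
            "seed": cfg.seed, "duration_s": cfg.duration_s}
    rec = Recording(data=data, fs=cfg.fs, channel_map=channel_map, meta=meta)
    truth = GroundTruth(window_starts_s=starts, nbg_window_flags=flags,
                        true_peak_freq=peak, true_kappa=true_kappa)
    return rec, truth


# --------------------------------------------------------------------------
# behavior generators
# --------------------------------------------------------------------------

def generate_trajectory(n_contra, n_ipsi, frame_rate=30.0, noise_px=0.0,
                        seed=None, lesion_side="right", n_partial=0,
                        radius_px=40.0, center_xy=(320.0, 240.0),
                        rotation_s=2.0, gap_s=2.0):
    """Pose table tracing exactly n_contra + n_ipsi complete rotations.

    Returns ``(table, events)`` where the table has columns front_x, front_y,
    center_x, center_y, likelihood (one row per frame) and events is the
    ground-truth list of (completion time s, direction).  Partial 7/8-turn
    arcs followed by a reversal can be injected with `n_partial`; a correct
    detector must not count them.

    Direction convention: with the lesion on the right, contraversive turning
    is counter-clockwise (positive heading angle) in y-up image coordinates.
    """
    if n_contra < 0 or n_ipsi < 0 or frame_rate <= 0:
        raise ValueError("counts must be >= 0 and frame_rate positive")
    rng = np.random.default_rng(seed)
    contra_sign = +1 if lesion_side == "right" else -1

    moves = [("full", contra_sign)] * n_contra + [("full", -contra_sign)] * n_ipsi \
        + [("partial", contra_sign)] * n_partial
    order = rng.permutation(len(moves))
    moves = [moves[i] for i in order]

    dt = 1.0 / frame_rate
    angle = [0.0]
    events = []

    def dwell(seconds):
        angle.extend([angle[-1]] * int(round(seconds * frame_rate)))

    dwell(gap_s)
    for kind, sign in moves:
        n_fr = max(8, int(round(rotation_s * frame_rate)))
        frac = 1.0 if kind == "full" else 7.0 / 8.0
        sweep = angle[-1] + sign * 2.0 * np.pi * frac * np.arange(1, n_fr + 1) / n_fr
        angle.extend(sweep.tolist())
        if kind == "full":
            events.append((len(angle) * dt, "contra" if sign == contra_sign else "ipsi"))
        else:
            # reverse back so no net advance remains
            back = angle[-1] - sign * 2.0 * np.pi * frac * np.arange(1, n_fr + 1) / n_fr
            angle.extend(back.tolist())
        dwell(gap_s)

    a = np.asarray(angle)
    cx, cy = center_xy
    front_x = cx + radius_px * np.cos(a) + rng.standard_normal(len(a)) * noise_px
    front_y = cy + radius_px * np.sin(a) + rng.standard_normal(len(a)) * noise_px
    center_x = cx + rng.standard_normal(len(a)) * noise_px
    center_y = cy + rng.standard_normal(len(a)) * noise_px
    table = pd.DataFrame({
        "front_x": front_x, "front_y": front_y,
        "center_x": center_x, "center_y": center_y,
        "likelihood": np.ones(len(a)),
    })
    table.attrs["frame_rate"] = float(frame_rate)
    return table, events


SEVERITY_SCALE = (0.0, 1.0, 2.0, 2.5)
AMPLITUDE_SCALE = (1, 2, 3, 4)
AIMS_SUBTYPES = ("axial", "limb", "orolingual")


def generate_aims_schedule(profile: DrugProfile | None, seed=None,
                           total_min=180.0, interval_min=10.0):
    """AIMs ratings: one observation per 10-min interval over 180 min.

    Severity (0/1/2/2.5) and amplitude (1-4) of each subtype follow the drug
    level with a small random wobble.  A null profile yields all-zero scores.
    """
    rng = np.random.default_rng(seed)
    t_bins = np.arange(interval_min, total_min + 1e-9, interval_min)
    cols = ["t_min", "subtype", "severity", "amplitude"]
    if len(t_bins) == 0:
        return pd.DataFrame(columns=cols)
    rows = []
    for t in t_bins:
        lv = profile.level(t) if profile is not None else 0.0
        for sub in AIMS_SUBTYPES:
            x = float(np.clip(lv + rng.uniform(-0.05, 0.05) * (lv > 0), 0.0, 1.0))
            if x < 0.125:
                sev = 0.0
            elif x < 0.5:
                sev = 1.0
            elif x < 0.9:
                sev = 2.0
            else:
                sev = 2.5
            amp = int(np.clip(round(4 * x), 1, 4))
            rows.append({"t_min": float(t), "subtype": sub,
                         "severity": sev, "amplitude": amp})
    return pd.DataFrame(rows)


def simulate_session(cfg: SessionConfig, rotations_per_min_peak=1.0) -> SessionBundle:
    """Full synthetic bundle: recording, trajectory, AIMs and joint ground truth."""
    rec, truth = generate_session(cfg)
    ss = np.random.SeedSequence(cfg.seed).spawn(3)
    trajectory = None
    aims = None
    if cfg.drug_profile is not None:
        minutes = cfg.duration_s / 60.0
        lv = cfg.drug_profile.level(np.arange(5.0, minutes, 10.0))
        n_contra = int(round(rotations_per_min_peak * 10.0 * np.sum(lv)))
        trajectory, events = generate_trajectory(
            n_contra=n_contra, n_ipsi=max(1, n_contra // 10), seed=ss[0],
            gap_s=max(1.0, cfg.duration_s / (3.0 * max(n_contra, 1) + 3)))
        truth.true_rotations = events
        aims = generate_aims_schedule(cfg.drug_profile, seed=ss[1],
                                      total_min=minutes)
        if len(aims) == 0:
            aims = None
        truth.true_aims = aims
    return SessionBundle(config=cfg, recording=rec, ground_truth=truth,
                         trajectory=trajectory, aims=aims)
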