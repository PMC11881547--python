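"""End-to-end orchestration: configuration, validation, staged execution, reports.

The pipeline ties the stages together on one session:

    spectral  -> per-structure fractal-normalized spectrograms (bipolar)
    detect    -> narrowband-gamma tracks per structure
    phase     -> structure-pair kappa connectivity matrix (monopolar)
    behavior  -> rotation counts and AIMs aggregation
    brainstate-> per-structure state spectra for the peak and late periods

Every run produces a :class:`SessionReport` that is bit-identically
reproducible from (config, seed, input): the report hash covers the full
JSON payload, and the configuration hash is embedded in it for provenance.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import behavior as bh
from . import brainstate as bs
from . import io as lio
from . import nbg, phase, spectral

logger = logging.getLogger("lidpipe")

__all__ = ["PipelineConfig", "SessionReport", "StageError", "run_pipeline",
           "validate_inputs", "ALL_STAGES"]

ALL_STAGES = ("spectral", "detect", "phase", "behavior", "brainstate")


class StageError(RuntimeError):
    """Raised when a pipeline stage fails; carries the stage name and any
    outputs produced by earlier stages."""

    def __init__(self, stage, cause, partial_report=None):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.partial_report = partial_report


@dataclass(frozen=True)
class PipelineConfig:
    """All knobs of one session analysis; defaults follow the study protocol.

    Analysis windows are in minutes post levodopa; peak = 40-80, late =
    120-160.  The NBG detection band is 65-110 Hz; the phase bandpass spans
    +/-5 Hz around the recording's median NBG frequency; rotation bins are
    10 min; the detection-rate gate for cross-structure comparisons is 5%.
    """

    recording_path: str | None = None
    trajectory_path: str | None = None
    aims_path: str | None = None
    lesion_side: str = "right"
    hemisphere: str = "lesioned"
    treatment: str | None = None
    injection_time_s: float = 0.0
    peak_window_min: tuple = (40.0, 80.0)
    late_window_min: tuple = (120.0, 160.0)
    band_class: str = "nbg"
    window_s: float = 8.0
    overlap: float = 0.5
    fmax_hz: float = 300.0
    irasa_factors: tuple = spectral.IRASA_FACTORS
    thresholds: nbg.DetectionThresholds = nbg.DetectionThresholds()
    phase_half_width_hz: float = 5.0
    phase_filter_order: int = phase.DEFAULT_FILTER_ORDER
    phase_decimate_s: float = 0.01
    detection_gate: float = 0.05
    rotation_bin_min: float = 10.0
    frame_rate: float = 30.0
    stages: tuple = ALL_STAGES
    seed: int = 0
    output_dir: str | None = None

    def __post_init__(self):
        wins = (*self.peak_window_min, *self.late_window_min)
        if not all(b > a for a, b in zip(wins[::2], wins[1::2])):
            raise ValueError("analysis windows must be ordered (t0 < t1)")
        if self.peak_window_min[1] > self.late_window_min[0]:
            raise ValueError("peak and late windows must not overlap")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    def to_dict(self):
        d = dataclasses.asdict(self)
        d["thresholds"] = dataclasses.asdict(self.thresholds)
        return d

    @property
    def config_hash(self):
        blob = json.dumps(self.to_dict(), sort_keys=True, default=_jsonify)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    @staticmethod
    def from_yaml(path, **overrides):
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update(overrides)
        if "thresholds" in raw and isinstance(raw["thresholds"], dict):
            raw["thresholds"] = nbg.DetectionThresholds(**raw["thresholds"])
        for key in ("peak_window_min", "late_window_min", "stages", "irasa_factors"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return PipelineConfig(**raw)


def _jsonify(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (tuple, set)):
        return list(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


@dataclass
class SessionReport:
    config_hash: str
    seed: int
    treatment: str | None
    stages: dict = field(default_factory=dict)
    timings_s: dict = field(default_factory=dict)

    def to_json(self):
        payload = {"config_hash": self.config_hash, "seed": self.seed,
                   "treatment": self.treatment, "stages": self.stages}
        return json.dumps(payload, sort_keys=True, default=_jsonify)

    @property
    def report_hash(self):
        return hashlib.sha256(self.to_json().encode()).hexdigest()

    def save(self, path):
        Path(path).write_text(self.to_json())


# --------------------------------------------------------------------------
# validation
# --------------------------------------------------------------------------

@dataclass
class ValidationReport:
    fatal: list = field(default_factory=list)
    warnings: list = field(default_factory=list)

    @property
    def ok(self):
        return not self.fatal


def validate_inputs(rec=None, trajectory=None, aims=None,
                    expected_fs=2000.0) -> ValidationReport:
    """Schema and contract checks; distinguishes warnings from fatal errors."""
    rep = ValidationReport()
    if rec is not None:
        mapped = set(rec.channel_map["channel"])
        missing = sorted(set(range(rec.n_channels)) - mapped)
        if missing:
            rep.fatal.append(f"channel map missing channels {missing}")
        bad_h = set(rec.channel_map["hemisphere"]) - {"lesioned", "intact"}
        if bad_h:
            rep.fatal.append(f"invalid hemisphere labels {sorted(bad_h)}")
        if rec.fs != expected_fs:
            rep.warnings.append(
                f"sampling rate {rec.fs} Hz differs from the {expected_fs} Hz "
                "contract; plan: resample before analysis")
    if trajectory is not None:
        need = {"front_x", "front_y", "center_x", "center_y"}
        missing = need - set(trajectory.columns)
        if missing:
            rep.fatal.append(f"trajectory missing columns {sorted(missing)}")
    if aims is not None:
        need = {"t_min", "subtype", "severity", "amplitude"}
        missing = need - set(aims.columns)
        if missing:
            rep.fatal.append(f"AIMs table missing columns {sorted(missing)}")
    return rep


# --------------------------------------------------------------------------
# staged execution
# --------------------------------------------------------------------------

def _round(x, nd=6):
    if isinstance(x, float):
        return round(x, nd)
    return x


def run_pipeline(cfg: PipelineConfig, rec=None, trajectory=None,
                 aims=None) -> SessionReport:
    """Execute the configured stages on one session and build its report.

    Inputs may be passed in memory or loaded from the paths in the config.
    Any stage failure aborts with a :class:`StageError` naming the stage;
    outputs of earlier stages are preserved on the exception.
    """
    if rec is None and cfg.recording_path:
        rec = lio.load_recording(cfg.recording_path)
    if trajectory is None and cfg.trajectory_path:
        trajectory = lio.load_trajectory_csv(cfg.trajectory_path,
                                             frame_rate=cfg.frame_rate)
    if aims is None and cfg.aims_path:
        aims = lio.load_aims_csv(cfg.aims_path)

    val = validate_inputs(rec, trajectory, aims)
    if not val.ok:
        raise StageError("validate", "; ".join(val.fatal))
    for w in val.warnings:
        logger.warning(w)

    report = SessionReport(config_hash=cfg.config_hash, seed=cfg.seed,
                           treatment=(cfg.treatment or
                                      (rec.meta.get("treatment") if rec else None)))
    spectrograms = {}
    tracks = {}

    def stage(name):
        return name in cfg.stages

    try:
        name = "spectral"
        if stage(name) and rec is not None:
            t0 = time.perf_counter()
            for s in rec.structures(cfg.hemisphere):
                chans = rec.channels_of(s, cfg.hemisphere)
                if len(chans) < 2:
                    logger.warning("structure %s has <2 wires; skipped", s)
                    continue
                spectrograms[s] = spectral.structure_normalized_spectrogram(
                    rec, s, hemisphere=cfg.hemisphere, window_s=cfg.window_s,
                    overlap=cfg.overlap, factors=cfg.irasa_factors,
                    fmax=cfg.fmax_hz)
            report.timings_s[name] = time.perf_counter() - t0
            report.stages[name] = {
                s: {"n_windows": int(len(sp.times)),
                    "freq_bins": int(len(sp.freqs))}
                for s, sp in spectrograms.items()}
            logger.info("spectral: %d structures, %.1f s", len(spectrograms),
                        report.timings_s[name])

        name = "detect"
        if stage(name) and spectrograms:
            t0 = time.perf_counter()
            out = {}
            for s, sp in spectrograms.items():
                tr = nbg.track_nbg(sp, s, band_class=cfg.band_class,
                                   thresholds=cfg.thresholds)
                tracks[s] = tr
                out[s] = {"detection_rate": _round(tr.detection_rate),
                          "median_peak_hz": _round(float(tr.median_peak_hz)
                                                   if np.isfinite(tr.median_peak_hz)
                                                   else None or np.nan),
                          "mean_band_power_db": _round(float(np.mean(
                              tr.band_power_series)))}
                if not np.isfinite(tr.median_peak_hz):
                    out[s]["median_peak_hz"] = None
            report.timings_s[name] = time.perf_counter() - t0
            report.stages[name] = out
            logger.info("detect: %d tracks, %.1f s", len(tracks),
                        report.timings_s[name])

        name = "phase"
        if stage(name) and rec is not None:
            t0 = time.perf_counter()
            meds = [t.median_peak_hz for t in tracks.values()
                    if np.isfinite(t.median_peak_hz)]
            lo, hi = nbg.BAND_CLASSES[cfg.band_class]
            center = float(np.median(meds)) if meds else 0.5 * (lo + hi)
            duration_min = rec.duration_s / 60.0
            window = None
            if duration_min >= cfg.late_window_min[1]:
                window = tuple(m * 60.0 for m in cfg.late_window_min)
            km = phase.kappa_matrix(
                rec, center, hemisphere=cfg.hemisphere, window_s=window,
                half_width_hz=cfg.phase_half_width_hz,
                order=cfg.phase_filter_order, decimate_s=cfg.phase_decimate_s)
            report.timings_s[name] = time.perf_counter() - t0
            report.stages[name] = {
                "center_hz": _round(center),
                "window_s": list(window) if window else None,
                "kappa": {f"{a}|{b}": _round(v)
                          for (a, b), v in sorted(km.entries.items())}}
            logger.info("phase: %d pairs, %.1f s", len(km.entries),
                        report.timings_s[name])

        name = "behavior"
        if stage(name) and (trajectory is not None or aims is not None):
            t0 = time.perf_counter()
            out = {}
            if trajectory is not None:
                sm = bh.smooth_coordinates(trajectory, frame_rate=cfg.frame_rate)
                ang = bh.heading_angle(sm)
                ev = bh.detect_rotations(ang, cfg.frame_rate, cfg.lesion_side)
                span = max(180.0, len(ang) / cfg.frame_rate / 60.0)
                ev = bh.bin_rotations(ev, session_span_min=span,
                                      bin_min=cfg.rotation_bin_min,
                                      t0_s=cfg.injection_time_s)
                out["rotations"] = {
                    "n_contra": ev.count("contra"), "n_ipsi": ev.count("ipsi"),
                    "bins": ev.bins.tolist(),
                    "peak_mean_per_min": _round(ev.peak_mean),
                    "late_mean_per_min": _round(ev.late_mean)}
            if aims is not None:
                ga = bh.global_aims(aims)
                out["aims"] = {
                    "global": [_round(float(v)) for v in ga["global"]],
                    "t_min": [float(v) for v in ga["t_min"]],
                    "peak_mean": _round(ga.attrs["peak_mean"]),
                    "late_mean": _round(ga.attrs["late_mean"])}
                if "nbg" in tracks or tracks:
                    best = max(tracks.values(), key=lambda t: t.detection_rate)
                    corr = nbg.aims_gamma_correlation(best, aims)
                    out["aims_gamma_r"] = (_round(corr.r) if corr.defined
                                           else None)
            report.timings_s[name] = time.perf_counter() - t0
            report.stages[name] = out

        name = "brainstate"
        if stage(name) and rec is not None:
            t0 = time.perf_counter()
            out = {}
            duration_min = rec.duration_s / 60.0
            for label, win in (("peak", cfg.peak_window_min),
                               ("late", cfg.late_window_min)):
                if duration_min < win[1]:
                    continue
                per = {}
                for s in rec.structures(cfg.hemisphere):
                    sp = bs.state_spectrum(rec, s, period_min=win,
                                           hemisphere=cfg.hemisphere,
                                           factors=cfg.irasa_factors)
                    per[s] = {"n_windows": sp.n_windows,
                              "normalized_db": [
                                  _round(float(v)) for v in sp.normalized_db]}
                out[label] = per
            report.timings_s[name] = time.perf_counter() - t0
            report.stages[name] = out
    except StageError:
        raise
    except Exception as exc:
        raise StageError(name, exc, partial_report=report) from exc

    if cfg.output_dir:
        outdir = Path(cfg.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        report.save(outdir / "report.json")
        for s, tr in tracks.items():
            tr.to_frame().to_csv(outdir / f"nbg_{s}.csv", index=False)
    return report
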