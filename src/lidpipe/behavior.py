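"""Rotational behavior from pose tracking and AIMs score aggregation.

Rotation counting follows the sector-crossing rule used for drug-induced
circling in hemiparkinsonian rodents: the heading angle (front body point
relative to the body center) is tracked through a circle divided into eight
45-degree sectors; a rotation is counted only when the angle advances through
all eight sectors in one direction without reversal, and incomplete arcs are
discarded.  Direction is mapped to contraversive/ipsiversive by the lesion
side (counter-clockwise in y-up image coordinates is contraversive for a
right-side lesion).

The AIMs (abnormal involuntary movements) arithmetic implements the ALO
global score: per observation, severity (0, 1, 2, 2.5) times amplitude
(1-4) summed over the axial, limb and orolingual subtypes, giving a global
score in [0, 30]; observations occur once per 10-min interval over 180 min.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

__all__ = [
    "RotationEvents",
    "smooth_coordinates",
    "heading_angle",
    "detect_rotations",
    "bin_rotations",
    "global_aims",
    "PEAK_WINDOW_MIN",
    "LATE_WINDOW_MIN",
]

PEAK_WINDOW_MIN = (40.0, 80.0)
LATE_WINDOW_MIN = (120.0, 160.0)

SEVERITY_SCALE = {0.0, 1.0, 2.0, 2.5}
AMPLITUDE_SCALE = {1, 2, 3, 4}
SUBTYPES = ("axial", "limb", "orolingual")


def smooth_coordinates(traj: pd.DataFrame, frame_rate=None, cutoff_hz=5.0,
                       likelihood_min=0.6) -> pd.DataFrame:
    """Zero-phase low-pass smoothing of the front/center coordinate columns.

    Frames with a tracking-confidence column below `likelihood_min` are
    linearly interpolated from their neighbours before filtering.
    """
    if frame_rate is None:
        frame_rate = float(traj.attrs.get("frame_rate", 30.0))
    if frame_rate <= 2.0 * cutoff_hz:
        raise ValueError("frame rate must exceed twice the smoothing cutoff")
    out = traj.copy()
    cols = ["front_x", "front_y", "center_x", "center_y"]
    if "likelihood" in out.columns:
        bad = out["likelihood"].to_numpy() < likelihood_min
        if bad.any():
            for c in cols:
                v = out[c].to_numpy(dtype=float)
                v[bad] = np.nan
                out[c] = pd.Series(v).interpolate(limit_direction="both").to_numpy()
    sos = signal.butter(4, cutoff_hz, btype="low", fs=frame_rate, output="sos")
    for c in cols:
        out[c] = signal.sosfiltfilt(sos, out[c].to_numpy(dtype=float))
    out.attrs["frame_rate"] = frame_rate
    return out


def heading_angle(traj: pd.DataFrame) -> np.ndarray:
    """atan2 of (front - center) per frame, wrapped to (-pi, pi].

    Frames where front and center coincide are returned as NaN.
    """
    dx = traj["front_x"].to_numpy(dtype=float) - traj["center_x"].to_numpy(dtype=float)
    dy = traj["front_y"].to_numpy(dtype=float) - traj["center_y"].to_numpy(dtype=float)
    ang = np.arctan2(dy, dx)
    ang[(dx == 0) & (dy == 0)] = np.nan
    return ang


@dataclass
class RotationEvents:
    events: list                       # (completion time s, 'contra' | 'ipsi')
    frame_rate: float
    bins: np.ndarray | None = None     # contra counts per 10-min bin
    bin_edges_min: np.ndarray | None = None
    peak_mean: float = np.nan          # contra counts/min, 40-80 min
    late_mean: float = np.nan          # contra counts/min, 120-160 min

    def count(self, direction):
        return sum(1 for _, d in self.events if d == direction)


def detect_rotations(angles, frame_rate, lesion_side, n_sectors=8,
                     hysteresis_deg=5.0, max_undefined_frac=0.05) -> RotationEvents:
    """Count complete rotations of the heading angle via sector crossings.

    The unwrapped angle is quantized into `n_sectors` sectors (sector 0
    centered on angle 0) with `hysteresis_deg` of hysteresis at each boundary
    to suppress jitter-induced transitions.  Consecutive same-direction
    crossings accumulate; reaching `n_sectors` registers a rotation and
    resets the accumulator, while any reversal resets it to the new
    direction.  Undefined frames are interpolated; more than
    `max_undefined_frac` of them is an error.

    `lesion_side` ('left' | 'right') maps signed rotations onto the
    contraversive/ipsiversive labels; there is deliberately no default.
    """
    if lesion_side not in ("left", "right"):
        raise ValueError("lesion_side must be 'left' or 'right'")
    a = np.asarray(angles, dtype=float)
    bad = ~np.isfinite(a)
    if bad.mean() > max_undefined_frac:
        raise ValueError("too many undefined heading frames")
    if bad.any():
        a = pd.Series(a).interpolate(limit_direction="both").to_numpy()
    a = np.unwrap(a)

    sector_width = 2.0 * np.pi / n_sectors
    hyst = np.deg2rad(hysteresis_deg)
    # boundaries of sector k on the unwrapped axis sit at (k +/- 1/2) * width;
    # sector 0 is centered on angle 0
    level = int(np.floor((a[0] + sector_width / 2.0) / sector_width))
    run = 0
    run_dir = 0
    contra_sign = +1 if lesion_side == "right" else -1
    events = []
    for idx in range(1, len(a)):
        x = a[idx]
        while x > (level + 0.5) * sector_width + hyst:
            level += 1
            if run_dir == +1:
                run += 1
            else:
                run_dir, run = +1, 1
            if run == n_sectors:
                events.append((idx / frame_rate,
                               "contra" if contra_sign > 0 else "ipsi"))
                run = 0
        while x < (level - 0.5) * sector_width - hyst:
            level -= 1
            if run_dir == -1:
                run += 1
            else:
                run_dir, run = -1, 1
            if run == n_sectors:
                events.append((idx / frame_rate,
                               "contra" if contra_sign < 0 else "ipsi"))
                run = 0
    return RotationEvents(events=events, frame_rate=frame_rate)


def bin_rotations(events: RotationEvents, session_span_min=180.0,
                  bin_min=10.0, t0_s=0.0) -> RotationEvents:
    """Contra rotation counts per non-overlapping 10-min bin plus window means.

    Events are timed relative to levodopa administration (`t0_s`); events
    before it are excluded.  Bins are half-open [t, t + bin) so boundary
    events land in the later bin.  Peak and late means are counts per minute
    over 40-80 and 120-160 min.
    """
    edges = np.arange(0.0, session_span_min + 1e-9, bin_min)
    t_min = np.array([(t - t0_s) / 60.0 for t, d in events.events
                      if d == "contra"])
    t_min = t_min[t_min >= 0.0]
    counts, _ = np.histogram(t_min, bins=edges)

    def window_mean(win):
        lo, hi = win
        inw = (t_min >= lo) & (t_min < hi)
        return float(inw.sum() / (hi - lo))

    return RotationEvents(events=events.events, frame_rate=events.frame_rate,
                          bins=counts, bin_edges_min=edges,
                          peak_mean=window_mean(PEAK_WINDOW_MIN),
                          late_mean=window_mean(LATE_WINDOW_MIN))


def global_aims(obs: pd.DataFrame) -> pd.DataFrame:
    """Global ALO score per observation time: sum of severity x amplitude.

    Input rows carry (t_min, subtype, severity, amplitude).  Values off the
    printed scales raise a validation error naming the row.  Returns one row
    per t_min with the global score and per-subtype products, plus peak/late
    window means in the frame attrs.
    """
    for idx, row in obs.iterrows():
        if float(row["severity"]) not in SEVERITY_SCALE:
            raise ValueError(f"row {idx}: severity {row['severity']} not on "
                             "the 0/1/2/2.5 scale")
        if int(row["amplitude"]) not in AMPLITUDE_SCALE:
            raise ValueError(f"row {idx}: amplitude {row['amplitude']} not in 1-4")
        if row["subtype"] not in SUBTYPES:
            raise ValueError(f"row {idx}: unknown subtype {row['subtype']!r}")
    prod = obs.assign(product=obs["severity"].astype(float)
                      * obs["amplitude"].astype(float))
    table = prod.pivot_table(index="t_min", columns="subtype", values="product",
                             aggfunc="sum").fillna(0.0)
    table["global"] = table.sum(axis=1)
    if (table["global"] > 30.0 + 1e-9).any():
        raise ValueError("global AIMs score exceeds the scale maximum of 30")
    out = table.reset_index()

    def window_mean(win):
        lo, hi = win
        inw = (out["t_min"] > lo) & (out["t_min"] <= hi)
        return float(out.loc[inw, "global"].mean()) if inw.any() else np.nan

    out.attrs["peak_mean"] = window_mean(PEAK_WINDOW_MIN)
    out.attrs["late_mean"] = window_mean(LATE_WINDOW_MIN)
    return out
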