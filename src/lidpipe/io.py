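"""File formats: HDF5 recording containers, pose/AIMs CSV tables, ground truth JSON.

Recordings are stored as HDF5 with datasets ``/data`` (channels x samples,
float32), ``/fs`` and ``/channel_map`` (channel, structure, hemisphere), and
session metadata in root attributes.  A flat binary + JSON sidecar variant is
provided for interoperability.  Pose tables are read either from
DeepLabCut-style CSVs (three header rows: scorer / bodyparts / coords) or
from a plain table with front/center x-y columns.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .synth import GroundTruth, Recording

__all__ = [
    "save_recording", "load_recording",
    "save_recording_flat", "load_recording_flat",
    "save_trajectory_csv", "load_trajectory_csv",
    "save_aims_csv", "load_aims_csv",
    "save_ground_truth", "load_ground_truth",
]


def save_recording(path, rec: Recording, dtype="float32"):
    with h5py.File(path, "w") as h5:
        h5.create_dataset("data", data=rec.data.astype(dtype))
        h5.create_dataset("fs", data=float(rec.fs))
        cm = rec.channel_map
        h5.create_dataset("channel_map/channel", data=cm["channel"].to_numpy(int))
        h5.create_dataset("channel_map/structure",
                          data=np.array(cm["structure"], dtype="S32"))
        h5.create_dataset("channel_map/hemisphere",
                          data=np.array(cm["hemisphere"], dtype="S16"))
        h5.attrs["meta"] = json.dumps(rec.meta, sort_keys=True)


def load_recording(path) -> Recording:
    with h5py.File(path, "r") as h5:
        data = np.asarray(h5["data"], dtype=np.float64)
        fs = float(h5["fs"][()])
        cm = pd.DataFrame({
            "channel": np.asarray(h5["channel_map/channel"], dtype=int),
            "structure": [s.decode() for s in h5["channel_map/structure"]],
            "hemisphere": [s.decode() for s in h5["channel_map/hemisphere"]],
        })
        meta = json.loads(h5.attrs.get("meta", "{}"))
    return Recording(data=data, fs=fs, channel_map=cm, meta=meta)


def save_recording_flat(path, rec: Recording, dtype="float32"):
    """Flat binary (channels x samples, row-major) with a JSON sidecar."""
    path = Path(path)
    rec.data.astype(dtype).tofile(path)
    sidecar = {
        "fs": rec.fs, "dtype": dtype, "n_channels": rec.n_channels,
        "n_samples": rec.data.shape[1],
        "channel_map": rec.channel_map.to_dict(orient="records"),
        "meta": rec.meta,
    }
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, sort_keys=True, indent=1))


def load_recording_flat(path) -> Recording:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    data = np.fromfile(path, dtype=sidecar["dtype"]).reshape(
        sidecar["n_channels"], sidecar["n_samples"]).astype(np.float64)
    return Recording(data=data, fs=float(sidecar["fs"]),
                     channel_map=pd.DataFrame(sidecar["channel_map"]),
                     meta=sidecar.get("meta", {}))


# --------------------------------------------------------------------------
# pose tables
# --------------------------------------------------------------------------

def save_trajectory_csv(path, traj: pd.DataFrame, style="plain"):
    """Write a pose table; `style='dlc'` emits the DeepLabCut 3-row header."""
    if style == "plain":
        out = traj.copy()
        out.attrs = {}
        out.to_csv(path, index=False)
        return
    parts = {"front": ("front_x", "front_y"), "center": ("center_x", "center_y")}
    cols = []
    data = {}
    for part, (cx, cy) in parts.items():
        for coord, src in zip(("x", "y"), (cx, cy)):
            cols.append(("tracker", part, coord))
            data[("tracker", part, coord)] = traj[src].to_numpy()
        cols.append(("tracker", part, "likelihood"))
        lk = traj["likelihood"].to_numpy() if "likelihood" in traj else np.ones(len(traj))
        data[("tracker", part, "likelihood")] = lk
    df = pd.DataFrame(data, columns=pd.MultiIndex.from_tuples(
        cols, names=["scorer", "bodyparts", "coords"]))
    df.to_csv(path, index_label="frame")


def load_trajectory_csv(path, frame_rate=30.0, front_parts=None,
                        center_parts=None) -> pd.DataFrame:
    """Read a pose table (auto-detects DeepLabCut multi-header vs plain CSV).

    For DeepLabCut tables the `front_parts` / `center_parts` body-part name
    lists are averaged into the front and center points (defaults: any of
    nose/mouth/ears/head for the front, tail_base/body_center/center for the
    center).
    """
    head = pd.read_csv(path, nrows=3, header=None)
    is_dlc = str(head.iloc[1, 1]).strip().lower() in {"bodyparts"} or \
        str(head.iloc[0, 0]).strip().lower() == "scorer"
    if not is_dlc:
        df = pd.read_csv(path)
        df.attrs["frame_rate"] = frame_rate
        return df
    df = pd.read_csv(path, header=[0, 1, 2], index_col=0)
    parts = df.columns.get_level_values(1)
    if front_parts is None:
        front_parts = [p for p in set(parts)
                       if p.lower() in {"nose", "mouth", "ear_left", "ear_right",
                                        "ears", "head", "front"}]
    if center_parts is None:
        center_parts = [p for p in set(parts)
                        if p.lower() in {"tail_base", "tailbase", "body_center",
                                         "bodycenter", "center"}]
    if not front_parts or not center_parts:
        raise ValueError("could not identify front/center body parts")

    def avg(ps, coord):
        cols = [c for c in df.columns if c[1] in ps and c[2] == coord]
        return df[cols].mean(axis=1).to_numpy()

    out = pd.DataFrame({
        "front_x": avg(front_parts, "x"), "front_y": avg(front_parts, "y"),
        "center_x": avg(center_parts, "x"), "center_y": avg(center_parts, "y"),
    })
    lk = [c for c in df.columns if c[2] == "likelihood"]
    if lk:
        out["likelihood"] = df[lk].min(axis=1).to_numpy()
    out.attrs["frame_rate"] = frame_rate
    return out


# --------------------------------------------------------------------------
# AIMs and ground truth
# --------------------------------------------------------------------------

def save_aims_csv(path, aims: pd.DataFrame):
    aims.to_csv(path, index=False)


def load_aims_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    need = {"t_min", "subtype", "severity", "amplitude"}
    missing = need - set(df.columns)
    if missing:
        raise ValueError(f"AIMs table missing columns: {sorted(missing)}")
    return df


def save_ground_truth(path, truth: GroundTruth):
    payload = {
        "window_starts_s": truth.window_starts_s.tolist(),
        "nbg_window_flags": truth.nbg_window_flags.astype(int).tolist(),
        "true_peak_freq": [None if not np.isfinite(v) else float(v)
                           for v in truth.true_peak_freq],
        "true_kappa": [{"pair": sorted(k), "kappa": v}
                       for k, v in sorted(truth.true_kappa.items(),
                                          key=lambda kv: sorted(kv[0]))],
        "true_rotations": [[float(t), d] for t, d in truth.true_rotations],
    }
    Path(path).write_text(json.dumps(payload, sort_keys=True, indent=1))


def load_ground_truth(path) -> GroundTruth:
    p = json.loads(Path(path).read_text())
    return GroundTruth(
        window_starts_s=np.array(p["window_starts_s"], dtype=float),
        nbg_window_flags=np.array(p["nbg_window_flags"], dtype=bool),
        true_peak_freq=np.array([np.nan if v is None else v
                                 for v in p["true_peak_freq"]], dtype=float),
        true_kappa={frozenset(e["pair"]): float(e["kappa"])
                    for e in p["true_kappa"]},
        true_rotations=[(float(t), d) for t, d in p["true_rotations"]],
    )
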