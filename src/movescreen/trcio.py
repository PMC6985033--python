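"""Text and container I/O for marker trials and channel series.

Marker trials round-trip through TRC-style tab-delimited files (the
motion-capture community's plain-text trajectory format: a header block
with sampling rate and marker names, then one row per frame of
``Frame#  Time  X1 Y1 Z1  X2 Y2 Z2 ...``) with a sidecar label file
(``frame,label`` CSV).  Whole cohorts persist to a compact ``.npz``
container.  Simulated-IMU series export to tidy CSV.
"""

from __future__ import annotations

import io
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import MarkerTrial

__all__ = [
    "write_trc",
    "read_trc",
    "write_labels",
    "read_labels",
    "save_cohort",
    "load_cohort",
    "imu_series_to_frame",
]


def write_trc(trial: MarkerTrial, path: str | Path) -> None:
    """Write a trial's marker trajectories as a TRC-style text file."""
    path = Path(path)
    n_frames, n_markers, _ = trial.coords.shape
    fs = trial.fs
    buf = io.StringIO()
    buf.write(f"PathFileType\t4\t(X/Y/Z)\t{path.name}\n")
    buf.write("DataRate\tCameraRate\tNumFrames\tNumMarkers\tUnits\t"
              "OrigDataRate\tOrigDataStartFrame\tOrigNumFrames\n")
    buf.write(f"{fs:g}\t{fs:g}\t{n_frames}\t{n_markers}\tm\t{fs:g}\t1\t{n_frames}\n")
    buf.write("Frame#\tTime\t" + "\t\t\t".join(trial.marker_names) + "\t\t\n")
    buf.write("\t\t" + "\t".join(
        f"X{i + 1}\tY{i + 1}\tZ{i + 1}" for i in range(n_markers)) + "\n")
    flat = trial.coords.reshape(n_frames, -1)
    for f in range(n_frames):
        row = "\t".join(f"{v:.8f}" for v in flat[f])
        buf.write(f"{f + 1}\t{f / fs:.6f}\t{row}\n")
    path.write_text(buf.getvalue())


def read_trc(path: str | Path, labels_path: str | Path | None = None,
             athlete_id: str = "athlete") -> MarkerTrial:
    """Read a TRC-style file (optionally with a sidecar label file)."""
    lines = Path(path).read_text().splitlines()
    header = lines[2].split("\t")
    fs = float(header[0])
    n_frames = int(header[2])
    n_markers = int(header[3])
    name_row = lines[3].split("\t")
    marker_names = tuple(n for n in name_row[2:] if n.strip())
    if len(marker_names) != n_markers:
        raise ValueError(f"{path}: expected {n_markers} marker names, "
                         f"found {len(marker_names)}")
    data = np.empty((n_frames, 3 * n_markers))
    for i, line in enumerate(lines[5:5 + n_frames]):
        parts = line.split("\t")
        data[i] = [float(v) for v in parts[2:2 + 3 * n_markers]]
    coords = data.reshape(n_frames, n_markers, 3)
    if labels_path is not None:
        labels = read_labels(labels_path, n_frames)
    else:
        labels = np.full(n_frames, "Null", dtype="U8")
    return MarkerTrial(athlete_id=athlete_id, coords=coords, fs=fs,
                       frame_labels=labels, marker_names=marker_names)


def write_labels(trial: MarkerTrial, path: str | Path) -> None:
    """Write the per-frame label sidecar (``frame,label`` CSV)."""
    pd.DataFrame({"frame": np.arange(trial.n_frames),
                  "label": trial.frame_labels}).to_csv(path, index=False)


def read_labels(path: str | Path, n_frames: int | None = None) -> np.ndarray:
    df = pd.read_csv(path)
    labels = df["label"].to_numpy(dtype="U8")
    if n_frames is not None and len(labels) != n_frames:
        raise ValueError(f"{path}: {len(labels)} labels for {n_frames} frames")
    return labels


def save_cohort(cohort: dict[str, list[MarkerTrial]], path: str | Path) -> None:
    """Persist a cohort to a compact ``.npz`` container."""
    arrays: dict[str, np.ndarray] = {}
    meta_rows = []
    for athlete_id, trials in cohort.items():
        for t_idx, trial in enumerate(trials):
            key = f"{athlete_id}__{t_idx}"
            arrays[f"coords_{key}"] = trial.coords
            arrays[f"labels_{key}"] = trial.frame_labels.astype("U8")
            meta_rows.append((athlete_id, t_idx, trial.fs, trial.movement_label))
    arrays["__meta__"] = np.array(
        [f"{a}\t{i}\t{fs}\t{mv}" for a, i, fs, mv in meta_rows], dtype="U64")
    arrays["__markers__"] = np.array(
        next(iter(cohort.values()))[0].marker_names, dtype="U16")
    np.savez_compressed(path, **arrays)


def load_cohort(path: str | Path) -> dict[str, list[MarkerTrial]]:
    cohort: dict[str, list[MarkerTrial]] = {}
    with np.load(path, allow_pickle=False) as z:
        markers = tuple(str(m) for m in z["__markers__"])
        for row in z["__meta__"]:
            athlete_id, t_idx, fs, movement = str(row).split("\t")
            key = f"{athlete_id}__{t_idx}"
            trial = MarkerTrial(
                athlete_id=athlete_id,
                coords=z[f"coords_{key}"],
                fs=float(fs),
                frame_labels=z[f"labels_{key}"],
                marker_names=markers,
                movement_label=movement,
            )
            cohort.setdefault(athlete_id, []).append(trial)
    return cohort


def imu_series_to_frame(series) -> pd.DataFrame:
    """Tidy (frame, time, segment, channel, value, label) export of an IMU series."""
    n, c = series.data.shape
    frames = np.repeat(np.arange(n), c)
    chans = np.tile(np.array(series.channel_names), n)
    segs = np.array([name.split(":")[0] for name in series.channel_names])
    return pd.DataFrame({
        "frame": frames,
        "time": frames / series.fs,
        "segment": np.tile(segs, n),
        "channel": chans,
        "value": series.data.ravel(),
        "label": np.repeat(series.frame_labels, c),
    })
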