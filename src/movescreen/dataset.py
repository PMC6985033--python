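"""Athlete-level splits, training-set normalization, and sliding windows.

The dataset pipeline follows the standard protocol: athletes (never trials)
are randomly partitioned into training / validation / test subsets; every
channel is z-normalized with the mean and standard deviation of all
training frames pooled across athletes and movements; trials are
concatenated into one continuous labeled matrix per subset; and a sliding
window of fixed length with stride = window/4 cuts the matrix into
classifier inputs, each labeled by the majority frame label it contains.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .synthetic import NULL_LABEL, SCREEN_TASK_CODES

__all__ = [
    "SplitSpec",
    "NormalizationStats",
    "WindowSpec",
    "WindowedDataset",
    "ConcatenatedSeries",
    "DEFAULT_VOCABULARY",
    "split_athletes",
    "fit_normalization",
    "concatenate_athlete_trials",
    "make_windows",
]

#: 13 screen movements + Null — the default 14-class vocabulary.
DEFAULT_VOCABULARY: tuple[str, ...] = SCREEN_TASK_CODES + (NULL_LABEL,)


@dataclass(frozen=True)
class SplitSpec:
    """Athlete-level split: ``train_fraction`` to training, remainder halved
    (floor to validation, ceil to test)."""

    train_fraction: float = 2.0 / 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")


def split_athletes(athlete_ids: list[str], spec: SplitSpec = SplitSpec()
                   ) -> tuple[list[str], list[str], list[str]]:
    """Randomly partition athlete ids into (train, validation, test).

    With the default 2/3 fraction, n = 417 gives (278, 69, 70), matching
    the full-scale subset counts.  Raises for fewer than 3 athletes.
    """
    ids = list(athlete_ids)
    n = len(ids)
    if n < 3:
        raise ValueError("need at least 3 athletes to split")
    rng = np.random.default_rng(spec.seed)
    order = rng.permutation(n)
    shuffled = [ids[i] for i in order]
    n_train = math.floor(n * spec.train_fraction + 1e-12)
    rem = n - n_train
    n_val = rem // 2
    train = shuffled[:n_train]
    val = shuffled[n_train:n_train + n_val]
    test = shuffled[n_train + n_val:]
    return train, val, test


@dataclass
class NormalizationStats:
    """Per-channel mean/sd fitted on training frames only."""

    mean: np.ndarray
    sd: np.ndarray
    epsilon: float = 1e-8

    def apply(self, x: np.ndarray) -> np.ndarray:
        return (np.asarray(x, dtype=float) - self.mean) / self.sd


def fit_normalization(training: np.ndarray, epsilon: float = 1e-8) -> NormalizationStats:
    """Pool all training frames and compute per-channel mean and sd.

    Constant channels get their sd floored at ``epsilon`` so they normalize
    to exactly zero rather than dividing by zero.
    """
    x = np.asarray(training, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("training matrix must be (frames >= 2, channels)")
    mean = x.mean(axis=0)
    sd = x.std(axis=0)
    sd = np.maximum(sd, epsilon)
    return NormalizationStats(mean=mean, sd=sd, epsilon=epsilon)


@dataclass
class ConcatenatedSeries:
    """Trials of one subset (or one athlete) stacked into a single matrix."""

    data: np.ndarray             # (frames, channels)
    frame_labels: np.ndarray     # (frames,) str codes
    boundaries: list[int]        # start frame of each source trial
    fs: float
    channel_names: list[str] | None = None


def concatenate_athlete_trials(trials: list) -> ConcatenatedSeries:
    """Row-concatenate labeled trials into one continuous series.

    Accepts any objects exposing ``channel_matrix()``, ``frame_labels`` and
    ``fs`` (both :class:`MarkerTrial` and :class:`SimulatedIMUSeries` do).
    Trial boundaries are recorded for bookkeeping.
    """
    if not trials:
        raise ValueError("no trials to concatenate")
    fs = trials[0].fs
    mats, labels, bounds = [], [], []
    n_ch = None
    offset = 0
    for t in trials:
        m = t.channel_matrix()
        if n_ch is None:
            n_ch = m.shape[1]
        elif m.shape[1] != n_ch:
            raise ValueError(
                f"channel mismatch: expected {n_ch}, got {m.shape[1]}")
        if t.fs != fs:
            raise ValueError("sampling-rate mismatch between trials")
        bounds.append(offset)
        offset += m.shape[0]
        mats.append(m)
        labels.append(np.asarray(t.frame_labels))
    names = t.channel_names() if hasattr(t, "channel_names") and callable(
        getattr(t, "channel_names")) else getattr(t, "channel_names", None)
    return ConcatenatedSeries(
        data=np.concatenate(mats, axis=0),
        frame_labels=np.concatenate(labels),
        boundaries=bounds,
        fs=fs,
        channel_names=list(names) if names is not None else None,
    )


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window geometry; stride defaults to window/4."""

    window_frames: int = 48
    stride_frames: int | None = None

    def __post_init__(self) -> None:
        if self.window_frames < 1:
            raise ValueError("window_frames must be positive")
        if self.stride_frames is None:
            if self.window_frames % 4 != 0:
                raise ValueError(
                    "window_frames must be divisible by 4 for the default stride")
            object.__setattr__(self, "stride_frames", self.window_frames // 4)
        elif self.stride_frames < 1:
            raise ValueError("stride_frames must be positive")


@dataclass
class WindowedDataset:
    """Fixed-length windows with majority labels and source bookkeeping."""

    windows: np.ndarray              # (n_windows, window_frames, channels)
    labels: np.ndarray               # (n_windows,) int class indices
    window_start_frames: np.ndarray  # (n_windows,)
    vocabulary: tuple[str, ...]
    spec: WindowSpec

    @property
    def n_windows(self) -> int:
        return self.windows.shape[0]

    @property
    def n_channels(self) -> int:
        return self.windows.shape[2]


def window_count(n_frames: int, spec: WindowSpec) -> int:
    if n_frames < spec.window_frames:
        return 0
    return (n_frames - spec.window_frames) // spec.stride_frames + 1


def make_windows(
    data: np.ndarray,
    frame_labels: np.ndarray,
    spec: WindowSpec,
    vocabulary: tuple[str, ...] = DEFAULT_VOCABULARY,
    dtype=np.float32,
) -> WindowedDataset:
    """Cut a labeled channel matrix into majority-labeled sliding windows.

    Windows start at 0, stride, 2*stride, ...; trailing frames that do not
    fill a complete window are dropped.  Each window takes the most
    frequent frame label it contains; ties prefer a movement class over
    ``"Null"``, then the label occurring earliest within the window.
    """
    x = np.asarray(data)
    labels = np.asarray(frame_labels)
    n = x.shape[0]
    if n < spec.window_frames:
        raise ValueError(
            f"series of {n} frames is shorter than one window ({spec.window_frames})")
    vocab_index = {c: i for i, c in enumerate(vocabulary)}
    try:
        lab_idx = np.array([vocab_index[str(c)] for c in labels], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"frame label {exc.args[0]!r} not in vocabulary") from None
    null_idx = vocab_index.get(NULL_LABEL, -1)

    n_win = window_count(n, spec)
    starts = np.arange(n_win) * spec.stride_frames
    win = np.stack([x[s:s + spec.window_frames] for s in starts]).astype(dtype)

    win_labels = np.empty(n_win, dtype=np.int64)
    k = len(vocabulary)
    for w, s in enumerate(starts):
        seg = lab_idx[s:s + spec.window_frames]
        counts = np.bincount(seg, minlength=k)
        best = counts.max()
        cands = np.flatnonzero(counts == best)
        if len(cands) > 1 and null_idx in cands:
            cands = cands[cands != null_idx]
        if len(cands) == 1:
            win_labels[w] = cands[0]
        else:
            # earliest occurrence within the window wins
            first_pos = {c: np.argmax(seg == c) for c in cands}
            win_labels[w] = min(cands, key=lambda c: first_pos[c])
    return WindowedDataset(
        windows=win,
        labels=win_labels,
        window_start_frames=starts,
        vocabulary=tuple(vocabulary),
        spec=spec,
    )
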