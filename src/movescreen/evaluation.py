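"""Frame-level evaluation, hyperparameter grids and the sensor ablation.

Window probabilities are fused into per-frame labels by averaging, for
each frame, the class-probability vectors of every window containing it
(argmax with ties to the lowest class index).  Frame-level confusion
matrices then yield per-class precision/recall/F1 and micro/macro
averages; the micro-averaged F1 equals micro precision, micro recall and
plain accuracy for single-label multiclass data, and that identity is
relied on throughout.

The two-stage hyperparameter search follows the standard protocol: the
SGD learning rate and momentum are tuned first on a fixed architecture
(5 x 5 grid), then the architecture parameters (window size with its
paired kernel options, convolution channels, LSTM cells) are tuned with
the winning learning parameters.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .dataset import (
    ConcatenatedSeries,
    NormalizationStats,
    WindowSpec,
    concatenate_athlete_trials,
    fit_normalization,
    make_windows,
)
from .nn import (
    ModelConfig,
    TrainConfig,
    TrainedModel,
    build_model,
    predict_window_proba,
    train_model,
)
from .sensors import SENSOR_CONFIGS, select_sensor_config
from .synthetic import MIRROR_CODE, NULL_LABEL

__all__ = [
    "LearningGrid",
    "ArchitectureGrid",
    "EvaluationReport",
    "frame_fusion",
    "confusion_matrix",
    "precision_recall_f1",
    "lr_confusion_rate",
    "grid_search_learning",
    "grid_search_architecture",
    "evaluate_athlete",
    "aggregate_reports",
    "run_sensor_ablation",
]


# --------------------------------------------------------------------- #
# fusion and metrics

def frame_fusion(
    window_probs: np.ndarray,
    window_starts: np.ndarray,
    sws: int,
    n_frames: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Average window probabilities into per-frame distributions.

    Each frame's distribution is the arithmetic mean of the probability
    vectors of all windows containing it; the frame label is the argmax
    (ties to the lowest class index).  Frames covered by no window inherit
    the distribution of the nearest covered frame.

    Returns ``(frame_classes, frame_probs)``.
    """
    probs = np.asarray(window_probs, dtype=float)
    starts = np.asarray(window_starts, dtype=int)
    if probs.ndim != 2 or probs.shape[0] == 0:
        raise ValueError("need at least one window probability vector")
    if probs.shape[0] != starts.shape[0]:
        raise ValueError("window_probs and window_starts length mismatch")
    k = probs.shape[1]
    sums = np.zeros((n_frames, k))
    counts = np.zeros(n_frames)
    for p, s in zip(probs, starts):
        hi = min(s + sws, n_frames)
        if hi > s:
            sums[s:hi] += p
            counts[s:hi] += 1.0
    covered = counts > 0
    if not covered.any():
        raise ValueError("no window covers any frame")
    cov_idx = np.flatnonzero(covered)
    frame_probs = np.empty_like(sums)
    frame_probs[covered] = sums[covered] / counts[covered, None]
    if not covered.all():
        # nearest covered frame (ties toward the earlier frame)
        uncov = np.flatnonzero(~covered)
        pos = np.searchsorted(cov_idx, uncov)
        left = np.clip(pos - 1, 0, len(cov_idx) - 1)
        right = np.clip(pos, 0, len(cov_idx) - 1)
        d_left = np.abs(uncov - cov_idx[left])
        d_right = np.abs(cov_idx[right] - uncov)
        nearest = np.where(d_left <= d_right, cov_idx[left], cov_idx[right])
        frame_probs[uncov] = frame_probs[nearest]
    return frame_probs.argmax(axis=1), frame_probs


def confusion_matrix(
    true_labels: np.ndarray,
    pred_labels: np.ndarray,
    vocabulary: tuple[str, ...],
) -> np.ndarray:
    """Count matrix with rows = true class, columns = predicted class.

    Labels may be class names or integer indices into ``vocabulary``.
    """
    k = len(vocabulary)

    def to_idx(arr):
        arr = np.asarray(arr)
        if np.issubdtype(arr.dtype, np.integer):
            if arr.size and (arr.min() < 0 or arr.max() >= k):
                raise ValueError("label index outside vocabulary")
            return arr.astype(np.int64)
        index = {c: i for i, c in enumerate(vocabulary)}
        try:
            return np.array([index[str(v)] for v in arr], dtype=np.int64)
        except KeyError as exc:
            raise ValueError(f"label {exc.args[0]!r} not in vocabulary") from None

    t = to_idx(true_labels)
    p = to_idx(pred_labels)
    if t.shape != p.shape:
        raise ValueError("true and predicted label arrays must have equal length")
    return np.bincount(t * k + p, minlength=k * k).reshape(k, k)


@dataclass
class EvaluationReport:
    """Frame-level confusion matrix with per-class and averaged metrics."""

    confusion: np.ndarray
    vocabulary: tuple[str, ...]
    per_class: pd.DataFrame
    micro: dict[str, float]
    macro: dict[str, float]
    n_frames: int

    def confusion_percent(self) -> np.ndarray:
        """Row-normalized confusion (percent of true-class frames)."""
        row = self.confusion.sum(axis=1, keepdims=True).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = 100.0 * self.confusion / row
        return np.where(row > 0, out, 0.0)

    def to_dict(self) -> dict:
        return {
            "vocabulary": list(self.vocabulary),
            "confusion": self.confusion.tolist(),
            "per_class": self.per_class.to_dict(orient="index"),
            "micro": self.micro,
            "macro": self.macro,
            "n_frames": self.n_frames,
        }


def precision_recall_f1(confusion: np.ndarray,
                        vocabulary: tuple[str, ...] | None = None) -> EvaluationReport:
    """Per-class and micro/macro precision, recall and F1 from counts.

    Degenerate 0/0 ratios are defined as 0.  Micro metrics pool all
    predictions, so micro precision = micro recall = micro F1 = accuracy.
    """
    cm = np.asarray(confusion)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1]:
        raise ValueError("confusion matrix must be square")
    if (cm < 0).any():
        raise ValueError("confusion counts must be nonnegative")
    total = cm.sum()
    if total == 0:
        raise ValueError("confusion matrix is all zeros")
    k = cm.shape[0]
    if vocabulary is None:
        vocabulary = tuple(str(i) for i in range(k))
    tp = np.diag(cm).astype(float)
    fp = cm.sum(axis=0) - tp
    fn = cm.sum(axis=1) - tp

    def safe(num, den):
        return np.where(den > 0, num / np.maximum(den, 1), 0.0)

    prec = safe(tp, tp + fp)
    rec = safe(tp, tp + fn)
    f1 = np.where(prec + rec > 0, 2 * prec * rec / np.maximum(prec + rec, 1e-300), 0.0)
    per_class = pd.DataFrame(
        {"precision": prec, "recall": rec, "f1": f1, "support": cm.sum(axis=1)},
        index=list(vocabulary))
    acc = float(tp.sum() / total)
    micro = {"precision": acc, "recall": acc, "f1": acc, "accuracy": acc}
    macro = {"precision": float(prec.mean()), "recall": float(rec.mean()),
             "f1": float(f1.mean())}
    return EvaluationReport(confusion=cm, vocabulary=tuple(vocabulary),
                            per_class=per_class, micro=micro, macro=macro,
                            n_frames=int(total))


def lr_confusion_rate(confusion: np.ndarray, vocabulary: tuple[str, ...],
                      pairs: dict[str, str] = MIRROR_CODE) -> float:
    """Fraction of mirror-pair-class frames predicted as the mirrored task.

    Pairs are derived from the vocabulary: codes listed in ``pairs`` plus
    any synthetic sided codes ending in R/L whose partner is present.
    """
    index = {c: i for i, c in enumerate(vocabulary)}

    def partner(code: str) -> str | None:
        if code in pairs:
            return pairs[code]
        if code != NULL_LABEL and len(code) > 1:
            if code.endswith("R") and code[:-1] + "L" in index:
                return code[:-1] + "L"
            if code.endswith("L") and code[:-1] + "R" in index:
                return code[:-1] + "R"
        return None

    num = 0.0
    den = 0.0
    for code, i in index.items():
        p = partner(code)
        if p is None or p not in index:
            continue
        j = index[p]
        num += confusion[i, j]
        den += confusion[i].sum()
    return float(num / den) if den > 0 else 0.0


# --------------------------------------------------------------------- #
# hyperparameter grids

@dataclass(frozen=True)
class LearningGrid:
    """SGD learning-rate x momentum grid (full cartesian product)."""

    learning_rates: tuple[float, ...] = (0.0001, 0.001, 0.01, 0.1, 1.0)
    momenta: tuple[float, ...] = (0.5, 0.7, 0.9, 0.95, 0.98)

    def points(self) -> list[tuple[float, float]]:
        return list(itertools.product(self.learning_rates, self.momenta))


@dataclass(frozen=True)
class ArchitectureGrid:
    """Architecture grid with kernel options paired to each window size."""

    window_frames: tuple[int, ...] = (24, 48)
    kernels_by_window: tuple[tuple[int, tuple[int, ...]], ...] = (
        (24, (5, 6)), (48, (6, 8)))
    conv_channels: tuple[int, ...] = (32, 64, 96)
    lstm_cells: tuple[int, ...] = (64, 128, 192)

    def points(self) -> list[dict]:
        kmap = dict(self.kernels_by_window)
        out = []
        for sws in self.window_frames:
            for k in kmap[sws]:
                for c in self.conv_channels:
                    for cells in self.lstm_cells:
                        out.append({"window_frames": sws, "kernel_frames": k,
                                    "conv_channels": c, "lstm_cells": cells})
        return out


def _train_and_score(cfg: ModelConfig, tcfg: TrainConfig, train_ds, val_ds
                     ) -> tuple[TrainedModel | None, float]:
    try:
        net = build_model(cfg, seed=tcfg.seed)
        trained = train_model(net, train_ds, val_ds, tcfg)
        probs = trained.predict_proba(val_ds.windows)
        f1 = float((probs.argmax(axis=1) == val_ds.labels).mean())
        return trained, f1
    except (RuntimeError, FloatingPointError) as exc:
        warnings.warn(f"training failed for {cfg} / {tcfg}: {exc}")
        return None, float("nan")


def grid_search_learning(
    grid: LearningGrid,
    fixed_arch: ModelConfig,
    train_ds,
    val_ds,
    base_tcfg: TrainConfig = TrainConfig(),
) -> tuple[tuple[float, float], pd.DataFrame]:
    """Stage 1: tune (learning rate, momentum) on a fixed architecture.

    Selects the argmax validation micro-F1; ties break toward the lower
    learning rate, then lower momentum.  Failed points are excluded.
    """
    rows = []
    for lr, mom in grid.points():
        tcfg = replace(base_tcfg, learning_rate=lr, momentum=mom)
        _, f1 = _train_and_score(fixed_arch, tcfg, train_ds, val_ds)
        rows.append({"learning_rate": lr, "momentum": mom, "val_f1": f1})
    table = pd.DataFrame(rows)
    ok = table.dropna(subset=["val_f1"])
    if ok.empty:
        raise RuntimeError("every learning-grid point failed")
    best = ok.sort_values(["val_f1", "learning_rate", "momentum"],
                          ascending=[False, True, True],
                          kind="mergesort").iloc[0]
    return (float(best.learning_rate), float(best.momentum)), table


def grid_search_architecture(
    grid: ArchitectureGrid,
    learning: tuple[float, float],
    train_series: ConcatenatedSeries,
    val_series: ConcatenatedSeries,
    base_cfg: ModelConfig,
    base_tcfg: TrainConfig = TrainConfig(),
    vocabulary: tuple[str, ...] | None = None,
) -> tuple[ModelConfig, pd.DataFrame]:
    """Stage 2: tune architecture with the tuned learning parameters.

    Window size changes the windowing itself, so each candidate re-windows
    the continuous (already normalized) training and validation series.
    Ties break toward the smaller model (fewer parameters).
    """
    from .dataset import DEFAULT_VOCABULARY

    if vocabulary is None:
        vocabulary = DEFAULT_VOCABULARY
    lr, mom = learning
    tcfg = replace(base_tcfg, learning_rate=lr, momentum=mom)
    rows = []
    ds_cache: dict[int, tuple] = {}
    for point in grid.points():
        cfg = replace(base_cfg, **point)
        sws = cfg.window_frames
        if sws not in ds_cache:
            wspec = WindowSpec(window_frames=sws)
            ds_cache[sws] = (
                make_windows(train_series.data, train_series.frame_labels,
                             wspec, vocabulary),
                make_windows(val_series.data, val_series.frame_labels,
                             wspec, vocabulary),
            )
        tr, va = ds_cache[sws]
        trained, f1 = _train_and_score(cfg, tcfg, tr, va)
        n_par = trained.model.n_parameters() if trained else build_model(cfg).n_parameters()
        rows.append({**point, "val_f1": f1, "n_parameters": n_par})
    table = pd.DataFrame(rows)
    ok = table.dropna(subset=["val_f1"])
    if ok.empty:
        raise RuntimeError("every architecture-grid point failed")
    best = ok.sort_values(["val_f1", "n_parameters"], ascending=[False, True],
                          kind="mergesort").iloc[0]
    best_cfg = replace(base_cfg,
                       window_frames=int(best.window_frames),
                       kernel_frames=int(best.kernel_frames),
                       conv_channels=int(best.conv_channels),
                       lstm_cells=int(best.lstm_cells))
    return best_cfg, table


# --------------------------------------------------------------------- #
# per-athlete evaluation and the ablation

def evaluate_athlete(
    model: TrainedModel,
    athlete_trials: list,
    wspec: WindowSpec,
    stats: NormalizationStats,
    vocabulary: tuple[str, ...],
) -> tuple[EvaluationReport, np.ndarray]:
    """Frame-level evaluation of one athlete.

    All the athlete's trials are concatenated, normalized with the training
    statistics, windowed, classified, and fused into per-frame labels.
    Returns the frame-level report and the per-frame predicted class
    indices.
    """
    series = concatenate_athlete_trials(athlete_trials)
    x = stats.apply(series.data)
    if x.shape[0] < wspec.window_frames:
        raise ValueError("athlete has fewer frames than one window")
    ds = make_windows(x, series.frame_labels, wspec, vocabulary)
    probs = predict_window_proba(model, ds.windows)
    pred, _ = frame_fusion(probs, ds.window_start_frames, wspec.window_frames,
                           x.shape[0])
    cm = confusion_matrix(series.frame_labels, pred, vocabulary)
    return precision_recall_f1(cm, vocabulary), pred


def aggregate_reports(reports: list[EvaluationReport]) -> EvaluationReport:
    """Combine per-athlete reports by summing their confusion matrices."""
    if not reports:
        raise ValueError("no reports to aggregate")
    cm = sum(r.confusion for r in reports)
    return precision_recall_f1(cm, reports[0].vocabulary)


def run_sensor_ablation(
    athlete_series: dict[str, "object"],
    config_names: list[str],
    split: tuple[list[str], list[str], list[str]],
    wspec: WindowSpec,
    base_cfg: ModelConfig,
    tcfg: TrainConfig,
    vocabulary: tuple[str, ...],
) -> tuple[dict[str, dict], pd.DataFrame]:
    """Retrain and evaluate the classifier for each sensor-set code.

    ``athlete_series`` maps athlete id -> list of full (13-segment)
    simulated-IMU trials.  For each code the listed segments' channels are
    selected, normalization is refit on the training subset of exactly
    those channels, a model is trained from scratch with the same tuned
    hyperparameters, and the test athletes are evaluated frame-wise and
    aggregated.  Per-config failures are recorded and the run continues.
    """
    train_ids, val_ids, test_ids = split
    results: dict[str, dict] = {}
    rows = []
    for code in config_names:
        if code not in SENSOR_CONFIGS:
            raise ValueError(f"unknown sensor config {code!r}")
        try:
            sel = {a: [select_sensor_config(s, code) for s in trials]
                   for a, trials in athlete_series.items()}
            train_series = concatenate_athlete_trials(
                [t for a in train_ids for t in sel[a]])
            stats = fit_normalization(train_series.data)
            train_ds = make_windows(stats.apply(train_series.data),
                                    train_series.frame_labels, wspec, vocabulary)
            val_ds = None
            if val_ids:
                val_series = concatenate_athlete_trials(
                    [t for a in val_ids for t in sel[a]])
                val_ds = make_windows(stats.apply(val_series.data),
                                      val_series.frame_labels, wspec, vocabulary)
            cfg = replace(base_cfg, input_channels=train_ds.n_channels)
            net = build_model(cfg, seed=tcfg.seed)
            trained = train_model(net, train_ds, val_ds, tcfg)
            per_athlete = {}
            for a in test_ids:
                rep, _ = evaluate_athlete(trained, sel[a], wspec, stats, vocabulary)
                per_athlete[a] = rep
            report = aggregate_reports(list(per_athlete.values()))
            results[code] = {"report": report, "per_athlete": per_athlete,
                             "model": trained, "stats": stats}
            row = {"config": code,
                   "n_segments": len(SENSOR_CONFIGS[code]),
                   "micro_f1": report.micro["f1"],
                   "macro_f1": report.macro["f1"],
                   "lr_confusion": lr_confusion_rate(report.confusion, vocabulary)}
            for cls in vocabulary:
                row[f"f1_{cls}"] = float(report.per_class.loc[cls, "f1"])
            rows.append(row)
        except Exception as exc:   # noqa: BLE001 - per-config isolation
            warnings.warn(f"sensor config {code} failed: {exc}")
            results[code] = {"error": str(exc)}
            rows.append({"config": code, "micro_f1": float("nan")})
    return results, pd.DataFrame(rows)
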