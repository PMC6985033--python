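"""Declarative end-to-end experiments.

One YAML (or dict) configuration drives the whole chain: generate a
synthetic cohort -> derive input channels (optical marker coordinates or
simulated-IMU channels for a chosen sensor set) -> athlete-level split ->
normalize and window -> optionally tune hyperparameters -> train ->
frame-level evaluation on the test athletes -> optional sensor ablation.
Every run writes a manifest sufficient to reproduce it bit for bit; the
cohort and report stages are cached keyed by a content hash of the
relevant sub-configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import trcio
from .body import build_default_segment_model
from .dataset import (
    DEFAULT_VOCABULARY,
    SplitSpec,
    WindowSpec,
    concatenate_athlete_trials,
    fit_normalization,
    make_windows,
    split_athletes,
)
from .evaluation import (
    LearningGrid,
    aggregate_reports,
    evaluate_athlete,
    grid_search_learning,
    run_sensor_ablation,
)
from .nn import ModelConfig, TrainConfig, build_model, conv_output_length, train_model
from .sensors import SENSOR_CONFIGS, FilterSpec, extract_simu_channels, select_sensor_config
from .synthetic import NULL_LABEL, assemble_cohort

__all__ = ["ExperimentConfig", "validate_config", "run_experiment",
           "synthetic_e2e_config", "run_synthetic_ablation", "STAGES"]

STAGES = ("generate", "features", "train", "tune", "evaluate", "ablate")


@dataclass
class CohortConfig:
    n_athletes: int = 24
    seed: int = 0
    noise_sd: float = 0.002
    amplitude_jitter_sd: float = 0.10
    time_jitter_sd: float = 0.08
    sway_amplitude: float = 0.004
    fs: float = 120.0
    null_lead_s: float = 0.5
    null_trail_s: float = 0.5


@dataclass
class InputConfig:
    mode: str = "sIMU"              # "OPT" or "sIMU"
    sensor_config: str = "sIMU13"


@dataclass
class TuningConfig:
    enabled: bool = False
    learning_rates: list = field(default_factory=lambda: [0.0001, 0.001, 0.01, 0.1, 1.0])
    momenta: list = field(default_factory=lambda: [0.5, 0.7, 0.9, 0.95, 0.98])


@dataclass
class AblationConfig:
    configs: list = field(default_factory=list)


@dataclass
class ModelSection:
    window_frames: int = 48
    kernel_frames: int = 6
    conv_channels: int = 32
    lstm_cells: int = 64
    conv_layers: int = 4
    lstm_layers: int = 2
    dropout_rate: float = 0.0


@dataclass
class ExperimentConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    input: InputConfig = field(default_factory=InputConfig)
    filter: FilterSpec = field(default_factory=FilterSpec)
    split: SplitSpec = field(default_factory=SplitSpec)
    model: ModelSection = field(default_factory=ModelSection)
    train: TrainConfig = field(default_factory=TrainConfig)
    tuning: TuningConfig = field(default_factory=TuningConfig)
    ablation: AblationConfig = field(default_factory=AblationConfig)
    window_stride: int | None = None          # default: window_frames // 4
    vocabulary: str | list = "auto"

    def window_spec(self) -> WindowSpec:
        return WindowSpec(self.model.window_frames, self.window_stride)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _build_section(cls, data: dict, path: str):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(fields)
    if unknown:
        raise ValueError(f"unknown config keys under '{path}': {sorted(unknown)}")
    return cls(**data)


def validate_config(source: str | Path | dict | None) -> ExperimentConfig:
    """Load, default-fill and cross-check an experiment configuration.

    ``source`` may be a YAML file path, a dict, or ``None``/empty (all
    defaults: 120 Hz capture, 15 Hz cutoff, batch 100, stride = window/4).
    Unknown keys and infeasible combinations raise ``ValueError``.
    """
    if source is None:
        data: dict = {}
    elif isinstance(source, dict):
        data = dict(source)
    else:
        text = Path(source).read_text()
        data = yaml.safe_load(text) or {}
        if not isinstance(data, dict):
            raise ValueError("config file must contain a YAML mapping")

    sections = {
        "cohort": CohortConfig, "input": InputConfig, "filter": FilterSpec,
        "split": SplitSpec, "model": ModelSection, "train": TrainConfig,
        "tuning": TuningConfig, "ablation": AblationConfig,
    }
    top_known = set(sections) | {"window_stride", "vocabulary"}
    unknown = set(data) - top_known
    if unknown:
        raise ValueError(f"unknown top-level config keys: {sorted(unknown)}")
    kwargs = {}
    for name, cls in sections.items():
        kwargs[name] = _build_section(cls, data.get(name, {}) or {}, name)
    cfg = ExperimentConfig(
        **kwargs,
        window_stride=data.get("window_stride"),
        vocabulary=data.get("vocabulary", "auto"),
    )

    # cross-field checks
    if cfg.filter.cutoff_hz >= cfg.cohort.fs / 2:
        raise ValueError(
            f"filter cutoff {cfg.filter.cutoff_hz} Hz is not below the Nyquist "
            f"frequency ({cfg.cohort.fs / 2} Hz)")
    conv_output_length(cfg.model.window_frames, cfg.model.kernel_frames,
                       cfg.model.conv_layers)
    if cfg.input.mode not in ("OPT", "sIMU"):
        raise ValueError("input.mode must be 'OPT' or 'sIMU'")
    if cfg.input.mode == "sIMU" and cfg.input.sensor_config not in SENSOR_CONFIGS:
        raise ValueError(f"unknown sensor config {cfg.input.sensor_config!r}")
    cfg.window_spec()
    return cfg


def synthetic_e2e_config(seed: int = 1, n_athletes: int = 24) -> ExperimentConfig:
    """The desk-scale end-to-end experiment on the default synthetic cohort.

    Uses a compact network (window 24, kernel 5, 16 convolution channels,
    32 LSTM cells) and a faster learning rate (0.02, momentum 0.9) than the
    full-data setting so training converges on a laptop-sized cohort in
    about a minute per sensor configuration; all other choices (120 Hz,
    15 Hz cutoff, stride = window/4, batch 100, athlete-level 2/3 split)
    are the standard protocol.
    """
    return validate_config({
        "cohort": {"n_athletes": n_athletes, "seed": seed},
        "split": {"seed": seed},
        "model": {"window_frames": 24, "kernel_frames": 5,
                  "conv_channels": 16, "lstm_cells": 32},
        "train": {"learning_rate": 0.02, "momentum": 0.9, "batch_size": 100,
                  "max_epochs": 100, "patience": 12, "seed": seed},
    })


def _hash(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str)
                          .encode()).hexdigest()[:16]


def _resolve_vocabulary(cfg: ExperimentConfig, cohort) -> tuple[str, ...]:
    """``"auto"``: the movement labels present in the cohort, sorted, plus
    ``"Null"``; ``"default"``: the full 14-class screen vocabulary; an
    explicit list is taken as is."""
    if isinstance(cfg.vocabulary, (list, tuple)):
        return tuple(cfg.vocabulary)
    if cfg.vocabulary == "default":
        return DEFAULT_VOCABULARY
    seen = {t.movement_label for trials in cohort.values() for t in trials}
    seen.discard(NULL_LABEL)
    return tuple(sorted(seen)) + (NULL_LABEL,)


def run_synthetic_ablation(seed: int, config_names: list[str],
                           n_athletes: int = 24):
    """Generate the default synthetic cohort and run the sensor ablation.

    Uses :func:`synthetic_e2e_config`; every source of randomness (cohort,
    split, weight initialization, batch shuffling) derives from ``seed``.
    Returns ``(results, table, vocabulary)`` as from
    :func:`movescreen.evaluation.run_sensor_ablation`.
    """
    cfg = synthetic_e2e_config(seed=seed, n_athletes=n_athletes)
    model = build_default_segment_model()
    cohort = assemble_cohort(
        n_athletes=cfg.cohort.n_athletes, seed=cfg.cohort.seed,
        noise_sd=cfg.cohort.noise_sd,
        amplitude_jitter_sd=cfg.cohort.amplitude_jitter_sd,
        time_jitter_sd=cfg.cohort.time_jitter_sd,
        sway_amplitude=cfg.cohort.sway_amplitude, fs=cfg.cohort.fs,
        null_lead_s=cfg.cohort.null_lead_s,
        null_trail_s=cfg.cohort.null_trail_s, model=model)
    full = {a: [extract_simu_channels(t, model, cfg.filter) for t in trials]
            for a, trials in cohort.items()}
    split = split_athletes(sorted(cohort), cfg.split)
    vocabulary = _resolve_vocabulary(cfg, cohort)
    mcfg = ModelConfig(
        window_frames=cfg.model.window_frames, input_channels=65,
        kernel_frames=cfg.model.kernel_frames,
        conv_channels=cfg.model.conv_channels,
        lstm_cells=cfg.model.lstm_cells, n_classes=len(vocabulary),
        conv_layers=cfg.model.conv_layers, lstm_layers=cfg.model.lstm_layers)
    results, table = run_sensor_ablation(
        full, config_names, split, cfg.window_spec(), mcfg, cfg.train,
        vocabulary)
    return results, table, vocabulary


def run_experiment(cfg: ExperimentConfig, out_dir: str | Path,
                   stages: tuple[str, ...] = STAGES) -> Path:
    """Execute the requested stages, writing artifacts under ``out_dir``.

    Returns the artifact directory.  Artifacts: ``manifest.json``,
    ``cohort.npz``, ``split.json``, ``checkpoint.npz``, ``report.json``,
    ``confusion.csv``, plus ``tuning_learning.csv`` and ``ablation.csv``
    when those stages run.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    manifest: dict = {"config": cfg.to_dict(), "stages": list(stages),
                      "artifacts": {}, "timings": timings}
    model = build_default_segment_model()

    def timed(name):
        class _T:
            def __enter__(self_):
                self_.t0 = time.perf_counter()

            def __exit__(self_, *a):
                timings[name] = round(time.perf_counter() - self_.t0, 3)
        return _T()

    # -- generate ------------------------------------------------------ #
    cohort_hash = _hash(dataclasses.asdict(cfg.cohort))
    cohort_path = out / "cohort.npz"
    hash_path = out / "cohort.hash"
    with timed("generate"):
        if cohort_path.exists() and hash_path.exists() \
                and hash_path.read_text() == cohort_hash:
            cohort = trcio.load_cohort(cohort_path)
        else:
            cohort = assemble_cohort(
                n_athletes=cfg.cohort.n_athletes, seed=cfg.cohort.seed,
                noise_sd=cfg.cohort.noise_sd,
                amplitude_jitter_sd=cfg.cohort.amplitude_jitter_sd,
                time_jitter_sd=cfg.cohort.time_jitter_sd,
                sway_amplitude=cfg.cohort.sway_amplitude, fs=cfg.cohort.fs,
                null_lead_s=cfg.cohort.null_lead_s,
                null_trail_s=cfg.cohort.null_trail_s, model=model)
            trcio.save_cohort(cohort, cohort_path)
            hash_path.write_text(cohort_hash)
    manifest["artifacts"]["cohort"] = cohort_path.name
    vocabulary = _resolve_vocabulary(cfg, cohort)
    manifest["vocabulary"] = list(vocabulary)
    if stages == ("generate",):
        _write_manifest(out, manifest)
        return out

    # -- features ------------------------------------------------------ #
    with timed("features"):
        if cfg.input.mode == "OPT":
            series = {a: list(trials) for a, trials in cohort.items()}
        else:
            full = {a: [extract_simu_channels(t, model, cfg.filter)
                        for t in trials] for a, trials in cohort.items()}
            series = {a: [select_sensor_config(s, cfg.input.sensor_config)
                          for s in trials] for a, trials in full.items()}

    # -- split / window ------------------------------------------------ #
    train_ids, val_ids, test_ids = split_athletes(sorted(cohort), cfg.split)
    split_path = out / "split.json"
    split_path.write_text(json.dumps(
        {"train": train_ids, "val": val_ids, "test": test_ids}, indent=1))
    manifest["artifacts"]["split"] = split_path.name

    wspec = cfg.window_spec()
    train_series = concatenate_athlete_trials([t for a in train_ids for t in series[a]])
    stats = fit_normalization(train_series.data)
    train_ds = make_windows(stats.apply(train_series.data),
                            train_series.frame_labels, wspec, vocabulary)
    val_ds = None
    if val_ids:
        val_series = concatenate_athlete_trials([t for a in val_ids for t in series[a]])
        val_ds = make_windows(stats.apply(val_series.data),
                              val_series.frame_labels, wspec, vocabulary)

    mcfg = ModelConfig(
        window_frames=cfg.model.window_frames,
        input_channels=train_ds.n_channels,
        kernel_frames=cfg.model.kernel_frames,
        conv_channels=cfg.model.conv_channels,
        lstm_cells=cfg.model.lstm_cells,
        n_classes=len(vocabulary),
        conv_layers=cfg.model.conv_layers,
        lstm_layers=cfg.model.lstm_layers,
        dropout_rate=cfg.model.dropout_rate,
    )
    tcfg = cfg.train

    # -- tune ---------------------------------------------------------- #
    if "tune" in stages and cfg.tuning.enabled:
        with timed("tune"):
            grid = LearningGrid(tuple(cfg.tuning.learning_rates),
                                tuple(cfg.tuning.momenta))
            (lr, mom), table = grid_search_learning(grid, mcfg, train_ds, val_ds,
                                                    tcfg)
            tcfg = dataclasses.replace(tcfg, learning_rate=lr, momentum=mom)
            table.to_csv(out / "tuning_learning.csv", index=False)
            manifest["artifacts"]["tuning_learning"] = "tuning_learning.csv"
            manifest["tuned_learning"] = {"learning_rate": lr, "momentum": mom}

    # -- train --------------------------------------------------------- #
    with timed("train"):
        net = build_model(mcfg, seed=tcfg.seed)
        trained = train_model(net, train_ds, val_ds, tcfg)
    ckpt = out / "checkpoint.npz"
    trained.save(ckpt)
    manifest["artifacts"]["checkpoint"] = ckpt.name

    # -- evaluate ------------------------------------------------------ #
    if "evaluate" in stages:
        with timed("evaluate"):
            reports = [evaluate_athlete(trained, series[a], wspec, stats,
                                        vocabulary)[0] for a in test_ids]
            report = aggregate_reports(reports)
        (out / "report.json").write_text(json.dumps(report.to_dict(), indent=1))
        np.savetxt(out / "confusion.csv", report.confusion, fmt="%d", delimiter=",",
                   header=",".join(vocabulary))
        manifest["artifacts"]["report"] = "report.json"
        manifest["artifacts"]["confusion"] = "confusion.csv"
        manifest["test_micro_f1"] = report.micro["f1"]
        manifest["test_macro_f1"] = report.macro["f1"]

    # -- ablate -------------------------------------------------------- #
    if "ablate" in stages and cfg.ablation.configs:
        if cfg.input.mode != "sIMU":
            raise ValueError("the sensor ablation requires input.mode == 'sIMU'")
        with timed("ablate"):
            _, table = run_sensor_ablation(
                full, list(cfg.ablation.configs),
                (train_ids, val_ids, test_ids), wspec, mcfg, tcfg, vocabulary)
        table.to_csv(out / "ablation.csv", index=False)
        manifest["artifacts"]["ablation"] = "ablation.csv"

    _write_manifest(out, manifest)
    return out


def _write_manifest(out: Path, manifest: dict) -> None:
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
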