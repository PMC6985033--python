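"""Shared tiny-training helpers for the evaluation and pipeline tests."""

import numpy as np

import movescreen as ms
from movescreen.dataset import WindowSpec, WindowedDataset


def tiny_windows(n=60, sws=16, channels=3, seed=0):
    """A separable 3-class (train, val) window pair."""
    def make(seed):
        rng = np.random.default_rng(seed)
        labels = np.arange(n) % 3
        x = rng.normal(0, 0.3, size=(n, sws, channels)).astype(np.float32)
        x += (labels[:, None, None] - 1.0).astype(np.float32) * 1.5
        return WindowedDataset(
            windows=x, labels=labels.astype(np.int64),
            window_start_frames=np.arange(n) * 4,
            vocabulary=("c0", "c1", "c2"),
            spec=WindowSpec(sws, 4))
    return make(seed), make(seed + 1)


def train_tiny_model(cohort, body_model, vocab, code="sIMU3L", epochs=15):
    """Train a small classifier on a cohort restricted to one sensor set."""
    series = {a: [ms.select_sensor_config(
        ms.extract_simu_channels(t, body_model), code) for t in trials]
        for a, trials in cohort.items()}
    all_trials = [t for a in sorted(series) for t in series[a]]
    concat = ms.concatenate_athlete_trials(all_trials)
    stats = ms.fit_normalization(concat.data)
    wspec = ms.WindowSpec(24)
    ds = ms.make_windows(stats.apply(concat.data), concat.frame_labels,
                         wspec, vocab)
    cfg = ms.ModelConfig(window_frames=24, input_channels=ds.n_channels,
                         kernel_frames=5, conv_channels=8, lstm_cells=16,
                         n_classes=len(vocab))
    tcfg = ms.TrainConfig(learning_rate=0.02, momentum=0.9, batch_size=100,
                          max_epochs=epochs, patience=epochs, seed=0)
    trained = ms.train_model(ms.build_model(cfg, seed=0), ds, None, tcfg)
    return trained, stats, wspec
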