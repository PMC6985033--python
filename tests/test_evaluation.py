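"""Frame fusion, confusion matrices, metrics, grids, per-athlete evaluation."""

import numpy as np
import pytest

import movescreen as ms
from movescreen.evaluation import lr_confusion_rate
from tests_util_small import train_tiny_model  # noqa: F401  (shared helper)

VOCAB3 = ("A", "B", "Null")


class TestFrameFusion:
    def test_single_window_covers_all(self):
        probs = np.array([[0.7, 0.2, 0.1]])
        cls, fp = ms.frame_fusion(probs, np.array([0]), sws=10, n_frames=10)
        assert np.all(cls == 0)
        assert np.allclose(fp, probs[0])

    def test_overlapping_windows_average(self):
        probs = np.array([[0.6, 0.4], [0.2, 0.8]])
        cls, fp = ms.frame_fusion(probs, np.array([0, 0]), sws=4, n_frames=4)
        assert np.allclose(fp, [0.4, 0.6])
        assert np.all(cls == 1)

    def test_partial_overlap_regions(self):
        probs = np.array([[1.0, 0.0], [0.0, 1.0]])
        cls, fp = ms.frame_fusion(probs, np.array([0, 2]), sws=4, n_frames=6)
        assert np.allclose(fp[:2], [1.0, 0.0])     # window 1 only
        assert np.allclose(fp[2:4], [0.5, 0.5])    # both windows
        assert np.allclose(fp[4:], [0.0, 1.0])     # window 2 only
        assert cls[2] == 0                          # argmax tie -> lowest index

    def test_uncovered_trailing_frames_inherit_nearest(self):
        probs = np.array([[0.9, 0.1]])
        cls, fp = ms.frame_fusion(probs, np.array([0]), sws=5, n_frames=15)
        assert np.allclose(fp[5:], fp[4])
        assert np.all(cls == 0)

    def test_probabilities_sum_to_one(self):
        rng = np.random.default_rng(0)
        p = rng.dirichlet(np.ones(4), size=20)
        starts = np.arange(20) * 3
        _, fp = ms.frame_fusion(p, starts, sws=12, n_frames=80)
        assert np.abs(fp.sum(axis=1) - 1).max() < 1e-12

    def test_no_windows_rejected(self):
        with pytest.raises(ValueError):
            ms.frame_fusion(np.empty((0, 3)), np.empty(0, int), 10, 10)


class TestConfusionMatrix:
    def test_perfect_prediction_is_diagonal(self):
        y = np.array(["A", "B", "Null", "A"])
        cm = ms.confusion_matrix(y, y, VOCAB3)
        assert np.array_equal(cm, np.diag([2, 1, 1]))

    def test_total_misclassification_single_cell(self):
        t = np.full(10, "A")
        p = np.full(10, "B")
        cm = ms.confusion_matrix(t, p, VOCAB3)
        assert cm[0, 1] == 10 and cm.sum() == 10
        rep = ms.precision_recall_f1(cm, VOCAB3)
        assert rep.confusion_percent()[0, 1] == 100.0

    def test_conservation_and_sklearn_agreement(self):
        from sklearn.metrics import confusion_matrix as sk_cm
        rng = np.random.default_rng(5)
        t = rng.integers(0, 3, size=500)
        p = rng.integers(0, 3, size=500)
        cm = ms.confusion_matrix(t, p, VOCAB3)
        assert cm.sum() == 500
        assert np.array_equal(cm, sk_cm(t, p, labels=[0, 1, 2]))

    def test_label_outside_vocabulary_rejected(self):
        with pytest.raises(ValueError, match="not in vocabulary"):
            ms.confusion_matrix(["A"], ["XX"], VOCAB3)


class TestPrecisionRecallF1:
    def test_diagonal_matrix_all_ones(self):
        rep = ms.precision_recall_f1(np.diag([5, 3, 2]), VOCAB3)
        assert rep.micro["f1"] == 1.0
        assert rep.macro["f1"] == 1.0
        assert (rep.per_class["f1"] == 1.0).all()

    def test_two_class_hand_computation(self):
        rep = ms.precision_recall_f1(np.array([[8, 2], [3, 7]]), ("P", "N"))
        assert rep.micro["f1"] == pytest.approx(0.75)
        assert rep.micro["accuracy"] == pytest.approx(0.75)
        assert rep.per_class.loc["P", "precision"] == pytest.approx(8 / 11)
        assert rep.per_class.loc["P", "recall"] == pytest.approx(0.8)

    def test_absent_class_metrics_are_zero(self):
        cm = np.array([[5, 0, 0], [0, 3, 0], [0, 0, 0]])
        rep = ms.precision_recall_f1(cm, VOCAB3)
        assert rep.per_class.loc["Null", "f1"] == 0.0

    def test_all_zero_matrix_rejected(self):
        with pytest.raises(ValueError, match="all zeros"):
            ms.precision_recall_f1(np.zeros((3, 3)))

    def test_sklearn_cross_check(self):
        from sklearn.metrics import f1_score, precision_score, recall_score
        rng = np.random.default_rng(8)
        t = rng.integers(0, 3, size=300)
        p = rng.integers(0, 3, size=300)
        rep = ms.precision_recall_f1(ms.confusion_matrix(t, p, VOCAB3), VOCAB3)
        assert rep.micro["f1"] == pytest.approx(f1_score(t, p, average="micro"))
        assert rep.macro["precision"] == pytest.approx(
            precision_score(t, p, average="macro", zero_division=0))
        assert rep.macro["recall"] == pytest.approx(
            recall_score(t, p, average="macro", zero_division=0))


class TestLrConfusionRate:
    def test_hand_case(self):
        vocab = ("LR", "LL", "DJ", "Null")
        cm = np.zeros((4, 4), dtype=int)
        cm[0, 0], cm[0, 1] = 6, 4       # LR: 4 of 10 predicted as LL
        cm[1, 1] = 10                    # LL perfect
        cm[2, 2] = 5
        assert lr_confusion_rate(cm, vocab) == pytest.approx(4 / 20)

    def test_no_pairs_gives_zero(self):
        vocab = ("DJ", "Null")
        assert lr_confusion_rate(np.eye(2, dtype=int), vocab) == 0.0


class TestGrids:
    def test_learning_grid_has_25_points(self):
        assert len(ms.LearningGrid().points()) == 25

    def test_architecture_grid_has_36_points(self):
        points = ms.ArchitectureGrid().points()
        assert len(points) == 36

    def test_kernel_window_pairing_respected(self):
        for p in ms.ArchitectureGrid().points():
            if p["window_frames"] == 24:
                assert p["kernel_frames"] in (5, 6)
            else:
                assert p["kernel_frames"] in (6, 8)
        assert not any(p["window_frames"] == 24 and p["kernel_frames"] == 8
                       for p in ms.ArchitectureGrid().points())


class TestGridSearch:
    def test_single_point_grid_returns_that_point(self):
        from tests_util_small import tiny_windows
        tr, va = tiny_windows()
        cfg = ms.ModelConfig(window_frames=16, input_channels=3,
                             kernel_frames=3, conv_channels=4, lstm_cells=4,
                             n_classes=3)
        grid = ms.LearningGrid(learning_rates=(0.05,), momenta=(0.9,))
        tcfg = ms.TrainConfig(batch_size=20, max_epochs=3, seed=0)
        best, table = ms.grid_search_learning(grid, cfg, tr, va, tcfg)
        assert best == (0.05, 0.9)
        assert len(table) == 1

    def test_argmax_contract_on_separable_data(self):
        from tests_util_small import tiny_windows
        tr, va = tiny_windows()
        cfg = ms.ModelConfig(window_frames=16, input_channels=3,
                             kernel_frames=3, conv_channels=4, lstm_cells=4,
                             n_classes=3)
        grid = ms.LearningGrid(learning_rates=(1e-5, 0.05), momenta=(0.9,))
        tcfg = ms.TrainConfig(batch_size=20, max_epochs=8, seed=0)
        best, table = ms.grid_search_learning(grid, cfg, tr, va, tcfg)
        assert table.val_f1.max() == table.set_index(
            ["learning_rate", "momentum"]).loc[best].val_f1

    def test_architecture_search_respects_pairing_and_returns_best(self):
        from movescreen.dataset import ConcatenatedSeries
        rng = np.random.default_rng(0)
        n = 400
        labels = np.array(["A", "B"])[rng.integers(0, 2, size=n)]
        x = rng.normal(size=(n, 3)) + (labels == "A")[:, None] * 2.0
        series = ConcatenatedSeries(x, labels, [0], 120.0)
        grid = ms.ArchitectureGrid(window_frames=(24,),
                                   kernels_by_window=((24, (5,)),),
                                   conv_channels=(4,), lstm_cells=(4, 8))
        base = ms.ModelConfig(window_frames=24, input_channels=3,
                              kernel_frames=5, conv_channels=4, lstm_cells=4,
                              n_classes=3)
        tcfg = ms.TrainConfig(batch_size=50, max_epochs=2, seed=0)
        best_cfg, table = ms.grid_search_architecture(
            grid, (0.05, 0.9), series, series, base, tcfg,
            vocabulary=("A", "B", "Null"))
        assert len(table) == 2
        assert best_cfg.window_frames == 24
        assert best_cfg.lstm_cells in (4, 8)


class TestEvaluateAthlete:
    def test_conservation_and_pooled_identity(self, body_model):
        templates = ms.default_templates()[:2]
        cohort = ms.assemble_cohort(3, templates=templates, seed=21)
        vocab = ("SDR", "SDL", "Null")
        trained, stats, wspec = train_tiny_model(cohort, body_model, vocab)
        ids = sorted(cohort)
        reports = []
        n_total = 0
        correct = 0
        for a in ids:
            rep, pred = ms.evaluate_athlete(trained, [
                ms.select_sensor_config(
                    ms.extract_simu_channels(t, body_model), "sIMU3L")
                for t in cohort[a]], wspec, stats, vocab)
            reports.append(rep)
            n_frames = sum(t.n_frames for t in cohort[a])
            assert rep.confusion.sum() == n_frames
            n_total += n_frames
            truth = np.concatenate([t.frame_labels for t in cohort[a]])
            vocab_idx = {c: i for i, c in enumerate(vocab)}
            correct += int((pred == np.array([vocab_idx[c] for c in truth])).sum())
        agg = ms.aggregate_reports(reports)
        assert agg.confusion.sum() == n_total
        assert agg.micro["accuracy"] == pytest.approx(correct / n_total)
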