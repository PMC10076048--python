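"""Training loop mechanics and the 1-NN cosine evaluation protocol."""

import numpy as np
import pytest

from pdflow import (
    RepresentationMatrix,
    TrainConfig,
    evaluate,
    extract_representations,
    knn1_classify,
    summarize_ablation,
    train,
)
from pdflow.errors import UndefinedSimilarityError
from pdflow.training import effective_lr


def _reps(rows, labels):
    rows = np.asarray(rows, dtype=float)
    return RepresentationMatrix(rows=rows, labels=labels,
                                ids=[str(i) for i in range(len(rows))])


class TestKnn1:
    def test_identical_row_recovers_label(self):
        train_r = _reps([[1.0, 0.0], [0.0, 1.0]], [7, 9])
        test_r = _reps([[0.0, 1.0]], [0])
        assert knn1_classify(train_r, test_r).tolist() == [9]

    def test_cosine_scale_invariance(self):
        train_r = _reps([[1.0, 0.0], [0.0, 1.0]], [0, 1])
        test_r = _reps([[3.0, 0.0]], [0])
        assert knn1_classify(train_r, test_r).tolist() == [0]

    def test_three_point_fixture(self):
        train_r = _reps([[1.0, 0.0], [0.0, 1.0]], [0, 1])  # A, B
        test_r = _reps([[0.9, 0.1]], [0])
        assert knn1_classify(train_r, test_r).tolist() == [0]

    def test_matches_brute_force_and_sklearn(self):
        from sklearn.neighbors import KNeighborsClassifier

        rng = np.random.default_rng(11)
        for _ in range(20):
            tr = _reps(rng.normal(size=(15, 6)), rng.integers(0, 4, 15))
            te = _reps(rng.normal(size=(8, 6)), rng.integers(0, 4, 8))
            pred = knn1_classify(tr, te)
            # brute force: normalize and take argmax dot product
            a = tr.rows / np.linalg.norm(tr.rows, axis=1, keepdims=True)
            b = te.rows / np.linalg.norm(te.rows, axis=1, keepdims=True)
            brute = tr.labels[np.argmax(b @ a.T, axis=1)]
            assert np.array_equal(pred, brute)
            clf = KNeighborsClassifier(n_neighbors=1, metric="cosine")
            clf.fit(tr.rows, tr.labels)
            assert np.array_equal(pred, clf.predict(te.rows))

    def test_tie_breaks_to_lowest_index(self):
        train_r = _reps([[1.0, 0.0], [2.0, 0.0]], [3, 4])  # same direction
        test_r = _reps([[5.0, 0.0]], [0])
        assert knn1_classify(train_r, test_r).tolist() == [3]

    def test_zero_norm_row_rejected(self):
        with pytest.raises(UndefinedSimilarityError):
            knn1_classify(_reps([[0.0, 0.0]], [0]), _reps([[1.0, 0.0]], [0]))


class TestEvaluate:
    def test_self_evaluation_is_perfect(self):
        rng = np.random.default_rng(1)
        r = _reps(rng.normal(size=(12, 5)), rng.integers(0, 3, 12))
        result = evaluate(r, r)
        assert result.accuracy == 1.0
        assert np.trace(result.confusion) == 12

    def test_confusion_bookkeeping(self):
        rng = np.random.default_rng(2)
        tr = _reps(rng.normal(size=(30, 4)), rng.integers(0, 3, 30))
        te = _reps(rng.normal(size=(20, 4)), rng.integers(0, 3, 20))
        res = evaluate(tr, te)
        assert res.confusion.sum() == 20
        assert np.isclose(np.trace(res.confusion) / 20, res.accuracy)
        counts = np.bincount(te.labels, minlength=3)
        assert np.array_equal(res.confusion.sum(axis=1), counts)

    def test_accuracy_invariant_to_label_permutation(self):
        rng = np.random.default_rng(3)
        rows_tr, rows_te = rng.normal(size=(25, 4)), rng.normal(size=(10, 4))
        lab_tr, lab_te = rng.integers(0, 4, 25), rng.integers(0, 4, 10)
        perm = np.array([2, 0, 3, 1])
        base = evaluate(_reps(rows_tr, lab_tr), _reps(rows_te, lab_te))
        permuted = evaluate(_reps(rows_tr, perm[lab_tr]), _reps(rows_te, perm[lab_te]))
        assert base.accuracy == permuted.accuracy

    def test_random_balanced_reps_hit_chance_level(self):
        # 1-NN on pure noise should be right about 1/K of the time
        rng = np.random.default_rng(4)
        k, n_test = 4, 400
        tr = _reps(rng.normal(size=(200, 16)), np.repeat(np.arange(k), 50))
        te = _reps(rng.normal(size=(n_test, 16)), np.tile(np.arange(k), n_test // k))
        acc = evaluate(tr, te).accuracy
        sigma = np.sqrt(0.25 * 0.75 / n_test)
        assert abs(acc - 1.0 / k) < 5 * sigma

    def test_disjoint_label_sets_warn(self):
        tr = _reps([[1.0, 0.0]], [0])
        te = _reps([[1.0, 0.0]], [5])
        with pytest.warns(UserWarning):
            res = evaluate(tr, te)
        assert res.accuracy == 0.0


class TestTrainLoop:
    def test_lr_schedule_decays_every_80_epochs(self):
        cfg = TrainConfig()
        assert effective_lr(cfg, epoch=0) == 1e-3
        assert effective_lr(cfg, epoch=79) == 1e-3
        assert np.isclose(effective_lr(cfg, epoch=80), 1e-4)  # the 81st epoch
        assert np.isclose(effective_lr(cfg, epoch=160), 1e-5)
        step_cfg = TrainConfig(lr_decay_unit="step")
        assert np.isclose(effective_lr(step_cfg, step=80), 1e-4)

    def test_zero_epochs_returns_initial_model(self, benchmark_data):
        train_data, _ = benchmark_data
        model, history = train(train_data, TrainConfig(max_epochs=0, hidden_dim=8))
        assert history == []
        assert model.variant == "pdf_g"

    def test_same_seed_reproduces_history(self, benchmark_data):
        train_data, _ = benchmark_data
        cfg = TrainConfig(variant="pdf_e", max_epochs=3, hidden_dim=8,
                          batch_size=4, seed=123)
        _, h1 = train(train_data, cfg)
        _, h2 = train(train_data, cfg)
        assert h1 == h2  # bit-identical loss history

    def test_history_contains_named_terms_and_uncertainties(self, benchmark_data):
        train_data, _ = benchmark_data
        cfg = TrainConfig(variant="pdf_g", max_epochs=2, hidden_dim=8,
                          batch_size=8, adaptive=True)
        _, history = train(train_data, cfg)
        row = history[-1]
        for key in ("total", "magnitude", "orientation", "pose_M", "pose_O", "s0", "s3"):
            assert key in row

    def test_loss_decreases_on_small_run(self, benchmark_data):
        train_data, _ = benchmark_data
        cfg = TrainConfig(variant="baseline", max_epochs=15, hidden_dim=16,
                          batch_size=8, seed=0, adaptive=False)
        _, history = train(train_data, cfg)
        assert history[-1]["total"] < history[0]["total"]

    def test_checkpoint_and_log_written(self, tmp_path, benchmark_data):
        train_data, _ = benchmark_data
        cfg = TrainConfig(variant="pdf_e", max_epochs=1, hidden_dim=8, batch_size=8)
        train(train_data, cfg, checkpoint_path=tmp_path / "m",
              log_path=tmp_path / "loss.csv")
        assert (tmp_path / "m.npz").exists()
        assert (tmp_path / "loss.csv").read_text().startswith("epoch,")


class TestRepresentations:
    def test_rows_match_per_sequence_encoding(self, benchmark_data):
        train_data, _ = benchmark_data
        model, _ = train(train_data, TrainConfig(max_epochs=0, hidden_dim=8))
        reps = extract_representations(model, train_data, batch_size=3)
        assert reps.rows.shape == (len(train_data), 8)
        one = model.encode(train_data.sequences[5].coords).data[0]
        assert np.allclose(reps.rows[5], one, atol=1e-6)

    def test_repeated_extraction_identical(self, benchmark_data):
        train_data, _ = benchmark_data
        model, _ = train(train_data, TrainConfig(max_epochs=0, hidden_dim=8))
        a = extract_representations(model, train_data)
        b = extract_representations(model, train_data)
        assert np.array_equal(a.rows, b.rows)


class TestAblationTable:
    def test_summary_shape_and_content(self):
        import pandas as pd

        runs = pd.DataFrame(
            {"variant": ["a", "a", "b"], "seed": [0, 1, 0],
             "accuracy": [0.5, 0.7, 0.9]}
        )
        summary = summarize_ablation(runs)
        assert summary.loc[summary.variant == "a", "mean_accuracy"].item() == 0.6
        assert summary.loc[summary.variant == "b", "sd_accuracy"].item() == 0.0
        assert summary.n_runs.tolist() == [2, 1]
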