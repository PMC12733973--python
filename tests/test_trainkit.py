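"""Schedule, metrics, SNR harness, k-fold protocol and training smoke checks."""

import logging

import numpy as np
import pytest
from sklearn.metrics import precision_recall_fscore_support

from sonovis.model import ModelConfig, load_checkpoint, save_checkpoint
from sonovis.synthio import SyntheticDatasetConfig, build_dataset
from sonovis.trainkit import (MetricsReport, TrainConfig, compute_metrics,
                              cosine_lr, evaluate, kfold, make_noise,
                              mix_at_snr, split_dataset, train)


class TestCosineSchedule:
    def test_endpoints_and_midpoint(self):
        assert cosine_lr(0, 100, 1e-5, 1e-3) == pytest.approx(1e-3)
        assert cosine_lr(100, 100, 1e-5, 1e-3) == pytest.approx(1e-5)
        assert cosine_lr(50, 100, 1e-5, 1e-3) == pytest.approx((1e-3 + 1e-5) / 2)

    def test_beyond_horizon_clamps_with_warning(self, caplog):
        with caplog.at_level("WARNING", logger="sonovis.trainkit"):
            lr = cosine_lr(150, 100, 1e-5, 1e-3)
        assert lr == 1e-5
        assert "clamp" in caplog.text

    def test_monotone_decreasing(self):
        vals = [cosine_lr(t, 200, 0.0, 1.0) for t in range(201)]
        assert all(a >= b for a, b in zip(vals, vals[1:]))


class TestMetrics:
    def test_perfect_predictions_score_one(self):
        labels = np.array([0, 1, 2, 0, 1, 2])
        scores = np.eye(3)[labels] * 5.0
        rep = compute_metrics(scores, labels)
        for v in (rep.accuracy, rep.precision, rep.recall, rep.f1, rep.map50,
                  rep.topk):
            assert v == pytest.approx(1.0)

    def test_hand_evaluated_confusion_counts(self):
        # class 0: TP=3, FP=1, FN=1  ->  precision = recall = f1 = 0.75
        labels = np.array([0, 0, 0, 0, 1, 1, 1])
        pred = np.array([0, 0, 0, 1, 0, 1, 1])
        scores = np.eye(2)[pred]
        rep = compute_metrics(scores, labels)
        assert rep.confusion[0] == {"tp": 3, "fp": 1, "fn": 1, "tn": 2}
        assert rep.confusion[0]["tp"] / 4 == pytest.approx(0.75)
        assert rep.micro_precision == pytest.approx(5 / 7)

    def test_k_equal_to_classes_gives_full_topk(self):
        rng = np.random.default_rng(0)
        scores = rng.normal(size=(50, 4))
        labels = rng.integers(0, 4, 50)
        assert compute_metrics(scores, labels, k=4).topk == 1.0

    def test_matches_bruteforce_oracle_on_random_cases(self):
        """100 random prediction sets against manual confusion-matrix math
        and sklearn's macro averages (exact agreement)."""
        rng = np.random.default_rng(1)
        logging.disable(logging.WARNING)
        try:
            for _ in range(100):
                n, c = int(rng.integers(5, 40)), int(rng.integers(2, 6))
                labels = rng.integers(0, c, n)
                if np.unique(labels).size < 2:
                    continue
                scores = rng.normal(size=(n, c))
                rep = compute_metrics(scores, labels)
                pred = scores.argmax(1)
                assert rep.accuracy == pytest.approx((pred == labels).mean())
                p, r, f, _ = precision_recall_fscore_support(
                    labels, pred, labels=range(c), average="macro",
                    zero_division=0)
                assert rep.precision == pytest.approx(p, abs=1e-12)
                assert rep.recall == pytest.approx(r, abs=1e-12)
                assert rep.f1 == pytest.approx(f, abs=1e-12)
                # independent envelope-interpolated AP oracle
                aps = []
                for cls in range(c):
                    hits = labels == cls
                    if not hits.any():
                        continue
                    order = np.argsort(-scores[:, cls], kind="stable")
                    h = hits[order]
                    prec = np.cumsum(h) / (np.arange(n) + 1)
                    rec = np.cumsum(h) / h.sum()
                    ap, best = 0.0, 0.0
                    prev_r = 0.0
                    for i in range(n - 1, -1, -1):
                        best = max(best, prec[i])
                        prec[i] = best
                    for i in range(n):
                        ap += prec[i] * (rec[i] - prev_r)
                        prev_r = rec[i]
                    aps.append(ap)
                assert rep.map50 == pytest.approx(np.mean(aps), abs=1e-12)
        finally:
            logging.disable(logging.NOTSET)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics(np.zeros((0, 3)), np.array([]))


class TestSNR:
    def test_zero_db_equalises_powers(self):
        rng = np.random.default_rng(2)
        clean = np.sin(2 * np.pi * 100 * np.arange(4410) / 4410)
        noise = rng.standard_normal(4410)
        mixed, achieved = mix_at_snr(clean, noise, 0.0)
        scaled = mixed - clean
        ratio = np.mean(clean ** 2) / np.mean(scaled ** 2)
        assert ratio == pytest.approx(1.0, abs=1e-4)
        assert achieved == pytest.approx(0.0, abs=1e-4)

    def test_infinite_target_returns_clean(self):
        clean = np.ones(100)
        mixed, achieved = mix_at_snr(clean, np.ones(100), np.inf)
        np.testing.assert_array_equal(mixed, clean)
        assert achieved == np.inf

    def test_ten_db_noise_power_is_tenth(self):
        rng = np.random.default_rng(3)
        clean = np.sqrt(2) * np.sin(np.linspace(0, 200 * np.pi, 44100))
        noise = rng.standard_normal(44100)
        mixed, achieved = mix_at_snr(clean, noise, 10.0)
        p_noise = np.mean((mixed - clean) ** 2)
        assert p_noise == pytest.approx(np.mean(clean ** 2) / 10.0, rel=1e-4)
        assert achieved == pytest.approx(10.0, abs=1e-6)

    def test_zero_power_clean_rejected(self):
        with pytest.raises(ValueError):
            mix_at_snr(np.zeros(10), np.ones(10), 0.0)

    @pytest.mark.parametrize("kind", ["gaussian", "wind", "rustle", "insect"])
    def test_noise_profiles_unit_rms(self, kind):
        noise = make_noise(kind, 22050, 22050, np.random.default_rng(4))
        assert np.sqrt(np.mean(noise ** 2)) == pytest.approx(1.0, abs=1e-9)

    def test_wind_energy_concentrated_below_300hz(self):
        from scipy.signal import periodogram
        noise = make_noise("wind", 44100, 22050, np.random.default_rng(5))
        freqs, pxx = periodogram(noise, fs=22050)
        low = pxx[freqs <= 300].sum()
        assert low / pxx.sum() > 0.95


class TestKFold:
    @staticmethod
    def _stub_pairs(n=100, classes=5):
        cfg = SyntheticDatasetConfig(n_classes=2, samples_per_class=1,
                                     image_size=64, clip_seconds=0.25, seed=0)
        pairs, _ = build_dataset(cfg)
        out = []
        for i in range(n):
            import copy
            p = copy.copy(pairs[i % 2])
            p.label = i % classes
            out.append(p)
        return out

    def test_partition_covers_each_sample_once(self):
        pairs = self._stub_pairs()
        seen = []

        def runner(tr, va, fold):
            seen.append([id(p) for p in va])
            assert len(va) == 20
            return MetricsReport(1, 1, 1, 1, 1, 1, 5, 1, 1, 1, {})

        kfold(pairs, 5, runner, seed=0)
        flat = [i for fold in seen for i in fold]
        assert len(flat) == 100 and len(set(flat)) == 100

    def test_deterministic_under_seed(self):
        pairs = self._stub_pairs()
        runs = []
        for _ in range(2):
            folds = []
            kfold(pairs, 5, lambda tr, va, f: (
                folds.append([p.label for p in va]),
                MetricsReport(1, 1, 1, 1, 1, 1, 5, 1, 1, 1, {}))[1], seed=3)
            runs.append(folds)
        assert runs[0] == runs[1]

    def test_mean_fold_accuracy_equals_pooled_for_equal_folds(self):
        """Algebraic identity on synthetic predictions with equal fold sizes."""
        pairs = self._stub_pairs()
        rng = np.random.default_rng(6)
        scores = {id(p): rng.normal(size=5) for p in pairs}
        correct = {id(p): rng.uniform() < 0.6 for p in pairs}

        def runner(tr, va, fold):
            acc = np.mean([correct[id(p)] for p in va])
            return MetricsReport(acc, 0, 0, 0, 0, 0, 5, 0, 0, 0, {})

        reports, summary = kfold(pairs, 5, runner, seed=1)
        pooled = np.mean([correct[id(p)] for p in pairs])
        assert summary["accuracy_mean"] == pytest.approx(pooled)

    def test_small_k_rejected(self):
        with pytest.raises(ValueError):
            kfold(self._stub_pairs(10), 1, lambda *a: None)


@pytest.fixture(scope="module")
def micro_dataset():
    cfg = SyntheticDatasetConfig(n_classes=2, samples_per_class=10,
                                 image_size=64, clip_seconds=0.25, seed=11)
    pairs, _ = build_dataset(cfg)
    return [p for p in pairs if p.aligned_flag]


@pytest.fixture(scope="module")
def micro_model_cfg():
    from sonovis.encoders import EncoderConfig
    return ModelConfig(n_classes=2, encoder=EncoderConfig.tiny(image_size=64))


class TestTraining:
    def test_split_is_stratified_and_complete(self, micro_dataset):
        tr, va, te = split_dataset(micro_dataset, (0.7, 0.15, 0.15), 0)
        assert len(tr) + len(va) + len(te) == len(micro_dataset)
        labels = [p.label for p in tr]
        assert abs(labels.count(0) - labels.count(1)) <= 1

    def test_contrast_and_xai_weights_zero_reduce_to_plain_ce(
            self, micro_dataset, micro_model_cfg):
        """Ablation identity: lambda1 = lambda2 = 0 and explanation loss off
        must reproduce the pure cross-entropy loss curve exactly."""
        import dataclasses
        from sonovis.contrast import ContrastConfig
        logging.disable(logging.WARNING)
        try:
            tr, va, _ = split_dataset(micro_dataset, (0.7, 0.15, 0.15), 0)
            base = TrainConfig(epochs=2, seed=4, use_contrast=False,
                               use_xai=False)
            zeroed_cfg = dataclasses.replace(
                micro_model_cfg,
                contrast=ContrastConfig(lambda_contrast=0.0, lambda_margin=0.0))
            run_a = train(tr, base, micro_model_cfg, val_pairs=va)
            run_b = train(tr, TrainConfig(epochs=2, seed=4, use_contrast=True,
                                          use_xai=False),
                          zeroed_cfg, val_pairs=va)
            np.testing.assert_allclose(run_a.history["lcls"],
                                       run_b.history["lcls"], atol=1e-6)
        finally:
            logging.disable(logging.NOTSET)

    def test_checkpoint_roundtrip_reproduces_loss(self, tmp_path,
                                                  micro_dataset,
                                                  micro_model_cfg):
        from sonovis import nn
        from sonovis.model import MultimodalClassifier, make_input_tensors
        from sonovis.nn import functional as F
        logging.disable(logging.WARNING)
        try:
            tr, va, _ = split_dataset(micro_dataset, (0.7, 0.15, 0.15), 0)
            res = train(tr, TrainConfig(epochs=1, seed=5, use_xai=False),
                        micro_model_cfg, val_pairs=va)
            save_checkpoint(tmp_path / "ck.npz", res.model)
            clone, _ = load_checkpoint(tmp_path / "ck.npz")
            imgs, mels, labels = make_input_tensors(va, micro_model_cfg.encoder)
            with nn.no_grad():
                a = F.cross_entropy(res.model(imgs, mels).logits, labels).item()
                b = F.cross_entropy(clone(imgs, mels).logits, labels).item()
            assert a == pytest.approx(b, abs=1e-6)
        finally:
            logging.disable(logging.NOTSET)

    def test_single_class_training_rejected(self, micro_dataset,
                                            micro_model_cfg):
        only0 = [p for p in micro_dataset if p.label == 0]
        with pytest.raises(ValueError):
            train(only0, TrainConfig(epochs=1), micro_model_cfg,
                  val_pairs=only0)

    def test_evaluate_with_snr_corruption_runs(self, micro_dataset,
                                               micro_model_cfg):
        logging.disable(logging.WARNING)
        try:
            tr, va, _ = split_dataset(micro_dataset, (0.7, 0.15, 0.15), 0)
            res = train(tr, TrainConfig(epochs=1, use_xai=False,
                                        use_contrast=False),
                        micro_model_cfg, val_pairs=va)
            rep = evaluate(res.model, va, snr_db=0.0, noise_kind="wind")
            assert 0.0 <= rep.accuracy <= 1.0
        finally:
            logging.disable(logging.NOTSET)
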