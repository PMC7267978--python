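"""Training loop: crops, fold hygiene, optimization and transfer mechanics."""

import numpy as np
import pytest

from fmridecoder import (
    Bold4DSample,
    FoldPlan,
    TrainConfig,
    build_model,
    deterministic_first_crop,
    make_fold_plan,
    random_temporal_crop,
    train,
    transfer,
    evaluate_model,
)
from fmridecoder.training import (
    audit_no_leakage,
    label_index,
    samples_to_batch,
    split_by_subject,
)


def _sample(n_frames=10, subject="sub-000", label="a", shape=(3, 3, 3)):
    data = np.arange(n_frames * np.prod(shape), dtype=np.float32)
    return Bold4DSample(data=data.reshape(n_frames, *shape), label=label,
                        subject_id=subject, tr_s=0.72)


class TestTemporalCrops:
    def test_random_crop_is_contiguous_window(self):
        s = _sample(n_frames=10)
        rng = np.random.default_rng(0)
        for _ in range(20):
            c = random_temporal_crop(s, 4, rng)
            assert c.n_frames == 4
            start = int(c.data[0, 0, 0, 0] // (27))
            assert np.array_equal(c.data, s.data[start:start + 4])

    def test_random_crop_covers_every_offset(self):
        s = _sample(n_frames=6)
        rng = np.random.default_rng(1)
        starts = {int(random_temporal_crop(s, 4, rng).data[0, 0, 0, 0] // 27)
                  for _ in range(100)}
        assert starts == {0, 1, 2}

    def test_first_crop_is_deterministic_prefix(self):
        s = _sample(n_frames=9)
        c = deterministic_first_crop(s, 4)
        assert np.array_equal(c.data, s.data[:4])

    def test_short_sample_raises(self):
        with pytest.raises(ValueError):
            deterministic_first_crop(_sample(n_frames=3), 4)


class TestFoldPlans:
    SUBJECTS = [f"sub-{i:03d}" for i in range(20)]

    def test_test_groups_partition_subjects(self):
        plan = make_fold_plan(self.SUBJECTS, seed=0)
        tests = [s for fold in plan for s in fold["test"]]
        assert sorted(tests) == sorted(self.SUBJECTS)

    def test_ratios_give_70_10_20_split(self):
        plan = make_fold_plan(self.SUBJECTS, seed=0)
        fold = plan[0]
        assert (len(fold["train"]), len(fold["val"]), len(fold["test"])) == (14, 2, 4)

    def test_no_subject_straddles_partitions(self):
        plan = make_fold_plan(self.SUBJECTS, seed=3)
        audit_no_leakage(plan)  # does not raise

    def test_audit_catches_leaky_plan(self):
        leaky = FoldPlan([{"train": ["s1", "s2"], "val": ["s2"], "test": ["s3"]}])
        with pytest.raises(ValueError, match="straddle"):
            audit_no_leakage(leaky)
        dup = FoldPlan([
            {"train": ["s1"], "val": ["s2"], "test": ["s3"]},
            {"train": ["s1"], "val": ["s2"], "test": ["s3"]},
        ])
        with pytest.raises(ValueError, match="more than one fold"):
            audit_no_leakage(dup)

    def test_split_by_subject_routes_samples(self):
        samples = [_sample(subject=s) for s in ("a", "a", "b", "c", "d")]
        fold = {"train": ["a"], "val": ["b"], "test": ["c"]}
        tr, va, te = split_by_subject(samples, fold)
        assert [s.subject_id for s in tr] == ["a", "a"]
        assert [s.subject_id for s in va] == ["b"]
        assert [s.subject_id for s in te] == ["c"]  # subject d is dropped


class TestBatching:
    def test_standardization_zero_mean_unit_sd(self):
        x = samples_to_batch([_sample(), _sample()], k=4, rng=None)
        assert np.allclose(x.mean(axis=(1, 2, 3, 4)), 0, atol=1e-5)
        assert np.allclose(x.std(axis=(1, 2, 3, 4)), 1, atol=1e-4)

    def test_label_index_is_sorted(self):
        samples = [_sample(label=l) for l in ("b", "a", "c", "a")]
        assert label_index(samples) == {"a": 0, "b": 1, "c": 2}


class TestTrainLoop:
    def _fold(self, design):
        subjects = [f"sub-{i:03d}" for i in range(design.n_subjects)]
        return {"train": subjects[:4], "val": subjects[4:5], "test": subjects[5:]}

    def test_loss_decreases_and_best_checkpoint_restored(
            self, tiny_arch, tiny_grid, tiny_design, tiny_samples):
        cfg = TrainConfig(k=4, batch_size=8, max_epochs=6, seed=3)
        model = build_model(tiny_arch, tiny_grid, seed=7)
        model, history = train(model, tiny_samples, self._fold(tiny_design), cfg)
        epochs = [h for h in history if "epoch" in h]
        meta = history[-1]["meta"]
        assert epochs[-1]["train_loss"] < epochs[0]["train_loss"]
        assert meta["best_val_loss"] == pytest.approx(
            min(h["val_loss"] for h in epochs))
        # the returned model really holds the best-epoch weights
        labels = meta["labels"]
        _, val_s, _ = split_by_subject(tiny_samples, self._fold(tiny_design))
        from fmridecoder.training import _eval_loss_acc
        val_loss, _ = _eval_loss_acc(model, val_s, labels, cfg)
        assert val_loss == pytest.approx(meta["best_val_loss"], abs=1e-5)

    def test_training_is_seed_deterministic(
            self, tiny_arch, tiny_grid, tiny_design, tiny_samples):
        cfg = TrainConfig(k=4, batch_size=8, max_epochs=2, seed=9)
        fold = self._fold(tiny_design)
        h1 = train(build_model(tiny_arch, tiny_grid, seed=7),
                   tiny_samples, fold, cfg)[1]
        h2 = train(build_model(tiny_arch, tiny_grid, seed=7),
                   tiny_samples, fold, cfg)[1]
        assert h1 == h2

    def test_plateau_decays_learning_rate(
            self, tiny_arch, tiny_grid, tiny_design, tiny_samples):
        cfg = TrainConfig(k=4, batch_size=8, max_epochs=8, seed=3,
                          plateau_patience_epochs=1, min_delta=10.0)
        model = build_model(tiny_arch, tiny_grid, seed=7)
        _, history = train(model, tiny_samples, self._fold(tiny_design), cfg)
        lrs = sorted({h["lr"] for h in history if "epoch" in h}, reverse=True)
        assert len(lrs) >= 2
        assert lrs[0] / lrs[1] == pytest.approx(10.0)

    def test_label_count_mismatch_raises(
            self, tiny_grid, tiny_design, tiny_samples):
        from fmridecoder import ArchitectureConfig

        arch3 = ArchitectureConfig(input_frames=4, n_ch1=2, conv2_channels=4,
                                   block_channels=(4, 6, 6, 8),
                                   final_conv_channels=8, fc_width=8, n_classes=3)
        model = build_model(arch3, tiny_grid, seed=7)
        with pytest.raises(ValueError, match="labels"):
            train(model, tiny_samples, self._fold(tiny_design),
                  TrainConfig(k=4, max_epochs=1))


class TestTransferMechanics:
    def test_transfer_starts_from_source_trunk(
            self, tiny_arch, tiny_grid, tiny_design, tiny_samples):
        source = build_model(tiny_arch, tiny_grid, seed=7)
        from fmridecoder.model import clone_model

        clone = clone_model(source, n_classes=3, seed=1)
        for a, b in zip(source.params()[:-2], clone.params()[:-2]):
            assert np.array_equal(a.value, b.value)
        assert clone.params()[-2].value.shape == (3, tiny_arch.fc_width)

    def test_transfer_trains_on_new_label_set(
            self, tiny_arch, tiny_grid, tiny_design, tiny_samples):
        source = build_model(tiny_arch, tiny_grid, seed=7)
        fold = {"train": ["sub-000", "sub-001"], "val": ["sub-002"],
                "test": ["sub-003"]}
        cfg = TrainConfig(k=4, batch_size=8, max_epochs=1, seed=3)
        model, history = transfer(source, 2, tiny_samples, fold, cfg)
        assert model.cfg.n_classes == 2
        assert any("epoch" in h for h in history)


class TestEvaluate:
    def test_evaluate_returns_consistent_scores(
            self, tiny_arch, tiny_grid, tiny_samples):
        model = build_model(tiny_arch, tiny_grid, seed=7)
        cfg = TrainConfig(k=4, batch_size=8)
        y, yhat, scores = evaluate_model(model, tiny_samples[:6], cfg)
        assert scores.shape == (6, 2)
        assert np.allclose(scores.sum(axis=1), 1.0, atol=1e-5)
        assert np.array_equal(yhat, scores.argmax(axis=1))
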