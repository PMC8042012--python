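"""Fold planning, augmentation, balancing, early stopping and the
learning-curve experiment loop (structural checks at toy scale)."""

import numpy as np
import pytest

import blastcurve as bc
from blastcurve.protocol import ProtocolError, _derive_seed


IDS_250 = [f"s{i:03d}" for i in range(250)]


def _reference_config(**kw):
    return bc.ProtocolConfig(**kw)


class TestPlanFolds:
    def test_reference_design_250(self, rng):
        plan = bc.plan_folds(IDS_250, _reference_config(), rng)
        assert len(plan.folds) == 10
        tests = [set(f.test_ids) for f in plan.folds]
        assert all(len(t) == 25 for t in tests)
        assert set().union(*tests) == set(IDS_250)
        for a in range(10):
            for b in range(a + 1, 10):
                assert not tests[a] & tests[b]

    def test_partition_within_fold(self, rng):
        plan = bc.plan_folds(IDS_250, _reference_config(), rng)
        for f in plan.folds:
            ids = set(f.test_ids) | set(f.val_ids) | set(f.pool_ids)
            assert ids == set(IDS_250)
            assert len(f.test_ids) + len(f.val_ids) + len(f.pool_ids) == 250

    def test_nested_subsets(self, rng):
        plan = bc.plan_folds(IDS_250, _reference_config(), rng)
        for f in plan.folds:
            assert len(f.pool_ids) == 200
            sizes = [len(s) for s in f.nested_subsets]
            assert sizes == list(range(10, 201, 10))
            prev = set()
            for sub in f.nested_subsets:
                cur = set(sub)
                assert prev < cur
                prev = cur

    def test_deterministic_under_seed(self):
        cfg = _reference_config()
        p1 = bc.plan_folds(IDS_250, cfg, np.random.default_rng(3))
        p2 = bc.plan_folds(IDS_250, cfg, np.random.default_rng(3))
        assert [f.test_ids for f in p1.folds] == [f.test_ids for f in p2.folds]
        assert [f.nested_subsets for f in p1.folds] == [f.nested_subsets for f in p2.folds]

    def test_insufficient_samples(self, rng):
        with pytest.raises(ProtocolError):
            bc.plan_folds(IDS_250[:100], _reference_config(), rng)

    def test_stratified_balanced_test_sets(self, rng):
        # large-dataset variant: balanced test sets, disjoint on the test side
        ids = [f"p{i}" for i in range(300)] + [f"n{i}" for i in range(700)]
        labels = {i: ("pos" if i.startswith("p") else "neg") for i in ids}
        cfg = _reference_config(
            n_folds=5, test_size=40, stratified_test=True, val_size=10,
            sizes=[10, 20],
        )
        plan = bc.plan_folds(ids, cfg, rng, labels=labels)
        assert not plan.covers_all
        tests = [f.test_ids for f in plan.folds]
        for t in tests:
            classes = [labels[i] for i in t]
            assert classes.count("pos") == classes.count("neg") == 20
        seen = set()
        for t in tests:
            assert not seen & set(t)
            seen |= set(t)


class TestAugmentation:
    def _sample(self, rng, size=9):
        return bc.ImageSample(pixels=rng.random((size, size, 3)), label="a", sample_id="s")

    def test_identity_transform(self, rng):
        s = self._sample(rng)
        out = bc.apply_augmentation(s)
        assert np.array_equal(out.pixels, s.pixels)

    def test_horizontal_flip_involution(self, rng):
        s = self._sample(rng)
        once = bc.apply_augmentation(s, flip_h=True)
        twice = bc.apply_augmentation(once, flip_h=True)
        assert np.array_equal(twice.pixels, s.pixels)
        assert not np.array_equal(once.pixels, s.pixels)

    def test_rotation_90_matches_index_permutation(self, rng):
        # 90-degree rotation about the image center is a pure index
        # permutation: compare the interpolating path against np.rot90
        for size in (9, 10):
            s = self._sample(rng, size=size)
            out = bc.apply_augmentation(s, angle_deg=90.0, fill=(0, 0, 0))
            assert np.allclose(out.pixels, np.rot90(s.pixels), atol=1e-9)

    def test_random_augment_preserves_contract(self, rng):
        s = self._sample(rng, size=21)
        out = bc.augment_image(s, rng)
        assert out.pixels.shape == s.pixels.shape
        assert out.label == s.label
        assert out.pixels.min() >= 0.0 and out.pixels.max() <= 1.0


class TestBalancing:
    def _dataset(self, rng, counts):
        samples = []
        for cls, n in counts.items():
            for i in range(n):
                samples.append(
                    bc.ImageSample(
                        pixels=rng.random((16, 16, 3)), label=cls, sample_id=f"{cls}_{i}"
                    )
                )
        return bc.LabeledDataset(samples, class_order=list(counts))

    def test_upsample_to_target(self, rng):
        ds = self._dataset(rng, {"a": 97, "b": 150})
        out = bc.balance_by_augmentation(ds, 150, rng)
        counts = out.class_counts()
        assert counts == {"a": 150, "b": 150}
        a_ids = [s.sample_id for s in out.samples if s.label == "a"]
        originals = [i for i in a_ids if "_aug" not in i]
        assert len(originals) == 97

    def test_already_balanced_is_identity(self, rng):
        ds = self._dataset(rng, {"a": 6, "b": 6})
        out = bc.balance_by_augmentation(ds, 6, rng)
        assert sorted(out.sample_ids) == sorted(ds.sample_ids)

    def test_provenance_of_heavy_upsampling(self, rng):
        ds = self._dataset(rng, {"a": 5, "b": 150})
        out = bc.balance_by_augmentation(ds, 150, rng)
        ancestors = {s.sample_id.split("_aug")[0] for s in out.samples if s.label == "a"}
        assert ancestors == {f"a_{i}" for i in range(5)}

    def test_oversized_class_subsampled(self, rng):
        ds = self._dataset(rng, {"a": 20, "b": 5})
        out = bc.balance_by_augmentation(ds, 10, rng)
        assert out.class_counts() == {"a": 10, "b": 10}
        a_ids = {s.sample_id for s in out.samples if s.label == "a"}
        assert a_ids <= {f"a_{i}" for i in range(20)}

    def test_empty_class_errors(self, rng):
        ds = self._dataset(rng, {"a": 3, "b": 3})
        ds.class_order.append("ghost")
        with pytest.raises(ProtocolError, match="ghost"):
            bc.balance_by_augmentation(ds, 5, rng)


class TestEarlyStopping:
    def test_strictly_decreasing_never_stops(self):
        losses = list(np.linspace(1.0, 0.1, 100))
        best, trained = bc.early_stop_epoch(losses, patience=50)
        assert trained == 100
        assert best == 99

    def test_flat_after_improvement_stops_at_patience(self):
        # best epoch 2 (0-based); flat thereafter -> stop patience epochs later
        losses = [1.0, 0.9, 0.8] + [0.8] * 200
        best, trained = bc.early_stop_epoch(losses, patience=50)
        assert best == 2
        assert trained == 2 + 50 + 1

    def test_tie_keeps_earliest_epoch(self):
        best, _ = bc.early_stop_epoch([1.0, 0.5, 0.5, 0.5], patience=10)
        assert best == 1
        # a later strict improvement moves the best epoch
        best2, _ = bc.early_stop_epoch([1.0, 0.5, 0.5, 0.5, 0.4], patience=10)
        assert best2 == 4


class TestTraining:
    def test_loss_decreases_on_separable_data(self, small_two_class, tiny_spec):
        ids = small_two_class.sample_ids
        train = small_two_class.subset(ids[:15] + ids[21:36])
        val = small_two_class.subset(ids[15:21] + ids[36:42])
        cfg = bc.ProtocolConfig(max_epochs=15, patience=50)
        model = bc.train_model(tiny_spec, train, val, cfg, seed=4)
        assert model.history["train_loss"][-1] < model.history["train_loss"][0]
        assert len(model.history["val_loss"]) == model.epochs_trained
        assert 0 <= model.best_epoch < model.epochs_trained

    def test_overlapping_train_val_rejected(self, small_two_class, tiny_spec):
        ids = small_two_class.sample_ids
        with pytest.raises(ProtocolError, match="overlap"):
            bc.train_model(
                tiny_spec,
                small_two_class.subset(ids[:10]),
                small_two_class.subset(ids[5:15]),
                bc.ProtocolConfig(max_epochs=1),
                seed=0,
            )


class TestLearningCurveExperiment:
    CFG = dict(
        n_folds=3, val_size=5, sizes=[5, 10], max_epochs=2, patience=50, seed=21
    )

    def test_record_structure(self, small_two_class):
        res = bc.run_learning_curve(small_two_class, bc.ProtocolConfig(**self.CFG))
        assert len(res.records) == 3 * 2  # folds x sizes
        assert set(res.records["train_size"]) == {5, 10}
        assert res.records["metric_value"].between(0, 1).all()
        assert (res.records["epochs_trained"] == 2).all()
        # fixed test set within a fold: predictions at both sizes share labels
        for k in range(3):
            y5, _ = res.predictions[(k, 5)]
            y10, _ = res.predictions[(k, 10)]
            assert np.array_equal(y5, y10)

    def test_end_to_end_determinism(self, small_two_class):
        cfg = bc.ProtocolConfig(**self.CFG)
        r1 = bc.run_learning_curve(small_two_class, cfg)
        r2 = bc.run_learning_curve(small_two_class, cfg)
        assert r1.records.equals(r2.records)

    def test_summary_and_csv_roundtrip(self, small_two_class, tmp_path):
        res = bc.run_learning_curve(small_two_class, bc.ProtocolConfig(**self.CFG))
        text = res.summary()
        assert "metric: roc_auc" in text
        path = tmp_path / "records.csv"
        res.to_csv(path)
        df = bc.LearningCurveResults.records_from_csv(path)
        assert len(df) == len(res.records)
        assert np.allclose(df["metric_value"], res.records["metric_value"])


def test_derived_seeds_stable_and_bounded():
    s1 = _derive_seed(0, 3, 100)
    s2 = _derive_seed(0, 3, 100)
    s3 = _derive_seed(0, 4, 100)
    assert s1 == s2 != s3
    assert 0 <= s1 < 2**31
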