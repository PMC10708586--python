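"""EEG classifier: architecture arithmetic, batch norm, training behaviour."""

import numpy as np
import pytest

from eegsaliency import nn
from eegsaliency.classifier import (
    ClassifierNetwork,
    ClassifierSpec,
    TrainConfig,
    batch_normalize,
    build_classifier,
    classify,
    count_parameters,
    crossvalidate,
    extract_features,
    predict_labels,
    train_classifier,
)
from eegsaliency.eeg_io import EEGRecord, prepare
from eegsaliency.synthetic import SynthConfig, generate_eeg_dataset


class TestBatchNormalizeOp:
    def test_constant_batch_maps_to_zero(self):
        out, _ = batch_normalize(np.full((5, 3), 4.2))
        np.testing.assert_allclose(out, 0.0, atol=1e-9)

    def test_plus_minus_one_batch(self):
        """Features {-1,+1}: variance 1, outputs -/+ 1/sqrt(1+eps)."""
        batch = np.array([[-1.0, 1.0], [1.0, -1.0]])
        out, state = batch_normalize(batch, eps=1e-5)
        np.testing.assert_allclose(np.abs(out), 1.0, atol=1e-4)
        np.testing.assert_allclose(out, batch / np.sqrt(1 + 1e-5), atol=1e-12)
        assert state.n == 2

    def test_output_standardised(self):
        rng = np.random.default_rng(0)
        out, _ = batch_normalize(rng.normal(3, 5, size=(64, 7)))
        np.testing.assert_allclose(out.mean(axis=0), 0, atol=1e-10)
        np.testing.assert_allclose(out.var(axis=0), 1, atol=1e-3)

    def test_matches_two_pass_oracle(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(16, 4))
        out, _ = batch_normalize(x, eps=1e-5)
        mu = x.sum(axis=0) / len(x)
        var = ((x - mu) ** 2).sum(axis=0) / len(x)
        np.testing.assert_allclose(out, (x - mu) / np.sqrt(var + 1e-5),
                                   atol=1e-10)

    def test_empty_batch_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            batch_normalize(np.zeros((0, 3)))


class TestArchitecture:
    def test_paper_profile_stage_shapes(self):
        """Activation chain (14,14,250) -> (10,14,250)x2 -> 3500 -> 2500 -> 10."""
        model = build_classifier(ClassifierSpec())
        shapes = [s for s in model.network.out_shapes]
        assert shapes[0] == (14, 14, 250)       # conv stage 1
        assert shapes[4] == (10, 14, 250)       # conv stage 2
        assert shapes[8] == (10, 14, 250)       # conv stage 3
        assert (3500,) in shapes and (2500,) in shapes
        assert model.network.output_shape == (10,)

    def test_desk_profile_only_shrinks_sizes(self):
        desk = ClassifierSpec.desk(n_classes=3)
        model = build_classifier(desk)
        assert model.network.out_shapes[0] == (4, 14, 250)
        assert model.spec.feature_length == 64
        assert len([l for l in model.network.layers
                    if isinstance(l, nn.Conv2d)]) == 3

    def test_count_parameters_dense_conventions(self):
        """2500->100 without bias = 250,000; 2888->1 with bias = 2,889."""
        net = nn.Sequential([nn.Dense(100, bias=False)], (2500,), seed=0)
        assert count_parameters(net)[0]["n_params"] == 250_000
        net = nn.Sequential([nn.Dense(1, bias=True)], (2888,), seed=0)
        assert count_parameters(net)[0]["n_params"] == 2_889

    def test_count_parameters_minimal_conv(self):
        net = nn.Sequential([nn.Conv2d(1, 1, padding="valid", bias=False)],
                            (1, 3, 3), seed=0)
        assert count_parameters(net)[0]["n_params"] == 1


@pytest.fixture(scope="module")
def toy_records():
    cfg = SynthConfig(n_per_class=8, n_classes=3, seed=4, noise_sd=0.2,
                      class_freqs=[6.0, 16.0, 28.0])
    return prepare(generate_eeg_dataset(cfg))


class TestClassifyAndFeatures:
    def test_log_probabilities_normalised(self, toy_records):
        model = build_classifier(ClassifierSpec.desk(n_classes=3), seed=0)
        model.class_labels = (0, 1, 2)
        logp = classify(model, toy_records[0])
        assert logp.shape == (3,)
        assert np.exp(logp).sum() == pytest.approx(1.0, abs=1e-6)

    def test_argmax_invariant_under_unit_scaling(self, toy_records):
        model = build_classifier(ClassifierSpec.desk(n_classes=3), seed=0)
        rec = toy_records[0]
        scaled = EEGRecord(rec.signal * 1.0, label=rec.label)
        a = classify(model, rec)
        b = classify(model, scaled)
        assert np.argmax(a) == np.argmax(b)

    def test_decomposition_feature_plus_head(self, toy_records):
        """classify == dense head applied manually to extract_features output."""
        model = build_classifier(ClassifierSpec.desk(n_classes=3), seed=1)
        rec = toy_records[0]
        feats = extract_features(model, rec)
        assert feats.shape == (64,)
        head_dense, head_softmax = model.network.layers[-2:]
        manual = head_softmax.forward(head_dense.forward(feats[None]))[0]
        np.testing.assert_allclose(classify(model, rec), manual, atol=1e-12)

    def test_features_deterministic_for_fixed_weights(self, toy_records):
        model = build_classifier(ClassifierSpec.desk(n_classes=3), seed=2)
        a = extract_features(model, toy_records[:3])
        b = extract_features(model, toy_records[:3])
        np.testing.assert_array_equal(a, b)

    def test_same_class_features_more_similar(self):
        """Within-class cosine similarity exceeds cross-class (noiseless)."""
        cfg = SynthConfig(n_per_class=6, n_classes=2, seed=5, noise_sd=0.0,
                          class_freqs=[7.0, 25.0])
        recs = prepare(generate_eeg_dataset(cfg))
        model, _ = train_classifier(recs, TrainConfig(iterations=120, seed=0))
        feats = extract_features(model, recs)
        labels = np.array([r.label for r in recs])
        f = feats / np.linalg.norm(feats, axis=1, keepdims=True)
        sims = f @ f.T
        same = sims[np.ix_(labels == 0, labels == 0)]
        cross = sims[np.ix_(labels == 0, labels == 1)]
        assert same.mean() > cross.mean()


class TestTraining:
    def test_single_class_rejected(self, toy_records):
        only = [r for r in toy_records if r.label == 0]
        with pytest.raises(ValueError, match="two classes"):
            train_classifier(only)

    def test_same_seed_identical_histories(self, toy_records):
        cfg = TrainConfig(iterations=40, seed=9)
        _, h1 = train_classifier(toy_records, cfg)
        _, h2 = train_classifier(toy_records, cfg)
        np.testing.assert_array_equal(h1["loss"].to_numpy(),
                                      h2["loss"].to_numpy())

    def test_indistinguishable_classes_stay_at_chance(self):
        """Identical signals relabeled into two classes: accuracy <= 1/2."""
        rng = np.random.default_rng(0)
        base = rng.normal(size=(14, 250))
        records = []
        for i in range(12):
            sig = base.copy()
            rec = EEGRecord(sig, label=i % 2, record_id=f"d{i}")
            records.append(rec)
        records = prepare(records)
        model, hist = train_classifier(
            records, TrainConfig(iterations=60, seed=1, batch_size=12))
        acc = hist["train_accuracy"].dropna().iloc[-1]
        # identical inputs get identical predictions: at most half correct
        assert acc <= 0.5 + 1e-12

    def test_noiseless_separable_reaches_full_train_accuracy(self):
        """Noiseless 3-class data, desk profile, <=300 iterations."""
        cfg = SynthConfig(n_per_class=20, n_classes=3, seed=1, noise_sd=0.0)
        recs = prepare(generate_eeg_dataset(cfg))
        model, hist = train_classifier(recs, TrainConfig(iterations=300, seed=0))
        assert hist["train_accuracy"].dropna().iloc[-1] == 1.0


class TestCrossValidation:
    def test_fold_structure(self, toy_records):
        folds, summary, (y_true, y_pred) = crossvalidate(
            toy_records, k=4, config=TrainConfig(iterations=20, seed=0))
        assert len(folds) == 4
        # union of test folds covers the dataset exactly once
        assert len(y_true) == len(toy_records)
        assert set(summary.index) == {"accuracy", "precision", "recall",
                                      "f1", "kappa"}

    def test_k2_on_four_records_enumerable(self):
        cfg = SynthConfig(n_per_class=2, n_classes=2, seed=6, noise_sd=0.1,
                          class_freqs=[8.0, 24.0])
        recs = prepare(generate_eeg_dataset(cfg))
        folds, _, (y_true, y_pred) = crossvalidate(
            recs, k=2, config=TrainConfig(iterations=10, seed=0))
        # each of the 2 folds holds one record per class
        assert len(folds) == 2
        assert sorted(y_true) == [0, 0, 1, 1]

    def test_class_smaller_than_k_rejected(self, toy_records):
        with pytest.raises(ValueError, match="stratification|members"):
            crossvalidate(toy_records, k=10)
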