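"""Classifier families, the NumPy network engine, and the training protocol."""

import numpy as np
import pytest

import matmotion as mm
from matmotion import nn
from matmotion.models import (MODEL_SPECS, SVM_C_GRID, SVM_GAMMA_GRID,
                              ModelSpec, TrainingConfig)


def numerical_gradcheck(model, x, y, n_entries=6, eps=1e-5):
    """Max relative error between backprop and central-difference gradients."""
    z = model.forward(x)
    model.backward(((nn.sigmoid(z) - y) / len(x)).astype(x.dtype))
    picker = np.random.default_rng(0)
    worst = 0.0
    for p, g in model.parameters():
        for idx in picker.choice(p.size, size=min(n_entries, p.size), replace=False):
            orig = p.flat[idx]
            p.flat[idx] = orig + eps
            lp = nn.bce_from_logits(model.forward(x), y)
            p.flat[idx] = orig - eps
            lm = nn.bce_from_logits(model.forward(x), y)
            p.flat[idx] = orig
            num = (lp - lm) / (2 * eps)
            worst = max(worst, abs(num - g.flat[idx]) / max(1e-8, abs(num) + abs(g.flat[idx])))
    return worst


class TestEngineGradients:
    @pytest.mark.parametrize("spec", [
        ModelSpec("gc-ffn", "ffn", "features12", fc_layers=(9, 5)),
        ModelSpec("gc-cnn", "cnn", "signals500x6",
                  conv_layers=((3, 5), (4, 3)), fc_layers=(7,), pool=2),
        ModelSpec("gc-lstm", "lstm", "signals500x6",
                  lstm_layers=(4, 3), fc_layers=(5,)),
    ], ids=lambda s: s.name)
    def test_backprop_matches_numerical_gradient(self, spec, rng):
        x = rng.normal(size=(3, 25, 6)) if spec.input_kind == "signals500x6" \
            else rng.normal(size=(3, 12))
        y = np.array([1.0, 0.0, 1.0])
        model = mm.build_model(spec, seed=0, n_steps=25, dtype=np.float64)
        assert numerical_gradcheck(model, x, y) < 1e-6


class TestBuildModel:
    def test_f11_parameter_count(self):
        # 12*100 + 100 + 100*1 + 1
        model = mm.build_model(MODEL_SPECS["F1.1"], seed=0)
        assert model.count_params() == 1401

    def test_cnn_forward_outputs_probability(self, rng):
        model = mm.build_model(MODEL_SPECS["C1F1.1"], seed=0)
        p = model.predict_proba(rng.normal(size=(1, 500, 6)).astype(np.float32))
        assert p.shape == (1,) and 0.0 < p[0] < 1.0

    def test_named_cnn_filter_shapes(self):
        assert MODEL_SPECS["C1F1.1"].conv_layers == ((4, 7),)
        assert MODEL_SPECS["C1F1.2"].conv_layers == ((16, 13),)
        assert MODEL_SPECS["C1F1.3"].conv_layers == ((64, 21),)

    def test_feature_widths_follow_derivative_contrast(self):
        # S1/F1.1 consume the 12 base features, S2 the 24 with derivatives
        assert MODEL_SPECS["S1.RBF"].n_features == 12
        assert MODEL_SPECS["S2.P1"].n_features == 24
        assert MODEL_SPECS["F1.1"].n_features == 12

    def test_svm_spec_rejected_by_builder(self):
        with pytest.raises(ValueError, match="train_svm_grid"):
            mm.build_model(MODEL_SPECS["S1.RBF"])

    def test_inconsistent_spec_rejected(self):
        with pytest.raises(ValueError, match="feature input"):
            ModelSpec("bad", "svm", "signals500x6", kernel="rbf")
        with pytest.raises(ValueError, match="signal input"):
            ModelSpec("bad", "cnn", "features12", conv_layers=((4, 7),))

    def test_spec_yaml_round_trip(self):
        import yaml

        from matmotion.models import spec_from_dict, spec_to_dict
        for spec in MODEL_SPECS.values():
            dumped = yaml.safe_dump(spec_to_dict(spec))
            assert spec_from_dict(yaml.safe_load(dumped)) == spec

    def test_every_registered_variant_builds_or_is_svm(self):
        for name, spec in MODEL_SPECS.items():
            if spec.family == "svm":
                continue
            model = mm.build_model(spec, seed=0, n_steps=100)
            assert model.count_params() > 0


def separable_features(rng, n=60, d=12):
    """Two Gaussian classes separated along every dimension."""
    y = rng.integers(0, 2, n).astype(bool)
    x = rng.normal(size=(n, d)) + 3.0 * y[:, None]
    return x, y


class TestSvmGrid:
    def test_exactly_25_fits_reported(self, rng):
        x, y = separable_features(rng)
        _, report = mm.train_svm_grid(x[:40], y[:40], x[40:], y[40:])
        assert len(report) == 25
        assert set(report["C"]) == set(SVM_C_GRID)
        assert set(report["gamma"]) == set(SVM_GAMMA_GRID)

    def test_separable_data_reaches_perfect_validation(self, rng):
        x, y = separable_features(rng)
        _, report = mm.train_svm_grid(x[:40], y[:40], x[40:], y[40:])
        assert report["val_accuracy"].max() == 1.0

    def test_tie_break_smallest_c_then_gamma(self, rng):
        x, y = separable_features(rng)
        best, report = mm.train_svm_grid(x[:40], y[:40], x[40:], y[40:])
        top = report["val_accuracy"].max()
        tied = report[report["val_accuracy"] == top]
        expect_c = tied["C"].min()
        expect_gamma = tied[tied["C"] == expect_c]["gamma"].min()
        assert best.named_steps["svc"].C == expect_c
        assert best.named_steps["svc"].gamma == expect_gamma

    def test_single_class_training_rejected(self, rng):
        x = rng.normal(size=(10, 12))
        with pytest.raises(ValueError, match="single class"):
            mm.train_svm_grid(x, np.zeros(10, bool), x, np.zeros(10, bool))


class TestTrainNetwork:
    def small_data(self, rng, n=40):
        y = rng.integers(0, 2, n).astype(float)
        x = rng.normal(size=(n, 12)).astype(np.float32) + 2.0 * y[:, None]
        return x, y

    def test_same_seed_identical_val_loss(self, rng):
        x, y = self.small_data(rng)
        cfg = TrainingConfig(n_restarts=1, max_epochs=15)
        spec = MODEL_SPECS["F1.1"]
        _, h1 = mm.train_network(spec, cfg, x[:30], y[:30], x[30:], y[30:], seed=5)
        _, h2 = mm.train_network(spec, cfg, x[:30], y[:30], x[30:], y[30:], seed=5)
        assert h1.best_val_loss == h2.best_val_loss
        assert h1.val_loss == h2.val_loss

    def test_validation_stop_restores_best_state(self, rng):
        x, y = self.small_data(rng)
        cfg = TrainingConfig(n_restarts=1, max_epochs=200, patience=5)
        model, hist = mm.train_network(MODEL_SPECS["F1.1"], cfg,
                                       x[:30], y[:30], x[30:], y[30:], seed=1)
        assert hist.stopped_epoch < 200 - 1 or hist.best_epoch == hist.stopped_epoch
        # restored weights reproduce the best validation loss
        z = model.forward(x[30:].astype(np.float32))
        assert nn.bce_from_logits(z, y[30:]) == pytest.approx(hist.best_val_loss, abs=1e-6)

    def test_constant_labels_converge_to_prior(self, rng):
        x = rng.normal(size=(24, 12)).astype(np.float32)
        y = np.ones(24)
        cfg = TrainingConfig(n_restarts=1, max_epochs=60, patience=10)
        model, hist = mm.train_network(MODEL_SPECS["F1.1"], cfg,
                                       x[:18], y[:18], x[18:], y[18:], seed=2)
        assert model.predict_proba(x).mean() > 0.9
        assert hist.val_loss[-1] < hist.val_loss[0]

    def test_empty_sets_rejected(self):
        cfg = TrainingConfig(n_restarts=1)
        with pytest.raises(ValueError, match="empty"):
            mm.train_network(MODEL_SPECS["F1.1"], cfg,
                             np.zeros((0, 12)), np.zeros(0),
                             np.zeros((2, 12)), np.zeros(2))


class TestRestarts:
    def test_restart_count_and_selection(self, rng):
        y = rng.integers(0, 2, 30).astype(float)
        x = rng.normal(size=(30, 12)).astype(np.float32) + y[:, None]
        cfg = TrainingConfig(n_restarts=4, max_epochs=10)
        model, losses = mm.train_with_restarts(MODEL_SPECS["F1.1"], cfg,
                                               x[:22], y[:22], x[22:], y[22:],
                                               master_seed=3)
        assert len(losses) == 4
        z = model.forward(x[22:].astype(np.float32))
        assert nn.bce_from_logits(z, y[22:]) == pytest.approx(min(losses), abs=1e-6)

    def test_single_restart_equals_plain_training(self, rng):
        y = rng.integers(0, 2, 30).astype(float)
        x = rng.normal(size=(30, 12)).astype(np.float32) + y[:, None]
        cfg = TrainingConfig(n_restarts=1, max_epochs=10)
        seed = int(np.random.default_rng(9).integers(0, 2**31 - 1, size=1)[0])
        _, losses = mm.train_with_restarts(MODEL_SPECS["F1.1"], cfg,
                                           x[:22], y[:22], x[22:], y[22:],
                                           master_seed=9)
        _, hist = mm.train_network(MODEL_SPECS["F1.1"], cfg,
                                   x[:22], y[:22], x[22:], y[22:], seed=seed)
        assert losses == [hist.best_val_loss]
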