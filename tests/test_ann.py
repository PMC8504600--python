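"""Network forward pass, pair extraction, LM training, sweep, reconstruction."""

import json
import math

import numpy as np
import pytest

from profile_restore.ann import (
    ANNModel,
    DataPairSet,
    SlidingWindowANN,
    TrainingConfig,
    extract_pairs,
    forward,
    load_model,
    reconstruct,
    sweep_hidden_nodes,
    train_lm,
)
from profile_restore.simulate import Profile


def random_model(rng, taps=7, nh=4):
    return ANNModel(
        rng.normal(0, 0.5, (taps, nh)),
        rng.normal(0, 0.5, nh),
        rng.normal(0, 1.0, nh),
        float(rng.normal(0, 0.2)),
    )


def naive_forward(model, s):
    """Brute-force double-loop evaluation of the three-layer network."""
    total = model.b_out
    for k in range(model.n_hidden):
        z = model.b_hidden[k]
        for j in range(model.window_taps):
            z += model.w_hidden[j, k] * s[j]
        total += model.w_out[k] * math.tanh(z)
    return total


class TestForward:
    def test_zero_network_outputs_zero(self):
        m = ANNModel(np.zeros((3, 2)), np.zeros(2), np.zeros(2), 0.0)
        assert forward(m, np.array([0.3, -0.4, 1.0])) == 0.0

    def test_hand_example(self):
        m = ANNModel(np.array([[1.0]]), np.array([0.0]), np.array([2.0]), 0.5)
        assert forward(m, np.array([1.0])) == pytest.approx(2.02319, abs=1e-5)
        assert forward(m, np.array([1.0])) == pytest.approx(2 * math.tanh(1) + 0.5, abs=1e-12)

    def test_collapsed_network_returns_bias(self):
        rng = np.random.default_rng(0)
        m = ANNModel(rng.normal(size=(5, 3)), rng.normal(size=3), np.zeros(3), 0.7)
        for _ in range(5):
            assert forward(m, rng.normal(size=5)) == pytest.approx(0.7, abs=1e-15)

    def test_matches_bruteforce_double_loop(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            m = random_model(rng, taps=int(rng.choice([1, 3, 5, 7, 9])), nh=int(rng.integers(1, 6)))
            s = rng.normal(size=m.window_taps)
            assert forward(m, s) == pytest.approx(naive_forward(m, s), abs=1e-12)

    def test_window_length_validation(self):
        m = ANNModel(np.zeros((3, 2)), np.zeros(2), np.zeros(2), 0.0)
        with pytest.raises(ValueError, match="window"):
            forward(m, np.zeros(4))

    def test_even_window_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            ANNModel(np.zeros((4, 2)), np.zeros(2), np.zeros(2), 0.0)


def grid_profiles(n=641, step=0.5):
    pos = (np.arange(n) - n // 2) * step
    base = np.tanh((80 - np.abs(pos)) / 5.0) * 0.5 + 0.5
    ref = np.tanh((80 - np.abs(pos)) / 3.0) * 0.5 + 0.5
    return Profile(pos, base), Profile(pos, ref)


class TestExtractPairs:
    def test_pair_count(self):
        a, b = grid_profiles()
        pairs = extract_pairs(a, b, window_mm=15.0)
        assert pairs.window_taps == 31
        assert len(pairs) == 641 - 31 + 1

    def test_identity_dataset_targets_are_window_centers(self):
        a, _ = grid_profiles()
        pairs = extract_pairs(a, a, window_mm=15.0)
        np.testing.assert_allclose(pairs.targets, pairs.inputs[:, 15], atol=0)

    def test_grid_mismatch_rejected(self):
        a, _ = grid_profiles()
        shifted = Profile(a.positions_mm + 0.25, a.values)
        with pytest.raises(ValueError, match="identical grid"):
            extract_pairs(a, shifted, 15.0)

    def test_split_fractions_and_determinism(self):
        a, b = grid_profiles()
        pairs = extract_pairs(a, b, 15.0).split((0.7, 0.15, 0.15), seed=4)
        n = len(pairs)
        n_train = pairs.partition("train")[1].size
        assert n_train == round(0.7 * n)
        again = extract_pairs(a, b, 15.0).split((0.7, 0.15, 0.15), seed=4)
        np.testing.assert_array_equal(pairs.labels, again.labels)


def teacher_pairs(seed=42, n=600, taps=7, nh=4):
    rng = np.random.default_rng(seed)
    teacher = random_model(rng, taps, nh)
    X = rng.uniform(0, 1, (n, taps))
    return teacher, DataPairSet(X, teacher.predict(X))


class TestTrainLm:
    def test_constant_targets_absorbed_by_bias(self):
        rng = np.random.default_rng(2)
        pairs = DataPairSet(rng.uniform(0, 1, (200, 5)), np.full(200, 0.7))
        res = train_lm(pairs, 2, TrainingConfig(restarts=2, seed=0, epochs=100))
        preds = res.model.predict(rng.uniform(0, 1, (50, 5)))
        np.testing.assert_allclose(preds, 0.7, atol=1e-6)

    @pytest.mark.parametrize("teacher_seed", [42, 43, 44, 45, 46])
    def test_teacher_student_recovery(self, teacher_seed):
        _, pairs = teacher_pairs(seed=teacher_seed)
        res = train_lm(pairs, 4, TrainingConfig(restarts=10, seed=7, patience=20))
        assert min(r["train_mse"] for r in res.restarts) < 1e-8

    def test_loss_non_increasing_over_accepted_steps(self):
        _, pairs = teacher_pairs(seed=1)
        res = train_lm(pairs, 4, TrainingConfig(restarts=2, seed=3, epochs=120))
        for hist in res.histories:
            losses = [row["train_mse"] for row in hist]
            assert all(b <= a + 1e-18 for a, b in zip(losses, losses[1:]))

    def test_seeded_determinism_bit_identical_history(self):
        _, pairs = teacher_pairs(seed=5)
        cfg = TrainingConfig(restarts=2, seed=9, epochs=60)
        a = train_lm(pairs, 3, cfg)
        b = train_lm(pairs, 3, cfg)
        assert a.histories == b.histories
        np.testing.assert_array_equal(a.model.w_hidden, b.model.w_hidden)

    def test_selection_uses_validation_mse(self):
        _, pairs = teacher_pairs(seed=6)
        res = train_lm(pairs, 4, TrainingConfig(restarts=4, seed=2, epochs=80))
        vals = [r["val_mse"] for r in res.restarts]
        assert res.restarts[res.selected_restart]["val_mse"] == min(vals)

    def test_capacity_warning(self):
        rng = np.random.default_rng(0)
        pairs = DataPairSet(rng.uniform(0, 1, (60, 9)), rng.uniform(0, 1, 60))
        with pytest.warns(UserWarning, match="training pairs"):
            train_lm(pairs, 4, TrainingConfig(restarts=1, seed=0, epochs=5))

    def test_summary_mentions_architecture(self):
        _, pairs = teacher_pairs(seed=8, n=400)
        res = train_lm(pairs, 4, TrainingConfig(restarts=1, seed=0, epochs=30))
        text = res.summary()
        assert "hidden nodes       4" in text
        assert "MSE" in text


class TestSweep:
    def test_curve_covers_requested_range_and_is_deterministic(self):
        _, pairs = teacher_pairs(seed=12, n=400)
        cfg = TrainingConfig(restarts=1, seed=5, epochs=40, sweep_range=(2, 4, 6))
        a = sweep_hidden_nodes(pairs, cfg)
        b = sweep_hidden_nodes(pairs, cfg)
        assert [nh for nh, _ in a.curve] == [2, 4, 6]
        assert [m for _, m in a.curve] == [m for _, m in b.curve]
        assert a.selected.model.n_hidden == min(a.curve, key=lambda t: t[1])[0]

    def test_default_sweep_range_has_ten_entries(self):
        cfg = TrainingConfig()
        assert cfg.sweep_range == tuple(range(2, 21, 2))


class TestReconstruct:
    def test_margins_copy_input(self):
        a, _ = grid_profiles()
        rng = np.random.default_rng(0)
        model = random_model(rng, taps=31, nh=3)
        out = reconstruct(model, a)
        # normalization rescales; margins must match the rescaled input
        scale = out.values[0] / a.values[0]
        np.testing.assert_allclose(out.values[:15], a.values[:15] * scale, rtol=1e-12)
        np.testing.assert_allclose(out.values[-15:], a.values[-15:] * scale, rtol=1e-12)

    def test_identity_trained_model_roundtrips_profile(self):
        a, _ = grid_profiles()
        pairs = extract_pairs(a, a, 15.0)
        res = train_lm(pairs, 6, TrainingConfig(restarts=2, seed=1, epochs=150, patience=30))
        out = res.reconstruct(a)
        assert np.max(np.abs(out.values - a.values)) < 1e-3

    def test_grid_step_mismatch_rejected(self):
        a, _ = grid_profiles()
        rng = np.random.default_rng(0)
        model = ANNModel(rng.normal(size=(31, 2)), rng.normal(size=2), rng.normal(size=2), 0.0,
                         grid_step_mm=0.25)
        with pytest.raises(ValueError, match="grid step"):
            reconstruct(model, a)


class TestSerialization:
    def test_json_roundtrip(self, tmp_path):
        _, pairs = teacher_pairs(seed=3, n=300)
        res = train_lm(pairs, 3, TrainingConfig(restarts=1, seed=0, epochs=30))
        path = tmp_path / "model.json"
        res.save(path)
        doc = json.loads(path.read_text())
        assert doc["architecture"]["activation_hidden"] == "tanh"
        assert "training" in doc and doc["training"]["restarts"]
        model = load_model(path)
        X = np.random.default_rng(0).uniform(0, 1, (10, model.window_taps))
        np.testing.assert_allclose(model.predict(X), res.model.predict(X), atol=0)
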