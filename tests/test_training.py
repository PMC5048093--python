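"""Step schedule, momentum updates, and the two training algorithms."""

import numpy as np
import pytest

from viewens.mcnn import ConvUnitSpec, MCNNConfig, forward_batch, init_model
from viewens.records import Dataset
from viewens.training import (
    TrainingConfig,
    TrainingError,
    bp_update,
    pooled_accuracy,
    step_schedule,
    train_explicit,
    train_implicit,
)

from conftest import make_dataset


def small_tc(**kw):
    defaults = dict(f2=40, p_max=4, max_epochs=2, seed=0)
    defaults.update(kw)
    return TrainingConfig(**defaults)


SMALL_CFG = MCNNConfig(2, 40, (ConvUnitSpec(5, 4, 3),), fc_width=6)


class TestStepSchedule:
    def test_initial_step(self):
        assert step_schedule(1, small_tc()) == 0.02

    def test_epochs_two_and_three_use_larger_decay(self):
        tc = small_tc()
        assert step_schedule(2, tc) == pytest.approx(0.02 * (1 - 0.0505))
        assert step_schedule(3, tc) == pytest.approx(0.02 * (1 - 0.0505) ** 2)

    def test_later_epochs_use_default_decay(self):
        tc = small_tc()
        assert step_schedule(4, tc) == pytest.approx(step_schedule(3, tc) * 0.99)
        assert step_schedule(10, tc) == pytest.approx(
            0.02 * (1 - 0.0505) ** 2 * 0.99**7
        )


class TestBpUpdate:
    def _model_and_grads(self, gval):
        model = init_model(SMALL_CFG, 0, dtype=np.float64)
        grads = {k: np.full_like(v, gval) for k, v in model.params.items()}
        return model, grads

    def test_zero_momentum_is_plain_gradient_descent(self):
        model, grads = self._model_and_grads(0.5)
        before = {k: v.copy() for k, v in model.params.items()}
        model, _ = bp_update(model, grads, None, step=0.1, momentum=0.0)
        for k in before:
            np.testing.assert_allclose(model.params[k], before[k] - 0.1 * 0.5)

    def test_zero_gradient_zero_velocity_is_noop(self):
        model, grads = self._model_and_grads(0.0)
        before = {k: v.copy() for k, v in model.params.items()}
        model, state = bp_update(model, grads, None, step=0.1, momentum=0.9)
        for k in before:
            np.testing.assert_array_equal(model.params[k], before[k])

    def test_two_momentum_steps_unroll(self):
        mu = 0.7
        model, grads = self._model_and_grads(1.0)
        before = {k: v.copy() for k, v in model.params.items()}
        model, state = bp_update(model, grads, None, step=0.1, momentum=mu)
        model, state = bp_update(model, grads, state, step=0.1, momentum=mu)
        for k in before:  # v1 = -s*g; v2 = mu*v1 - s*g; total = -s*g*(2+mu)
            np.testing.assert_allclose(model.params[k], before[k] - 0.1 * 1.0 * (2 + mu))

    def test_non_finite_gradient_raises(self):
        model, grads = self._model_and_grads(1.0)
        grads["fc_w"][0, 0] = np.nan
        with pytest.raises(TrainingError, match="fc_w"):
            bp_update(model, grads, None, step=0.1, momentum=0.9)


def tiny_sets(n_train=12, n_val=6):
    train = make_dataset(n=n_train, c=2, f=50, seed=1)
    val = make_dataset(n=n_val, c=2, f=50, seed=2)
    val = Dataset([r.with_data(r.data) for r in val.records])
    for i, r in enumerate(val.records):
        r.id = f"v{i}"
    return train, val


class TestTrainExplicit:
    def test_checkpoints_follow_running_max_rule(self):
        train, val = tiny_sets()
        model = init_model(SMALL_CFG, 0)
        best, hist = train_explicit(model, train, val, small_tc(max_epochs=4))
        saved = hist.saved_scores()
        assert len(saved) >= 1
        assert all(b > a for a, b in zip(saved, saved[1:]))  # strictly increasing
        # every non-saved cycle must not beat the running best
        running = -1.0
        for e in hist.entries:
            if e.checkpoint_saved:
                assert e.val_accuracy > running
                running = e.val_accuracy
            else:
                assert e.val_accuracy <= running

    def test_returned_model_reproduces_logged_best_accuracy(self):
        train, val = tiny_sets()
        model = init_model(SMALL_CFG, 1)
        cfg = small_tc(max_epochs=3)
        best, hist = train_explicit(model, train, val, cfg)
        views = np.stack([r.data[:, :40] for r in val.records])
        probs = forward_batch(best, views)
        acc = float(np.mean((probs >= 0.5).astype(int) == val.labels()))
        assert acc == pytest.approx(hist.best_val_accuracy)

    def test_determinism_given_seed(self):
        train, val = tiny_sets()
        cfg = small_tc(max_epochs=2)
        b1, h1 = train_explicit(init_model(SMALL_CFG, 0), train, val, cfg)
        b2, h2 = train_explicit(init_model(SMALL_CFG, 0), train, val, cfg)
        assert [e.__dict__ for e in h1.entries] == [e.__dict__ for e in h2.entries]
        assert all(np.array_equal(b1.params[k], b2.params[k]) for k in b1.params)

    def test_empty_validation_rejected(self):
        train, _ = tiny_sets()
        with pytest.raises(ValueError, match="validation"):
            train_explicit(init_model(SMALL_CFG, 0), train, Dataset([]), small_tc())

    def test_oversized_p_max_warns_and_uses_one_cycle_per_epoch(self):
        train, val = tiny_sets(n_train=6)
        with pytest.warns(UserWarning, match="p_max"):
            _, hist = train_explicit(
                init_model(SMALL_CFG, 0), train, val, small_tc(p_max=100, max_epochs=2)
            )
        assert len([e for e in hist.entries if e.scope == "cycle"]) == 2

    def test_validation_uses_fixed_offset_without_distortion(self):
        train, val = tiny_sets()
        _, hist = train_explicit(init_model(SMALL_CFG, 0), train, val, small_tc())
        assert all(e.val_offset == 1 and not e.val_distorted for e in hist.entries)


class TestTrainImplicit:
    def test_pooled_accuracy_arithmetic(self):
        assert pooled_accuracy([400, 420], [560, 560]) == pytest.approx(820 / 1120)

    def test_checkpoints_only_at_epoch_boundaries(self):
        train, _ = tiny_sets()
        _, hist = train_implicit(init_model(SMALL_CFG, 0), train, small_tc(max_epochs=3))
        for e in hist.entries:
            if e.checkpoint_saved:
                assert e.scope == "epoch"
        assert len([e for e in hist.entries if e.scope == "epoch"]) == 3

    def test_epoch_accuracy_pools_cycle_counts(self):
        train, _ = tiny_sets()
        cfg = small_tc(max_epochs=1, p_max=4)
        _, hist = train_implicit(init_model(SMALL_CFG, 0), train, cfg)
        cycles = [e for e in hist.entries if e.scope == "cycle"]
        epoch = [e for e in hist.entries if e.scope == "epoch"][0]
        # 12 samples in cycles of 4 -> three cycles of equal weight
        assert epoch.val_accuracy == pytest.approx(np.mean([c.val_accuracy for c in cycles]))

    def test_determinism_given_seed(self):
        train, _ = tiny_sets()
        cfg = small_tc(max_epochs=2)
        b1, h1 = train_implicit(init_model(SMALL_CFG, 2), train, cfg)
        b2, h2 = train_implicit(init_model(SMALL_CFG, 2), train, cfg)
        assert [e.__dict__ for e in h1.entries] == [e.__dict__ for e in h2.entries]
        assert all(np.array_equal(b1.params[k], b2.params[k]) for k in b1.params)


def test_easy_benchmark_learnability(fitted_easy):
    """Both trainers separate the easy synthetic classes well within 30 epochs."""
    assert fitted_easy["explicit"].best_val_accuracy >= 0.9
    assert fitted_easy["implicit"].best_val_accuracy >= 0.9
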