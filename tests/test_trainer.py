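"""Task training, best-epoch selection and progressive weight transfer."""

import numpy as np
import pytest

from progself.trainer import (
    ClassifierState,
    TrainConfig,
    predict_proba,
    progressive_train,
    train_non_progressive,
    train_task,
)
from progself.windowing import TaskData


def _separable_task(n=200, T=3, F=4, seed=0, flip=0.0):
    """Sequences whose last-step first feature determines the label."""
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, T, F))
    y = (X[:, -1, 0] > 0).astype(float)
    if flip:
        sel = rng.uniform(size=n) < flip
        y[sel] = 1 - y[sel]
    return TaskData(X, y, tuple(range(1, T + 1)), T + 1)


CFG = TrainConfig(
    batch_size=32,
    dropout=0.0,
    n_layers=1,
    hidden_size=8,
    max_epochs=40,
    patience=40,
    learning_rate=0.01,
    seed=5,
)


def test_separable_task_reaches_high_auc():
    tr = _separable_task(seed=1)
    va = _separable_task(seed=2)
    state = train_task(None, tr, va, CFG)
    assert state.best_val_auc >= 0.99


def test_zero_epochs_returns_initialization_unchanged():
    tr = _separable_task(seed=1)
    va = _separable_task(seed=2)
    from progself.trainer import fresh_state

    init = fresh_state(4, CFG)
    before = {k: v.copy() for k, v in init.params.items()}
    from dataclasses import replace

    out = train_task(init, tr, va, replace(CFG, max_epochs=0))
    assert out.best_epoch == 0
    assert all(np.array_equal(out.params[k], before[k]) for k in before)


def test_same_seed_same_weights():
    tr = _separable_task(seed=1)
    va = _separable_task(seed=2)
    a = train_task(None, tr, va, CFG)
    b = train_task(None, tr, va, CFG)
    assert a.best_epoch == b.best_epoch
    assert all(np.array_equal(a.params[k], b.params[k]) for k in a.params)


def test_single_class_validation_rejected():
    tr = _separable_task(seed=1)
    va = _separable_task(seed=2)
    va.targets[:] = 1.0
    with pytest.raises(ValueError, match="re-strat"):
        train_task(None, tr, va, CFG)


def test_input_width_mismatch_rejected():
    from progself.trainer import fresh_state

    init = fresh_state(7, CFG)
    tr = _separable_task(seed=1)  # width 4
    va = _separable_task(seed=2)
    with pytest.raises(ValueError, match="input width"):
        train_task(init, tr, va, CFG)


class TestProgressive:
    def _tasks(self, k=3, seed=0):
        out = []
        for i in range(k):
            out.append(
                (
                    _separable_task(seed=seed + 2 * i, flip=0.1),
                    _separable_task(seed=seed + 2 * i + 1, flip=0.1),
                )
            )
        return out

    def test_single_task_equals_train_task(self):
        tasks = self._tasks(k=1)
        a = progressive_train(tasks, CFG)
        b = train_task(None, tasks[0][0], tasks[0][1], CFG, task_tag=0)
        assert all(np.array_equal(a.params[k], b.params[k]) for k in a.params)

    def test_weight_transfer_initialization_identity(self):
        """Task k's model at epoch 0 reproduces task k-1's best outputs."""
        from dataclasses import replace

        tasks = self._tasks(k=2)
        state1 = train_task(None, tasks[0][0], tasks[0][1], CFG, task_tag=0)
        frozen = train_task(
            state1, tasks[1][0], tasks[1][1], replace(CFG, max_epochs=0)
        )
        X = tasks[1][1].inputs
        assert np.array_equal(predict_proba(state1, X), predict_proba(frozen, X))

    def test_task_log_records_every_task(self):
        tasks = self._tasks(k=3)
        state = progressive_train(tasks, CFG)
        assert [e["task"] for e in state.task_log] == [1, 2, 3]
        for e in state.task_log:
            assert 0.0 <= e["best_val_auc"] <= 1.0

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            progressive_train([], CFG)


def test_non_progressive_is_one_shot_training():
    tr = _separable_task(seed=3)
    va = _separable_task(seed=4)
    a = train_non_progressive(tr, va, CFG)
    b = train_task(None, tr, va, CFG)
    assert all(np.array_equal(a.params[k], b.params[k]) for k in a.params)


def test_predict_proba_bounds_and_determinism():
    tr = _separable_task(seed=1)
    va = _separable_task(seed=2)
    state = train_task(None, tr, va, CFG)
    p = predict_proba(state, va.inputs)
    assert ((p > 0) & (p < 1)).all()
    assert np.array_equal(p, predict_proba(state, va.inputs))


def test_state_round_trip(tmp_path):
    tr = _separable_task(seed=1)
    va = _separable_task(seed=2)
    state = train_task(None, tr, va, CFG)
    path = tmp_path / "model.npz"
    state.save(path)
    back = ClassifierState.load(path)
    assert back.best_epoch == state.best_epoch
    assert np.array_equal(
        predict_proba(back, va.inputs), predict_proba(state, va.inputs)
    )


def test_gru_and_rnn_cells_run_same_loop():
    from dataclasses import replace

    tr = _separable_task(seed=1)
    va = _separable_task(seed=2)
    for cell in ("gru", "rnn"):
        state = train_task(None, tr, va, replace(CFG, cell_kind=cell, max_epochs=10))
        assert state.cell_kind == cell
        assert 0.5 <= state.best_val_auc <= 1.0
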