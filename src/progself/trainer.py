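"""Task training with best-epoch-by-AUC selection and weight transfer.

One *submodel* is a multilayer recurrent classifier trained over an
ordered sequence of tasks: the first task starts from a fresh
initialization, and every later task is initialized with the weights of
the previous task's best epoch, where "best" means maximal validation
AUC (earliest epoch on ties).  Non-progressive baselines train the same
architecture once on a fixed subset of input steps predicting the final
step's label.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from sklearn.metrics import roc_auc_score

from .nn import RecurrentClassifier, bce_with_logits, init_params, make_optimizer
from .windowing import TaskData, TaskSequence, WindowScheme, materialize


@dataclass
class TrainConfig:
    """Training hyperparameters.

    Batch size 32, dropout 0.2 and BCE-with-sigmoid loss are the study's
    stated settings; optimizer, learning rate, hidden size and epoch
    budget are package defaults, all exposed here.
    """

    batch_size: int = 32
    dropout: float = 0.2
    n_layers: int = 4
    hidden_size: int = 64
    max_epochs: int = 100
    patience: int = 15
    learning_rate: float = 1e-3
    optimizer_name: str = "adam"
    seed: int = 0
    cell_kind: str = "lstm"

    def __post_init__(self) -> None:
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")
        if self.n_layers < 1:
            raise ValueError("n_layers must be >= 1")
        if self.batch_size < 1 or self.max_epochs < 0:
            raise ValueError("batch_size >= 1 and max_epochs >= 0 required")


@dataclass
class ClassifierState:
    """Weights plus architecture descriptor of one trained classifier."""

    cell_kind: str
    n_layers: int
    hidden_size: int
    input_size: int
    params: dict[str, np.ndarray]
    best_epoch: int = 0
    best_val_auc: float = float("nan")
    task_log: list[dict] = field(default_factory=list)

    def to_classifier(self, dropout: float = 0.0) -> RecurrentClassifier:
        return RecurrentClassifier(
            input_size=self.input_size,
            hidden_size=self.hidden_size,
            n_layers=self.n_layers,
            cell_kind=self.cell_kind,
            dropout=dropout,
            params={k: v.copy() for k, v in self.params.items()},
        )

    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savez(path, **self.params)
        desc = {
            "cell_kind": self.cell_kind,
            "n_layers": self.n_layers,
            "hidden_size": self.hidden_size,
            "input_size": self.input_size,
            "best_epoch": self.best_epoch,
            "best_val_auc": self.best_val_auc,
            "task_log": self.task_log,
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(desc))

    @classmethod
    def load(cls, path: str | Path) -> "ClassifierState":
        path = Path(path)
        desc = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        with np.load(path if path.suffix == ".npz" else str(path) + ".npz") as z:
            params = {k: z[k] for k in z.files}
        return cls(params=params, **desc)


def fresh_state(input_size: int, config: TrainConfig, seed_offset: int = 0) -> ClassifierState:
    rng = np.random.default_rng([config.seed, 100 + seed_offset])
    params = init_params(
        input_size, config.hidden_size, config.n_layers, config.cell_kind, rng
    )
    return ClassifierState(
        cell_kind=config.cell_kind,
        n_layers=config.n_layers,
        hidden_size=config.hidden_size,
        input_size=input_size,
        params=params,
    )


def _val_auc(model: RecurrentClassifier, val: TaskData) -> float:
    y = val.targets
    if len(np.unique(y)) < 2:
        raise ValueError(
            "validation fold contains a single class; AUC is undefined — "
            "re-stratify the folds on the outcome"
        )
    return float(roc_auc_score(y, model.predict_proba(val.inputs)))


def train_task(
    init: ClassifierState | None,
    train_data: TaskData,
    val_data: TaskData,
    config: TrainConfig,
    task_tag: int = 0,
) -> ClassifierState:
    """Train one task; return the weights of the best validation-AUC epoch.

    ``init=None`` starts from a fresh seeded initialization; otherwise the
    given state's weights initialize the model (weight transfer).  With
    ``max_epochs == 0`` the initialization is returned unchanged (its
    validation AUC is still recorded).
    """
    input_size = train_data.inputs.shape[2]
    if init is None:
        state = fresh_state(input_size, config, seed_offset=task_tag)
    else:
        if init.input_size != input_size:
            raise ValueError(
                f"transferred weights expect input width {init.input_size}, "
                f"task provides {input_size}"
            )
        state = init

    model = RecurrentClassifier(
        input_size=input_size,
        hidden_size=config.hidden_size,
        n_layers=config.n_layers,
        cell_kind=config.cell_kind,
        dropout=config.dropout,
        params={k: v.copy() for k, v in state.params.items()},
    )
    best_params = model.copy_params()
    best_auc = _val_auc(model, val_data)
    best_epoch = 0

    if config.max_epochs == 0:
        return replace(
            state,
            params=best_params,
            best_epoch=0,
            best_val_auc=best_auc,
            task_log=[],
        )

    rng = np.random.default_rng([config.seed, 200 + task_tag])
    opt = make_optimizer(config.optimizer_name, model.params, config.learning_rate)
    n = len(train_data.targets)
    log = []
    since_best = 0
    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            xb = train_data.inputs[idx]
            yb = train_data.targets[idx]
            logits, cache = model.forward(xb, training=True, rng=rng)
            loss, dlogits = bce_with_logits(logits, yb)
            grads = model.backward(cache, dlogits)
            opt.step(model.params, grads)
            epoch_loss += loss * len(idx)
        auc = _val_auc(model, val_data)
        log.append({"epoch": epoch, "train_loss": epoch_loss / n, "val_auc": auc})
        if auc > best_auc:  # strict: ties keep the earliest epoch
            best_auc = auc
            best_epoch = epoch
            best_params = model.copy_params()
            since_best = 0
        else:
            since_best += 1
            if since_best >= config.patience:
                break

    return ClassifierState(
        cell_kind=config.cell_kind,
        n_layers=config.n_layers,
        hidden_size=config.hidden_size,
        input_size=input_size,
        params=best_params,
        best_epoch=best_epoch,
        best_val_auc=best_auc,
        task_log=log,
    )


def progressive_train(
    task_datasets: list[tuple[TaskData, TaskData]], config: TrainConfig
) -> ClassifierState:
    """Sequentially train a task list with best-epoch weight transfer.

    ``task_datasets`` is an ordered list of (train, validation) pairs;
    task 1 trains from scratch, task k > 1 from task k-1's best weights.
    The returned state is the final task's, with a per-task summary in
    ``task_log``.
    """
    if not task_datasets:
        raise ValueError("progressive_train needs at least one task")
    state: ClassifierState | None = None
    summary = []
    for i, (tr, va) in enumerate(task_datasets):
        state = train_task(state, tr, va, config, task_tag=i)
        summary.append(
            {
                "task": i + 1,
                "input_steps": list(tr.input_steps),
                "label_step": tr.label_step,
                "best_epoch": state.best_epoch,
                "best_val_auc": state.best_val_auc,
            }
        )
    state.task_log = summary
    return state


def make_task(panel, labels, input_steps, label_step) -> TaskData:
    """Materialize a single (input-steps -> label-step) dataset."""
    scheme = WindowScheme("rolling", N=max(label_step, panel.n_steps), n=1)
    seq = TaskSequence([(tuple(input_steps), label_step)], scheme)
    return materialize(panel, labels, seq)[0]


def train_non_progressive(
    train_task_data: TaskData, val_task_data: TaskData, config: TrainConfig
) -> ClassifierState:
    """One-shot baseline: train directly on a fixed input-step subset."""
    return train_task(None, train_task_data, val_task_data, config)


def predict_proba(state: ClassifierState, inputs: np.ndarray) -> np.ndarray:
    """Per-participant positive-class probability (dropout disabled)."""
    return state.to_classifier().predict_proba(inputs)
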