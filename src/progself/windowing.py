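"""Supervised task construction from the longitudinal panel.

Each progressive submodel is defined by an ordered sequence of
(input-steps, label-step) tasks built from one of three window schemes
over ``N`` 1-based time-steps:

* **expanding** — the window starts at width ``n`` and grows by one step
  per task: task ``i`` uses steps ``1..i+n-1`` to predict step ``i+n``.
* **rolling** — the window keeps width ``n`` and slides forward: task
  ``i`` uses steps ``i..i+n-1`` to predict step ``i+n``.
* **skipping** — the time resolution is coarsened by a skip interval
  ``w``: task ``i`` predicts step ``i+w+2`` from every ``(w+1)``-th step
  walking backwards from ``i+w+1`` until the first step, i.e. indices
  ``i + (1-s)(w+1)`` for ``s = 0, 1, 2, ...`` while the index stays >= 1.

Both expanding and rolling schemes yield ``p = N - n`` tasks; the
skipping scheme yields ``p = N - w - 2``.  Every scheme's final task
predicts step ``N``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .labeling import UNDEFINED_LABEL, LabelSeries
from .panel import CohortPanel

SCHEME_KINDS = ("expanding", "rolling", "skipping")


@dataclass(frozen=True)
class WindowScheme:
    kind: str  # one of SCHEME_KINDS
    N: int  # total number of time-steps
    n: int | None = None  # initial window width (expanding / rolling)
    w: int | None = None  # skip interval (skipping)

    def __post_init__(self) -> None:
        if self.kind not in SCHEME_KINDS:
            raise ValueError(f"unknown scheme kind {self.kind!r}")
        if self.kind in ("expanding", "rolling"):
            if self.n is None or not (1 <= self.n < self.N):
                raise ValueError("expanding/rolling require 1 <= n < N")
        else:
            if self.w is None or not (1 <= self.w <= self.N - 3):
                raise ValueError("skipping requires 1 <= w <= N - 3")


@dataclass
class TaskSequence:
    """Ordered supervised tasks for one submodel."""

    tasks: list[tuple[tuple[int, ...], int]]  # (input_steps, label_step)
    scheme: WindowScheme

    def __post_init__(self) -> None:
        for steps, label_step in self.tasks:
            if not steps:
                raise ValueError("task with empty input steps")
            if any(not (1 <= s <= self.scheme.N) for s in steps):
                raise ValueError("input step outside [1, N]")
            if label_step <= max(steps) or label_step > self.scheme.N:
                raise ValueError("label step must follow all input steps")

    @property
    def p(self) -> int:
        return len(self.tasks)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "scheme": {
                        "kind": self.scheme.kind,
                        "N": self.scheme.N,
                        "n": self.scheme.n,
                        "w": self.scheme.w,
                    },
                    "tasks": [
                        {"input_steps": list(s), "label_step": y}
                        for s, y in self.tasks
                    ],
                }
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "TaskSequence":
        d = json.loads(Path(path).read_text())
        scheme = WindowScheme(**d["scheme"])
        tasks = [
            (tuple(t["input_steps"]), t["label_step"]) for t in d["tasks"]
        ]
        return cls(tasks, scheme)


def build_expanding_tasks(N: int, n: int) -> TaskSequence:
    """Growing-window tasks: ``[1..n] -> n+1``, ``[1..n+1] -> n+2``, ..."""
    scheme = WindowScheme("expanding", N=N, n=n)
    tasks = [
        (tuple(range(1, i + n)), i + n) for i in range(1, N - n + 1)
    ]
    return TaskSequence(tasks, scheme)


def build_rolling_tasks(N: int, n: int) -> TaskSequence:
    """Fixed-width sliding-window tasks: ``[i..i+n-1] -> i+n``."""
    scheme = WindowScheme("rolling", N=N, n=n)
    tasks = [
        (tuple(range(i, i + n)), i + n) for i in range(1, N - n + 1)
    ]
    return TaskSequence(tasks, scheme)


def build_skipping_tasks(N: int, w: int) -> TaskSequence:
    """Coarsened-resolution tasks with skip interval ``w``.

    Task ``i`` predicts step ``i + w + 2``; its inputs are every
    ``(w+1)``-th step backwards from ``i + w + 1`` down to step 1,
    returned in ascending time order.
    """
    scheme = WindowScheme("skipping", N=N, w=w)
    tasks = []
    for i in range(1, N - w - 1):
        steps = []
        s = 0
        while True:
            idx = i + (1 - s) * (w + 1)
            if idx < 1:
                break
            steps.append(idx)
            s += 1
        tasks.append((tuple(sorted(steps)), i + w + 2))
    return TaskSequence(tasks, scheme)


def submodel_sequences(N: int, n: int = 3) -> dict[int, TaskSequence]:
    """The four canonical submodel task sequences.

    1 — expanding window, 2 — rolling window, 3 — skip interval 1
    (doubled resolution), 4 — skip interval 2 (tripled resolution).
    """
    return {
        1: build_expanding_tasks(N, n),
        2: build_rolling_tasks(N, n),
        3: build_skipping_tasks(N, 1),
        4: build_skipping_tasks(N, 2),
    }


@dataclass
class TaskData:
    """One task's supervised dataset: sequences and binary targets."""

    inputs: np.ndarray  # (P, L, F)
    targets: np.ndarray  # (P,)
    input_steps: tuple[int, ...]
    label_step: int


def materialize(
    panel: CohortPanel, labels: LabelSeries, sequence: TaskSequence
) -> list[TaskData]:
    """Slice the panel into each task's per-participant sequences.

    The panel must be complete (mask all True) and the labels defined at
    every label step; the participant set is identical across tasks.
    """
    if panel.n_features == 0:
        raise ValueError("panel has no features (empty feature selection?)")
    if not panel.mask.all():
        raise ValueError("panel must be imputed (complete) before materializing")
    out = []
    for steps, label_step in sequence.tasks:
        if label_step > panel.n_steps:
            raise ValueError(
                f"label step {label_step} beyond panel's {panel.n_steps} steps"
            )
        y = labels.labels[:, label_step - 1]
        if (y == UNDEFINED_LABEL).any():
            raise ValueError(f"undefined labels at step {label_step}")
        idx = [s - 1 for s in steps]
        out.append(
            TaskData(
                inputs=panel.values[:, idx, :],
                targets=y.astype(float),
                input_steps=steps,
                label_step=label_step,
            )
        )
    return out
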