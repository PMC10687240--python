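"""Window-scheme task construction against independent enumeration oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from progself.labeling import LabelSeries
from progself.windowing import (
    TaskSequence,
    WindowScheme,
    build_expanding_tasks,
    build_rolling_tasks,
    build_skipping_tasks,
    materialize,
    submodel_sequences,
)

from conftest import make_panel


# ----- independent oracles (simple loops, no shared code) -----------------


def oracle_expanding(N, n):
    out = []
    for i in range(1, N - n + 1):
        out.append((tuple(range(1, i + n)), i + n))
    return out


def oracle_rolling(N, n):
    out = []
    for i in range(1, N - n + 1):
        out.append((tuple(range(i, i + n)), i + n))
    return out


def oracle_skipping(N, w):
    out = []
    for i in range(1, N - w - 1):
        steps = set()
        s = 0
        while i + (1 - s) * (w + 1) >= 1:
            steps.add(i + (1 - s) * (w + 1))
            s += 1
        out.append((tuple(sorted(steps)), i + w + 2))
    return out


def test_expanding_canonical():
    seq = build_expanding_tasks(7, 3)
    assert seq.tasks == [
        ((1, 2, 3), 4),
        ((1, 2, 3, 4), 5),
        ((1, 2, 3, 4, 5), 6),
        ((1, 2, 3, 4, 5, 6), 7),
    ]


def test_rolling_canonical():
    seq = build_rolling_tasks(7, 3)
    assert seq.tasks == [
        ((1, 2, 3), 4),
        ((2, 3, 4), 5),
        ((3, 4, 5), 6),
        ((4, 5, 6), 7),
    ]


def test_skipping_canonical():
    assert build_skipping_tasks(7, 1).tasks == [
        ((1, 3), 4),
        ((2, 4), 5),
        ((1, 3, 5), 6),
        ((2, 4, 6), 7),
    ]
    assert build_skipping_tasks(7, 2).tasks == [
        ((1, 4), 5),
        ((2, 5), 6),
        ((3, 6), 7),
    ]


def test_boundary_single_task():
    assert build_expanding_tasks(4, 3).tasks == [((1, 2, 3), 4)]


def test_exhaustive_against_oracles():
    """All valid (N <= 12, n, w) match brute-force enumeration and the
    closed-form task counts."""
    for N in range(2, 13):
        for n in range(1, N):
            e = build_expanding_tasks(N, n)
            r = build_rolling_tasks(N, n)
            assert e.tasks == oracle_expanding(N, n)
            assert r.tasks == oracle_rolling(N, n)
            assert e.p == r.p == N - n
            assert e.tasks[-1][1] == r.tasks[-1][1] == N
        for w in range(1, N - 2):
            s = build_skipping_tasks(N, w)
            assert s.tasks == oracle_skipping(N, w)
            assert s.p == N - w - 2
            assert s.tasks[-1][1] == N


@settings(deadline=None, max_examples=60)
@given(st.integers(2, 20), st.data())
def test_properties(N, data):
    """Label step strictly follows inputs; skipping gaps are exactly w+1;
    rolling windows keep constant width; schemes coincide at task 1."""
    n = data.draw(st.integers(1, N - 1))
    e, r = build_expanding_tasks(N, n), build_rolling_tasks(N, n)
    assert e.tasks[0] == r.tasks[0]
    for steps, y in e.tasks + r.tasks:
        assert y > max(steps)
    assert all(len(steps) == n for steps, _ in r.tasks)
    if N >= 4:
        w = data.draw(st.integers(1, N - 3))
        for steps, y in build_skipping_tasks(N, w).tasks:
            assert y > max(steps)
            gaps = np.diff(steps)
            assert (gaps == w + 1).all()


def test_invalid_parameters_rejected():
    with pytest.raises(ValueError):
        build_expanding_tasks(5, 5)
    with pytest.raises(ValueError):
        build_rolling_tasks(5, 0)
    with pytest.raises(ValueError):
        build_skipping_tasks(7, 5)


def test_json_round_trip(tmp_path):
    seq = build_skipping_tasks(7, 1)
    path = tmp_path / "tasks.json"
    seq.to_json(path)
    back = TaskSequence.from_json(path)
    assert back.tasks == seq.tasks
    assert back.scheme == seq.scheme


class TestMaterialize:
    def _fixture(self, P=6, T=7, F=4):
        rng = np.random.default_rng(0)
        panel = make_panel(rng.standard_normal((P, T, F)))
        labels = LabelSeries(rng.integers(0, 2, (P, T)), panel.participant_ids)
        return panel, labels

    def test_shapes_and_row_counts(self):
        panel, labels = self._fixture()
        tasks = materialize(panel, labels, build_expanding_tasks(7, 3))
        assert [t.inputs.shape for t in tasks] == [
            (6, 3, 4),
            (6, 4, 4),
            (6, 5, 4),
            (6, 6, 4),
        ]
        for t in tasks:
            assert len(t.targets) == panel.n_participants

    def test_targets_are_label_step_labels(self):
        panel, labels = self._fixture()
        tasks = materialize(panel, labels, build_rolling_tasks(7, 3))
        for t in tasks:
            assert np.array_equal(
                t.targets, labels.labels[:, t.label_step - 1].astype(float)
            )

    def test_incomplete_panel_rejected(self):
        panel, labels = self._fixture()
        panel.mask[0, 0, 0] = False
        with pytest.raises(ValueError):
            materialize(panel, labels, build_expanding_tasks(7, 3))

    def test_label_step_beyond_panel_rejected(self):
        panel, labels = self._fixture(T=5)
        seq = build_expanding_tasks(7, 3)
        with pytest.raises(ValueError):
            materialize(panel, labels, seq)

    def test_concatenation_not_addition(self):
        """Window 'sums' are ordered concatenation of step blocks."""
        panel, labels = self._fixture()
        task = materialize(panel, labels, build_skipping_tasks(7, 1))[2]
        assert task.input_steps == (1, 3, 5)
        assert np.array_equal(task.inputs[:, 1, :], panel.values[:, 2, :])


def test_submodel_sequences_cover_four_schemes():
    seqs = submodel_sequences(7)
    assert {k: s.p for k, s in seqs.items()} == {1: 4, 2: 4, 3: 4, 4: 3}
    assert seqs[1].scheme.kind == "expanding"
    assert seqs[2].scheme.kind == "rolling"
    assert seqs[3].scheme.w == 1 and seqs[4].scheme.w == 2
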