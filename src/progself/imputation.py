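"""Bidirectional recurrent imputation of missing panel values.

The default imputer follows the BRITS idea: per time direction, a
recurrent estimator with per-feature temporal decay regresses each step's
feature vector from the decayed hidden history; missing entries are
replaced in-stream by the running estimate so the recurrence can continue
across gaps.  Training minimizes reconstruction error on observed
entries in both directions plus a forward/backward consistency penalty.
Imputation fills each missing cell with the unweighted mean of the two
directional estimates; observed cells are always preserved exactly.

Only the imputation objective is implemented — the classification branch
of the original multi-task formulation is intentionally omitted, since
the downstream classifier is a separate model.  A fast fallback imputer
(per-feature linear interpolation in time, then feature mean) is
available via ``method="interp"``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .nn import make_optimizer
from .panel import CohortPanel


@dataclass
class ImputationModel:
    """Fitted imputer: directional estimators plus normalization stats."""

    method: str  # "brits" or "interp"
    feature_names: list[str]
    mean: np.ndarray  # per-feature mean of observed entries
    sd: np.ndarray  # per-feature SD of observed entries (>= floor)
    hidden_size: int = 0
    params: dict[str, np.ndarray] | None = None  # f_* and b_* parameter groups
    loss_history: list[float] = field(default_factory=list)

    def decay_rates(self, deltas: np.ndarray, direction: str = "f") -> np.ndarray:
        """Effective (non-negative) temporal decay exponents for given gaps."""
        if self.params is None:
            raise ValueError("fallback imputer has no decay parameters")
        W, b = self.params[f"{direction}_Wg"], self.params[f"{direction}_bg"]
        return np.maximum(deltas @ W + b, 0.0)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        header = {
            "method": self.method,
            "feature_names": self.feature_names,
            "mean": self.mean.tolist(),
            "sd": self.sd.tolist(),
            "hidden_size": self.hidden_size,
            "loss_history": self.loss_history,
        }
        np.savez(path, **(self.params or {}))
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(header))

    @classmethod
    def load(cls, path: str | Path) -> "ImputationModel":
        path = Path(path)
        header = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        npz = path if str(path).endswith(".npz") else Path(str(path) + ".npz")
        params = None
        if npz.exists():
            with np.load(npz) as z:
                params = {k: z[k] for k in z.files} or None
        return cls(
            method=header["method"],
            feature_names=header["feature_names"],
            mean=np.array(header["mean"]),
            sd=np.array(header["sd"]),
            hidden_size=header["hidden_size"],
            params=params,
            loss_history=header["loss_history"],
        )


def fit_imputer(
    panel: CohortPanel,
    epochs: int = 100,
    seed: int = 0,
    hidden_size: int = 32,
    learning_rate: float = 1e-2,
    batch_size: int = 128,
    consistency_weight: float = 0.1,
    method: str = "brits",
) -> ImputationModel:
    """Fit an imputation model on the observed entries of the panel."""
    if panel.n_steps < 2:
        raise ValueError("imputation needs at least 2 time-steps")
    obs_per_feature = panel.mask.reshape(-1, panel.n_features).sum(axis=0)
    dead = np.flatnonzero(obs_per_feature == 0)
    if dead.size:
        names = [panel.feature_names[i] for i in dead]
        raise ValueError(f"features with zero observed values: {names}")

    mean, sd = _observed_stats(panel)
    if method == "interp":
        return ImputationModel("interp", list(panel.feature_names), mean, sd)
    if method != "brits":
        raise ValueError(f"unknown imputation method {method!r}")

    F, H = panel.n_features, hidden_size
    rng = np.random.default_rng([seed, 3])
    params: dict[str, np.ndarray] = {}
    k = 1.0 / np.sqrt(H)
    for d in ("f", "b"):
        params[f"{d}_Wg"] = rng.uniform(0.0, 0.2, size=(F, H))
        params[f"{d}_bg"] = np.zeros(H)
        params[f"{d}_Wo"] = rng.uniform(-k, k, size=(H, F))
        params[f"{d}_bo"] = np.zeros(F)
        params[f"{d}_Wi"] = rng.uniform(-k, k, size=(2 * F, H))
        params[f"{d}_Wh"] = rng.uniform(-k, k, size=(H, H))
        params[f"{d}_bi"] = np.zeros(H)

    xn = (panel.values - mean) / sd
    xn = np.where(panel.mask, xn, 0.0)
    m = panel.mask.astype(float)
    P = panel.n_participants

    opt = make_optimizer("adam", params, learning_rate)
    history = []
    for _ in range(epochs):
        order = rng.permutation(P)
        total, nobs = 0.0, 0.0
        for start in range(0, P, batch_size):
            idx = order[start : start + batch_size]
            loss, grads, n_batch_obs = _brits_loss_and_grads(
                params, xn[idx], m[idx], consistency_weight
            )
            opt.step(params, grads)
            total += loss * n_batch_obs
            nobs += n_batch_obs
        history.append(total / max(nobs, 1.0))

    return ImputationModel(
        "brits",
        list(panel.feature_names),
        mean,
        sd,
        hidden_size=H,
        params=params,
        loss_history=history,
    )


def impute(model: ImputationModel, panel: CohortPanel) -> CohortPanel:
    """Fill missing cells; observed cells are preserved bitwise."""
    if list(panel.feature_names) != list(model.feature_names):
        raise ValueError(
            "feature set mismatch between imputation model and panel"
        )
    if panel.mask.all():
        filled = panel.values.copy()
    elif model.method == "interp":
        filled = _interp_fill(panel, model)
    else:
        xn = (panel.values - model.mean) / model.sd
        xn = np.where(panel.mask, xn, 0.0)
        m = panel.mask.astype(float)
        est_f = _direction_forward(model.params, "f", xn, m)[0]
        est_b = _direction_forward(
            model.params, "b", xn[:, ::-1], m[:, ::-1]
        )[0][:, ::-1]
        est = 0.5 * (est_f + est_b)
        filled = np.where(panel.mask, panel.values, est * model.sd + model.mean)
    return CohortPanel(
        participant_ids=panel.participant_ids,
        values=filled,
        mask=np.ones_like(panel.mask),
        feature_names=list(panel.feature_names),
        biomarker_index=dict(panel.biomarker_index),
        survey_flags=panel.survey_flags.copy(),
    )


def mean_impute(panel: CohortPanel) -> CohortPanel:
    """Per-feature observed-mean fill (baseline for comparisons)."""
    mean, _ = _observed_stats(panel)
    filled = np.where(panel.mask, panel.values, mean[None, None, :])
    return CohortPanel(
        participant_ids=panel.participant_ids,
        values=filled,
        mask=np.ones_like(panel.mask),
        feature_names=list(panel.feature_names),
        biomarker_index=dict(panel.biomarker_index),
        survey_flags=panel.survey_flags.copy(),
    )


# ----- internals ----------------------------------------------------------


def _observed_stats(panel: CohortPanel) -> tuple[np.ndarray, np.ndarray]:
    flat = panel.values.reshape(-1, panel.n_features)
    mask = panel.mask.reshape(-1, panel.n_features)
    n = mask.sum(axis=0)
    mean = np.where(n > 0, (flat * mask).sum(axis=0) / np.maximum(n, 1), 0.0)
    var = (((flat - mean) * mask) ** 2).sum(axis=0) / np.maximum(n, 1)
    sd = np.sqrt(var)
    sd = np.where(sd < 1e-8, 1.0, sd)
    return mean, sd


def _deltas(m: np.ndarray) -> np.ndarray:
    """Per-feature time since last observation (unit step gaps)."""
    B, T, F = m.shape
    d = np.zeros((B, T, F))
    for t in range(1, T):
        d[:, t] = 1.0 + (1.0 - m[:, t - 1]) * d[:, t - 1]
    return d


def _direction_forward(params, d, xn, m):
    """One directional pass; returns estimates, hidden states and caches."""
    Wg, bg = params[f"{d}_Wg"], params[f"{d}_bg"]
    Wo, bo = params[f"{d}_Wo"], params[f"{d}_bo"]
    Wi, Wh, bi = params[f"{d}_Wi"], params[f"{d}_Wh"], params[f"{d}_bi"]
    B, T, F = xn.shape
    H = Wh.shape[0]
    delta = _deltas(m)
    h = np.zeros((B, H))
    est = np.empty((B, T, F))
    caches = []
    for t in range(T):
        gdec = delta[:, t] @ Wg + bg
        gpos = np.maximum(gdec, 0.0)
        gamma = np.exp(-gpos)
        hdec = gamma * h
        xhat = hdec @ Wo + bo
        xc = m[:, t] * xn[:, t] + (1.0 - m[:, t]) * xhat
        u = np.concatenate([xc, m[:, t]], axis=1)
        a = u @ Wi + hdec @ Wh + bi
        h_new = np.tanh(a)
        est[:, t] = xhat
        caches.append((delta[:, t], gdec, gamma, h, hdec, xhat, u, h_new))
        h = h_new
    return est, caches


def _direction_backward(params, d, xn, m, caches, dest):
    """Backprop one direction given d(loss)/d(estimates)."""
    Wg = params[f"{d}_Wg"]
    Wo = params[f"{d}_Wo"]
    Wi, Wh = params[f"{d}_Wi"], params[f"{d}_Wh"]
    B, T, F = xn.shape
    H = Wh.shape[0]
    g = {
        f"{d}_Wg": np.zeros_like(Wg),
        f"{d}_bg": np.zeros(H),
        f"{d}_Wo": np.zeros_like(Wo),
        f"{d}_bo": np.zeros(F),
        f"{d}_Wi": np.zeros_like(Wi),
        f"{d}_Wh": np.zeros_like(Wh),
        f"{d}_bi": np.zeros(H),
    }
    dh = np.zeros((B, H))
    for t in range(T - 1, -1, -1):
        delta_t, gdec, gamma, h_prev, hdec, xhat, u, h_new = caches[t]
        da = dh * (1.0 - h_new * h_new)
        g[f"{d}_Wi"] += u.T @ da
        g[f"{d}_bi"] += da.sum(axis=0)
        g[f"{d}_Wh"] += hdec.T @ da
        du = da @ Wi.T
        dxc = du[:, :F]
        dhdec = da @ Wh.T
        dxhat = dest[:, t] + dxc * (1.0 - m[:, t])
        g[f"{d}_Wo"] += hdec.T @ dxhat
        g[f"{d}_bo"] += dxhat.sum(axis=0)
        dhdec += dxhat @ Wo.T
        dgamma = dhdec * h_prev
        dh = dhdec * gamma
        dgdec = -gamma * dgamma * (gdec > 0.0)
        g[f"{d}_Wg"] += delta_t.T @ dgdec
        g[f"{d}_bg"] += dgdec.sum(axis=0)
    return g


def _brits_loss_and_grads(params, xn, m, consistency_weight):
    est_f, cache_f = _direction_forward(params, "f", xn, m)
    xr, mr = xn[:, ::-1], m[:, ::-1]
    est_b_rev, cache_b = _direction_forward(params, "b", xr, mr)
    est_b = est_b_rev[:, ::-1]

    n_obs = m.sum()
    resid_f = (est_f - xn) * m
    resid_b = (est_b - xn) * m
    loss_rec = (resid_f**2).sum() / n_obs + (resid_b**2).sum() / n_obs
    diff = est_f - est_b
    loss_cons = consistency_weight * (diff**2).mean()
    loss = loss_rec + loss_cons

    dcons = 2.0 * consistency_weight * diff / diff.size
    dest_f = 2.0 * resid_f / n_obs + dcons
    dest_b = 2.0 * resid_b / n_obs - dcons

    grads = _direction_backward(params, "f", xn, m, cache_f, dest_f)
    grads.update(
        _direction_backward(params, "b", xr, mr, cache_b, dest_b[:, ::-1])
    )
    return float(loss), grads, float(n_obs)


def _interp_fill(panel: CohortPanel, model: ImputationModel) -> np.ndarray:
    """Per-participant linear interpolation in time, then feature mean."""
    filled = panel.values.copy()
    T = panel.n_steps
    grid = np.arange(T, dtype=float)
    for p in range(panel.n_participants):
        for f in range(panel.n_features):
            obs = panel.mask[p, :, f]
            if obs.all():
                continue
            if not obs.any():
                filled[p, :, f] = model.mean[f]
                continue
            filled[p, ~obs, f] = np.interp(
                grid[~obs], grid[obs], panel.values[p, obs, f]
            )
    return filled
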