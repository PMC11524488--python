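"""Local parameter updates and the full training loops.

Monte Carlo predictive coding trains by Monte Carlo expectation-maximization:
per mini-batch, latents are warmed up by MAP descent and then sampled with
Langevin dynamics (E-step); the parameters then take a gradient step on the
sampled joint log-likelihood (M-step), which is the local Hebbian-like rule

    dW_l = (1/S) sum_samples sum_batch  eps_l f(x_{l+1})^T
    dmu  = (1/S) sum_samples sum_batch  eps_L

The classic predictive-coding baseline replaces the sample average by the
single converged MAP state.  Deltas are applied through a learning optimizer
(Adam by default) with optional weight decay.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from ._optim import make_optimizer
from .dynamics import InferenceSchedule, Trajectory, mcpc_step, pc_inference
from .model import GenerativeModel, NetworkState, init_state, joint_energy, prediction_errors

__all__ = [
    "TrainConfig",
    "TrainLog",
    "TrainDivergence",
    "mcpc_param_update",
    "pc_param_update",
    "train",
]

#: |W| ceiling beyond which PC training is declared diverged instead of
#: being allowed to overflow (weight blow-up is its expected failure mode).
WEIGHT_CAP = 1e6


class TrainDivergence(RuntimeError):
    """Raised when parameters become non-finite; carries epoch/batch info."""


@dataclass
class TrainConfig:
    """Hyperparameters of one training run.

    Defaults are the Gaussian-task values: 75 epochs, batch 256, Adam
    learning rate 0.02 with no decay, inference schedule of 150 Adam warm-up
    steps followed by 150 mixing and 1 sampling Langevin step at h = 0.02.
    """

    epochs: int = 75
    batch_size: int = 256
    lr: float = 0.02
    weight_decay: float = 0.0
    optimizer: str = "adam"
    schedule: InferenceSchedule = field(default_factory=InferenceSchedule)
    seed: int = 0
    shuffle: bool = True
    param_log_every: int | None = None
    checkpoint_updates: tuple[int, ...] = ()

    def __post_init__(self):
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")
        if self.lr < 0:
            raise ValueError("learning rate must be >= 0")
        if self.weight_decay < 0:
            raise ValueError("weight decay must be >= 0")


@dataclass
class TrainLog:
    """Per-update records (scalars for small models, norms otherwise)."""

    records: list[dict] = field(default_factory=list)
    checkpoints: dict[int, GenerativeModel] = field(default_factory=dict)
    status: str = "ok"

    def append(self, rec: dict) -> None:
        if self.records and rec["update"] <= self.records[-1]["update"]:
            raise ValueError("update counter must be monotone")
        self.records.append(rec)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records)

    def save_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _param_deltas_from_states(
    model: GenerativeModel, states: Sequence[NetworkState]
) -> dict[str, np.ndarray]:
    """Average over states, sum over the batch, of -dF/dtheta."""
    if not states:
        raise ValueError("no sampling-phase states provided")
    S = len(states)
    dW = [np.zeros_like(W) for W in model.weights]
    dmu = np.zeros_like(model.prior_mean)
    f = model.f
    for st in states:
        eps = prediction_errors(model, st).errors
        for l in range(model.L):
            dW[l] += eps[l].T @ f(st.activities[l + 1])
        dmu += eps[model.L].sum(axis=0)
    deltas = {f"W{l}": dW[l] / S for l in range(model.L)}
    deltas["mu"] = dmu / S
    return deltas


def mcpc_param_update(
    model: GenerativeModel,
    trajectory: Trajectory | Sequence[NetworkState],
    *,
    weight_decay: float = 0.0,
) -> dict[str, np.ndarray]:
    """Parameter deltas from the sampling-phase states of one inference run.

    Accepts either a :class:`Trajectory` (all layers recorded) or an explicit
    sequence of states.  The Bernoulli input layer uses the same rule with its
    sigmoid-defined ``eps_0``.
    """
    if isinstance(trajectory, Trajectory):
        if len(trajectory) == 0:
            raise ValueError("empty trajectory: no sampling-phase states to learn from")
        states = [
            NetworkState([trajectory.layer(l)[t] for l in range(model.L + 1)])
            for t in range(len(trajectory))
        ]
    else:
        states = list(trajectory)
    deltas = _param_deltas_from_states(model, states)
    if weight_decay:
        for l in range(model.L):
            deltas[f"W{l}"] -= weight_decay * model.weights[l]
    return deltas


def pc_param_update(
    model: GenerativeModel,
    converged_state: NetworkState,
    *,
    weight_decay: float = 0.0,
) -> dict[str, np.ndarray]:
    """Single-point (MAP) version of the update, summed over the batch."""
    deltas = _param_deltas_from_states(model, [converged_state])
    if weight_decay:
        for l in range(model.L):
            deltas[f"W{l}"] -= weight_decay * model.weights[l]
    return deltas


def _apply_deltas(model: GenerativeModel, deltas: dict[str, np.ndarray], opt) -> None:
    params = model.weights + [model.prior_mean]
    grads = [-deltas[f"W{l}"] for l in range(model.L)] + [-deltas["mu"]]
    opt.step(params, grads)


def _n_params(model: GenerativeModel) -> int:
    return sum(W.size for W in model.weights) + model.prior_mean.size


def _log_record(model: GenerativeModel, update: int, epoch: int, mean_F: float, small: bool) -> dict:
    rec = {"update": update, "epoch": epoch, "mean_F": mean_F}
    if small:
        for l, W in enumerate(model.weights):
            rec[f"W{l}"] = float(W.ravel()[0]) if W.size == 1 else float(np.linalg.norm(W))
        rec["mu"] = float(model.prior_mean[0]) if model.prior_mean.size == 1 \
            else float(np.linalg.norm(model.prior_mean))
    else:
        rec["W_norm"] = float(np.sqrt(sum(np.sum(W**2) for W in model.weights)))
        rec["mu_norm"] = float(np.linalg.norm(model.prior_mean))
    return rec


def train(
    model: GenerativeModel,
    dataset: np.ndarray,
    config: TrainConfig,
    method: str = "mcpc",
) -> tuple[GenerativeModel, TrainLog]:
    """Full training loop (in place on a copy of ``model``).

    ``method='mcpc'`` follows warm-up -> mixing -> sampling inference per
    batch and averages the plasticity over the sampling phase;
    ``method='pc'`` runs MAP inference only and updates from the converged
    state.  Fully reproducible from ``config.seed``.

    PC on over-dispersed data is expected to push ``|W|`` toward infinity;
    the loop stops with ``log.status == 'diverged'`` once any weight exceeds
    ``WEIGHT_CAP``, after the growth has been captured in the log.
    """
    if method not in ("mcpc", "pc"):
        raise ValueError(f"unknown method {method!r}")
    model = model.copy()
    data = np.atleast_2d(np.asarray(dataset, dtype=float))
    if data.shape[0] < config.batch_size:
        raise ValueError("dataset smaller than one batch")
    rng = np.random.default_rng(config.seed)
    opt = make_optimizer(config.optimizer, config.lr)
    sched = config.schedule
    log = TrainLog()
    small = _n_params(model) <= 10
    log_every = config.param_log_every or (1 if small else max(1, data.shape[0] // config.batch_size))
    n_batches = data.shape[0] // config.batch_size
    update = 0
    if 0 in config.checkpoint_updates:
        log.checkpoints[0] = model.copy()
    for epoch in range(config.epochs):
        order = rng.permutation(data.shape[0]) if config.shuffle else np.arange(data.shape[0])
        for b in range(n_batches):
            y = data[order[b * config.batch_size : (b + 1) * config.batch_size]]
            state = init_state(model, y, rng, clamp_input=True)
            try:
                if method == "pc":
                    pc_inference(model, state, sched.warmup_lr, sched.map_steps, sched.map_optimizer)
                    deltas = pc_param_update(model, state, weight_decay=config.weight_decay)
                    mean_F = float(np.mean(joint_energy(model, state)))
                else:
                    pc_inference(model, state, sched.warmup_lr, sched.map_steps, sched.map_optimizer)
                    states = []
                    for i in range(sched.mixing_steps + sched.sampling_steps):
                        mcpc_step(model, state, sched.h, rng, step_index=i)
                        if i >= sched.mixing_steps:
                            states.append(state.copy())
                    deltas = mcpc_param_update(model, states, weight_decay=config.weight_decay)
                    mean_F = float(np.mean(joint_energy(model, state)))
            except RuntimeError as err:
                raise TrainDivergence(f"epoch {epoch}, batch {b}: {err}") from err
            _apply_deltas(model, deltas, opt)
            update += 1
            if not all(np.isfinite(W).all() for W in model.weights + [model.prior_mean]):
                raise TrainDivergence(f"non-finite parameters at epoch {epoch}, batch {b}")
            if update % log_every == 0 or update == 1:
                log.append(_log_record(model, update, epoch, mean_F, small))
            if update in config.checkpoint_updates:
                log.checkpoints[update] = model.copy()
            if max(np.abs(W).max() for W in model.weights) > WEIGHT_CAP:
                log.status = "diverged"
                return model, log
    return model, log
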