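"""Inference and generation dynamics.

Three discrete-time steppers over network activities:

* :func:`mcpc_step` — one Euler–Maruyama step of the Langevin dynamics
  ``dx_l/dt = -grad_l F + n_l(t)``, discretised as
  ``x_l <- x_l - h grad_l F + sqrt(2 h) n_l`` with ``n_l ~ N(0, sigma_n^2 I)``.
  With this scaling the chain targets the stationary density
  ``exp(-F / sigma_n^2)``, i.e. the posterior over latents when the input is
  clamped and the model's own joint when it is not.
* :func:`pc_inference` — noiseless descent on ``F`` to the posterior mode
  (classic predictive coding; optionally Adam-preconditioned).
* :func:`run_unclamped` — the same Langevin dynamics with the input layer
  freed, which samples the model's marginal over inputs.

Batch elements evolve independently; all noise comes from one seeded
``numpy.random.Generator`` so trajectories are exactly reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np

from ._optim import make_optimizer
from .model import (
    GenerativeModel,
    NetworkState,
    init_state,
    latent_energy_gradient,
    prediction_errors,
    sigmoid,
)

__all__ = [
    "InferenceSchedule",
    "Trajectory",
    "mcpc_step",
    "pc_inference",
    "run_mcpc_inference",
    "run_unclamped",
]


@dataclass
class InferenceSchedule:
    """Step sizes and phase lengths of one inference run.

    ``h`` is the Euler step of the stochastic phase; ``map_steps`` noiseless
    warm-up steps (with ``map_optimizer`` at rate ``map_lr``, default ``h``)
    precede ``mixing_steps`` discarded and ``sampling_steps`` recorded
    Langevin steps.  The stochastic phase always uses plain steps: adaptive
    preconditioning would change the stationary distribution, so Adam is
    allowed in the warm-up only.
    """

    h: float = 0.02
    map_steps: int = 150
    mixing_steps: int = 150
    sampling_steps: int = 1
    map_optimizer: str = "adam"
    map_lr: float | None = None
    record_stride: int = 1

    def __post_init__(self):
        if self.h <= 0:
            raise ValueError("euler step h must be > 0")
        if min(self.map_steps, self.mixing_steps) < 0 or self.sampling_steps < 0:
            raise ValueError("step counts must be non-negative")
        if self.record_stride < 1:
            raise ValueError("record_stride must be >= 1")

    @property
    def warmup_lr(self) -> float:
        return self.h if self.map_lr is None else self.map_lr


@dataclass
class Trajectory:
    """Time-indexed record of activities during inference or generation.

    ``layers`` maps a layer name (``"x0" .. "xL"``, or ``"y_pred"`` for the
    predicted Bernoulli mean) to an array of shape ``(n_recorded, batch, d)``.
    """

    steps: np.ndarray
    layers: dict[str, np.ndarray]
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.steps = np.asarray(self.steps)
        if self.steps.size > 1 and not (np.diff(self.steps) > 0).all():
            raise ValueError("step indices must be strictly increasing")

    def __len__(self) -> int:
        return int(self.steps.size)

    def layer(self, l: int) -> np.ndarray:
        return self.layers[f"x{l}"]

    def latents(self) -> np.ndarray:
        """Latent layers concatenated along the neuron axis: (T, batch, n_latent)."""
        keys = sorted((k for k in self.layers if k.startswith("x") and k != "x0"),
                      key=lambda k: int(k[1:]))
        return np.concatenate([self.layers[k] for k in keys], axis=2)

    def save(self, path) -> None:
        import json

        arrays = {f"layer_{k}": v for k, v in self.layers.items()}
        arrays["steps"] = self.steps
        arrays["meta"] = np.frombuffer(json.dumps(self.meta).encode(), dtype=np.uint8)
        with open(path, "wb") as fh:
            np.savez(fh, **arrays)

    @staticmethod
    def load(path) -> "Trajectory":
        import json

        with np.load(path) as data:
            layers = {k[6:]: data[k] for k in data.files if k.startswith("layer_")}
            meta = json.loads(bytes(data["meta"]).decode()) if "meta" in data.files else {}
            steps = data["steps"]
        return Trajectory(steps=steps, layers=layers, meta=meta)


def _check_finite(state: NetworkState, step: int) -> None:
    for a in state.activities:
        if not np.isfinite(a).all():
            raise RuntimeError(f"non-finite activities at step {step}")


def _free_layers(model: GenerativeModel, state: NetworkState) -> list[int]:
    """Indices of layers the dynamics update."""
    free = list(range(1, model.L + 1))
    if not state.input_clamped and model.input_kind == "gaussian":
        free = [0] + free
    return free


def _energy_grads(model: GenerativeModel, state: NetworkState) -> dict[int, np.ndarray]:
    """Gradients of F for every free layer, keyed by layer index."""
    data_term = state.input_clamped or model.input_kind == "gaussian"
    latent = latent_energy_gradient(model, state, data_term=data_term)
    grads = {l: latent[l - 1] for l in range(1, model.L + 1)}
    if not state.input_clamped and model.input_kind == "gaussian":
        grads[0] = prediction_errors(model, state)[0]
    return grads


def mcpc_step(
    model: GenerativeModel,
    state: NetworkState,
    h: float,
    rng: np.random.Generator,
    *,
    step_index: int = 0,
) -> NetworkState:
    """One Euler–Maruyama Langevin step on every unclamped layer (in place).

    Noise is freshly drawn per step, per layer and per batch element.  With
    ``sigma_n^2 = 0`` this reduces to a plain gradient-descent step on ``F``.
    """
    grads = _energy_grads(model, state)
    sn = np.sqrt(model.noise_variance)
    amp = np.sqrt(2.0 * h) * sn
    for l, g in grads.items():
        x = state.activities[l]
        x -= h * g
        if sn > 0:
            x += amp * rng.standard_normal(x.shape)
    _check_finite(state, step_index)
    return state


def pc_inference(
    model: GenerativeModel,
    state: NetworkState,
    h: float,
    K: int,
    optimizer: str = "plain",
) -> NetworkState:
    """``K`` noiseless descent steps on ``F`` (MAP inference; in place).

    ``optimizer='plain'`` is exact gradient descent, under which ``F`` is
    non-increasing for sufficiently small ``h``; ``'adam'`` is the adaptive
    variant used to speed up convergence.
    """
    if K == 0:
        return state
    opt = make_optimizer(optimizer, h)
    free = _free_layers(model, state)
    for k in range(K):
        grads = _energy_grads(model, state)
        opt.step([state.activities[l] for l in free], [grads[l] for l in free])
        _check_finite(state, k)
    return state


def run_mcpc_inference(
    model: GenerativeModel,
    y: np.ndarray,
    schedule: InferenceSchedule,
    rng: np.random.Generator,
    *,
    return_state: bool = False,
):
    """Posterior-sampling run: clamp ``x_0 = y``, warm up, mix, then sample.

    Returns a :class:`Trajectory` of the last ``sampling_steps`` states (all
    layers), recorded every ``record_stride`` steps.  With
    ``mixing_steps + sampling_steps = 0`` the trajectory is empty and the
    warm-up state is available via ``return_state``.
    """
    state = init_state(model, y, rng, clamp_input=True)
    pc_inference(model, state, schedule.warmup_lr, schedule.map_steps, schedule.map_optimizer)
    M, S = schedule.mixing_steps, schedule.sampling_steps
    rec_steps: list[int] = []
    rec: list[list[np.ndarray]] = []
    for i in range(M + S):
        mcpc_step(model, state, schedule.h, rng, step_index=i)
        if i >= M and (i - M) % schedule.record_stride == 0:
            rec_steps.append(i + 1)
            rec.append([a.copy() for a in state.activities])
    layers = {
        f"x{l}": np.stack([snap[l] for snap in rec]) if rec else
        np.empty((0,) + state.activities[l].shape)
        for l in range(model.L + 1)
    }
    traj = Trajectory(
        steps=np.array(rec_steps, dtype=int),
        layers=layers,
        meta={"kind": "posterior", "model": model.param_hash(),
              "schedule": vars(schedule).copy()},
    )
    if return_state:
        return traj, state
    return traj


def run_unclamped(
    model: GenerativeModel,
    steps: int,
    rng: np.random.Generator,
    *,
    batch_size: int = 1,
    record_stride: int = 1,
    h: float = 0.02,
    burn_in: int = 0,
    init_state_from: NetworkState | None = None,
) -> Trajectory:
    """Spontaneous (generative) dynamics with the input layer freed.

    Gaussian models evolve all layers including ``x_0``; for Bernoulli models
    the discrete input layer is kept out of the dynamics (the latents then
    sample the model's prior) and the predicted Bernoulli mean
    ``s(W_0 f(x_1))`` is recorded under ``"y_pred"`` instead of ``x0``.
    """
    if init_state_from is not None:
        state = init_state_from
        state.input_clamped = False
    else:
        state = init_state(model, batch_size, rng, clamp_input=False)
    bern = model.input_kind == "bernoulli"
    rec_steps: list[int] = []
    rec: list[list[np.ndarray]] = []
    for i in range(burn_in + steps):
        mcpc_step(model, state, h, rng, step_index=i)
        if i >= burn_in and (i - burn_in) % record_stride == 0:
            rec_steps.append(i + 1)
            snap = [a.copy() for a in state.activities[1:]]
            if bern:
                snap.append(sigmoid(model.f(state.activities[1]) @ model.weights[0].T))
            else:
                snap.append(state.activities[0].copy())
            rec.append(snap)
    layers: dict[str, np.ndarray] = {}
    for j, l in enumerate(range(1, model.L + 1)):
        layers[f"x{l}"] = np.stack([snap[j] for snap in rec])
    if bern:
        layers["y_pred"] = np.stack([snap[-1] for snap in rec])
    else:
        layers["x0"] = np.stack([snap[-1] for snap in rec])
    return Trajectory(
        steps=np.array(rec_steps, dtype=int),
        layers=layers,
        meta={"kind": "unclamped", "model": model.param_hash(), "h": h},
    )
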