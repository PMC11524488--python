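"""Hierarchical Gaussian generative model, its energy, prediction errors and gradients.

The generative model stacks ``L`` latent layers above an input layer::

    p(y, x; theta) = prod_{l=0}^{L-1} N(x_l; W_l f(x_{l+1}), sigma^2 I) * N(x_L; mu, sigma^2 I)

with ``x_0 = y`` when an input is present.  ``theta`` comprises the weights
``W_0 .. W_{L-1}`` and the prior mean ``mu`` of the top layer.  The energy

    F = -ln p(y, x; theta)
      = sum_l ||x_l - W_l f(x_{l+1})||^2 / (2 sigma^2) + ||x_L - mu||^2 / (2 sigma^2)

is the quantity both inference (over activities) and learning (over parameters)
descend.  For binary image data the input layer can be switched to a Bernoulli
likelihood through a sigmoid, replacing the ``l = 0`` term of ``F`` by the
negative Bernoulli log-likelihood of ``y`` given the mean ``s(W_0 f(x_1))``.

Prediction errors carry the ``1/sigma^2`` precision factor, so that the latent
gradients below are the exact gradients of ``F`` for any ``sigma^2`` (checked
against finite differences in the test suite).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "ACTIVATIONS",
    "GenerativeModel",
    "NetworkState",
    "PredictionErrors",
    "joint_energy",
    "prediction_errors",
    "latent_energy_gradient",
    "init_state",
    "save_model",
    "load_model",
    "sigmoid",
]


def sigmoid(a: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * a))


def _relu(x):
    return np.maximum(x, 0.0)


def _relu_prime(x):
    # subgradient at the kink x = 0 is defined as 0 for reproducibility
    return (x > 0.0).astype(float)


def _tanh_prime(x):
    return 1.0 - np.tanh(x) ** 2


#: name -> (f, f') pairs usable as layer activation
ACTIVATIONS: dict[str, tuple[Callable, Callable]] = {
    "linear": (lambda x: x, lambda x: np.ones_like(x)),
    "relu": (_relu, _relu_prime),
    "tanh": (np.tanh, _tanh_prime),
}

_FORMAT_VERSION = 1


@dataclass
class GenerativeModel:
    """Parameters ``theta`` of the hierarchical Gaussian model.

    Parameters
    ----------
    weights
        ``W_0 .. W_{L-1}``; ``W_l`` has shape ``(d_l, d_{l+1})`` and maps the
        activated layer ``l+1`` activity to the prediction of layer ``l``.
    prior_mean
        ``mu``, the mean of the Gaussian prior of the top layer (length ``d_L``).
    layer_variance
        ``sigma^2 > 0``, shared by every Gaussian layer.
    noise_variance
        ``sigma_n^2 >= 0``, the Langevin noise variance.  It does not enter the
        energy; it scales the stationary distribution of the stochastic
        dynamics so that each generative layer has effective variance
        ``sigma^2 sigma_n^2``.
    activation
        ``linear``, ``relu`` or ``tanh``.
    input_kind
        ``gaussian`` or ``bernoulli``; a Bernoulli input layer requires binary
        data and predicts pixel means through a sigmoid.
    """

    weights: list[np.ndarray]
    prior_mean: np.ndarray
    layer_variance: float = 1.0
    noise_variance: float = 1.0
    activation: str = "linear"
    input_kind: str = "gaussian"

    def __post_init__(self):
        self.weights = [np.asarray(W, dtype=float) for W in self.weights]
        self.prior_mean = np.atleast_1d(np.asarray(self.prior_mean, dtype=float))
        if not self.weights:
            raise ValueError("at least one weight matrix (L >= 1) is required")
        if self.layer_variance <= 0:
            raise ValueError("layer_variance must be > 0")
        if self.noise_variance < 0:
            raise ValueError("noise_variance must be >= 0")
        if self.activation not in ACTIVATIONS:
            raise ValueError(f"unknown activation {self.activation!r}")
        if self.input_kind not in ("gaussian", "bernoulli"):
            raise ValueError(f"unknown input_kind {self.input_kind!r}")
        for l in range(self.L - 1):
            if self.weights[l].shape[1] != self.weights[l + 1].shape[0]:
                raise ValueError(
                    f"weight shapes do not chain at layer {l}: "
                    f"W_{l} is {self.weights[l].shape}, W_{l + 1} is {self.weights[l + 1].shape}"
                )
        if self.prior_mean.shape[0] != self.weights[-1].shape[1]:
            raise ValueError(
                f"prior_mean has length {self.prior_mean.shape[0]} but the top "
                f"layer {self.L} has width {self.weights[-1].shape[1]}"
            )

    @property
    def L(self) -> int:
        """Number of latent layers."""
        return len(self.weights)

    @property
    def dims(self) -> list[int]:
        """Layer widths ``d_0 .. d_L``."""
        return [W.shape[0] for W in self.weights] + [self.weights[-1].shape[1]]

    @property
    def f(self) -> Callable:
        return ACTIVATIONS[self.activation][0]

    @property
    def f_prime(self) -> Callable:
        return ACTIVATIONS[self.activation][1]

    def copy(self) -> "GenerativeModel":
        return GenerativeModel(
            weights=[W.copy() for W in self.weights],
            prior_mean=self.prior_mean.copy(),
            layer_variance=self.layer_variance,
            noise_variance=self.noise_variance,
            activation=self.activation,
            input_kind=self.input_kind,
        )

    def param_hash(self) -> str:
        """Short content hash of the parameter arrays (for run metadata)."""
        import hashlib

        h = hashlib.sha256()
        for W in self.weights:
            h.update(np.ascontiguousarray(W).tobytes())
        h.update(np.ascontiguousarray(self.prior_mean).tobytes())
        h.update(
            f"{self.layer_variance}:{self.noise_variance}:{self.activation}:{self.input_kind}".encode()
        )
        return h.hexdigest()[:16]

    @staticmethod
    def random(
        dims: Sequence[int],
        rng: np.random.Generator,
        *,
        weight_scale: float | None = None,
        layer_variance: float = 1.0,
        noise_variance: float = 1.0,
        activation: str = "linear",
        input_kind: str = "gaussian",
    ) -> "GenerativeModel":
        """Model with Gaussian-initialised weights and zero prior mean.

        ``weight_scale`` defaults to ``1/sqrt(d_in)`` fan-in scaling per layer.
        """
        weights = []
        for l in range(len(dims) - 1):
            scale = weight_scale if weight_scale is not None else 1.0 / np.sqrt(dims[l + 1])
            weights.append(scale * rng.standard_normal((dims[l], dims[l + 1])))
        return GenerativeModel(
            weights=weights,
            prior_mean=np.zeros(dims[-1]),
            layer_variance=layer_variance,
            noise_variance=noise_variance,
            activation=activation,
            input_kind=input_kind,
        )


@dataclass
class NetworkState:
    """Batched activities ``x_0 .. x_L``; the object the dynamics mutate.

    ``activities[l]`` has shape ``(batch, d_l)``.  When ``input_clamped`` is
    true, ``x_0`` holds the data and is never modified by any dynamics step.
    """

    activities: list[np.ndarray]
    input_clamped: bool = True

    @property
    def batch_size(self) -> int:
        return self.activities[0].shape[0]

    def copy(self) -> "NetworkState":
        return NetworkState([a.copy() for a in self.activities], self.input_clamped)

    def latents(self) -> np.ndarray:
        """All latent activities concatenated to one ``(batch, sum d_l)`` array."""
        return np.concatenate(self.activities[1:], axis=1)


@dataclass
class PredictionErrors:
    """Precision-scaled prediction errors ``eps_0 .. eps_L``."""

    errors: list[np.ndarray]

    def __getitem__(self, l: int) -> np.ndarray:
        return self.errors[l]


def _check_shapes(model: GenerativeModel, state: NetworkState) -> None:
    dims = model.dims
    if len(state.activities) != model.L + 1:
        raise ValueError(
            f"state has {len(state.activities)} layers, model expects {model.L + 1}"
        )
    for l, (a, d) in enumerate(zip(state.activities, dims)):
        if a.ndim != 2 or a.shape[1] != d:
            raise ValueError(
                f"layer {l} activity has shape {a.shape}, expected (batch, {d})"
            )


def _check_binary(y: np.ndarray) -> None:
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("bernoulli input layer requires data in {0, 1}")


def prediction_errors(model: GenerativeModel, state: NetworkState) -> PredictionErrors:
    """Prediction errors of every layer.

    Gaussian layers: ``eps_l = (x_l - W_l f(x_{l+1})) / sigma^2`` and
    ``eps_L = (x_L - mu) / sigma^2``.  A Bernoulli input layer instead uses
    ``eps_0 = y - s(W_0 f(x_1))``, each component in ``[-1, 1]``.
    """
    _check_shapes(model, state)
    f = model.f
    s2 = model.layer_variance
    x = state.activities
    errs = []
    if model.input_kind == "bernoulli":
        errs.append(x[0] - sigmoid(f(x[1]) @ model.weights[0].T))
    else:
        errs.append((x[0] - f(x[1]) @ model.weights[0].T) / s2)
    for l in range(1, model.L):
        errs.append((x[l] - f(x[l + 1]) @ model.weights[l].T) / s2)
    errs.append((x[model.L] - model.prior_mean) / s2)
    return PredictionErrors(errs)


def joint_energy(model: GenerativeModel, state: NetworkState) -> np.ndarray:
    """Energy ``F = -ln p(y, x; theta)`` per batch element (up to constants).

    The Gaussian case is the sum of squared-error terms divided by
    ``2 sigma^2``; the Bernoulli case replaces the ``l = 0`` term with the
    negative Bernoulli log-likelihood of the clamped data through a sigmoid.
    """
    _check_shapes(model, state)
    f = model.f
    s2 = model.layer_variance
    x = state.activities
    if model.input_kind == "bernoulli":
        if state.input_clamped:
            _check_binary(x[0])
        a = f(x[1]) @ model.weights[0].T
        # numerically safe -[y ln s(a) + (1-y) ln(1-s(a))] = sum softplus(a) - y a
        F = np.sum(np.logaddexp(0.0, a) - x[0] * a, axis=1)
    else:
        r0 = x[0] - f(x[1]) @ model.weights[0].T
        F = 0.5 * np.sum(r0**2, axis=1) / s2
    for l in range(1, model.L):
        r = x[l] - f(x[l + 1]) @ model.weights[l].T
        F = F + 0.5 * np.sum(r**2, axis=1) / s2
    rL = x[model.L] - model.prior_mean
    return F + 0.5 * np.sum(rL**2, axis=1) / s2


def latent_energy_gradient(
    model: GenerativeModel, state: NetworkState, *, data_term: bool = True
) -> list[np.ndarray]:
    """Exact gradients ``dF/dx_l`` for the latent layers ``l = 1 .. L``.

    ``grad_l = eps_l - f'(x_l) * (W_{l-1}^T eps_{l-1})``; for a Bernoulli
    input layer the ``l = 1`` coupling uses the sigmoid-defined ``eps_0``.
    When ``data_term`` is false the input-layer coupling is dropped entirely
    (used for spontaneous dynamics of models with a discrete input layer,
    where the latents then descend the prior energy only).

    Returned list index ``l - 1`` holds the gradient for layer ``l``.
    """
    eps = prediction_errors(model, state).errors
    fp = model.f_prime
    x = state.activities
    grads = []
    for l in range(1, model.L + 1):
        g = eps[l].copy()
        if l > 1 or data_term:
            g -= fp(x[l]) * (eps[l - 1] @ model.weights[l - 1])
        grads.append(g)
    return grads


def init_state(
    model: GenerativeModel,
    data_or_batch: np.ndarray | int,
    rng: np.random.Generator,
    clamp_input: bool = True,
) -> NetworkState:
    """Fresh network state with standard-normal latents.

    With ``clamp_input`` the first argument is the data batch pinned to
    ``x_0``; otherwise it may be an integer batch size and ``x_0`` is drawn
    standard normal like the latents.
    """
    dims = model.dims
    if clamp_input:
        y = np.atleast_2d(np.asarray(data_or_batch, dtype=float))
        if y.shape[1] != dims[0]:
            raise ValueError(f"data has width {y.shape[1]}, model input width is {dims[0]}")
        if model.input_kind == "bernoulli":
            _check_binary(y)
        batch = y.shape[0]
        acts = [y.copy()]
    else:
        batch = int(data_or_batch) if np.isscalar(data_or_batch) else np.asarray(data_or_batch).shape[0]
        acts = [rng.standard_normal((batch, dims[0]))]
    for d in dims[1:]:
        acts.append(rng.standard_normal((batch, d)))
    return NetworkState(acts, input_clamped=clamp_input)


def save_model(model: GenerativeModel, path) -> None:
    """Serialize to a single ``.npz`` container with a JSON header.

    Arrays round-trip bit-exactly (stored at double precision).
    """
    header = json.dumps(
        {
            "format_version": _FORMAT_VERSION,
            "dims": model.dims,
            "layer_variance": model.layer_variance,
            "noise_variance": model.noise_variance,
            "activation": model.activation,
            "input_kind": model.input_kind,
        }
    )
    arrays = {f"W{l}": W for l, W in enumerate(model.weights)}
    arrays["mu"] = model.prior_mean
    arrays["header"] = np.frombuffer(header.encode(), dtype=np.uint8)
    with open(path, "wb") as fh:
        np.savez(fh, **arrays)


def load_model(path) -> GenerativeModel:
    with np.load(path) as data:
        header = json.loads(bytes(data["header"]).decode())
        if header.get("format_version") != _FORMAT_VERSION:
            raise ValueError(f"unsupported model format version {header.get('format_version')}")
        L = len(header["dims"]) - 1
        weights = [data[f"W{l}"] for l in range(L)]
        mu = data["mu"]
    return GenerativeModel(
        weights=weights,
        prior_mean=mu,
        layer_variance=header["layer_variance"],
        noise_variance=header["noise_variance"],
        activation=header["activation"],
        input_kind=header["input_kind"],
    )
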