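"""Ancestral sampling and model-quality evaluation.

Covers the generative-side toolbox: top-down ancestral sampling, a Monte
Carlo estimate of the marginal log-likelihood, MAP completion of masked
inputs, per-neuron feature visualisation, and pixel-correlation comparison
between generated and reference image sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from ._optim import make_optimizer
from .model import GenerativeModel, init_state, prediction_errors, sigmoid
from .dynamics import InferenceSchedule

__all__ = [
    "EvalReport",
    "ancestral_sample",
    "mc_marginal_loglik",
    "reconstruct_masked",
    "neuron_feature",
    "pixel_correlation",
]


@dataclass
class EvalReport:
    """A stochastic metric with the sample size and seed that produced it."""

    metric: str
    value: float
    n: int
    seed: int | None = None
    model_hash: str | None = None
    extra: dict = field(default_factory=dict)


def _sample_latents(model: GenerativeModel, n: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Top-down draws of x_L .. x_1 from the prior, each (n, d_l)."""
    s = np.sqrt(model.layer_variance * model.noise_variance)
    xs = [model.prior_mean + s * rng.standard_normal((n, model.prior_mean.size))]
    for l in range(model.L - 1, 0, -1):
        mean = model.f(xs[-1]) @ model.weights[l].T
        xs.append(mean + s * rng.standard_normal(mean.shape))
    xs.reverse()  # now x_1 .. x_L
    return xs


def ancestral_sample(
    model: GenerativeModel,
    n: int,
    rng: np.random.Generator,
    *,
    binarize: bool = False,
) -> np.ndarray:
    """``n`` input-space samples drawn top-down through the hierarchy.

    Each layer is drawn from its conditional Gaussian with variance
    ``sigma^2 sigma_n^2`` (the effective variance of the stochastic
    dynamics).  Bernoulli models return the predicted pixel means
    ``s(W_0 f(x_1))``, or binarised draws with ``binarize=True``.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    latents = _sample_latents(model, n, rng)
    mean0 = model.f(latents[0]) @ model.weights[0].T
    if model.input_kind == "bernoulli":
        p = sigmoid(mean0)
        if binarize:
            return (rng.random(p.shape) < p).astype(float)
        return p
    s = np.sqrt(model.layer_variance * model.noise_variance)
    return mean0 + s * rng.standard_normal(mean0.shape)


def mc_marginal_loglik(
    model: GenerativeModel,
    data: np.ndarray,
    n_samples: int,
    rng: np.random.Generator,
    *,
    chunk: int = 512,
) -> EvalReport:
    """Monte Carlo estimate of the negative marginal log-likelihood.

    Draws ``n_samples`` latent configurations from the prior and, per datum,
    averages the conditional likelihood ``p(y | x_s)`` in log space
    (log-sum-exp, with the 1/n normalisation inside the log), then sums the
    negative logs over the dataset:

        -ln p(data) ~= - sum_i ln [ (1/n) sum_s p(y_i | x_s) ]
    """
    if n_samples < 100:
        raise ValueError("n_samples must be >= 100")
    data = np.atleast_2d(np.asarray(data, dtype=float))
    latents = _sample_latents(model, n_samples, rng)
    a = model.f(latents[0]) @ model.weights[0].T  # (n_samples, d0) conditional mean / logits
    total = 0.0
    sv = model.layer_variance * model.noise_variance
    for start in range(0, data.shape[0], chunk):
        y = data[start : start + chunk]  # (m, d0)
        if model.input_kind == "bernoulli":
            # log p(y|x_s) = sum_j [y a - softplus(a)]
            ll = y @ a.T - np.logaddexp(0.0, a).sum(axis=1)[None, :]
        else:
            d2 = ((y[:, None, :] - a[None, :, :]) ** 2).sum(axis=2)
            ll = -0.5 * d2 / sv - 0.5 * y.shape[1] * np.log(2 * np.pi * sv)
        if not np.isfinite(ll).all():
            raise RuntimeError("non-finite conditional log-likelihoods")
        total += float(np.sum(logsumexp(ll, axis=1) - np.log(n_samples)))
    return EvalReport(
        metric="neg_marginal_loglik", value=-total, n=n_samples,
        model_hash=model.param_hash(),
    )


def reconstruct_masked(
    model: GenerativeModel,
    observed: np.ndarray,
    mask: np.ndarray,
    schedule: InferenceSchedule | None = None,
) -> np.ndarray:
    """MAP completion of partially observed inputs.

    ``mask`` is true on *missing* entries.  Observed entries are clamped;
    missing entries are treated as extra latent variables and optimised
    jointly with all latents by noiseless descent on the energy.  Bernoulli
    inputs are parameterised by a logit so the completion stays in (0, 1).
    Returns the completed inputs with observed entries untouched.
    """
    if schedule is None:
        schedule = InferenceSchedule(h=0.1, map_steps=400, mixing_steps=0, sampling_steps=0)
    observed = np.atleast_2d(np.asarray(observed, dtype=float))
    mask = np.broadcast_to(np.asarray(mask, dtype=bool), observed.shape)
    if not mask.any():
        return observed.copy()
    rng = np.random.default_rng(0)
    bern = model.input_kind == "bernoulli"
    y0 = observed.copy()
    if bern:
        y0[mask] = 0.0  # placeholder so init_state's binary check passes
    state = init_state(model, y0, rng, clamp_input=True)
    # missing-pixel parameters: raw values (gaussian) or logits (bernoulli)
    z = np.zeros(observed.shape)
    opt = make_optimizer(schedule.map_optimizer, schedule.warmup_lr)
    free = list(range(1, model.L + 1))
    from .model import latent_energy_gradient

    for _ in range(schedule.map_steps):
        x0 = state.activities[0]
        if bern:
            x0[mask] = sigmoid(z[mask])
        else:
            x0[mask] = z[mask]
        state.input_clamped = False  # allow fractional values past shape checks
        grads = latent_energy_gradient(model, state, data_term=True)
        eps0 = prediction_errors(model, state)[0]
        if bern:
            # dF/dy = -logits; chain through y = s(z)
            a = model.f(state.activities[1]) @ model.weights[0].T
            gz = (-a) * x0 * (1.0 - x0)
        else:
            gz = eps0
        gz = np.where(mask, gz, 0.0)
        opt.step([state.activities[l] for l in free] + [z],
                 [g for g in grads] + [gz])
    out = observed.copy()
    out[mask] = (sigmoid(z) if bern else z)[mask]
    return out


def neuron_feature(
    model: GenerativeModel,
    layer_index: int,
    neuron_index: int,
    drive: float = 10.0,
) -> np.ndarray:
    """Input-space pattern generated by driving one neuron of one layer.

    The neuron's activity is set to ``drive`` with the rest of its layer at
    zero, then propagated down through activations and weights to the input
    (ending with the sigmoid for Bernoulli models).
    """
    if not 1 <= layer_index <= model.L:
        raise IndexError(f"layer_index must be in 1..{model.L}")
    d = model.dims[layer_index]
    if not 0 <= neuron_index < d:
        raise IndexError(f"neuron_index must be in 0..{d - 1}")
    a = np.zeros(d)
    a[neuron_index] = drive
    for l in range(layer_index - 1, -1, -1):
        a = model.weights[l] @ model.f(a)
    if model.input_kind == "bernoulli":
        a = sigmoid(a)
    return a


def pixel_correlation(
    sample_images: np.ndarray,
    reference_images: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Absolute Pearson pixel-correlation matrices and their mean difference.

    Pixels that are constant in the *reference* set are excluded from both
    matrices (their correlation is undefined).  Returns
    ``(sample_corr, reference_corr, mean_abs_difference)`` on the retained
    pixels.
    """
    S = np.asarray(sample_images, dtype=float).reshape(len(sample_images), -1)
    R = np.asarray(reference_images, dtype=float).reshape(len(reference_images), -1)
    if S.shape[0] < 2 or R.shape[0] < 2:
        raise ValueError("need at least 2 images per set")
    keep = R.std(axis=0) > 0
    if keep.sum() < 2:
        raise ValueError("fewer than 2 non-constant reference pixels")
    S, R = S[:, keep], R[:, keep]
    # guard: a pixel constant in the sample set would make corrcoef emit NaN
    Sc = np.abs(np.corrcoef(S, rowvar=False))
    Rc = np.abs(np.corrcoef(R, rowvar=False))
    Sc = np.nan_to_num(Sc, nan=0.0)
    off = ~np.eye(Sc.shape[0], dtype=bool)
    return Sc, Rc, float(np.mean(np.abs(Sc - Rc)[off]))
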