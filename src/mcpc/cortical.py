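"""Cortical-variability analyses and latent-state decoding.

Two neural-phenomenology analyses carried out on trained models:

* **Variability quenching** — the drop in temporal variability of latent
  activity at stimulus onset.  Sampling dynamics are broad before onset
  (latents roam the prior) and narrow after (the posterior is sharper than
  the prior); noiseless MAP dynamics instead collapse to a fixed point both
  before and after, apart from an onset transient.
* **Spontaneous-vs-evoked similarity** — the KL divergence between the
  distribution of spontaneous latent activity and the pooled steady-state
  activity evoked by a class of stimuli, estimated non-parametrically from
  samples with a k-nearest-neighbour estimator.  As the generative model
  learns, spontaneous activity grows similar to activity evoked by
  training-like stimuli specifically.

A linear softmax decoder maps latent states to class probabilities and to
2-D coordinates on a circle of class anchors for visualisation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from ._optim import make_optimizer
from .dynamics import mcpc_step, pc_inference, run_unclamped
from .model import GenerativeModel, init_state

__all__ = [
    "VariabilityCurve",
    "SimilarityReport",
    "sliding_window_std",
    "onset_variability",
    "knn_kl",
    "spontaneous_evoked_similarity",
    "latent_decoder",
    "decode_to_circle",
]


@dataclass
class VariabilityCurve:
    """Across-neuron mean sliding-window std around stimulus onset.

    ``offsets`` are window-centre steps relative to onset (negative = before).
    """

    offsets: np.ndarray
    mean_std: np.ndarray
    sem: np.ndarray
    window: int

    def pre_post_means(self) -> tuple[float, float]:
        pre = self.mean_std[self.offsets < 0]
        post = self.mean_std[self.offsets > 0]
        return float(pre.mean()), float(post.mean())


@dataclass
class SimilarityReport:
    """Per-class spontaneous-vs-evoked KL divergences at one checkpoint."""

    checkpoint: int
    kl: dict[str, float]
    neuron_subset: tuple[int, ...]
    seed: int
    n_spont: int = 0
    n_evoked: int = 0


def sliding_window_std(trajectory: np.ndarray, window: int) -> np.ndarray:
    """Per-neuron sample standard deviation over a sliding time window.

    ``trajectory`` has time on axis 0 (any further axes are kept); the result
    has ``T - window + 1`` window positions, each the ddof=1 standard
    deviation of the ``window`` consecutive time points.
    """
    x = np.asarray(trajectory, dtype=float)
    if window < 2:
        raise ValueError("window must be >= 2")
    if x.shape[0] < window:
        raise ValueError("trajectory shorter than the window")
    c1 = np.cumsum(np.concatenate([np.zeros((1,) + x.shape[1:]), x]), axis=0)
    c2 = np.cumsum(np.concatenate([np.zeros((1,) + x.shape[1:]), x**2]), axis=0)
    s1 = c1[window:] - c1[:-window]
    s2 = c2[window:] - c2[:-window]
    var = (s2 - s1**2 / window) / (window - 1)
    return np.sqrt(np.maximum(var, 0.0))


def onset_variability(
    model: GenerativeModel,
    stimuli: np.ndarray,
    pre_steps: int = 5000,
    post_steps: int = 5000,
    window: int = 1000,
    rng: np.random.Generator | None = None,
    *,
    method: str = "mcpc",
    h: float = 0.02,
    map_optimizer: str = "plain",
) -> VariabilityCurve:
    """Mean temporal variability of all latent neurons around stimulus onset.

    Each stimulus defines one onset: the network runs unclamped for
    ``pre_steps``, the stimulus is then clamped to the input layer and the
    run continues for ``post_steps``.  The sliding-window standard deviation
    is averaged over latent neurons; the s.e.m. is across stimuli.
    ``method='pc'`` uses the noiseless dynamics throughout (the baseline in
    which variability collapses to zero away from the onset transient).
    """
    if rng is None:
        rng = np.random.default_rng(0)
    y = np.atleast_2d(np.asarray(stimuli, dtype=float))
    n = y.shape[0]
    state = init_state(model, n, rng, clamp_input=False)
    noiseless = method == "pc"
    rec = np.empty((pre_steps + post_steps, n, sum(model.dims[1:])))

    def run_phase(start, steps):
        # one optimizer per phase so adaptive MAP descent keeps its state
        opt = make_optimizer(map_optimizer, h) if noiseless else None
        from .dynamics import _energy_grads, _free_layers

        free = _free_layers(model, state)
        for i in range(start, start + steps):
            if noiseless:
                grads = _energy_grads(model, state)
                opt.step([state.activities[l] for l in free],
                         [grads[l] for l in free])
            else:
                mcpc_step(model, state, h, rng, step_index=i)
            rec[i] = state.latents()

    run_phase(0, pre_steps)
    state.activities[0] = y.copy()
    state.input_clamped = True
    run_phase(pre_steps, post_steps)
    sw = sliding_window_std(rec, window)  # (positions, n, neurons)
    per_stim = sw.mean(axis=2)  # average over neurons
    centers = np.arange(sw.shape[0]) + (window - 1) / 2.0
    offsets = centers - pre_steps + 0.5
    return VariabilityCurve(
        offsets=offsets,
        mean_std=per_stim.mean(axis=1),
        sem=per_stim.std(axis=1, ddof=1) / np.sqrt(n),
        window=window,
    )


def knn_kl(
    samples_p: np.ndarray,
    samples_q: np.ndarray,
    k: int = 1,
    jitter: float = 1e-12,
    rng: np.random.Generator | None = None,
) -> float:
    """k-nearest-neighbour estimate of KL(p || q) from two sample sets.

    Uses the classic nearest-neighbour construction: with ``r_k`` the
    distance of each p-sample to its k-th neighbour within ``samples_p``
    (excluding itself) and ``s_k`` the distance to its k-th neighbour in
    ``samples_q``,

        KL ~= (d/n) sum_i ln(s_k(i) / r_k(i)) + ln(m / (n - 1)).

    Duplicate points give zero distances; a tiny jitter (fixed seed unless a
    generator is passed) breaks the ties.
    """
    P = np.atleast_2d(np.asarray(samples_p, dtype=float))
    Q = np.atleast_2d(np.asarray(samples_q, dtype=float))
    if P.ndim != 2 or Q.ndim != 2 or P.shape[1] != Q.shape[1]:
        raise ValueError("sample sets must be 2-D with a common dimension")
    if P.shape[0] < 50 or Q.shape[0] < 50:
        raise ValueError("need at least 50 points per set")
    if jitter:
        jrng = rng if rng is not None else np.random.default_rng(12345)
        P = P + jitter * jrng.standard_normal(P.shape)
        Q = Q + jitter * jrng.standard_normal(Q.shape)
    n, d = P.shape
    m = Q.shape[0]
    r = cKDTree(P).query(P, k=k + 1)[0][:, -1]  # k-th excluding self
    s = cKDTree(Q).query(P, k=k)[0]
    if k > 1:
        s = s[:, -1]
    s = np.maximum(s, np.finfo(float).tiny)
    r = np.maximum(r, np.finfo(float).tiny)
    return float(d * np.mean(np.log(s / r)) + np.log(m / (n - 1.0)))


def _evoked_latents(
    model: GenerativeModel,
    stimuli: np.ndarray,
    neurons: tuple[int, ...],
    steps: int,
    burn_in: int,
    record_stride: int,
    h: float,
    rng: np.random.Generator,
    warmup: int,
) -> np.ndarray:
    """Pooled steady-state x_1 activity of the selected neurons, (N, k)."""
    state = init_state(model, stimuli, rng, clamp_input=True)
    pc_inference(model, state, h, warmup, "adam")
    out = []
    for i in range(steps):
        mcpc_step(model, state, h, rng, step_index=i)
        if i >= burn_in and (i - burn_in) % record_stride == 0:
            out.append(state.activities[1][:, neurons].copy())
    return np.concatenate(out, axis=0)


def spontaneous_evoked_similarity(
    model_checkpoints: dict[int, GenerativeModel],
    stimulus_sets: dict[str, np.ndarray],
    n_neurons: int = 5,
    steps: int = 9500,
    rng: np.random.Generator | None = None,
    *,
    burn_in: int | None = None,
    record_stride: int = 10,
    h: float = 0.02,
    warmup: int = 100,
    spont_batch: int = 16,
    max_points: int = 5000,
    seed: int = 0,
) -> list[SimilarityReport]:
    """KL(spontaneous || pooled evoked) per stimulus class and checkpoint.

    For each checkpoint the same randomly selected first-latent-layer neurons
    are recorded (i) during clamped steady-state inference pooled across all
    stimuli of each class and (ii) during spontaneous (unclamped) dynamics,
    and compared with :func:`knn_kl`.  Pooling the per-stimulus steady states
    into one sample set realises the "average evoked distribution" as a
    mixture over stimuli.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    first = next(iter(model_checkpoints.values()))
    d1 = first.dims[1]
    neurons = tuple(rng.choice(d1, size=min(n_neurons, d1), replace=False).tolist())
    if burn_in is None:
        burn_in = steps // 4
    reports = []
    for ckpt in sorted(model_checkpoints):
        m = model_checkpoints[ckpt]
        spont = run_unclamped(
            m, steps - burn_in, rng, batch_size=spont_batch,
            record_stride=record_stride, h=h, burn_in=burn_in,
        ).layer(1)[:, :, neurons].reshape(-1, len(neurons))
        kl = {}
        n_ev = 0
        for name, stim in stimulus_sets.items():
            ev = _evoked_latents(
                m, stim, neurons, steps, burn_in, record_stride, h, rng, warmup
            )
            sp, evs = spont, ev
            if sp.shape[0] > max_points:
                sp = sp[rng.choice(sp.shape[0], max_points, replace=False)]
            if evs.shape[0] > max_points:
                evs = evs[rng.choice(evs.shape[0], max_points, replace=False)]
            kl[name] = knn_kl(sp, evs)
            n_ev = evs.shape[0]
        reports.append(
            SimilarityReport(
                checkpoint=ckpt, kl=kl, neuron_subset=neurons, seed=seed,
                n_spont=spont.shape[0], n_evoked=n_ev,
            )
        )
    return reports


def latent_decoder(train_latents: np.ndarray, labels: np.ndarray):
    """Multinomial linear (softmax) classifier over latent states."""
    from sklearn.linear_model import LogisticRegression

    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("need at least two classes to fit a decoder")
    clf = LogisticRegression(max_iter=2000)
    clf.fit(np.asarray(train_latents, dtype=float), labels)
    return clf


def decode_to_circle(decoder, latents: np.ndarray, n_classes: int | None = None) -> np.ndarray:
    """Map decoded class probabilities to 2-D circle coordinates.

    Class ``k`` of ``K`` is anchored at angle ``pi/2 - 2 pi k / K`` (first
    class at the top, proceeding clockwise); each probability vector maps to
    the convex combination of the anchors, so a one-hot vector lands on its
    anchor and the uniform vector at the origin.
    """
    probs = decoder.predict_proba(np.atleast_2d(np.asarray(latents, dtype=float)))
    K = n_classes or probs.shape[1]
    angles = np.pi / 2 - 2 * np.pi * np.arange(K) / K
    anchors = np.stack([np.cos(angles), np.sin(angles)], axis=1)
    return probs @ anchors
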