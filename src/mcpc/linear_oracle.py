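"""Exact oracle for the one-latent linear model.

For a linear model with a single input neuron and a single latent state,

    p(y, x; theta) = N(y; W0 x, s) N(x; mu, s),     s = sigma^2 sigma_n^2,

everything is tractable in closed form: the marginal over inputs is
``N(W0 mu, s (W0^2 + 1))``, the posterior over the latent is
``N((W0 y + mu) / (W0^2 + 1), s / (W0^2 + 1))``, and the parameters that
exactly reproduce Gaussian data ``N(mu_data, var_data)`` are the sign-
symmetric pair

    W0_opt = +/- sqrt(var_data / s - 1),   mu_opt = mu_data / W0_opt,

which exists only while ``var_data > s``; below that the best the model can
do is collapse the weight to zero.  These closed forms are the ground truth
against which the stochastic dynamics and learning rules are tested, and
:func:`expected_update_field` gives the expected parameter flow (Monte Carlo
EM for the sampling learner, MAP-EM for classic predictive coding) whose zero
contours are the training nullclines.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "LinearModelParams",
    "GaussianDist",
    "OptimalParams",
    "marginal",
    "posterior",
    "optimal_params",
    "expected_update_field",
]


@dataclass(frozen=True)
class LinearModelParams:
    """Scalar parameters (W0, mu) plus the two variance constants."""

    W0: float
    mu: float
    sigma2: float = 1.0
    sigma_n2: float = 1.0

    def __post_init__(self):
        if self.sigma2 <= 0 or self.sigma_n2 <= 0:
            raise ValueError("variances must be positive")

    @property
    def s(self) -> float:
        """Effective per-layer variance sigma^2 sigma_n^2."""
        return self.sigma2 * self.sigma_n2


@dataclass(frozen=True)
class GaussianDist:
    mean: float
    variance: float

    def __post_init__(self):
        if self.variance <= 0:
            raise ValueError("variance must be positive")

    @property
    def std(self) -> float:
        return float(np.sqrt(self.variance))

    def logpdf(self, y) -> np.ndarray:
        y = np.asarray(y, dtype=float)
        return -0.5 * ((y - self.mean) ** 2 / self.variance + np.log(2 * np.pi * self.variance))

    def pdf(self, y) -> np.ndarray:
        return np.exp(self.logpdf(y))

    def cdf(self, y) -> np.ndarray:
        from scipy.stats import norm

        return norm.cdf(y, loc=self.mean, scale=self.std)


@dataclass(frozen=True)
class OptimalParams:
    """The two sign-symmetric optima, or the W0 = 0 boundary solution."""

    plus: tuple[float, float]
    minus: tuple[float, float]
    at_boundary: bool = False


def marginal(params: LinearModelParams) -> GaussianDist:
    """Marginal over the input: N(W0 mu, sigma^2 sigma_n^2 (W0^2 + 1))."""
    return GaussianDist(params.W0 * params.mu, params.s * (params.W0**2 + 1.0))


def posterior(params: LinearModelParams, y: float) -> GaussianDist:
    """Posterior over the latent given input ``y``.

    ``N((W0 y + mu)/(W0^2+1), sigma^2 sigma_n^2/(W0^2+1))`` — the prior when
    ``W0 = 0``, and progressively sharper as ``|W0|`` grows.
    """
    c = params.W0**2 + 1.0
    return GaussianDist((params.W0 * y + params.mu) / c, params.s / c)


def optimal_params(
    mu_data: float,
    var_data: float,
    sigma2: float = 1.0,
    sigma_n2: float = 1.0,
) -> OptimalParams:
    """Parameters that make the model marginal equal the data distribution.

    When ``var_data <= sigma^2 sigma_n^2`` no real weight matches the data
    variance; the boundary solution ``W0 = 0`` (with the prior mean carrying
    the data mean) is returned flagged.
    """
    if var_data <= 0:
        raise ValueError("data variance must be positive")
    s = sigma2 * sigma_n2
    excess = var_data / s - 1.0
    if excess <= 0:
        return OptimalParams(plus=(0.0, mu_data), minus=(0.0, mu_data), at_boundary=True)
    w = float(np.sqrt(excess))
    return OptimalParams(plus=(w, mu_data / w), minus=(-w, -mu_data / w))


def _gauss_hermite_nodes(mean: float, var: float, n: int):
    t, w = np.polynomial.hermite_e.hermegauss(n)  # weights for N(0,1)
    return mean + np.sqrt(var) * t, w / np.sqrt(2 * np.pi)


def expected_update_field(
    params: LinearModelParams,
    data_mean: float,
    data_var: float,
    method: str = "mcpc",
    n_mc: int = 200,
    rng: np.random.Generator | None = None,
    quadrature: bool = True,
) -> tuple[float, float]:
    """Expected per-datum parameter update (E[dW0], E[dmu]) under the data law.

    For the sampling learner the inner expectation over the posterior is
    analytic (first two posterior moments); for the MAP learner the update is
    evaluated at the exact posterior mode.  The outer expectation over
    ``y ~ N(data_mean, data_var)`` uses Gauss–Hermite quadrature by default
    (deterministic fields) or Monte Carlo with ``n_mc`` draws.

    Nullclines of training are the zero contours of each component.
    """
    if method not in ("mcpc", "pc"):
        raise ValueError(f"unknown method {method!r}")
    if not quadrature:
        if n_mc < 100:
            raise ValueError("n_mc must be >= 100")
        if rng is None:
            rng = np.random.default_rng(0)
        ys = data_mean + np.sqrt(data_var) * rng.standard_normal(n_mc)
        wts = np.full(n_mc, 1.0 / n_mc)
    else:
        ys, wts = _gauss_hermite_nodes(data_mean, data_var, max(n_mc, 64))
    W0, mu, s2 = params.W0, params.mu, params.sigma2
    c = W0**2 + 1.0
    m = (W0 * ys + mu) / c  # posterior mean per y
    if method == "mcpc":
        v = params.s / c  # posterior variance
        dW0 = (ys * m - W0 * (m**2 + v)) / s2
        dmu = (m - mu) / s2
    else:
        dW0 = (ys - W0 * m) * m / s2
        dmu = (m - mu) / s2
    return float(np.sum(wts * dW0)), float(np.sum(wts * dmu))
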