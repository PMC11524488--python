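"""Local plasticity rules and the training loops."""

import numpy as np
import pytest

from mcpc.dynamics import InferenceSchedule
from mcpc.learning import (
    TrainConfig,
    TrainDivergence,
    mcpc_param_update,
    pc_param_update,
    train,
)
from mcpc.linear_oracle import LinearModelParams, posterior
from mcpc.model import GenerativeModel, NetworkState, init_state
from mcpc.config import default_gaussian_config, build_model, make_dataset
from mcpc.datasets import gaussian_data


def scalar_model(W0=2.0, mu=0.5, sn2=1.0):
    return GenerativeModel(weights=[np.array([[W0]])], prior_mean=[mu],
                           noise_variance=sn2)


def states_from_posterior(model_params, ys, rng, n_states=1):
    """i.i.d. oracle-posterior states for a batch of scalar inputs."""
    out = []
    for _ in range(n_states):
        xs = np.array([
            [posterior(model_params, y).mean
             + posterior(model_params, y).std * rng.standard_normal()]
            for y in ys
        ])
        out.append(NetworkState([ys.reshape(-1, 1).astype(float), xs]))
    return out


class TestParamUpdates:
    def test_zero_errors_give_zero_deltas(self):
        m = scalar_model()
        st = NetworkState([np.array([[1.0]]), np.array([[0.5]])])
        d = pc_param_update(m, st)
        assert d["W0"] == pytest.approx(0.0) and d["mu"] == pytest.approx(0.0)

    def test_pc_update_is_negative_param_gradient_at_mode(self, rng):
        m = GenerativeModel.random([3, 2], rng, activation="tanh")
        y = rng.standard_normal((4, 3))
        st = init_state(m, y, rng)
        d = pc_param_update(m, st)
        # numerical parameter gradient of total F
        from mcpc.model import joint_energy

        h = 1e-6
        num = np.zeros_like(m.weights[0])
        for idx in np.ndindex(*m.weights[0].shape):
            mp, mm = m.copy(), m.copy()
            mp.weights[0][idx] += h
            mm.weights[0][idx] -= h
            num[idx] = (joint_energy(mp, st).sum() - joint_energy(mm, st).sum()) / (2 * h)
        np.testing.assert_allclose(d["W0"], -num, atol=1e-6)

    def test_sample_average_normalization(self, rng):
        m = scalar_model()
        states = states_from_posterior(LinearModelParams(2.0, 0.5),
                                       np.array([1.0, -0.5]), rng, n_states=3)
        d1 = mcpc_param_update(m, states)
        d2 = mcpc_param_update(m, states + states)  # duplicated samples
        assert d2["W0"] == pytest.approx(d1["W0"])
        assert d2["mu"] == pytest.approx(d1["mu"])

    def test_weight_decay_term(self, rng):
        m = scalar_model()
        states = states_from_posterior(LinearModelParams(2.0, 0.5),
                                       np.array([1.0]), rng)
        d0 = mcpc_param_update(m, states)
        d1 = mcpc_param_update(m, states, weight_decay=0.1)
        assert d1["W0"] == pytest.approx(d0["W0"] - 0.1 * 2.0)

    def test_empty_trajectory_rejected(self):
        with pytest.raises(ValueError, match="empty|no sampling"):
            mcpc_param_update(scalar_model(), [])

    def test_expected_update_zero_at_optimum(self):
        """With exact posterior samples and data from N(1,5), the expected
        update vanishes at the optimum (stationarity of the marginal-likelihood
        gradient)."""
        rng = np.random.default_rng(12)
        m = scalar_model(2.0, 0.5)
        p = LinearModelParams(2.0, 0.5)
        n = 40000
        ys = gaussian_data(1.0, 5.0, n, rng).ravel()
        c = p.W0**2 + 1
        xs = (p.W0 * ys + p.mu) / c + np.sqrt(p.s / c) * rng.standard_normal(n)
        st = NetworkState([ys.reshape(-1, 1), xs.reshape(-1, 1)])
        d = mcpc_param_update(m, [st])
        # per-sample SE of the summed update
        per_W = (ys - p.W0 * xs) * xs
        per_m = xs - p.mu
        assert abs(d["W0"][0, 0]) < 4 * per_W.std() * np.sqrt(n)
        assert abs(d["mu"][0]) < 4 * per_m.std() * np.sqrt(n)


class TestMcemConsistency:
    def test_expected_update_matches_marginal_loglik_gradient(self):
        """Monte Carlo EM: oracle-posterior expected updates equal the
        analytic gradient of the average marginal log-likelihood (10 random
        parameter points, 4 SE)."""
        rng = np.random.default_rng(77)
        t, w = np.polynomial.hermite_e.hermegauss(80)
        yq, wq = 1.0 + np.sqrt(5.0) * t, w / np.sqrt(2 * np.pi)

        def avg_ll(W0, mu):
            v = W0**2 + 1
            return np.sum(wq * (-0.5 * ((yq - W0 * mu) ** 2 / v + np.log(2 * np.pi * v))))

        for _ in range(10):
            W0 = rng.uniform(-3, 3)
            mu = rng.uniform(-1.5, 1.5)
            p = LinearModelParams(W0, mu)
            n = 40000
            ys = 1.0 + np.sqrt(5.0) * rng.standard_normal(n)
            c = W0**2 + 1
            xs = (W0 * ys + mu) / c + np.sqrt(1.0 / c) * rng.standard_normal(n)
            dW = (ys - W0 * xs) * xs
            dm = xs - mu
            h = 1e-5
            gW = (avg_ll(W0 + h, mu) - avg_ll(W0 - h, mu)) / (2 * h)
            gm = (avg_ll(W0, mu + h) - avg_ll(W0, mu - h)) / (2 * h)
            assert abs(dW.mean() - gW) < 4 * dW.std() / np.sqrt(n)
            assert abs(dm.mean() - gm) < 4 * dm.std() / np.sqrt(n)


class TestTrainLoop:
    def test_zero_learning_rate_keeps_parameters(self, rng):
        m = scalar_model(1.0, 0.2)
        cfg = TrainConfig(epochs=2, batch_size=8, lr=0.0,
                          schedule=InferenceSchedule(map_steps=10, mixing_steps=5,
                                                     sampling_steps=1), seed=1)
        data = gaussian_data(1.0, 5.0, 32, rng)
        trained, _ = train(m, data, cfg, method="mcpc")
        assert trained.weights[0][0, 0] == pytest.approx(1.0)
        assert trained.prior_mean[0] == pytest.approx(0.2)

    def test_reproducible_from_seed(self, rng):
        data = gaussian_data(1.0, 5.0, 64, np.random.default_rng(3))
        cfg = TrainConfig(epochs=3, batch_size=32, lr=0.02,
                          schedule=InferenceSchedule(map_steps=20, mixing_steps=20,
                                                     sampling_steps=1), seed=5)
        outs = [train(scalar_model(0.3, 0.0), data, cfg, method="mcpc")[0]
                for _ in range(2)]
        np.testing.assert_array_equal(outs[0].weights[0], outs[1].weights[0])

    def test_log_counter_monotone_and_checkpoints(self, rng):
        data = gaussian_data(1.0, 5.0, 64, rng)
        cfg = TrainConfig(epochs=2, batch_size=32, lr=0.02,
                          schedule=InferenceSchedule(map_steps=10, mixing_steps=10,
                                                     sampling_steps=1),
                          seed=2, checkpoint_updates=(0, 4))
        trained, log = train(scalar_model(0.5, 0.0), data, cfg, method="mcpc")
        ups = [r["update"] for r in log.records]
        assert all(b > a for a, b in zip(ups, ups[1:]))
        assert set(log.checkpoints) == {0, 4}
        assert log.checkpoints[0].weights[0][0, 0] == pytest.approx(0.5)


@pytest.mark.parametrize("data_var, expect_boundary", [(2.0, False), (5.0, False),
                                                       (0.5, True)])
def test_data_variance_law(data_var, expect_boundary):
    """Trained models match the data variance when they can; when the data
    variance is below the layer variance they saturate at the layer floor."""
    cfg = default_gaussian_config("mcpc", seed=0)
    cfg.data_variance = data_var
    model = build_model(cfg)
    data = make_dataset(cfg)
    trained, _ = train(model, data, cfg.train, method="mcpc")
    from mcpc.dynamics import run_unclamped

    traj = run_unclamped(trained, 10000, np.random.default_rng(42), batch_size=32,
                         burn_in=2000, h=0.02)
    gen_var = traj.layers["x0"].var(ddof=1)
    if expect_boundary:
        assert gen_var >= 1.0 - 0.05  # cannot shrink below sigma^2 sn^2
        assert abs(trained.weights[0][0, 0]) < 0.4
    else:
        assert gen_var == pytest.approx(data_var, rel=0.15)


def test_high_variance_data_reaches_discrete_chain_fixed_point():
    """At high data variance the posterior is stiff and the Euler-discretised
    sampler equilibrates at a slightly inflated posterior variance
    (factor 1/(1 - h kappa / 2), kappa = W0^2 + 1), so learning settles at the
    fixed point of the *discrete* chain, a little below the continuous-time
    optimum.  The learned weight is checked against that fixed point, solved
    independently from the closed-form moment equations."""
    from scipy.optimize import brentq

    Sigma, mu_d, h = 10.0, 1.0, 0.02

    def expected_dW_zero(W0):
        c = W0**2 + 1
        mu = mu_d / W0  # mean-matching nullcline
        v_disc = 1.0 / c / (1 - h * c / 2)
        Eym = (W0 * (Sigma + mu_d**2) + mu * mu_d) / c
        Em2 = (W0**2 * (Sigma + mu_d**2) + 2 * W0 * mu * mu_d + mu**2) / c**2
        return Eym - W0 * (Em2 + v_disc)

    W_pred = brentq(expected_dW_zero, 0.3, 6.0)
    Ws, gen_vars = [], []
    for seed in range(3):
        cfg = default_gaussian_config("mcpc", seed)
        cfg.data_variance = Sigma
        model = build_model(cfg)
        trained, _ = train(model, make_dataset(cfg), cfg.train, method="mcpc")
        Ws.append(abs(trained.weights[0][0, 0]))
        from mcpc.dynamics import run_unclamped

        traj = run_unclamped(trained, 8000, np.random.default_rng(60 + seed),
                             batch_size=32, burn_in=2000, h=0.02)
        gen_vars.append(traj.layers["x0"].var(ddof=1))
    W_mean = float(np.mean(Ws))
    assert abs(W_mean - W_pred) < 0.25
    # generated variance is consistent with the learned model's own marginal
    assert np.mean(gen_vars) == pytest.approx(W_mean**2 + 1, rel=0.12)
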