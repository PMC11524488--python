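import numpy as np
import pytest

from mcpc.config import default_image_config, build_model, make_dataset
from mcpc.learning import train
from mcpc.model import GenerativeModel


@pytest.fixture
def linear_model():
    """The reference one-latent linear model: W0 = 2, mu = 0.5, unit variances."""
    return GenerativeModel(weights=[np.array([[2.0]])], prior_mean=[0.5])


@pytest.fixture
def rng():
    return np.random.default_rng(20240)


def _random_model(rng, input_kind, activation):
    dims = [rng.integers(2, 5) for _ in range(rng.integers(2, 4) + 1)]
    return GenerativeModel.random(dims, rng, activation=activation, input_kind=input_kind)


@pytest.fixture
def random_models(rng):
    """Small random models covering both input kinds and all activations."""
    models = []
    for input_kind in ("gaussian", "bernoulli"):
        for activation in ("linear", "relu", "tanh"):
            models.append(_random_model(rng, input_kind, activation))
    return models


@pytest.fixture(scope="session")
def glyph_run():
    """One trained desk-scale glyph model (Bernoulli input), with checkpoints.

    Session-scoped: training takes a few seconds and several analyses reuse it.
    """
    cfg = default_image_config("mcpc", seed=0)
    n_updates = cfg.train.epochs * (cfg.n_data // cfg.train.batch_size)
    cfg.train.checkpoint_updates = (0, n_updates)
    model = build_model(cfg)
    data = make_dataset(cfg)
    trained, log = train(model, data, cfg.train, method="mcpc")
    return {"config": cfg, "model": trained, "log": log, "data": data}
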