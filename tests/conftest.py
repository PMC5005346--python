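import numpy as np
import pytest

from burstmodes import BurstyGeneModel, FeedbackFunction, get_preset


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture
def no_feedback_mu6():
    return get_preset("no_feedback", 6)


@pytest.fixture
def noncoop_mu6():
    """Non-cooperative saturating feedback with medium bursts: bimodal."""
    return get_preset("noncoop", 6)


@pytest.fixture
def coop_bistable_mu1():
    return get_preset("coop_bistable", 1)


def random_model(rng: np.random.Generator) -> BurstyGeneModel:
    """A random bounded-feedback model with moderate stationary support."""
    variant = rng.choice(["constant", "michaelis_menten", "hill"])
    b = float(rng.uniform(0.5, 15.0))
    delta = float(rng.uniform(0.5, 2.0))
    mu = float(rng.uniform(1.0, 8.0))
    if variant == "constant":
        f = FeedbackFunction.constant(b)
    elif variant == "michaelis_menten":
        f = FeedbackFunction.michaelis_menten(
            b=b, v=float(rng.uniform(5.0, 40.0)), K=float(rng.uniform(3.0, 40.0))
        )
    else:
        f = FeedbackFunction.hill(
            b=b,
            v=float(rng.uniform(5.0, 40.0)),
            K_half=float(rng.uniform(5.0, 30.0)),
            h=float(rng.uniform(1.5, 4.0)),
        )
    return BurstyGeneModel(f=f, mu_star=mu, delta=delta)
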