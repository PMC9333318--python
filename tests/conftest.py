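import numpy as np
import pytest

from quorumbd import ModelParameters, SignalingMode, Strategy


def random_model(rng: np.random.Generator) -> tuple:
    """One random (params, strategy, signaling) draw spanning the model space."""
    ka_kind = rng.choice(["finite", "finite", "finite", "zero", "infinity"])
    Ka = {"finite": float(rng.uniform(2, 20)), "zero": "zero", "infinity": "infinity"}[ka_kind]
    p = ModelParameters(
        lambda0=float(rng.uniform(0, 0.5)),
        g=1.0,
        a=float(rng.choice([0.0, rng.uniform(0, 0.3)])),
        c=float(rng.uniform(0, 0.3)),
        mu0=float(rng.uniform(0.005, 0.05)),
        Kg=float(rng.uniform(2, 20)),
        hg=float(rng.uniform(0.5, 4)),
        Ka=Ka,
        ha=float(rng.uniform(0.5, 4)),
    )
    strategy = Strategy(rng.choice(["QS", "QS", "AO", "NP"]))
    signaling = SignalingMode(
        rng.choice(["producers_only", "producers_and_cheaters"])
    )
    return p, strategy, signaling


@pytest.fixture(scope="session")
def model_draws():
    """20 seeded random model draws shared by the oracle-equivalence tests."""
    rng = np.random.default_rng(91731)
    return [random_model(rng) for _ in range(20)]


@pytest.fixture
def destructive_params():
    """No alternative nutrient, moderate cost: the destructive/mixed exemplar."""
    return ModelParameters(lambda0=0.0, c=0.1)


@pytest.fixture
def constructive_params():
    """Alternative nutrient present, moderate cost: the constructive exemplar."""
    return ModelParameters(lambda0=0.2, c=0.15)
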