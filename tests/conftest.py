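import logging

import numpy as np
import pytest

import dtni

logging.getLogger("dtni").setLevel(logging.ERROR)


@pytest.fixture
def cascade():
    """3-gene cascade with known interactions: g1 -> g2 (activating),
    g2 -> g3 (inhibiting), first-order self-degradation."""
    A = np.array([[-1.0, 0.0, 0.0],
                  [0.8, -1.8, 0.0],
                  [0.0, -0.5, -1.5]])
    b = np.array([1.0, 0.0, 0.0])
    gold = {(0, 1), (1, 2)}  # (source j, target i)
    return A, b, gold


@pytest.fixture
def dense_cascade_tensor(cascade):
    A, b, _ = cascade
    times = np.linspace(0.2, 8.0, 40)
    return dtni.simulate_linear_dataset(
        A, b, times=times, doses=[1.0, 5.0, 25.0],
        noise=dtni.NoiseModel(sigma=0.0, replicates=1))


@pytest.fixture
def noise_tensor():
    """Pure-noise tensor on the standard 3x3x2 design (global null)."""
    rng = np.random.default_rng(7)
    values = rng.normal(0.0, 0.2, size=(6, 3, 3, 1, 2))
    return dtni.ExpressionTensor(
        [f"g{i}" for i in range(6)], [2.0, 8.0, 24.0], [[1.0, 5.0, 25.0]],
        ["cpd1"], values)


@pytest.fixture(scope="session")
def nfkb_model():
    return dtni.add_drug_reactions(dtni.ikb_nfkb_module(),
                                   dtni.default_drug_spec())


@pytest.fixture(scope="session")
def nfkb_tensor(nfkb_model):
    return dtni.simulate_dataset(nfkb_model,
                                 noise=dtni.NoiseModel(sigma=0.0, replicates=1))
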