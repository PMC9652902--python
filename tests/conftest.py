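import numpy as np
import pytest

from bicoss import GWASData, SimSettings, simulate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_dataset(
    seed,
    n=150,
    L=200,
    causal=(),
    beta=(),
    rho=0.0,
    tau=0.1,
    sigma2=0.2,
    model="mixed",
    n_blocks=4,
):
    """Small simulated dataset wrapped in GWASData, plus its truth."""
    if L % n_blocks:
        n_blocks = 1
    settings = SimSettings(
        n=n, L=L, n_blocks=n_blocks, rho=rho,
        causal_positions=list(causal), beta=list(beta),
        tau=tau, sigma2=sigma2, model=model, seed=seed,
    )
    G, K, Y, truth = simulate_dataset(settings)
    return GWASData(Y=Y, G=G, K=K), truth


@pytest.fixture
def small_data():
    return make_dataset(seed=7, n=120, L=80, causal=[10, 50], beta=[1.0, 0.8])
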