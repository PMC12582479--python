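import numpy as np
import pytest

import thermoload as tl


@pytest.fixture(scope="session")
def protocol():
    return tl.default_protocol()


@pytest.fixture(scope="session")
def hr_grid(protocol):
    return tl.build_grid(protocol, "hr")


@pytest.fixture(scope="session")
def skin_grid(protocol):
    return tl.build_grid(protocol, "skin")


@pytest.fixture(scope="session")
def toy_params():
    """Small, fast configuration: short series with a 4-point room cycle."""
    return tl.HyperParams(
        sigma_obs={c: 0.3 for c in tl.CONDITIONS},
        sigma_base=0.1,
        sigma_load=0.08,
        sigma_env=0.1,
        h=0.5,
        period=4,
    )


@pytest.fixture(scope="session")
def toy_truth(toy_params):
    return tl.model_dataset(toy_params, T=12, seed=42)


@pytest.fixture(scope="session")
def toy_posterior(toy_truth):
    """A quick multi-chain fit shared by tests that only need draw plumbing."""
    return tl.fit(
        toy_truth.y, mcmc=tl.MCMCConfig(chains=2, warmup=100, sampling=150, seed=5)
    )


def make_series(y, modality="hf", period=4):
    return tl.MeasurementSeries(modality=modality, y=np.asarray(y, float), period=period)
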