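import logging

import pytest

from chromacontact import synthetic_data as sd


@pytest.fixture(autouse=True)
def quiet_info_logging():
    logging.disable(logging.INFO)
    yield
    logging.disable(logging.NOTSET)


@pytest.fixture(scope="session")
def small_proteome():
    """A 60-protein synthetic proteome with planted IDR contacts."""
    config = sd.ProteomeConfig(n_proteins=60, chromatin_fraction=0.2)
    sequences, regions, truth = sd.generate_proteome(config, seed=5)
    return sequences, regions, truth


@pytest.fixture
def noise_free_truth():
    """A tiny truth with noise and missingness switched off."""
    config = sd.ProteomeConfig(
        n_proteins=12,
        chromatin_fraction=0.25,
        effect_log2fc=2.0,
        noise=sd.NoiseModel(s0sq_true=0.0, missing_p_max=0.0),
    )
    sequences, regions, truth = sd.generate_proteome(config, seed=3)
    return sequences, regions, truth
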