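import pytest

from consistentprot import synthdata as sd


@pytest.fixture(scope="session")
def small_config():
    """A fast, fully featured study: 300 proteins, 4 donors x 4 runs."""
    return sd.SynthConfig(
        seed=11,
        n_proteins=300,
        n_decoys=20,
        n_keratin_contaminants=4,
        n_endogenous_keratins=3,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return sd.generate_dataset(small_config)


@pytest.fixture(scope="session")
def noise_free_config():
    """No noise, no censoring: ratios recover the planted effects exactly."""
    return sd.SynthConfig(
        seed=5,
        n_proteins=100,
        donor_sd=0.0,
        tech_sd=0.0,
        detect_limit=-1e9,
        n_decoys=0,
        n_keratin_contaminants=0,
        n_endogenous_keratins=0,
    )


@pytest.fixture(scope="session")
def noise_free_dataset(noise_free_config):
    return sd.generate_dataset(noise_free_config)
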