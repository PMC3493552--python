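import pytest

from acedrift import SyntheticDesign, generate_experiment


@pytest.fixture(scope="session")
def null_experiment():
    """A full-size unbiased synthetic experiment (2 x 10 chains x 10 gens)."""
    return generate_experiment(SyntheticDesign(sigma=0.0343, seed=42))


@pytest.fixture(scope="session")
def null_records(null_experiment):
    return null_experiment.records
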