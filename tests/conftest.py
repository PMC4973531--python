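import numpy as np
import pytest
import yaml

from drscreen import markov, synthetic


@pytest.fixture(scope="session")
def demo_model():
    """The bundled illustrative cohort model."""
    with open(markov.demo_model_path()) as fh:
        config = yaml.safe_load(fh)
    return markov.model_from_config(config)


@pytest.fixture(scope="session")
def small_registry():
    """A small deterministic synthetic registry (two years, 3,000 patients)."""
    config = synthetic.GeneratorConfig(n_patients=3000, years=(2007, 2008), seed=11)
    return config, synthetic.generate_registry(config)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
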