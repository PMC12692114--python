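import numpy as np
import pytest

import nirfuse as nf


@pytest.fixture(scope="session")
def default_dataset():
    """Spectra + traits at the study conditions (120 samples, 129-point grid)."""
    return nf.generate(nf.default_config(seed=7))


@pytest.fixture(scope="session")
def preprocessed(default_dataset):
    """Trimmed (15/15) and SNV-corrected spectra with the matching traits."""
    block, traits = default_dataset
    return nf.snv(nf.trim_head_tail(block, 15, 15)), traits


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
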