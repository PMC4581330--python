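import numpy as np
import pytest

from idrbrnn import SyntheticConfig, generate_corpus


@pytest.fixture(scope="session")
def tiny_corpus():
    """12 fully annotated chains, small MSAs, high-identity templates."""
    cfg = SyntheticConfig(
        n_chains=12,
        length_range=(60, 120),
        msa_depth=8,
        template_identities=(0.9, 0.6),
        template_label_noise=0.05,
        seed=42,
    )
    return generate_corpus(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
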