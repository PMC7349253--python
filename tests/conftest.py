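import numpy as np
import pytest

from mveeg import PipelineConfig, SimConfig, generate_trialset


@pytest.fixture(scope="session")
def small_trials():
    """Compact high-SNR 4-class trial set for feature-level unit tests."""
    cfg = SimConfig(n_trials_per_class=16, n_channels=8, snr=5.0, seed=11)
    return generate_trialset(cfg)


@pytest.fixture(scope="session")
def tiny_cfg():
    """A pipeline configuration sized for second-scale end-to-end tests."""
    from dataclasses import replace

    base = PipelineConfig().scaled_down(
        hidden_widths=(16, 16, 32), d=4, rbm_epochs=3, finetune_epochs=3)
    return replace(base, tsne=replace(base.tsne, batch_size=20, perplexity=8.0))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
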