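import numpy as np
import pytest

from eogkit import (PipelineConfig, STATES, TraceConfig, generate_trial,
                    process_trace, train)


@pytest.fixture(scope="session")
def noise_free_config() -> TraceConfig:
    return TraceConfig().noise_free()


@pytest.fixture(scope="session")
def default_config() -> TraceConfig:
    return TraceConfig()


@pytest.fixture(scope="session")
def pipeline_config() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture(scope="session")
def clean_feature_set(noise_free_config, pipeline_config):
    """Raw feature matrix + labels for 20 noise-free trials per state."""
    feats, labels = [], []
    for rep in range(20):
        for idx, state in enumerate(STATES):
            tr = generate_trial(state, noise_free_config,
                                seed=10_000 + 31 * rep + idx)
            feats.append(process_trace(tr, pipeline_config).features)
            labels.append(state)
    return np.vstack(feats), labels


@pytest.fixture(scope="session")
def clean_model(clean_feature_set):
    feats, labels = clean_feature_set
    return train(feats, labels, seed=0)
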