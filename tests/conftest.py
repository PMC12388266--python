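import numpy as np
import pytest

from piezodenoise import (DBNModel, TrainConfig, SyntheticConfig,
                          make_training_set, make_benchmark, pretrain,
                          fine_tune)
from piezodenoise.baseline_cnn import build_default_cnn, train_cnn


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def synth_cfg():
    return SyntheticConfig()


@pytest.fixture(scope="session")
def benchmark(synth_cfg):
    """Default (clean, noisy) evaluation pair."""
    return make_benchmark(synth_cfg)


@pytest.fixture(scope="session")
def training_pairs(synth_cfg):
    return make_training_set(synth_cfg, 2048, L=64)


@pytest.fixture(scope="session")
def trained_dbn(training_pairs):
    """DBN trained at the default benchmark scale (shared across tests)."""
    noisy_w, clean_w = training_pairs
    cfg = TrainConfig(pretrain_epochs=3, finetune_epochs=100,
                      batch_size=32, seed=0)
    model = DBNModel.initialize(64, (256, 128, 64), seed=0)
    model = pretrain(model, noisy_w, cfg)
    model, history = fine_tune(model, noisy_w, clean_w, cfg)
    return model, history


@pytest.fixture(scope="session")
def trained_cnn(training_pairs):
    """Comparator trained at reduced scale (fraction of the corpus, short
    schedule) to keep the suite fast; shares data with the DBN run."""
    noisy_w, clean_w = training_pairs
    spec = build_default_cnn()
    cfg = TrainConfig(finetune_epochs=10, batch_size=32, seed=0)
    weights, history = train_cnn(spec, noisy_w[:256], clean_w[:256], cfg)
    return spec, weights, history
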