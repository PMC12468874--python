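import numpy as np
import pytest

from heartpcg.pipeline import PipelineConfig
from heartpcg.ramm import RAMMConfig, TrainConfig
from heartpcg.spectrogram import STFTConfig
from heartpcg.synthetic import SynthConfig, write_dataset
from heartpcg.feature_selection import NCAParams, ReliefFParams


def tiny_model_config(**overrides) -> RAMMConfig:
    """A minute network for fast structural tests (40x40 input)."""
    kwargs = dict(
        input_size=40,
        residual_widths=(4, 8),
        reduce_channels=4,
        mixer_patch=20,
        mixer_hidden=16,
        mixer_token_dim=8,
        mixer_channel_dim=16,
        feature_dim=50,
    )
    kwargs.update(overrides)
    return RAMMConfig(**kwargs)


@pytest.fixture(scope="session")
def tiny_synth_dir(tmp_path_factory):
    """12 short synthetic records (8 healthy / 4 unhealthy) on disk."""
    out = tmp_path_factory.mktemp("synthdata")
    cfg = SynthConfig(n_healthy=8, n_unhealthy=4, duration=2.0, seed=7)
    manifest_path, records = write_dataset(cfg, out)
    return manifest_path, records


@pytest.fixture(scope="session")
def tiny_pipeline_config():
    cfg = PipelineConfig(
        spectrogram=STFTConfig(out_size=40),
        model=tiny_model_config(),
        train=TrainConfig(epochs=2, batch_size=4, val_fraction=0.0),
        synth=SynthConfig(n_healthy=16, n_unhealthy=8, duration=2.0),
        nca=NCAParams(max_iters=15),
        relieff=ReliefFParams(k=3),
        top_x=20,
        folds=4,
        repeats=1,
        seed=5,
    )
    cfg.apply_seed()
    return cfg


@pytest.fixture()
def separable_features():
    """40 samples x 6 features; the first feature separates the classes."""
    rng = np.random.default_rng(11)
    y = np.array([0] * 20 + [1] * 20)
    X = rng.normal(size=(40, 6))
    X[:, 0] = y * 3.0 + 0.1 * rng.normal(size=40)
    return X, y
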