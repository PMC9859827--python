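import numpy as np
import pandas as pd
import pytest

from txconcord.pipeline import PipelineConfig, run_pipeline
from txconcord.syndata import SyntheticConfig, generate_experiment

# the packaged synthetic design: 4 model-system groups x 6 samples,
# 2000 genes, 10% planted genes, log2 shift 2.0, 20% dropout, seed 17
FIXTURE_SEED = 17


@pytest.fixture(scope="session")
def fixture_config() -> SyntheticConfig:
    return SyntheticConfig(seed=FIXTURE_SEED)


@pytest.fixture(scope="session")
def fixture_experiment(fixture_config):
    return generate_experiment(fixture_config)


@pytest.fixture(scope="session")
def fixture_pipeline(fixture_config, tmp_path_factory):
    """One full pipeline run on the packaged design, shared across tests."""
    out = tmp_path_factory.mktemp("pipeline")
    cfg = PipelineConfig(
        output_dir=out,
        synthetic=fixture_config,
        k_clusters=4,
        seed=FIXTURE_SEED,
    )
    result = run_pipeline(cfg)
    return cfg, result


@pytest.fixture
def small_experiment():
    """A light 2-group experiment for fast unit tests."""
    cfg = SyntheticConfig(
        n_genes=300,
        groups=(("vivo", 4, False), ("vitro", 4, True)),
        seed=3,
    )
    return generate_experiment(cfg)


@pytest.fixture
def toy_matrix():
    """Tiny deterministic expression matrix with known zeros."""
    tpm = pd.DataFrame(
        {
            "s1": [500000.0, 300000.0, 200000.0, 0.0],
            "s2": [400000.0, 350000.0, 250000.0, 0.0],
            "s3": [0.0, 600000.0, 0.0, 400000.0],
        },
        index=["g1", "g2", "g3", "g4"],
    )
    meta = pd.DataFrame(
        {"group": ["a", "a", "b"], "is_focus": [True, True, False]},
        index=pd.Index(["s1", "s2", "s3"], name="sample_id"),
    )
    return tpm, meta


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
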