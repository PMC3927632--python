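import numpy as np
import pytest

from orphanlc.reporting import run_pipeline
from orphanlc.simulate import SimulationConfig, simulate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def small_config(seed: int = 11) -> SimulationConfig:
    return SimulationConfig(
        seed=seed,
        n_genes_per_class={0: 25, 1: 25, 2: 20, 3: 15, 4: 15, 5: 60},
    )


@pytest.fixture(scope="session")
def small_bundle_dir(tmp_path_factory):
    out = tmp_path_factory.mktemp("bundle")
    simulate_dataset(small_config(), out)
    return out


@pytest.fixture(scope="session")
def pipeline_results(small_bundle_dir, tmp_path_factory):
    out = tmp_path_factory.mktemp("results")
    return run_pipeline(small_bundle_dir, out, seed=5), out


@pytest.fixture(scope="session")
def default_pipeline(tmp_path_factory):
    """Default-scale bundle and pipeline run (seed 42 / 9), shared by the
    direction checks and the determinism test."""
    bundle = tmp_path_factory.mktemp("default_bundle")
    out = tmp_path_factory.mktemp("default_out")
    simulate_dataset(SimulationConfig(seed=42), bundle)
    tables = run_pipeline(bundle, out, seed=9)
    return bundle, out, tables
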