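import numpy as np
import pytest

from shapebind.pipeline import desk_space, run_study
from shapebind.simulate import SimulationConfig, make_shape_table_fixture


@pytest.fixture(scope="session")
def shape_table():
    return make_shape_table_fixture(seed=0)


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale study: 300-kb nuclear contig, 300 planted instances."""
    return SimulationConfig(
        contigs={"Chr1": 300_000, "ChrC": 30_000, "ChrM": 20_000},
        n_instances=300,
        seed=11,
    )


@pytest.fixture(scope="session")
def study_result(small_config, tmp_path_factory):
    """One trained end-to-end run shared by model-dependent tests."""
    workdir = tmp_path_factory.mktemp("study")
    return run_study(
        small_config,
        workdir=workdir,
        space=desk_space(small_config.seed, iterations=4, folds=3),
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
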