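import numpy as np
import pytest

from gevescan.simulate import (SimulationConfig, StrainPair, emit_evidence_files,
                               simulate_strain_pair)


def small_config(**overrides) -> SimulationConfig:
    base = dict(seed=101, n_chromosomes=2, chromosome_lengths=(300_000, 200_000),
                n_viral_insertions_per_strain=3, insertion_length=(15_000, 30_000),
                n_nonviral_insertions_per_strain=1, hic_bin_size=5_000)
    base.update(overrides)
    return SimulationConfig(**base)


@pytest.fixture(scope="session")
def small_pair() -> StrainPair:
    return simulate_strain_pair(small_config())


@pytest.fixture(scope="session")
def small_dir(small_pair, tmp_path_factory):
    d = tmp_path_factory.mktemp("evidence")
    emit_evidence_files(small_pair, d)
    return d


@pytest.fixture(scope="session")
def default_pair() -> StrainPair:
    """Default-scale pair (~2 x 4.5 Mbp) used by the end-to-end recovery tests."""
    return simulate_strain_pair(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def default_run(default_pair, tmp_path_factory):
    from gevescan.pipeline import run_pipeline
    data = tmp_path_factory.mktemp("default_evidence")
    emit_evidence_files(default_pair, data)
    out = tmp_path_factory.mktemp("default_out")
    reports = run_pipeline(str(data), str(out))
    return {"pair": default_pair, "data": data, "out": out, "reports": reports}


@pytest.fixture
def rng():
    return np.random.default_rng(0)
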