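import numpy as np
import pytest

from cortnet import PipelineConfig, SimulationConfig, run_pipeline
from cortnet.simulate import simulate_cohort


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """Small but fully detectable two-tissue cohort used across modules."""
    return SimulationConfig(
        n_samples=200, n_genes_per_tissue=150, n_trans_genes=10,
        trans_effect_size=0.8, n_regulators=2, targets_per_regulator=8,
        edge_effect_size=0.8, n_tissues=2, replication_attenuation=0.8,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return simulate_cohort(small_config)


@pytest.fixture(scope="session")
def pipeline_run(small_config, tmp_path_factory):
    """One full pipeline run shared by the integration tests."""
    out = tmp_path_factory.mktemp("run")
    cfg = PipelineConfig(out_dir=out, simulation=small_config)
    manifest = run_pipeline(cfg)
    return cfg, manifest


def draw_genotype(rng: np.random.Generator, n: int, maf: float = 0.3,
                  k: int = 3) -> np.ndarray:
    """Binomial dosage vector guaranteed to show ``k`` categories."""
    while True:
        E = rng.binomial(2, maf, n)
        if np.unique(E).size == k:
            return E
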