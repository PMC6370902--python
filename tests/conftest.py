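from pathlib import Path

import pytest

from wgsdepth import SimulationConfig, generate_truth
from wgsdepth.config import ErrorModel

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def data_dir() -> Path:
    return DATA_DIR


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """Desk-scale study conditions shared across fast tests."""
    return SimulationConfig(
        genome_length=500_000,
        n_variants=3_000,
        depth_schedule=[0.5, 5.0, 50.0],
        n_replicates=3,
        base_seed=7,
    )


@pytest.fixture(scope="session")
def small_truth(small_config):
    return generate_truth(small_config)


def zero_error_model(**overrides) -> ErrorModel:
    """An error model that copies truth genotypes verbatim."""
    params = dict(
        read_sampling=False,
        min_reads=0,
        per_read_error=0.0,
        het_error_rate=0.0,
        hom_error_rate=0.0,
        ref_error_rate=0.0,
        alt_error_rate=0.0,
        fp_site_rate=0.0,
        low_cov_artifact_rate=0.0,
        haplotype_artifact_max=0.0,
        indel_repr_error_max=0.0,
    )
    params.update(overrides)
    return ErrorModel(**params)
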