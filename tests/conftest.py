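import numpy as np
import pytest

from metataxa.pipeline import PipelineConfig, run_pipeline
from metataxa.synthetic_data import build_reference_db, sample_reads, simulate_communities


@pytest.fixture(scope="session")
def tiny_db():
    """1 phylum, 2 families x 2 genera x 3 species + outgroup."""
    return build_reference_db(
        1, 2, 3, seed=42, families_per_order=2, stem_genera_per_family=1
    )


@pytest.fixture(scope="session")
def small_run():
    """A small but complete synthetic run shared across invariant tests."""
    cfg = PipelineConfig(n_samples=12, depth=250, frac_type_P=0.5)
    return run_pipeline(cfg, seed=11)


@pytest.fixture(scope="session")
def small_reads(tiny_db):
    comm = simulate_communities(tiny_db, 6, 0.5, seed=3)
    return sample_reads(comm, tiny_db, depth=50, error_rate=0.00159, seed=4), comm


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)
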