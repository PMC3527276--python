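import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from shdrop.model import PipelineConfig, ShRNALibrary, ShRNARecord
from shdrop.simulate import SimConfig, make_library

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def tiny_library() -> ShRNALibrary:
    """Three hand-written hairpins with well-separated cores."""
    return ShRNALibrary(
        [
            ShRNARecord("sh1", "GENEA", "ACGTACGTACGTACGTACGTA"),
            ShRNARecord("sh2", "GENEA", "TTTTTTTTTTGGGGGGGGGGG"),
            ShRNARecord("sh3", "GENEB", "CCCCCCCCCCAAAAAAAAAAA"),
        ],
        flank5="AATTCC",
        flank3="GGCCTT",
    )


@pytest.fixture
def pipeline_config() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture(scope="session")
def small_sim():
    """A 20-gene x 2 simulated library with truth, reused across tests."""
    cfg = SimConfig(
        n_genes=20,
        shrnas_per_gene=2,
        depth_per_sample=20_000,
        fraction_synthetic=0.2,
        fraction_essential_both=0.1,
        rng_seed=7,
    )
    library, truth = make_library(cfg, np.random.default_rng(7))
    return cfg, library, truth
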