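import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from pmsnet import SynthConfig, generate, igf1r_axis_fixture, run_pipeline
from pmsnet.synthetic import SyntheticBundle


@pytest.fixture(scope="session")
def default_bundle() -> SyntheticBundle:
    """Full-scale synthetic bundle at the generator's default study conditions."""
    return generate(SynthConfig(seed=1))


@pytest.fixture(scope="session")
def default_result(default_bundle):
    """The whole pipeline run on the default bundle."""
    return run_pipeline(
        default_bundle.risk_genes,
        default_bundle.pathways,
        default_bundle.predictions,
        default_bundle.mirsnps,
    )


@pytest.fixture(scope="session")
def small_config() -> SynthConfig:
    """Scaled-down conditions for tests that regenerate bundles repeatedly."""
    return SynthConfig(
        seed=11,
        universe_size=2000,
        n_pathways=40,
        pathway_size_range=(15, 60),
        n_risk_genes=30,
        n_planted_pathways=4,
        n_mirnas=50,
        target_count_range=(10, 40),
        n_target_site_snps=20,
        n_mirna_gene_snps=6,
        crosstalk_block_size=10,
    )


@pytest.fixture(scope="session")
def axis_fixture():
    return igf1r_axis_fixture()
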