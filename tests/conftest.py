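import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from burdenscan import SimConfig, PlantedEffect, simulate_cohort, write_bundle


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """A compact cohort exercising every generator feature."""
    return SimConfig(
        n_participants=400,
        n_genes=20,
        variants_per_gene=3,
        seed=11,
        planted_effects=[PlantedEffect("G0002", 1.0, target_carrier_frac=0.05)],
        frac_related_pairs=0.02,
        frac_high_missing_sites=0.05,
        het_fail_rate=0.05,
    )


@pytest.fixture(scope="session")
def small_sim(small_config):
    return simulate_cohort(small_config)


@pytest.fixture(scope="session")
def small_bundle(small_config, tmp_path_factory):
    out = tmp_path_factory.mktemp("bundle")
    return write_bundle(small_config, out)
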