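import numpy as np
import pytest

from aromapanel.data import PipelineConfig, summarize_by_region
from aromapanel.reference import packaged_compound_meta, region_mean_table
from aromapanel.synthetic import generate, packaged_table1_spec

# The published per-region OAV matrix (compound -> {region: printed value}),
# used as the desk-check target for the quantification stage.
PRINTED_OAV = {
    "Methyl acetate": {"BJ": 41.22, "SD": 200.90, "HB": 32.50},
    "(E)-Hex-2-enal": {"BJ": 20.21, "SD": 89.61, "HB": 2.19},
    "Benzaldehyde": {"BJ": 2.06, "SD": 6.48, "HB": 4.84},
    "[(Z)-Hex-3-enyl] acetate": {"BJ": 195.98, "SD": 60.28, "HB": 65.60},
    "Hexyl acetate": {"BJ": 191.51, "SD": 229.10, "HB": 178.00},
    "Nonan-1-ol": {"BJ": 2.87, "SD": 0.89, "HB": 0.76},
    "5-Ethyloxolan-2-one": {"BJ": 2.71, "SD": 0.24, "HB": 7.70},
}

# Reported pairwise candidate sets and the final marker panel.
EXPECTED_CANDIDATES = {
    ("BJ", "SD"): {"Methyl acetate", "Benzaldehyde", "(E)-Hex-2-enal",
                   "[(Z)-Hex-3-enyl] acetate"},
    ("BJ", "HB"): {"Benzaldehyde", "(E)-Hex-2-enal",
                   "[(Z)-Hex-3-enyl] acetate", "5-Ethyloxolan-2-one"},
    ("HB", "SD"): {"Methyl acetate", "(E)-Hex-2-enal", "5-Ethyloxolan-2-one"},
}
EXPECTED_PANEL = {"Methyl acetate", "(E)-Hex-2-enal", "Benzaldehyde",
                  "[(Z)-Hex-3-enyl] acetate", "5-Ethyloxolan-2-one"}


@pytest.fixture(scope="session")
def metas():
    return packaged_compound_meta()


@pytest.fixture(scope="session")
def mean_table():
    return region_mean_table()


@pytest.fixture(scope="session")
def mean_summaries(mean_table):
    return summarize_by_region(mean_table)


@pytest.fixture(scope="session")
def synth_table():
    """Seed-1 synthetic study table: 3 regions x 12 samples x 23 compounds."""
    return generate(packaged_table1_spec(seed=1))


@pytest.fixture()
def config():
    return PipelineConfig(seed=1, n_permutations=50)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
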