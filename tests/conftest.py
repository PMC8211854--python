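from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from dmrkit.intervals import IntervalSet
from dmrkit.simulate import (SimulationParams, make_genome, simulate_annotations,
                             simulate_window_counts)

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def small_genome():
    return make_genome({"chr1": 1_000_000, "chr2": 500_000}, seed=1)


@pytest.fixture(scope="session")
def annotations(small_genome):
    return simulate_annotations(small_genome, seed=3)


@pytest.fixture(scope="session")
def null_matrix(small_genome):
    params = SimulationParams(planted_fraction=0.0, dispersion=0.1,
                              mean_rpkm=10, seed=5)
    wcm, truth = simulate_window_counts(small_genome, params)
    return wcm, truth


@pytest.fixture()
def fixture_vcf_path():
    return DATA_DIR / "variants_fixture.vcf"


@pytest.fixture()
def toy_intervals():
    return IntervalSet(pd.DataFrame({
        "chrom": ["chr1", "chr1", "chr1", "chr2"],
        "start": [100, 300, 1000, 50],
        "end": [200, 450, 1500, 150],
    }))
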