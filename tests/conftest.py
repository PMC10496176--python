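import numpy as np
import pandas as pd
import pytest

from copath.genotypes import GenotypeMatrix
from copath.simulate import SimulationConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """One modest cohort reused by read-only tests."""
    config = SimulationConfig(n_per_site=(600, 300), n_variants=30, seed=11)
    return generate_cohort(config)


@pytest.fixture()
def tiny_gm():
    """Hand-built 4-variant x 6-sample matrix with known properties."""
    variants = pd.DataFrame(
        {
            "id": ["v1", "v2", "v3", "v4"],
            "chrom": ["1", "1", "2", "2"],
            "pos": [100, 200, 100, 300],
            "ref": ["A", "C", "G", "T"],
            "alt": ["G", "T", "A", "C"],
            "imputation_r2": [np.nan, 0.95, 0.79, 0.9],
        }
    )
    dosages = np.array(
        [
            [0, 1, 1, 2, 0, 1],
            [0, 0, 1, 1, 2, 2],
            [1, 1, 0, 2, 1, 0],
            [0, 0, 0, 1, 0, 0],
        ],
        dtype=float,
    )
    return GenotypeMatrix(
        variants=variants,
        samples=["s1", "s2", "s3", "s4", "s5", "s6"],
        dosages=dosages,
        hard_genotypes=dosages.copy(),
    )
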