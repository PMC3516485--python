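import numpy as np
import pandas as pd
import pytest

from trknob import GenotypeTable, SimulationConfig, study_scale_fixture


@pytest.fixture(scope="session")
def bundle():
    """Study-scale synthetic dataset (143 loci, 8+8 isolates, 28/9 planted)."""
    return study_scale_fixture(seed=7)


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(
        n_micro_loci=8, n_mini_loci=6, n_fixed_comparisons=5,
        n_unexpressed_comparisons=3, n_variance_reduced_loci=3,
        n_background_genes=20,
    )


@pytest.fixture
def toy_genotypes():
    """Three loci, 2+2 isolates, with a missing call and a fixed locus."""
    lengths = pd.DataFrame(
        {
            "a1": [150.0, 200.0, 300.0],
            "a2": [160.0, 200.0, np.nan],
            "b1": [180.0, 200.0, 330.0],
            "b2": [150.0, 200.0, 300.0],
        },
        index=["L1", "L2", "L3"],
    )
    pop = pd.Series({"a1": "ory", "a2": "ory", "b1": "fla", "b2": "fla"})
    return GenotypeTable(lengths=lengths, population=pop)
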