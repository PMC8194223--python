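import numpy as np
import pytest

import ssuvar as sv


@pytest.fixture
def toy_aln():
    """Four taxa, mixed gaps/ambiguity, length 12."""
    return sv.MultipleAlignment(
        [
            ("t1", "--ACGTACGT--"),
            ("t2", "ACACGTACGTAC"),
            ("t3", "ACACGAACGTAC"),
            ("t4", "ACRCGTANGTAC"),
        ]
    )


@pytest.fixture(scope="session")
def small_sim():
    """Seeded small synthetic data set shared across tests (8 taxa/clade, 600 sites)."""
    cfg = sv.SimulationConfig(seed=11, taxa_per_clade=(8, 8, 8), n_sites=600)
    aln, groups, truth = sv.simulate_alignment(cfg)
    return cfg, aln, groups, truth


@pytest.fixture(scope="session")
def study_sim():
    """The default study conditions: 20 taxa/clade, 1800 sites, 60% invariant."""
    cfg = sv.SimulationConfig(seed=1)
    aln, groups, truth = sv.simulate_alignment(cfg)
    return cfg, aln, groups, truth
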