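import numpy as np
import pytest

import lincdiscover as ld


@pytest.fixture(scope="session")
def small_cohort():
    """Default-shaped cohort (7 pairs, 2 degraded) at a small marker count."""
    cfg = ld.SimConfig(n_markers=200, n_loci=30, seed=11)
    return ld.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def clean_cohort():
    """Cohort with no degraded pairs, for calling-accuracy checks."""
    cfg = ld.SimConfig(n_markers=300, n_loci=40, n_degraded_pairs=0, seed=23)
    return ld.simulate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
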