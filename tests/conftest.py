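import matplotlib

matplotlib.use("Agg")

import numpy as np
import pytest

import macrobiota as mb


@pytest.fixture
def toy_table() -> mb.AbundanceTable:
    """3 species x 2 samples with one absent species."""
    return mb.AbundanceTable(
        counts=np.array([[1, 0], [2, 3], [0, 0]]),
        species_ids=["a", "b", "c"],
        sample_ids=["s1", "s2"],
    )


@pytest.fixture(scope="session")
def mssd_cohort() -> mb.AbundanceTable:
    """One MSSD cohort at the reference conditions (S=500, R=100, N=1e5, A=0.5)."""
    spec = mb.ModelSpec(
        model="mssd", mu=-9.0, lam=1.4, A=0.5, S=500, depths=np.full(100, 100_000)
    )
    return mb.sample_mssd(spec, seed=0)


@pytest.fixture(scope="session")
def md_cohort() -> mb.AbundanceTable:
    """One Dirichlet-multinomial cohort (S=500, R=100, N=1e5, A=0.01)."""
    spec = mb.ModelSpec(
        model="md", mu=-9.0, lam=1.4, A=0.01, S=500, depths=np.full(100, 100_000)
    )
    return mb.sample_md(spec, seed=0)
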