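import numpy as np
import pytest

from ssrkit.genotypes import GenotypeTable
from ssrkit.simulate import PanelParams, generate_panel


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture
def two_allele_table():
    """Ten individuals all heterozygous 180/184 at one locus."""
    inds = [f"i{k}" for k in range(10)]
    cells = {(i, "L1"): (180, 184) for i in inds}
    return GenotypeTable(inds, ["L1"], cells)


@pytest.fixture(scope="session")
def panel105():
    """Cohort-scale simulated panel: 105 individuals, 20 loci, K=4."""
    return generate_panel(PanelParams(), seed=11)


@pytest.fixture(scope="session")
def small_panel():
    """Fast panel for EM tests: 60 individuals, 12 loci, K=3."""
    return generate_panel(PanelParams(n=60, L=12, K=3, alpha=0.3), seed=5)
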