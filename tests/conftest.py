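import numpy as np
import pytest

from phylomass import (
    SimulationConfig,
    parse_newick,
    simulate_dataset,
    simulate_traits,
    simulate_tree,
)
from phylomass.datasets import load_subfossil_specimens


@pytest.fixture(scope="session")
def three_taxon_tree():
    """((A:1,B:1):1,C:2) — covariance known by hand."""
    return parse_newick("((A:1,B:1):1,C:2):0;")


@pytest.fixture(scope="session")
def extant_tree():
    """Synthetic 62-taxon ultrametric reference tree (unit depth)."""
    return simulate_tree(62, seed=20)


@pytest.fixture(scope="session")
def extant_traits(extant_tree):
    """One synthetic species-mean trait table on the reference tree."""
    cfg = SimulationConfig(include_fl=True, seed=21)
    return simulate_traits(extant_tree, cfg, rng=np.random.default_rng(21))


@pytest.fixture(scope="session")
def small_dataset():
    """A complete synthetic study at modest size (fast fits)."""
    return simulate_dataset(
        SimulationConfig(n_extant=40, n_fossil_species=6,
                         specimens_per_species=(1, 4), seed=11)
    )


@pytest.fixture(scope="session")
def specimen_table():
    """The packaged subfossil lemur specimen table (127 femora)."""
    return load_subfossil_specimens()


@pytest.fixture(scope="session")
def reference_coefficients(specimen_table):
    """(intercept, slope) of the published allometry, recovered by OLS."""
    x = np.log(specimen_table["fcsa_mm2"].to_numpy(float))
    y = np.log(specimen_table["published_bm_kg"].to_numpy(float) * 1000.0)
    slope, intercept = np.polyfit(x, y, 1)
    return float(intercept), float(slope)
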