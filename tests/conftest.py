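import numpy as np
import pytest

from rilgs import markers, simulate, varcomp


@pytest.fixture(scope="session")
def gmap():
    """Small genetic map: 7 chromosomes x 100 cM, 60 markers each."""
    return simulate.default_map(7, 100.0, 60, seed=1)


@pytest.fixture(scope="session")
def panel(gmap):
    """Default connected three-population panel with plot phenotypes."""
    G, plots, truth = simulate.simulate_panel(
        simulate.SimConfig(seed=7), genome_map=gmap, seed=7
    )
    return G, plots, truth


@pytest.fixture(scope="session")
def filtered_panel(panel):
    G, plots, truth = panel
    Gf, _ = markers.filter_pipeline(G)
    return Gf, plots, truth


@pytest.fixture(scope="session")
def protein_blups(filtered_panel):
    _, plots, _ = filtered_panel
    return varcomp.blups_per_environment(plots, "protein")


@pytest.fixture(scope="session")
def yield_blups(filtered_panel):
    _, plots, _ = filtered_panel
    return varcomp.blups_per_environment(plots, "yield")


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
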