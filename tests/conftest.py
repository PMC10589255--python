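import numpy as np
import pytest

import paraquant as pq


@pytest.fixture(scope="session")
def scenario():
    """Small four-strain study design (CN 3-6, 3 replicates)."""
    return pq.default_scenario(seed=11, library_size=2_000)


@pytest.fixture(scope="session")
def panels(scenario):
    return pq.simulate_panel(scenario)[0]


@pytest.fixture(scope="session")
def panel(panels):
    """One representative 5-copy strain panel."""
    return panels["S5"]


@pytest.fixture(scope="session")
def catalog(panel):
    return pq.design_motifs(panel)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260922)
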