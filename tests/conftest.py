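import numpy as np
import pytest
from hypothesis import settings

from mccn import AbundanceTable, scenario_suite, simulate

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20250922)


@pytest.fixture
def toy_table():
    """3 OTUs x 5 time points, counts."""
    return AbundanceTable(
        ["OTU1", "OTU2", "OTU3"],
        ["d1", "d2", "d3", "d4", "d5"],
        np.array(
            [
                [2.0, 1.0, 3.0, 2.0, 4.0],
                [3.0, 5.0, 2.0, 1.0, 2.0],
                [5.0, 4.0, 5.0, 7.0, 4.0],
            ]
        ),
        taxonomy={"OTU1": "k__Bacteria;p__Nitrospirae", "OTU2": "k__Bacteria"},
    )


@pytest.fixture(scope="session")
def chain_run():
    """One simulated chain community pushed through stationarity + Granger."""
    from mccn import all_pairs_causality, make_stationary

    community = scenario_suite("chain", k=5, T=200, seed=11)
    sim = simulate(community)
    sset = make_stationary(sim.table)
    cmat = all_pairs_causality(sset)
    return community, sim, sset, cmat
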