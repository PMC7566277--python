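import numpy as np
import pandas as pd
import pytest

from nitflow.community import CommunityTable
from nitflow.scenarios import get_scenario, run_scenario


@pytest.fixture(scope="session")
def scenario_run():
    """One noisy paper-default scenario realization, shared across tests."""
    sim, counts = run_scenario("paper_default", seed=7)
    return sim, counts


@pytest.fixture(scope="session")
def scenario_table(scenario_run):
    _, counts = scenario_run
    return CommunityTable(counts=counts.counts,
                          sample_days=counts.sample_days,
                          taxonomy=counts.taxonomy)


@pytest.fixture
def small_table():
    """Tiny hand-written community: 4 samples x 3 taxa."""
    counts = pd.DataFrame(
        [[6, 2, 0], [2, 2, 4], [0, 4, 4], [1, 1, 6]],
        index=[1.0, 2.0, 3.0, 4.0],
        columns=["taxA", "taxB", "taxC"],
    )
    taxonomy = pd.DataFrame(
        {"genus": ["GenA", "GenA", "GenB"],
         "phylum": ["PhyX", "PhyX", "PhyY"]},
        index=pd.Index(["taxA", "taxB", "taxC"], name="taxon_id"),
    )
    return CommunityTable(counts=counts,
                          sample_days=np.array([1.0, 2.0, 3.0, 4.0]),
                          taxonomy=taxonomy)
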