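import numpy as np
import pytest

import metapgs as mp


@pytest.fixture(scope="session")
def toy3_scenario():
    """4-reaction chain: EX -> R1(g1) -> R2(g2 or g3) -> biomass; uptake 10."""
    return mp.toy3()


@pytest.fixture(scope="session")
def toy3_dataset(toy3_scenario):
    """Seeded population of 200 on the TOY3 chain, LP-verified on 20 rows."""
    return mp.scenario_dataset(toy3_scenario, 200, sigma=0.1, seed=1, lp_check=20)


@pytest.fixture(scope="session")
def branched_scenario():
    """3-precursor branched network with a fully limiting shared upstream enzyme."""
    return mp.toy_branched(n_precursors=3, shared_upstream=True, slack_upstream=1.0)


@pytest.fixture(scope="session")
def mixed_chain_scenario():
    """Chain exercising isozyme, complex, and reversible steps together."""
    return mp.toy_chain(
        length=4,
        isozyme_positions=(2,),
        complex_positions=(3,),
        reversible_positions=(4,),
        ref_slack={1: 1.0, 2: 1.2, 3: 1.5, 4: 2.0},
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
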