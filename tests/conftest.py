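import matplotlib

matplotlib.use("Agg", force=True)

import pytest

from hqrisk import (
    RandomStream,
    builtin_glyphosate_scenario,
    cell_seed,
    deterministic_assessment,
    run_simulation,
)

#: shared base seed for the session-scoped simulation fixtures
BASE_SEED = 20220901


@pytest.fixture(scope="session")
def config():
    return builtin_glyphosate_scenario()


@pytest.fixture(scope="session")
def det_results(config):
    return deterministic_assessment(config.exposure_scenarios())


@pytest.fixture(scope="session")
def sims_100k(config):
    """100,000-iteration simulations for all six cells, seeded per cell."""
    out = {}
    for group, source in config.probabilistic_cells():
        scenario = config.probabilistic_scenario(group, source)
        stream = RandomStream(cell_seed(BASE_SEED, group, source))
        out[(group, source)] = run_simulation(scenario, 100_000, stream)
    return out
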