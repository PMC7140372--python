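import numpy as np
import pytest

from admixbench import PopulationSpec, default_sac_schedule, make_genetic_map, simulate_panels, split_reference

import helpers


@pytest.fixture(scope="session")
def flagship_world():
    """Small five-way world: 50 cM chromosome, Balding–Nichols panels,
    11 founders per population, the bundled G=15 schedule."""
    gmap = make_genetic_map(50_000_000, 50.0, 200, seed=7)
    specs = [
        PopulationSpec("Bantu", 15, 0.06),
        PopulationSpec("KhoeSan", 15, 0.05),
        PopulationSpec("European", 15, 0.12),
        PopulationSpec("EastAsian", 15, 0.25),
        PopulationSpec("SouthEastAsian", 15, 0.10),
    ]
    panel = simulate_panels(specs, 500, gmap, seed=1)
    founders, holdout = split_reference(panel, 11, seed=2)
    return {
        "gmap": gmap,
        "panel": panel,
        "founders": founders,
        "holdout": holdout,
        "schedule": default_sac_schedule(),
    }


@pytest.fixture(scope="session")
def perfect_world():
    panel, gmap, window_cm = helpers.perfect_world()
    return {"panel": panel, "gmap": gmap, "window_cm": window_cm}


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
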