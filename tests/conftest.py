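import numpy as np
import pytest

import dmnassoc as da


@pytest.fixture(scope="session")
def null_cohort():
    """One default (global-null) cohort at the reference size n = 134."""
    rng = np.random.default_rng(1234)
    return da.simulate_cohort(da.SimulationConfig(), rng)


@pytest.fixture(scope="session")
def effect_cohort():
    """One cohort with a negative interaction injected on PCC-right MTG."""
    cfg = da.SimulationConfig(
        effect_specs=[da.EffectSpec("rs6313", "R_MTG", 0.0, -0.0025)],
        severity_effects={"R_MTG": 0.0025},
    )
    rng = np.random.default_rng(99)
    return cfg, da.simulate_cohort(cfg, rng)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
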