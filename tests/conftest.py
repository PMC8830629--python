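import warnings

import numpy as np
import pytest

import landconnect as lc

# the ensemble warns below 20 presences; small fixtures trip it on purpose
warnings.filterwarnings("ignore", message="only .* presences")


@pytest.fixture(scope="session")
def small_landscape():
    """64x64 synthetic landscape with the default study conditions."""
    spec = lc.LandscapeSpec(n_rows=64, n_cols=64, seed=3)
    stack = lc.generate_predictor_stack(spec)
    truth = lc.TrueModel(
        {"env1": 2.5, "env2": -2.0, "dist_roads": -1.0}, intercept=-4.0
    )
    occ = lc.simulate_occurrences(truth, stack, 188, seed=3)
    return spec, stack, truth, occ


@pytest.fixture(scope="session")
def fitted_small(small_landscape):
    spec, stack, truth, occ = small_landscape
    ens = lc.fit_ensemble(occ, stack, lc.ModelConfig(seed=3))
    hs = lc.predict_suitability(ens, stack)
    return spec, stack, occ, ens, hs


@pytest.fixture
def uniform_resistance():
    """Uniform R = 1 surface on 100 m cells (20 x 40)."""
    hs = lc.Grid(np.ones((20, 40)), 100.0, origin=(0.0, 2000.0))
    return lc.suitability_to_resistance(hs)
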