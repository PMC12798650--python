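"""Shared fixtures.

Expensive simulations are session-scoped and shared between unit and
acceptance tests; trial counts and grids are the study's operating
conditions (20 trials, 10 s, 100 Hz, order 15) where a criterion pins
them, and desk-scale reductions elsewhere.
"""

from __future__ import annotations

import numpy as np
import pytest

from nmgc import experiments as ex
from nmgc import neural_mass as nm


@pytest.fixture(scope="session")
def cfg20() -> ex.ScenarioConfig:
    return ex.ScenarioConfig(n_trials=20, base_seed=0)


@pytest.fixture(scope="session")
def preset_sims() -> dict[str, nm.SimOutput]:
    """One 11 s isolated-ROI simulation per band preset (seed 1)."""
    out = {}
    for band in nm.BANDS:
        net = nm.Network(rois=(nm.preset(band),))
        out[band] = nm.simulate(net, duration=11.0, seed=1, store_psp=False)
    return out


@pytest.fixture(scope="session")
def gamma_theta_sweep(cfg20):
    """Reciprocal excitatory gamma->theta sweep at W in {20, 60, 120}.

    Swept connection: gamma -> theta; reverse fixed at 40.  20 trials per
    grid value with trial-averaged PSDs.
    """
    return ex.run_two_roi_sweep(
        pair=("gamma", "theta"), grid=(20.0, 60.0, 120.0), fixed_W=40.0,
        cfg=cfg20, collect_psds=True,
    )


@pytest.fixture(scope="session")
def alpha_beta_sweeps(cfg20):
    """Endpoint runs (W = 20 and 120) of the alpha<->beta sweeps, both ways."""
    fwd = ex.run_two_roi_sweep(pair=("alpha", "beta"), grid=(20.0, 120.0),
                               fixed_W=40.0, cfg=cfg20)
    rev = ex.run_two_roi_sweep(pair=("beta", "alpha"), grid=(20.0, 120.0),
                               fixed_W=40.0, cfg=cfg20)
    return fwd, rev


@pytest.fixture(scope="session")
def common_input_table(cfg20):
    return ex.run_common_input(grid=(20.0, 40.0, 60.0, 80.0, 100.0, 120.0), cfg=cfg20)


@pytest.fixture(scope="session")
def fig8_conditional(cfg20):
    """Conditional-GC trial aggregate of the 7-ROI mixed network."""
    cfg = ex.ScenarioConfig(n_trials=20, base_seed=0, modes=("conditional",))
    aggregates, results = ex.run_network("fig8_mixed", cfg=cfg)
    return aggregates["conditional"], results["conditional"]


@pytest.fixture(scope="session")
def aic_orders():
    """Akaike-selected orders for all six two-ROI rhythm pairs at W=40."""
    cfg = ex.ScenarioConfig(n_trials=10, base_seed=0)
    return ex.select_orders_two_roi(p_max=30, cfg=cfg)


@pytest.fixture(scope="session")
def fig7_networks():
    cfg = ex.ScenarioConfig(n_trials=5, base_seed=0)
    return ex.run_network("fig7_variants", cfg=cfg)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
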