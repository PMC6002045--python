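from __future__ import annotations

import numpy as np
import pytest

from sdmrisk.grids import ClimateGrid, GridStack, align_stack
from sdmrisk.synthetic import TruthParams, make_climate, sample_presences, true_suitability


@pytest.fixture
def flat_grid() -> ClimateGrid:
    """5×5 unmasked grid of ones near the equator, 1° cells."""
    shape = (5, 5)
    return ClimateGrid("flat", np.ones(shape), np.zeros(shape, bool),
                       origin=(0.0, 2.5), cell_size=1.0)


@pytest.fixture(scope="session")
def climate() -> GridStack:
    return make_climate(seed=7)


@pytest.fixture(scope="session")
def truth_and_presences(climate):
    params = TruthParams(n_presence=300, seed=7)
    truth = true_suitability(climate, params)
    occ = sample_presences(truth, None, params.n_presence, seed=7)
    return params, truth, occ


@pytest.fixture(scope="session")
def small_training_data(climate, truth_and_presences):
    """Per-variable presence/background covariate vectors for fitting tests."""
    _, _, occ = truth_and_presences
    rng = np.random.default_rng(11)
    cells = rng.integers(0, climate.shape[0], size=(1500, 2))
    values_bg = {n: climate[n].values[cells[:, 0], cells[:, 1]] for n in climate.names}
    values_pres = climate.values_at_points(occ.points)
    return values_pres, values_bg


@pytest.fixture(scope="session")
def quickstart_run(tmp_path_factory):
    """One synthetic quick-start pipeline run, shared across tests."""
    from sdmrisk.pipeline import quickstart_config, run_all

    outdir = tmp_path_factory.mktemp("qs") / "run"
    cfg = quickstart_config(str(outdir), seed=3)
    run_all(cfg)
    return cfg, str(outdir)
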