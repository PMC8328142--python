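import numpy as np
import pytest

from amrdmd.pipeline import analyze, preset, simulate


@pytest.fixture(scope="session")
def seird1d_run():
    """One full adaptive 1D epidemic run with DMD analysis, shared by the
    forecasting and rank-study tests (the expensive end-to-end computation)."""
    cfg = preset("seird1d")
    sim = simulate(cfg)
    analyses = analyze(sim.series, cfg, seed=1)
    return cfg, sim, analyses


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
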