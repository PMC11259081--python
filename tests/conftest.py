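import numpy as np
import pytest

from circgenome import make_default_parameters


@pytest.fixture
def params():
    return make_default_parameters()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def small_params(**over):
    """A small grid with the default event probabilities."""
    p = make_default_parameters().replace(N=5, T_NPB=4000)
    return p.replace(**over) if over else p


@pytest.fixture(scope="session")
def spread_runs():
    """Three desk-scale one-gene runs (shared by several tests).

    Grid 15x15, quarter material endowment, 50 linear REP + 50 control
    molecules inoculated at step 1000, 30000 steps.
    """
    from circgenome.scenario_runner import preset, run
    out = []
    for seed in (1, 2, 3):
        cfg = preset("fig2a_scaled")
        cfg.steps = 30_000
        cfg.seed = seed
        out.append(run(cfg))
    return out
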