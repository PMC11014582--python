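import numpy as np
import pytest

from metastable.params import ArousalSpec, NetworkSpec, SimulationConfig
from metastable.network import build_clustered, build_uniform, draw_arousal_inputs


def small_spec(**kw) -> NetworkSpec:
    """A miniature clustered spec for fast structural tests."""
    base = dict(
        NE=200, NI=50, p=4, fE=0.2, fI=0.2,
        p_conn={"E": {"E": 0.2, "I": 0.4}, "I": {"E": 0.4, "I": 0.4}},
    )
    base.update(kw)
    return NetworkSpec(**base)


@pytest.fixture(scope="session")
def default_spec() -> NetworkSpec:
    return NetworkSpec()


@pytest.fixture(scope="session")
def small_clustered():
    spec = small_spec()
    return spec, build_clustered(spec, seed=1)


@pytest.fixture(scope="session")
def small_uniform():
    spec = small_spec()
    return spec, build_uniform(spec, seed=1)


@pytest.fixture(scope="session")
def arousal_none(default_spec):
    return draw_arousal_inputs(default_spec, ArousalSpec(mode="none"), 0)


# ---------------------------------------------------------------------------
# Heavier shared simulations (session-scoped so several tests reuse them)
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def spont_campaign_df(default_spec):
    """Spontaneous campaign over the arousal grid (shared by several tests)."""
    from metastable.workflows import spontaneous_campaign
    return spontaneous_campaign(default_spec, [0.0, 0.1, 0.2, 0.3, 0.4],
                                n_realizations=3, n_trials=10,
                                master_seed=1000)


@pytest.fixture(scope="session")
def evoked_campaign_dfs(default_spec):
    """Clustered + uniform evoked campaigns over the arousal grid."""
    from metastable.workflows import evoked_campaign
    grid = [0.0, 0.1, 0.2, 0.3, 0.4]
    dfc = evoked_campaign(default_spec, grid, arch="clustered",
                          n_realizations=3, n_trials_per_stimulus=10,
                          master_seed=7)
    dfu = evoked_campaign(default_spec, grid, arch="uniform",
                          n_realizations=3, n_trials_per_stimulus=10,
                          master_seed=7, T_trial=1.0, t_stim=0.3,
                          n_feature_runs=10)
    return dfc, dfu


@pytest.fixture(scope="session")
def synthetic_session():
    from metastable.synth import SyntheticSessionSpec, gen_session
    spec = SyntheticSessionSpec(n_units=60, duration=1800.0, seed=11)
    return gen_session(spec)
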