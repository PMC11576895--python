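import hypothesis
import pandas as pd
import pytest

import mpbpk

hypothesis.settings.register_profile(
    "ci", derandomize=True, max_examples=50, deadline=None
)
hypothesis.settings.load_profile("ci")


@pytest.fixture(scope="session")
def mouse():
    return mpbpk.load_species("mouse")


@pytest.fixture(scope="session")
def human():
    return mpbpk.load_species("human")


@pytest.fixture(scope="session")
def fixtures():
    return mpbpk.scenario_fixtures()


@pytest.fixture(scope="session")
def wt_case(fixtures):
    """Wild-type mouse IgG scenario resolved to (params, schedule)."""
    return fixtures["mouse_igg_wt"].build()


@pytest.fixture(scope="session")
def wt_profile(wt_case):
    params, sched = wt_case
    return mpbpk.simulate(params, sched, t_end=504.0)


@pytest.fixture(scope="session")
def tissue_table():
    """Small per-tissue table: the four tight tissues plus liver."""
    return pd.DataFrame({
        "tissue": ["brain", "muscle", "skin", "adipose", "liver"],
        "V_v_L": [1e-5, 2e-4, 1.5e-4, 2e-5, 1.6e-4],
        "V_e_L": [2e-6, 5e-5, 2.5e-5, 1e-5, 1e-5],
        "V_is_L": [9e-5, 1.5e-3, 1.6e-3, 3e-4, 4e-4],
        "Q_L_per_h": [0.012, 0.086, 0.028, 0.013, 0.094],
        "L_L_per_h": [2.4e-5, 1.7e-4, 5.6e-5, 2.7e-5, 1.9e-4],
    })


@pytest.fixture(scope="session")
def species_params():
    return dict(
        species_name="testmouse", body_weight_kg=0.028, V_p_L=9.44e-4,
        V_lymph_L=1.13e-4, V_ep_L=1e-4, FcRn_total_nM=49800.0,
        GFR_L_per_h=0.01668, endosomal_transit_time_h=8 / 60, sigma_L=0.2,
    )
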