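import numpy as np
import pytest

from simmkit.bifurcation import map_control_plane
from simmkit.models import build_cln_sic_clb, build_mcc_apc, build_simm
from simmkit.params import get_preset
from simmkit.steady_state import integrate_to_steady_state


@pytest.fixture(scope="session")
def simm():
    params = get_preset("simm")
    return build_simm(params), params


@pytest.fixture(scope="session")
def simm_star():
    params = get_preset("simm_star")
    from simmkit.models import build_simm_star

    return build_simm_star(params), params


@pytest.fixture(scope="session")
def mcc():
    params = get_preset("mcc_apc")
    return build_mcc_apc(params), params


@pytest.fixture(scope="session")
def cycb():
    params = get_preset("cycb_mcc_apc")
    from simmkit.models import build_cycb_mcc_apc

    return build_cycb_mcc_apc(params), params


@pytest.fixture(scope="session")
def mcc_disengaged_at_full_tension(mcc):
    model, params = mcc
    res = integrate_to_steady_state(
        model, np.array([0.0, 0.0, 0.1]), params.with_updates(X_tens=1.0)
    )
    assert res.converged
    return res.state


@pytest.fixture(scope="session")
def simm_control_plane(simm):
    """Bistable V of the basic motif in the (I_T, A_T) plane."""
    model, params = simm
    return map_control_plane(
        model, params, "I_T", "A_T", ((1.0, 8.0), (0.2, 3.0)),
        n_grid=20, n_starts=16,
    )


@pytest.fixture(scope="session")
def cln_control_plane():
    """Bistable V of the G1/S model in the (ClnT, ClbT) plane."""
    params = get_preset("cln_sic_clb")
    model = build_cln_sic_clb(params)
    return map_control_plane(
        model, params, "ClnT", "ClbT", ((0.0, 0.8), (0.1, 1.4)),
        n_grid=20, n_starts=16,
    )


@pytest.fixture(scope="session")
def g1s_result():
    from simmkit.scenarios import g1s_cycle_scenario

    return g1s_cycle_scenario(get_preset("cln_sic_clb"))


@pytest.fixture(scope="session")
def invitro_result():
    from simmkit.scenarios import mitotic_release_in_vitro

    return mitotic_release_in_vitro(get_preset("mcc_apc"))
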