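import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import brentq

from simmkit.models import (
    MODEL_BUILDERS,
    ModelDefinition,
    ValidationError,
    build_cln_sic_clb,
    build_cycb_mcc_apc,
    build_mcc_apc,
    build_model,
    build_sic_clb,
    build_simm,
    build_simm_star,
    build_tqssa,
    tqssa_complex,
)
from simmkit.params import ParameterError, get_preset
from simmkit.steady_state import integrate_to_steady_state
from simmkit.bifurcation import find_threshold

_PRESET_FOR = {"tqssa": "simm_star"}


@pytest.mark.parametrize("name", sorted(MODEL_BUILDERS))
def test_conserved_quantities_are_annihilated_by_the_rhs(name):
    """Every declared linear conservation law has zero time-derivative at 100
    randomized admissible states."""
    params = get_preset(_PRESET_FOR.get(name, name))
    model = build_model(name, params)
    rng = np.random.default_rng(42)
    for _ in range(100):
        y = model.sample_state(rng, params)
        dy = model.rhs(y, params)
        for law in model.conservations:
            ldot = sum(
                c * dy[model.state_vars.index(v)] for v, c in law.coeffs.items()
            )
            assert abs(ldot) < 1e-10


@pytest.mark.parametrize("name", sorted(MODEL_BUILDERS))
def test_rhs_finite_on_admissible_region(name):
    params = get_preset(_PRESET_FOR.get(name, name))
    model = build_model(name, params)
    rng = np.random.default_rng(7)
    for _ in range(50):
        y = model.sample_state(rng, params)
        assert np.all(np.isfinite(model.rhs(y, params)))


def test_simm_initial_binding_flux(simm):
    """With all inhibitor free and all enzyme free, the only active flux is
    association: dI/dt = -k_as1 * A_T * I_T."""
    model, params = simm
    y = np.array([params["I_T"], 0, 0, 0, 0])
    dy = model.rhs(y, params)
    expected = -params["k_as1"] * params["A_T"] * params["I_T"]
    assert dy[model.state_vars.index("I")] == pytest.approx(expected)
    # the complex gains exactly what free I loses
    assert dy[model.state_vars.index("C")] == pytest.approx(-expected)


def test_missing_symbol_and_negative_parameter_are_errors():
    with pytest.raises(ParameterError):
        build_simm(get_preset("sic_clb"))
    with pytest.raises(ParameterError):
        get_preset("simm").with_updates(k_cat1=-1.0)


def test_simm_star_without_enzyme_relaxes_to_unmodified_pool(simm_star):
    """A_T = 0: only de-modification remains, so I -> I_T and I_MM -> 0."""
    model, params = simm_star
    p0 = params.with_updates(A_T=0.0)
    init = np.array([0.0, 1.0, 3.0, 0.0])  # all inhibitor modified
    res = integrate_to_steady_state(model, init, p0)
    assert res.converged
    assert res.state[model.state_vars.index("I")] == pytest.approx(4.0, abs=1e-6)
    assert res.state[model.state_vars.index("I_MM")] == pytest.approx(0.0, abs=1e-8)


class TestTqssaComplex:
    def test_no_inhibitor_means_no_complex(self):
        assert tqssa_complex(0.0, 2.0, 0.01) == 0.0

    def test_infinitely_weak_binding_means_no_complex(self):
        assert tqssa_complex(3.0, 1.0, 1e12) == pytest.approx(0.0, abs=1e-9)

    def test_negative_arguments_rejected(self):
        with pytest.raises(ValidationError):
            tqssa_complex(-1.0, 1.0, 0.01)

    def test_matches_bisection_oracle_in_tight_binding_regime(self):
        i_hat, a_t, k_m1 = 3.0, 1.0, 0.01
        c = tqssa_complex(i_hat, a_t, k_m1)
        quad = lambda x: x * x - (a_t + i_hat + k_m1) * x + a_t * i_hat
        assert abs(quad(c)) < 1e-12
        c_oracle = brentq(quad, 0.0, min(a_t, i_hat), xtol=1e-14)
        assert c == pytest.approx(c_oracle, abs=1e-12)

    @settings(derandomize=True, max_examples=200)
    @given(
        i_hat=st.floats(0, 50),
        a_t=st.floats(0, 50),
        k_m1=st.floats(1e-6, 1e3),
    )
    def test_admissible_root_bounds(self, i_hat, a_t, k_m1):
        c = tqssa_complex(i_hat, a_t, k_m1)
        assert -1e-12 <= c <= min(a_t, i_hat) + 1e-9


def test_tqssa_matches_simm_star_steady_states(simm_star):
    """The two-variable reduction reproduces the full simplified motif's
    steady states within 10% when binding is tight (K_m1 << A_T)."""
    from simmkit.steady_state import find_steady_states

    _, params = simm_star
    pset = params.with_updates(A_T=2.0, I_T=6.0)
    star = build_simm_star(pset)
    red = build_tqssa(pset)
    roots_star = find_steady_states(star, pset)
    roots_red = find_steady_states(red, pset)
    assert len(roots_star) == len(roots_red) == 3
    for rs, rr in zip(roots_star, roots_red):
        # compare on the shared coordinates (I_hat = I + C, I_MM)
        i_hat_star = rs.state[0] + rs.state[3]
        imm_star = rs.state[2]
        assert rr.state[0] == pytest.approx(i_hat_star, rel=0.10, abs=0.02)
        assert rr.state[1] == pytest.approx(imm_star, rel=0.10, abs=0.02)


def test_cln_model_without_cln_reduces_to_sic_clb():
    params = get_preset("cln_sic_clb").with_updates(ClnT=0.0, ClbT=0.7)
    full = build_cln_sic_clb(params)
    base = build_sic_clb(params)
    rng = np.random.default_rng(3)
    for _ in range(25):
        y3 = base.sample_state(rng, params)
        y4 = np.insert(y3, 2, 0.0)  # ClnSic = 0
        d4 = full.rhs(y4, params)
        d3 = base.rhs(y3, params)
        assert np.allclose(np.delete(d4, 2), d3, atol=1e-12)
        assert d4[2] == 0.0


def test_sic_clb_without_kinase_steady_state():
    """[ClbT] = 0: Sic1 balances synthesis against background turnover,
    [SicT] = k_s/k_d = 4 U, with no complex and no phosphoform."""
    params = get_preset("sic_clb").with_updates(ClbT=0.0)
    model = build_sic_clb(params)
    res = integrate_to_steady_state(model, np.zeros(3), params)
    assert res.converged
    assert res.state[0] == pytest.approx(4.0, rel=1e-6)
    assert res.state[1] == pytest.approx(0.0, abs=1e-9)
    assert res.state[2] == pytest.approx(0.0, abs=1e-9)


def test_mcc_apc_with_full_tension_and_no_mcc(mcc):
    """X_tens = 1 with no checkpoint complexes: nothing assembles, all APC is
    free, and securin settles at k_ssec/(k_dsec + k_dsec_apc*[APCT])."""
    model, params = mcc
    p1 = params.with_updates(X_tens=1.0)
    res = integrate_to_steady_state(model, np.array([0.0, 0.0, 0.0]), p1)
    assert res.converged
    mcct, mccu, securin = res.state
    assert mcct == pytest.approx(0.0, abs=1e-8)
    assert mccu == pytest.approx(0.0, abs=1e-8)
    expected = params["k_ssec"] / (
        params["k_dsec"] + params["k_dsec_apc"] * params["APC_T"]
    )
    assert securin == pytest.approx(expected, rel=1e-6)
    aux = model.eval_aux(res.state, p1)
    assert aux["APC"] == pytest.approx(params["APC_T"], abs=1e-8)


def test_tension_fraction_outside_unit_interval_rejected():
    params = get_preset("mcc_apc").with_updates(X_tens=1.5)
    with pytest.raises(ValidationError):
        build_mcc_apc(params)


def test_cycb_model_reduces_to_mcc_apc_when_centromere_activity_is_held():
    """With the CycB->centromere coupling cut (k_an = 0) and X_0A frozen at
    1 - X_tens, the cyclin-coupled model's (MCCT, MCCU) steady states match
    the TQSSA-closed MCC-APC model at the same activation rate."""
    from simmkit.steady_state import find_steady_states

    x_tens = 0.5
    pf = get_preset("cycb_mcc_apc").with_updates(
        X_tens=x_tens, k_an=0.0, k_a_NT=1.0
    )
    base = build_cycb_mcc_apc(pf)
    frozen = ModelDefinition(
        name="cycb_mcc_apc",
        state_vars=base.state_vars,
        param_symbols=base.param_symbols,
        aux=list(base.aux),
        odes={**base.odes, "X_0A": "0.0*X_0A"},
        param_bounds=base.param_bounds,
        init_default=base.init_default,
    )
    init = np.array([2.0, 0.0, 1.0, 0.5, 2.0, 1.0 - x_tens])
    res = integrate_to_steady_state(frozen, init, pf)
    assert res.converged

    pe = get_preset("mcc_apc").with_updates(X_tens=x_tens)
    ref = build_mcc_apc(pe)
    roots = find_steady_states(ref, pe)
    engaged = max(roots, key=lambda r: r.state[0])
    assert res.state[0] == pytest.approx(engaged.state[0], rel=0.02)
    assert res.state[1] == pytest.approx(engaged.state[1], rel=0.05, abs=1e-3)


@pytest.mark.parametrize("name", sorted(MODEL_BUILDERS))
def test_integration_preserves_nonnegativity(name):
    """Trajectories from admissible initial conditions never dip below
    -1e-8 U (solver tolerance)."""
    from scipy.integrate import solve_ivp

    params = get_preset(_PRESET_FOR.get(name, name))
    model = build_model(name, params)
    rng = np.random.default_rng(11)
    f = model.rhs_fn(params)
    for _ in range(5):
        y0 = model.sample_state(rng, params)
        sol = solve_ivp(
            lambda t, y: f(y), (0, 200.0), y0,
            method="LSODA", rtol=1e-9, atol=1e-11,
            t_eval=np.linspace(0, 200, 80),
        )
        assert sol.success
        assert sol.y.min() > -1e-8


def test_threshold_ratios_invariant_under_concentration_rescaling(simm):
    """Multiplying all concentrations and dividing all bimolecular constants
    by a common factor leaves dimensionless observables unchanged: the fold
    in I_T at fixed A_T scales exactly with the factor."""
    model, params = simm
    fold = find_threshold(
        model, params.with_updates(A_T=1.0), "I_T", "down", (1.5, 4.0)
    )
    s = 2.5
    scaled = params.with_updates(
        A_T=1.0 * s, k_as1=params["k_as1"] / s, k_as2=params["k_as2"] / s
    )
    model_s = build_simm(scaled)
    fold_s = find_threshold(
        model_s, scaled, "I_T", "down", (1.5 * s, 4.0 * s)
    )
    assert fold_s.value / s == pytest.approx(fold.value, rel=1e-3)
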