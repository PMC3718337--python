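import numpy as np
import pytest

from simmkit.bifurcation import hysteresis_protocol
from simmkit.models import ValidationError, build_mcc_apc
from simmkit.params import get_preset
from simmkit.scenarios import (
    EventSchedule,
    detect_transition,
    default_tension_ramp,
    g1s_cycle_scenario,
    mitotic_release_in_vitro,
    mitotic_release_in_vivo,
    simulate_schedule,
)
from simmkit.steady_state import integrate_to_steady_state


class TestEventSchedule:
    def test_event_times_must_increase(self):
        with pytest.raises(ValidationError):
            EventSchedule(events=[(5.0, "x", 1.0), (5.0, "x", 2.0)], horizon=10.0)

    def test_events_must_lie_inside_horizon(self):
        with pytest.raises(ValidationError):
            EventSchedule(events=[(12.0, "x", 1.0)], horizon=10.0)


def test_empty_schedule_from_stable_root_is_constant(simm_star):
    model, params = simm_star
    root = integrate_to_steady_state(model, model.init_default, params).state
    traj = simulate_schedule(
        model, params, EventSchedule(events=[], horizon=50.0), root
    )
    assert len(traj.times) >= 200
    assert np.max(np.abs(traj.states - root)) < 1e-7


def test_transient_signal_locks_switch_in_disengaged_state(simm):
    """Dropping the inhibitor total below the release threshold and then
    restoring it quasi-statically leaves the checkpoint disengaged: the
    transition is a one-way ratchet."""
    model, params = simm
    engaged = integrate_to_steady_state(model, model.init_default, params).state
    events = [(10.0, "I_T", 1.6)]
    for k, v in enumerate(np.linspace(1.6, 4.0, 11)[1:]):
        events.append((30.0 + 5.0 * k, "I_T", float(v)))
    sched = EventSchedule(events=events, horizon=130.0)
    traj = simulate_schedule(model, params, sched, engaged)
    assert model.classify(traj.final_state, params) == "disengaged"
    # the inhibitor total is restored exactly
    assert traj.final_state.sum() == pytest.approx(4.0, abs=1e-8)


def test_conservation_holds_piecewise_between_events(simm):
    """Within each schedule segment the inhibitor total is constant to 1e-8 U
    even though events move it between segments."""
    model, params = simm
    engaged = integrate_to_steady_state(model, model.init_default, params).state
    sched = EventSchedule(events=[(20.0, "I_T", 2.5), (40.0, "I_T", 4.0)], horizon=60.0)
    traj = simulate_schedule(model, params, sched, engaged)
    sums = traj.states.sum(axis=1)
    # segments are concatenated with a duplicated sample at each event time
    breaks = [0] + list(np.flatnonzero(np.diff(traj.times) == 0) + 1) + [len(sums)]
    assert len(breaks) == len(traj.segment_params) + 1
    for a, b in zip(breaks, breaks[1:]):
        seg = sums[a:b]
        assert seg.max() - seg.min() < 1e-8


class TestDetectTransition:
    def test_no_crossing_returns_none(self, simm_star):
        model, params = simm_star
        root = integrate_to_steady_state(model, model.init_default, params).state
        traj = simulate_schedule(
            model, params, EventSchedule(events=[], horizon=10.0), root
        )
        assert detect_transition(traj, "I_MM", ("rises_above", 99.0)) is None

    def test_step_crossing_located_within_one_sample(self, simm_star):
        model, params = simm_star
        root = integrate_to_steady_state(model, model.init_default, params).state
        traj = simulate_schedule(
            model, params, EventSchedule(events=[], horizon=10.0), root
        )
        # synthetic step observable: jumps at t = 4
        obs = lambda tr: (tr.times > 4.0).astype(float)
        t = detect_transition(traj, obs, ("rises_above", 0.5))
        dt = np.max(np.diff(traj.times))
        assert abs(t - 4.0) <= dt

    def test_rule_validated(self, simm_star):
        model, params = simm_star
        root = integrate_to_steady_state(model, model.init_default, params).state
        traj = simulate_schedule(
            model, params, EventSchedule(events=[], horizon=10.0), root
        )
        with pytest.raises(ValidationError):
            detect_transition(traj, "I_MM", ("wiggles", 1.0))


class TestG1SCycle:
    def test_cycle_disengages_then_reengages_after_division(self, g1s_result):
        """Cyclin accumulation flips the switch (Sic1 collapses, Clb-kinase
        activates); after division the cyclins decay and G1 is re-established
        with Sic1 re-accumulated."""
        r = g1s_result
        assert r.transition_time is not None
        assert 0 < r.transition_time < 50.0
        assert r.final_label == "engaged"
        sic_end = r.trajectory.column("SicT")[-1]
        assert sic_end > 2.0  # Sic1 re-accumulated toward k_s/k_d = 4

    def test_projected_path_crosses_upper_fold_locus_once_before_cln_off(
        self, g1s_result, cln_control_plane
    ):
        """The ([ClnT], [ClbT]) path generated by the cyclin program crosses
        the upper boundary of the bistable V exactly once before Cln
        synthesis shuts off."""
        cp = cln_control_plane
        tr = g1s_result.trajectory
        mask = tr.times <= 30.0
        xs = tr.column("ClnT")[mask]
        ys = tr.column("ClbT")[mask]
        finite = ~np.isnan(cp.upper)
        upper = np.interp(xs, cp.x_grid[finite], cp.upper[finite])
        above = ys > upper
        crossings = np.sum(np.diff(above.astype(int)) == 1)
        assert crossings == 1

    def test_quasistatic_disengagement_coincides_with_plane_crossing(
        self, g1s_result, cln_control_plane
    ):
        """Driven quasi-statically along the projected cyclin path, the
        occupied state's label flips within one vertex (1 T of path time) of
        the geometric crossing of the upper fold locus."""
        cp = cln_control_plane
        tr = g1s_result.trajectory
        finite = ~np.isnan(cp.upper)
        # geometric crossing time of the projected path
        ts = np.linspace(5.0, 29.0, 481)
        xs = np.interp(ts, tr.times, tr.column("ClnT"))
        ys = np.interp(ts, tr.times, tr.column("ClbT"))
        above = ys > np.interp(xs, cp.x_grid[finite], cp.upper[finite])
        t_cross = ts[np.flatnonzero(np.diff(above.astype(int)) == 1)[0]]

        params = get_preset("cln_sic_clb")
        from simmkit.models import build_cln_sic_clb

        model = build_cln_sic_clb(params)
        vertex_times = np.arange(np.floor(t_cross) - 4, np.ceil(t_cross) + 5)
        path = [
            {
                "ClnT": float(np.interp(t, tr.times, tr.column("ClnT"))),
                "ClbT": float(np.interp(t, tr.times, tr.column("ClbT"))),
            }
            for t in vertex_times
        ]
        records = hysteresis_protocol(model, params, path, dwell=400.0)
        labels = [r["label"] for r in records]
        assert labels[0] == "engaged" and labels[-1] == "disengaged"
        flip = next(i for i, lab in enumerate(labels) if lab != "engaged")
        t_flip = vertex_times[flip]
        assert abs(t_flip - t_cross) <= 1.0

    def test_zero_cyclin_synthesis_stays_engaged(self):
        r = g1s_cycle_scenario(
            get_preset("cln_sic_clb"), {"ks_cln": 0.0, "ks_clb": 0.0}
        )
        assert r.transition_time is None
        assert r.trajectory.column("SicT")[-1] == pytest.approx(4.0, rel=1e-3)

    def test_unknown_config_key_rejected(self):
        with pytest.raises(ValidationError):
            g1s_cycle_scenario(get_preset("cln_sic_clb"), {"bogus": 1.0})


class TestInVitroRelease:
    def test_lag_before_functional_mcc_reaches_apc_level(self, invitro_result):
        """Stepping X_tens to 1 releases the checkpoint only after a long lag
        (~45 T) while excess functional MCC is chewed down to the APC level."""
        r = invitro_result
        assert r.transition_time == pytest.approx(45.0, rel=0.20)
        assert r.final_label == "disengaged"

    def test_release_accelerates_after_the_lag(self, invitro_result):
        """Functional MCC decline is autocatalytic: its log-derivative grows
        in magnitude once free APC appears."""
        tr = invitro_result.trajectory
        fm = tr.column("MCCT") - tr.column("MCCU")
        lag = invitro_result.transition_time
        mask = (tr.times > 5.0) & (fm > 1e-6)
        t, lf = tr.times[mask], np.log(fm[mask])
        rate_early = -(np.gradient(lf, t)[t < 0.5 * lag]).mean()
        rate_late = -(np.gradient(lf, t)[(t > lag) & (t < 1.3 * lag)]).mean()
        assert rate_late > 3.0 * rate_early

    def test_deubiquitinase_prolongs_the_lag(self):
        """Without the de-ubiquitinase recycling MCCU back to functional MCC,
        release is strictly faster."""
        params = get_preset("mcc_apc")
        fast = mitotic_release_in_vitro(params.with_updates(k_du=0.0))
        slow = mitotic_release_in_vitro(params)
        assert fast.transition_time < slow.transition_time

    def test_lag_monotone_in_ubiquitination_rates(self):
        """Across a grid around the catalogue values the lag increases with
        de-ubiquitination k_du and decreases with poly-ubiquitination k_u."""
        params = get_preset("mcc_apc")
        lags_du = [
            mitotic_release_in_vitro(params.with_updates(k_du=v)).transition_time
            for v in (2.5, 5.0, 7.5, 10.0)
        ]
        assert all(a < b for a, b in zip(lags_du, lags_du[1:]))
        lags_u = [
            mitotic_release_in_vitro(params.with_updates(k_u=v)).transition_time
            for v in (5.0, 10.0, 15.0, 20.0)
        ]
        assert all(a > b for a, b in zip(lags_u, lags_u[1:]))


class TestInVivoRelease:
    def test_checkpoint_does_not_reengage_after_anaphase(self):
        """On the cyclin-B-coupled model the full tension ramp (up and back
        down) ends disengaged with cyclin B destroyed."""
        r = mitotic_release_in_vivo(get_preset("cycb_mcc_apc"))
        assert r.final_label == "disengaged"
        assert r.trajectory.column("CycB")[-1] < 0.05
        assert r.transition_time is not None

    def test_basic_mcc_model_reengages_on_the_same_ramp(self):
        """Without cyclin B coupling the checkpoint re-engages as tension
        falls below the lower fold (~0.89)."""
        params = get_preset("mcc_apc")
        model = build_mcc_apc(params)
        engaged = integrate_to_steady_state(model, model.init_default, params).state
        ramp = default_tension_ramp()
        traj = simulate_schedule(model, params, ramp, engaged)
        # released during the hold ...
        i_hold = np.argmin(np.abs(traj.times - 110.0))
        assert model.classify(traj.states[i_hold], traj.params_at(110.0)) == "disengaged"
        # ... but re-engaged once tension is gone
        assert model.classify(traj.final_state, traj.params_at(ramp.horizon)) == "engaged"

    def test_subthreshold_ramp_never_disengages(self):
        base = default_tension_ramp()
        low = EventSchedule(
            events=[(t, s, v * 0.85) for t, s, v in base.events],
            horizon=base.horizon,
        )
        r = mitotic_release_in_vivo(get_preset("cycb_mcc_apc"), tension_ramp=low)
        assert r.final_label == "engaged"
        assert r.transition_time is None

    def test_outcome_independent_of_ramp_speed(self):
        """Irreversibility is structural: 10x slower tension legs give the
        same final state."""
        fast = mitotic_release_in_vivo(
            get_preset("cycb_mcc_apc"),
            tension_ramp=default_tension_ramp(t_up=8.0, t_down=8.0),
        )
        slow = mitotic_release_in_vivo(
            get_preset("cycb_mcc_apc"),
            tension_ramp=default_tension_ramp(t_up=80.0, t_down=80.0),
        )
        assert fast.final_label == slow.final_label == "disengaged"
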