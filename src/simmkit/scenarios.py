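"""Checkpoint time-course scenarios.

Three canonical experiments are packaged here:

* :func:`g1s_cycle_scenario` - one budding-yeast cell cycle through Start,
  the G1/S transition and division, with cyclin totals as dynamical variables
  driven by a synthesis/degradation program.
* :func:`mitotic_release_in_vitro` - checkpoint release after all
  centromeres come under tension at once (``X_tens`` stepped 0 -> 1), with
  the characteristic lag while excess functional MCC is ubiquitinated.
* :func:`mitotic_release_in_vivo` - a tension ramp up (chromosome alignment)
  and back down (anaphase) on the cyclin-B-coupled model, demonstrating that
  the checkpoint does not re-engage when tension is lost in anaphase.

Time courses are driven by :class:`EventSchedule` objects: ordered
piecewise-constant parameter switches applied between stiff integration
segments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np
from scipy.integrate import solve_ivp

from .models import (
    ModelDefinition,
    ValidationError,
    build_cln_sic_clb,
    build_cycb_mcc_apc,
    build_mcc_apc,
)
from .params import ParameterSet
from .steady_state import integrate_to_steady_state

__all__ = [
    "EventSchedule",
    "Trajectory",
    "ScenarioResult",
    "simulate_schedule",
    "detect_transition",
    "g1s_cycle_scenario",
    "mitotic_release_in_vitro",
    "mitotic_release_in_vivo",
    "G1S_CYCLIN_DEFAULTS",
    "build_g1s_model",
]


@dataclass
class EventSchedule:
    """Ordered piecewise-constant parameter switches.

    ``events`` is a sequence of ``(time, symbol, new_value)``; times must be
    strictly increasing and lie inside ``(0, horizon)``.
    """

    events: list[tuple[float, str, float]]
    horizon: float

    def __post_init__(self) -> None:
        times = [t for t, _, _ in self.events]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValidationError("event times must be strictly increasing")
        if times and (times[0] <= 0 or times[-1] >= self.horizon):
            raise ValidationError("event times must lie inside (0, horizon)")
        if self.horizon <= 0:
            raise ValidationError("horizon must be positive")

    def segments(self, params: ParameterSet):
        """Yield (t_start, t_end, params) with all switches applied."""
        t_prev, cur = 0.0, params
        for t, sym, val in self.events:
            yield t_prev, t, cur
            cur = cur.with_updates(**{sym: val})
            t_prev = t
        yield t_prev, self.horizon, cur


@dataclass
class Trajectory:
    """Sampled time course with the parameter program that produced it."""

    times: np.ndarray
    states: np.ndarray  # (n_samples, n_state)
    state_names: list[str]
    events: list[tuple[float, str, float]] = field(default_factory=list)
    segment_params: list[tuple[float, float, ParameterSet]] = field(default_factory=list)
    model: ModelDefinition | None = None

    def column(self, name: str) -> np.ndarray:
        if name in self.state_names:
            return self.states[:, self.state_names.index(name)]
        if self.model is not None:
            vals = np.empty(len(self.times))
            for i, (t, y) in enumerate(zip(self.times, self.states)):
                vals[i] = self.model.eval_aux(y, self.params_at(t))[name]
            return vals
        raise KeyError(name)

    def params_at(self, t: float) -> ParameterSet:
        for t0, t1, p in self.segment_params:
            if t0 <= t <= t1:
                return p
        return self.segment_params[-1][2]

    @property
    def final_state(self) -> np.ndarray:
        return self.states[-1]

    def to_tsv(self) -> str:
        header = ["time"] + self.state_names
        lines = ["\t".join(header)]
        ev = {t for t, _, _ in self.events}
        for t, y in zip(self.times, self.states):
            row = [f"{t:.10g}"] + [f"{v:.10g}" for v in y]
            if any(abs(t - e) < 1e-9 for e in ev):
                row.append("# event")
            lines.append("\t".join(row))
        return "\n".join(lines) + "\n"


@dataclass
class ScenarioResult:
    trajectory: Trajectory
    transition_time: float | None
    final_label: str
    notes: dict = field(default_factory=dict)


def _rebase_totals(model, y, old_params, new_params):
    """Apply a jump in a conserved total to the state.

    Changing, say, the inhibitor total of a closed motif means physically
    adding or removing molecules; the difference is booked against the free
    pool (the variable the conservation law eliminates), clamped at zero.
    """
    y = np.asarray(y, dtype=float).copy()
    for law in model.conservations:
        delta = new_params[law.total_symbol] - old_params[law.total_symbol]
        if delta == 0.0:
            continue
        i = model.state_vars.index(law.eliminate)
        moved = y[i] + delta / law.coeffs[law.eliminate]
        if moved < 0.0:
            import warnings

            warnings.warn(
                f"total {law.total_symbol} drop exceeds the free pool of "
                f"{law.eliminate}; clamping at 0",
                RuntimeWarning,
                stacklevel=3,
            )
            moved = 0.0
        y[i] = moved
    return y


def simulate_schedule(
    model: ModelDefinition,
    params: ParameterSet,
    schedule: EventSchedule,
    init,
    n_samples: int = 400,
    rtol: float = 1e-9,
    atol: float = 1e-11,
) -> Trajectory:
    """Integrate the model through a piecewise-constant parameter program.

    The stiff integrator restarts at every event with updated parameters;
    the trajectory is sampled densely (at least 200 samples over the
    horizon, proportionally allocated to segments).
    """
    model.validate_params(params)
    y = np.asarray(init, dtype=float)
    if np.any(y < -1e-12):
        raise ValidationError("initial state must be nonnegative")
    n_samples = max(n_samples, 200)
    times_all, states_all, seg_params = [], [], []
    prev_pset = None
    for t0, t1, pset in schedule.segments(params):
        if prev_pset is not None:
            y = _rebase_totals(model, y, prev_pset, pset)
        prev_pset = pset
        if t1 <= t0:
            continue
        f = model.rhs_fn(pset)
        n_seg = max(int(round(n_samples * (t1 - t0) / schedule.horizon)), 5)
        t_eval = np.linspace(t0, t1, n_seg)
        sol = solve_ivp(
            lambda _t, _y: f(_y), (t0, t1), y,
            method="LSODA", t_eval=t_eval, rtol=rtol, atol=atol,
        )
        if not sol.success:
            raise RuntimeError(
                f"integration failed on segment [{t0}, {t1}]: {sol.message}"
            )
        times_all.append(sol.t)
        states_all.append(sol.y.T)
        seg_params.append((t0, t1, pset))
        y = sol.y[:, -1]
    return Trajectory(
        times=np.concatenate(times_all),
        states=np.vstack(states_all),
        state_names=list(model.state_vars),
        events=list(schedule.events),
        segment_params=seg_params,
        model=model,
    )


def detect_transition(
    traj: Trajectory,
    observable,
    threshold_rule: tuple[str, float],
) -> float | None:
    """First time the observable crosses the rule, by linear interpolation.

    ``observable`` is a column name (state or auxiliary) or a callable
    mapping the trajectory to an array; ``threshold_rule`` is
    ``("falls_below" | "rises_above", value)``.  Returns None if there is no
    crossing.
    """
    mode, thr = threshold_rule
    if mode not in ("falls_below", "rises_above"):
        raise ValidationError("rule must be 'falls_below' or 'rises_above'")
    vals = observable(traj) if callable(observable) else traj.column(observable)
    vals = np.asarray(vals, dtype=float)
    if mode == "falls_below":
        hit = vals < thr
    else:
        hit = vals > thr
    if hit[0]:
        return float(traj.times[0])
    idx = np.flatnonzero(hit)
    if len(idx) == 0:
        return None
    i = idx[0]
    t0, t1 = traj.times[i - 1], traj.times[i]
    v0, v1 = vals[i - 1], vals[i]
    if v1 == v0:
        return float(t1)
    return float(t0 + (thr - v0) * (t1 - t0) / (v1 - v0))


# ---------------------------------------------------------------------------
# G1/S cycle (yeast)
# ---------------------------------------------------------------------------

#: Cyclin synthesis/degradation program for one cell cycle.  The cyclin rates
#: are not constrained by the rate-constant table; these values are chosen so
#: the projected ([ClbT], [ClnT]) path traverses the control-plane V exactly
#: once on the way up (disengaging the switch) and re-enters the engaged
#: region only after division.  All overridable.
G1S_CYCLIN_DEFAULTS = {
    "ks_cln": 0.025,   # U/T, Cln synthesis from Start until t_cln_off
    "kd_cln": 0.15,    # 1/T, Cln degradation after t_cln_off
    "ks_clb": 0.035,   # U/T, Clb synthesis until division
    "kd_clb_low": 0.01,   # 1/T, basal Clb turnover before division
    "kd_clb_high": 0.15,  # 1/T, Clb degradation after division
    "t_cln_off": 30.0,    # T, S-phase shutoff of Cln synthesis
    "t_division": 50.0,   # T, division: Clb synthesis off, degradation up
    "horizon": 100.0,
}


def build_g1s_model(params: ParameterSet) -> ModelDefinition:
    """G1/S switch with the cyclin totals promoted to dynamical variables."""
    base = build_cln_sic_clb(
        params.with_updates(ClbT=params.values.get("ClbT", 0.0),
                            ClnT=params.values.get("ClnT", 0.0))
    )
    psyms = [s for s in base.param_symbols if s not in ("ClbT", "ClnT")]
    psyms += ["ks_cln", "kd_cln", "ks_clb", "kd_clb"]
    odes = dict(base.odes)
    odes["ClnT"] = "ks_cln - kd_cln*ClnT"
    odes["ClbT"] = "ks_clb - kd_clb*ClbT"
    return ModelDefinition(
        name="g1s_cycle",
        state_vars=base.state_vars + ["ClnT", "ClbT"],
        param_symbols=psyms,
        aux=list(base.aux),
        odes=odes,
        init_default=np.concatenate([base.init_default, [0.0, 0.0]]),
        description="G1/S switch with driven cyclin totals",
    )


def g1s_cycle_scenario(
    params: ParameterSet,
    cyclin_dynamics: dict | None = None,
) -> ScenarioResult:
    """One budding-yeast cycle: Start, G1/S transition, division, reset.

    Cln and Clb synthesis switch on at t = 0; at ``t_cln_off`` Cln synthesis
    stops and Cln degradation starts; at ``t_division`` Clb synthesis stops
    and Clb degradation speeds up.  The G1/S transition time is the first
    moment free Clb-kinase exceeds half of the Clb total (a declared
    convention).  The scenario reports failure (``transition_time is None``)
    rather than raising when the switch never flips.
    """
    cfg = dict(G1S_CYCLIN_DEFAULTS)
    if cyclin_dynamics:
        unknown = set(cyclin_dynamics) - set(cfg)
        if unknown:
            raise ValidationError(f"unknown cyclin config keys {sorted(unknown)}")
        cfg.update(cyclin_dynamics)
    model = build_g1s_model(params)
    run_params = params.with_updates(
        ks_cln=cfg["ks_cln"], kd_cln=0.0, ks_clb=cfg["ks_clb"],
        kd_clb=cfg["kd_clb_low"],
    )
    schedule = EventSchedule(
        events=[
            (cfg["t_cln_off"], "ks_cln", 0.0),
            (cfg["t_cln_off"] + 1e-9, "kd_cln", cfg["kd_cln"]),
            (cfg["t_division"], "ks_clb", 0.0),
            (cfg["t_division"] + 1e-9, "kd_clb", cfg["kd_clb_high"]),
        ],
        horizon=cfg["horizon"],
    )
    # start in G1: Sic1 at its synthesis/turnover balance, no cyclins
    init = model.init_default.copy()
    traj = simulate_schedule(model, run_params, schedule, init)

    def clb_activity(tr: Trajectory) -> np.ndarray:
        clb_total = tr.column("ClbT")
        free_clb = tr.column("Clb")
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(clb_total > 1e-9, free_clb / clb_total, 0.0)

    t_gs = detect_transition(traj, clb_activity, ("rises_above", 0.5))
    final_label = model.classify(traj.final_state, traj.params_at(cfg["horizon"]))
    return ScenarioResult(
        trajectory=traj,
        transition_time=t_gs,
        final_label=final_label,
        notes={"config": cfg},
    )


# ---------------------------------------------------------------------------
# mitotic checkpoint release
# ---------------------------------------------------------------------------

def functional_mcc(traj: Trajectory) -> np.ndarray:
    """Free plus APC-bound MCC (everything not yet poly-ubiquitinated)."""
    return traj.column("MCCT") - traj.column("MCCU")


def mitotic_release_in_vitro(
    params: ParameterSet,
    totals: dict | None = None,
    horizon: float = 200.0,
) -> ScenarioResult:
    """Checkpoint release when every centromere comes under tension at once.

    Starts from the engaged steady state at ``X_tens = 0`` and steps
    ``X_tens`` to 1 at t = 0.  The reported transition time is the lag until
    functional MCC first falls to the APC total - the moment free APC
    becomes available in quantity and release turns autocatalytic.
    """
    if totals:
        params = params.with_updates(**totals)
    p0 = params.with_updates(X_tens=0.0)
    model = build_mcc_apc(p0)
    engaged = integrate_to_steady_state(model, model.init_default, p0).state
    p1 = params.with_updates(X_tens=1.0)
    schedule = EventSchedule(events=[], horizon=horizon)
    traj = simulate_schedule(model, p1, schedule, engaged)
    lag = detect_transition(
        traj, functional_mcc, ("falls_below", params["APC_T"])
    )
    final_label = model.classify(traj.final_state, p1)
    return ScenarioResult(
        trajectory=traj,
        transition_time=lag,
        final_label=final_label,
        notes={"engaged_init": engaged},
    )


def default_tension_ramp(
    t_up: float = 40.0, t_hold: float = 80.0, t_down: float = 40.0,
    t_tail: float = 60.0, n_steps: int = 25,
) -> EventSchedule:
    """Staircase X_tens program: 0 -> 1 (alignment), hold, 1 -> 0 (anaphase).

    The hold at full tension outlasts the checkpoint's sluggish release lag
    (~47 T for the cyclin-B model), so metaphase completes before the
    tension signal collapses in anaphase.
    """
    events: list[tuple[float, str, float]] = []
    for k in range(1, n_steps + 1):
        events.append((t_up * k / n_steps, "X_tens", k / n_steps))
    t0 = t_up + t_hold
    for k in range(1, n_steps + 1):
        events.append((t0 + t_down * k / n_steps, "X_tens", 1.0 - k / n_steps))
    return EventSchedule(events=events, horizon=t0 + t_down + t_tail)


def mitotic_release_in_vivo(
    params: ParameterSet,
    totals: dict | None = None,
    tension_ramp: EventSchedule | None = None,
    securin_fraction: float = 0.25,
) -> ScenarioResult:
    """Anaphase on the cyclin-B-coupled model: release is irreversible.

    ``X_tens`` ramps 0 -> 1 as chromosomes align, then back to 0 as sister
    chromatids separate and tension is lost.  Because APC has degraded
    cyclin B by then, tensionless centromeres can no longer activate MCC
    assembly and the checkpoint stays disengaged.  The transition time is
    the moment securin falls below ``securin_fraction`` of its engaged level
    (anaphase onset, a declared convention; the default 0.25 sits safely
    above the disengaged securin floor, which is ~0.12 of the engaged level
    at the default totals, and the collapse is fast enough that the timing
    is insensitive to the exact fraction).
    """
    if totals:
        params = params.with_updates(**totals)
    ramp = tension_ramp or default_tension_ramp()
    p0 = params.with_updates(X_tens=0.0)
    model = build_cycb_mcc_apc(p0)
    engaged = integrate_to_steady_state(model, model.init_default, p0).state
    traj = simulate_schedule(model, p0, ramp, engaged)
    sec0 = engaged[model.state_vars.index("Securin")]
    t_ana = detect_transition(
        traj, "Securin", ("falls_below", securin_fraction * sec0)
    )
    final_label = model.classify(traj.final_state, traj.params_at(ramp.horizon))
    return ScenarioResult(
        trajectory=traj,
        transition_time=t_ana,
        final_label=final_label,
        notes={"engaged_init": engaged},
    )
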