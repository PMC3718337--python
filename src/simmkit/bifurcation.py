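"""Signal-response curves, control planes and hysteresis protocols.

Fold (saddle-node) points are located without pseudo-arclength continuation:
for these S-shaped one-dimensional response curves it is enough to bisect on
either the multistart root count (:func:`sweep_signal_response`) or on the
survival of a warm-started Newton branch (:func:`find_threshold`).  Both
locate the same folds; the second is much cheaper and is what the scan
modules use.

A two-parameter *control plane* is assembled column by column: at each value
of the x-parameter the bistable interval of the y-parameter is bracketed and
bisected, giving lower and upper fold loci that bound the V-shaped bistable
region.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root as _scipy_root

from .models import ModelDefinition, ValidationError
from .params import ParameterSet
from .steady_state import (
    RESIDUAL_TOL,
    SteadyStateResult,
    _reduced_rhs,
    _reduction,
    _admissible,
    _on_clamp_boundary,
    classify_stability,
    find_steady_states,
    integrate_to_steady_state,
)

__all__ = [
    "FOLD_RTOL",
    "FoldPoint",
    "Branch",
    "BifurcationDiagram",
    "ControlPlane",
    "sweep_signal_response",
    "find_threshold",
    "map_control_plane",
    "hysteresis_protocol",
]

#: relative parameter tolerance for fold localisation
FOLD_RTOL = 1e-4


@dataclass(frozen=True)
class FoldPoint:
    """A saddle-node: parameter value where a branch pair annihilates."""

    symbol: str
    value: float
    vanishing_branch: str  # engaged | disengaged | intermediate


@dataclass
class Branch:
    """A stability-homogeneous run of steady states along the sweep."""

    parameter_values: list[float] = field(default_factory=list)
    states: list[SteadyStateResult] = field(default_factory=list)
    stable: bool = True
    label: str = "intermediate"


@dataclass
class BifurcationDiagram:
    symbol: str
    sweep_range: tuple[float, float]
    branches: list[Branch]
    folds: list[FoldPoint]
    grid: list[float] = field(default_factory=list)
    root_counts: list[int] = field(default_factory=list)

    def to_tsv(self) -> str:
        lines = ["branch\t" + self.symbol + "\tactivity\tstable\tlabel"]
        for bi, br in enumerate(self.branches):
            for p, r in zip(br.parameter_values, br.states):
                lines.append(
                    f"{bi}\t{p:.10g}\t{r.activity:.10g}\t{int(r.stable)}\t{r.label}"
                )
        for f in self.folds:
            lines.append(f"fold\t{f.value:.10g}\t-\t-\t{f.vanishing_branch}")
        return "\n".join(lines) + "\n"


@dataclass
class ControlPlane:
    """Bistable-region boundaries in a two-parameter plane.

    For each x-grid value the y-interval ``(lower, upper)`` bounds the
    bistable region (either may be NaN when absent).  ``label_below`` /
    ``label_above`` record which monostable state lives on each side.
    """

    symbol_x: str
    symbol_y: str
    x_grid: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    label_below: str = "engaged"
    label_above: str = "disengaged"

    def classify(self, x: float, y: float) -> str:
        """monostable-engaged | bistable | monostable-disengaged at (x, y)."""
        lo = np.interp(x, self.x_grid, self.lower)
        hi = np.interp(x, self.x_grid, self.upper)
        if np.isnan(lo) or np.isnan(hi):
            # no bistable window in this column; sides meet at the cusp
            return f"monostable-{self.label_below}" if np.isnan(hi) else (
                f"monostable-{self.label_above}"
            )
        if y < lo:
            return f"monostable-{self.label_below}"
        if y > hi:
            return f"monostable-{self.label_above}"
        return "bistable"

    def to_tsv(self) -> str:
        lines = [f"{self.symbol_x}\tlower_{self.symbol_y}\tupper_{self.symbol_y}"]
        for x, lo, hi in zip(self.x_grid, self.lower, self.upper):
            lines.append(f"{x:.10g}\t{lo:.10g}\t{hi:.10g}")
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _count_roots(model, params, symbol, value, seed, n_starts, warm):
    res = find_steady_states(
        model,
        params.with_updates(**{symbol: float(value)}),
        n_starts=n_starts,
        seed=seed,
        extra_starts=warm,
    )
    return res


def _bisect_fold(model, params, symbol, lo, hi, n_lo, seed, n_starts, warm):
    """Bisect a root-count change between lo and hi to FOLD_RTOL."""
    scale = max(abs(lo), abs(hi), 1e-12)
    while (hi - lo) > FOLD_RTOL * scale:
        mid = 0.5 * (lo + hi)
        roots = _count_roots(model, params, symbol, mid, seed, n_starts, warm)
        if len(roots) == n_lo:
            lo = mid
        else:
            hi = mid
        warm = [r.state for r in roots] or warm
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def sweep_signal_response(
    model: ModelDefinition,
    params: ParameterSet,
    sweep_symbol: str,
    sweep_range: tuple[float, float],
    n_points: int = 40,
    n_starts: int = 32,
    seed: int = 0,
    _depth: int = 0,
) -> BifurcationDiagram:
    """One-parameter bifurcation diagram with fold points.

    Runs multistart root finding on a grid (warm-started from the previous
    grid value), assembles stability-homogeneous branches by state
    continuity, and bisects every root-count change to locate folds.  A
    root-count jump of more than 2 between adjacent grid values triggers one
    4x grid refinement of the offending interval; if the jump persists an
    error is raised.
    """
    if n_points < 10:
        raise ValidationError("n_points must be >= 10")
    lo, hi = map(float, sweep_range)
    if not lo < hi:
        raise ValidationError("sweep_range must be increasing")
    grid = list(np.linspace(lo, hi, n_points))
    per_point: list[list[SteadyStateResult]] = []
    warm: list[np.ndarray] = []
    for g in grid:
        roots = _count_roots(model, params, sweep_symbol, g, seed, n_starts, warm)
        per_point.append(roots)
        warm = [r.state for r in roots]

    # grid refinement on pathological count jumps
    counts = [len(r) for r in per_point]
    for i in range(len(grid) - 1):
        if abs(counts[i + 1] - counts[i]) > 2:
            if _depth >= 2:
                raise RuntimeError(
                    f"root count changes by more than 2 near "
                    f"{sweep_symbol} in [{grid[i]}, {grid[i+1]}] after refinement"
                )
            sub = sweep_signal_response(
                model, params, sweep_symbol, (grid[i], grid[i + 1]),
                n_points=10, n_starts=n_starts, seed=seed, _depth=_depth + 1,
            )
            # splice refined grid/roots in place of the bad interval
            grid = grid[: i + 1] + sub.grid[1:-1] + grid[i + 1:]
            per_point = (
                per_point[: i + 1] + sub._per_point[1:-1] + per_point[i + 1:]
            )
            counts = [len(r) for r in per_point]

    # fold localisation
    folds: list[FoldPoint] = []
    for i in range(len(grid) - 1):
        if counts[i] != counts[i + 1]:
            warm_i = [r.state for r in per_point[i] + per_point[i + 1]]
            v = _bisect_fold(
                model, params, sweep_symbol, grid[i], grid[i + 1],
                counts[i], seed, n_starts, warm_i,
            )
            # the vanishing pair: stable states present on the rich side only
            rich, poor = (
                (per_point[i], per_point[i + 1])
                if counts[i] > counts[i + 1]
                else (per_point[i + 1], per_point[i])
            )
            poor_act = [r.activity for r in poor]
            gone = [
                r
                for r in rich
                if r.stable
                and all(abs(r.activity - a) > 0.02 for a in poor_act)
            ]
            label = gone[0].label if gone else "intermediate"
            folds.append(FoldPoint(symbol=sweep_symbol, value=v, vanishing_branch=label))

    # branch assembly by nearest-state continuation
    branches: list[Branch] = []
    open_branches: list[Branch] = []
    for g, roots in zip(grid, per_point):
        taken = [False] * len(roots)
        still_open = []
        for br in open_branches:
            prev = br.states[-1].state
            best, best_d = None, np.inf
            for k, r in enumerate(roots):
                if taken[k] or r.stable != br.stable:
                    continue
                d = np.linalg.norm(r.state - prev) / (1.0 + np.linalg.norm(prev))
                if d < best_d:
                    best, best_d = k, d
            if best is not None and best_d < 0.5:
                br.parameter_values.append(g)
                br.states.append(roots[best])
                taken[best] = True
                still_open.append(br)
            else:
                branches.append(br)
        open_branches = still_open
        for k, r in enumerate(roots):
            if not taken[k]:
                nb = Branch(
                    parameter_values=[g], states=[r], stable=r.stable, label=r.label
                )
                open_branches.append(nb)
    branches.extend(open_branches)
    for br in branches:  # a branch keeps the label of its clearest member
        labels = [r.label for r in br.states if r.label != "intermediate"]
        if labels:
            br.label = max(set(labels), key=labels.count)

    diag = BifurcationDiagram(
        symbol=sweep_symbol,
        sweep_range=(lo, hi),
        branches=branches,
        folds=folds,
        grid=grid,
        root_counts=counts,
    )
    diag._per_point = per_point
    return diag


def find_threshold(
    model: ModelDefinition,
    params: ParameterSet,
    sweep_symbol: str,
    direction: str,
    sweep_range: tuple[float, float],
    start_state=None,
    n_steps: int = 60,
) -> FoldPoint | None:
    """Quasi-static continuation of the occupied stable branch to its fold.

    The branch is tracked by warm-started Newton steps with secant
    extrapolation; a step is rejected when Newton fails, leaves the
    admissible region, loses stability, or lands far from the extrapolated
    branch (a jump to the other attractor).  Rejection halves the step;
    the fold is the bracketed parameter at relative tolerance 1e-4.
    Returns None when the branch survives the whole range.
    """
    lo, hi = map(float, sweep_range)
    if direction not in ("up", "down"):
        raise ValidationError("direction must be 'up' or 'down'")
    p0 = lo if direction == "up" else hi
    p_end = hi if direction == "up" else lo
    sgn = 1.0 if direction == "up" else -1.0
    pset0 = params.with_updates(**{sweep_symbol: p0})
    if start_state is None:
        # re-impose conservation totals on the default init (the swept symbol
        # may be a conserved total, e.g. I_T)
        _, expand0, project0 = _reduction(model, pset0)
        init0 = np.maximum(expand0(project0(model.init_default)), 0.0)
        start_state = integrate_to_steady_state(model, init0, pset0).state
    res0 = classify_stability(model, _polish(model, start_state, pset0), pset0)
    if not (res0.stable or res0.degenerate):
        # boundary attractors foil finite-difference spectra; fall back to the
        # integration oracle: a perturbed start must relax back to the root
        probe = np.maximum(res0.state + 1e-3, 0.0)
        back = integrate_to_steady_state(model, probe, pset0).state
        if np.linalg.norm(back - res0.state) > 1e-4 * (1 + np.linalg.norm(res0.state)):
            raise ValidationError("start state is not on a stable branch")
    label = model.classify(res0.state, pset0)

    scale = max(abs(lo), abs(hi), 1e-12)
    step = (hi - lo) / n_steps
    p_prev, y_prev = p0, res0.state
    p_before, y_before = p0, res0.state  # one step back, for secant slope
    while sgn * (p_end - p_prev) > 0:
        h = min(step, abs(p_end - p_prev))
        p_try = p_prev + sgn * h
        # secant extrapolation of the branch
        if p_prev != p_before:
            y_guess = y_prev + (y_prev - y_before) * (p_try - p_prev) / (
                p_prev - p_before
            )
        else:
            y_guess = y_prev
        y_new = _branch_step(model, params, sweep_symbol, p_try, y_guess, y_prev)
        if y_new is not None:
            p_before, y_before = p_prev, y_prev
            p_prev, y_prev = p_try, y_new
            step = min(step * 1.5, (hi - lo) / n_steps)
            continue
        if h <= FOLD_RTOL * scale:
            return FoldPoint(
                symbol=sweep_symbol,
                value=p_prev + sgn * 0.5 * h,
                vanishing_branch=label,
            )
        step = h / 2.0
    return None


def _polish(model, y, params):
    rhs_r, expand = _reduced_rhs(model, params)
    _, _, project = _reduction(model, params)
    sol = _scipy_root(rhs_r, project(np.asarray(y, dtype=float)), method="hybr", tol=1e-12)
    return expand(sol.x) if sol.success else np.asarray(y, dtype=float)


def _branch_step(model, params, symbol, value, y_guess, y_prev):
    """One continuation step; None when the branch is lost."""
    pset = params.with_updates(**{symbol: float(value)})
    rhs_r, expand = _reduced_rhs(model, pset)
    _, _, project = _reduction(model, pset)
    y = None
    guess = project(np.asarray(y_guess, dtype=float))
    for attempt in (0, 1):
        sol = _scipy_root(rhs_r, guess, method="hybr", tol=1e-12)
        if sol.success:
            cand = expand(sol.x)
            if float(np.max(np.abs(model.rhs(cand, pset)))) <= RESIDUAL_TOL:
                y = cand
                break
        if attempt == 0:
            # walk into the root's basin: short relaxation of the full ODEs
            f = model.rhs_fn(pset)
            relax = solve_ivp(
                lambda _t, _y: f(_y), (0.0, 50.0),
                np.maximum(np.asarray(y_guess, dtype=float), 0.0),
                method="LSODA", rtol=1e-10, atol=1e-12,
            )
            if not relax.success:
                return None
            guess = project(relax.y[:, -1])
    if y is None:
        return None
    if not _admissible(model, y, pset) or _on_clamp_boundary(model, y, pset):
        return None
    # at a fold the tracked branch annihilates with its unstable partner, so
    # a warm-started Newton step can only fail or jump to the far attractor;
    # a large state jump therefore marks the branch as lost
    jump = np.linalg.norm(y - y_prev) / (1.0 + np.linalg.norm(y_prev))
    if jump > 0.35:
        return None
    return y


def map_control_plane(
    model: ModelDefinition,
    params: ParameterSet,
    symbol_x: str,
    symbol_y: str,
    ranges: tuple[tuple[float, float], tuple[float, float]],
    n_grid: int = 20,
    n_starts: int = 24,
    seed: int = 0,
) -> ControlPlane:
    """Two-parameter bistable-region map (lower/upper fold loci).

    For each x-grid value a root-count scan over the y-range brackets the
    bistable interval; both edges are bisected to FOLD_RTOL.  Columns with no
    bistable window get NaN loci.
    """
    (x_lo, x_hi), (y_lo, y_hi) = ranges
    if n_grid < 20:
        raise ValidationError("n_grid must be >= 20")
    if min(x_lo, x_hi, y_lo, y_hi) < 0:
        raise ValidationError("ranges must be nonnegative")
    xs = np.linspace(x_lo, x_hi, n_grid)
    ys = np.linspace(y_lo, y_hi, n_grid)
    lower = np.full(n_grid, np.nan)
    upper = np.full(n_grid, np.nan)
    label_below = label_above = None
    for i, x in enumerate(xs):
        base = params.with_updates(**{symbol_x: float(x)})
        warm: list[np.ndarray] = []
        col: list[list[SteadyStateResult]] = []
        for y in ys:
            roots = _count_roots(model, base, symbol_y, y, seed, n_starts, warm)
            col.append(roots)
            warm = [r.state for r in roots]
        counts = [len(r) for r in col]
        bi = [j for j, c in enumerate(counts) if c >= 3]
        if not bi:
            continue
        j_lo, j_hi = bi[0], bi[-1]
        if j_lo > 0:
            lower[i] = _bisect_fold(
                model, base, symbol_y, ys[j_lo - 1], ys[j_lo],
                counts[j_lo - 1], seed, n_starts,
                [r.state for r in col[j_lo - 1] + col[j_lo]],
            )
        else:
            lower[i] = ys[0]
        if j_hi < n_grid - 1:
            upper[i] = _bisect_fold(
                model, base, symbol_y, ys[j_hi], ys[j_hi + 1],
                counts[j_hi], seed, n_starts,
                [r.state for r in col[j_hi] + col[j_hi + 1]],
            )
        else:
            upper[i] = ys[-1]
        if label_below is None:
            below = col[max(j_lo - 1, 0)]
            above = col[min(j_hi + 1, n_grid - 1)]
            stab_b = [r for r in below if r.stable]
            stab_a = [r for r in above if r.stable]
            if len(stab_b) == 1 and len(stab_a) == 1:
                label_below = stab_b[0].label
                label_above = stab_a[0].label
    return ControlPlane(
        symbol_x=symbol_x,
        symbol_y=symbol_y,
        x_grid=xs,
        lower=lower,
        upper=upper,
        label_below=label_below or "engaged",
        label_above=label_above or "disengaged",
    )


def hysteresis_protocol(
    model: ModelDefinition,
    params: ParameterSet,
    path: Sequence[dict],
    dwell: float = 200.0,
    init=None,
    settle_tol: float = 1e-6,
) -> list[dict]:
    """Drag the system quasi-statically along a parameter polyline.

    ``path`` is a list of vertices, each a dict of parameter overrides.  The
    full ODEs are integrated while parameters move piecewise-linearly between
    consecutive vertices over ``dwell`` time units each.  The occupied
    state's label (and a settled flag: RHS residual below ``settle_tol``)
    is reported at every vertex.
    """
    if not path:
        raise ValidationError("path must contain at least one vertex")
    pset0 = params.with_updates(**path[0])
    if init is None:
        _, expand0, project0 = _reduction(model, pset0)
        init0 = np.maximum(expand0(project0(model.init_default)), 0.0)
        init = integrate_to_steady_state(model, init0, pset0).state
    y = np.asarray(init, dtype=float)

    records = []

    def record(vertex, pset, y):
        res = float(np.max(np.abs(model.rhs(y, pset))))
        if res > settle_tol:
            warnings.warn(
                f"state not settled at vertex {vertex} (residual {res:.2e}); "
                "dwell may be too short",
                RuntimeWarning,
                stacklevel=3,
            )
        records.append(
            {
                "vertex": dict(vertex),
                "label": model.classify(y, pset),
                "activity": model.activity(y, pset),
                "settled": res <= settle_tol,
                "state": y.copy(),
            }
        )

    # settle at the first vertex
    y = integrate_to_steady_state(model, y, pset0, t_max=dwell * 10).state
    record(path[0], pset0, y)

    for a, b in zip(path[:-1], path[1:]):
        pa = params.with_updates(**a)
        pb = params.with_updates(**b)
        va = model.pvec(pa)
        vb = model.pvec(pb)

        raw = model._rhs
        # moving a conserved total adds/removes molecules through the free
        # pool (the conservation law's eliminated variable)
        sources = []
        for law in model.conservations:
            i_sym = model.param_symbols.index(law.total_symbol)
            rate = (vb[i_sym] - va[i_sym]) / dwell
            if rate != 0.0:
                sources.append(
                    (model.state_vars.index(law.eliminate),
                     rate / law.coeffs[law.eliminate])
                )

        def rhs_t(t, yy, va=va, vb=vb, sources=sources):
            pv = va + (vb - va) * min(max(t / dwell, 0.0), 1.0)
            dy = np.asarray(raw(yy, pv))
            for i, rate in sources:
                dy[i] += rate
            return dy

        sol = solve_ivp(
            rhs_t, (0.0, dwell), y, method="LSODA", rtol=1e-9, atol=1e-11
        )
        if not sol.success:
            raise RuntimeError(f"integration failed between {a} and {b}")
        y = sol.y[:, -1]
        # let the state settle at the vertex before labelling
        y = integrate_to_steady_state(model, y, pb, t_max=dwell * 10).state
        record(b, pb, y)
    return records
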