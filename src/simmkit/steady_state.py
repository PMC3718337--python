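"""Steady states of a checkpoint model and their stability.

Steady states are found by multistart damped Newton iteration (scipy's hybrid
Powell solver) from Latin-hypercube-seeded admissible states.  Models whose
state space contains a conserved linear combination (the SIMM and SIMM*
inhibitor totals) are solved on the reduced system obtained by eliminating one
variable through the conservation identity - the same substitution the printed
equations use for the enzyme totals - which keeps the Jacobian nonsingular.

Stability is decided from the eigenvalue spectrum of a central-finite-
difference Jacobian of the reduced system: stable iff every real part is below
``-STABILITY_MARGIN``; roots with a real part inside the margin band are
flagged degenerate rather than silently classified.
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

__all__ = [
    "STABILITY_MARGIN",
    "DEDUP_RTOL",
    "RESIDUAL_TOL",
    "SteadyStateResult",
    "find_steady_states",
    "classify_stability",
    "integrate_to_steady_state",
    "IntegrationResult",
    "results_to_tsv",
]

#: eigenvalue real-part margin (T^-1) separating stable / degenerate / unstable
STABILITY_MARGIN = 1e-6
#: relative tolerance used to deduplicate roots
DEDUP_RTOL = 1e-6
#: max-norm residual (U/T) below which a state counts as a root
RESIDUAL_TOL = 1e-9


@dataclass
class SteadyStateResult:
    """One root of the right-hand side with stability and checkpoint label."""

    state: np.ndarray
    residual: float
    eigenvalues: np.ndarray
    stable: bool
    degenerate: bool
    label: str
    activity: float
    state_names: list[str] = field(default_factory=list)

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.state_names, map(float, self.state)))


@dataclass
class IntegrationResult:
    """Terminal state of a relaxation integration."""

    state: np.ndarray
    t_end: float
    residual: float
    converged: bool


# ---------------------------------------------------------------------------
# reduced-system plumbing
# ---------------------------------------------------------------------------

def _reduction(model: ModelDefinition, params: ParameterSet):
    """Return (reduced_indices, expand, project) for conserved-direction
    elimination; identity maps when the model declares no conservation law."""
    n = len(model.state_vars)
    if not model.conservations:
        idx = list(range(n))
        return idx, (lambda yr: np.asarray(yr, dtype=float)), (lambda y: np.asarray(y, dtype=float))
    if len(model.conservations) > 1:
        raise NotImplementedError("at most one state-space conservation law")
    law = model.conservations[0]
    elim = model.state_vars.index(law.eliminate)
    coeff = dict(law.coeffs)
    total = params[law.total_symbol]
    keep = [i for i in range(n) if i != elim]

    def expand(yr):
        y = np.empty(n)
        y[keep] = yr
        acc = total
        for v, c in coeff.items():
            i = model.state_vars.index(v)
            if i != elim:
                acc -= c * y[i]
        y[elim] = acc / coeff[law.eliminate]
        return y

    def project(y):
        return np.asarray(y, dtype=float)[keep]

    return keep, expand, project


def _reduced_rhs(model: ModelDefinition, params: ParameterSet):
    keep, expand, _ = _reduction(model, params)
    f = model.rhs_fn(params)
    return lambda yr: f(expand(yr))[keep], expand


def _jacobian(fun, y: np.ndarray, scale: float) -> np.ndarray:
    """Central finite-difference Jacobian, step scaled to state magnitude.

    Falls back to a forward difference in coordinates where a central step
    would leave the nonnegative orthant (boundary steady states), so that the
    clamped region never contaminates the spectrum.
    """
    n = len(y)
    jac = np.empty((n, n))
    f0 = None
    for j in range(n):
        h = 1e-6 * max(abs(y[j]), scale, 1e-8)
        yp = y.copy(); yp[j] += h
        ym = y.copy(); ym[j] -= h
        if ym[j] >= 0.0:
            jac[:, j] = (np.asarray(fun(yp)) - np.asarray(fun(ym))) / (2 * h)
        else:
            if f0 is None:
                f0 = np.asarray(fun(y))
            jac[:, j] = (np.asarray(fun(yp)) - f0) / h
    return jac


def _admissible(model: ModelDefinition, y: np.ndarray, params: ParameterSet) -> bool:
    tol = 1e-8 * (1.0 + float(np.max(np.abs(y))))
    if np.any(y < -tol):
        return False
    aux = model.eval_aux(y, params)
    # derived free species must be (numerically) nonnegative: the aux layer
    # clamps them, so reject roots that sit on a clamped boundary
    for name, _ in model.aux:
        if name == model.activity_aux:
            continue
        if aux[name] < -tol:
            return False
    return True


def _on_clamp_boundary(model: ModelDefinition, y, params) -> bool:
    """True when a clamped derived species is exactly at its floor, which can
    create spurious Newton roots outside the admissible region."""
    raw = dict(zip(model.state_vars, y))
    raw.update(params.as_dict())
    # recompute the un-clamped combinations that the standard models use
    checks = {
        "simm": lambda: raw["A_T"] - raw["C"] - raw["C_M"],
        "simm_star": lambda: raw["A_T"] - raw["C"],
        "sic_clb": lambda: min(raw["SicT"] - raw["ClbSic"] - raw["SicP"],
                               raw["ClbT"] - raw["ClbSic"]),
        "cln_sic_clb": lambda: min(
            raw["SicT"] - raw["ClbSic"] - raw["ClnSic"] - raw["SicP"],
            raw["ClbT"] - raw["ClbSic"], raw["ClnT"] - raw["ClnSic"]),
        "mcc_apc": lambda: min(raw["MCCT"] - raw["MCCU"],
                               raw["Mad2_T"] - raw["MCCT"]),
        "cycb_mcc_apc": lambda: min(
            raw["MCCT"] - raw["APCMCC"] - raw["MCCU"],
            raw["APC_T"] - raw["APCMCC"], raw["Mad2_T"] - raw["MCCT"]),
    }
    fn = checks.get(model.name)
    if fn is None:
        return False
    return fn() < -1e-6 * (1.0 + float(np.max(np.abs(y))))


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def find_steady_states(
    model: ModelDefinition,
    params: ParameterSet,
    n_starts: int = 64,
    seed: int = 0,
    extra_starts: Sequence[np.ndarray] = (),
) -> list[SteadyStateResult]:
    """All steady states reachable by multistart Newton, sorted by activity.

    Deterministic for a given ``seed``.  Start points mix Latin-hypercube
    samples of the admissible box (via the model's sampler) with any
    ``extra_starts`` (warm starts from a neighbouring parameter value).
    Returns an empty list when no start converges.
    """
    if n_starts < 1:
        raise ValidationError("n_starts must be >= 1")
    model.validate_params(params)
    rhs_r, expand = _reduced_rhs(model, params)
    _, _, project = _reduction(model, params)
    rng = np.random.default_rng(seed)
    starts = [project(model.sample_state(rng, params)) for _ in range(n_starts)]
    starts.extend(project(np.asarray(s, dtype=float)) for s in extra_starts)
    starts.append(project(model.init_default))

    roots: list[np.ndarray] = []
    for y0 in starts:
        sol = _scipy_root(rhs_r, y0, method="hybr", tol=1e-12)
        if not sol.success:
            continue
        y = expand(sol.x)
        res = float(np.max(np.abs(model.rhs(y, params))))
        if res > RESIDUAL_TOL:
            continue
        if not _admissible(model, y, params) or _on_clamp_boundary(model, y, params):
            continue
        if any(
            np.linalg.norm(y - q) <= DEDUP_RTOL * (1.0 + np.linalg.norm(q))
            for q in roots
        ):
            continue
        roots.append(y)

    results = [classify_stability(model, y, params) for y in roots]
    results.sort(key=lambda r: r.activity)
    return results


def classify_stability(
    model: ModelDefinition, state, params: ParameterSet
) -> SteadyStateResult:
    """Stability of a root from the reduced-system Jacobian spectrum.

    Raises :class:`ValidationError` when the input is not a root (residual
    above :data:`RESIDUAL_TOL`).  Unstable and degenerate roots are labelled
    ``intermediate``; stable roots get the model's engaged/disengaged label.
    """
    y = np.asarray(state, dtype=float)
    residual = float(np.max(np.abs(model.rhs(y, params))))
    if residual > RESIDUAL_TOL:
        raise ValidationError(
            f"state is not a steady state (residual {residual:.3e})"
        )
    rhs_r, expand = _reduced_rhs(model, params)
    _, _, project = _reduction(model, params)
    yr = project(y)
    scale = max(float(np.max(np.abs(y))), 1e-6)
    jac = _jacobian(rhs_r, yr, scale=1e-3 * scale)
    eig = np.linalg.eigvals(jac)
    max_re = float(np.max(eig.real))
    degenerate = abs(max_re) <= STABILITY_MARGIN
    stable = max_re < -STABILITY_MARGIN
    label = model.classify(y, params) if stable else "intermediate"
    return SteadyStateResult(
        state=y,
        residual=residual,
        eigenvalues=eig,
        stable=stable,
        degenerate=degenerate,
        label=label,
        activity=model.activity(y, params),
        state_names=list(model.state_vars),
    )


def integrate_to_steady_state(
    model: ModelDefinition,
    init,
    params: ParameterSet,
    t_max: float = 5000.0,
    tol: float = 1e-10,
) -> IntegrationResult:
    """Relax the full ODEs from ``init`` until ``||RHS||_inf < tol``.

    This is the brute-force oracle for :func:`find_steady_states`: stiff
    integration (LSODA) in geometrically growing time chunks.  If ``t_max``
    is reached first the result carries ``converged=False`` and the last
    state (with a warning).
    """
    model.validate_params(params)
    y = np.asarray(init, dtype=float)
    if np.any(y < -1e-12):
        raise ValidationError("initial state must be nonnegative")
    f = model.rhs_fn(params)
    if float(np.max(np.abs(f(y)))) < tol:
        return IntegrationResult(state=y, t_end=0.0, residual=0.0, converged=True)
    t, chunk = 0.0, 50.0
    while t < t_max:
        t_next = min(t + chunk, t_max)
        sol = solve_ivp(
            lambda _t, _y: f(_y), (t, t_next), y,
            method="LSODA", rtol=1e-10, atol=1e-12,
        )
        if not sol.success:
            raise RuntimeError(f"integration failed on [{t}, {t_next}]: {sol.message}")
        y = sol.y[:, -1]
        t = t_next
        res = float(np.max(np.abs(f(y))))
        if res < tol:
            return IntegrationResult(state=y, t_end=t, residual=res, converged=True)
        chunk *= 2.0
    res = float(np.max(np.abs(f(y))))
    warnings.warn(
        f"integrate_to_steady_state hit t_max={t_max} with residual {res:.2e}",
        RuntimeWarning,
        stacklevel=2,
    )
    return IntegrationResult(state=y, t_end=t, residual=res, converged=False)


def results_to_tsv(results: Sequence[SteadyStateResult]) -> str:
    """One row per root: state values, eigenvalue real parts, flags, label."""
    if not results:
        return ""
    names = results[0].state_names
    header = names + ["residual", "max_re_eig", "stable", "degenerate", "label"]
    lines = ["\t".join(header)]
    for r in results:
        row = [f"{v:.10g}" for v in r.state]
        row += [
            f"{r.residual:.3e}",
            f"{float(np.max(r.eigenvalues.real)):.6g}",
            str(int(r.stable)),
            str(int(r.degenerate)),
            r.label,
        ]
        lines.append("\t".join(row))
    return "\n".join(lines) + "\n"
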