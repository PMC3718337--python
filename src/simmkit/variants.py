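"""Robustness analyses: partial processivity and parameter scans.

* :func:`processive_fraction_model` - a SIMM variant in which a fraction
  ``p`` of first-modification catalysis proceeds processively (the enzyme
  completes both modifications in one binding event, releasing IMM directly)
  while ``1 - p`` is distributive (releases IM).  ``p = 0`` reduces exactly
  to the plain SIMM motif; bistability survives moderate processivity but is
  lost as ``p`` approaches 1.
* :func:`scan_disengage_threshold` - how the checkpoint disengagement
  threshold of the MCC-APC switch moves under fold-change perturbations of
  single rate constants.
* :func:`sensitivity_irreversibility_region` - which fold-change
  perturbations of the cyclin-B-coupled model preserve both checkpoint
  *sensitivity* (disengagement only very near full tension) and
  *irreversibility* (no re-engagement fold on the way back down).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .models import (
    Conservation,
    ModelDefinition,
    ValidationError,
    _SIMM_SYMBOLS,
    _SAMPLERS,
    build_cycb_mcc_apc,
    build_mcc_apc,
)
from .params import ParameterSet
from .bifurcation import find_threshold
from .steady_state import integrate_to_steady_state

__all__ = [
    "ScanResult",
    "processive_fraction_model",
    "scan_disengage_threshold",
    "sensitivity_irreversibility_region",
    "MCC_CORE_RATE_SYMBOLS",
    "CYCB_CORE_RATE_SYMBOLS",
]

#: rate constants entering the MCC-APC switch equations (securin excluded:
#: it is a downstream indicator and cannot move the threshold)
MCC_CORE_RATE_SYMBOLS = ["K_m", "k_u", "k_du", "k_cat", "k_a_NT"]

#: rate constants of the cyclin-B-coupled switch (again without securin)
CYCB_CORE_RATE_SYMBOLS = [
    "k_u", "k_du", "k_cat", "k_a_NT",
    "k_scyc", "k_dcyc", "k_dcyc_apc", "k_an", "k_in_CAPP", "k_as", "k_di",
]


@dataclass
class ScanResult:
    """Per-grid-point derived quantities for a one-at-a-time parameter scan."""

    symbols: list[str]
    #: map symbol -> grid of parameter values scanned
    grids: dict[str, np.ndarray]
    #: map symbol -> derived quantity per grid point (NaN = not found)
    values: dict[str, np.ndarray]
    #: map symbol -> per-point annotation ('' | 'monostable' | 'failed')
    notes: dict[str, list[str]] = field(default_factory=dict)
    summary: dict = field(default_factory=dict)

    def to_tsv(self) -> str:
        lines = ["symbol\tparameter_value\tvalue\tnote"]
        for s in self.symbols:
            for g, v, n in zip(self.grids[s], self.values[s], self.notes[s]):
                lines.append(f"{s}\t{g:.10g}\t{v:.10g}\t{n}")
        return "\n".join(lines) + "\n"


def processive_fraction_model(params: ParameterSet, p: float) -> ModelDefinition:
    """SIMM variant with a fraction ``p`` of processive dual modification.

    The catalytic step of the tight A:I complex branches: with probability
    ``1 - p`` it releases IM (distributive route, as in the plain motif) and
    with probability ``p`` it carries straight through to IMM without
    releasing the intermediate.
    """
    if not 0.0 <= p <= 1.0:
        raise ValidationError(f"processive fraction must be in [0, 1], got {p}")
    for s in _SIMM_SYMBOLS:
        params[s]
    # the branching fraction is frozen into the rate laws, so the variant is
    # parameterised by exactly the plain-motif symbols
    model = ModelDefinition(
        name="simm_processive",
        state_vars=["I", "I_M", "I_MM", "C", "C_M"],
        param_symbols=list(_SIMM_SYMBOLS),
        aux=[
            ("A", "max(A_T - C - C_M, 0.0)"),
            ("activity", "A / max(A_T, 1e-12)"),
        ],
        odes={
            "I": "-k_as1*A*I + k_di1*C + k_dm1*I_M",
            "I_M": f"(1 - {p!r})*k_cat1*C - k_as2*A*I_M + k_di2*C_M"
                   " - k_dm1*I_M + k_dm2*I_MM",
            "I_MM": f"{p!r}*k_cat1*C + k_cat2*C_M - k_dm2*I_MM",
            "C": "k_as1*A*I - (k_di1 + k_cat1)*C",
            "C_M": "k_as2*A*I_M - (k_di2 + k_cat2)*C_M",
        },
        conservations=[
            Conservation(
                coeffs={"I": 1, "I_M": 1, "I_MM": 1, "C": 1, "C_M": 1},
                total_symbol="I_T",
                eliminate="I",
            )
        ],
        init_default=np.array([params["I_T"], 0, 0, 0, 0], dtype=float),
        description=f"SIMM with processive fraction p={p}",
    )
    _SAMPLERS.setdefault("simm_processive", _SAMPLERS["simm"])
    return model


def _log_grid(value: float, fold_range: float, n_grid: int) -> np.ndarray:
    if fold_range < 1.0:
        raise ValidationError("fold_range must be >= 1")
    if n_grid == 1:
        return np.array([value])
    return value * np.logspace(-1, 1, n_grid, base=fold_range)


def scan_disengage_threshold(
    params: ParameterSet,
    symbols: list[str] | None = None,
    fold_range: float = 2.0,
    n_grid: int = 5,
) -> ScanResult:
    """Disengagement threshold of the MCC-APC switch under one-at-a-time
    fold-change perturbations.

    For each symbol, each grid value in ``[value/fold_range,
    value*fold_range]`` (log-spaced) replaces the baseline and the
    tension threshold at which the engaged branch disappears is recomputed
    by branch continuation.  Points where the engaged branch never folds in
    ``X_tens`` within [0, 1] are marked 'monostable'.
    """
    symbols = list(symbols or MCC_CORE_RATE_SYMBOLS)
    base = params.with_updates(X_tens=0.0)
    build_mcc_apc(base)  # validate symbol presence up front
    grids, values, notes = {}, {}, {}
    for s in symbols:
        grid = _log_grid(params[s], fold_range, n_grid)
        vals = np.full(len(grid), np.nan)
        note = [""] * len(grid)
        for i, g in enumerate(grid):
            pset = base.with_updates(**{s: float(g)})
            model = build_mcc_apc(pset)
            try:
                fold = find_threshold(model, pset, "X_tens", "up", (0.0, 1.0))
            except Exception:
                note[i] = "failed"
                continue
            if fold is None:
                note[i] = "monostable"
            else:
                vals[i] = fold.value
        grids[s], values[s], notes[s] = grid, vals, note
    finite = np.concatenate([v[np.isfinite(v)] for v in values.values()])
    summary = {
        "min": float(np.min(finite)) if len(finite) else float("nan"),
        "max": float(np.max(finite)) if len(finite) else float("nan"),
        "n_monostable": sum(n.count("monostable") for n in notes.values()),
        "n_failed": sum(n.count("failed") for n in notes.values()),
    }
    return ScanResult(symbols=symbols, grids=grids, values=values,
                      notes=notes, summary=summary)


def sensitivity_irreversibility_region(
    params: ParameterSet,
    symbols: list[str] | None = None,
    fold_range: float = 2.0,
    n_grid: int = 3,
    sensitivity_threshold: float = 0.95,
) -> ScanResult:
    """Fraction of one-at-a-time perturbations of the cyclin-B model that
    keep the checkpoint both sensitive and irreversible.

    *Sensitive*: the engaged branch survives until
    ``X_tens > sensitivity_threshold``.  *Irreversible*: the disengaged
    branch has no re-engagement fold anywhere in ``X_tens`` in [0, 1].  The
    value stored per grid point is 1.0 (both hold) or 0.0; the summary
    reports the passing fraction.
    """
    symbols = list(symbols or CYCB_CORE_RATE_SYMBOLS)
    base = params.with_updates(X_tens=0.0)
    build_cycb_mcc_apc(base)
    grids, values, notes = {}, {}, {}
    n_pass = n_tot = 0
    for s in symbols:
        grid = _log_grid(params[s], fold_range, n_grid)
        vals = np.full(len(grid), np.nan)
        note = [""] * len(grid)
        for i, g in enumerate(grid):
            pset = base.with_updates(**{s: float(g)})
            model = build_cycb_mcc_apc(pset)
            try:
                up = find_threshold(model, pset, "X_tens", "up", (0.0, 1.0))
                sensitive = up is not None and up.value > sensitivity_threshold
                dis = integrate_to_steady_state(
                    model, model.init_default * 0.0,
                    pset.with_updates(X_tens=1.0),
                ).state
                down = find_threshold(
                    model, pset, "X_tens", "down", (0.0, 1.0), start_state=dis
                )
                irreversible = down is None
            except Exception:
                note[i] = "failed"
                n_tot += 1
                continue
            ok = sensitive and irreversible
            vals[i] = float(ok)
            if up is None:
                note[i] = "monostable"
            n_pass += int(ok)
            n_tot += 1
        grids[s], values[s], notes[s] = grid, vals, note
    summary = {
        "fraction_passing": n_pass / n_tot if n_tot else float("nan"),
        "n_points": n_tot,
        "sensitivity_threshold": sensitivity_threshold,
    }
    return ScanResult(symbols=symbols, grids=grids, values=values,
                      notes=notes, summary=summary)
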