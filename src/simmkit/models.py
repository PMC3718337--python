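"""Mass-action ODE models of bistable cell-cycle checkpoint switches.

The common theme is the SIMM motif (substrate-inhibitor, multiply modified):
an inhibitor I stalls a cell-cycle transition by stoichiometrically binding
the activator enzyme A, while A modifies I in two distributive steps; the
hypo-modified inhibitor is a tight-binding, slowly processed substrate and the
once-modified form is a loosely bound, quickly processed one.  The doubly
modified inhibitor no longer binds A.  This double-negative feedback loop
yields two stable steady states, checkpoint *engaged* (A sequestered) and
*disengaged* (A free), separated by an unstable state.

Seven builders are provided:

* :func:`build_simm` - the full five-variable motif (both modifications as
  elementary binding/catalysis steps).
* :func:`build_simm_star` - four variables; the weakly binding second
  modification collapsed to a bimolecular mass-action step ``A + IM -> A + IMM``
  with rate constant ``k_m = k_cat2*k_as2/(k_cat2 + k_di2)``.
* :func:`build_tqssa` - two slow variables (total functional inhibitor
  ``I_hat = I + C`` and ``I_MM``) after eliminating the tight A:I complex with
  the total quasi-steady-state approximation (TQSSA).
* :func:`build_sic_clb` and :func:`build_cln_sic_clb` - the budding-yeast
  G1/S switch: Sic1 as substrate/inhibitor of Clb:Cdk1, optionally with the
  Cln:Cdk1 module (weakly bound, quickly processed, never inhibited).
* :func:`build_mcc_apc` and :func:`build_cycb_mcc_apc` - the mitotic
  (spindle-assembly) checkpoint: the mitotic checkpoint complex MCC as
  substrate/inhibitor of the anaphase-promoting complex APC, with securin as a
  transition indicator, and optionally with cyclin B closing a second
  double-negative loop that makes anaphase irreversible.

States are plain ``numpy`` arrays ordered as ``model.state_vars``.  Each model
is defined by expression-text rate laws (see :mod:`simmkit.expr`), compiled
once into a fast scalar right-hand side; the same expressions are what
:mod:`simmkit.odeio` writes to ``.ode`` files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from . import expr
from .params import ParameterSet, ParameterError

__all__ = [
    "ValidationError",
    "Conservation",
    "ModelDefinition",
    "tqssa_complex",
    "build_simm",
    "build_simm_star",
    "build_tqssa",
    "build_sic_clb",
    "build_cln_sic_clb",
    "build_mcc_apc",
    "build_cycb_mcc_apc",
    "MODEL_BUILDERS",
    "build_model",
]


class ValidationError(ValueError):
    """Inadmissible argument (negative concentration, fraction out of range...)."""


@dataclass(frozen=True)
class Conservation:
    """A linear functional of the state that the RHS annihilates.

    ``sum(coeffs[v] * state[v]) == params[total_symbol]`` along every
    trajectory; ``eliminate`` names the state variable removed when solving
    steady states on the reduced system.
    """

    coeffs: Mapping[str, float]
    total_symbol: str
    eliminate: str


@dataclass
class ModelDefinition:
    """A named dynamical system defined by expression-text rate laws."""

    name: str
    state_vars: list[str]
    param_symbols: list[str]
    aux: list[tuple[str, str]]
    odes: dict[str, str]
    conservations: list[Conservation] = field(default_factory=list)
    #: auxiliary name measuring free-activator fraction in [0, 1]
    activity_aux: str = "activity"
    #: activity <= bands[0] -> engaged, >= bands[1] -> disengaged
    activity_bands: tuple[float, float] = (0.05, 0.15)
    #: inclusive admissibility bounds for selected parameters
    param_bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    init_default: np.ndarray | None = None
    description: str = ""

    def __post_init__(self) -> None:
        self._rhs = expr.compile_system(
            self.state_vars, self.param_symbols, self.aux, self.odes
        )
        self._aux_fn = expr.compile_aux(
            self.state_vars, self.param_symbols, self.aux
        )
        if self.init_default is None:
            self.init_default = np.zeros(len(self.state_vars))

    # -- parameters -----------------------------------------------------------

    def pvec(self, params: ParameterSet) -> np.ndarray:
        """Parameter vector in ``param_symbols`` order (missing -> error)."""
        return np.array([params[s] for s in self.param_symbols], dtype=float)

    def validate_params(self, params: ParameterSet) -> None:
        for s in self.param_symbols:
            v = params[s]
            if not v >= 0:
                raise ValidationError(f"{s} must be nonnegative, got {v}")
            lo, hi = self.param_bounds.get(s, (0.0, math.inf))
            if not (lo <= v <= hi):
                raise ValidationError(f"{s}={v} outside admissible [{lo}, {hi}]")

    # -- dynamics -------------------------------------------------------------

    def rhs(self, y, params_or_pvec) -> np.ndarray:
        """Time derivative (U/T) at state ``y``."""
        pv = (
            params_or_pvec
            if isinstance(params_or_pvec, np.ndarray)
            else self.pvec(params_or_pvec)
        )
        return np.asarray(self._rhs(np.asarray(y, dtype=float), pv))

    def rhs_fn(self, params: ParameterSet) -> Callable:
        """Closure ``f(y) -> ndarray`` with parameters frozen (hot path)."""
        pv = self.pvec(params)
        raw = self._rhs
        return lambda y: np.asarray(raw(y, pv))

    def eval_aux(self, y, params: ParameterSet) -> dict[str, float]:
        """Values of all auxiliary (derived) quantities at ``y``."""
        pv = self.pvec(params)
        names = [a for a, _ in self.aux]
        vals = self._aux_fn(np.asarray(y, dtype=float), pv)
        return dict(zip(names, vals))

    def activity(self, y, params: ParameterSet) -> float:
        """Free-activator fraction (0 = fully sequestered, 1 = fully free)."""
        return float(self.eval_aux(y, params)[self.activity_aux])

    def classify(self, y, params: ParameterSet) -> str:
        """Label a state engaged / disengaged / intermediate by activity."""
        a = self.activity(y, params)
        lo, hi = self.activity_bands
        if a <= lo:
            return "engaged"
        if a >= hi:
            return "disengaged"
        return "intermediate"

    def conserved_values(self, y, params: ParameterSet) -> dict[str, float]:
        out = {}
        y = np.asarray(y, dtype=float)
        for law in self.conservations:
            val = sum(
                c * y[self.state_vars.index(v)] for v, c in law.coeffs.items()
            )
            out[law.total_symbol] = float(val)
        return out

    def sample_state(self, rng: np.random.Generator, params: ParameterSet) -> np.ndarray:
        """One random admissible state (honours totals and nonnegativity)."""
        return _SAMPLERS[self.name](rng, params)


def tqssa_complex(i_hat: float, a_total: float, k_m1: float) -> float:
    """Tight-binding complex concentration under the TQSSA.

    Returns the physically admissible (smaller) root of
    ``C**2 - (a_total + i_hat + k_m1)*C + a_total*i_hat = 0``, computed in the
    cancellation-free form ``2*a*i / (b + sqrt(b**2 - 4*a*i))``; satisfies
    ``0 <= C <= min(a_total, i_hat)``.
    """
    if i_hat < 0 or a_total < 0 or k_m1 < 0:
        raise ValidationError("tqssa_complex arguments must be nonnegative")
    if i_hat == 0.0 or a_total == 0.0:
        return 0.0
    b = a_total + i_hat + k_m1
    return 2.0 * a_total * i_hat / (b + math.sqrt(b * b - 4.0 * a_total * i_hat))


_TQSSA_CLOSURE = (
    "2*{AT}*{IH}/(({AT} + {IH} + {KM}) "
    "+ sqrt(({AT} + {IH} + {KM})**2 - 4*{AT}*{IH}))"
)


def _require(params: ParameterSet, symbols: Sequence[str]) -> None:
    for s in symbols:
        params[s]  # ParameterError on missing; nonnegativity checked at creation


# ---------------------------------------------------------------------------
# builders
# ---------------------------------------------------------------------------

_SIMM_SYMBOLS = [
    "k_as1", "k_as2", "k_di1", "k_di2", "k_cat1", "k_cat2",
    "k_dm1", "k_dm2", "A_T", "I_T",
]


def build_simm(params: ParameterSet) -> ModelDefinition:
    """Full SIMM motif: two distributive Michaelis-Menten modifications.

    Reactions (all elementary):
    ``A + I <-> A:I -> A + IM`` (k_as1, k_di1, k_cat1),
    ``A + IM <-> A:IM -> A + IMM`` (k_as2, k_di2, k_cat2),
    ``IM -> I`` (k_dm1), ``IMM -> IM`` (k_dm2).
    Free enzyme ``A = A_T - C - C_M`` is algebraic; the inhibitor total
    ``I + C + I_M + C_M + I_MM = I_T`` is a declared conservation law.
    """
    _require(params, _SIMM_SYMBOLS)
    return ModelDefinition(
        name="simm",
        state_vars=["I", "I_M", "I_MM", "C", "C_M"],
        param_symbols=_SIMM_SYMBOLS,
        aux=[
            ("A", "max(A_T - C - C_M, 0.0)"),
            ("activity", "A / max(A_T, 1e-12)"),
        ],
        odes={
            "I": "-k_as1*A*I + k_di1*C + k_dm1*I_M",
            "I_M": "k_cat1*C - k_as2*A*I_M + k_di2*C_M - k_dm1*I_M + k_dm2*I_MM",
            "I_MM": "k_cat2*C_M - k_dm2*I_MM",
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
        description="substrate-inhibitor multiply modified, full mass action",
    )


_SIMM_STAR_SYMBOLS = ["k_as1", "k_di1", "k_cat1", "k_m", "k_dm1", "k_dm2", "A_T", "I_T"]


def build_simm_star(params: ParameterSet) -> ModelDefinition:
    """SIMM* motif: second modification as one bimolecular mass-action step.

    Valid because the second modification is weakly binding
    (``K_m2 = (k_di2 + k_cat2)/k_as2 >> K_m1``), so ``A + IM -> A + IMM``
    proceeds at ``k_m*A*I_M`` with ``k_m = k_cat2*k_as2/(k_cat2 + k_di2)``.
    """
    _require(params, _SIMM_STAR_SYMBOLS)
    return ModelDefinition(
        name="simm_star",
        state_vars=["I", "I_M", "I_MM", "C"],
        param_symbols=_SIMM_STAR_SYMBOLS,
        aux=[
            ("A", "max(A_T - C, 0.0)"),
            ("activity", "A / max(A_T, 1e-12)"),
        ],
        odes={
            "I": "-k_as1*A*I + k_di1*C + k_dm1*I_M",
            "I_M": "k_cat1*C - k_m*A*I_M - k_dm1*I_M + k_dm2*I_MM",
            "I_MM": "k_m*A*I_M - k_dm2*I_MM",
            "C": "k_as1*A*I - (k_di1 + k_cat1)*C",
        },
        conservations=[
            Conservation(
                coeffs={"I": 1, "I_M": 1, "I_MM": 1, "C": 1},
                total_symbol="I_T",
                eliminate="I",
            )
        ],
        init_default=np.array([params["I_T"], 0, 0, 0], dtype=float),
        description="SIMM with mass-action second modification",
    )


_TQSSA_SYMBOLS = ["K_m1", "k_cat1", "k_m", "k_dm1", "k_dm2", "A_T", "I_T"]


def build_tqssa(params: ParameterSet) -> ModelDefinition:
    """Two-variable TQSSA reduction of SIMM* in (I_hat, I_MM).

    ``I_hat = I + C`` is the total functional inhibitor; the tight complex is
    eliminated by the algebraic closure ``C = C(I_hat)`` (smaller root of the
    tight-binding quadratic, see :func:`tqssa_complex`), and
    ``I_M = I_T - I_hat - I_MM``.
    """
    _require(params, _TQSSA_SYMBOLS)
    closure = _TQSSA_CLOSURE.format(AT="A_T", IH="max(I_hat, 0.0)", KM="K_m1")
    return ModelDefinition(
        name="tqssa",
        state_vars=["I_hat", "I_MM"],
        param_symbols=_TQSSA_SYMBOLS,
        aux=[
            ("C", closure),
            ("A", "max(A_T - C, 0.0)"),
            ("I_M", "max(I_T - I_hat - I_MM, 0.0)"),
            ("activity", "A / max(A_T, 1e-12)"),
        ],
        odes={
            "I_hat": "k_dm1*I_M - k_cat1*C",
            "I_MM": "k_m*A*I_M - k_dm2*I_MM",
        },
        init_default=np.array([params["I_T"], 0], dtype=float),
        description="TQSSA phase-plane reduction of SIMM*",
    )


_SIC_CLB_SYMBOLS = ["k_s", "k_d", "k_as_b", "k_di_b", "k_p_b", "k_dp", "k_cat_b", "ClbT"]


def build_sic_clb(params: ParameterSet) -> ModelDefinition:
    """Sic1 / Clb-kinase switch: SIMM* plus Sic1 synthesis and turnover.

    Sic1 is synthesised at ``k_s`` and every form is degraded at the
    background rate ``k_d``.  Clb:Cdk1 binds Sic1 tightly (``k_as_b, k_di_b``)
    and slowly phosphorylates it once (``k_cat_b``); the Clb-dependent second
    phosphorylation ``k_p_b*[Clb]*[SicP]`` produces a doubly phosphorylated
    form that is degraded so fast it never appears as a pool - the flux is a
    pure sink from the Sic1 total.  ``k_dp`` undoes the first phosphorylation.
    ``[ClbT]`` is the bifurcation signal.
    """
    _require(params, _SIC_CLB_SYMBOLS)
    return ModelDefinition(
        name="sic_clb",
        state_vars=["SicT", "ClbSic", "SicP"],
        param_symbols=_SIC_CLB_SYMBOLS,
        aux=[
            ("Sic", "max(SicT - ClbSic - SicP, 0.0)"),
            ("Clb", "max(ClbT - ClbSic, 0.0)"),
            ("activity", "Clb / max(ClbT, 1e-12)"),
        ],
        odes={
            "SicT": "k_s - k_d*SicT - k_p_b*Clb*SicP",
            "ClbSic": "k_as_b*Clb*Sic - (k_di_b + k_cat_b + k_d)*ClbSic",
            "SicP": "k_cat_b*ClbSic - (k_dp + k_d)*SicP - k_p_b*Clb*SicP",
        },
        init_default=np.array([params["k_s"] / max(params["k_d"], 1e-12), 0, 0]),
        description="budding-yeast Sic1-Clb bistable switch",
    )


_CLN_SIC_CLB_SYMBOLS = _SIC_CLB_SYMBOLS + [
    "k_as_n", "k_di_n", "k_p_n", "k_cat_n", "ClnT",
]


def build_cln_sic_clb(params: ParameterSet) -> ModelDefinition:
    """G1/S model: the Sic1-Clb switch plus a Cln:Cdk1 module.

    Cln:Cdk1 is not inhibited by Sic1, which is encoded purely by weak binding
    and fast processing (``k_as_n`` small, ``k_di_n``/``k_cat_n`` large); Cln
    also carries out the second phosphorylation at ``k_p_n*[Cln]*[SicP]``.
    With ``[ClnT] = 0`` and no Cln:Sic present the right-hand side reduces
    exactly to :func:`build_sic_clb` on the shared state.
    """
    _require(params, _CLN_SIC_CLB_SYMBOLS)
    return ModelDefinition(
        name="cln_sic_clb",
        state_vars=["SicT", "ClbSic", "ClnSic", "SicP"],
        param_symbols=_CLN_SIC_CLB_SYMBOLS,
        aux=[
            ("Sic", "max(SicT - ClbSic - ClnSic - SicP, 0.0)"),
            ("Clb", "max(ClbT - ClbSic, 0.0)"),
            ("Cln", "max(ClnT - ClnSic, 0.0)"),
            ("activity", "Clb / max(ClbT, 1e-12)"),
        ],
        odes={
            "SicT": "k_s - k_d*SicT - (k_p_b*Clb + k_p_n*Cln)*SicP",
            "ClbSic": "k_as_b*Clb*Sic - (k_di_b + k_cat_b + k_d)*ClbSic",
            "ClnSic": "k_as_n*Cln*Sic - (k_di_n + k_cat_n + k_d)*ClnSic",
            "SicP": "k_cat_b*ClbSic + k_cat_n*ClnSic - (k_dp + k_d)*SicP"
                    " - (k_p_b*Clb + k_p_n*Cln)*SicP",
        },
        init_default=np.array([params["k_s"] / max(params["k_d"], 1e-12), 0, 0, 0]),
        description="budding-yeast G1/S switch with Cln and Clb kinases",
    )


_MCC_APC_SYMBOLS = [
    "K_m", "k_u", "k_du", "k_cat", "k_a_NT", "X_tens",
    "k_ssec", "k_dsec", "k_dsec_apc", "APC_T", "Mad2_T",
]


def build_mcc_apc(params: ParameterSet) -> ModelDefinition:
    """Mitotic-checkpoint switch: MCC vs APC with a TQSSA complex closure.

    Tensionless kinetochores assemble new MCC from the free Mad2 pool at
    ``k_a_NT*(1 - X_tens)*[Mad2]``.  MCC binds APC tightly; the complex is
    eliminated by the TQSSA quadratic in the functional-MCC total
    ``[MCC] + [APC:MCC] = [MCCT] - [MCCU]`` with ``K_m = (k_di + k_cat)/k_as``.
    APC mono-ubiquitinates bound MCC (``k_cat``, releasing MCCU + APC), free
    APC poly-ubiquitinates MCCU (``k_u``, mass action) which destroys Cdc20
    and returns Mad2 to the free pool, and a de-ubiquitinase recycles MCCU
    back to functional MCC at ``k_du``.  Securin tracks anaphase onset.
    """
    _require(params, _MCC_APC_SYMBOLS)
    closure = _TQSSA_CLOSURE.format(AT="APC_T", IH="Mhat", KM="K_m")
    model = ModelDefinition(
        name="mcc_apc",
        state_vars=["MCCT", "MCCU", "Securin"],
        param_symbols=_MCC_APC_SYMBOLS,
        aux=[
            ("Mhat", "max(MCCT - MCCU, 0.0)"),
            ("APCMCC", closure),
            ("APC", "max(APC_T - APCMCC, 0.0)"),
            ("Mad2", "max(Mad2_T - MCCT, 0.0)"),
            ("activity", "APC / max(APC_T, 1e-12)"),
        ],
        odes={
            "MCCT": "k_a_NT*(1 - X_tens)*Mad2 - k_u*APC*MCCU",
            "MCCU": "k_cat*APCMCC - k_du*MCCU - k_u*APC*MCCU",
            "Securin": "k_ssec - k_dsec*Securin - k_dsec_apc*APC*Securin",
        },
        param_bounds={"X_tens": (0.0, 1.0)},
        init_default=np.array(
            [params["Mad2_T"], 0.0, params["k_ssec"] / max(params["k_dsec"], 1e-12)]
        ),
        description="spindle-assembly checkpoint, MCC-APC core",
    )
    model.validate_params(params)
    return model


_CYCB_SYMBOLS = [
    "k_u", "k_du", "k_cat", "k_a_NT", "X_tens",
    "k_ssec", "k_dsec", "k_dsec_apc", "APC_T", "Mad2_T",
    "k_scyc", "k_dcyc", "k_dcyc_apc", "k_an", "k_in_CAPP", "k_as", "k_di",
]


def build_cycb_mcc_apc(params: ParameterSet) -> ModelDefinition:
    """Irreversible mitotic checkpoint: MCC-APC plus cyclin B coupling.

    The APC:MCC complex is now an explicit dynamical species (``k_as, k_di,
    k_cat``).  Cyclin B is synthesised at ``k_scyc`` and degraded basally
    (``k_dcyc``) and by free APC (``k_dcyc_apc``); tensionless centromeres
    must be *activated* by CycB-kinase (``k_an``) before they assemble MCC,
    and a counteracting phosphatase inactivates them (composite rate
    ``k_in_CAPP``).  ``X_0A`` is the fraction of centromeres that are both
    tensionless and activating.  Once APC destroys CycB, centromere activity
    cannot recover, so the checkpoint never re-engages in anaphase.
    """
    _require(params, _CYCB_SYMBOLS)
    model = ModelDefinition(
        name="cycb_mcc_apc",
        state_vars=["MCCT", "MCCU", "APCMCC", "CycB", "Securin", "X_0A"],
        param_symbols=_CYCB_SYMBOLS,
        aux=[
            ("APC", "max(APC_T - APCMCC, 0.0)"),
            ("MCC", "max(MCCT - APCMCC - MCCU, 0.0)"),
            ("Mad2", "max(Mad2_T - MCCT, 0.0)"),
            ("activity", "APC / max(APC_T, 1e-12)"),
        ],
        odes={
            "MCCT": "k_a_NT*X_0A*Mad2 - k_u*APC*MCCU",
            "MCCU": "k_cat*APCMCC - k_du*MCCU - k_u*APC*MCCU",
            "APCMCC": "k_as*APC*MCC - (k_di + k_cat)*APCMCC",
            "CycB": "k_scyc - k_dcyc*CycB - k_dcyc_apc*APC*CycB",
            "Securin": "k_ssec - k_dsec*Securin - k_dsec_apc*APC*Securin",
            "X_0A": "k_an*CycB*(1 - X_tens - X_0A) - k_in_CAPP*X_0A",
        },
        param_bounds={"X_tens": (0.0, 1.0)},
        init_default=np.array(
            [
                params["Mad2_T"],
                0.0,
                min(params["APC_T"], params["Mad2_T"]),
                1.0,
                params["k_ssec"] / max(params["k_dsec"], 1e-12),
                0.2,
            ]
        ),
        description="spindle-assembly checkpoint with cyclin B irreversibility",
    )
    model.validate_params(params)
    return model


# ---------------------------------------------------------------------------
# admissible-state samplers (multistart root finding, randomized invariants)
# ---------------------------------------------------------------------------

def _sample_simm(rng, params):
    it, at = params["I_T"], params["A_T"]
    y = rng.dirichlet(np.ones(5)) * it  # I, I_M, I_MM, C, C_M
    bound = y[3] + y[4]
    if bound > at:
        y[3:] *= 0.95 * at / bound
        y[0] += bound - (y[3] + y[4])
    return y


def _sample_simm_star(rng, params):
    it, at = params["I_T"], params["A_T"]
    y = rng.dirichlet(np.ones(4)) * it  # I, I_M, I_MM, C
    if y[3] > at:
        extra = y[3] - 0.95 * at
        y[3] -= extra
        y[0] += extra
    return y


def _sample_tqssa(rng, params):
    it = params["I_T"]
    parts = rng.dirichlet(np.ones(3)) * it  # I_hat, I_M, I_MM
    return np.array([parts[0], parts[2]])


def _sample_sic(rng, params):
    cap = 2.0 * params["k_s"] / max(params["k_d"], 1e-12)
    sic_t = rng.uniform(0, cap)
    parts = rng.dirichlet(np.ones(3)) * sic_t  # Sic, ClbSic, SicP
    clb_sic = min(parts[1], params["ClbT"])
    return np.array([parts[0] + clb_sic + parts[2], clb_sic, parts[2]])


def _sample_cln_sic(rng, params):
    cap = 2.0 * params["k_s"] / max(params["k_d"], 1e-12)
    sic_t = rng.uniform(0, cap)
    parts = rng.dirichlet(np.ones(4)) * sic_t  # Sic, ClbSic, ClnSic, SicP
    clb_sic = min(parts[1], params["ClbT"])
    cln_sic = min(parts[2], params["ClnT"])
    return np.array(
        [parts[0] + clb_sic + cln_sic + parts[3], clb_sic, cln_sic, parts[3]]
    )


def _sample_mcc(rng, params):
    mcct = rng.uniform(0, params["Mad2_T"])
    mccu = rng.uniform(0, mcct)
    sec = rng.uniform(0, 2.0 * params["k_ssec"] / max(params["k_dsec"], 1e-12))
    return np.array([mcct, mccu, sec])


def _sample_cycb(rng, params):
    mcct = rng.uniform(0, params["Mad2_T"])
    parts = rng.dirichlet(np.ones(3)) * mcct  # MCC, APCMCC, MCCU
    apcmcc = min(parts[1], params["APC_T"])
    cycb = rng.uniform(0, 1.2 * params["k_scyc"] / max(params["k_dcyc"], 1e-12))
    sec = rng.uniform(0, 2.0 * params["k_ssec"] / max(params["k_dsec"], 1e-12))
    x0a = rng.uniform(0, max(1.0 - params["X_tens"], 1e-9))
    return np.array([parts[0] + apcmcc + parts[2], parts[2], apcmcc, cycb, sec, x0a])


_SAMPLERS = {
    "simm": _sample_simm,
    "simm_star": _sample_simm_star,
    "tqssa": _sample_tqssa,
    "sic_clb": _sample_sic,
    "cln_sic_clb": _sample_cln_sic,
    "mcc_apc": _sample_mcc,
    "cycb_mcc_apc": _sample_cycb,
}

MODEL_BUILDERS: dict[str, Callable[[ParameterSet], ModelDefinition]] = {
    "simm": build_simm,
    "simm_star": build_simm_star,
    "tqssa": build_tqssa,
    "sic_clb": build_sic_clb,
    "cln_sic_clb": build_cln_sic_clb,
    "mcc_apc": build_mcc_apc,
    "cycb_mcc_apc": build_cycb_mcc_apc,
}


def build_model(name: str, params: ParameterSet) -> ModelDefinition:
    """Build any of the named models (see :data:`MODEL_BUILDERS`)."""
    try:
        builder = MODEL_BUILDERS[name]
    except KeyError:
        raise ParameterError(
            f"unknown model {name!r}; available: {sorted(MODEL_BUILDERS)}"
        ) from None
    return builder(params)
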