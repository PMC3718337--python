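"""Rate-constant catalogues for the bistable checkpoint models.

All concentrations are expressed in the unit U (~10 nM) and all times in the
unit T (~1 min).  Bimolecular rate constants therefore carry units U^-1 T^-1,
unimolecular constants T^-1, zeroth-order synthesis rates U T^-1, and totals
and Michaelis constants U.

Six named presets are shipped, one per model family:

========  =================================================
name      model
========  =================================================
simm          five-variable substrate-inhibitor motif
simm_star     four-variable simplification (mass-action 2nd step)
sic_clb       Sic1 / Clb-kinase switch (budding yeast G1/S core)
cln_sic_clb   Sic1 / Cln + Clb kinases (full G1/S model)
mcc_apc       MCC / APC mitotic-checkpoint switch
cycb_mcc_apc  MCC / APC / cyclin B irreversible checkpoint
========  =================================================

The APC and Mad2 totals of the two mitotic-checkpoint presets are not part of
the published rate-constant table; the defaults here (APC_T = 1 U,
Mad2_T = 2 U) are reconstructed so that the models reproduce the published
disengagement threshold (~0.97), re-engagement threshold (~0.89) and in-vitro
release lag (~45 T).  They are ordinary parameters and can be overridden.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping

__all__ = [
    "ParameterError",
    "ParameterSet",
    "PRESETS",
    "get_preset",
    "BIMOLECULAR",
    "UNIMOLECULAR",
    "SYNTHESIS",
    "CONCENTRATION",
    "DIMENSIONLESS",
]

BIMOLECULAR = "U^-1 T^-1"
UNIMOLECULAR = "T^-1"
SYNTHESIS = "U T^-1"
CONCENTRATION = "U"
DIMENSIONLESS = "-"


class ParameterError(KeyError):
    """Missing or invalid rate constant."""


@dataclass(frozen=True)
class ParameterSet:
    """A named map of nonnegative rate constants with declared units.

    Lookup of a symbol that is not present raises :class:`ParameterError`;
    there are no silent defaults.
    """

    name: str
    values: Mapping[str, float]
    units: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for sym, val in self.values.items():
            if not (val >= 0.0):  # also rejects NaN
                raise ParameterError(
                    f"parameter {sym!r} must be nonnegative, got {val!r}"
                )

    def __getitem__(self, symbol: str) -> float:
        try:
            return self.values[symbol]
        except KeyError:
            raise ParameterError(
                f"parameter {symbol!r} not defined in set {self.name!r} "
                f"(available: {sorted(self.values)})"
            ) from None

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.values

    def __iter__(self) -> Iterator[str]:
        return iter(self.values)

    def unit(self, symbol: str) -> str:
        self[symbol]  # raise on missing
        return self.units.get(symbol, DIMENSIONLESS)

    def with_updates(self, **overrides: float) -> "ParameterSet":
        """Return a copy with some values replaced (symbols may be new)."""
        vals = dict(self.values)
        vals.update(overrides)
        units = dict(self.units)
        return ParameterSet(name=self.name, values=vals, units=units)

    def subset(self, symbols) -> dict:
        return {s: self[s] for s in symbols}

    def as_dict(self) -> dict:
        return dict(self.values)


def _pset(name, pairs):
    values = {s: v for s, v, _ in pairs}
    units = {s: u for s, _, u in pairs}
    return ParameterSet(name=name, values=values, units=units)


# -- preset (a): the basic five-variable motif -------------------------------
_SIMM = [
    ("k_as1", 100.0, BIMOLECULAR),   # I binds A strongly
    ("k_as2", 50.0, BIMOLECULAR),    # IM binds A more weakly
    ("k_di1", 0.5, UNIMOLECULAR),
    ("k_di2", 1.0, UNIMOLECULAR),
    ("k_cat1", 0.5, UNIMOLECULAR),   # A:I processed slowly
    ("k_cat2", 50.0, UNIMOLECULAR),  # A:IM processed quickly
    ("k_dm1", 1.0, UNIMOLECULAR),
    ("k_dm2", 1.0, UNIMOLECULAR),
    # neutral point of the control plane: inside the bistable V
    ("A_T", 1.0, CONCENTRATION),
    ("I_T", 4.0, CONCENTRATION),
]

# -- preset (b): simplified motif, second modification by mass action --------
_SIMM_STAR = _SIMM + [
    ("k_m", 50.0, BIMOLECULAR),      # A + IM -> A + IMM
    ("K_m1", 0.01, CONCENTRATION),   # Michaelis constant of first modification
]

# -- preset (c): Sic1 - Clb:Cdk1 switch --------------------------------------
_SIC_CLB = [
    ("k_s", 0.2, SYNTHESIS),         # Sic1 synthesis
    ("k_d", 0.05, UNIMOLECULAR),     # background degradation, all Sic1 forms
    ("k_as_b", 100.0, BIMOLECULAR),  # Sic1 + Clb:Cdk1 association
    ("k_di_b", 0.01, UNIMOLECULAR),
    ("k_p_b", 20.0, BIMOLECULAR),    # Clb-kinase second phosphorylation of SicP
    ("k_dp", 0.5, UNIMOLECULAR),     # dephosphorylation SicP -> Sic
    ("k_cat_b", 0.5, UNIMOLECULAR),  # Clb:Sic -> Clb + SicP
    ("ClbT", 0.7, CONCENTRATION),    # bifurcation signal; default inside the V
]

# -- preset (d): Cln module added --------------------------------------------
_CLN_SIC_CLB = _SIC_CLB[:-1] + [
    ("ClbT", 0.3, CONCENTRATION),
    ("k_as_n", 2.0, BIMOLECULAR),    # Sic1 binds Cln:Cdk1 weakly
    ("k_di_n", 2.0, UNIMOLECULAR),
    ("k_p_n", 0.1, BIMOLECULAR),     # Cln-kinase second phosphorylation
    ("k_cat_n", 2.0, UNIMOLECULAR),  # Cln:Sic processed quickly
    ("ClnT", 0.0, CONCENTRATION),
]

# -- preset (e): MCC - APC mitotic checkpoint --------------------------------
_MCC_APC = [
    ("K_m", 0.01, CONCENTRATION),    # Michaelis constant of the APC:MCC complex
    ("k_u", 10.0, BIMOLECULAR),      # poly-ubiquitination of MCCU by free APC
    ("k_du", 5.0, UNIMOLECULAR),     # de-ubiquitination MCCU -> MCC
    ("k_cat", 0.5, UNIMOLECULAR),    # APC:MCC -> MCCU + APC
    ("k_a_NT", 1.0, UNIMOLECULAR),   # composite k_a*N_T, Mad2 activation
    ("X_tens", 0.0, DIMENSIONLESS),  # fraction of centromeres under tension
    ("k_ssec", 0.1, SYNTHESIS),
    ("k_dsec", 0.05, UNIMOLECULAR),
    ("k_dsec_apc", 0.5, BIMOLECULAR),
    # totals: reconstructed defaults, see module docstring
    ("APC_T", 1.0, CONCENTRATION),
    ("Mad2_T", 2.0, CONCENTRATION),
]

# -- preset (f): cyclin B coupling added -------------------------------------
_CYCB_MCC_APC = [p for p in _MCC_APC if p[0] != "k_a_NT"] + [
    ("k_a_NT", 5.0, UNIMOLECULAR),
    ("k_scyc", 0.01, SYNTHESIS),
    ("k_dcyc", 0.01, UNIMOLECULAR),
    ("k_dcyc_apc", 1.0, BIMOLECULAR),
    ("k_an", 1.0, BIMOLECULAR),      # CycB activates tensionless centromeres
    ("k_in_CAPP", 2.0, UNIMOLECULAR),  # composite k_in*[CAPP]
    ("k_as", 100.0, BIMOLECULAR),    # explicit APC:MCC association
    ("k_di", 0.5, UNIMOLECULAR),
]

PRESETS: dict[str, ParameterSet] = {
    "simm": _pset("simm", _SIMM),
    "simm_star": _pset("simm_star", _SIMM_STAR),
    "sic_clb": _pset("sic_clb", _SIC_CLB),
    "cln_sic_clb": _pset("cln_sic_clb", _CLN_SIC_CLB),
    "mcc_apc": _pset("mcc_apc", _MCC_APC),
    "cycb_mcc_apc": _pset("cycb_mcc_apc", _CYCB_MCC_APC),
}


def get_preset(name: str) -> ParameterSet:
    """Return the built-in parameter set for one of the six model presets."""
    try:
        return PRESETS[name]
    except KeyError:
        raise ParameterError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}"
        ) from None
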