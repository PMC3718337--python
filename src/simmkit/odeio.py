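"""Reader/writer for a restricted XPPAUT ``.ode`` dialect.

Supported line forms (case-insensitive directives, ``#`` comments):

* ``par name=value[, name=value ...]`` (also ``param``, ``number``)
* ``init var=value[, var=value ...]``
* ``aux name=expression`` - algebraic definitions usable in later expressions
* ``dVAR/dt=expression`` or ``VAR'=expression``
* ``done`` - end of file
* ``@ ...`` and other XPP directives - warned about and skipped

Expressions use the arithmetic dialect of :mod:`simmkit.expr` (XPP's ``^``
power is accepted and written).  Every symbol in an expression must resolve
to a parameter, a state variable or an earlier aux definition; anything else
is an error naming the symbol.  Written files round-trip bit-exactly through
the reader.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import expr
from .models import ModelDefinition
from .params import ParameterSet

__all__ = ["OdeSyntaxError", "OdeFileModel", "read_ode", "write_ode", "model_to_ode_text"]

_UNIT_BANNER = "U, concentration unit (approx. 10 nM); T, time unit (approx. 1 min)"


class OdeSyntaxError(ValueError):
    """Malformed .ode input, reported with its line number."""


@dataclass
class OdeFileModel:
    """Parsed content of a restricted-dialect .ode file."""

    name: str
    parameters: dict[str, float] = field(default_factory=dict)
    odes: dict[str, str] = field(default_factory=dict)  # var -> expression text
    init: dict[str, float] = field(default_factory=dict)
    aux: list[tuple[str, str]] = field(default_factory=list)
    skipped: list[str] = field(default_factory=list)

    @property
    def state_vars(self) -> list[str]:
        return list(self.odes)

    def build(self) -> tuple[ModelDefinition, ParameterSet]:
        """Compile the parsed expressions into an executable model."""
        model = ModelDefinition(
            name=self.name,
            state_vars=self.state_vars,
            param_symbols=list(self.parameters),
            aux=list(self.aux),
            odes=dict(self.odes),
            activity_aux=(
                "activity" if any(a == "activity" for a, _ in self.aux) else
                (self.aux[0][0] if self.aux else self.state_vars[0])
            ),
            init_default=np.array(
                [self.init.get(v, 0.0) for v in self.state_vars]
            ),
            description=f"parsed from .ode ({self.name})",
        )
        pset = ParameterSet(name=self.name, values=dict(self.parameters))
        return model, pset


_DERIV_RE = re.compile(r"^d([A-Za-z_]\w*)/dt\s*=\s*(.+)$")
_PRIME_RE = re.compile(r"^([A-Za-z_]\w*)'\s*=\s*(.+)$")


def _parse_assignments(body: str, lineno: int) -> list[tuple[str, float]]:
    out = []
    for piece in body.split(","):
        piece = piece.strip()
        if not piece:
            continue
        if "=" not in piece:
            raise OdeSyntaxError(f"line {lineno}: expected name=value in {piece!r}")
        name, _, val = piece.partition("=")
        try:
            out.append((name.strip(), float(val)))
        except ValueError:
            raise OdeSyntaxError(
                f"line {lineno}: non-numeric value in {piece!r}"
            ) from None
    return out


def read_ode(source) -> tuple[ParameterSet, OdeFileModel]:
    """Parse a restricted-dialect .ode file (path, or text with newlines)."""
    if isinstance(source, Path) or (isinstance(source, str) and "\n" not in source):
        path = Path(source)
        text = path.read_text()
        name = path.stem
    else:
        text = str(source)
        name = "ode_model"
    ofm = OdeFileModel(name=name)
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        low = line.lower()
        if low == "done":
            break
        if low.startswith(("par ", "param ", "number ")):
            body = line.split(None, 1)[1]
            for name_, val in _parse_assignments(body, lineno):
                ofm.parameters[name_] = val
            continue
        if low.startswith("init "):
            for name_, val in _parse_assignments(line.split(None, 1)[1], lineno):
                ofm.init[name_] = val
            continue
        if low.startswith("aux "):
            body = line.split(None, 1)[1]
            if "=" not in body:
                raise OdeSyntaxError(f"line {lineno}: aux needs name=expression")
            name_, _, rhs = body.partition("=")
            ofm.aux.append((name_.strip(), rhs.strip()))
            continue
        m = _DERIV_RE.match(line) or _PRIME_RE.match(line)
        if m:
            ofm.odes[m.group(1)] = m.group(2).strip()
            continue
        if low.startswith("@") or low.startswith(("set ", "opt ", "table ", "wiener ")):
            ofm.skipped.append(line)
            warnings.warn(
                f"line {lineno}: skipping unsupported directive {line!r}",
                stacklevel=2,
            )
            continue
        raise OdeSyntaxError(f"line {lineno}: cannot parse {line!r}")

    # symbol resolution: every name must be a parameter, state or earlier aux
    known = set(ofm.parameters) | set(ofm.odes)
    for name_, rhs in ofm.aux:
        bad = expr.free_symbols(rhs) - known
        if bad:
            raise OdeSyntaxError(
                f"undefined symbol(s) {sorted(bad)} in aux {name_!r}"
            )
        known.add(name_)
    for var, rhs in ofm.odes.items():
        bad = expr.free_symbols(rhs) - known
        if bad:
            raise OdeSyntaxError(
                f"undefined symbol(s) {sorted(bad)} in d{var}/dt"
            )
    pset = ParameterSet(name=ofm.name, values=dict(ofm.parameters))
    return pset, ofm


def model_to_ode_text(
    model: ModelDefinition, params: ParameterSet, init=None
) -> str:
    """Serialize a model as restricted-dialect .ode text."""
    init = model.init_default if init is None else np.asarray(init, dtype=float)
    lines = [f"# {model.name} - {model.description}", f"# {_UNIT_BANNER}"]
    for s in model.param_symbols:
        lines.append(f"par {s}={params[s]!r}")
    for v, x in zip(model.state_vars, init):
        lines.append(f"init {v}={float(x)!r}")
    for name, text in model.aux:
        lines.append(f"aux {name}={text.replace('**', '^')}")
    for v in model.state_vars:
        lines.append(f"d{v}/dt={model.odes[v].replace('**', '^')}")
    lines.append("done")
    return "\n".join(lines) + "\n"


def write_ode(
    model: ModelDefinition,
    params: ParameterSet,
    init=None,
    path=None,
) -> str:
    """Write the model to ``path`` (if given) and return the .ode text."""
    text = model_to_ode_text(model, params, init)
    if path is not None:
        Path(path).write_text(text)
    return text
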