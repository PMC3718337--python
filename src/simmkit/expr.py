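"""A restricted arithmetic-expression language for rate laws.

Models in this package are defined by plain-text right-hand-side expressions
(the same dialect used by the ``.ode`` reader/writer), which are compiled once
into fast scalar Python functions.  The grammar covers exactly what mass-action
rate laws and tight-binding closures need: names, numbers, ``+ - * /``, powers
(``**`` or the XPPAUT-style ``^``), unary minus, parentheses and calls to a
small set of functions (``sqrt exp log abs min max``).
"""

from __future__ import annotations

import ast
import math
from typing import Callable, Mapping, Sequence

__all__ = [
    "ExpressionError",
    "parse_expr",
    "free_symbols",
    "compile_system",
    "compile_aux",
]

_FUNCTIONS: dict[str, Callable] = {
    "sqrt": math.sqrt,
    "exp": math.exp,
    "log": math.log,
    "abs": abs,
    "min": min,
    "max": max,
}

_ALLOWED_NODES = (
    ast.Expression,
    ast.BinOp,
    ast.UnaryOp,
    ast.Add,
    ast.Sub,
    ast.Mult,
    ast.Div,
    ast.Pow,
    ast.USub,
    ast.UAdd,
    ast.Call,
    ast.Name,
    ast.Load,
    ast.Constant,
)


class ExpressionError(ValueError):
    """Malformed or disallowed expression text."""


def _normalise(text: str) -> str:
    return text.strip().replace("^", "**")


def parse_expr(text: str) -> ast.Expression:
    """Parse and validate one expression; raise ExpressionError otherwise."""
    try:
        tree = ast.parse(_normalise(text), mode="eval")
    except SyntaxError as exc:
        raise ExpressionError(f"cannot parse expression {text!r}: {exc}") from None
    for node in ast.walk(tree):
        if not isinstance(node, _ALLOWED_NODES):
            raise ExpressionError(
                f"disallowed construct {type(node).__name__} in {text!r}"
            )
        if isinstance(node, ast.Call):
            if not isinstance(node.func, ast.Name) or node.func.id not in _FUNCTIONS:
                raise ExpressionError(f"disallowed function call in {text!r}")
        if isinstance(node, ast.Constant) and not isinstance(node.value, (int, float)):
            raise ExpressionError(f"non-numeric constant in {text!r}")
    return tree


def free_symbols(text: str) -> set[str]:
    """Names referenced by the expression, excluding function names."""
    tree = parse_expr(text)
    return {
        n.id
        for n in ast.walk(tree)
        if isinstance(n, ast.Name) and n.id not in _FUNCTIONS
    }


def compile_system(
    state_vars: Sequence[str],
    param_symbols: Sequence[str],
    aux: Sequence[tuple[str, str]],
    odes: Mapping[str, str],
) -> Callable:
    """Compile a system of rate laws into ``f(y, pv) -> tuple``.

    ``y`` is indexed by ``state_vars`` order and ``pv`` by ``param_symbols``
    order.  Auxiliary definitions are evaluated in the given order before the
    derivatives; every symbol appearing in an expression must be a state
    variable, a parameter, an earlier auxiliary or a known function.
    """
    known = set(state_vars) | set(param_symbols)
    lines = ["def _rhs(y, pv):"]
    for i, v in enumerate(state_vars):
        lines.append(f"    {v} = y[{i}]")
    for i, s in enumerate(param_symbols):
        lines.append(f"    {s} = pv[{i}]")
    for name, text in aux:
        undefined = free_symbols(text) - known
        if undefined:
            raise ExpressionError(
                f"auxiliary {name!r} uses undefined symbols {sorted(undefined)}"
            )
        lines.append(f"    {name} = {_normalise(text)}")
        known.add(name)
    returns = []
    for v in state_vars:
        text = odes[v]
        undefined = free_symbols(text) - known
        if undefined:
            raise ExpressionError(
                f"d{v}/dt uses undefined symbols {sorted(undefined)}"
            )
        returns.append(f"({_normalise(text)})")
    lines.append("    return (" + ", ".join(returns) + ("," if len(returns) == 1 else "") + ")")
    namespace: dict = dict(_FUNCTIONS)
    exec(compile("\n".join(lines), "<simmkit-model>", "exec"), namespace)
    return namespace["_rhs"]


def compile_aux(
    state_vars: Sequence[str],
    param_symbols: Sequence[str],
    aux: Sequence[tuple[str, str]],
) -> Callable:
    """Compile ``f(y, pv) -> tuple`` returning all auxiliary values in order."""
    known = set(state_vars) | set(param_symbols)
    lines = ["def _aux(y, pv):"]
    for i, v in enumerate(state_vars):
        lines.append(f"    {v} = y[{i}]")
    for i, s in enumerate(param_symbols):
        lines.append(f"    {s} = pv[{i}]")
    names = []
    for name, text in aux:
        undefined = free_symbols(text) - known
        if undefined:
            raise ExpressionError(
                f"auxiliary {name!r} uses undefined symbols {sorted(undefined)}"
            )
        lines.append(f"    {name} = {_normalise(text)}")
        known.add(name)
        names.append(name)
    lines.append("    return (" + ", ".join(names) + ("," if len(names) == 1 else "") + ")")
    namespace: dict = dict(_FUNCTIONS)
    exec(compile("\n".join(lines), "<simmkit-aux>", "exec"), namespace)
    return namespace["_aux"]
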