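"""Safe arithmetic expression evaluation for rules and opaque kinetic laws.

Expressions are plain arithmetic over named quantities (species concentrations
and parameters), e.g. ``"k_syn * PIP2 / (Km + PIP2)"``.  They are parsed once
into a restricted Python AST (no attribute access, no subscripts, no calls
except a small math whitelist) and compiled to a code object evaluated against
a name->value environment.
"""

from __future__ import annotations

import ast
import math
from typing import Callable, Mapping

from .errors import ValidationError

_ALLOWED_CALLS = {
    "exp": math.exp,
    "log": math.log,
    "log10": math.log10,
    "sqrt": math.sqrt,
    "pow": pow,
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
    ast.Name,
    ast.Constant,
    ast.Call,
    ast.Load,
)


def names_in(expression: str) -> set[str]:
    """Return the set of free names referenced by *expression* (excluding functions)."""
    tree = ast.parse(expression, mode="eval")
    out: set[str] = set()
    for node in ast.walk(tree):
        if isinstance(node, ast.Name):
            out.add(node.id)
        if isinstance(node, ast.Call) and isinstance(node.func, ast.Name):
            out.discard(node.func.id)
    return out - set(_ALLOWED_CALLS)


def compile_expression(expression: str) -> Callable[[Mapping[str, float]], float]:
    """Compile *expression* into ``f(env) -> float``.

    Raises
    ------
    ValidationError
        If the expression uses any construct outside plain arithmetic and the
        whitelisted math functions.
    """
    try:
        tree = ast.parse(expression, mode="eval")
    except SyntaxError as exc:
        raise ValidationError(f"cannot parse expression {expression!r}: {exc}") from exc
    for node in ast.walk(tree):
        if not isinstance(node, _ALLOWED_NODES):
            raise ValidationError(
                f"disallowed construct {type(node).__name__!r} in expression {expression!r}"
            )
        if isinstance(node, ast.Call):
            if not (isinstance(node.func, ast.Name) and node.func.id in _ALLOWED_CALLS):
                raise ValidationError(f"disallowed call in expression {expression!r}")
    code = compile(tree, "<expression>", "eval")

    def evaluate(env: Mapping[str, float]) -> float:
        scope = dict(_ALLOWED_CALLS)
        scope.update(env)
        return float(eval(code, {"__builtins__": {}}, scope))  # noqa: S307 - AST vetted above

    evaluate.source = expression  # type: ignore[attr-defined]
    return evaluate
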