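"""Restricted arithmetic expressions for kinetic rate laws.

Rate laws are parsed into a small immutable expression tree supporting
numbers, named symbols (species densities and parameters), the four
arithmetic operations and powers.  The tree can be evaluated, analytically
differentiated, and compiled to a plain Python function for use in hot
loops (Newton iterations, parameter scans, stochastic simulation).

The deliberate restriction to this node set keeps rate laws analysable:
both symbolic and finite-difference derivatives are always available, and
no user-supplied code is ever executed.
"""

from __future__ import annotations

import ast
import math
from typing import Callable, Iterable, Mapping

__all__ = [
    "Expr",
    "ExprError",
    "parse",
    "evaluate",
    "diff",
    "symbols",
    "compile_expr",
    "to_source",
    "num",
    "sym",
    "add",
    "sub",
    "mul",
    "div",
    "pow_",
    "neg",
]

# An expression is a nested tuple: ("num", float) | ("sym", str) |
# (op, left, right) with op in {add, sub, mul, div, pow} | ("neg", child).
Expr = tuple


class ExprError(ValueError):
    """Raised for malformed or unsupported rate-law expressions."""


def num(value: float) -> Expr:
    return ("num", float(value))


def sym(name: str) -> Expr:
    return ("sym", name)


def _is_num(e: Expr, value: float | None = None) -> bool:
    return e[0] == "num" and (value is None or e[1] == value)


def add(a: Expr, b: Expr) -> Expr:
    if _is_num(a, 0.0):
        return b
    if _is_num(b, 0.0):
        return a
    if _is_num(a) and _is_num(b):
        return num(a[1] + b[1])
    return ("add", a, b)


def sub(a: Expr, b: Expr) -> Expr:
    if _is_num(b, 0.0):
        return a
    if _is_num(a) and _is_num(b):
        return num(a[1] - b[1])
    if _is_num(a, 0.0):
        return neg(b)
    return ("sub", a, b)


def mul(a: Expr, b: Expr) -> Expr:
    if _is_num(a, 0.0) or _is_num(b, 0.0):
        return num(0.0)
    if _is_num(a, 1.0):
        return b
    if _is_num(b, 1.0):
        return a
    if _is_num(a) and _is_num(b):
        return num(a[1] * b[1])
    return ("mul", a, b)


def div(a: Expr, b: Expr) -> Expr:
    if _is_num(a, 0.0):
        return num(0.0)
    if _is_num(b, 1.0):
        return a
    return ("div", a, b)


def pow_(a: Expr, b: Expr) -> Expr:
    if _is_num(b, 1.0):
        return a
    if _is_num(b, 0.0):
        return num(1.0)
    if _is_num(a) and _is_num(b):
        return num(a[1] ** b[1])
    return ("pow", a, b)


def neg(a: Expr) -> Expr:
    if _is_num(a):
        return num(-a[1])
    if a[0] == "neg":
        return a[1]
    return ("neg", a)


_BINOPS = {
    ast.Add: add,
    ast.Sub: sub,
    ast.Mult: mul,
    ast.Div: div,
    ast.Pow: pow_,
}


def _convert(node: ast.AST, source: str) -> Expr:
    if isinstance(node, ast.Expression):
        return _convert(node.body, source)
    if isinstance(node, ast.Constant):
        if isinstance(node.value, (int, float)) and not isinstance(node.value, bool):
            return num(node.value)
        raise ExprError(f"non-numeric constant {node.value!r} in {source!r}")
    if isinstance(node, ast.Name):
        return sym(node.id)
    if isinstance(node, ast.BinOp):
        op = _BINOPS.get(type(node.op))
        if op is None:
            raise ExprError(f"unsupported operator in {source!r}")
        return op(_convert(node.left, source), _convert(node.right, source))
    if isinstance(node, ast.UnaryOp):
        if isinstance(node.op, ast.USub):
            return neg(_convert(node.operand, source))
        if isinstance(node.op, ast.UAdd):
            return _convert(node.operand, source)
        raise ExprError(f"unsupported unary operator in {source!r}")
    raise ExprError(
        f"unsupported syntax ({type(node).__name__}) in rate law {source!r}"
    )


def parse(source: str | float | Expr) -> Expr:
    """Parse an infix formula into an expression tree.

    Accepts ``^`` as a synonym for ``**``.  Numbers and already-parsed
    trees pass through unchanged.
    """
    if isinstance(source, (int, float)):
        return num(source)
    if isinstance(source, tuple):
        return source
    text = source.replace("^", "**")
    try:
        tree = ast.parse(text, mode="eval")
    except SyntaxError as exc:
        raise ExprError(f"cannot parse rate law {source!r}: {exc}") from exc
    return _convert(tree, source)


def symbols(e: Expr) -> set[str]:
    """All symbol names referenced by the expression."""
    kind = e[0]
    if kind == "sym":
        return {e[1]}
    if kind == "num":
        return set()
    out: set[str] = set()
    for child in e[1:]:
        out |= symbols(child)
    return out


def evaluate(e: Expr, env: Mapping[str, float]) -> float:
    kind = e[0]
    if kind == "num":
        return e[1]
    if kind == "sym":
        try:
            return env[e[1]]
        except KeyError:
            raise ExprError(f"undefined symbol {e[1]!r}") from None
    if kind == "neg":
        return -evaluate(e[1], env)
    a = evaluate(e[1], env)
    b = evaluate(e[2], env)
    if kind == "add":
        return a + b
    if kind == "sub":
        return a - b
    if kind == "mul":
        return a * b
    if kind == "div":
        if b == 0.0:
            raise ZeroDivisionError("division by zero in rate law")
        return a / b
    if kind == "pow":
        return a**b
    raise ExprError(f"unknown node kind {kind!r}")


def diff(e: Expr, var: str) -> Expr:
    """Analytic partial derivative d(e)/d(var)."""
    kind = e[0]
    if kind == "num":
        return num(0.0)
    if kind == "sym":
        return num(1.0) if e[1] == var else num(0.0)
    if kind == "neg":
        return neg(diff(e[1], var))
    a, b = e[1], e[2]
    da, db = diff(a, var), diff(b, var)
    if kind == "add":
        return add(da, db)
    if kind == "sub":
        return sub(da, db)
    if kind == "mul":
        return add(mul(da, b), mul(a, db))
    if kind == "div":
        # (a/b)' = a'/b - a b' / b^2
        return sub(div(da, b), div(mul(a, db), mul(b, b)))
    if kind == "pow":
        if _is_num(b):
            # d(a^c) = c a^(c-1) a'
            return mul(mul(b, pow_(a, num(b[1] - 1.0))), da)
        if db == num(0.0):
            return mul(mul(b, pow_(a, sub(b, num(1.0)))), da)
        raise ExprError("differentiation of symbolic exponents is not supported")
    raise ExprError(f"unknown node kind {kind!r}")


def to_source(e: Expr, name_map: Mapping[str, str] | None = None) -> str:
    """Render the tree back to Python source.

    ``name_map`` rewrites symbol names, e.g. to array subscripts when
    compiling a vectorised function.
    """
    kind = e[0]
    if kind == "num":
        return repr(e[1])
    if kind == "sym":
        return name_map[e[1]] if name_map else e[1]
    if kind == "neg":
        return f"(-{to_source(e[1], name_map)})"
    a = to_source(e[1], name_map)
    b = to_source(e[2], name_map)
    op = {"add": "+", "sub": "-", "mul": "*", "div": "/", "pow": "**"}[kind]
    return f"({a} {op} {b})"


def compile_expr(
    e: Expr, args: Iterable[str], name_map: Mapping[str, str] | None = None
) -> Callable[..., float]:
    """Compile a tree into a Python function of ``args``.

    The generated source contains only arithmetic over the declared
    argument names (optionally rewritten by ``name_map``); nothing else is
    in scope.
    """
    src = f"def _f({', '.join(args)}):\n    return {to_source(e, name_map)}\n"
    namespace: dict = {"__builtins__": {}, "math": math}
    exec(compile(src, "<rate-law>", "exec"), namespace)
    return namespace["_f"]
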