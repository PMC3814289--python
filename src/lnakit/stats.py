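"""Noise statistics over an LNA result and constrained objectives for the
closed loop.

Objectives are arithmetic expressions over the statistics ``var(X)``,
``cov(X, Y)``, ``corr(X, Y)``, ``cv(X)``, ``fano(X)`` and ``mean(X)``,
evaluated on a single LNA computation per candidate parameter set.
Steady-state particle-number constraints (absolute, or relative to the
unmodified model's reference means — "within 50%–200% of their original
values") gate feasibility.  Inside the closed loop nothing raises: a
failed steady state, an unstable fixed point or a violated constraint is
encoded as an infeasible evaluation with a sentinel objective value that
any optimiser treats as always-worse.
"""

from __future__ import annotations

import ast
import math
from dataclasses import dataclass, field

import numpy as np

from .lna import LNAError, LNAResult, lna
from .model import ModelError, ReactionNetwork
from .steady_state import SteadyStateError

__all__ = [
    "StatisticError",
    "Constraint",
    "ObjectiveSpec",
    "ObjectiveEvaluation",
    "statistic",
    "reference_means",
    "evaluate_objective",
]


class StatisticError(ValueError):
    """A statistic is undefined for the given result (zero variance,
    non-positive mean, unknown species...)."""


@dataclass(frozen=True)
class Constraint:
    """Bounds on a species' steady-state particle number.

    With ``relative=True`` the bounds are fractions of the reference
    (original-model) steady-state value, e.g. ``lower=0.5, upper=2.0``
    for the 50%–200% window.
    """

    species: str
    lower: float | None = None
    upper: float | None = None
    relative: bool = False

    def __post_init__(self) -> None:
        if self.lower is not None and self.upper is not None:
            if self.lower > self.upper:
                raise ValueError(f"constraint on {self.species!r}: lower > upper")

    def bounds(self, reference: float | None) -> tuple[float, float]:
        lo = -np.inf if self.lower is None else self.lower
        hi = np.inf if self.upper is None else self.upper
        if self.relative:
            if reference is None:
                raise StatisticError(
                    f"relative constraint on {self.species!r} needs a reference value"
                )
            lo, hi = lo * reference, hi * reference
        return float(lo), float(hi)


@dataclass
class ObjectiveSpec:
    """A noise statistic (or expression of statistics) to optimise."""

    expression: str
    direction: str = "maximise"  # or "minimise"
    constraints: list[Constraint] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.direction not in ("maximise", "minimise"):
            raise ValueError(f"unknown direction {self.direction!r}")

    @property
    def sentinel(self) -> float:
        return -math.inf if self.direction == "maximise" else math.inf


def _species_arg(node: ast.AST, source: str) -> str:
    if isinstance(node, ast.Name):
        return node.id
    if isinstance(node, ast.Constant) and isinstance(node.value, str):
        return node.value
    raise StatisticError(f"expected a species name in {source!r}")


def _stat_value(result: LNAResult, fname: str, args: list[str]) -> float:
    def var(i):
        return result.variance(i)

    def mean(i):
        return result.mean(i)

    if fname in ("var", "variance"):
        (i,) = args
        return var(i)
    if fname in ("cov", "covariance"):
        i, j = args
        return result.covariance(i, j)
    if fname in ("corr", "correlation", "rho"):
        i, j = args
        vi, vj = var(i), var(j)
        if vi <= 0 or vj <= 0:
            raise StatisticError(
                f"correlation({i},{j}) undefined: a variance is not positive"
            )
        return result.covariance(i, j) / math.sqrt(vi * vj)
    if fname == "cv":
        (i,) = args
        m = mean(i)
        if m <= 0:
            raise StatisticError(f"cv({i}) undefined: mean is not positive")
        return math.sqrt(max(var(i), 0.0)) / m
    if fname == "fano":
        (i,) = args
        m = mean(i)
        if m <= 0:
            raise StatisticError(f"fano({i}) undefined: mean is not positive")
        return var(i) / m
    if fname == "mean":
        (i,) = args
        return mean(i)
    raise StatisticError(f"unknown statistic {fname!r}")


_ARITY = {
    "var": 1, "variance": 1, "cov": 2, "covariance": 2,
    "corr": 2, "correlation": 2, "rho": 2, "cv": 1, "fano": 1, "mean": 1,
}


def _eval_node(node: ast.AST, result: LNAResult, source: str) -> float:
    if isinstance(node, ast.Expression):
        return _eval_node(node.body, result, source)
    if isinstance(node, ast.Constant) and isinstance(node.value, (int, float)):
        return float(node.value)
    if isinstance(node, ast.Call):
        if not isinstance(node.func, ast.Name) or node.func.id not in _ARITY:
            raise StatisticError(f"unknown function in statistic {source!r}")
        fname = node.func.id
        args = [_species_arg(a, source) for a in node.args]
        if len(args) != _ARITY[fname]:
            raise StatisticError(
                f"{fname} takes {_ARITY[fname]} species argument(s) in {source!r}"
            )
        return _stat_value(result, fname, args)
    if isinstance(node, ast.BinOp):
        a = _eval_node(node.left, result, source)
        b = _eval_node(node.right, result, source)
        if isinstance(node.op, ast.Add):
            return a + b
        if isinstance(node.op, ast.Sub):
            return a - b
        if isinstance(node.op, ast.Mult):
            return a * b
        if isinstance(node.op, ast.Div):
            if b == 0:
                raise StatisticError(f"division by zero in statistic {source!r}")
            return a / b
        if isinstance(node.op, ast.Pow):
            return a**b
        raise StatisticError(f"unsupported operator in {source!r}")
    if isinstance(node, ast.UnaryOp) and isinstance(node.op, ast.USub):
        return -_eval_node(node.operand, result, source)
    raise StatisticError(f"unsupported syntax in statistic {source!r}")


def statistic(result: LNAResult, spec: "ObjectiveSpec | str") -> float:
    """Evaluate a statistic expression against an LNA result."""
    source = spec.expression if isinstance(spec, ObjectiveSpec) else spec
    try:
        tree = ast.parse(source, mode="eval")
    except SyntaxError as exc:
        raise StatisticError(f"cannot parse statistic {source!r}: {exc}") from exc
    return _eval_node(tree, result, source)


def validate_statistic(net: ReactionNetwork, expression: str) -> None:
    """Check species names and arity without running an LNA."""
    tree = ast.parse(expression, mode="eval")
    for node in ast.walk(tree):
        if isinstance(node, ast.Call):
            if not isinstance(node.func, ast.Name) or node.func.id not in _ARITY:
                raise StatisticError(f"unknown function in statistic {expression!r}")
            for a in node.args:
                sp = _species_arg(a, expression)
                if sp not in net.species_index:
                    raise StatisticError(
                        f"statistic {expression!r} references unknown species {sp!r}"
                    )


def reference_means(net: ReactionNetwork) -> dict[str, float]:
    """Steady-state particle numbers of the unmodified model — the
    reference values that relative constraints are measured against."""
    result = lna(net)
    return dict(zip(net.species_ids, map(float, result.means)))


@dataclass
class ObjectiveEvaluation:
    value: float
    feasible: bool
    reason: str = ""
    result: LNAResult | None = None


def evaluate_objective(
    net: ReactionNetwork,
    assignment: dict[str, float],
    objective: ObjectiveSpec,
    references: dict[str, float] | None = None,
) -> ObjectiveEvaluation:
    """One closed-loop evaluation: set parameters → LNA → statistic,
    with constraint checking.

    Returns an infeasible evaluation carrying the objective's sentinel
    value (±∞) instead of raising, for every failure mode the loop can
    encounter: no steady state, unstable steady state, violated
    constraint, undefined statistic.
    """
    if references is None and any(c.relative for c in objective.constraints):
        references = reference_means(net)
    try:
        result = lna(net, assignment or None)
    except (SteadyStateError, LNAError) as exc:
        return ObjectiveEvaluation(objective.sentinel, False, str(exc))
    for c in objective.constraints:
        if c.species not in net.species_index:
            raise ModelError(f"constraint references unknown species {c.species!r}")
        ref = references.get(c.species) if references else None
        try:
            lo, hi = c.bounds(ref)
        except StatisticError as exc:
            return ObjectiveEvaluation(objective.sentinel, False, str(exc))
        n = result.mean(c.species)
        if not (lo <= n <= hi):
            return ObjectiveEvaluation(
                objective.sentinel,
                False,
                f"constraint violated: {c.species} = {n:.4g} ∉ [{lo:.4g}, {hi:.4g}]",
                result,
            )
    try:
        value = statistic(result, objective)
    except StatisticError as exc:
        return ObjectiveEvaluation(objective.sentinel, False, str(exc), result)
    if not np.isfinite(value):
        return ObjectiveEvaluation(
            objective.sentinel, False, "non-finite statistic", result
        )
    return ObjectiveEvaluation(float(value), True, "", result)
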