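"""Parameter scanning and stochastic global optimisation.

Grid scans evaluate a statistic over a regular parameter grid with the
full closed loop (steady state → LNA → statistic) at every point;
infeasible points are flagged rather than dropped.  Two population-based
global optimisers are provided: global-best particle swarm (standard
constriction coefficients) and classical self-adaptive evolutionary
programming with tournament survivor selection.  Both minimise a plain
callable over box bounds, are fully deterministic under a seed, and
never evaluate outside the declared bounds.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .model import ParameterRange, ReactionNetwork
from .stats import ObjectiveSpec, evaluate_objective, reference_means, validate_statistic

__all__ = [
    "ScanResult",
    "OptimizationResult",
    "scan",
    "particle_swarm",
    "evolutionary_programming",
    "optimise",
]

log = logging.getLogger(__name__)


@dataclass
class ScanResult:
    """A statistic over a regular grid.

    ``values`` has one axis per scanned parameter, in range order
    (row-major: the first parameter varies slowest when flattened).
    """

    parameters: list[str]
    grids: list[np.ndarray]
    values: np.ndarray
    feasible: np.ndarray

    def argbest(self, direction: str = "maximise") -> tuple[dict[str, float], float]:
        """Best feasible grid point and its value."""
        vals = np.where(self.feasible, self.values, np.nan)
        if np.all(np.isnan(vals)):
            raise ValueError("no feasible grid point")
        idx = (
            np.unravel_index(np.nanargmax(vals), vals.shape)
            if direction == "maximise"
            else np.unravel_index(np.nanargmin(vals), vals.shape)
        )
        point = {p: float(g[i]) for p, g, i in zip(self.parameters, self.grids, idx)}
        return point, float(vals[idx])


def scan(
    net: ReactionNetwork,
    objective: ObjectiveSpec | str,
    ranges: Sequence[ParameterRange],
    points_per_dim: int | Sequence[int],
) -> ScanResult:
    """Evaluate a statistic over a regular grid of parameter values."""
    if isinstance(objective, str):
        objective = ObjectiveSpec(expression=objective)
    validate_statistic(net, objective.expression)
    if isinstance(points_per_dim, int):
        points_per_dim = [points_per_dim] * len(ranges)
    if any(p < 2 for p in points_per_dim):
        raise ValueError("need at least 2 points per scanned dimension")
    for r in ranges:
        if r.upper <= r.lower:
            raise ValueError(f"degenerate range for {r.path!r}")
    grids = [
        np.linspace(r.lower, r.upper, p) for r, p in zip(ranges, points_per_dim)
    ]
    shape = tuple(points_per_dim)
    values = np.full(shape, np.nan)
    feasible = np.zeros(shape, dtype=bool)
    references = (
        reference_means(net) if any(c.relative for c in objective.constraints) else None
    )
    for idx in itertools.product(*(range(p) for p in points_per_dim)):
        assignment = {r.path: float(g[i]) for r, g, i in zip(ranges, grids, idx)}
        ev = evaluate_objective(net, assignment, objective, references)
        values[idx] = ev.value if ev.feasible else np.nan
        feasible[idx] = ev.feasible
        log.debug("scan %s -> %s (%s)", assignment, ev.value, ev.reason or "ok")
    return ScanResult(
        parameters=[r.path for r in ranges],
        grids=grids,
        values=values,
        feasible=feasible,
    )


@dataclass
class OptimizationResult:
    """Outcome of a stochastic optimisation run."""

    best_parameters: dict[str, float]
    best_value: float
    evaluation_count: int
    trace: list[float]  # best-so-far per iteration
    seed: int
    termination: str
    feasible: bool
    algorithm: str = ""
    diagnostics: dict = field(default_factory=dict)


def _check_ranges(ranges: Sequence[ParameterRange]):
    lo = np.array([r.lower for r in ranges], dtype=float)
    hi = np.array([r.upper for r in ranges], dtype=float)
    if not (np.all(np.isfinite(lo)) and np.all(np.isfinite(hi))):
        raise ValueError("optimisation bounds must be finite")
    if np.any(hi <= lo):
        raise ValueError("degenerate optimisation range")
    return lo, hi


def _safe_call(fn: Callable, x: np.ndarray) -> float:
    v = fn(x)
    return float(v) if np.isfinite(v) else np.inf


_STALL_WINDOW = 80
_STALL_RTOL = 1e-6


def _stalled(trace: list[float]) -> bool:
    if len(trace) < _STALL_WINDOW or not np.isfinite(trace[-1]):
        return False
    prev = trace[-_STALL_WINDOW]
    if not np.isfinite(prev):
        return False
    return abs(prev - trace[-1]) <= _STALL_RTOL * max(abs(trace[-1]), 1e-12)


def particle_swarm(
    objective_fn: Callable[[np.ndarray], float],
    ranges: Sequence[ParameterRange],
    swarm_size: int = 50,
    max_iter: int = 200,
    seed: int = 0,
) -> OptimizationResult:
    """Global-best PSO minimising ``objective_fn`` over box bounds.

    Standard constriction parameterisation: inertia 0.729, cognitive and
    social coefficients 1.49445; velocities clamped to half the range,
    positions clipped to the bounds.  Non-finite objective values
    (infeasible closed-loop evaluations) are treated as +∞.
    """
    if swarm_size < 2:
        raise ValueError("swarm_size must be at least 2")
    lo, hi = _check_ranges(ranges)
    d = len(ranges)
    rng = np.random.default_rng(seed)
    w, c1, c2 = 0.729, 1.49445, 1.49445
    vmax = 0.5 * (hi - lo)

    x = lo + rng.random((swarm_size, d)) * (hi - lo)
    v = (rng.random((swarm_size, d)) - 0.5) * (hi - lo)
    fx = np.array([_safe_call(objective_fn, xi) for xi in x])
    evals = swarm_size
    pbest, fpbest = x.copy(), fx.copy()
    g = int(np.argmin(fpbest))
    gbest, fgbest = pbest[g].copy(), float(fpbest[g])
    trace = [fgbest]
    termination = "max_iter"
    for _ in range(max_iter):
        r1 = rng.random((swarm_size, d))
        r2 = rng.random((swarm_size, d))
        v = w * v + c1 * r1 * (pbest - x) + c2 * r2 * (gbest - x)
        v = np.clip(v, -vmax, vmax)
        x = np.clip(x + v, lo, hi)
        fx = np.array([_safe_call(objective_fn, xi) for xi in x])
        evals += swarm_size
        improved = fx < fpbest
        pbest[improved] = x[improved]
        fpbest[improved] = fx[improved]
        g = int(np.argmin(fpbest))
        if fpbest[g] < fgbest:
            gbest, fgbest = pbest[g].copy(), float(fpbest[g])
        trace.append(fgbest)
        log.debug("pso iter %d best %.6g", len(trace) - 1, fgbest)
        if _stalled(trace):
            termination = "stall"
            break
    feasible = np.isfinite(fgbest)
    return OptimizationResult(
        best_parameters={r.path: float(b) for r, b in zip(ranges, gbest)},
        best_value=fgbest if feasible else np.inf,
        evaluation_count=evals,
        trace=trace,
        seed=seed,
        termination=termination if feasible else "all_infeasible",
        feasible=bool(feasible),
        algorithm="particle_swarm",
    )


def evolutionary_programming(
    objective_fn: Callable[[np.ndarray], float],
    ranges: Sequence[ParameterRange],
    population: int = 20,
    generations: int = 200,
    seed: int = 0,
) -> OptimizationResult:
    """Classical self-adaptive (meta-)EP minimising over box bounds.

    Each individual carries per-parameter Gaussian mutation step sizes,
    log-normally self-adapted; survivors of the merged parent+offspring
    pool are chosen by stochastic tournament (q = 10% of the pool,
    at least 2 opponents).
    """
    if population < 2:
        raise ValueError("population must be at least 2")
    lo, hi = _check_ranges(ranges)
    d = len(ranges)
    rng = np.random.default_rng(seed)
    span = hi - lo
    tau = 1.0 / np.sqrt(2.0 * np.sqrt(d))
    tau_p = 1.0 / np.sqrt(2.0 * d)
    sigma_floor = 1e-8 * span

    x = lo + rng.random((population, d)) * span
    sigma = np.full((population, d), 0.1) * span
    fx = np.array([_safe_call(objective_fn, xi) for xi in x])
    evals = population
    g = int(np.argmin(fx))
    best_x, best_f = x[g].copy(), float(fx[g])
    trace = [best_f]
    termination = "max_iter"
    for _ in range(generations):
        common = rng.standard_normal((population, 1))
        sig_o = sigma * np.exp(
            tau_p * common + tau * rng.standard_normal((population, d))
        )
        sig_o = np.maximum(sig_o, sigma_floor)
        x_o = np.clip(x + sig_o * rng.standard_normal((population, d)), lo, hi)
        f_o = np.array([_safe_call(objective_fn, xi) for xi in x_o])
        evals += population
        pool_x = np.vstack([x, x_o])
        pool_s = np.vstack([sigma, sig_o])
        pool_f = np.concatenate([fx, f_o])
        q = max(2, round(0.1 * len(pool_f)))
        wins = np.zeros(len(pool_f))
        for i in range(len(pool_f)):
            opponents = rng.integers(0, len(pool_f), size=q)
            wins[i] = np.sum(pool_f[i] <= pool_f[opponents])
        order = np.lexsort((pool_f, -wins))[:population]
        x, sigma, fx = pool_x[order], pool_s[order], pool_f[order]
        g = int(np.argmin(fx))
        if fx[g] < best_f:
            best_x, best_f = x[g].copy(), float(fx[g])
        trace.append(best_f)
        log.debug("ep gen %d best %.6g", len(trace) - 1, best_f)
        if _stalled(trace):
            termination = "stall"
            break
    feasible = np.isfinite(best_f)
    return OptimizationResult(
        best_parameters={r.path: float(b) for r, b in zip(ranges, best_x)},
        best_value=best_f if feasible else np.inf,
        evaluation_count=evals,
        trace=trace,
        seed=seed,
        termination=termination if feasible else "all_infeasible",
        feasible=bool(feasible),
        algorithm="evolutionary_programming",
    )


_ALGORITHMS = {
    "particle_swarm": particle_swarm,
    "pso": particle_swarm,
    "evolutionary_programming": evolutionary_programming,
    "ep": evolutionary_programming,
}


def optimise(
    net: ReactionNetwork,
    objective: ObjectiveSpec | str,
    ranges: Sequence[ParameterRange],
    algorithm: str = "particle_swarm",
    seed: int = 0,
    **options,
) -> OptimizationResult:
    """Closed-loop optimisation of a noise statistic over parameter ranges.

    Wraps the statistic in a sign-adjusted callable (optimisers minimise),
    captures reference steady-state means once for relative constraints,
    and reports the best value back on the objective's own scale.
    """
    if isinstance(objective, str):
        objective = ObjectiveSpec(expression=objective)
    validate_statistic(net, objective.expression)
    try:
        algo = _ALGORITHMS[algorithm]
    except KeyError:
        raise ValueError(f"unknown algorithm {algorithm!r}") from None
    references = (
        reference_means(net) if any(c.relative for c in objective.constraints) else None
    )
    sign = -1.0 if objective.direction == "maximise" else 1.0
    names = [r.path for r in ranges]
    infeasible = {"count": 0, "reasons": {}}

    def fn(vec: np.ndarray) -> float:
        assignment = dict(zip(names, map(float, vec)))
        ev = evaluate_objective(net, assignment, objective, references)
        log.debug(
            "closed-loop %s -> %s (%s)", assignment, ev.value, ev.reason or "feasible"
        )
        if not ev.feasible:
            infeasible["count"] += 1
            key = ev.reason.split("(")[0].strip()
            infeasible["reasons"][key] = infeasible["reasons"].get(key, 0) + 1
            return np.inf
        return sign * ev.value

    res = algo(fn, ranges, seed=seed, **options)
    res.best_value = sign * res.best_value if res.feasible else objective.sentinel
    res.trace = [sign * t if np.isfinite(t) else objective.sentinel for t in res.trace]
    res.diagnostics["objective"] = objective.expression
    res.diagnostics["direction"] = objective.direction
    res.diagnostics["infeasible_evaluations"] = infeasible["count"]
    res.diagnostics["infeasible_reasons"] = infeasible["reasons"]
    return res
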