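"""Steady-state location and stability classification.

The LNA is evaluated about an asymptotically stable fixed point of the
reduced deterministic system.  The solver strategy is damped Newton from
the supplied starting densities; if that fails, the ODEs are integrated
over progressively longer horizons with a stiff adaptive integrator and
Newton is restarted from each endpoint.  A clean "no steady state found"
failure is raised otherwise — the closed loop converts it into an
infeasible-evaluation penalty rather than a crash.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .conservation import ReducedSystem, reduce
from .model import ReactionNetwork

__all__ = [
    "SteadyState",
    "SteadyStateError",
    "find_steady_state",
    "assess_stability",
    "find_instability_point",
]


class SteadyStateError(RuntimeError):
    """No acceptable steady state could be located."""


@dataclass
class SteadyState:
    """A fixed point of the reduced system plus derived quantities.

    ``x_red`` holds the K independent densities; ``x_full`` all K̂
    densities in the network's declared order (dependent species
    reconstructed through the conservation relations).
    """

    x_red: np.ndarray
    x_full: np.ndarray
    mean_particles: np.ndarray
    residual: float
    jacobian: np.ndarray
    eigenvalues: np.ndarray
    stable: bool

    @property
    def max_real_eigenvalue(self) -> float:
        return float(np.max(self.eigenvalues.real))


def assess_stability(A: np.ndarray) -> tuple[np.ndarray, bool]:
    """Eigenvalues of a drift matrix and asymptotic stability.

    Stable means every eigenvalue has strictly negative real part; a
    purely imaginary pair (Hopf point) is classified unstable since the
    stationary covariance is undefined there.
    """
    A = np.asarray(A, dtype=float)
    if not np.all(np.isfinite(A)):
        raise ValueError("non-finite drift matrix")
    eig = np.linalg.eigvals(A)
    return eig, bool(np.max(eig.real) < 0)


def _newton(reduced: ReducedSystem, x0, params, tol, max_iter=60):
    x = np.asarray(x0, dtype=float).copy()
    for _ in range(max_iter):
        r = reduced.rhs(x, params)
        scale = max(
            1e-300,
            float(
                np.max(
                    np.abs(
                        reduced.network.macroscopic_rates(
                            np.clip(reduced.full_densities(x), 0, None), params
                        )
                    )
                )
            ),
            1.0,
        )
        if np.max(np.abs(r)) < tol * scale:
            return x
        J = reduced.drift_jacobian(x, params)
        try:
            step = np.linalg.solve(J, -r)
        except np.linalg.LinAlgError:
            step, *_ = np.linalg.lstsq(J, -r, rcond=None)
        # damp the step to keep all (full) densities non-negative and the
        # residual non-increasing
        lam = 1.0
        r0 = float(np.linalg.norm(r))
        while lam > 1e-10:
            x_new = x + lam * step
            full = reduced.full_densities(x_new)
            if np.min(full) >= -1e-12:
                try:
                    r_new = float(np.linalg.norm(reduced.rhs(x_new, params)))
                except Exception:
                    r_new = np.inf
                if np.isfinite(r_new) and (r_new < r0 or lam < 1e-6):
                    break
            lam *= 0.5
        else:
            return None
        x = x + lam * step
    # converged only if the residual test passes
    r = reduced.rhs(x, params)
    scale = max(1.0, float(np.max(np.abs(r))) if r.size else 1.0)
    return x if np.max(np.abs(r)) < tol * scale else None


def find_steady_state(
    reduced: ReducedSystem,
    x0=None,
    params=None,
    tol: float = 1e-9,
    require_stable: bool = False,
) -> SteadyState:
    """Locate a steady state of the reduced deterministic system.

    Parameters
    ----------
    reduced : ReducedSystem
    x0 : array-like, optional
        Starting independent densities; defaults to the model's initial
        densities.
    tol : float
        Residual tolerance, relative to the characteristic flux magnitude.
    require_stable : bool
        If true, an unstable fixed point raises :class:`SteadyStateError`.
    """
    if x0 is None:
        x0 = reduced.reduced_initial_densities()
    x0 = np.asarray(x0, dtype=float)
    if np.any(x0 < 0):
        raise ValueError("starting densities must be non-negative")

    x = _newton(reduced, x0, params, tol)
    if x is None:
        # integrate towards the attractor, retrying Newton from endpoints
        rhs = lambda t, y: reduced.rhs(y, params)
        y = x0
        for horizon in (1e2, 1e4, 1e6):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                sol = solve_ivp(
                    rhs, (0.0, horizon), y, method="LSODA", rtol=1e-8, atol=1e-10
                )
            if not sol.success:
                break
            y = np.clip(sol.y[:, -1], 0.0, None)
            x = _newton(reduced, y, params, tol)
            if x is not None:
                break
    if x is None:
        raise SteadyStateError("no steady state found")

    x_full = reduced.full_densities(x)
    if np.min(x_full) < -1e-12:
        raise SteadyStateError("steady state has negative densities")
    x_full = np.clip(x_full, 0.0, None)
    A = reduced.drift_jacobian(x, params)
    eig, stable = assess_stability(A)
    if require_stable and not stable:
        raise SteadyStateError(
            f"steady state is unstable (max Re(λ) = {np.max(eig.real):.3g})"
        )
    residual = float(np.max(np.abs(reduced.rhs(x, params))))
    return SteadyState(
        x_red=x,
        x_full=x_full,
        mean_particles=reduced.network.system_size * x_full,
        residual=residual,
        jacobian=A,
        eigenvalues=eig,
        stable=stable,
    )


def _max_real_eig(net: ReactionNetwork, param: str, value: float, x_start=None):
    reduced = reduce(net.with_parameters({param: value}))
    ss = find_steady_state(reduced, x0=x_start)
    return ss.max_real_eigenvalue, ss


def find_instability_point(
    net: ReactionNetwork,
    param: str,
    interval: tuple[float, float],
    tol: float = 1e-4,
) -> float:
    """Bisect for the parameter value where the steady state loses
    stability (max Re(λ) crosses zero), e.g. at a Hopf bifurcation.

    Raises if the stability does not change sign across ``interval``.
    Steady states are tracked by warm-starting each solve from the
    previous endpoint's solution.
    """
    lo, hi = float(interval[0]), float(interval[1])
    f_lo, ss_lo = _max_real_eig(net, param, lo)
    f_hi, ss_hi = _max_real_eig(net, param, hi, ss_lo.x_red)
    if np.sign(f_lo) == np.sign(f_hi):
        raise ValueError(
            f"max Re(λ) does not change sign over [{lo}, {hi}] "
            f"({f_lo:.3g} vs {f_hi:.3g})"
        )
    x_warm = ss_lo.x_red
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        f_mid, ss_mid = _max_real_eig(net, param, mid, x_warm)
        x_warm = ss_mid.x_red
        if np.sign(f_mid) == np.sign(f_lo):
            lo, f_lo = mid, f_mid
        else:
            hi, f_hi = mid, f_mid
    return 0.5 * (lo + hi)
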