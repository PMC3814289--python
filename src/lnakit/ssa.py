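"""Exact stochastic simulation (Gillespie Direct Method) and stationary
moment estimation.

The Direct Method samples the chemical master equation exactly: waiting
times are exponential in the total propensity and the next reaction is
chosen with probability T_μ/ΣT.  Stationary means and covariances are
time-weighted (ergodic) averages over one long trajectory after a
burn-in, with batch-means standard errors.  This is the independent
oracle against which the LNA covariances are validated.

The inner loop is compiled with numba when available (the rate-law
expression tree is code-generated into a jittable propensity function);
a pure-Python loop with chunked random-number draws is the fallback.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import expr as ex
from .model import ModelError, ReactionNetwork, stoichiometry_matrix

__all__ = [
    "Trajectory",
    "MomentEstimate",
    "ComparisonReport",
    "gillespie_direct",
    "stationary_moments",
    "simulate_moments",
    "compare_lna_ssa",
]

_CHUNK = 1 << 20


@dataclass
class Trajectory:
    """One SSA realisation: state after each reaction event.

    ``times[0] = 0`` with the initial state; ``absorbed`` marks an early
    stop because every propensity vanished.
    """

    times: np.ndarray
    states: np.ndarray  # (n_events+1, K̂) integer counts
    seed: int
    t_end: float
    absorbed: bool
    species_ids: list[str]

    @property
    def n_events(self) -> int:
        return len(self.times) - 1


@dataclass
class MomentEstimate:
    """Time-weighted stationary moments of a trajectory window."""

    mean: np.ndarray
    cov: np.ndarray
    std_error: np.ndarray  # batch-means SE per covariance entry
    mean_std_error: np.ndarray
    window: float  # t_end − burn_in actually averaged
    burn_in: float
    n_blocks: int


@dataclass
class ComparisonReport:
    """Per-entry LNA vs SSA covariance comparison."""

    species_ids: list[str]
    lna_cov: np.ndarray
    ssa_cov: np.ndarray
    ssa_std_error: np.ndarray
    lna_mean: np.ndarray
    ssa_mean: np.ndarray
    seed: int
    t_end: float
    burn_in: float

    @property
    def relative_difference(self) -> np.ndarray:
        return (self.ssa_cov - self.lna_cov) / self.lna_cov

    @property
    def max_abs_relative_difference(self) -> float:
        return float(np.max(np.abs(self.relative_difference)))


# -- propensity compilation --------------------------------------------------


def _props_source(net: ReactionNetwork) -> str:
    nm = net._name_map()
    lines = ["def _props(x, p, out):"]
    for mu, r in enumerate(net.reactions):
        lines.append(f"    out[{mu}] = {ex.to_source(r.rate_expression(), nm)}")
    lines.append("    return out")
    return "\n".join(lines)


def _compile_props(net: ReactionNetwork, jit: bool):
    ns: dict = {"__builtins__": {}}
    exec(compile(_props_source(net), "<propensities>", "exec"), ns)
    fn = ns["_props"]
    if jit:
        import numba

        fn = numba.njit(fn, cache=False)
    return fn


def _get_kernels(jit: bool):
    """Build (and cache) the SSA loop kernels, optionally numba-compiled."""
    key = "jit" if jit else "py"
    if key in _KERNELS:
        return _KERNELS[key]

    def _traj_kernel(props, nu, n, p, omega, t0, t_end, times, states, seed_state):
        # simulate up to len(times) events or t_end; returns (count, t, absorbed)
        M, K = nu.shape[1], nu.shape[0]
        out = np.empty(M)
        t = t0
        count = 0
        cap = times.shape[0]
        x = np.empty(K)
        while t < t_end and count < cap:
            for i in range(K):
                x[i] = n[i] / omega
            props(x, p, out)
            a0 = 0.0
            for mu in range(M):
                v = omega * out[mu]
                if v < 0.0:
                    v = 0.0
                out[mu] = v
                a0 += v
            if a0 <= 0.0:
                return count, t, True
            u1 = np.random.random()
            u2 = np.random.random()
            t = t - np.log(u1) / a0
            if t > t_end:
                return count, t_end, False
            target = u2 * a0
            acc = 0.0
            mu = 0
            for j in range(M):
                acc += out[j]
                if acc >= target:
                    mu = j
                    break
            for i in range(K):
                n[i] += nu[i, mu]
            times[count] = t
            for i in range(K):
                states[count, i] = n[i]
            count += 1
        return count, t, False

    def _moment_kernel(
        props, nu, n, p, omega, t_end, burn_in, S, Q, Tw, S_tot, Q_tot
    ):
        # time-weighted accumulation into batch blocks; returns (t, absorbed,
        # total_window).  S[b,i] = ∫ n_i dt, Q[b,i,j] = ∫ n_i n_j dt per block.
        M, K = nu.shape[1], nu.shape[0]
        B = Tw.shape[0]
        block_len = (t_end - burn_in) / B
        out = np.empty(M)
        x = np.empty(K)
        t = 0.0
        absorbed = False
        while t < t_end:
            for i in range(K):
                x[i] = n[i] / omega
            props(x, p, out)
            a0 = 0.0
            for mu in range(M):
                v = omega * out[mu]
                if v < 0.0:
                    v = 0.0
                out[mu] = v
                a0 += v
            if a0 <= 0.0:
                t_next = t_end
                absorbed = True
            else:
                u1 = np.random.random()
                t_next = t - np.log(u1) / a0
                if t_next > t_end:
                    t_next = t_end
            # accumulate the holding interval clipped to (burn_in, t_end]
            lo = t if t > burn_in else burn_in
            if t_next > lo:
                w = t_next - lo
                b = int((lo - burn_in) / block_len)
                if b >= B:
                    b = B - 1
                Tw[b] += w
                for i in range(K):
                    ni = n[i]
                    S[b, i] += w * ni
                    S_tot[i] += w * ni
                    for j in range(K):
                        Q[b, i, j] += w * ni * n[j]
                        Q_tot[i, j] += w * ni * n[j]
            if absorbed or t_next >= t_end:
                return t_next, absorbed
            t = t_next
            u2 = np.random.random()
            target = u2 * a0
            acc = 0.0
            mu = 0
            for j in range(M):
                acc += out[j]
                if acc >= target:
                    mu = j
                    break
            for i in range(K):
                n[i] += nu[i, mu]
        return t, absorbed

    def _seed(s):
        np.random.seed(s)

    if jit:
        import numba

        _traj_kernel = numba.njit(_traj_kernel, cache=False)
        _moment_kernel = numba.njit(_moment_kernel, cache=False)
        # numba's np.random state is separate from numpy's; seed inside jit
        _seed = numba.njit(_seed, cache=False)
    _KERNELS[key] = (_traj_kernel, _moment_kernel, _seed)
    return _KERNELS[key]


_KERNELS: dict = {}


def _prepare(net: ReactionNetwork, n0):
    nu = stoichiometry_matrix(net).astype(np.float64)
    if n0 is None:
        n0 = np.round(net.system_size * net.initial_densities())
    n0 = np.asarray(n0, dtype=np.float64)
    if np.any(n0 < 0) or np.any(n0 != np.round(n0)):
        raise ModelError("initial particle numbers must be non-negative integers")
    p = net._param_vector()
    return nu, n0.copy(), p


def _use_jit(net: ReactionNetwork, jit: bool | None) -> bool:
    if jit is False:
        return False
    try:
        import numba  # noqa: F401

        return True
    except Exception:
        if jit is True:
            raise
        return False


def gillespie_direct(
    net: ReactionNetwork,
    n0=None,
    t_end: float = 100.0,
    seed: int = 0,
    max_events: int = 10_000_000,
    jit: bool | None = None,
) -> Trajectory:
    """Simulate one exact SSA trajectory.

    ``n0`` defaults to the rounded initial particle numbers Ω·x(0).
    Recording stops at ``t_end``, at ``max_events`` events, or when the
    system absorbs (all propensities zero).
    """
    nu, n, p = _prepare(net, n0)
    use_jit = _use_jit(net, jit)
    props = _compile_props(net, use_jit)
    traj_kernel, _, seed_fn = _get_kernels(use_jit)
    seed_fn(seed % (2**32))
    all_times = [np.array([0.0])]
    all_states = [n.copy()[None, :]]
    t = 0.0
    absorbed = False
    remaining = max_events
    while t < t_end and remaining > 0:
        cap = min(_CHUNK, remaining)
        times = np.empty(cap)
        states = np.empty((cap, net.n_species))
        count, t, absorbed = traj_kernel(
            props, nu, n, p, net.system_size, t, t_end, times, states, None
        )
        if count:
            all_times.append(times[:count])
            all_states.append(states[:count])
        remaining -= count
        if absorbed:
            break
        if count == 0:
            break
    return Trajectory(
        times=np.concatenate(all_times),
        states=np.concatenate(all_states).astype(np.int64),
        seed=seed,
        t_end=t_end,
        absorbed=absorbed,
        species_ids=net.species_ids,
    )


def stationary_moments(traj: Trajectory, burn_in: float | None = None) -> MomentEstimate:
    """Time-weighted stationary moments of a recorded trajectory.

    The state is piecewise constant between events; moments are averages
    over (burn_in, t_end].  ``burn_in`` defaults to 10% of the horizon.
    """
    if burn_in is None:
        burn_in = 0.1 * traj.t_end
    if burn_in >= traj.t_end:
        raise ValueError("burn_in must be smaller than the trajectory horizon")
    times = np.append(traj.times, traj.t_end)
    starts = np.clip(times[:-1], burn_in, None)
    ends = np.clip(times[1:], burn_in, None)
    w = ends - starts
    total = w.sum()
    if total <= 0:
        raise ValueError("empty averaging window after burn-in")
    X = traj.states.astype(float)
    mean = (w @ X) / total
    Xc = X - mean
    cov = (Xc.T * w) @ Xc / total
    # batch-means standard errors over 20 equal-time blocks
    B = 20
    edges = np.linspace(burn_in, traj.t_end, B + 1)
    block_covs = np.empty((B, X.shape[1], X.shape[1]))
    block_means = np.empty((B, X.shape[1]))
    for b in range(B):
        s = np.clip(times[:-1], edges[b], edges[b + 1])
        e = np.clip(times[1:], edges[b], edges[b + 1])
        wb = e - s
        tb = wb.sum()
        if tb <= 0:
            block_means[b] = mean
            block_covs[b] = cov
            continue
        mb = (wb @ X) / tb
        Xb = X - mb
        block_covs[b] = (Xb.T * wb) @ Xb / tb
        block_means[b] = mb
    se = block_covs.std(axis=0, ddof=1) / np.sqrt(B)
    mse = block_means.std(axis=0, ddof=1) / np.sqrt(B)
    return MomentEstimate(
        mean=mean,
        cov=cov,
        std_error=se,
        mean_std_error=mse,
        window=float(total),
        burn_in=float(burn_in),
        n_blocks=B,
    )


def simulate_moments(
    net: ReactionNetwork,
    t_end: float,
    burn_in: float | None = None,
    seed: int = 0,
    n0=None,
    n_blocks: int = 20,
    jit: bool | None = None,
) -> MomentEstimate:
    """Run the SSA accumulating stationary moments online (no trajectory
    storage) — the memory-safe route for very long horizons."""
    if burn_in is None:
        burn_in = 0.1 * t_end
    if burn_in >= t_end:
        raise ValueError("burn_in must be smaller than t_end")
    nu, n, p = _prepare(net, n0)
    use_jit = _use_jit(net, jit)
    props = _compile_props(net, use_jit)
    _, moment_kernel, seed_fn = _get_kernels(use_jit)
    seed_fn(seed % (2**32))
    K = net.n_species
    S = np.zeros((n_blocks, K))
    Q = np.zeros((n_blocks, K, K))
    Tw = np.zeros(n_blocks)
    S_tot = np.zeros(K)
    Q_tot = np.zeros((K, K))
    moment_kernel(
        props, nu, n, p, net.system_size, t_end, burn_in, S, Q, Tw, S_tot, Q_tot
    )
    total = Tw.sum()
    if total <= 0:
        raise ValueError("empty averaging window after burn-in")
    mean = S_tot / total
    cov = Q_tot / total - np.outer(mean, mean)
    good = Tw > 0
    bm = S[good] / Tw[good, None]
    bc = Q[good] / Tw[good, None, None] - bm[:, :, None] * bm[:, None, :]
    nb = int(good.sum())
    se = bc.std(axis=0, ddof=1) / np.sqrt(nb) if nb > 1 else np.full_like(cov, np.nan)
    mse = bm.std(axis=0, ddof=1) / np.sqrt(nb) if nb > 1 else np.full_like(mean, np.nan)
    return MomentEstimate(
        mean=mean,
        cov=cov,
        std_error=se,
        mean_std_error=mse,
        window=float(total),
        burn_in=float(burn_in),
        n_blocks=nb,
    )


def compare_lna_ssa(
    net: ReactionNetwork,
    t_end: float,
    burn_in: float | None = None,
    seed: int = 0,
    jit: bool | None = None,
) -> ComparisonReport:
    """LNA covariance vs a long-run SSA estimate on the same network.

    The SSA starts from the rounded LNA steady-state particle numbers to
    shorten burn-in (unbiased at stationarity).
    """
    from .lna import lna

    result = lna(net)
    n0 = np.round(result.means)
    est = simulate_moments(
        net, t_end=t_end, burn_in=burn_in, seed=seed, n0=n0, jit=jit
    )
    return ComparisonReport(
        species_ids=net.species_ids,
        lna_cov=result.C_full,
        ssa_cov=est.cov,
        ssa_std_error=est.std_error,
        lna_mean=result.means,
        ssa_mean=est.mean,
        seed=seed,
        t_end=t_end,
        burn_in=est.burn_in,
    )
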