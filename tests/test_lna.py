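"""LNA engine: drift/diffusion matrices, Lyapunov solve, covariance
recovery and the analytic oracles the approximation must reproduce."""

import numpy as np
import pytest

from lnakit import (
    LNAError,
    birth_death,
    expand_covariance,
    find_steady_state,
    linear_chain,
    lna,
    michaelis_menten,
    reduce,
    solve_lyapunov,
)
from lnakit.lna import diffusion_B, jacobian_A


def kron_solve(A, B, omega):
    """Brute-force oracle: vectorise A C + C Aᵀ = −ΩB."""
    K = A.shape[0]
    lhs = np.kron(np.eye(K), A) + np.kron(A, np.eye(K))
    return np.linalg.solve(lhs, -omega * B.reshape(-1)).reshape(K, K)


class TestDriftDiffusion:
    def test_michaelis_menten_A(self, mm):
        red = reduce(mm)
        ss = find_steady_state(red)
        expected = np.array(
            [[-9.0, 11.0 / 9.0, 0.0], [9.0, -20.0 / 9.0, 0.0], [0.0, 1.0, -1.0]]
        )
        assert jacobian_A(red, ss.x_red) == pytest.approx(expected, rel=1e-8)

    def test_michaelis_menten_B(self, mm):
        red = reduce(mm)
        ss = find_steady_state(red)
        expected = np.array([[4.0, -3.0, 0.0], [-3.0, 4.0, -1.0], [0.0, -1.0, 2.0]])
        assert diffusion_B(red, ss.x_red) == pytest.approx(expected, rel=1e-8)

    def test_birth_death_A_and_B(self, bd):
        red = reduce(bd)
        ss = find_steady_state(red)
        assert jacobian_A(red, ss.x_red) == pytest.approx(np.array([[-0.5]]))
        # k + d·x* = 2k
        assert diffusion_B(red, ss.x_red) == pytest.approx(np.array([[10.0]]))

    def test_analytic_jacobian_matches_finite_difference(self, erk):
        red = reduce(erk)
        ss = find_steady_state(red)
        A = jacobian_A(red, ss.x_red)
        fd = np.empty_like(A)
        for j in range(red.K):
            h = 1e-6 * max(abs(ss.x_red[j]), 1e-2)
            up, dn = ss.x_red.copy(), ss.x_red.copy()
            up[j] += h
            dn[j] -= h
            fd[:, j] = (red.rhs(up) - red.rhs(dn)) / (2 * h)
        assert np.max(np.abs(A - fd)) / np.max(np.abs(A)) < 1e-6

    def test_B_equals_weighted_stoichiometry_identity(self, erk):
        red = reduce(erk)
        ss = find_steady_state(red)
        f = erk.macroscopic_rates(ss.x_full)
        direct = red.N_red @ np.diag(f) @ red.N_red.T
        assert diffusion_B(red, ss.x_red) == pytest.approx(direct, rel=1e-12)


class TestLyapunovSolve:
    def test_scalar(self):
        C = solve_lyapunov(np.array([[-1.0]]), np.array([[2.0]]), 1.0)
        assert C == pytest.approx(np.array([[1.0]]))

    def test_decoupled_diagonal(self):
        C = solve_lyapunov(np.diag([-1.0, -2.0]), np.eye(2), 2.0)
        assert C == pytest.approx(np.diag([1.0, 0.5]))

    def test_matches_kronecker_oracle_on_random_stable_systems(self, rng):
        for _ in range(50):
            K = int(rng.integers(2, 7))
            A = rng.standard_normal((K, K))
            A -= (np.max(np.linalg.eigvals(A).real) + 1.0) * np.eye(K)
            G = rng.standard_normal((K, K))
            B = G @ G.T
            C = solve_lyapunov(A, B, 1.0)
            C_ref = kron_solve(A, B, 1.0)
            assert np.max(np.abs(C - C_ref)) / np.max(np.abs(C_ref)) < 1e-8

    def test_unstable_drift_rejected(self):
        with pytest.raises(LNAError, match="unique"):
            solve_lyapunov(np.array([[1e-3]]), np.array([[1.0]]), 1.0)

    def test_marginal_drift_rejected(self):
        with pytest.raises(LNAError):
            solve_lyapunov(np.array([[0.0, 1.0], [-1.0, 0.0]]), np.eye(2), 1.0)


class TestExpandCovariance:
    def test_identity_link_is_noop(self, rng):
        C = rng.standard_normal((3, 3))
        C = C @ C.T
        assert np.array_equal(expand_covariance(C, np.eye(3)), C)

    def test_dimension_mismatch(self):
        with pytest.raises(Exception):
            expand_covariance(np.eye(3), np.eye(4)[:, :2])


class TestPipeline:
    def test_birth_death_poisson(self, bd):
        res = lna(bd)
        assert res.C_full == pytest.approx(np.array([[100.0]]))
        assert res.means == pytest.approx([100.0])

    def test_linear_chain_product_form_poisson(self):
        res = lna(linear_chain(influx=5.0, rates=(1.0, 0.5, 2.0), omega=10.0))
        C, m = res.C_full, res.means
        assert np.diag(C) == pytest.approx(m, rel=1e-8)
        off = C - np.diag(np.diag(C))
        assert np.max(np.abs(off)) < 1e-8 * np.trace(C)
        assert m == pytest.approx([50.0, 100.0, 25.0])

    def test_michaelis_menten_invariants(self, mm):
        res = lna(mm)
        C = res.C_full
        assert np.max(np.abs(C - C.T)) < 1e-12
        assert np.min(np.linalg.eigvalsh(C)) > -1e-9 * np.trace(C)
        # Lyapunov residual on the reduced system
        omega_B = mm.system_size * res.B
        resid = res.A @ res.C_red + res.C_red @ res.A.T + omega_B
        assert np.max(np.abs(resid)) < 1e-9 * np.max(np.abs(omega_B))

    def test_conserved_total_does_not_fluctuate(self, mm, erk):
        for net in (mm, erk):
            res = lna(net)
            for rel in res.reduced.relations:
                g = np.array(rel.null_vector, dtype=float)
                assert abs(g @ res.C_full @ g) < 1e-9 * np.trace(res.C_full)

    @pytest.mark.parametrize("factor", [10.0])
    def test_covariance_scales_linearly_with_system_size(self, factor):
        base = michaelis_menten(omega=100.0)
        scaled = michaelis_menten(omega=100.0 * factor)
        assert lna(scaled).C_full == pytest.approx(factor * lna(base).C_full, rel=1e-9)

    def test_reversible_network_rejected(self):
        from lnakit import build_network

        net = build_network(
            {
                "species": [{"id": "A", "initial": 1.0}, {"id": "B"}],
                "parameters": {"kf": 1.0, "kr": 1.0},
                "reactions": [
                    {"id": "r", "reactants": {"A": 1}, "products": {"B": 1},
                     "rate": "kf*A - kr*B", "reversible": True}
                ],
            }
        )
        with pytest.raises(Exception, match="split"):
            lna(net)

    def test_unstable_steady_state_raises(self, erk):
        with pytest.raises(LNAError, match="unstable"):
            lna(erk, {"V2": 0.5})
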