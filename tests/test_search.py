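"""Parameter scans and the two global optimisers."""

import numpy as np
import pytest

from lnakit import (
    ObjectiveSpec,
    ParameterRange,
    birth_death,
    evolutionary_programming,
    optimise,
    particle_swarm,
    scan,
)


def sphere(center=0.3):
    return lambda x: float(np.sum((x - center) ** 2))


BOX5 = [ParameterRange(f"p{i}", -5.0, 5.0) for i in range(5)]


class TestScan:
    def test_birth_death_variance_decreasing_in_d(self, bd):
        res = scan(bd, "var(X)", [ParameterRange("d", 0.25, 1.0)], 7)
        assert np.all(np.diff(res.values) < 0)
        assert res.feasible.all()
        # closed form var = Ωk/d
        assert res.values == pytest.approx(10 * 5.0 / res.grids[0])

    def test_infeasible_points_flagged_not_dropped(self, erk):
        res = scan(erk, "var(MKKK)", [ParameterRange("V2", 0.40, 0.50)], 6)
        assert res.values.shape == (6,)
        assert res.feasible.any() and not res.feasible.all()
        assert np.isnan(res.values[~res.feasible]).all()

    def test_grid_ordering_row_major(self, bd):
        res = scan(bd, "var(X)", [ParameterRange("k", 1.0, 2.0),
                                  ParameterRange("d", 0.5, 1.0)], [2, 3])
        assert res.values.shape == (2, 3)
        # var = Ωk/d: first axis scales with k, second with 1/d
        assert res.values[1, 0] == pytest.approx(2 * res.values[0, 0])

    def test_degenerate_range_rejected(self, bd):
        with pytest.raises(ValueError):
            scan(bd, "var(X)", [ParameterRange("d", 1.0, 1.0)], 5)


class TestParticleSwarm:
    def test_sphere_minimum_found(self):
        res = particle_swarm(sphere(), BOX5, swarm_size=50, max_iter=200, seed=3)
        assert res.best_value < 1e-6
        assert np.allclose(list(res.best_parameters.values()), 0.3, atol=1e-3)

    def test_same_seed_identical_traces(self):
        a = particle_swarm(sphere(), BOX5, swarm_size=20, max_iter=50, seed=11)
        b = particle_swarm(sphere(), BOX5, swarm_size=20, max_iter=50, seed=11)
        assert a.trace == b.trace
        assert a.best_parameters == b.best_parameters

    def test_candidates_stay_in_bounds(self):
        seen = []

        def recorder(x):
            seen.append(x.copy())
            return sphere()(x)

        ranges = [ParameterRange("a", 0.0, 1.0), ParameterRange("b", -2.0, -1.0)]
        particle_swarm(recorder, ranges, swarm_size=10, max_iter=30, seed=5)
        pts = np.array(seen)
        assert pts[:, 0].min() >= 0.0 and pts[:, 0].max() <= 1.0
        assert pts[:, 1].min() >= -2.0 and pts[:, 1].max() <= -1.0

    def test_trace_monotone_nonworsening(self):
        res = particle_swarm(sphere(), BOX5, swarm_size=10, max_iter=80, seed=7)
        assert all(b <= a + 1e-15 for a, b in zip(res.trace, res.trace[1:]))

    def test_all_infeasible_flagged(self):
        res = particle_swarm(lambda x: np.inf, BOX5[:2], swarm_size=5,
                             max_iter=10, seed=1)
        assert not res.feasible and res.termination == "all_infeasible"


class TestEvolutionaryProgramming:
    def test_sphere_convergence(self):
        res = evolutionary_programming(
            sphere(), BOX5, population=20, generations=200, seed=2
        )
        assert res.best_value < 1e-4

    def test_boundary_optimum_returned(self):
        # optimum of (x−10)² over [−5, 5] sits at the upper bound
        res = evolutionary_programming(
            lambda x: float((x[0] - 10.0) ** 2),
            [ParameterRange("x", -5.0, 5.0)],
            population=20,
            generations=100,
            seed=4,
        )
        assert res.best_parameters["x"] == pytest.approx(5.0, abs=1e-6)

    def test_same_seed_identical(self):
        kw = dict(population=10, generations=40, seed=9)
        a = evolutionary_programming(sphere(), BOX5, **kw)
        b = evolutionary_programming(sphere(), BOX5, **kw)
        assert a.trace == b.trace


class TestClosedLoop:
    ERK_RANGES = [
        ParameterRange("V2", 0.22, 0.41),
        ParameterRange("k4", 0.015, 0.035),
    ]

    def test_optimiser_and_scan_agree_on_unimodal_landscape(self, bd):
        # var(X) = Ωk/d is monotone: the argmin over d must hit the upper bound
        obj = ObjectiveSpec("var(X)", "minimise")
        res = scan(bd, obj, [ParameterRange("d", 0.25, 1.0)], 9)
        opt = optimise(bd, obj, [ParameterRange("d", 0.25, 1.0)],
                       algorithm="pso", seed=1, swarm_size=10, max_iter=40)
        grid_best, grid_val = res.argbest("minimise")
        assert opt.best_value <= grid_val + 1e-9
        assert abs(opt.best_parameters["d"] - 1.0) < 1e-6

    def test_pso_and_ep_find_same_erk_optimum_region(self, erk):
        obj = ObjectiveSpec("cov(MKKK, MKK_P)", "maximise")
        pso = optimise(erk, obj, self.ERK_RANGES, algorithm="pso",
                       seed=1, swarm_size=20, max_iter=40)
        ep = optimise(erk, obj, self.ERK_RANGES, algorithm="ep",
                      seed=1, population=20, generations=40)
        assert pso.feasible and ep.feasible
        assert ep.best_value == pytest.approx(pso.best_value, rel=0.01)

    def test_infeasible_evaluations_recorded_without_raising(self, erk):
        # range deliberately reaches past the Hopf point into instability
        obj = ObjectiveSpec("var(MKKK)", "maximise")
        res = optimise(erk, obj, [ParameterRange("V2", 0.30, 0.60)],
                       algorithm="pso", seed=2, swarm_size=10, max_iter=15)
        assert res.feasible
        assert res.diagnostics["infeasible_evaluations"] > 0
        assert any("unstable" in r for r in res.diagnostics["infeasible_reasons"])
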