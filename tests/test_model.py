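"""Network data model: construction, splitting, stoichiometry, rates,
propensities."""

import numpy as np
import pytest

from lnakit import (
    ModelError,
    build_network,
    michaelis_menten,
    birth_death,
    split_reversible,
    stoichiometry_matrix,
)


def test_michaelis_menten_structure(mm):
    assert mm.n_species == 4 and mm.n_reactions == 5
    assert mm.species_ids == ["S", "SE", "P", "E"]


def test_empty_species_list_rejected():
    with pytest.raises(ModelError):
        build_network({"species": [], "reactions": [], "parameters": {}})


def test_undeclared_species_in_rate_law_named_in_error():
    with pytest.raises(ModelError, match="'Q'"):
        build_network(
            {
                "species": [{"id": "A", "initial": 1.0}],
                "parameters": {"k": 1.0},
                "reactions": [
                    {"id": "r", "reactants": {"A": 1}, "products": {}, "rate": "k*Q"}
                ],
            }
        )


def test_duplicate_species_ids_rejected():
    with pytest.raises(ModelError):
        build_network(
            {"species": [{"id": "A"}, {"id": "A"}], "reactions": [], "parameters": {}}
        )


def test_nonpositive_system_size_rejected():
    with pytest.raises(ModelError):
        build_network({"species": [{"id": "A"}], "system_size": 0.0})


def _reversible_pair():
    return build_network(
        {
            "system_size": 1.0,
            "species": [{"id": "A", "initial": 2.0}, {"id": "B", "initial": 1.0}],
            "parameters": {"kf": 2.0, "kr": 0.5},
            "reactions": [
                {
                    "id": "iso",
                    "reactants": {"A": 1},
                    "products": {"B": 1},
                    "rate": "kf*A - kr*B",
                    "reversible": True,
                }
            ],
        }
    )


class TestSplitReversible:
    def test_separable_difference_splits_into_two_reactions(self):
        net = split_reversible(_reversible_pair())
        assert net.n_reactions == 2
        assert not any(r.reversible for r in net.reactions)
        x = np.array([3.0, 5.0])
        f = net.macroscopic_rates(x)
        assert f == pytest.approx([2.0 * 3.0, 0.5 * 5.0])

    def test_irreversible_network_returned_unchanged(self, mm):
        assert split_reversible(mm) is mm

    def test_split_preserves_deterministic_drift(self, rng):
        original = _reversible_pair()
        split = split_reversible(original)
        N_split = stoichiometry_matrix(split)
        for _ in range(10):
            x = rng.uniform(0.0, 5.0, size=2)
            # net rate of the reversible form vs ν·f of the split form
            kf, kr = 2.0, 0.5
            drift_orig = np.array([-1.0, 1.0]) * (kf * x[0] - kr * x[1])
            drift_split = N_split @ split.macroscopic_rates(x)
            assert np.max(np.abs(drift_orig - drift_split)) < 1e-12

    def test_split_columns_are_negations(self):
        N = stoichiometry_matrix(split_reversible(_reversible_pair()))
        assert np.array_equal(N[:, 0], -N[:, 1])

    def test_inseparable_rate_law_errors_with_instruction(self):
        net = build_network(
            {
                "species": [{"id": "A", "initial": 1.0}, {"id": "B"}],
                "parameters": {"k": 1.0},
                "reactions": [
                    {
                        "id": "bad",
                        "reactants": {"A": 1},
                        "products": {"B": 1},
                        "rate": "k*A*B",
                        "reversible": True,
                    }
                ],
            }
        )
        with pytest.raises(ModelError, match="manually"):
            split_reversible(net)


class TestStoichiometry:
    def test_michaelis_menten_columns(self, mm):
        N = stoichiometry_matrix(mm)
        expected = np.array(
            [
                [1, -1, 1, 0, 0],
                [0, 1, -1, -1, 0],
                [0, 0, 0, 1, -1],
                [0, -1, 1, 1, 0],
            ]
        )
        assert np.array_equal(N, expected)

    def test_birth_death(self, bd):
        assert np.array_equal(stoichiometry_matrix(bd), [[1, -1]])

    def test_every_reaction_changes_something(self, mm, erk):
        for net in (mm, erk):
            N = stoichiometry_matrix(net)
            assert np.all(np.abs(N).sum(axis=0) >= 1)


class TestRates:
    def test_mass_action_arithmetic(self, mm):
        x = np.array([3.0, 0.0, 0.0, 4.0])
        f = mm.macroscopic_rates(x, {"k2": 2.0})
        assert f[1] == pytest.approx(24.0)

    def test_zero_state_only_influx_active(self, mm):
        f = mm.macroscopic_rates(np.zeros(4))
        assert f == pytest.approx([1.0, 0, 0, 0, 0])

    def test_flux_balance_at_analytic_steady_state(self):
        # substituting the closed-form fixed point, the complex SE is in
        # flux balance: formation rate equals the two consumption rates
        k1 = k2 = k3 = k4 = k5 = 1.0
        beta = 10.0
        x_se = k1 / k4
        x_s = (k1 * k3 + k1 * k4) / (k2 * k4 * (beta - k1 / k4))
        x = np.array([x_s, x_se, k1 / k5, beta - x_se])
        f = michaelis_menten().macroscopic_rates(x)
        assert f[1] == pytest.approx(f[2] + f[3], rel=1e-12)

    def test_drift_matches_handwritten_odes(self, mm, rng):
        # ν·f(x) against the textbook four-species ODE right-hand side
        N = stoichiometry_matrix(mm)
        for _ in range(20):
            x = rng.uniform(0.0, 5.0, size=4)
            s, se, p, e = x
            hand = np.array(
                [
                    1 - s * e + se,
                    s * e - 2 * se,
                    se - p,
                    2 * se - s * e,
                ]
            )
            assert np.max(np.abs(N @ mm.macroscopic_rates(x) - hand)) < 1e-12

    def test_division_by_zero_names_reaction(self):
        net = build_network(
            {
                "species": [{"id": "S", "initial": 1.0}],
                "parameters": {"V": 1.0, "K": 1.0},
                "reactions": [
                    {"id": "sat", "reactants": {"S": 1}, "products": {},
                     "rate": "V*S/(K + S)"}
                ],
            }
        )
        with pytest.raises(ModelError, match="sat"):
            net.macroscopic_rates(np.array([1.0]), {"K": -1.0})


class TestPropensities:
    def test_density_form_scaling(self, bd):
        T = bd.propensities(np.array([20.0]))
        # Ω f(n/Ω) with Ω=10: birth 10·k, death 10·d·(20/10)
        assert T == pytest.approx([10 * 5.0, 10 * 0.5 * 2.0])

    def test_zero_state_only_influx(self, mm):
        T = mm.propensities(np.zeros(4))
        assert T[0] > 0 and np.all(T[1:] == 0)

    def test_negative_particle_numbers_rejected(self, bd):
        with pytest.raises(ModelError):
            bd.propensities(np.array([-1.0]))

    @pytest.mark.parametrize("omega", [1.0, 10.0, 1000.0])
    def test_omega_scaling_identity(self, omega):
        net = birth_death(k=2.0, d=0.25, omega=omega)
        x = np.array([4.0])
        assert net.propensities(omega * x) / omega == pytest.approx(
            net.macroscopic_rates(x)
        )
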