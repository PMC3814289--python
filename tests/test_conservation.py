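"""Conserved-moiety detection, link matrices and system reduction."""

import numpy as np
import pytest

from lnakit import (
    birth_death,
    closed_cycle,
    erk_cascade,
    lna,
    michaelis_menten,
    reduce,
    stoichiometry_matrix,
)
from lnakit.conservation import build_link_matrix, find_conservation_relations


class TestDetection:
    def test_michaelis_menten_single_relation(self, mm):
        N = stoichiometry_matrix(mm)
        relations, independent, dependent = find_conservation_relations(
            N, mm.initial_densities()
        )
        assert len(relations) == 1
        (rel,) = relations
        assert rel.dependent_index == 3  # E depends on SE
        # E = β − SE: coefficient −1 on SE, constant β = 10
        assert dict(rel.coefficients) == {1: -1}
        assert rel.constant == pytest.approx(10.0)

    def test_birth_death_has_none(self, bd):
        relations, independent, _ = find_conservation_relations(
            stoichiometry_matrix(bd)
        )
        assert relations == [] and independent == [0]

    def test_closed_cycle_total_conserved(self):
        net = closed_cycle()
        N = stoichiometry_matrix(net)
        relations, *_ = find_conservation_relations(N, net.initial_densities())
        assert len(relations) == 1
        assert relations[0].null_vector == (1, 1, 1)
        assert relations[0].constant == pytest.approx(30.0)

    @pytest.mark.parametrize(
        "factory, n_relations", [(michaelis_menten, 1), (birth_death, 0),
                                 (closed_cycle, 1), (erk_cascade, 3)]
    )
    def test_null_vectors_annihilate_stoichiometry_exactly(self, factory, n_relations):
        net = factory()
        N = stoichiometry_matrix(net)
        relations, *_ = find_conservation_relations(N)
        assert len(relations) == n_relations
        for rel in relations:
            g = np.array(rel.null_vector, dtype=object)
            assert all(v == 0 for v in g @ N)  # integer arithmetic, exact


class TestLinkMatrix:
    def test_michaelis_menten_link(self, mm):
        red = reduce(mm)
        expected = np.array([[1, 0, 0], [0, 1, 0], [0, 0, 1], [0, -1, 0]], dtype=float)
        assert np.array_equal(red.link_matrix, expected)

    def test_identity_when_no_relations(self, bd):
        red = reduce(bd)
        assert np.array_equal(red.link_matrix, np.eye(1))

    def test_cycle_link(self):
        red = reduce(closed_cycle())
        assert np.array_equal(
            red.link_matrix, np.array([[1, 0], [0, 1], [-1, -1]], dtype=float)
        )

    def test_top_block_is_identity(self, erk):
        red = reduce(erk)
        assert np.array_equal(red.link_matrix[: red.K], np.eye(red.K))

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(Exception):
            build_link_matrix([], [0, 1], 4)


class TestReduction:
    def test_michaelis_menten_reduced_odes(self, mm, rng):
        red = reduce(mm)
        assert red.K == 3
        # reduced drift equals the eliminated-variable form
        # (k1 − k2·x1·(β−x2) + k3·x2, k2·x1·(β−x2) − 2x2, x2 − x3)
        for _ in range(20):
            x = rng.uniform(0.0, 3.0, size=3)
            x1, x2, x3 = x
            beta = 10.0
            hand = np.array(
                [
                    1 - x1 * (beta - x2) + x2,
                    x1 * (beta - x2) - 2 * x2,
                    x2 - x3,
                ]
            )
            assert np.max(np.abs(red.rhs(x) - hand)) < 1e-12

    def test_reduction_is_identity_without_relations(self, bd):
        red = reduce(bd)
        assert red.K == 1 and red.permutation == [0]

    def test_erk_moiety_counts(self, erk):
        red = reduce(erk)
        assert red.K == 5 and red.n_conserved == 3

    def test_reduced_stoichiometry_full_rank(self, mm, erk):
        for net in (mm, erk):
            red = reduce(net)
            assert np.linalg.matrix_rank(red.N_red) == red.K

    def test_full_densities_respect_constants_exactly(self, erk, rng):
        red = reduce(erk)
        for _ in range(5):
            x = rng.uniform(0.0, 50.0, size=red.K)
            full = red.full_densities(x)
            for rel in red.relations:
                g = np.array(rel.null_vector, dtype=float)
                assert g @ full == pytest.approx(
                    g @ erk.initial_densities(), rel=1e-12
                )

    def test_report_mentions_conserved_sum(self, mm):
        assert "[E]" in reduce(mm).report() and "[SE]" in reduce(mm).report()


def test_full_covariance_invariant_under_species_declaration_order(mm):
    """Whatever species end up dependent, the recovered full covariance is
    the same physical object (matched by species id)."""
    from lnakit import build_network
    from lnakit.io import network_to_dict

    spec = network_to_dict(mm)
    # declare E first so it becomes independent and SE dependent
    order = [3, 0, 2, 1]
    spec["species"] = [spec["species"][i] for i in order]
    permuted = build_network(spec)
    a = lna(mm)
    b = lna(permuted)
    for si in mm.species_ids:
        for sj in mm.species_ids:
            assert a.covariance(si, sj) == pytest.approx(
                b.covariance(si, sj), rel=1e-9, abs=1e-9
            )
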