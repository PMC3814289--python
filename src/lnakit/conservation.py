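"""Conserved-moiety detection and stoichiometric reduction.

Mass-conservation relations are left null vectors of the stoichiometry
matrix: linear combinations of particle numbers that no reaction changes.
Each relation removes one degree of freedom, so a network with K̂ species
and Λ relations has only K = K̂ − Λ independent species.  The reduction is
required before the stationary covariance can be computed: with dependent
species kept in, the drift matrix has zero eigenvalues and the Lyapunov
equation has no unique solution.

All null-space computations here are exact (rational row reduction over
``fractions.Fraction``): a conservation relation that only holds to
rounding error would leave the reduced system singular in disguise.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

import numpy as np

from .model import ModelError, ReactionNetwork, stoichiometry_matrix

__all__ = [
    "ConservationRelation",
    "ReducedSystem",
    "find_conservation_relations",
    "build_link_matrix",
    "reduce",
]


@dataclass(frozen=True)
class ConservationRelation:
    """One relation x_j = c_j + Σ_k α_jk x_k (density scale).

    ``dependent_index`` and the keys of ``coefficients`` refer to species
    positions in the network's original declared order.  ``null_vector``
    is the integer left-null vector g of the stoichiometry matrix
    (gᵀN = 0 exactly); gᵀn is the conserved particle total.
    """

    dependent_index: int
    coefficients: dict[int, Fraction]
    constant: float
    null_vector: tuple[int, ...]


def _exact_left_nullspace(N: np.ndarray):
    """Greedy independent-row selection with exact elimination.

    Scans rows in declared order; a row that is a rational combination of
    previously retained rows becomes dependent and yields its combination
    coefficients.  Returns (independent, dependent, alphas) where
    ``alphas[j]`` maps independent row index → Fraction coefficient.
    """
    n_rows, n_cols = N.shape
    rows = [[Fraction(int(v)) for v in N[i]] for i in range(n_rows)]
    # Each basis entry: (rref_row, pivot_col, combo over independent indices)
    basis: list[tuple[list[Fraction], int, dict[int, Fraction]]] = []
    independent: list[int] = []
    dependent: list[int] = []
    alphas: dict[int, dict[int, Fraction]] = {}
    for i in range(n_rows):
        row = list(rows[i])
        combo: dict[int, Fraction] = {i: Fraction(1)}
        for brow, piv, bcombo in basis:
            factor = row[piv]
            if factor:
                for c in range(n_cols):
                    row[c] -= factor * brow[c]
                for k, v in bcombo.items():
                    combo[k] = combo.get(k, Fraction(0)) - factor * v
        pivot = next((c for c in range(n_cols) if row[c]), None)
        if pivot is None:
            # row_i = Σ_k α_k · row_k over independent rows
            dependent.append(i)
            alphas[i] = {
                k: -v for k, v in combo.items() if k != i and v
            }
        else:
            inv = Fraction(1) / row[pivot]
            row = [v * inv for v in row]
            combo = {k: v * inv for k, v in combo.items()}
            basis.append((row, pivot, combo))
            independent.append(i)
    return independent, dependent, alphas


def find_conservation_relations(
    N: np.ndarray, initial_densities: Sequence[float] | None = None
):
    """Detect conserved moieties of an integer stoichiometry matrix.

    Returns ``(relations, independent_indices, dependent_indices)``.
    Λ = K̂ − rank(N) relations are found; constants c_j are evaluated from
    ``initial_densities`` when given (else 0).  Every returned integer
    null vector satisfies gᵀN = 0 exactly.
    """
    N = np.asarray(N)
    independent, dependent, alphas = _exact_left_nullspace(N)
    x0 = (
        np.zeros(N.shape[0])
        if initial_densities is None
        else np.asarray(initial_densities, dtype=float)
    )
    relations = []
    for j in dependent:
        coeffs = alphas[j]
        # g = e_j − Σ α_jk e_k, scaled to integers by the denominator lcm
        denom = 1
        for v in coeffs.values():
            denom = denom * v.denominator // np.gcd(denom, v.denominator)
        g = [0] * N.shape[0]
        g[j] = denom
        for k, v in coeffs.items():
            g[k] = int(-v * denom)
        assert all(
            sum(g[i] * int(N[i, mu]) for i in range(N.shape[0])) == 0
            for mu in range(N.shape[1])
        ), "inexact conservation relation"
        constant = float(x0[j] - sum(float(v) * x0[k] for k, v in coeffs.items()))
        relations.append(
            ConservationRelation(
                dependent_index=j,
                coefficients=dict(coeffs),
                constant=constant,
                null_vector=tuple(g),
            )
        )
    return relations, independent, dependent


def build_link_matrix(
    relations: Sequence[ConservationRelation],
    independent: Sequence[int],
    n_species: int,
) -> np.ndarray:
    """Link matrix L = [I_K ; L0] in independent-first species order.

    Row j of L0 holds the α_jk of dependent species j over the independent
    species k (reduced ordering).
    """
    K = len(independent)
    if K + len(relations) != n_species:
        raise ModelError("link matrix dimension mismatch")
    pos = {orig: k for k, orig in enumerate(independent)}
    L = np.zeros((n_species, K))
    L[:K, :K] = np.eye(K)
    for row, rel in enumerate(relations):
        for orig_k, alpha in rel.coefficients.items():
            L[K + row, pos[orig_k]] = float(alpha)
    return L


class ReducedSystem:
    """A network together with its conservation-aware reduction.

    Works in two index spaces: the network's declared species order
    ("original") and the independent-first reordering used by the link
    matrix.  ``permutation[r]`` is the original index of reordered
    position r.
    """

    def __init__(self, network: ReactionNetwork):
        if any(r.reversible for r in network.reactions):
            raise ModelError(
                "network contains reversible reactions; split them before reduction"
            )
        self.network = network
        self.N = stoichiometry_matrix(network)
        relations, independent, dependent = find_conservation_relations(
            self.N, network.initial_densities()
        )
        self.relations = relations
        self.independent_indices = list(independent)
        self.dependent_indices = list(dependent)
        self.permutation = self.independent_indices + self.dependent_indices
        self.K = len(independent)
        self.n_conserved = len(relations)
        self.link_matrix = build_link_matrix(
            relations, independent, network.n_species
        )
        # Same rows, but in original species order (for covariance output).
        inv = np.argsort(self.permutation)
        self.link_matrix_original = self.link_matrix[inv, :]
        self.N_red = self.N[self.independent_indices, :]
        self.constants = np.array([r.constant for r in relations])
        if np.linalg.matrix_rank(self.N_red) != self.K:
            raise ModelError("reduced stoichiometry is rank deficient")

    @property
    def reduced_species_ids(self) -> list[str]:
        return [self.network.species[i].id for i in self.independent_indices]

    def reduced_initial_densities(self) -> np.ndarray:
        return self.network.initial_densities()[self.independent_indices]

    def full_densities(self, x_red: Sequence[float]) -> np.ndarray:
        """Reconstruct all K̂ densities (original order) from the K
        independent ones via the conservation relations."""
        x_red = np.asarray(x_red, dtype=float)
        offset = np.zeros(self.network.n_species)
        offset[self.dependent_indices] = self.constants
        return offset + self.link_matrix_original @ x_red

    def rhs(self, x_red, params=None) -> np.ndarray:
        """Reduced deterministic drift dx_k/dt = Σ_μ ν_kμ f_μ(x).

        Densities are clipped at zero before rate evaluation so that
        transient solver overshoot cannot abort an integration; validity
        of a converged state is checked unclipped by the caller.
        """
        x_full = np.clip(self.full_densities(x_red), 0.0, None)
        f = self.network.macroscopic_rates(x_full, params)
        return self.N_red @ f

    def drift_jacobian(self, x_red, params=None) -> np.ndarray:
        """Jacobian of the reduced drift (the LNA drift matrix A at a
        steady state), with dependent densities eliminated by the chain
        rule through the link matrix."""
        x_full = np.clip(self.full_densities(x_red), 0.0, None)
        dfdx = self.network.rate_jacobian(x_full, params)
        return self.N_red @ dfdx @ self.link_matrix_original

    def report(self) -> str:
        """Human-readable list of conserved sums."""
        ids = self.network.species_ids
        if not self.relations:
            return "no conservation relations"
        x0 = self.network.initial_densities()
        lines = []
        for rel in self.relations:
            g = rel.null_vector
            terms = [
                (f"{g[i]}·" if abs(g[i]) != 1 else ("-" if g[i] == -1 else ""))
                + f"[{ids[i]}]"
                for i in range(len(ids))
                if g[i]
            ]
            total = float(np.dot(g, x0))
            lines.append(" + ".join(terms).replace("+ -", "- ") + f" = {total:g}")
        return "\n".join(lines)


def reduce(network: ReactionNetwork) -> ReducedSystem:
    """Reduce a network to its independent species (identity when Λ = 0)."""
    return ReducedSystem(network)
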