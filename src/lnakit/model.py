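"""Data model for single-compartment stochastic reaction networks.

A :class:`ReactionNetwork` holds an ordered species list, irreversible (or
to-be-split reversible) reactions with kinetic rate laws, named parameters
and a system size Ω.  Densities x (numbers per unit Ω) and particle numbers
n are linked by n = Ω·x; macroscopic rates f_μ(x) induce the stochastic
propensities T_μ(n) = Ω·f_μ(n/Ω).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np

from . import expr as ex

__all__ = [
    "Species",
    "RateLaw",
    "Reaction",
    "ReactionNetwork",
    "ParameterRange",
    "ModelError",
    "build_network",
    "split_reversible",
    "stoichiometry_matrix",
    "macroscopic_rates",
    "propensities",
]


class ModelError(ValueError):
    """Raised for structurally invalid networks or rate laws."""


@dataclass(frozen=True)
class Species:
    id: str
    name: str = ""
    initial_density: float = 0.0

    def __post_init__(self) -> None:
        if not self.id or not self.id.isidentifier():
            raise ModelError(f"species id {self.id!r} is not a valid token")
        if self.initial_density < 0:
            raise ModelError(
                f"species {self.id!r}: initial density must be non-negative"
            )


@dataclass(frozen=True)
class RateLaw:
    """Kinetic law of a reaction.

    ``mass_action`` laws reference a single rate-constant parameter; the
    monomial in reactant densities is implied by the reaction's reactant
    stoichiometry.  ``expression`` laws carry an arbitrary arithmetic
    formula over species densities and parameters (Michaelis–Menten,
    Hill-with-inhibition, ...).
    """

    kind: str  # "mass_action" | "expression"
    constant: str | None = None
    formula: str | None = None

    def __post_init__(self) -> None:
        if self.kind == "mass_action":
            if not self.constant:
                raise ModelError("mass_action law requires a rate constant name")
        elif self.kind == "expression":
            if self.formula is None:
                raise ModelError("expression law requires a formula")
        else:
            raise ModelError(f"unknown rate law kind {self.kind!r}")


@dataclass(frozen=True)
class Reaction:
    id: str
    reactants: Mapping[str, int]
    products: Mapping[str, int]
    rate_law: RateLaw
    reversible: bool = False

    def __post_init__(self) -> None:
        if not self.reactants and not self.products:
            raise ModelError(f"reaction {self.id!r} has no reactants and no products")
        for side in (self.reactants, self.products):
            for sp, coeff in side.items():
                if int(coeff) != coeff or coeff < 0:
                    raise ModelError(
                        f"reaction {self.id!r}: stoichiometric coefficient for "
                        f"{sp!r} must be a non-negative integer"
                    )

    def rate_expression(self) -> ex.Expr:
        """The macroscopic rate f_μ as an expression over densities."""
        if self.rate_law.kind == "expression":
            return ex.parse(self.rate_law.formula)
        e = ex.sym(self.rate_law.constant)
        for sp, coeff in self.reactants.items():
            e = ex.mul(e, ex.pow_(ex.sym(sp), ex.num(coeff)))
        return e


@dataclass(frozen=True)
class ParameterRange:
    """A scan/optimisation range for one parameter."""

    path: str
    lower: float
    upper: float
    reference: float | None = None

    def __post_init__(self) -> None:
        if self.lower > self.upper:
            raise ModelError(f"range for {self.path!r}: lower > upper")
        if self.reference is not None and not (
            self.lower <= self.reference <= self.upper
        ):
            raise ModelError(f"range for {self.path!r}: reference outside bounds")


class ReactionNetwork:
    """An ordered, validated reaction network.

    Parameters
    ----------
    species : sequence of Species
    reactions : sequence of Reaction
    parameters : mapping of parameter name to value
    system_size : float
        Ω > 0, particles per unit density (e.g. N_A·V·10⁻⁹ for nM units).
    name : str
    """

    def __init__(
        self,
        species: Sequence[Species],
        reactions: Sequence[Reaction],
        parameters: Mapping[str, float],
        system_size: float,
        name: str = "",
    ) -> None:
        if not species:
            raise ModelError("network has no species")
        ids = [s.id for s in species]
        if len(set(ids)) != len(ids):
            raise ModelError("duplicate species ids")
        rids = [r.id for r in reactions]
        if len(set(rids)) != len(rids):
            raise ModelError("duplicate reaction ids")
        if system_size <= 0:
            raise ModelError("system size Ω must be positive")
        self.species = tuple(species)
        self.reactions = tuple(reactions)
        self.parameters = dict(parameters)
        self.system_size = float(system_size)
        self.name = name
        self.species_index = {s.id: i for i, s in enumerate(self.species)}
        self._validate_symbols()
        self._cache: dict = {}

    # -- structure ---------------------------------------------------------

    def _validate_symbols(self) -> None:
        declared = set(self.species_index) | set(self.parameters)
        for r in self.reactions:
            for sp in list(r.reactants) + list(r.products):
                if sp not in self.species_index:
                    raise ModelError(
                        f"reaction {r.id!r} references undeclared species {sp!r}"
                    )
            for name in ex.symbols(r.rate_expression()):
                if name not in declared:
                    raise ModelError(
                        f"rate law of reaction {r.id!r} references "
                        f"undeclared symbol {name!r}"
                    )

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    @property
    def species_ids(self) -> list[str]:
        return [s.id for s in self.species]

    def initial_densities(self) -> np.ndarray:
        return np.array([s.initial_density for s in self.species], dtype=float)

    def with_parameters(self, updates: Mapping[str, float]) -> "ReactionNetwork":
        """A copy of the network with some parameter values replaced."""
        unknown = set(updates) - set(self.parameters)
        if unknown:
            raise ModelError(f"unknown parameters: {sorted(unknown)}")
        params = dict(self.parameters)
        params.update(updates)
        net = ReactionNetwork(
            self.species, self.reactions, params, self.system_size, self.name
        )
        net._cache = self._cache  # compiled code depends only on structure
        return net

    def with_initial_densities(self, x0: Sequence[float]) -> "ReactionNetwork":
        sp = [replace(s, initial_density=float(v)) for s, v in zip(self.species, x0)]
        net = ReactionNetwork(
            sp, self.reactions, self.parameters, self.system_size, self.name
        )
        net._cache = self._cache
        return net

    def __eq__(self, other) -> bool:
        if not isinstance(other, ReactionNetwork):
            return NotImplemented
        return (
            self.species == other.species
            and self.reactions == other.reactions
            and self.parameters == other.parameters
            and self.system_size == other.system_size
        )

    def __repr__(self) -> str:
        return (
            f"<ReactionNetwork {self.name!r}: {self.n_species} species, "
            f"{self.n_reactions} reactions, Ω={self.system_size:g}>"
        )

    # -- compiled evaluators ----------------------------------------------

    @property
    def _param_order(self) -> list[str]:
        return sorted(self.parameters)

    def _param_vector(self, overrides: Mapping[str, float] | None = None) -> np.ndarray:
        p = dict(self.parameters)
        if overrides:
            p.update(overrides)
        return np.array([p[k] for k in self._param_order], dtype=float)

    def _name_map(self) -> dict[str, str]:
        nm = {s.id: f"x[{i}]" for i, s in enumerate(self.species)}
        nm.update({k: f"p[{j}]" for j, k in enumerate(self._param_order)})
        return nm

    def _compiled_rates(self) -> Callable:
        """f(x, p, out) filling the length-M macroscopic rate vector."""
        fn = self._cache.get("rates")
        if fn is None:
            nm = self._name_map()
            lines = ["def _rates(x, p, out):"]
            for mu, r in enumerate(self.reactions):
                lines.append(f"    out[{mu}] = {ex.to_source(r.rate_expression(), nm)}")
            lines.append("    return out")
            ns: dict = {"__builtins__": {}}
            exec(compile("\n".join(lines), "<rates>", "exec"), ns)
            fn = self._cache["rates"] = ns["_rates"]
        return fn

    def _compiled_rate_jacobian(self) -> Callable:
        """df(x, p, out) filling the M × K̂ matrix ∂f_μ/∂x_i."""
        fn = self._cache.get("rate_jac")
        if fn is None:
            nm = self._name_map()
            lines = ["def _jac(x, p, out):"]
            for mu, r in enumerate(self.reactions):
                e = r.rate_expression()
                for i, s in enumerate(self.species):
                    d = ex.diff(e, s.id)
                    if d != ex.num(0.0):
                        lines.append(f"    out[{mu}, {i}] = {ex.to_source(d, nm)}")
            lines.append("    return out")
            ns: dict = {"__builtins__": {}}
            exec(compile("\n".join(lines), "<rate-jacobian>", "exec"), ns)
            fn = self._cache["rate_jac"] = ns["_jac"]
        return fn

    # -- evaluation --------------------------------------------------------

    def macroscopic_rates(
        self, x: Sequence[float], params: Mapping[str, float] | None = None
    ) -> np.ndarray:
        """Macroscopic rate vector f(x), length M (densities per time)."""
        x = np.asarray(x, dtype=float)
        if x.shape != (self.n_species,):
            raise ModelError(
                f"density vector has shape {x.shape}, expected ({self.n_species},)"
            )
        if not np.all(np.isfinite(x)):
            raise ModelError("non-finite density")
        if np.any(x < -1e-12):
            raise ModelError(f"negative density: {x}")
        x = np.clip(x, 0.0, None)
        p = self._param_vector(params)
        out = np.empty(self.n_reactions)
        try:
            self._compiled_rates()(x, p, out)
        except ZeroDivisionError:
            raise ModelError(
                f"division by zero in rate law of reaction "
                f"{self._locate_zero_division(x, params)!r}"
            ) from None
        if not np.all(np.isfinite(out)):
            bad = self.reactions[int(np.argmax(~np.isfinite(out)))].id
            raise ModelError(f"non-finite rate in reaction {bad!r}")
        return out

    def _locate_zero_division(self, x, params) -> str:
        env = {s.id: v for s, v in zip(self.species, x)}
        env.update(self.parameters)
        if params:
            env.update(params)
        for r in self.reactions:
            try:
                ex.evaluate(r.rate_expression(), env)
            except ZeroDivisionError:
                return r.id
        return "<unknown>"

    def rate_jacobian(
        self, x: Sequence[float], params: Mapping[str, float] | None = None
    ) -> np.ndarray:
        """∂f_μ/∂x_i as an M × K̂ matrix (analytic)."""
        x = np.clip(np.asarray(x, dtype=float), 0.0, None)
        p = self._param_vector(params)
        out = np.zeros((self.n_reactions, self.n_species))
        self._compiled_rate_jacobian()(x, p, out)
        if not np.all(np.isfinite(out)):
            mu = int(np.argmax(~np.isfinite(out).any(axis=1)))
            raise ModelError(
                f"non-finite rate derivative in reaction {self.reactions[mu].id!r}"
            )
        return out

    def propensities(
        self, n: Sequence[float], params: Mapping[str, float] | None = None
    ) -> np.ndarray:
        """Stochastic propensities T_μ(n) = Ω·f_μ(n/Ω), length M."""
        n = np.asarray(n, dtype=float)
        if np.any(n < 0):
            raise ModelError("negative particle number")
        return self.system_size * self.macroscopic_rates(n / self.system_size, params)


# -- module-level operations ------------------------------------------------


def build_network(spec: Mapping) -> ReactionNetwork:
    """Build a validated network from a structured description.

    The description mirrors the native model format: keys ``species``
    (list of ``{id, name?, initial}``), ``reactions`` (list of
    ``{id, reactants, products, rate | mass_action, reversible?}``),
    ``parameters`` (name → value) and ``system_size``.
    """
    try:
        species = [
            Species(
                id=s["id"],
                name=s.get("name", ""),
                initial_density=float(s.get("initial", 0.0)),
            )
            for s in spec["species"]
        ]
        reactions = []
        for i, r in enumerate(spec.get("reactions", [])):
            if "mass_action" in r:
                law = RateLaw(kind="mass_action", constant=r["mass_action"])
            else:
                law = RateLaw(kind="expression", formula=str(r["rate"]))
            reactions.append(
                Reaction(
                    id=r.get("id", f"r{i + 1}"),
                    reactants={k: int(v) for k, v in (r.get("reactants") or {}).items()},
                    products={k: int(v) for k, v in (r.get("products") or {}).items()},
                    rate_law=law,
                    reversible=bool(r.get("reversible", False)),
                )
            )
        return ReactionNetwork(
            species=species,
            reactions=reactions,
            parameters={k: float(v) for k, v in (spec.get("parameters") or {}).items()},
            system_size=float(spec.get("system_size", 1.0)),
            name=spec.get("name", ""),
        )
    except KeyError as exc:
        raise ModelError(f"model description missing key {exc}") from None


def split_reversible(net: ReactionNetwork) -> ReactionNetwork:
    """Split every reversible reaction into two irreversible ones.

    A reversible rate law must be syntactically separable into forward and
    backward parts, i.e. its formula must be a top-level difference
    ``forward - backward``; anything else raises with instructions to split
    the reaction manually.  Networks without reversible reactions are
    returned unchanged.
    """
    if not any(r.reversible for r in net.reactions):
        return net
    out: list[Reaction] = []
    for r in net.reactions:
        if not r.reversible:
            out.append(r)
            continue
        e = r.rate_expression()
        if e[0] != "sub":
            raise ModelError(
                f"reversible reaction {r.id!r}: rate law is not of the separable "
                f"form 'forward - backward'; split it into two irreversible "
                f"reactions manually"
            )
        fwd, bwd = e[1], e[2]
        out.append(
            Reaction(
                id=f"{r.id}_fwd",
                reactants=dict(r.reactants),
                products=dict(r.products),
                rate_law=RateLaw(kind="expression", formula=ex.to_source(fwd)),
            )
        )
        out.append(
            Reaction(
                id=f"{r.id}_rev",
                reactants=dict(r.products),
                products=dict(r.reactants),
                rate_law=RateLaw(kind="expression", formula=ex.to_source(bwd)),
            )
        )
    return ReactionNetwork(
        net.species, out, net.parameters, net.system_size, net.name
    )


def stoichiometry_matrix(net: ReactionNetwork) -> np.ndarray:
    """Integer stoichiometry matrix N with N[i, μ] = p_iμ − r_iμ (K̂ × M)."""
    if any(r.reversible for r in net.reactions):
        raise ModelError("network contains reversible reactions; split them first")
    N = np.zeros((net.n_species, net.n_reactions), dtype=int)
    for mu, r in enumerate(net.reactions):
        for sp, coeff in r.reactants.items():
            N[net.species_index[sp], mu] -= coeff
        for sp, coeff in r.products.items():
            N[net.species_index[sp], mu] += coeff
    return N


def macroscopic_rates(net, x, params=None) -> np.ndarray:
    return net.macroscopic_rates(x, params)


def propensities(net, n, params=None) -> np.ndarray:
    return net.propensities(n, params)
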