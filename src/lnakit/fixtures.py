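"""Bundled reaction-network fixtures.

All fixtures are constructed programmatically so every analysis surface
(conservation detection, steady states, LNA, scanning, optimisation, SSA)
can be exercised without external files.  Analytic fixtures (birth–death,
linear chain, cycle) have closed-form stationary laws and serve as
oracles; the Michaelis–Menten system and the ERK MAPK cascade are the
literature models the tool's headline computations run on.
"""

from __future__ import annotations

import math

from .model import ReactionNetwork, build_network

__all__ = [
    "michaelis_menten",
    "birth_death",
    "linear_chain",
    "closed_cycle",
    "erk_cascade",
    "two_branch_cascade",
    "AVOGADRO",
    "list_fixtures",
]

AVOGADRO = 6.02214076e23

#: Michaelis–Menten parameter set used for the LNA-vs-SSA validation runs.
#: Chosen so that every pairwise stationary correlation is non-negligible
#: (|ρ| ≳ 0.12) and means are O(10²) particles, i.e. every covariance
#: entry is estimable to a few percent from an ergodic average of
#: practical length while staying well inside the LNA's validity regime.
MM_SSA_COMPARISON = {
    "k1": 5.0, "k2": 2.5, "k3": 0.2, "k4": 5.0, "k5": 4.0,
    "beta": 2.0, "omega": 100.0,
}


def michaelis_menten(
    k1: float = 1.0,
    k2: float = 1.0,
    k3: float = 1.0,
    k4: float = 1.0,
    k5: float = 1.0,
    beta: float = 10.0,
    omega: float = 100.0,
) -> ReactionNetwork:
    """Open Michaelis–Menten mechanism: ∅→S, S+E⇄SE→P+E, P→∅.

    Substrate S is supplied at constant flux k1, binds the enzyme E into
    the complex SE (k2 forward, k3 back), which converts to product P
    (k4); P leaves the system (k5).  Total enzyme [E]+[SE] = β is
    conserved (Λ = 1, so K = 3 of the 4 species are independent).

    The positive steady state x_S = (k1 k3 + k1 k4)/(k2 k4 (β − k1/k4)),
    x_SE = k1/k4, x_P = k1/k5 requires β > k1/k4, else a warning-worthy
    regime with no physical fixed point.  Defaults (all rates 1, β = 10,
    Ω = 100) give means of order 10²–10³ particles.
    """
    if min(k1, k2, k3, k4, k5) <= 0 or beta <= 0:
        raise ValueError("all rate constants and β must be positive")
    if beta <= k1 / k4:
        import warnings

        warnings.warn(
            "β ≤ k1/k4: the deterministic steady state is non-physical",
            stacklevel=2,
        )
    # start S and P at their fixed-point values scale-free; E carries the
    # conserved total
    return build_network(
        {
            "name": "michaelis-menten",
            "system_size": omega,
            "species": [
                {"id": "S", "name": "substrate", "initial": k1 / k4},
                {"id": "SE", "name": "enzyme-substrate complex", "initial": 0.0},
                {"id": "P", "name": "product", "initial": k1 / k5},
                {"id": "E", "name": "free enzyme", "initial": beta},
            ],
            "parameters": {"k1": k1, "k2": k2, "k3": k3, "k4": k4, "k5": k5},
            "reactions": [
                {"id": "v1", "reactants": {}, "products": {"S": 1}, "rate": "k1"},
                {
                    "id": "v2",
                    "reactants": {"S": 1, "E": 1},
                    "products": {"SE": 1},
                    "mass_action": "k2",
                },
                {
                    "id": "v3",
                    "reactants": {"SE": 1},
                    "products": {"S": 1, "E": 1},
                    "mass_action": "k3",
                },
                {
                    "id": "v4",
                    "reactants": {"SE": 1},
                    "products": {"P": 1, "E": 1},
                    "mass_action": "k4",
                },
                {"id": "v5", "reactants": {"P": 1}, "products": {}, "mass_action": "k5"},
            ],
        }
    )


def birth_death(k: float = 5.0, d: float = 0.5, omega: float = 10.0) -> ReactionNetwork:
    """∅ → X (rate k), X → ∅ (rate d·x).  Stationary law Poisson(Ωk/d)."""
    return build_network(
        {
            "name": "birth-death",
            "system_size": omega,
            "species": [{"id": "X", "initial": k / d}],
            "parameters": {"k": k, "d": d},
            "reactions": [
                {"id": "birth", "reactants": {}, "products": {"X": 1}, "rate": "k"},
                {"id": "death", "reactants": {"X": 1}, "products": {}, "mass_action": "d"},
            ],
        }
    )


def linear_chain(
    influx: float = 5.0, rates: tuple = (1.0, 1.0, 1.0), omega: float = 10.0
) -> ReactionNetwork:
    """Open monomolecular chain ∅ → X1 → X2 → … → ∅ with first-order steps.

    The stationary law is product-form Poisson (independent species,
    var_i = mean_i = Ω·influx/rate_i), which the LNA reproduces exactly —
    a sharp oracle for the whole pipeline.
    """
    if len(rates) < 2:
        raise ValueError("chain needs at least two steps")
    n = len(rates)
    species = [
        {"id": f"X{i + 1}", "initial": influx / rates[i]} for i in range(n)
    ]
    params = {"kin": influx}
    params.update({f"c{i + 1}": rates[i] for i in range(n)})
    reactions = [
        {"id": "influx", "reactants": {}, "products": {"X1": 1}, "rate": "kin"}
    ]
    for i in range(n - 1):
        reactions.append(
            {
                "id": f"step{i + 1}",
                "reactants": {f"X{i + 1}": 1},
                "products": {f"X{i + 2}": 1},
                "mass_action": f"c{i + 1}",
            }
        )
    reactions.append(
        {
            "id": "efflux",
            "reactants": {f"X{n}": 1},
            "products": {},
            "mass_action": f"c{n}",
        }
    )
    return build_network(
        {
            "name": f"linear-chain-{n}",
            "system_size": omega,
            "species": species,
            "parameters": params,
            "reactions": reactions,
        }
    )


def closed_cycle(
    ka: float = 1.0, kb: float = 2.0, kc: float = 3.0, total: float = 30.0,
    omega: float = 1.0,
) -> ReactionNetwork:
    """Closed mass-action cycle A→B→C→A; A+B+C is conserved (Λ = 1)."""
    return build_network(
        {
            "name": "closed-cycle",
            "system_size": omega,
            "species": [
                {"id": "A", "initial": total},
                {"id": "B", "initial": 0.0},
                {"id": "C", "initial": 0.0},
            ],
            "parameters": {"ka": ka, "kb": kb, "kc": kc},
            "reactions": [
                {"id": "ab", "reactants": {"A": 1}, "products": {"B": 1}, "mass_action": "ka"},
                {"id": "bc", "reactants": {"B": 1}, "products": {"C": 1}, "mass_action": "kb"},
                {"id": "ca", "reactants": {"C": 1}, "products": {"A": 1}, "mass_action": "kc"},
            ],
        }
    )


def erk_cascade(K_I: float = 45.0, V_cell: float = 1e-14) -> ReactionNetwork:
    """Kholodenko's ultrasensitive ERK MAPK cascade with negative feedback.

    Three phosphorylation tiers — MKKK, MKK (doubly phosphorylated) and
    MAPK (doubly phosphorylated) — with Michaelis–Menten kinetics for
    every (de)phosphorylation and a feedback inhibition of the first
    activation step by the cascade output MAPK-PP (Hill-type term
    1/(1 + (MAPK_PP/K_I)^n)).  Concentrations are in nM, time in
    seconds.  The default K_I = 45 weakens the feedback so that a stable
    steady state (rather than a limit cycle) exists at reference
    parameters; the phosphatase activity V2 destabilises it through a
    Hopf bifurcation when raised towards ≈0.45 nM/s.

    Ω converts nM to particles in a cell volume ``V_cell`` (litres):
    Ω = 10⁻⁹·N_A·V_cell ≈ 6.022 particles per nM at 10⁻¹⁴ l.

    Conserved moieties: the three tier totals (MKKK, MKK and MAPK forms),
    so Λ = 3 and K = 5.
    """
    omega = 1e-9 * AVOGADRO * V_cell
    mm = lambda v, s, k: f"{v} * {s} / ({k} + {s})"  # noqa: E731
    return build_network(
        {
            "name": "erk-mapk-cascade",
            "system_size": omega,
            "species": [
                {"id": "MKKK", "name": "MAPK kinase kinase", "initial": 90.0},
                {"id": "MKKK_P", "name": "phospho-MKKK", "initial": 10.0},
                {"id": "MKK", "name": "MAPK kinase", "initial": 280.0},
                {"id": "MKK_P", "name": "phospho-MKK", "initial": 10.0},
                {"id": "MKK_PP", "name": "bisphospho-MKK", "initial": 10.0},
                {"id": "MAPK", "name": "MAPK (ERK)", "initial": 280.0},
                {"id": "MAPK_P", "name": "phospho-MAPK", "initial": 10.0},
                {"id": "MAPK_PP", "name": "bisphospho-MAPK", "initial": 10.0},
            ],
            "parameters": {
                "V1": 2.5, "Ki": K_I, "n": 1.0, "K1": 10.0,
                "V2": 0.25, "K2": 8.0,
                "k3": 0.025, "K3": 15.0,
                "k4": 0.025, "K4": 15.0,
                "V5": 0.75, "K5": 15.0,
                "V6": 0.75, "K6": 15.0,
                "k7": 0.025, "K7": 15.0,
                "k8": 0.025, "K8": 15.0,
                "V9": 0.5, "K9": 15.0,
                "V10": 0.5, "K10": 15.0,
            },
            "reactions": [
                {
                    "id": "v1_MKKK_activation",
                    "reactants": {"MKKK": 1},
                    "products": {"MKKK_P": 1},
                    "rate": "V1 * MKKK / ((1 + (MAPK_PP / Ki)^n) * (K1 + MKKK))",
                },
                {
                    "id": "v2_MKKK_deactivation",
                    "reactants": {"MKKK_P": 1},
                    "products": {"MKKK": 1},
                    "rate": mm("V2", "MKKK_P", "K2"),
                },
                {
                    "id": "v3_MKK_phosphorylation",
                    "reactants": {"MKK": 1},
                    "products": {"MKK_P": 1},
                    "rate": "k3 * MKKK_P * MKK / (K3 + MKK)",
                },
                {
                    "id": "v4_MKKP_phosphorylation",
                    "reactants": {"MKK_P": 1},
                    "products": {"MKK_PP": 1},
                    "rate": "k4 * MKKK_P * MKK_P / (K4 + MKK_P)",
                },
                {
                    "id": "v5_MKKPP_dephosphorylation",
                    "reactants": {"MKK_PP": 1},
                    "products": {"MKK_P": 1},
                    "rate": mm("V5", "MKK_PP", "K5"),
                },
                {
                    "id": "v6_MKKP_dephosphorylation",
                    "reactants": {"MKK_P": 1},
                    "products": {"MKK": 1},
                    "rate": mm("V6", "MKK_P", "K6"),
                },
                {
                    "id": "v7_MAPK_phosphorylation",
                    "reactants": {"MAPK": 1},
                    "products": {"MAPK_P": 1},
                    "rate": "k7 * MKK_PP * MAPK / (K7 + MAPK)",
                },
                {
                    "id": "v8_MAPKP_phosphorylation",
                    "reactants": {"MAPK_P": 1},
                    "products": {"MAPK_PP": 1},
                    "rate": "k8 * MKK_PP * MAPK_P / (K8 + MAPK_P)",
                },
                {
                    "id": "v9_MAPKPP_dephosphorylation",
                    "reactants": {"MAPK_PP": 1},
                    "products": {"MAPK_P": 1},
                    "rate": mm("V9", "MAPK_PP", "K9"),
                },
                {
                    "id": "v10_MAPKP_dephosphorylation",
                    "reactants": {"MAPK_P": 1},
                    "products": {"MAPK": 1},
                    "rate": mm("V10", "MAPK_P", "K10"),
                },
            ],
        }
    )


def two_branch_cascade(
    activation: float = 1.0,
    deactivation: float = 1.0,
    omega: float = 10.0,
) -> ReactionNetwork:
    """Synthetic two-branch signalling cascade (p38-like topology).

    An active receptor complex R* activates two parallel kinases KA and
    KB (the MKK3/MKK6-like branches); both activated forms converge on a
    shared downstream kinase D (p38-like), whose active form drives an
    output species OUT (Hsp27-like).  Every activation has a matching
    first-order deactivation, and the receptor turns over (∅⇄R*) so the
    network is open upstream.  All kinetics are mass action.

    This fixture is synthetic: it emulates the branch/convergence
    structure of the p38 pathway for exercising correlation and CV
    objectives under steady-state constraints, not any published model.
    """
    a, d = activation, deactivation
    spec = {
        "name": "two-branch-cascade",
        "system_size": omega,
        "species": [
            {"id": "Rstar", "name": "active receptor complex", "initial": 1.0},
            {"id": "KA", "name": "branch-A kinase", "initial": 10.0},
            {"id": "KAstar", "name": "active branch-A kinase", "initial": 0.0},
            {"id": "KB", "name": "branch-B kinase", "initial": 10.0},
            {"id": "KBstar", "name": "active branch-B kinase", "initial": 0.0},
            {"id": "D", "name": "downstream kinase", "initial": 10.0},
            {"id": "Dstar", "name": "active downstream kinase", "initial": 0.0},
            {"id": "OUT", "name": "output protein", "initial": 10.0},
            {"id": "OUTstar", "name": "active output protein", "initial": 0.0},
        ],
        "parameters": {
            "r_on": a, "r_off": d,
            "a_ka": 0.2 * a, "d_ka": d,
            "a_kb": 0.2 * a, "d_kb": d,
            "a_d": 0.1 * a, "d_d": d,
            "a_out": 0.1 * a, "d_out": d,
        },
        "reactions": [
            {"id": "r_act", "reactants": {}, "products": {"Rstar": 1}, "rate": "r_on"},
            {"id": "r_deact", "reactants": {"Rstar": 1}, "products": {}, "mass_action": "r_off"},
            {"id": "ka_act", "reactants": {"Rstar": 1, "KA": 1},
             "products": {"Rstar": 1, "KAstar": 1}, "mass_action": "a_ka"},
            {"id": "ka_deact", "reactants": {"KAstar": 1}, "products": {"KA": 1},
             "mass_action": "d_ka"},
            {"id": "kb_act", "reactants": {"Rstar": 1, "KB": 1},
             "products": {"Rstar": 1, "KBstar": 1}, "mass_action": "a_kb"},
            {"id": "kb_deact", "reactants": {"KBstar": 1}, "products": {"KB": 1},
             "mass_action": "d_kb"},
            {"id": "d_act_a", "reactants": {"KAstar": 1, "D": 1},
             "products": {"KAstar": 1, "Dstar": 1}, "mass_action": "a_d"},
            {"id": "d_act_b", "reactants": {"KBstar": 1, "D": 1},
             "products": {"KBstar": 1, "Dstar": 1}, "mass_action": "a_d"},
            {"id": "d_deact", "reactants": {"Dstar": 1}, "products": {"D": 1},
             "mass_action": "d_d"},
            {"id": "out_act", "reactants": {"Dstar": 1, "OUT": 1},
             "products": {"Dstar": 1, "OUTstar": 1}, "mass_action": "a_out"},
            {"id": "out_deact", "reactants": {"OUTstar": 1}, "products": {"OUT": 1},
             "mass_action": "d_out"},
        ],
    }
    return build_network(spec)


def list_fixtures() -> dict[str, object]:
    """Name → zero-argument constructor for every bundled fixture."""
    return {
        "michaelis-menten": michaelis_menten,
        "birth-death": birth_death,
        "linear-chain": linear_chain,
        "closed-cycle": closed_cycle,
        "erk-mapk-cascade": erk_cascade,
        "two-branch-cascade": two_branch_cascade,
    }
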