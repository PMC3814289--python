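"""Model file formats and result writers.

The native model format is a YAML document with sections ``species``,
``reactions`` (each with ``reactants``, ``products`` and a ``rate``
formula or ``mass_action`` constant), ``parameters`` and ``system_size``
— see the bundled Michaelis–Menten file for the reference schema.  A
convenience importer accepts a subset of single-compartment SBML Level
2/3 with irreversible reactions and explicit kinetic laws; reversible
reactions and multi-compartment documents are rejected with explicit
messages.  Matrices go out as TSV with full float precision, reports as
JSON — both byte-deterministic.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import yaml

from . import expr as ex
from .model import ModelError, ReactionNetwork, build_network

__all__ = [
    "load_model",
    "load_native",
    "save_native",
    "load_sbml",
    "write_covariance",
    "read_covariance",
    "write_json_report",
]


def load_model(path: str | Path) -> ReactionNetwork:
    """Load a network from a native YAML file or an SBML subset file."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    head = path.read_bytes()[:512].lstrip()
    if head.startswith(b"<"):
        return load_sbml(path)
    return load_native(path)


def load_native(path: str | Path) -> ReactionNetwork:
    with open(path) as fh:
        try:
            spec = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise ModelError(f"cannot parse model file {path}: {exc}") from exc
    if not isinstance(spec, dict):
        raise ModelError(f"model file {path} is not a mapping")
    return build_network(spec)


def network_to_dict(net: ReactionNetwork) -> dict:
    reactions = []
    for r in net.reactions:
        entry: dict = {"id": r.id}
        if r.reactants:
            entry["reactants"] = dict(r.reactants)
        if r.products:
            entry["products"] = dict(r.products)
        if r.rate_law.kind == "mass_action":
            entry["mass_action"] = r.rate_law.constant
        else:
            entry["rate"] = r.rate_law.formula
        if r.reversible:
            entry["reversible"] = True
        reactions.append(entry)
    return {
        "name": net.name,
        "system_size": net.system_size,
        "species": [
            {"id": s.id, "name": s.name, "initial": s.initial_density}
            for s in net.species
        ],
        "parameters": dict(net.parameters),
        "reactions": reactions,
    }


def save_native(net: ReactionNetwork, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(network_to_dict(net), fh, sort_keys=False)


# -- SBML subset -------------------------------------------------------------

_SBML_NS = "http://www.sbml.org/sbml/{}"
_MATHML_NS = "http://www.w3.org/1998/Math/MathML"


def _local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _mathml_to_expr(node) -> ex.Expr:
    tag = _local(node.tag)
    if tag == "math":
        children = [c for c in node if isinstance(c.tag, str)]
        if len(children) != 1:
            raise ModelError("SBML kinetic law: expected a single MathML root")
        return _mathml_to_expr(children[0])
    if tag == "cn":
        text = (node.text or "").strip()
        if node.get("type") == "e-notation":
            parts = [t.strip() for t in node.itertext() if t.strip()]
            return ex.num(float(f"{parts[0]}e{parts[1]}"))
        return ex.num(float(text))
    if tag == "ci":
        return ex.sym((node.text or "").strip())
    if tag == "apply":
        children = [c for c in node if isinstance(c.tag, str)]
        op = _local(children[0].tag)
        args = [_mathml_to_expr(c) for c in children[1:]]
        if op == "plus":
            out = args[0] if args else ex.num(0.0)
            for a in args[1:]:
                out = ex.add(out, a)
            return out
        if op == "minus":
            if len(args) == 1:
                return ex.neg(args[0])
            return ex.sub(args[0], args[1])
        if op == "times":
            out = args[0]
            for a in args[1:]:
                out = ex.mul(out, a)
            return out
        if op == "divide":
            return ex.div(args[0], args[1])
        if op == "power":
            return ex.pow_(args[0], args[1])
        raise ModelError(f"unsupported MathML operator <{op}> in SBML kinetic law")
    raise ModelError(f"unsupported MathML element <{tag}> in SBML kinetic law")


def load_sbml(path: str | Path) -> ReactionNetwork:
    """Import a single-compartment SBML Level 2/3 subset.

    Supported: species with initial concentration or amount, global and
    reaction-local parameters, irreversible reactions with explicit
    arithmetic kinetic laws (amount/time convention: the law is divided
    by the compartment size to obtain a density-scale rate).

    Rejected with explicit messages: more than one compartment,
    reversible reactions, rules/events/function definitions.
    """
    from lxml import etree

    tree = etree.parse(str(path))
    root = tree.getroot()
    if _local(root.tag) != "sbml":
        raise ModelError(f"{path} is not an SBML document")
    model = next((c for c in root if _local(c.tag) == "model"), None)
    if model is None:
        raise ModelError("SBML document has no <model>")

    def section(name):
        el = next((c for c in model if _local(c.tag) == name), None)
        return list(el) if el is not None else []

    for unsupported in ("listOfRules", "listOfEvents", "listOfFunctionDefinitions"):
        if section(unsupported):
            raise ModelError(
                f"unsupported SBML construct {unsupported}: only plain "
                f"reaction networks are handled"
            )
    compartments = [c for c in section("listOfCompartments") if _local(c.tag) == "compartment"]
    if len(compartments) > 1:
        raise ModelError(
            f"SBML model has {len(compartments)} compartments; only "
            f"single-compartment models are supported"
        )
    comp_size = float(compartments[0].get("size", 1.0)) if compartments else 1.0
    comp_id = compartments[0].get("id") if compartments else None

    species = []
    for s in section("listOfSpecies"):
        if _local(s.tag) != "species":
            continue
        conc = s.get("initialConcentration")
        if conc is None:
            amount = s.get("initialAmount")
            conc = float(amount) / comp_size if amount is not None else 0.0
        species.append(
            {"id": s.get("id"), "name": s.get("name", ""), "initial": float(conc)}
        )

    parameters = {}
    for p in section("listOfParameters"):
        if _local(p.tag) == "parameter":
            parameters[p.get("id")] = float(p.get("value", 0.0))
    if comp_id:
        parameters.setdefault(comp_id, comp_size)

    reactions = []
    for r in section("listOfReactions"):
        if _local(r.tag) != "reaction":
            continue
        rid = r.get("id")
        if r.get("reversible", "true").lower() == "true":
            raise ModelError(
                f"SBML reaction {rid!r} is reversible; split all reversible "
                f"reactions into irreversible pairs before import"
            )

        def refs(name, r=r):
            el = next((c for c in r if _local(c.tag) == name), None)
            out = {}
            for ref in el if el is not None else []:
                if _local(ref.tag) == "speciesReference":
                    sp = ref.get("species")
                    out[sp] = out.get(sp, 0) + int(float(ref.get("stoichiometry", 1)))
            return out

        kl = next((c for c in r if _local(c.tag) == "kineticLaw"), None)
        if kl is None:
            raise ModelError(f"SBML reaction {rid!r} has no kinetic law")
        for lp in kl:
            if _local(lp.tag) in ("listOfParameters", "listOfLocalParameters"):
                for p in lp:
                    if _local(p.tag) in ("parameter", "localParameter"):
                        parameters[p.get("id")] = float(p.get("value", 0.0))
        math_el = next((c for c in kl if _local(c.tag) == "math"), None)
        if math_el is None:
            raise ModelError(f"SBML reaction {rid!r}: kinetic law has no math")
        # SBML kinetic laws are substance/time; divide by compartment size
        # for the density-scale macroscopic rate
        rate = ex.div(_mathml_to_expr(math_el), ex.num(comp_size))
        reactions.append(
            {
                "id": rid,
                "reactants": refs("listOfReactants"),
                "products": refs("listOfProducts"),
                "rate": ex.to_source(rate),
            }
        )

    return build_network(
        {
            "name": model.get("id", "") or model.get("name", ""),
            "system_size": 1.0,
            "species": species,
            "parameters": parameters,
            "reactions": reactions,
        }
    )


# -- writers -----------------------------------------------------------------


def write_covariance(C: np.ndarray, species_names, path: str | Path) -> None:
    """Write a labelled covariance matrix as TSV (full repr precision)."""
    C = np.asarray(C)
    names = list(species_names)
    if C.ndim != 2 or C.shape[0] != C.shape[1] or C.shape[0] != len(names):
        raise ValueError("covariance matrix and species names do not match")
    with open(path, "w") as fh:
        fh.write("\t" + "\t".join(names) + "\n")
        for name, row in zip(names, C):
            fh.write(name + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def read_covariance(path: str | Path) -> tuple[list[str], np.ndarray]:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
        rows = []
        for line in fh:
            rows.append([float(v) for v in line.rstrip("\n").split("\t")[1:]])
    return header, np.array(rows)


def write_json_report(data: dict, path: str | Path) -> None:
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        raise TypeError(f"not JSON serialisable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(data, fh, indent=2, default=default, sort_keys=True)
        fh.write("\n")
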