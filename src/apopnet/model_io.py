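"""Model serialization: constrained mass-action SBML and tabular TSV.

The SBML dialect handled here is deliberately narrow: species with initial
amounts, global (or promoted local) parameters, and reactions whose kinetic
law is a pure mass-action monomial ``k * prod C_i^n_i`` over the reaction's
reactants (catalysts appearing in the law are folded in as
reactant-and-product species).  Anything else — rational rate laws, sums,
events, assignment rules — is rejected with a message naming the offending
reaction, never silently approximated.

Feedback terms injected into a network's balance equations are materialized
as ordinary reactions on export (positive: catalytic zeroth-order-in-target
production; negative: bimolecular degradation), so exported files are
self-contained mass-action models.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from lxml import etree

from .network import (
    ExtraRateTerm,
    RateParameter,
    ReactionDef,
    ReactionNetwork,
    SpeciesDef,
)

__all__ = [
    "ModelManifest",
    "SBMLParseError",
    "UnsupportedKineticsError",
    "load_sbml",
    "load_toy",
    "write_network",
    "load_network_tsv",
    "materialize_feedback",
]

SBML_NS_L3 = "http://www.sbml.org/sbml/level3/version1/core"
MATHML_NS = "http://www.w3.org/1998/Math/MathML"

KEY_ROLES = (
    "tnf_input",
    "complex1",
    "complex2",
    "nfkb_active",
    "caspase3_active",
    "caspase8_active",
    "caspase6_active",
)


class SBMLParseError(ValueError):
    """The file is not parseable as the supported SBML subset."""


class UnsupportedKineticsError(SBMLParseError):
    """A reaction's rate law cannot be expressed as mass action."""


@dataclass
class ModelManifest:
    source: str  # 'sbml-file' or 'builtin-toy'
    species_count: int
    reaction_count: int
    parameter_count: int
    key_species_map: dict[str, str] = field(default_factory=dict)
    substance_units: str | None = None  # as declared by the file; not converted

    def validate_against(self, network: ReactionNetwork) -> None:
        if (self.species_count != len(network.species)
                or self.reaction_count != len(network.reactions)
                or self.parameter_count != len(network.parameters)):
            raise ValueError("manifest counts do not match the network")
        ids = set(network.species_ids)
        for role, sid in self.key_species_map.items():
            if sid not in ids:
                raise ValueError(f"role {role!r} maps to unknown species {sid!r}")


def load_toy(config=None) -> tuple[ReactionNetwork, ModelManifest]:
    """The bundled reduced survival/apoptosis network (see `synthetic`)."""
    from .synthetic import make_toy_network

    toy = make_toy_network(config)
    net = toy.network
    manifest = ModelManifest(
        source="builtin-toy",
        species_count=len(net.species),
        reaction_count=len(net.reactions),
        parameter_count=len(net.parameters),
        key_species_map=dict(toy.key_species_map),
        substance_units="amol",
    )
    manifest.validate_against(net)
    return net, manifest


# --------------------------------------------------------------------- SBML in


def _local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _findall(el, name):
    return [c for c in el.iter() if _local(c.tag) == name]


def _children(el, name):
    return [c for c in el if _local(c.tag) == name]


def _parse_mathml_monomial(math_el, rxn_id: str):
    """Flatten a MathML expression into (symbols with powers); reject non-monomials."""

    def walk(el) -> list[tuple[str, float]]:
        tag = _local(el.tag)
        if tag == "math":
            kids = list(el)
            if len(kids) != 1:
                raise UnsupportedKineticsError(
                    f"reaction {rxn_id}: kinetic law is not a single expression"
                )
            return walk(kids[0])
        if tag == "ci":
            return [(el.text.strip(), 1.0)]
        if tag == "cn":
            raise UnsupportedKineticsError(
                f"reaction {rxn_id}: numeric literal {el.text!r} in rate law; "
                "fold constants into the rate parameter"
            )
        if tag == "apply":
            kids = list(el)
            op = _local(kids[0].tag)
            if op == "times":
                out = []
                for k in kids[1:]:
                    out.extend(walk(k))
                return out
            if op == "power":
                if len(kids) != 3 or _local(kids[1].tag) != "ci" or _local(kids[2].tag) != "cn":
                    raise UnsupportedKineticsError(
                        f"reaction {rxn_id}: unsupported power expression"
                    )
                exp = float(kids[2].text)
                if exp != int(exp) or exp <= 0:
                    raise UnsupportedKineticsError(
                        f"reaction {rxn_id}: non-positive-integer exponent {exp}"
                    )
                return [(kids[1].text.strip(), exp)]
            raise UnsupportedKineticsError(
                f"reaction {rxn_id}: operator {op!r} is not mass-action"
            )
        raise UnsupportedKineticsError(
            f"reaction {rxn_id}: unsupported MathML element {tag!r}"
        )

    return walk(math_el)


def load_sbml(
    path: str | Path,
    key_species_map: dict[str, str] | None = None,
    parameter_categories: dict[str, str] | None = None,
) -> tuple[ReactionNetwork, ModelManifest]:
    """Load an SBML (Level 2/3) model whose kinetic laws are mass-action
    monomials.

    ``key_species_map`` assigns the named roles (tnf_input, caspase3_active,
    ...) to species ids of the file — species naming in deposited models
    cannot be assumed, so the mapping is caller-supplied.  The species mapped
    to ``tnf_input`` becomes the clamped stimulus.  ``parameter_categories``
    optionally assigns {association, dissociation, degradation, enzymatic,
    production} per parameter id (default: enzymatic).
    """
    path = Path(path)
    try:
        tree = etree.parse(str(path))
    except (etree.XMLSyntaxError, OSError) as exc:
        raise SBMLParseError(f"{path}: not parseable XML: {exc}") from exc
    root = tree.getroot()
    if _local(root.tag) != "sbml":
        raise SBMLParseError(f"{path}: root element is {_local(root.tag)!r}, not sbml")
    models = _findall(root, "model")
    if not models:
        raise SBMLParseError(f"{path}: no model element")
    model = models[0]
    substance_units = model.get("substanceUnits")

    compartments = {
        c.get("id"): float(c.get("size", "1") or 1)
        for c in _findall(model, "compartment")
    }

    key_species_map = dict(key_species_map or {})
    input_id = key_species_map.get("tnf_input")

    species: list[SpeciesDef] = []
    for s in _findall(model, "species"):
        sid = s.get("id")
        amt = s.get("initialAmount")
        if amt is None:
            amt = s.get("initialConcentration", "0")
        species.append(SpeciesDef(id=sid, name=s.get("name", "") or "",
                                  initial_amount=float(amt or 0),
                                  is_input=(sid == input_id)))
    if not species:
        raise SBMLParseError(f"{path}: model declares no species")
    species_ids = {s.id for s in species}

    cats = parameter_categories or {}
    parameters: list[RateParameter] = []
    for p in _children(_children(model, "listOfParameters")[0], "parameter") \
            if _children(model, "listOfParameters") else []:
        parameters.append(RateParameter(id=p.get("id"), value=float(p.get("value", "0") or 0),
                                        category=cats.get(p.get("id"), "enzymatic")))
    param_ids = {p.id for p in parameters}

    reactions: list[ReactionDef] = []
    for r in _findall(model, "reaction"):
        rid = r.get("id")
        reactants: dict[str, int] = {}
        products: dict[str, int] = {}
        for lst, target in (("listOfReactants", reactants), ("listOfProducts", products)):
            for ref in (_children(_children(r, lst)[0], "speciesReference")
                        if _children(r, lst) else []):
                st = float(ref.get("stoichiometry", "1") or 1)
                if st != int(st) or st <= 0:
                    raise SBMLParseError(
                        f"{path}: reaction {rid}: non-positive-integer stoichiometry {st}"
                    )
                target[ref.get("species")] = target.get(ref.get("species"), 0) + int(st)

        kls = _children(r, "kineticLaw")
        if not kls:
            raise UnsupportedKineticsError(f"reaction {rid}: no kinetic law")
        kl = kls[0]
        # promote local parameters with a reaction-scoped prefix
        local_seen: dict[str, str] = {}
        for lp in _findall(kl, "localParameter") + [
            p for lst in _children(kl, "listOfParameters") for p in lst
        ]:
            promoted = f"{rid}__{lp.get('id')}"
            parameters.append(RateParameter(id=promoted,
                                            value=float(lp.get("value", "0") or 0),
                                            category=cats.get(promoted, "enzymatic")))
            param_ids.add(promoted)
            local_seen[lp.get("id")] = promoted

        maths = [c for c in kl if _local(c.tag) == "math"]
        if not maths:
            raise UnsupportedKineticsError(f"reaction {rid}: kinetic law has no math")
        factors = _parse_mathml_monomial(maths[0], rid)

        k_id = None
        law_powers: dict[str, float] = {}
        for sym, exp in factors:
            sym = local_seen.get(sym, sym)
            if sym in param_ids:
                if k_id is not None or exp != 1.0:
                    raise UnsupportedKineticsError(
                        f"reaction {rid}: rate law is not k * product(species)"
                    )
                k_id = sym
            elif sym in species_ids:
                law_powers[sym] = law_powers.get(sym, 0.0) + exp
            elif sym in compartments and compartments[sym] == 1.0 and exp == 1.0:
                continue  # unit compartment factor
            else:
                raise UnsupportedKineticsError(
                    f"reaction {rid}: unknown symbol {sym!r} in rate law"
                )
        if k_id is None:
            raise UnsupportedKineticsError(f"reaction {rid}: no rate constant in law")

        # the law must cover the listed reactants exactly; extra law species are
        # catalysts, folded in on both sides
        for sid, n in reactants.items():
            if law_powers.get(sid, 0) != n:
                raise UnsupportedKineticsError(
                    f"reaction {rid}: law power of {sid} != reactant stoichiometry {n}"
                )
        for sid, p in law_powers.items():
            if sid not in reactants:
                if p != int(p):
                    raise UnsupportedKineticsError(
                        f"reaction {rid}: fractional catalyst power for {sid}"
                    )
                reactants[sid] = int(p)
                products[sid] = products.get(sid, 0) + int(p)
        reactions.append(ReactionDef(id=rid, rate_constant_id=k_id,
                                     reactants=reactants, products=products))

    network = ReactionNetwork(species, reactions, parameters)
    manifest = ModelManifest(
        source="sbml-file",
        species_count=len(species),
        reaction_count=len(reactions),
        parameter_count=len(parameters),
        key_species_map=key_species_map,
        substance_units=substance_units,
    )
    manifest.validate_against(network)
    return network, manifest


# -------------------------------------------------------------------- SBML out


def materialize_feedback(network: ReactionNetwork) -> ReactionNetwork:
    """Replace injected balance-equation terms by equivalent reactions.

    positive (+k·[src] on target):   src -> src + target      (production)
    negative (−k·[src]·[target]):    src + target -> src      (degradation)
    """
    if not network.extra_rate_terms:
        return network
    species = list(network.species)
    reactions = list(network.reactions)
    params = list(network.parameters.values())
    for i, term in enumerate(network.extra_rate_terms):
        pid = f"k_fb_{term.sign}_{i}"
        if term.sign == "positive":
            params.append(RateParameter(pid, term.strength, "production"))
            reactions.append(ReactionDef(
                id=f"r_fb_{term.sign}_{i}", rate_constant_id=pid,
                reactants={term.source: 1},
                products={term.source: 1, term.target: 1}))
        else:
            params.append(RateParameter(pid, term.strength, "degradation"))
            reactions.append(ReactionDef(
                id=f"r_fb_{term.sign}_{i}", rate_constant_id=pid,
                reactants={term.source: 1, term.target: 1},
                products={term.source: 1}))
    return ReactionNetwork(species, reactions, params, extra_rate_terms=[])


def _mathml_monomial(k_id: str, powers: dict[str, int]):
    M = "{%s}" % MATHML_NS
    factors = [(k_id, 1)] + sorted(powers.items())
    math = etree.Element(f"{M}math")
    if len(factors) == 1 and factors[0][1] == 1:
        ci = etree.SubElement(math, f"{M}ci")
        ci.text = f" {k_id} "
        return math
    apply = etree.SubElement(math, f"{M}apply")
    etree.SubElement(apply, f"{M}times")
    for sym, exp in factors:
        if exp == 1:
            ci = etree.SubElement(apply, f"{M}ci")
            ci.text = f" {sym} "
        else:
            pw = etree.SubElement(apply, f"{M}apply")
            etree.SubElement(pw, f"{M}power")
            ci = etree.SubElement(pw, f"{M}ci")
            ci.text = f" {sym} "
            cn = etree.SubElement(pw, f"{M}cn")
            cn.set("type", "integer")
            cn.text = f" {exp} "
    return math


def _write_sbml(network: ReactionNetwork, path: Path) -> None:
    S = "{%s}" % SBML_NS_L3
    root = etree.Element(f"{S}sbml", nsmap={None: SBML_NS_L3})
    root.set("level", "3")
    root.set("version", "1")
    model = etree.SubElement(root, f"{S}model")
    model.set("id", "network")
    model.set("substanceUnits", "item")  # amounts (amol) as substance units

    lc = etree.SubElement(model, f"{S}listOfCompartments")
    comp = etree.SubElement(lc, f"{S}compartment")
    comp.set("id", "cell")
    comp.set("size", "1")
    comp.set("constant", "true")

    ls = etree.SubElement(model, f"{S}listOfSpecies")
    for sp in network.species:
        el = etree.SubElement(ls, f"{S}species")
        el.set("id", sp.id)
        if sp.name:
            el.set("name", sp.name)
        el.set("compartment", "cell")
        el.set("initialAmount", repr(sp.initial_amount))
        el.set("hasOnlySubstanceUnits", "true")
        el.set("boundaryCondition", "true" if sp.is_input else "false")
        el.set("constant", "false")

    lp = etree.SubElement(model, f"{S}listOfParameters")
    for p in network.parameters.values():
        el = etree.SubElement(lp, f"{S}parameter")
        el.set("id", p.id)
        el.set("value", repr(p.value))
        el.set("constant", "true")
        el.set("name", f"category:{p.category}")

    lr = etree.SubElement(model, f"{S}listOfReactions")
    for rxn in network.reactions:
        el = etree.SubElement(lr, f"{S}reaction")
        el.set("id", rxn.id)
        el.set("reversible", "false")
        el.set("fast", "false")
        if rxn.reactants:
            lst = etree.SubElement(el, f"{S}listOfReactants")
            for sid, n in rxn.reactants.items():
                ref = etree.SubElement(lst, f"{S}speciesReference")
                ref.set("species", sid)
                ref.set("stoichiometry", str(n))
                ref.set("constant", "true")
        if rxn.products:
            lst = etree.SubElement(el, f"{S}listOfProducts")
            for sid, n in rxn.products.items():
                ref = etree.SubElement(lst, f"{S}speciesReference")
                ref.set("species", sid)
                ref.set("stoichiometry", str(n))
                ref.set("constant", "true")
        kl = etree.SubElement(el, f"{S}kineticLaw")
        kl.append(_mathml_monomial(rxn.rate_constant_id, rxn.reactants))

    path.write_bytes(etree.tostring(root, pretty_print=True,
                                    xml_declaration=True, encoding="UTF-8"))


# --------------------------------------------------------------------- TSV i/o


def _encode_side(side: dict[str, int]) -> str:
    return ";".join(f"{s}:{n}" for s, n in side.items())


def _decode_side(text) -> dict[str, int]:
    if text is None or (isinstance(text, float) and pd.isna(text)) or text == "":
        return {}
    out = {}
    for item in str(text).split(";"):
        sid, n = item.split(":")
        out[sid] = int(n)
    return out


def _write_tsv(network: ReactionNetwork, path: Path) -> None:
    path.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        [{"id": s.id, "name": s.name, "initial_amount": repr(s.initial_amount),
          "is_input": s.is_input} for s in network.species]
    ).to_csv(path / "species.tsv", sep="\t", index=False)
    pd.DataFrame(
        [{"id": p.id, "value": repr(p.value), "category": p.category}
         for p in network.parameters.values()]
    ).to_csv(path / "parameters.tsv", sep="\t", index=False)
    pd.DataFrame(
        [{"id": r.id, "rate_constant_id": r.rate_constant_id,
          "reactants": _encode_side(r.reactants), "products": _encode_side(r.products)}
         for r in network.reactions]
    ).to_csv(path / "reactions.tsv", sep="\t", index=False)


def load_network_tsv(path: str | Path) -> ReactionNetwork:
    path = Path(path)
    sp = pd.read_csv(path / "species.tsv", sep="\t")
    pa = pd.read_csv(path / "parameters.tsv", sep="\t")
    rx = pd.read_csv(path / "reactions.tsv", sep="\t")
    species = [SpeciesDef(id=r["id"], name="" if pd.isna(r["name"]) else str(r["name"]),
                          initial_amount=float(r["initial_amount"]),
                          is_input=bool(r["is_input"]))
               for _, r in sp.iterrows()]
    params = [RateParameter(id=r["id"], value=float(r["value"]), category=r["category"])
              for _, r in pa.iterrows()]
    reactions = [ReactionDef(id=r["id"], rate_constant_id=r["rate_constant_id"],
                             reactants=_decode_side(r["reactants"]),
                             products=_decode_side(r["products"]))
                 for _, r in rx.iterrows()]
    return ReactionNetwork(species, reactions, params)


def write_network(
    network: ReactionNetwork,
    path: str | Path,
    format: str = "sbml",
    materialize: bool = True,
) -> None:
    """Serialize to SBML (single file) or TSV tables (directory).

    Networks carrying injected feedback terms are exported only after those
    terms are materialized as reactions (``materialize=True``); otherwise the
    export is refused, because neither format can express bare balance-equation
    terms.
    """
    if network.extra_rate_terms:
        if not materialize:
            raise ValueError(
                "network has injected feedback terms; export refused "
                "(pass materialize=True to write them as reactions)"
            )
        network = materialize_feedback(network)
    path = Path(path)
    if format == "sbml":
        _write_sbml(network, path)
    elif format == "tsv":
        _write_tsv(network, path)
    else:
        raise ValueError(f"unknown format {format!r} (expected 'sbml' or 'tsv')")
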