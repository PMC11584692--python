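"""SBML Level 3 Version 2 export/import.

The writer emits a self-contained L3V2 document with one kinetic law per
reaction, written as explicit MathML (mass action times saturating
regulator factors).  Machine-readable annotations in the bmecsim namespace
carry the structured rate-law metadata (kind, Hill constants, regulator
modes, module labels, role tags), which makes the import side lossless: a
re-imported model rebuilds the exact :class:`ModelNetwork`/
:class:`ParameterSet` pair and reproduces native trajectories.  The reader
supports this documented subset of SBML, not arbitrary third-party models.
"""

from __future__ import annotations

import json
import re
import xml.etree.ElementTree as ET

import numpy as np

from .network import (
    ModelNetwork,
    ParameterSet,
    RateLaw,
    Reaction,
    Regulator,
    SpeciesDef,
)

SBML_NS = "http://www.sbml.org/sbml/level3/version2/core"
MATHML_NS = "http://www.w3.org/1998/Math/MathML"
BMEC_NS = "https://bmecsim.invalid/sbml/1"

_SID_RE = re.compile(r"^[A-Za-z_][A-Za-z0-9_]*$")


def sanitize_id(sid: str, taken: set[str]) -> str:
    """Deterministic mapping of an arbitrary id to a valid SBML SId."""
    out = re.sub(r"[^A-Za-z0-9_]", "_", sid)
    if not out or not re.match(r"[A-Za-z_]", out[0]):
        out = "x_" + out
    base = out
    i = 2
    while out in taken:
        out = f"{base}_{i}"
        i += 1
    taken.add(out)
    return out


def _math_flux(reaction: Reaction, param_sid: str, sp_map: dict[str, str]) -> ET.Element:
    """MathML expression for the reaction flux."""

    def ci(name: str) -> ET.Element:
        e = ET.Element(f"{{{MATHML_NS}}}ci")
        e.text = f" {name} "
        return e

    def cn(value: float) -> ET.Element:
        e = ET.Element(f"{{{MATHML_NS}}}cn")
        e.text = f" {value:.17g} "
        return e

    def apply(op: str, *args: ET.Element) -> ET.Element:
        a = ET.Element(f"{{{MATHML_NS}}}apply")
        a.append(ET.Element(f"{{{MATHML_NS}}}{op}"))
        for x in args:
            a.append(x)
        return a

    def power(base: ET.Element, n: float) -> ET.Element:
        if n == 1:
            return base
        return apply("power", base, cn(n))

    def hill(species: str, K: float, n: float, inhibit: bool) -> ET.Element:
        kn = cn(K**n)
        sn = power(ci(sp_map[species]), n)
        denom = apply("plus", cn(K**n), power(ci(sp_map[species]), n))
        num = kn if inhibit else sn
        return apply("divide", num, denom)

    factors: list[ET.Element] = [ci(param_sid)]
    kind = reaction.rate_law.kind
    if kind == "michaelis_menten":
        sp, _ = reaction.reactants[0]
        factors.append(
            hill(sp, reaction.rate_law.hill_K, reaction.rate_law.hill_n, False)
        )
    elif kind != "zeroth_order_synthesis":
        for sp, st in reaction.reactants:
            factors.append(power(ci(sp_map[sp]), st))
    for i, reg in enumerate(reaction.regulators):
        K, n, mode = reg.K, reg.n, reg.mode
        if i == 0 and kind in ("hill_activation", "hill_inhibition"):
            K = reaction.rate_law.hill_K if K is None else K
            n = reaction.rate_law.hill_n if reg.K is None else n
            if mode == "linear":
                mode = "activate" if kind == "hill_activation" else "inhibit"
        if mode == "linear":
            factors.append(ci(sp_map[reg.species]))
        else:
            factors.append(hill(reg.species, K, n, mode == "inhibit"))
    math = ET.Element(f"{{{MATHML_NS}}}math")
    if len(factors) == 1:
        math.append(factors[0])
    else:
        math.append(apply("times", *factors))
    return math


def export_sbml(
    network: ModelNetwork,
    params: ParameterSet,
    initial_state: np.ndarray | None = None,
) -> bytes:
    """Serialize the model as an SBML L3V2 document (UTF-8 bytes)."""
    network.check_parameters(params)
    state = (
        np.asarray(initial_state, dtype=float)
        if initial_state is not None
        else network.initial_state()
    )
    ET.register_namespace("", SBML_NS)
    ET.register_namespace("math", MATHML_NS)
    ET.register_namespace("bmec", BMEC_NS)
    root = ET.Element(f"{{{SBML_NS}}}sbml", {"level": "3", "version": "2"})
    model = ET.SubElement(root, f"{{{SBML_NS}}}model",
                          {"id": str(network.metadata.get("name", "model")).replace("-", "_")})

    taken: set[str] = set()
    compartments = sorted({s.compartment for s in network.species})
    comp_map = {c: sanitize_id(c, taken) for c in compartments}
    sp_map = {s.id: sanitize_id(s.id, taken) for s in network.species}
    rx_taken: set[str] = set(taken)
    rx_map = {r.id: sanitize_id(r.id, rx_taken) for r in network.reactions}
    par_taken = set(rx_taken)
    par_ids = sorted(params.values)
    par_map = {p: sanitize_id(p, par_taken) for p in par_ids}

    lc = ET.SubElement(model, f"{{{SBML_NS}}}listOfCompartments")
    for c in compartments:
        ET.SubElement(lc, f"{{{SBML_NS}}}compartment",
                      {"id": comp_map[c], "constant": "true", "size": "1"})
    ls = ET.SubElement(model, f"{{{SBML_NS}}}listOfSpecies")
    for s, amount in zip(network.species, state):
        el = ET.SubElement(
            ls, f"{{{SBML_NS}}}species",
            {
                "id": sp_map[s.id],
                "compartment": comp_map[s.compartment],
                "initialAmount": f"{amount:.17g}",
                "hasOnlySubstanceUnits": "true",
                "boundaryCondition": (
                    "true" if "environment" in s.role_tags else "false"
                ),
                "constant": "false",
            },
        )
        ann = ET.SubElement(el, f"{{{SBML_NS}}}annotation")
        ET.SubElement(ann, f"{{{BMEC_NS}}}speciesInfo", {
            "originalId": s.id,
            "roleTags": ",".join(sorted(s.role_tags)),
            "declaredInitial": f"{s.initial_amount:.17g}",
        })
    lp = ET.SubElement(model, f"{{{SBML_NS}}}listOfParameters")
    for p in par_ids:
        el = ET.SubElement(lp, f"{{{SBML_NS}}}parameter",
                           {"id": par_map[p], "value": f"{params.values[p]:.17g}",
                            "constant": "true"})
        if p in params.bounds:
            lo, hi = params.bounds[p]
            ann = ET.SubElement(el, f"{{{SBML_NS}}}annotation")
            ET.SubElement(ann, f"{{{BMEC_NS}}}parameterInfo", {
                "originalId": p, "low": f"{lo:.17g}", "high": f"{hi:.17g}",
            })
    lr = ET.SubElement(model, f"{{{SBML_NS}}}listOfReactions")
    for r in network.reactions:
        el = ET.SubElement(lr, f"{{{SBML_NS}}}reaction",
                           {"id": rx_map[r.id], "reversible": "false"})
        ann = ET.SubElement(el, f"{{{SBML_NS}}}annotation")
        ET.SubElement(ann, f"{{{BMEC_NS}}}rateLaw", {
            "originalId": r.id,
            "module": r.module,
            "kind": r.rate_law.kind,
            "parameterId": r.parameter_id,
            "hillK": "" if r.rate_law.hill_K is None else f"{r.rate_law.hill_K:.17g}",
            "hillN": f"{r.rate_law.hill_n:.17g}",
            "regulators": json.dumps(
                [[g.species, g.mode,
                  None if g.K is None else g.K, g.n]
                 for g in r.regulators]
            ),
        })
        if r.reactants:
            lre = ET.SubElement(el, f"{{{SBML_NS}}}listOfReactants")
            for sp, st in r.reactants:
                ET.SubElement(lre, f"{{{SBML_NS}}}speciesReference",
                              {"species": sp_map[sp], "stoichiometry": str(st),
                               "constant": "true"})
        if r.products:
            lpr = ET.SubElement(el, f"{{{SBML_NS}}}listOfProducts")
            for sp, st in r.products:
                ET.SubElement(lpr, f"{{{SBML_NS}}}speciesReference",
                              {"species": sp_map[sp], "stoichiometry": str(st),
                               "constant": "true"})
        mods = [m for m in r.modifiers if m not in {x for x, _ in r.reactants}]
        if mods:
            lm = ET.SubElement(el, f"{{{SBML_NS}}}listOfModifiers")
            for m in dict.fromkeys(mods):
                ET.SubElement(lm, f"{{{SBML_NS}}}modifierSpeciesReference",
                              {"species": sp_map[m]})
        kl = ET.SubElement(el, f"{{{SBML_NS}}}kineticLaw")
        kl.append(_math_flux(r, par_map[r.parameter_id], sp_map))
    ET.indent(root)
    return ET.tostring(root, encoding="utf-8", xml_declaration=True)


def validate_sbml(document: bytes) -> list[str]:
    """Structural checks of a document against the supported subset."""
    problems = []
    try:
        root = ET.fromstring(document)
    except ET.ParseError as exc:
        return [f"not well-formed XML: {exc}"]
    if root.tag != f"{{{SBML_NS}}}sbml":
        problems.append("root element is not sbml (L3V2 core namespace)")
    if root.get("level") != "3":
        problems.append("level is not 3")
    model = root.find(f"{{{SBML_NS}}}model")
    if model is None:
        problems.append("missing model element")
        return problems
    seen = set()
    for sp in model.iter(f"{{{SBML_NS}}}species"):
        sid = sp.get("id", "")
        if not _SID_RE.match(sid):
            problems.append(f"invalid species id {sid!r}")
        if sid in seen:
            problems.append(f"duplicate id {sid!r}")
        seen.add(sid)
        if float(sp.get("initialAmount", "0")) < 0:
            problems.append(f"negative initial amount for {sid!r}")
    for rx in model.iter(f"{{{SBML_NS}}}reaction"):
        if rx.find(f"{{{SBML_NS}}}kineticLaw") is None:
            problems.append(f"reaction {rx.get('id')!r} lacks a kinetic law")
    return problems


def import_sbml(document: bytes) -> tuple[ModelNetwork, ParameterSet, np.ndarray]:
    """Rebuild (network, parameters, initial state) from an exported model."""
    problems = validate_sbml(document)
    if problems:
        raise ValueError("invalid SBML document: " + "; ".join(problems))
    root = ET.fromstring(document)
    model = root.find(f"{{{SBML_NS}}}model")

    species: list[SpeciesDef] = []
    amounts: list[float] = []
    sid_rev: dict[str, str] = {}
    comp_rev = {}
    for c in model.iter(f"{{{SBML_NS}}}compartment"):
        comp_rev[c.get("id")] = c.get("id")
    for sp in model.iter(f"{{{SBML_NS}}}species"):
        info = sp.find(f"{{{SBML_NS}}}annotation/{{{BMEC_NS}}}speciesInfo")
        if info is None:
            raise ValueError(
                f"species {sp.get('id')!r}: missing bmecsim annotation "
                "(only documents exported by this package are supported)"
            )
        orig = info.get("originalId")
        sid_rev[sp.get("id")] = orig
        tags = frozenset(t for t in info.get("roleTags", "").split(",") if t)
        species.append(
            SpeciesDef(orig, comp_rev[sp.get("compartment")],
                       float(info.get("declaredInitial")), tags)
        )
        amounts.append(float(sp.get("initialAmount")))

    values: dict[str, float] = {}
    bounds: dict[str, tuple[float, float]] = {}
    for p in model.iter(f"{{{SBML_NS}}}parameter"):
        info = p.find(f"{{{SBML_NS}}}annotation/{{{BMEC_NS}}}parameterInfo")
        orig = info.get("originalId") if info is not None else p.get("id")
        values[orig] = float(p.get("value"))
        if info is not None and info.get("low"):
            bounds[orig] = (float(info.get("low")), float(info.get("high")))

    reactions: list[Reaction] = []
    for rx in model.iter(f"{{{SBML_NS}}}reaction"):
        info = rx.find(f"{{{SBML_NS}}}annotation/{{{BMEC_NS}}}rateLaw")
        if info is None:
            raise ValueError(f"reaction {rx.get('id')!r}: missing rate-law annotation")
        regs = [
            Regulator(sp, mode, K, n)
            for sp, mode, K, n in json.loads(info.get("regulators"))
        ]
        hill_K = info.get("hillK") or None
        reactions.append(
            Reaction(
                id=info.get("originalId"),
                reactants=[
                    (sid_rev[e.get("species")], int(float(e.get("stoichiometry"))))
                    for e in rx.findall(
                        f"{{{SBML_NS}}}listOfReactants/{{{SBML_NS}}}speciesReference"
                    )
                ],
                products=[
                    (sid_rev[e.get("species")], int(float(e.get("stoichiometry"))))
                    for e in rx.findall(
                        f"{{{SBML_NS}}}listOfProducts/{{{SBML_NS}}}speciesReference"
                    )
                ],
                regulators=regs,
                rate_law=RateLaw(
                    kind=info.get("kind"),
                    hill_K=None if hill_K is None else float(hill_K),
                    hill_n=float(info.get("hillN")),
                ),
                parameter_id=info.get("parameterId"),
                module=info.get("module"),
            )
        )
    net = ModelNetwork(species, reactions, {"name": model.get("id")})
    return net, ParameterSet(values, bounds), np.asarray(amounts)
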