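"""SBML reading and writing (Level 2 Version 4, tolerant reader for L2V1–L3V1).

Supports the construct subset these models use: compartments, species,
global/local parameters, reactions with reactants/products/modifiers, kinetic
laws as content MathML, and assignment rules.  Kinetic laws whose local
parameters follow the ``k1 / kr1 / k2 / Km`` convention are mapped back to
structured mass-action / Michaelis–Menten rate laws and the mapping is
verified numerically against the original MathML on random states; anything
else is retained as an opaque expression evaluated symbolically.  Events,
delays, algebraic and rate rules raise an explicit unsupported-construct
error rather than being skipped silently.
"""

from __future__ import annotations

import ast
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from lxml import etree

from .errors import SbmlFormatError, ValidationError
from .expressions import compile_expression, names_in
from .reaction_network import (
    COMPARTMENTS,
    MASS_ACTION_IRREVERSIBLE,
    MASS_ACTION_REVERSIBLE,
    MICHAELIS_MENTEN,
    OPAQUE_EXPRESSION,
    RateLaw,
    Reaction,
    ReactionNetwork,
    Rule,
    Species,
    validate_network,
)

log = logging.getLogger(__name__)

SBML_L2V4_NS = "http://www.sbml.org/sbml/level2/version4"
MATHML_NS = "http://www.w3.org/1998/Math/MathML"

_UNSUPPORTED = (
    "listOfEvents",
    "listOfConstraints",
    "algebraicRule",
    "rateRule",
    "delay",
    "listOfSubmodels",  # hierarchical composition
    "listOfFunctionDefinitions",
)


@dataclass
class SbmlDocumentInfo:
    """Summary of a parsed or written SBML document."""

    level: int
    version: int
    n_species: int
    n_reactions: int
    n_parameters: int
    n_rules: int
    unresolved_constructs: list[str] = field(default_factory=list)

    @property
    def counts(self) -> tuple[int, int, int, int]:
        return (self.n_species, self.n_reactions, self.n_parameters, self.n_rules)


# ---------------------------------------------------------------------------
# expression <-> content MathML
# ---------------------------------------------------------------------------

_MATHML_OPS = {"plus": "+", "minus": "-", "times": "*", "divide": "/", "power": "**"}


def mathml_to_expression(node: etree._Element) -> str:
    """Convert a content-MathML element (``<math>`` or operand) to an
    arithmetic expression string."""
    tag = etree.QName(node).localname
    if tag == "math":
        children = [c for c in node if isinstance(c.tag, str)]
        if len(children) != 1:
            raise SbmlFormatError("MathML <math> must have exactly one child")
        return mathml_to_expression(children[0])
    if tag == "ci":
        return node.text.strip()
    if tag == "cn":
        if node.get("type") == "e-notation":
            parts = [t.strip() for t in node.itertext() if t.strip()]
            return f"({parts[0]}e{parts[1]})"
        return node.text.strip()
    if tag == "csymbol":
        return node.text.strip()
    if tag == "apply":
        children = [c for c in node if isinstance(c.tag, str)]
        op = etree.QName(children[0]).localname
        args = [mathml_to_expression(c) for c in children[1:]]
        if op in _MATHML_OPS:
            if op == "minus" and len(args) == 1:
                return f"(-{args[0]})"
            return "(" + f" {_MATHML_OPS[op]} ".join(args) + ")"
        if op in ("exp", "ln", "log", "root"):
            fn = {"exp": "exp", "ln": "log", "log": "log10", "root": "sqrt"}[op]
            return f"{fn}({args[0]})"
        raise SbmlFormatError(f"unsupported MathML operator <{op}>")
    raise SbmlFormatError(f"unsupported MathML element <{tag}>")


def _expr_ast_to_mathml(node: ast.expr) -> etree._Element:
    m = "{%s}" % MATHML_NS
    if isinstance(node, ast.Constant):
        el = etree.Element(m + "cn")
        el.text = repr(float(node.value))
        return el
    if isinstance(node, ast.Name):
        el = etree.Element(m + "ci")
        el.text = node.id
        return el
    if isinstance(node, ast.UnaryOp) and isinstance(node.op, ast.USub):
        apply = etree.Element(m + "apply")
        etree.SubElement(apply, m + "minus")
        apply.append(_expr_ast_to_mathml(node.operand))
        return apply
    if isinstance(node, ast.BinOp):
        ops = {ast.Add: "plus", ast.Sub: "minus", ast.Mult: "times",
               ast.Div: "divide", ast.Pow: "power"}
        opname = ops.get(type(node.op))
        if opname is None:
            raise ValidationError(f"cannot render operator {type(node.op).__name__} to MathML")
        apply = etree.Element(m + "apply")
        etree.SubElement(apply, m + opname)
        apply.append(_expr_ast_to_mathml(node.left))
        apply.append(_expr_ast_to_mathml(node.right))
        return apply
    if isinstance(node, ast.Call) and isinstance(node.func, ast.Name):
        fns = {"exp": "exp", "log": "ln", "log10": "log", "sqrt": "root"}
        if node.func.id not in fns:
            raise ValidationError(f"cannot render call {node.func.id!r} to MathML")
        apply = etree.Element(m + "apply")
        etree.SubElement(apply, m + fns[node.func.id])
        for arg in node.args:
            apply.append(_expr_ast_to_mathml(arg))
        return apply
    raise ValidationError(f"cannot render AST node {type(node).__name__} to MathML")


def expression_to_mathml(expression: str) -> etree._Element:
    """Render an arithmetic expression string as a content-MathML ``<math>``."""
    math = etree.Element("{%s}math" % MATHML_NS, nsmap={None: MATHML_NS})
    math.append(_expr_ast_to_mathml(ast.parse(expression, mode="eval").body))
    return math


def _rate_law_expression(rxn: Reaction) -> str:
    """Canonical expression string for a structured rate law."""
    law = rxn.rate_law
    if law.form == OPAQUE_EXPRESSION:
        return law.expression
    if law.form in (MASS_ACTION_IRREVERSIBLE, MASS_ACTION_REVERSIBLE):
        fwd = " * ".join(["k1"] + [f"{s}**{n}" if n > 1 else s for s, n in rxn.reactants])
        if law.form == MASS_ACTION_IRREVERSIBLE:
            return fwd
        rev = " * ".join(["kr1"] + [f"{s}**{n}" if n > 1 else s for s, n in rxn.products])
        return f"{fwd} - {rev}"
    substrate = rxn.reactants[0][0]
    et = " + ".join(rxn.modifiers)
    return f"k2 * ({et}) * {substrate} / (Km + {substrate})"


def _local_parameters(law: RateLaw) -> dict[str, float]:
    if law.form == MASS_ACTION_IRREVERSIBLE:
        return {"k1": law.k1}
    if law.form == MASS_ACTION_REVERSIBLE:
        return {"k1": law.k1, "kr1": law.kr1}
    if law.form == MICHAELIS_MENTEN:
        return {"k2": law.k2, "Km": law.Km}
    return {}


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------


def write_sbml(network: ReactionNetwork, path: str | Path) -> SbmlDocumentInfo:
    """Write *network* as SBML Level 2 Version 4 with MathML kinetic laws.

    Concentrations are nanomolar and times seconds; unit definitions for both
    are included.  Returns a document summary.
    """
    report = validate_network(network)
    if not report.ok:
        raise ValidationError(
            f"network does not validate: {report.dangling_references + report.negative_values}"
        )
    ns = "{%s}" % SBML_L2V4_NS
    root = etree.Element(ns + "sbml", nsmap={None: SBML_L2V4_NS})
    root.set("level", "2")
    root.set("version", "4")
    model = etree.SubElement(root, ns + "model")
    model.set("id", _sbml_id(network.name))
    model.set("name", network.name)

    units = etree.SubElement(model, ns + "listOfUnitDefinitions")
    for uid, (kind, scale, exponent) in {
        "substance": ("mole", -9, 1),      # nanomole
        "time": ("second", 0, 1),
    }.items():
        ud = etree.SubElement(units, ns + "unitDefinition")
        ud.set("id", uid)
        lou = etree.SubElement(ud, ns + "listOfUnits")
        u = etree.SubElement(lou, ns + "unit")
        u.set("kind", kind)
        u.set("scale", str(scale))
        u.set("exponent", str(exponent))

    comps = etree.SubElement(model, ns + "listOfCompartments")
    for cid in sorted({s.compartment for s in network.species.values()} or {"cytoplasm"}):
        c = etree.SubElement(comps, ns + "compartment")
        c.set("id", cid)
        c.set("size", "1")

    if network.species:
        los = etree.SubElement(model, ns + "listOfSpecies")
        for sp in network.species.values():
            el = etree.SubElement(los, ns + "species")
            el.set("id", sp.id)
            el.set("name", sp.display_name)
            el.set("compartment", sp.compartment)
            el.set("initialConcentration", repr(sp.initial_amount))
            el.set("constant", "true" if sp.is_constant else "false")

    if network.parameters:
        lop = etree.SubElement(model, ns + "listOfParameters")
        for name, value in network.parameters.items():
            p = etree.SubElement(lop, ns + "parameter")
            p.set("id", name)
            p.set("value", repr(value))

    if network.rules:
        lor = etree.SubElement(model, ns + "listOfRules")
        for rule in network.rules.values():
            el = etree.SubElement(lor, ns + "assignmentRule")
            el.set("variable", rule.target)
            el.append(expression_to_mathml(rule.expression))

    if network.reactions:
        lor = etree.SubElement(model, ns + "listOfReactions")
        for rxn in network.reactions.values():
            el = etree.SubElement(lor, ns + "reaction")
            el.set("id", rxn.id)
            el.set("reversible",
                   "true" if rxn.rate_law.form == MASS_ACTION_REVERSIBLE else "false")
            if rxn.reactants:
                lst = etree.SubElement(el, ns + "listOfReactants")
                for sid, coeff in rxn.reactants:
                    ref = etree.SubElement(lst, ns + "speciesReference")
                    ref.set("species", sid)
                    ref.set("stoichiometry", str(coeff))
            if rxn.products:
                lst = etree.SubElement(el, ns + "listOfProducts")
                for sid, coeff in rxn.products:
                    ref = etree.SubElement(lst, ns + "speciesReference")
                    ref.set("species", sid)
                    ref.set("stoichiometry", str(coeff))
            if rxn.modifiers:
                lst = etree.SubElement(el, ns + "listOfModifiers")
                for sid in rxn.modifiers:
                    ref = etree.SubElement(lst, ns + "modifierSpeciesReference")
                    ref.set("species", sid)
            kl = etree.SubElement(el, ns + "kineticLaw")
            kl.append(expression_to_mathml(_rate_law_expression(rxn)))
            locals_ = _local_parameters(rxn.rate_law)
            if locals_:
                lopl = etree.SubElement(kl, ns + "listOfParameters")
                for name, value in locals_.items():
                    p = etree.SubElement(lopl, ns + "parameter")
                    p.set("id", name)
                    p.set("value", repr(value))

    tree = etree.ElementTree(root)
    try:
        tree.write(str(path), xml_declaration=True, encoding="UTF-8", pretty_print=True)
    except OSError as exc:
        raise SbmlFormatError(f"cannot write SBML to {path}: {exc}") from exc
    n_sp, n_rx, n_par, n_ru = network.counts()
    return SbmlDocumentInfo(2, 4, n_sp, n_rx, n_par, n_ru)


def _sbml_id(name: str) -> str:
    out = "".join(ch if ch.isalnum() or ch == "_" else "_" for ch in name)
    return out if out and (out[0].isalpha() or out[0] == "_") else "m_" + out


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------


def _local(tag) -> str:
    return etree.QName(tag).localname if isinstance(tag, str) else ""


def _find(parent: etree._Element, name: str) -> list[etree._Element]:
    return [c for c in parent if isinstance(c.tag, str) and _local(c.tag) == name]


def _unit_factor_to_nM(model: etree._Element, unit_id: str | None) -> float | None:
    """Concentration factor to nM for a mole-based unit definition (size-1
    compartments); None when it cannot be determined."""
    if unit_id is None:
        return None
    for lod in _find(model, "listOfUnitDefinitions"):
        for ud in _find(lod, "unitDefinition"):
            if ud.get("id") != unit_id:
                continue
            for lou in _find(ud, "listOfUnits"):
                units = _find(lou, "unit")
                if len(units) == 1 and units[0].get("kind") == "mole":
                    scale = int(units[0].get("scale", "0"))
                    mult = float(units[0].get("multiplier", "1"))
                    return mult * 10.0 ** (scale + 9)
    return None


def read_sbml(path: str | Path) -> tuple[ReactionNetwork, SbmlDocumentInfo]:
    """Parse an SBML file into a :class:`ReactionNetwork` plus a document info.

    Raises
    ------
    SbmlFormatError
        For non-SBML XML, malformed documents, or explicitly unsupported
        constructs (events, delays, algebraic/rate rules, comp models).
    """
    path = Path(path)
    if not path.exists():
        raise SbmlFormatError(f"no such file: {path}")
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise SbmlFormatError(f"{path}: not well-formed XML (line {exc.lineno}): {exc.msg}") from exc
    root = tree.getroot()
    if _local(root.tag) != "sbml":
        raise SbmlFormatError(f"{path}: root element is <{_local(root.tag)}>, not <sbml>")
    level = int(root.get("level", "2"))
    version = int(root.get("version", "1"))
    models = _find(root, "model")
    if not models:
        raise SbmlFormatError(f"{path}: document has no <model>")
    model = models[0]

    for el in model.iter():
        if isinstance(el.tag, str) and _local(el.tag) in _UNSUPPORTED:
            raise SbmlFormatError(
                f"{path}: unsupported SBML construct <{_local(el.tag)}>"
            )

    net = ReactionNetwork(model.get("name") or model.get("id") or path.stem)
    net.metadata["sbml_level"] = (level, version)
    unresolved: list[str] = []

    compartment_map: dict[str, str] = {}
    for loc in _find(model, "listOfCompartments"):
        for comp in _find(loc, "compartment"):
            cid = comp.get("id")
            compartment_map[cid] = cid if cid in COMPARTMENTS else "cytoplasm"
            if cid not in COMPARTMENTS:
                log.warning("compartment %r not in the canonical set; mapped to cytoplasm", cid)

    default_factor = _unit_factor_to_nM(model, model.get("substanceUnits")) or \
        _unit_factor_to_nM(model, "substance")
    for los in _find(model, "listOfSpecies"):
        for sp in _find(los, "species"):
            init = sp.get("initialConcentration", sp.get("initialAmount", "0"))
            factor = _unit_factor_to_nM(model, sp.get("substanceUnits")) or default_factor
            if factor is None:
                factor = 1.0
                if sp.get("substanceUnits"):
                    log.warning("species %r: undeclared/unmapped units; assuming nM", sp.get("id"))
            net.add_species(Species(
                id=sp.get("id"),
                display_name=sp.get("name") or sp.get("id"),
                compartment=compartment_map.get(sp.get("compartment"), "cytoplasm"),
                initial_amount=float(init) * factor,
                is_constant=sp.get("constant") == "true" or sp.get("boundaryCondition") == "true",
            ))

    for lop in _find(model, "listOfParameters"):
        for p in _find(lop, "parameter"):
            net.set_parameter(p.get("id"), float(p.get("value", "0")))

    for lor in _find(model, "listOfRules"):
        for i, rule in enumerate(_find(lor, "assignmentRule")):
            maths = _find(rule, "math")
            if not maths:
                raise SbmlFormatError(f"{path}: assignmentRule without <math>")
            net.add_rule(Rule(f"rule_{i}", rule.get("variable"), mathml_to_expression(maths[0])))

    rng = np.random.default_rng(0)
    for lor in _find(model, "listOfReactions"):
        for rx in _find(lor, "reaction"):
            reactants = [
                (ref.get("species"), int(float(ref.get("stoichiometry", "1"))))
                for lst in _find(rx, "listOfReactants")
                for ref in _find(lst, "speciesReference")
            ]
            products = [
                (ref.get("species"), int(float(ref.get("stoichiometry", "1"))))
                for lst in _find(rx, "listOfProducts")
                for ref in _find(lst, "speciesReference")
            ]
            modifiers = [
                ref.get("species")
                for lst in _find(rx, "listOfModifiers")
                for ref in _find(lst, "modifierSpeciesReference")
            ]
            laws = _find(rx, "kineticLaw")
            if not laws:
                unresolved.append(f"reaction {rx.get('id')}: no kineticLaw")
                law, expr = RateLaw(MASS_ACTION_IRREVERSIBLE, k1=0.0), None
            else:
                locals_ = {
                    p.get("id"): float(p.get("value", "0"))
                    for lst in (_find(laws[0], "listOfParameters") + _find(laws[0], "listOfLocalParameters"))
                    for p in _find(lst, "parameter") + _find(lst, "localParameter")
                }
                maths = _find(laws[0], "math")
                if not maths:
                    raise SbmlFormatError(f"{path}: kineticLaw without <math> in {rx.get('id')}")
                expr = mathml_to_expression(maths[0])
                law = _classify_kinetic_law(
                    expr, locals_, reactants, products, modifiers, net, rng
                )
                if law.form == OPAQUE_EXPRESSION:
                    unresolved.append(f"reaction {rx.get('id')}: opaque kinetic law")
            rxn = Reaction(rx.get("id"), reactants, products, modifiers, law)
            net.add_reaction(rxn)

    n_sp, n_rx, n_par, n_ru = net.counts()
    info = SbmlDocumentInfo(level, version, n_sp, n_rx, n_par, n_ru, unresolved)
    net.metadata["sbml_info"] = info
    return net, info


def _classify_kinetic_law(
    expr: str,
    locals_: dict[str, float],
    reactants,
    products,
    modifiers,
    net: ReactionNetwork,
    rng: np.random.Generator,
    n_checks: int = 100,
    rtol: float = 1e-10,
) -> RateLaw:
    """Map a MathML kinetic expression back to a structured rate law when the
    local-parameter convention (k1/kr1/k2/Km) matches, verifying numerically
    on random non-negative states; otherwise keep the expression opaque."""
    candidate: RateLaw | None = None
    if set(locals_) == {"k1"}:
        candidate = RateLaw(MASS_ACTION_IRREVERSIBLE, k1=locals_["k1"])
    elif set(locals_) == {"k1", "kr1"}:
        candidate = RateLaw(MASS_ACTION_REVERSIBLE, k1=locals_["k1"], kr1=locals_["kr1"])
    elif set(locals_) == {"k2", "Km"} and len(reactants) == 1 and modifiers:
        if locals_["Km"] > 0:
            candidate = RateLaw(MICHAELIS_MENTEN, k2=locals_["k2"], Km=locals_["Km"])

    fallback_expr = _substitute_locals(expr, locals_)
    if candidate is None:
        return RateLaw(OPAQUE_EXPRESSION, expression=fallback_expr)

    reference = compile_expression(expr)
    ids = [sid for sid, _ in reactants] + [sid for sid, _ in products] + list(modifiers)
    for _ in range(n_checks):
        state = {sid: float(rng.uniform(0.0, 100.0)) for sid in ids}
        env = {**net.parameters, **locals_, **state, "t": 0.0}
        try:
            want = reference(env)
        except Exception:
            return RateLaw(OPAQUE_EXPRESSION, expression=fallback_expr)
        if candidate.form == MICHAELIS_MENTEN:
            got = candidate.k2 * sum(state[m] for m in modifiers) * state[reactants[0][0]] / (
                candidate.Km + state[reactants[0][0]]
            )
        else:
            got = candidate.k1 * float(np.prod([state[s] ** n for s, n in reactants]))
            if candidate.form == MASS_ACTION_REVERSIBLE:
                got -= candidate.kr1 * float(np.prod([state[s] ** n for s, n in products]))
        if abs(got - want) > rtol * max(1.0, abs(want)):
            return RateLaw(OPAQUE_EXPRESSION, expression=fallback_expr)
    return candidate


def _substitute_locals(expr: str, locals_: dict[str, float]) -> str:
    """Inline kinetic-law local parameters so the expression is evaluable
    against network-level ids only."""
    if not locals_:
        return expr
    names = names_in(expr)
    out = expr
    for name, value in locals_.items():
        if name in names:
            # word-boundary textual substitution is safe for SBML identifiers
            import re

            out = re.sub(rf"\b{re.escape(name)}\b", repr(value), out)
    return out
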