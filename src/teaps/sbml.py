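"""Read-only SBML import (plus round-trip export of the built-ins).

A narrow SBML Level 2/3 reader: species become state variables (boundary
or constant species get an identically zero derivative), reaction kinetic
laws written in content MathML are assembled into the stoichiometry-
weighted right-hand side, and local reaction parameters are renamed to
``<reaction>_<parameter>`` when they would clash.  Constructs outside the
ODE-reaction core — rules, events, function definitions, constraints,
initial assignments — are rejected with an explicit error rather than
ignored.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import sympy as sp
from lxml import etree

from .models import ODESystem

__all__ = ["import_sbml", "export_sbml", "SBMLImportError"]

_MATHML_NS = "http://www.w3.org/1998/Math/MathML"


class SBMLImportError(ValueError):
    """The file is not SBML this reader supports; the message names the
    offending construct."""


def _local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


_BINARY_OPS = {
    "plus": lambda *a: sp.Add(*a),
    "times": lambda *a: sp.Mul(*a),
}


def _parse_mathml(node, symbols: dict[str, sp.Symbol]) -> sp.Expr:
    tag = _local(node.tag)
    if tag == "math":
        children = [c for c in node if isinstance(c.tag, str)]
        if len(children) != 1:
            raise SBMLImportError("MathML <math> must contain exactly one expression")
        return _parse_mathml(children[0], symbols)
    if tag == "ci":
        name = (node.text or "").strip()
        if not name:
            raise SBMLImportError("empty <ci> identifier")
        return symbols.setdefault(name, sp.Symbol(name))
    if tag == "cn":
        cn_type = node.get("type", "real")
        if cn_type in ("real", "integer", "double"):
            return sp.Float((node.text or "").strip()) if cn_type == "real" else sp.Integer(int((node.text or "").strip()))
        if cn_type == "e-notation":
            parts = [t.strip() for t in node.itertext() if t.strip()]
            if len(parts) != 2:
                raise SBMLImportError("malformed e-notation <cn>")
            return sp.Float(f"{parts[0]}e{parts[1]}")
        if cn_type == "rational":
            parts = [t.strip() for t in node.itertext() if t.strip()]
            return sp.Rational(int(parts[0]), int(parts[1]))
        raise SBMLImportError(f"unsupported <cn> type {cn_type!r}")
    if tag == "apply":
        children = [c for c in node if isinstance(c.tag, str)]
        op = _local(children[0].tag)
        args = [_parse_mathml(c, symbols) for c in children[1:]]
        if op in _BINARY_OPS:
            return _BINARY_OPS[op](*args)
        if op == "minus":
            if len(args) == 1:
                return -args[0]
            if len(args) == 2:
                return args[0] - args[1]
            raise SBMLImportError("<minus> takes one or two arguments")
        if op == "divide":
            if len(args) != 2:
                raise SBMLImportError("<divide> takes two arguments")
            return args[0] / args[1]
        if op == "power":
            if len(args) != 2:
                raise SBMLImportError("<power> takes two arguments")
            return args[0] ** args[1]
        if op == "exp":
            return sp.exp(args[0])
        if op == "ln":
            return sp.log(args[0])
        if op == "root":
            return sp.sqrt(args[0]) if len(args) == 1 else args[-1] ** (1 / args[0])
        raise SBMLImportError(f"unsupported MathML operator <{op}>")
    if tag == "pi":
        return sp.pi
    if tag == "exponentiale":
        return sp.E
    raise SBMLImportError(f"unsupported MathML node <{tag}>")


def import_sbml(path) -> ODESystem:
    """Build an :class:`ODESystem` from an SBML L2/L3 file."""
    path = Path(path)
    try:
        tree = etree.parse(str(path))
    except (etree.XMLSyntaxError, OSError) as exc:
        raise SBMLImportError(f"cannot parse {path.name}: {exc}") from exc
    root = tree.getroot()
    if _local(root.tag) != "sbml":
        raise SBMLImportError(f"{path.name}: root element is <{_local(root.tag)}>, not <sbml>")
    model_el = next((c for c in root if _local(c.tag) == "model"), None)
    if model_el is None:
        raise SBMLImportError(f"{path.name}: no <model> element")

    def list_of(parent, name):
        el = next((c for c in parent if _local(c.tag) == name), None)
        return [] if el is None else [c for c in el if isinstance(c.tag, str)]

    for forbidden in (
        "listOfRules",
        "listOfEvents",
        "listOfFunctionDefinitions",
        "listOfConstraints",
        "listOfInitialAssignments",
    ):
        if list_of(model_el, forbidden):
            raise SBMLImportError(f"{path.name}: {forbidden} is not supported")

    species = []
    constant_species = set()
    for s in list_of(model_el, "listOfSpecies"):
        sid = s.get("id") or s.get("name")
        if not sid:
            raise SBMLImportError("species without id")
        species.append(sid)
        if s.get("boundaryCondition") == "true" or s.get("constant") == "true":
            constant_species.add(sid)

    params: dict[str, Optional[float]] = {}
    for p in list_of(model_el, "listOfParameters"):
        pid = p.get("id")
        if not pid:
            raise SBMLImportError("parameter without id")
        params[pid] = None

    symbols: dict[str, sp.Symbol] = {n: sp.Symbol(n) for n in species}
    symbols.update({n: sp.Symbol(n) for n in params})

    reactions: dict[str, sp.Expr] = {}
    net: dict[str, dict[str, float]] = {sid: {} for sid in species}
    for r in list_of(model_el, "listOfReactions"):
        rid = r.get("id") or f"re{len(reactions) + 1}"
        kin = next((c for c in r if _local(c.tag) == "kineticLaw"), None)
        if kin is None:
            raise SBMLImportError(f"reaction {rid}: missing kineticLaw")
        local_subs = {}
        for lp_list_name in ("listOfParameters", "listOfLocalParameters"):
            for lp in list_of(kin, lp_list_name):
                lpid = lp.get("id")
                if not lpid:
                    continue
                unique = lpid if lpid not in params and lpid not in species else f"{rid}_{lpid}"
                params[unique] = None
                symbols[unique] = sp.Symbol(unique)
                if unique != lpid:
                    local_subs[lpid] = sp.Symbol(unique)
        math_el = next((c for c in kin if _local(c.tag) == "math"), None)
        if math_el is None:
            raise SBMLImportError(f"reaction {rid}: kineticLaw without <math>")
        expr = _parse_mathml(math_el, symbols)
        if local_subs:
            expr = expr.subs({sp.Symbol(k): v for k, v in local_subs.items()})
        reactions[rid] = expr
        for side, sign in (("listOfReactants", -1.0), ("listOfProducts", 1.0)):
            side_el = next((c for c in r if _local(c.tag) == side), None)
            if side_el is None:
                continue
            for ref in side_el:
                if not isinstance(ref.tag, str):
                    continue
                sid = ref.get("species")
                if sid not in net:
                    raise SBMLImportError(f"reaction {rid}: unknown species {sid!r}")
                stoich = float(ref.get("stoichiometry", "1"))
                net[sid][rid] = net[sid].get(rid, 0.0) + sign * stoich

    # any symbol in a kinetic law that is neither a species nor a declared
    # parameter becomes an implicitly declared parameter
    declared = set(species) | set(params)
    for expr in reactions.values():
        for sym in expr.free_symbols:
            if str(sym) not in declared:
                params[str(sym)] = None
                declared.add(str(sym))

    rids = list(reactions)
    rhs = []
    stoich_rows = []
    for sid in species:
        if sid in constant_species:
            rhs.append(sp.Integer(0))
            stoich_rows.append(tuple(0.0 for _ in rids))
            continue
        coeffs = net[sid]
        expr = sp.Add(*[coeffs.get(r, 0.0) * reactions[r] for r in rids if coeffs.get(r)])
        rhs.append(sp.expand(expr))
        stoich_rows.append(tuple(coeffs.get(r, 0.0) for r in rids))

    return ODESystem(
        name=model_el.get("id") or model_el.get("name") or path.stem,
        species_names=tuple(species),
        parameter_names=tuple(params),
        reactions=reactions,
        rhs=tuple(rhs),
        stoichiometry=tuple(stoich_rows),
    )


# ---------------------------------------------------------------------------
# Export (round-trip support for the built-ins)
# ---------------------------------------------------------------------------


def _emit_mathml(expr: sp.Expr, parent: etree._Element) -> None:
    """Emit content MathML for the expression grammar the rate laws use
    (sums, products, rational powers, symbols, numbers)."""
    m = f"{{{_MATHML_NS}}}"

    def apply(op: str, args) -> None:
        ap = etree.SubElement(parent, f"{m}apply")
        etree.SubElement(ap, f"{m}{op}")
        for a in args:
            _emit_mathml(a, ap)

    if isinstance(expr, sp.Symbol):
        ci = etree.SubElement(parent, f"{m}ci")
        ci.text = expr.name
    elif isinstance(expr, sp.Integer):
        cn = etree.SubElement(parent, f"{m}cn", type="integer")
        cn.text = str(int(expr))
    elif isinstance(expr, sp.Rational):
        apply("divide", [sp.Integer(expr.p), sp.Integer(expr.q)])
    elif isinstance(expr, sp.Float):
        cn = etree.SubElement(parent, f"{m}cn")
        cn.text = repr(float(expr))
    elif isinstance(expr, sp.Add):
        apply("plus", expr.args)
    elif isinstance(expr, sp.Mul):
        num, den = sp.fraction(sp.together(expr))
        if den != 1:
            apply("divide", [num, den])
        else:
            apply("times", expr.args)
    elif isinstance(expr, sp.Pow):
        base, exponent = expr.args
        if exponent == -1:
            apply("divide", [sp.Integer(1), base])
        else:
            apply("power", [base, exponent])
    else:
        raise ValueError(f"cannot express {expr!r} as supported content MathML")


def _to_mathml(expr: sp.Expr) -> etree._Element:
    """Content MathML element for a rate law."""
    math = etree.Element(f"{{{_MATHML_NS}}}math", nsmap={None: _MATHML_NS})
    _emit_mathml(sp.together(expr), math)
    return math


def export_sbml(model: ODESystem, path) -> None:
    """Write the model as SBML Level 2 Version 4.

    Requires the reaction composition (``stoichiometry``); intended for
    round-tripping the built-in models.
    """
    if model.stoichiometry is None:
        raise ValueError("model has no stoichiometric composition to export")
    ns = "http://www.sbml.org/sbml/level2/version4"
    sbml = etree.Element(f"{{{ns}}}sbml", level="2", version="4", nsmap={None: ns})
    mel = etree.SubElement(sbml, f"{{{ns}}}model", id=model.name)
    comps = etree.SubElement(mel, f"{{{ns}}}listOfCompartments")
    etree.SubElement(comps, f"{{{ns}}}compartment", id="default", size="1")
    sl = etree.SubElement(mel, f"{{{ns}}}listOfSpecies")
    for sid, const in zip(model.species_names, model.constant_mask):
        etree.SubElement(
            sl,
            f"{{{ns}}}species",
            id=sid,
            compartment="default",
            initialConcentration="1",
            boundaryCondition="true" if const else "false",
        )
    pl = etree.SubElement(mel, f"{{{ns}}}listOfParameters")
    for pid in model.parameter_names:
        etree.SubElement(pl, f"{{{ns}}}parameter", id=pid, value="1")
    rl = etree.SubElement(mel, f"{{{ns}}}listOfReactions")
    rids = list(model.reactions)
    for j, rid in enumerate(rids):
        rel = etree.SubElement(rl, f"{{{ns}}}reaction", id=rid, reversible="false")
        reactants = etree.SubElement(rel, f"{{{ns}}}listOfReactants")
        products = etree.SubElement(rel, f"{{{ns}}}listOfProducts")
        for i, sid in enumerate(model.species_names):
            c = model.stoichiometry[i][j]
            if c < 0:
                etree.SubElement(
                    reactants, f"{{{ns}}}speciesReference", species=sid, stoichiometry=str(-c)
                )
            elif c > 0:
                etree.SubElement(
                    products, f"{{{ns}}}speciesReference", species=sid, stoichiometry=str(c)
                )
        kin = etree.SubElement(rel, f"{{{ns}}}kineticLaw")
        kin.append(_to_mathml(model.reactions[rid]))
    etree.ElementTree(sbml).write(
        str(path), xml_declaration=True, encoding="UTF-8", pretty_print=True
    )
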