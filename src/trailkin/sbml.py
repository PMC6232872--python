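"""Export a network as SBML Level 3 Version 1 (export-only).

The writer emits plain SBML core with mass-action kinetic laws so the model
can be inspected or re-simulated in standard systems-biology tooling.  It is
intentionally one-way: the TSV fixture remains the canonical description.
"""

from __future__ import annotations

import re
import xml.etree.ElementTree as ET

from .network import NetworkModel, ReactionDef

__all__ = ["network_to_sbml"]

_NS = "http://www.sbml.org/sbml/level3/version1/core"


def _sid(name: str) -> str:
    """Map a species name to a valid SBML SId (deterministic, collision-safe
    for the fixture's naming scheme)."""
    out = name.replace(":", "_cx_").replace("*", "_a")
    out = re.sub(r"[^A-Za-z0-9_]", "_", out)
    if not re.match(r"[A-Za-z_]", out):
        out = "s_" + out
    return out


def _math_times(*factors: str) -> ET.Element:
    math = ET.Element("math", xmlns="http://www.w3.org/1998/Math/MathML")
    if len(factors) == 1:
        ci = ET.SubElement(math, "ci")
        ci.text = f" {factors[0]} "
        return math
    apply_ = ET.SubElement(math, "apply")
    ET.SubElement(apply_, "times")
    for f in factors:
        ci = ET.SubElement(apply_, "ci")
        ci.text = f" {f} "
    return math


def _add_reaction(lom, rid, reactants, products, rate_factors, parameters):
    r = ET.SubElement(lom, "reaction", id=rid, reversible="false", fast="false")
    if reactants:
        lor = ET.SubElement(r, "listOfReactants")
        for sid, stoich in reactants:
            ET.SubElement(lor, "speciesReference", species=sid,
                          stoichiometry=str(stoich), constant="true")
    if products:
        lop = ET.SubElement(r, "listOfProducts")
        for sid, stoich in products:
            ET.SubElement(lop, "speciesReference", species=sid,
                          stoichiometry=str(stoich), constant="true")
    kl = ET.SubElement(r, "kineticLaw")
    kl.append(_math_times(*rate_factors))
    lolp = ET.SubElement(kl, "listOfLocalParameters")
    for pid, value in parameters:
        ET.SubElement(lolp, "localParameter", id=pid, value=repr(value))


def _emit(lom, r: ReactionDef) -> None:
    E, S, ES, P = (r.enzyme, r.substrate, r.complex, r.product)
    if r.paradigm == 4:
        src, dst = _sid(S), _sid(P)
        _add_reaction(lom, f"{_sid(r.label)}_fwd", [(src, 1)], [(dst, 1)],
                      ("k", src), [("k", r.k_plus)])
        if r.k_minus:
            _add_reaction(lom, f"{_sid(r.label)}_rev", [(dst, 1)], [(src, 1)],
                          ("k", dst), [("k", r.k_minus)])
        return
    e, s, es = _sid(E), _sid(S), _sid(ES)
    if E == S:
        _add_reaction(lom, f"{_sid(r.label)}_bind", [(e, 2)], [(es, 1)],
                      ("k", e, e), [("k", r.k_plus)])
        _add_reaction(lom, f"{_sid(r.label)}_unbind", [(es, 1)], [(e, 2)],
                      ("k", es), [("k", r.k_minus)])
    else:
        _add_reaction(lom, f"{_sid(r.label)}_bind", [(e, 1), (s, 1)], [(es, 1)],
                      ("k", e, s), [("k", r.k_plus)])
        _add_reaction(lom, f"{_sid(r.label)}_unbind", [(es, 1)], [(e, 1), (s, 1)],
                      ("k", es), [("k", r.k_minus)])
    if r.paradigm == 1:
        _add_reaction(lom, f"{_sid(r.label)}_cat", [(es, 1)],
                      [(e, 1), (_sid(P), 1)], ("k", es), [("k", r.k_cat)])
    elif r.paradigm == 2:
        _add_reaction(lom, f"{_sid(r.label)}_conv", [(es, 1)],
                      [(_sid(P), 1)], ("k", es), [("k", r.k_cat)])


def network_to_sbml(model: NetworkModel, model_id: str = "trailkin_model") -> str:
    """Serialize ``model`` as an SBML L3V1 document string."""
    ET.register_namespace("", _NS)
    sbml = ET.Element(f"{{{_NS}}}sbml", level="3", version="1")
    mdl = ET.SubElement(sbml, "model", id=model_id, substanceUnits="item",
                        timeUnits="second", extentUnits="item")
    loc = ET.SubElement(mdl, "listOfCompartments")
    for comp in ("surface", "cytosol", "mitochondria"):
        ET.SubElement(loc, "compartment", id=comp, constant="true",
                      spatialDimensions="3", size="1")
    los = ET.SubElement(mdl, "listOfSpecies")
    for sp in model.species:
        ET.SubElement(
            los, "species", id=_sid(sp.name), name=sp.name,
            compartment=sp.compartment, initialAmount=repr(sp.initial),
            hasOnlySubstanceUnits="true", boundaryCondition="false",
            constant="false")
    lom = ET.SubElement(mdl, "listOfReactions")
    for r in model.reactions:
        _emit(lom, r)
    ET.indent(sbml)
    return ET.tostring(sbml, encoding="unicode", xml_declaration=True)
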