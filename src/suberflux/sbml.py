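"""SBML Level 3 + FBC v2 reading and writing.

Round-trip contract: ``read_sbml(write_sbml(m))`` preserves component
counts, stoichiometry, bounds, formulas/charges and canonicalized GPR
strings.  Level 2 documents with notes-encoded GPRs/bounds are tolerated
on read.  Missing flux bounds default to (-1000, 1000) with a warning.
"""

from __future__ import annotations

import math
import re
import warnings
from typing import Optional

import libsbml

from .gpr import GPR, parse_gpr
from .model import (
    DEFAULT_LOWER,
    DEFAULT_UPPER,
    MetabolicModel,
    Metabolite,
    Reaction,
)

__all__ = ["read_sbml", "write_sbml", "read_sbml_string", "write_sbml_string"]

_SID_BAD = re.compile(r"[^A-Za-z0-9_]")


def _sid(raw: str) -> str:
    sid = _SID_BAD.sub("_", raw)
    if not sid or sid[0].isdigit():
        sid = "_" + sid
    return sid


def _check(value, message: str) -> None:
    if value is None:
        raise RuntimeError(f"libsbml returned None: {message}")
    if isinstance(value, int) and value != libsbml.LIBSBML_OPERATION_SUCCESS:
        raise RuntimeError(f"libsbml error {value}: {message}")


# ----------------------------------------------------------------- write

def _build_association(parent, node) -> None:
    """Recursively mirror a GPR tree into an FBC association object."""
    if isinstance(node, str):
        ref = parent.createGeneProductRef()
        _check(ref.setGeneProduct(_sid("G_" + node)), f"gene ref {node}")
        return
    op, children = node
    assoc = parent.createAnd() if op == "and" else parent.createOr()
    for child in children:
        _build_association(assoc, child)


def write_sbml_string(model: MetabolicModel) -> str:
    """Serialize a model to an SBML L3V1 + FBC v2 document string."""
    model.validate()
    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sm = doc.createModel()
    _check(sm.setId(_sid(model.id)), "model id")
    fbc = sm.getPlugin("fbc")
    fbc.setStrict(False)

    for cid, cname in sorted(model.compartments.items()):
        comp = sm.createCompartment()
        _check(comp.setId(_sid(cid)), f"compartment {cid}")
        comp.setName(cname)
        comp.setConstant(True)

    for mid in sorted(model.metabolites):
        met = model.metabolites[mid]
        sp = sm.createSpecies()
        _check(sp.setId(_sid(mid)), f"species {mid}")
        sp.setName(met.name or mid)
        if met.compartment:
            sp.setCompartment(_sid(met.compartment))
        sp.setConstant(False)
        sp.setBoundaryCondition(False)
        sp.setHasOnlySubstanceUnits(False)
        sfbc = sp.getPlugin("fbc")
        if met.formula:
            sfbc.setChemicalFormula(met.formula)
        if met.charge is not None:
            sfbc.setCharge(int(met.charge))

    # one shared constant parameter per distinct bound value
    bound_params: dict[float, str] = {}

    def bound_param(value: float) -> str:
        if value not in bound_params:
            pid = f"fb_{len(bound_params)}"
            par = sm.createParameter()
            par.setId(pid)
            par.setValue(value)
            par.setConstant(True)
            bound_params[value] = pid
        return bound_params[value]

    for gene in sorted(model.genes):
        gp = fbc.createGeneProduct()
        _check(gp.setId(_sid("G_" + gene)), f"gene product {gene}")
        gp.setLabel(gene)

    for rid in sorted(model.reactions):
        rxn = model.reactions[rid]
        sr = sm.createReaction()
        _check(sr.setId(_sid(rid)), f"reaction {rid}")
        sr.setName(rxn.name or rid)
        sr.setReversible(rxn.lower_bound < 0)
        sr.setFast(False)
        if rxn.pathway:
            sr.setNotes(
                "<body xmlns='http://www.w3.org/1999/xhtml'>"
                f"<p>SUBSYSTEM: {rxn.pathway}</p></body>"
            )
        for mid, coeff in sorted(rxn.stoichiometry.items()):
            ref = sr.createReactant() if coeff < 0 else sr.createProduct()
            _check(ref.setSpecies(_sid(mid)), f"{rid}:{mid}")
            ref.setStoichiometry(abs(coeff))
            ref.setConstant(True)
        rfbc = sr.getPlugin("fbc")
        rfbc.setLowerFluxBound(bound_param(rxn.lower_bound))
        rfbc.setUpperFluxBound(bound_param(rxn.upper_bound))
        if rxn.gpr:
            gpa = rfbc.createGeneProductAssociation()
            _build_association(gpa, rxn.gpr.root)

    if model.biomass_reaction_id is not None:
        obj = fbc.createObjective()
        obj.setId("obj")
        obj.setType("maximize")
        fo = obj.createFluxObjective()
        fo.setReaction(_sid(model.biomass_reaction_id))
        fo.setCoefficient(1.0)
        fbc.setActiveObjectiveId("obj")

    return libsbml.writeSBMLToString(doc)


def write_sbml(model: MetabolicModel, path: str) -> None:
    with open(path, "w") as handle:
        handle.write(write_sbml_string(model))


# ------------------------------------------------------------------ read

def _association_to_node(assoc):
    if assoc is None:
        return None
    code = assoc.getTypeCode()
    if code == libsbml.SBML_FBC_GENEPRODUCTREF:
        return assoc.getGeneProduct()
    op = "and" if code == libsbml.SBML_FBC_AND else "or"
    children = [
        _association_to_node(assoc.getAssociation(i))
        for i in range(assoc.getNumAssociations())
    ]
    children = [c for c in children if c is not None]
    if not children:
        return None
    return children[0] if len(children) == 1 else (op, children)


_NOTE_FIELD = re.compile(r"(GENE[ _]?ASSOCIATION|SUBSYSTEM)\s*:\s*([^<]*)", re.I)


def _parse_notes(notes: Optional[str]) -> dict[str, str]:
    out: dict[str, str] = {}
    if notes:
        for key, value in _NOTE_FIELD.findall(notes):
            out[key.upper().replace(" ", "_")] = value.strip()
    return out


def _read_document(doc: libsbml.SBMLDocument, source: str) -> MetabolicModel:
    errors = [
        doc.getError(i)
        for i in range(doc.getNumErrors())
        if doc.getError(i).getSeverity() >= libsbml.LIBSBML_SEV_ERROR
    ]
    if errors:
        detail = "; ".join(
            f"line {e.getLine()}: {e.getMessage().strip()}" for e in errors[:5]
        )
        raise ValueError(f"malformed SBML in {source}: {detail}")
    sm = doc.getModel()
    if sm is None:
        raise ValueError(f"no model element in {source}")
    fbc = sm.getPlugin("fbc")

    model = MetabolicModel(sm.getId() or "model")
    for i in range(sm.getNumCompartments()):
        comp = sm.getCompartment(i)
        model.add_compartment(comp.getId(), comp.getName())
    if not model.compartments:
        model.add_compartment("default")

    for i in range(sm.getNumSpecies()):
        sp = sm.getSpecies(i)
        sfbc = sp.getPlugin("fbc")
        formula = None
        charge = None
        if sfbc is not None:
            if sfbc.isSetChemicalFormula():
                formula = sfbc.getChemicalFormula()
            if sfbc.isSetCharge():
                charge = sfbc.getCharge()
        model.add_metabolite(
            Metabolite(
                id=sp.getId(),
                name=sp.getName(),
                compartment=sp.getCompartment() or next(iter(model.compartments)),
                formula=formula,
                charge=charge,
            )
        )

    gene_labels: dict[str, str] = {}
    if fbc is not None:
        for i in range(fbc.getNumGeneProducts()):
            gp = fbc.getGeneProduct(i)
            gene_labels[gp.getId()] = gp.getLabel() or gp.getId()

    def node_with_labels(node):
        if node is None:
            return None
        if isinstance(node, str):
            return gene_labels.get(node, node)
        op, children = node
        return (op, [node_with_labels(c) for c in children])

    for i in range(sm.getNumReactions()):
        sr = sm.getReaction(i)
        rid = sr.getId()
        stoich: dict[str, float] = {}
        for j in range(sr.getNumReactants()):
            ref = sr.getReactant(j)
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) - ref.getStoichiometry()
        for j in range(sr.getNumProducts()):
            ref = sr.getProduct(j)
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) + ref.getStoichiometry()

        notes = _parse_notes(sr.getNotesString() if sr.isSetNotes() else None)
        lb = ub = None
        gpr = GPR(None)
        rfbc = sr.getPlugin("fbc")
        if rfbc is not None:
            for attr, setter in (("getLowerFluxBound", "lb"), ("getUpperFluxBound", "ub")):
                pid = getattr(rfbc, attr)()
                if pid:
                    par = sm.getParameter(pid)
                    if par is not None and not math.isnan(par.getValue()):
                        if setter == "lb":
                            lb = par.getValue()
                        else:
                            ub = par.getValue()
            if rfbc.isSetGeneProductAssociation():
                node = _association_to_node(
                    rfbc.getGeneProductAssociation().getAssociation()
                )
                gpr = GPR(node_with_labels(node))
        if not gpr and "GENE_ASSOCIATION" in notes:
            gpr = parse_gpr(notes["GENE_ASSOCIATION"])
        if sr.isSetKineticLaw() and (lb is None or ub is None):
            kl = sr.getKineticLaw()
            for j in range(kl.getNumParameters()):
                par = kl.getParameter(j)
                if par.getId() == "LOWER_BOUND" and lb is None:
                    lb = par.getValue()
                elif par.getId() == "UPPER_BOUND" and ub is None:
                    ub = par.getValue()
        if lb is None or ub is None:
            reversible = sr.getReversible()
            if lb is None:
                lb = DEFAULT_LOWER if reversible else 0.0
            if ub is None:
                ub = DEFAULT_UPPER
            warnings.warn(
                f"reaction {rid}: missing flux bounds, defaulting to ({lb}, {ub})"
            )
        model.add_reaction(
            Reaction(
                id=rid,
                stoichiometry=stoich,
                lower_bound=lb,
                upper_bound=ub,
                gpr=gpr,
                name=sr.getName(),
                pathway=notes.get("SUBSYSTEM"),
            )
        )

    if fbc is not None:
        obj = fbc.getActiveObjective()
        if obj is not None and obj.getNumFluxObjectives() > 0:
            rid = obj.getFluxObjective(0).getReaction()
            if rid in model.reactions:
                model.biomass_reaction_id = rid
    return model


def read_sbml(path: str) -> MetabolicModel:
    doc = libsbml.readSBMLFromFile(path)
    return _read_document(doc, path)


def read_sbml_string(text: str) -> MetabolicModel:
    doc = libsbml.readSBMLFromString(text)
    return _read_document(doc, "<string>")
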