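"""Readers and writers: SBML Level 3 + FBC v2, and a JSON model dialect.

The JSON dialect is intentionally minimal::

    {
      "id": "...",
      "metabolites": [{"id", "name", "compartment", "formula", "charge"}, ...],
      "reactions":   [{"id", "stoichiometry": {met: coeff}, "lb", "ub",
                       "gene_rule", "subsystem"}, ...],
      "objective": "<reaction id>"
    }

Unknown top-level fields are preserved in ``MetabolicModel.extras`` and
written back on save.  Both formats round-trip stoichiometry, bounds and
the objective exactly.
"""

from __future__ import annotations

import json
from pathlib import Path

import libsbml

from .model import MetabolicModel, Metabolite, ModelError, Reaction

__all__ = ["load_sbml", "save_sbml", "load_json_model", "save_json_model"]

_SPECIES_PREFIX = "M_"
_REACTION_PREFIX = "R_"
_GENE_PREFIX = "G_"


class SBMLParseError(ModelError):
    """Malformed or unsupported SBML input."""


def _strip(prefix: str, sid: str) -> str:
    return sid[len(prefix):] if sid.startswith(prefix) else sid


def _clip(prefix: str, sid: str) -> str:
    return sid if sid.startswith(prefix) else prefix + sid


def _assoc_to_infix(assoc) -> str:
    """Render an FBC gene-product association tree as a boolean infix string."""
    if isinstance(assoc, libsbml.GeneProductRef):
        return _strip(_GENE_PREFIX, assoc.getGeneProduct())
    if isinstance(assoc, libsbml.FbcAnd):
        parts = [_assoc_to_infix(assoc.getAssociation(i)) for i in range(assoc.getNumAssociations())]
        return "(" + " and ".join(parts) + ")"
    if isinstance(assoc, libsbml.FbcOr):
        parts = [_assoc_to_infix(assoc.getAssociation(i)) for i in range(assoc.getNumAssociations())]
        return "(" + " or ".join(parts) + ")"
    raise SBMLParseError(f"unsupported gene association node {type(assoc).__name__}")


def _notes_subsystem(sbase) -> str:
    """Extract a ``SUBSYSTEM: x`` line from SBML notes, if present."""
    if not sbase.isSetNotes():
        return ""
    text = sbase.getNotesString()
    for line in text.replace("<p>", "\n").replace("</p>", "\n").splitlines():
        line = line.strip()
        if line.upper().startswith("SUBSYSTEM:"):
            return line.split(":", 1)[1].strip()
    return ""


def load_sbml(path: str | Path) -> MetabolicModel:
    """Load an SBML Level 3 model with the FBC (flux bounds + objective)
    extension.

    Raises :class:`SBMLParseError` naming the offending element for
    malformed XML, and an explicit unsupported-dialect error when the FBC
    package is absent.
    """
    doc = libsbml.readSBMLFromFile(str(Path(path)))
    if doc.getNumErrors() > 0:
        for i in range(doc.getNumErrors()):
            err = doc.getError(i)
            if err.getSeverity() >= libsbml.LIBSBML_SEV_ERROR:
                raise SBMLParseError(
                    f"SBML parse error at line {err.getLine()}: {err.getMessage()}"
                )
    sbml_model = doc.getModel()
    if sbml_model is None:
        raise SBMLParseError("document contains no <model> element")
    fbc = sbml_model.getPlugin("fbc")
    if fbc is None:
        raise SBMLParseError(
            "unsupported dialect: SBML document lacks the FBC package "
            "(flux bounds and objectives)"
        )

    metabolites = []
    for i in range(sbml_model.getNumSpecies()):
        sp = sbml_model.getSpecies(i)
        sp_fbc = sp.getPlugin("fbc")
        formula = sp_fbc.getChemicalFormula() if sp_fbc and sp_fbc.isSetChemicalFormula() else ""
        charge = sp_fbc.getCharge() if sp_fbc and sp_fbc.isSetCharge() else 0
        metabolites.append(Metabolite(
            id=_strip(_SPECIES_PREFIX, sp.getId()),
            name=sp.getName() or "",
            compartment=sp.getCompartment(),
            formula=formula,
            charge=charge,
        ))

    def _bound_value(param_id: str, which: str, rxn_id: str) -> float:
        param = sbml_model.getParameter(param_id)
        if param is None:
            raise SBMLParseError(f"reaction {rxn_id}: {which} bound parameter {param_id!r} missing")
        return param.getValue()

    reactions = []
    for i in range(sbml_model.getNumReactions()):
        rx = sbml_model.getReaction(i)
        rx_fbc = rx.getPlugin("fbc")
        if rx_fbc is None or not rx_fbc.isSetLowerFluxBound() or not rx_fbc.isSetUpperFluxBound():
            raise SBMLParseError(
                f"unsupported dialect: reaction {rx.getId()} lacks FBC flux bounds"
            )
        stoich: dict[str, float] = {}
        for j in range(rx.getNumReactants()):
            ref = rx.getReactant(j)
            mid = _strip(_SPECIES_PREFIX, ref.getSpecies())
            stoich[mid] = stoich.get(mid, 0.0) - ref.getStoichiometry()
        for j in range(rx.getNumProducts()):
            ref = rx.getProduct(j)
            mid = _strip(_SPECIES_PREFIX, ref.getSpecies())
            stoich[mid] = stoich.get(mid, 0.0) + ref.getStoichiometry()
        gene_rule = ""
        if rx_fbc.isSetGeneProductAssociation():
            root = rx_fbc.getGeneProductAssociation().getAssociation()
            if root is not None:
                gene_rule = _assoc_to_infix(root)
                if gene_rule.startswith("(") and gene_rule.endswith(")"):
                    gene_rule = gene_rule[1:-1]
        reactions.append(Reaction(
            id=_strip(_REACTION_PREFIX, rx.getId()),
            stoichiometry=stoich,
            lower_bound=_bound_value(rx_fbc.getLowerFluxBound(), "lower", rx.getId()),
            upper_bound=_bound_value(rx_fbc.getUpperFluxBound(), "upper", rx.getId()),
            gene_rule=gene_rule,
            subsystem=_notes_subsystem(rx),
            name=rx.getName() or "",
        ))

    objective_id = ""
    active = fbc.getActiveObjective() if fbc.getNumObjectives() else None
    if active is not None and active.getNumFluxObjectives() > 0:
        # take the (first) reaction with nonzero objective coefficient
        for j in range(active.getNumFluxObjectives()):
            fo = active.getFluxObjective(j)
            if fo.getCoefficient() != 0:
                objective_id = _strip(_REACTION_PREFIX, fo.getReaction())
                break
    if not objective_id:
        raise SBMLParseError("unsupported dialect: no active FBC objective with a nonzero coefficient")

    return MetabolicModel(metabolites, reactions, objective_id,
                          id=sbml_model.getId() or "model")


def save_sbml(model: MetabolicModel, path: str | Path) -> None:
    """Write ``model`` as SBML Level 3 Version 1 with FBC v2."""
    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sm = doc.createModel()
    sm.setId(model.id or "model")
    fbc = sm.getPlugin("fbc")
    fbc.setStrict(True)

    for comp_id in sorted({m.compartment for m in model.metabolites}):
        comp = sm.createCompartment()
        comp.setId(comp_id)
        comp.setConstant(True)

    for m in model.metabolites:
        sp = sm.createSpecies()
        sp.setId(_clip(_SPECIES_PREFIX, m.id))
        sp.setName(m.name or m.id)
        sp.setCompartment(m.compartment)
        sp.setHasOnlySubstanceUnits(False)
        sp.setBoundaryCondition(False)
        sp.setConstant(False)
        sp_fbc = sp.getPlugin("fbc")
        if m.formula:
            sp_fbc.setChemicalFormula(m.formula)
        sp_fbc.setCharge(int(m.charge))

    gene_ids: list[str] = []
    for r in model.reactions:
        for tok in r.gene_rule.replace("(", " ").replace(")", " ").split():
            if tok not in ("and", "or", "AND", "OR") and tok not in gene_ids:
                gene_ids.append(tok)
    for gid in gene_ids:
        gp = fbc.createGeneProduct()
        gp.setId(_clip(_GENE_PREFIX, gid))
        gp.setLabel(gid)

    def _make_param(pid: str, value: float) -> str:
        param = sm.createParameter()
        param.setId(pid)
        param.setValue(float(value))
        param.setConstant(True)
        return pid

    for r in model.reactions:
        rx = sm.createReaction()
        rid = _clip(_REACTION_PREFIX, r.id)
        rx.setId(rid)
        rx.setName(r.name or r.id)
        rx.setFast(False)
        rx.setReversible(r.lower_bound < 0)
        if r.subsystem:
            rx.setNotes(
                "<body xmlns=\"http://www.w3.org/1999/xhtml\">"
                f"<p>SUBSYSTEM: {r.subsystem}</p></body>"
            )
        for mid, coeff in r.stoichiometry.items():
            ref = rx.createReactant() if coeff < 0 else rx.createProduct()
            ref.setSpecies(_clip(_SPECIES_PREFIX, mid))
            ref.setStoichiometry(abs(float(coeff)))
            ref.setConstant(True)
        rx_fbc = rx.getPlugin("fbc")
        rx_fbc.setLowerFluxBound(_make_param(f"{rid}_lb", r.lower_bound))
        rx_fbc.setUpperFluxBound(_make_param(f"{rid}_ub", r.upper_bound))
        if r.gene_rule.strip():
            gpa = rx_fbc.createGeneProductAssociation()
            infix = " ".join(
                _clip(_GENE_PREFIX, tok) if tok not in ("and", "or", "(", ")") else tok
                for tok in r.gene_rule.replace("(", " ( ").replace(")", " ) ").split()
            )
            gpa.setAssociation(infix, True, False)  # match gene products by id

    objective = fbc.createObjective()
    objective.setId("obj")
    objective.setType("maximize")
    fo = objective.createFluxObjective()
    fo.setReaction(_clip(_REACTION_PREFIX, model.objective_id))
    fo.setCoefficient(1.0)
    fbc.setActiveObjectiveId("obj")

    if not libsbml.writeSBMLToFile(doc, str(Path(path))):
        raise ModelError(f"failed to write SBML to {path}")  # pragma: no cover


# ---------------------------------------------------------------------------
# JSON dialect

_MET_KEYS = {"id", "name", "compartment", "formula", "charge"}
_RXN_KEYS = {"id", "stoichiometry", "lb", "ub", "gene_rule", "subsystem", "name"}


def load_json_model(path: str | Path) -> MetabolicModel:
    """Load the documented JSON model dialect.

    Schema violations raise :class:`ModelError` naming the offending
    field; unknown top-level fields are kept in ``model.extras``.
    """
    with open(path) as fh:
        doc = json.load(fh)
    for key in ("metabolites", "reactions", "objective"):
        if key not in doc:
            raise ModelError(f"JSON model missing required field {key!r}")
    metabolites = []
    for entry in doc["metabolites"]:
        if "id" not in entry:
            raise ModelError("metabolite entry missing field 'id'")
        metabolites.append(Metabolite(
            id=entry["id"],
            name=entry.get("name", ""),
            compartment=entry.get("compartment", "c"),
            formula=entry.get("formula", ""),
            charge=int(entry.get("charge", 0)),
        ))
    reactions = []
    for entry in doc["reactions"]:
        for key in ("id", "stoichiometry", "lb", "ub"):
            if key not in entry:
                raise ModelError(f"reaction entry {entry.get('id', '?')!r} missing field {key!r}")
        reactions.append(Reaction(
            id=entry["id"],
            stoichiometry={m: float(c) for m, c in entry["stoichiometry"].items()},
            lower_bound=float(entry["lb"]),
            upper_bound=float(entry["ub"]),
            gene_rule=entry.get("gene_rule", ""),
            subsystem=entry.get("subsystem", ""),
            name=entry.get("name", ""),
        ))
    extras = {k: v for k, v in doc.items()
              if k not in ("id", "metabolites", "reactions", "objective")}
    return MetabolicModel(metabolites, reactions, doc["objective"],
                          id=doc.get("id", "model"), extras=extras)


def save_json_model(model: MetabolicModel, path: str | Path) -> None:
    """Write the JSON dialect with sorted keys (byte-stable round trips)."""
    with open(path, "w") as fh:
        fh.write(model_to_json(model))


def model_to_json(model: MetabolicModel) -> str:
    doc = {
        "id": model.id,
        "metabolites": [
            {"id": m.id, "name": m.name, "compartment": m.compartment,
             "formula": m.formula, "charge": m.charge}
            for m in model.metabolites
        ],
        "reactions": [
            {"id": r.id,
             "stoichiometry": {m: float(c) for m, c in sorted(r.stoichiometry.items())},
             "lb": float(r.lower_bound), "ub": float(r.upper_bound),
             "gene_rule": r.gene_rule, "subsystem": r.subsystem, "name": r.name}
            for r in model.reactions
        ],
        "objective": model.objective_id,
    }
    doc.update(model.extras)
    return json.dumps(doc, indent=1, sort_keys=True)
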