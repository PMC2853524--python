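"""SBML and tabular I/O for :class:`~switchfba.model.MetabolicModel`.

Reads both legacy level-2 files (bounds in kinetic-law parameters, GPR rules
in ``GENE_ASSOCIATION`` notes — the dialect of 2010-era supplementary models)
and level-3 files using the ``fbc`` package.  Always writes level 3 + fbc v2.
Reaction kind and subsystem, which SBML has no first-class slot for, travel in
the reaction notes.
"""

from __future__ import annotations

import re
from pathlib import Path

import libsbml
import pandas as pd

from .errors import SBMLParseError, ValidationError
from .gpr import genes as gpr_genes
from .model import MetabolicModel, Metabolite, Reaction, infer_reaction_kinds

_NOTE_FIELDS = ("GENE_ASSOCIATION", "GENE ASSOCIATION", "SUBSYSTEM", "KIND")


def _check(value, message: str):
    if value is None or (isinstance(value, int) and value != libsbml.LIBSBML_OPERATION_SUCCESS):
        raise ValidationError(f"libsbml error while {message} (code {value})")
    return value


def _note_field(notes: str, field: str) -> str | None:
    m = re.search(rf"{field}\s*:\s*([^<\n]*)", notes)
    return m.group(1).strip() if m else None


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

def read_sbml(path: str | Path, infer_kinds: bool = True) -> MetabolicModel:
    """Read an SBML file into a :class:`MetabolicModel`.

    Bounds and gene associations are preserved exactly.  Reaction kinds are
    taken from notes when present, otherwise inferred heuristically (see
    :func:`~switchfba.model.infer_reaction_kinds`) unless ``infer_kinds`` is
    off.

    Raises
    ------
    SBMLParseError
        Malformed XML; the message names the offending line.
    ValidationError
        Structurally invalid model (e.g. stoichiometry referencing an
        undeclared species), listing the offending reaction ids.
    """
    path = Path(path)
    if not path.exists():
        raise SBMLParseError(f"no such file: {path}")
    doc = libsbml.readSBML(str(path))
    errors = [
        doc.getError(i)
        for i in range(doc.getNumErrors())
        if doc.getError(i).getSeverity() >= libsbml.LIBSBML_SEV_ERROR
    ]
    if errors:
        first = errors[0]
        raise SBMLParseError(
            f"{path}: line {first.getLine()}: {first.getMessage().strip()}"
        )
    smodel = doc.getModel()
    if smodel is None:
        raise SBMLParseError(f"{path}: document contains no model")

    mets = []
    for i in range(smodel.getNumSpecies()):
        sp = smodel.getSpecies(i)
        if sp.getBoundaryCondition():
            continue  # boundary species are the implicit ∅ side of exchanges
        formula = None
        fsp = sp.getPlugin("fbc")
        if fsp is not None and fsp.isSetChemicalFormula():
            formula = fsp.getChemicalFormula()
        mets.append(
            Metabolite(
                id=sp.getId(),
                name=sp.getName() or "",
                compartment=sp.getCompartment() or "c",
                formula=formula,
            )
        )
    declared = {m.id for m in mets}
    boundary = {
        smodel.getSpecies(i).getId()
        for i in range(smodel.getNumSpecies())
        if smodel.getSpecies(i).getBoundaryCondition()
    }

    fmodel = smodel.getPlugin("fbc")
    gp_label = {}
    if fmodel is not None:
        for i in range(fmodel.getNumGeneProducts()):
            gp = fmodel.getGeneProduct(i)
            gp_label[gp.getId()] = gp.getLabel() or gp.getId()

    reactions = []
    bad = []
    for i in range(smodel.getNumReactions()):
        srxn = smodel.getReaction(i)
        stoich: dict[str, float] = {}
        undeclared = False
        for ref, sign in (
            *((srxn.getReactant(j), -1.0) for j in range(srxn.getNumReactants())),
            *((srxn.getProduct(j), +1.0) for j in range(srxn.getNumProducts())),
        ):
            sid = ref.getSpecies()
            if sid in boundary:
                continue
            if sid not in declared:
                undeclared = True
                continue
            stoich[sid] = stoich.get(sid, 0.0) + sign * ref.getStoichiometry()
        if undeclared:
            bad.append(srxn.getId())

        lb, ub = _read_bounds(smodel, srxn)
        rule = _read_gpr(srxn, gp_label)
        notes = srxn.getNotesString() if srxn.isSetNotes() else ""
        kind = _note_field(notes, "KIND")
        subsystem = _note_field(notes, "SUBSYSTEM")
        reactions.append(
            Reaction(
                id=srxn.getId(),
                name=srxn.getName() or "",
                stoichiometry={m: c for m, c in stoich.items() if c != 0},
                lower_bound=lb,
                upper_bound=ub,
                gene_association=rule,
                subsystem=subsystem or None,
                kind=kind or None,
            )
        )
    if bad:
        raise ValidationError(
            "stoichiometry references undeclared species in reactions: "
            + ", ".join(sorted(bad))
        )

    objective = _read_objective(smodel, fmodel)
    model = MetabolicModel(
        metabolites=mets,
        reactions=reactions,
        objective=objective,
        id=smodel.getId() or "model",
    )
    if infer_kinds:
        infer_reaction_kinds(model)
    return model


def _read_bounds(smodel, srxn) -> tuple[float, float]:
    inf = float("inf")
    frxn = srxn.getPlugin("fbc")
    if frxn is not None and frxn.isSetLowerFluxBound():
        lb = smodel.getParameter(frxn.getLowerFluxBound()).getValue()
        ub = smodel.getParameter(frxn.getUpperFluxBound()).getValue()
        return lb, ub
    kl = srxn.getKineticLaw()
    if kl is not None:
        plb = kl.getParameter("LOWER_BOUND")
        pub = kl.getParameter("UPPER_BOUND")
        if plb is not None and pub is not None:
            return plb.getValue(), pub.getValue()
    return (-inf if srxn.getReversible() else 0.0), inf


def _read_gpr(srxn, gp_label: dict[str, str]) -> str:
    frxn = srxn.getPlugin("fbc")
    if frxn is not None and frxn.isSetGeneProductAssociation():
        assoc = frxn.getGeneProductAssociation().getAssociation()
        if assoc is not None:
            infix = assoc.toInfix()
            # map gene-product SIds back to their labels
            def sub(m):
                tok = m.group(0)
                return gp_label.get(tok, tok)

            return re.sub(r"[^\s()]+", lambda m: sub(m)
                          if m.group(0).lower() not in ("and", "or") else m.group(0),
                          infix)
    notes = srxn.getNotesString() if srxn.isSetNotes() else ""
    for fld in ("GENE_ASSOCIATION", "GENE ASSOCIATION"):
        rule = _note_field(notes, fld)
        if rule:
            return rule
    return ""


def _read_objective(smodel, fmodel) -> dict[str, float]:
    if fmodel is not None and fmodel.getActiveObjective() is not None:
        obj = fmodel.getActiveObjective()
        out = {}
        for i in range(obj.getNumFluxObjectives()):
            fo = obj.getFluxObjective(i)
            out[fo.getReaction()] = fo.getCoefficient()
        if out:
            return out
    # legacy: OBJECTIVE_COEFFICIENT kinetic-law parameters
    out = {}
    for i in range(smodel.getNumReactions()):
        srxn = smodel.getReaction(i)
        kl = srxn.getKineticLaw()
        if kl is not None:
            p = kl.getParameter("OBJECTIVE_COEFFICIENT")
            if p is not None and p.getValue() != 0:
                out[srxn.getId()] = p.getValue()
    return out


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------

def write_sbml(model: MetabolicModel, path: str | Path) -> None:
    """Write *model* as SBML level 3 version 1 with the fbc-v2 package.

    The emitted file re-parses (via :func:`read_sbml`) to an equivalent model:
    identical ids, stoichiometry, bounds, GPR gene sets, objective, kinds.
    """
    model.validate()
    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    smodel = doc.createModel()
    _check(smodel.setId(model.id or "model"), "setting model id")
    fmodel = smodel.getPlugin("fbc")
    fmodel.setStrict(False)

    compartments = sorted({m.compartment for m in model.metabolites} or {"c"})
    for cid in compartments:
        comp = smodel.createCompartment()
        _check(comp.setId(cid), f"creating compartment {cid!r}")
        comp.setConstant(True)

    for met in model.metabolites:
        sp = smodel.createSpecies()
        if sp.setId(met.id) != libsbml.LIBSBML_OPERATION_SUCCESS:
            raise ValidationError(f"metabolite id {met.id!r} is not a valid SBML SId")
        sp.setName(met.name)
        sp.setCompartment(met.compartment)
        sp.setHasOnlySubstanceUnits(False)
        sp.setBoundaryCondition(False)
        sp.setConstant(False)
        if met.formula:
            sp.getPlugin("fbc").setChemicalFormula(met.formula)

    # flux-bound parameters, shared where values coincide
    bound_param: dict[float, str] = {}

    def param_for(value: float) -> str:
        if value in bound_param:
            return bound_param[value]
        pid = f"fb_{len(bound_param)}"
        p = smodel.createParameter()
        p.setId(pid)
        p.setValue(value)
        p.setConstant(True)
        bound_param[value] = pid
        return pid

    gene_ids: dict[str, str] = {}

    def gene_product_for(gene: str) -> str:
        if gene in gene_ids:
            return gene_ids[gene]
        gid = "G_" + re.sub(r"\W", "_", gene)
        gp = fmodel.createGeneProduct()
        _check(gp.setId(gid), f"creating gene product for {gene!r}")
        gp.setLabel(gene)
        gene_ids[gene] = gid
        return gid

    objective = fmodel.createObjective()
    objective.setId("obj")
    objective.setType("maximize")
    fmodel.setActiveObjectiveId("obj")

    for rxn in model.reactions:
        srxn = smodel.createReaction()
        if srxn.setId(rxn.id) != libsbml.LIBSBML_OPERATION_SUCCESS:
            raise ValidationError(f"reaction id {rxn.id!r} is not a valid SBML SId")
        srxn.setName(rxn.name)
        srxn.setReversible(rxn.reversible)
        srxn.setFast(False)
        for met, coef in sorted(rxn.stoichiometry.items()):
            ref = srxn.createReactant() if coef < 0 else srxn.createProduct()
            ref.setSpecies(met)
            ref.setStoichiometry(abs(float(coef)))
            ref.setConstant(True)
        frxn = srxn.getPlugin("fbc")
        frxn.setLowerFluxBound(param_for(float(rxn.lower_bound)))
        frxn.setUpperFluxBound(param_for(float(rxn.upper_bound)))
        if rxn.gene_association:
            for g in sorted(gpr_genes(rxn.gene_association)):
                gene_product_for(g)
            gpa = frxn.createGeneProductAssociation()
            # tokens are matched against gene-product labels (usingId=False),
            # so the rule is passed with its original gene names
            _check(gpa.setAssociation(rxn.gene_association),
                   f"setting GPR of {rxn.id}")
        notes = []
        if rxn.gene_association:
            notes.append(f"GENE_ASSOCIATION: {rxn.gene_association}")
        if rxn.subsystem:
            notes.append(f"SUBSYSTEM: {rxn.subsystem}")
        if rxn.kind:
            notes.append(f"KIND: {rxn.kind}")
        if notes:
            body = "".join(f"<p>{n}</p>" for n in notes)
            srxn.setNotes(
                f'<body xmlns="http://www.w3.org/1999/xhtml">{body}</body>'
            )
        weight = model.objective.get(rxn.id, 0.0)
        if weight != 0:
            fo = objective.createFluxObjective()
            fo.setReaction(rxn.id)
            fo.setCoefficient(float(weight))

    if libsbml.writeSBMLToFile(doc, str(path)) != 1:
        raise OSError(f"could not write SBML to {path}")


# ---------------------------------------------------------------------------
# tabular export
# ---------------------------------------------------------------------------

def metabolite_table(model: MetabolicModel) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "id": m.id,
                "name": m.name,
                "compartment": m.compartment,
                "formula": m.formula or "",
            }
            for m in model.metabolites
        ]
    )


def reaction_table(model: MetabolicModel) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "id": r.id,
                "name": r.name,
                "equation": r.equation(),
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                "genes": r.gene_association,
                "subsystem": r.subsystem or "",
                "kind": r.kind or "",
            }
            for r in model.reactions
        ]
    )


def export_tables(model: MetabolicModel, metabolites_path, reactions_path) -> None:
    """TSV export of the metabolite and reaction tables."""
    metabolite_table(model).to_csv(metabolites_path, sep="\t", index=False)
    reaction_table(model).to_csv(reactions_path, sep="\t", index=False)
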