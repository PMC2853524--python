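"""Stoichiometric genome-scale model data structures.

The central object is :class:`MetabolicModel`: a list of metabolites, a list of
bounded reactions with gene-protein-reaction (GPR) rules, and an objective
(by default the lumped biomass reaction, whose flux is the specific growth
rate μ in 1/h).  The stoichiometric matrix S (metabolites × reactions) is
derived from the per-reaction stoichiometry maps; mass balance at steady state
is S·v = 0.

Sign conventions
----------------
Stoichiometric coefficients are negative for consumed and positive for
produced metabolites.  An exchange reaction is a boundary pseudo-reaction
written ``met ↔ ∅`` (single metabolite, coefficient −1): uptake is a negative
flux, so an uptake limit of u mmol/gDW/h is the lower bound −u.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
from scipy import sparse

from . import gpr
from .errors import ValidationError

#: Reaction kinds. ``enzymatic`` covers metabolite biosynthesis/degradation,
#: ``exchange`` the boundary input/output constraints of the system.
REACTION_KINDS = ("enzymatic", "transport", "exchange", "biomass", "maintenance")

DEFAULT_BIOMASS_PATTERNS = (r"biomass", r"growth")
DEFAULT_MAINTENANCE_PATTERNS = (r"maintenance", r"atpm", r"ngam")


@dataclass
class Metabolite:
    """A metabolite in a compartment.

    Parameters
    ----------
    id : str
        Non-empty identifier, unique within a model.
    name : str
        Free-text name.
    compartment : str
        Compartment code, e.g. ``"c"`` (cytosol) or ``"e"`` (extracellular).
    formula : str, optional
        Elemental formula, used e.g. to derive molecular weights.
    """

    id: str
    name: str = ""
    compartment: str = "c"
    formula: Optional[str] = None

    def __post_init__(self):
        if not self.id:
            raise ValidationError("metabolite id must be non-empty")


@dataclass
class Reaction:
    """A bounded reaction with stoichiometry and an optional GPR rule.

    ``stoichiometry`` maps metabolite id → signed coefficient.  Bounds are
    fluxes in mmol/gDW/h (the biomass reaction's flux is in 1/h).  The GPR
    ``gene_association`` is a boolean expression over gene ids ("and"/"or");
    an empty string means no associated gene.
    """

    id: str
    stoichiometry: dict[str, float] = field(default_factory=dict)
    lower_bound: float = -1000.0
    upper_bound: float = 1000.0
    name: str = ""
    gene_association: str = ""
    subsystem: Optional[str] = None
    kind: Optional[str] = None

    def __post_init__(self):
        if not self.id:
            raise ValidationError("reaction id must be non-empty")
        if self.lower_bound > self.upper_bound:
            raise ValidationError(
                f"reaction {self.id}: lower_bound {self.lower_bound} > "
                f"upper_bound {self.upper_bound}"
            )
        if self.kind is not None and self.kind not in REACTION_KINDS:
            raise ValidationError(f"reaction {self.id}: unknown kind {self.kind!r}")

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0

    @property
    def genes(self) -> set[str]:
        return gpr.genes(self.gene_association)

    @property
    def is_exchange(self) -> bool:
        return len(self.stoichiometry) == 1

    def equation(self) -> str:
        """Human-readable equation string, e.g. ``"2 A + B --> C"``."""

        def side(items):
            parts = []
            for met, coef in sorted(items):
                coef = abs(coef)
                parts.append(met if coef == 1 else f"{coef:g} {met}")
            return " + ".join(parts)

        lhs = side((m, c) for m, c in self.stoichiometry.items() if c < 0)
        rhs = side((m, c) for m, c in self.stoichiometry.items() if c > 0)
        arrow = "<=>" if self.reversible else "-->"
        return f"{lhs} {arrow} {rhs}".strip()


@dataclass
class MetabolicModel:
    """A genome-scale stoichiometric model.

    The objective maps reaction id → weight; by default the single biomass
    reaction gets weight 1, so the LP optimum is the specific growth rate.
    """

    metabolites: list[Metabolite] = field(default_factory=list)
    reactions: list[Reaction] = field(default_factory=list)
    objective: dict[str, float] = field(default_factory=dict)
    id: str = "model"

    def __post_init__(self):
        self.validate()
        if not self.objective:
            biomass = [r.id for r in self.reactions if r.kind == "biomass"]
            if len(biomass) == 1:
                self.objective = {biomass[0]: 1.0}

    # -- lookups ---------------------------------------------------------
    @property
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def metabolite(self, met_id: str) -> Metabolite:
        try:
            return next(m for m in self.metabolites if m.id == met_id)
        except StopIteration:
            raise KeyError(met_id) from None

    def reaction(self, rxn_id: str) -> Reaction:
        try:
            return next(r for r in self.reactions if r.id == rxn_id)
        except StopIteration:
            raise KeyError(rxn_id) from None

    @property
    def genes(self) -> set[str]:
        out: set[str] = set()
        for r in self.reactions:
            out |= r.genes
        return out

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        met_ids = [m.id for m in self.metabolites]
        if len(set(met_ids)) != len(met_ids):
            dupes = sorted({m for m in met_ids if met_ids.count(m) > 1})
            raise ValidationError(f"duplicate metabolite ids: {dupes}")
        rxn_ids = [r.id for r in self.reactions]
        if len(set(rxn_ids)) != len(rxn_ids):
            dupes = sorted({r for r in rxn_ids if rxn_ids.count(r) > 1})
            raise ValidationError(f"duplicate reaction ids: {dupes}")
        known = set(met_ids)
        offending = [
            r.id
            for r in self.reactions
            if any(m not in known for m in r.stoichiometry)
        ]
        if offending:
            raise ValidationError(
                "reactions reference undeclared metabolites: " + ", ".join(offending)
            )
        bad_obj = sorted(set(self.objective) - set(rxn_ids))
        if bad_obj:
            raise ValidationError(f"objective references unknown reactions: {bad_obj}")


def stoichiometric_matrix(model: MetabolicModel, dense: bool = False):
    """The stoichiometric matrix S, metabolites × reactions.

    Entry (i, j) is the coefficient of metabolite i in reaction j: negative if
    consumed, positive if produced.  Returned as a CSC sparse matrix unless
    ``dense`` is set.
    """
    met_index = {m.id: i for i, m in enumerate(model.metabolites)}
    rows, cols, vals = [], [], []
    for j, rxn in enumerate(model.reactions):
        for met, coef in rxn.stoichiometry.items():
            rows.append(met_index[met])
            cols.append(j)
            vals.append(float(coef))
    S = sparse.csc_matrix(
        (vals, (rows, cols)), shape=(len(model.metabolites), len(model.reactions))
    )
    return S.toarray() if dense else S


def gene_reaction_map(model: MetabolicModel) -> dict[str, set[str]]:
    """Map gene id → set of reaction ids whose GPR rule mentions it.

    Reactions with empty GPR rules contribute nothing; every returned gene
    occurs in at least one rule (no phantom genes).
    """
    out: dict[str, set[str]] = {}
    for rxn in model.reactions:
        for g in rxn.genes:
            out.setdefault(g, set()).add(rxn.id)
    return out


def placeholder_genes(model: MetabolicModel) -> set[str]:
    """Unknown-gene placeholder tokens present in the model's GPR rules."""
    return {g for g in model.genes if gpr.is_placeholder(g)}


def infer_reaction_kinds(
    model: MetabolicModel,
    biomass_patterns: Iterable[str] = DEFAULT_BIOMASS_PATTERNS,
    maintenance_patterns: Iterable[str] = DEFAULT_MAINTENANCE_PATTERNS,
) -> None:
    """Fill in missing ``Reaction.kind`` tags in place.

    Heuristics (applied only where ``kind is None``): a single-metabolite
    reaction is an exchange; a reaction moving the same base species between
    two compartments is a transport; ids matching the biomass or maintenance
    patterns (case-insensitive substring regexes) are tagged accordingly;
    everything else is enzymatic.
    """
    bm = [re.compile(p, re.IGNORECASE) for p in biomass_patterns]
    mnt = [re.compile(p, re.IGNORECASE) for p in maintenance_patterns]
    comp = {m.id: m.compartment for m in model.metabolites}

    def base_species(met_id: str) -> str:
        # strip a compartment suffix like "_c" / "[e]" if present
        m = re.match(r"^(.*?)(?:_([a-z0-9]{1,2})|\[([a-z0-9]{1,2})\])$", met_id)
        return m.group(1) if m else met_id

    for rxn in model.reactions:
        if rxn.kind is not None:
            continue
        if any(p.search(rxn.id) or p.search(rxn.name) for p in bm):
            rxn.kind = "biomass"
        elif any(p.search(rxn.id) or p.search(rxn.name) for p in mnt):
            rxn.kind = "maintenance"
        elif rxn.is_exchange:
            rxn.kind = "exchange"
        else:
            consumed = {
                (base_species(m), comp[m]) for m, c in rxn.stoichiometry.items() if c < 0
            }
            produced = {
                (base_species(m), comp[m]) for m, c in rxn.stoichiometry.items() if c > 0
            }
            crossing = {
                b for b, _ in consumed
            } & {b for b, _ in produced}
            is_transport = any(
                bc != bp
                for (b1, bc) in consumed
                for (b2, bp) in produced
                if b1 == b2 and b1 in crossing
            )
            rxn.kind = "transport" if is_transport else "enzymatic"


@dataclass
class ModelSummary:
    """Structural counts: metabolites, reactions by kind, genes."""

    n_metabolites: int
    n_reactions: int
    reactions_by_kind: dict[str, int]
    n_genes: int
    n_gene_associated_reactions: int

    def as_dict(self) -> dict:
        return {
            "n_metabolites": self.n_metabolites,
            "n_reactions": self.n_reactions,
            "reactions_by_kind": dict(self.reactions_by_kind),
            "n_genes": self.n_genes,
            "n_gene_associated_reactions": self.n_gene_associated_reactions,
        }


def model_summary(model: MetabolicModel) -> ModelSummary:
    """Count metabolites, reactions per kind, and distinct genes.

    The per-kind counts partition the reaction set (kinds are mutually
    exclusive; reactions with no kind tag count as enzymatic).
    """
    by_kind = {k: 0 for k in REACTION_KINDS}
    n_assoc = 0
    for rxn in model.reactions:
        by_kind[rxn.kind or "enzymatic"] += 1
        if rxn.genes:
            n_assoc += 1
    return ModelSummary(
        n_metabolites=len(model.metabolites),
        n_reactions=len(model.reactions),
        reactions_by_kind=by_kind,
        n_genes=len(model.genes),
        n_gene_associated_reactions=n_assoc,
    )
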