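"""Flux balance analysis: the linear-programming core.

Standard FBA maximizes an objective c·v (usually the biomass reaction, whose
flux is the specific growth rate μ) subject to steady-state mass balance
S·v = 0 and per-reaction flux bounds.  The LP optimum μ* is unique even when
the optimal flux vector is not; :func:`parsimonious_flux` resolves that
degeneracy by minimizing total absolute flux Σ|v| at the fixed optimum, which
yields a reproducible flux vector and zeroes out internal loops.

The chemostat panel applies measured uptake/production rates as bounds and
compares the predicted μ against the observed dilution rate D (at steady
state in a chemostat, μ = D).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

from .errors import ConfigError, SolverError
from .model import MetabolicModel, stoichiometric_matrix
from .units import molecular_weight

#: default numerical tolerances (all configurable per call)
FEASIBILITY_TOL = 1e-9
MASS_BALANCE_TOL = 1e-6


@dataclass
class FluxState:
    """Result of one LP solve.

    ``fluxes`` maps reaction id → flux in mmol/gDW/h (biomass in 1/h).
    ``objective_value`` is the LP optimum (μ for a pure biomass objective).
    ``status`` is one of ``optimal``, ``infeasible``, ``unbounded``.
    """

    fluxes: dict[str, float]
    objective_value: Optional[float]
    status: str
    unbounded_reaction: Optional[str] = None

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


def _lp_inputs(model, objective, bound_overrides):
    if objective is None:
        objective = model.objective
    if not objective:
        raise ConfigError("no objective given and model has none")
    rxn_index = {r.id: j for j, r in enumerate(model.reactions)}
    unknown = sorted(set(objective) - set(rxn_index))
    if unknown:
        raise ConfigError(f"objective references unknown reactions: {unknown}")
    n = len(model.reactions)
    c = np.zeros(n)
    for rid, w in objective.items():
        c[rxn_index[rid]] = w
    bounds = [(r.lower_bound, r.upper_bound) for r in model.reactions]
    if bound_overrides:
        unknown = sorted(set(bound_overrides) - set(rxn_index))
        if unknown:
            raise ConfigError(f"bound overrides reference unknown reactions: {unknown}")
        for rid, (lb, ub) in bound_overrides.items():
            if lb > ub:
                raise ConfigError(f"override for {rid}: lower {lb} > upper {ub}")
            bounds[rxn_index[rid]] = (lb, ub)
    S = stoichiometric_matrix(model)
    return c, S, bounds


def solve_fba(
    model: MetabolicModel,
    objective: Optional[dict[str, float]] = None,
    bound_overrides: Optional[dict[str, tuple[float, float]]] = None,
    feasibility_tol: float = FEASIBILITY_TOL,
) -> FluxState:
    """Maximize ``objective``·v subject to S·v = 0 and flux bounds.

    Parameters
    ----------
    model : MetabolicModel
    objective : dict, optional
        Reaction id → weight; defaults to the model's objective (biomass).
    bound_overrides : dict, optional
        Reaction id → (lower, upper), replacing that reaction's bounds for
        this solve only.
    feasibility_tol : float
        Primal feasibility tolerance passed to the LP solver.

    Returns
    -------
    FluxState
        With ``status`` reported faithfully: an infeasible bound set yields
        ``infeasible`` (no flux vector), an unbounded objective yields
        ``unbounded`` with a best-effort culprit reaction named.
    """
    c, S, bounds = _lp_inputs(model, objective, bound_overrides)
    res = linprog(
        -c,
        A_eq=S,
        b_eq=np.zeros(S.shape[0]),
        bounds=bounds,
        method="highs",
        options={"primal_feasibility_tolerance": feasibility_tol},
    )
    if res.status == 2:
        return FluxState(fluxes={}, objective_value=None, status="infeasible")
    if res.status == 3:
        obj = objective if objective is not None else model.objective
        culprit = None
        for rxn, (lb, ub) in zip(model.reactions, bounds):
            w = obj.get(rxn.id, 0.0)
            if (w > 0 and np.isinf(ub)) or (w < 0 and np.isinf(lb)):
                culprit = rxn.id
                break
        return FluxState(
            fluxes={}, objective_value=None, status="unbounded",
            unbounded_reaction=culprit,
        )
    if res.status != 0:
        raise SolverError(f"LP solver failed: {res.message}")
    fluxes = {r.id: float(v) for r, v in zip(model.reactions, res.x)}
    return FluxState(fluxes=fluxes, objective_value=float(-res.fun), status="optimal")


def parsimonious_flux(
    model: MetabolicModel,
    objective: Optional[dict[str, float]] = None,
    optimum: Optional[float] = None,
    bound_overrides: Optional[dict[str, tuple[float, float]]] = None,
    optimum_tol: float = 1e-9,
    feasibility_tol: float = FEASIBILITY_TOL,
) -> FluxState:
    """Minimize Σ|v| among flux vectors attaining the given optimum.

    ``optimum`` is the objective value of a prior :func:`solve_fba`; if not
    supplied it is computed first.  The returned state keeps
    ``objective_value`` equal to the original optimum (the secondary
    minimization changes only the flux vector).  Internal loops (closed
    cycles that add |v| without changing the objective) carry zero flux in
    the parsimonious solution.
    """
    if optimum is None:
        first = solve_fba(model, objective, bound_overrides, feasibility_tol)
        if not first.optimal:
            return first
        optimum = first.objective_value
    c, S, bounds = _lp_inputs(model, objective, bound_overrides)
    n = len(bounds)
    # split v = p - q, p, q >= 0; minimize sum(p + q)
    lb = np.array([b[0] for b in bounds])
    ub = np.array([b[1] for b in bounds])
    p_hi = np.maximum(ub, 0.0)
    q_hi = np.maximum(-lb, 0.0)
    p_lo = np.maximum(lb, 0.0)  # if lb > 0 the positive part is forced
    q_lo = np.maximum(-ub, 0.0)
    split_bounds = list(zip(p_lo, p_hi)) + list(zip(q_lo, q_hi))
    A_eq = sparse.hstack([S, -S], format="csc")
    slack = optimum_tol * max(1.0, abs(optimum))
    # objective constraint: c·(p - q) >= optimum - slack
    A_ub = sparse.hstack([-sparse.csr_matrix(c), sparse.csr_matrix(c)])
    res = linprog(
        np.ones(2 * n),
        A_eq=A_eq,
        b_eq=np.zeros(S.shape[0]),
        A_ub=A_ub,
        b_ub=np.array([-(optimum - slack)]),
        bounds=split_bounds,
        method="highs",
        options={"primal_feasibility_tolerance": feasibility_tol},
    )
    if res.status == 2:
        raise SolverError(
            "parsimonious resolve infeasible at the fixed optimum "
            f"{optimum:g}; consider relaxing optimum_tol (currently {optimum_tol:g})"
        )
    if res.status != 0:
        raise SolverError(f"parsimonious LP failed: {res.message}")
    v = res.x[:n] - res.x[n:]
    fluxes = {r.id: float(x) for r, x in zip(model.reactions, v)}
    return FluxState(fluxes=fluxes, objective_value=float(optimum), status="optimal")


def mass_balance_residual(model: MetabolicModel, state: FluxState) -> float:
    """max |(S·v)_i| for an optimal state — should be ≤ the mass-balance tol."""
    if not state.optimal:
        raise ConfigError("mass balance is defined only for optimal states")
    S = stoichiometric_matrix(model)
    v = np.array([state.fluxes[r.id] for r in model.reactions])
    return float(np.max(np.abs(S @ v))) if len(v) else 0.0


# ---------------------------------------------------------------------------
# chemostat validation panel
# ---------------------------------------------------------------------------

@dataclass
class ChemostatCondition:
    """One chemostat steady state, rates as printed (all non-negative).

    Uptake rates (glucose, O2) are in mmol/gDW/h, CO2 production in
    mmol/gDW/h, actinorhodin production in μg/gDW/h.  The sign convention
    (uptake = negative exchange flux) is applied internally.
    """

    glucose_uptake: float
    o2_uptake: float
    co2_production: float
    actinorhodin_production: float
    observed_dilution_rate: Optional[float] = None

    def __post_init__(self):
        for name in ("glucose_uptake", "o2_uptake", "co2_production",
                     "actinorhodin_production"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative as printed")


@dataclass
class ExchangeMap:
    """Names the model's exchange reactions for the constrained metabolites.

    Any entry may be None, in which case that rate is simply not applied
    (useful for reduced synthetic models without e.g. an oxygen exchange).
    """

    glucose: Optional[str] = None
    o2: Optional[str] = None
    co2: Optional[str] = None
    actinorhodin: Optional[str] = None


def condition_overrides(
    model: MetabolicModel,
    condition: ChemostatCondition,
    exchanges: ExchangeMap,
    actinorhodin_mw: Optional[float] = None,
    production_mode: str = "equality",
) -> dict[str, tuple[float, float]]:
    """Translate a chemostat condition into exchange-bound overrides.

    Glucose and O2 are uptake caps (lower bound −rate, upper bound 0).  CO2
    and actinorhodin are measured productions: in ``equality`` mode (default)
    the flux is pinned to the measured rate, in ``cap`` mode it is an upper
    bound.  Actinorhodin μg/gDW/h is converted to mmol/gDW/h via its
    molecular weight (g/mol), taken from the model species formula when not
    given explicitly.
    """
    if production_mode not in ("equality", "cap"):
        raise ConfigError(f"unknown production_mode {production_mode!r}")
    rxn_ids = set(model.reaction_ids)
    overrides: dict[str, tuple[float, float]] = {}

    def require(rid, what):
        if rid not in rxn_ids:
            raise ConfigError(f"model has no exchange reaction {rid!r} for {what}")

    if exchanges.glucose is not None:
        require(exchanges.glucose, "glucose")
        overrides[exchanges.glucose] = (-condition.glucose_uptake, 0.0)
    if exchanges.o2 is not None:
        require(exchanges.o2, "oxygen")
        overrides[exchanges.o2] = (-condition.o2_uptake, 0.0)
    if exchanges.co2 is not None:
        require(exchanges.co2, "carbon dioxide")
        r = condition.co2_production
        overrides[exchanges.co2] = (r, r) if production_mode == "equality" else (0.0, r)
    if exchanges.actinorhodin is not None:
        require(exchanges.actinorhodin, "actinorhodin")
        mw = actinorhodin_mw
        if mw is None:
            mw = _actinorhodin_mw_from_model(model, exchanges.actinorhodin)
        # μg/gDW/h ÷ (g/mol) = μmol/gDW/h; ÷ 1000 → mmol/gDW/h
        r = condition.actinorhodin_production / mw / 1000.0
        overrides[exchanges.actinorhodin] = (
            (r, r) if production_mode == "equality" else (0.0, r)
        )
    return overrides


#: actinorhodin C32H26O14, used when the model species carries no formula
ACTINORHODIN_MW = 634.54


def _actinorhodin_mw_from_model(model: MetabolicModel, exchange_id: str) -> float:
    met_id = next(iter(model.reaction(exchange_id).stoichiometry))
    formula = model.metabolite(met_id).formula
    if formula:
        try:
            return molecular_weight(formula)
        except ValueError:
            pass
    return ACTINORHODIN_MW


def chemostat_panel(
    model: MetabolicModel,
    conditions: Sequence[ChemostatCondition],
    exchanges: ExchangeMap,
    objective: Optional[dict[str, float]] = None,
    actinorhodin_mw: Optional[float] = None,
    production_mode: str = "equality",
) -> list[tuple[ChemostatCondition, float]]:
    """Predict μ for each chemostat condition (one biomass-maximizing solve
    per condition; output order matches input order).

    Infeasible conditions yield ``nan`` rather than being dropped.
    """
    out = []
    for cond in conditions:
        overrides = condition_overrides(
            model, cond, exchanges, actinorhodin_mw, production_mode
        )
        state = solve_fba(model, objective, overrides)
        out.append((cond, state.objective_value if state.optimal else float("nan")))
    return out


def read_conditions_tsv(path) -> list[ChemostatCondition]:
    """Read a chemostat condition table.

    Columns are matched case-insensitively by prefix: glucose, o2 (or
    oxygen), co2, actinorhodin, observed.  Extra columns are ignored.
    """
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    if df.empty:
        return []

    def col(*prefixes, required=True):
        for c in df.columns:
            norm = c.strip().lower().replace("_", " ")
            if any(norm.startswith(p) for p in prefixes):
                return c
        if required:
            raise ConfigError(
                f"condition table lacks a column starting with {prefixes[0]!r}"
            )
        return None

    g, o, c2, a = col("glucose"), col("o2", "oxygen"), col("co2"), col("actinorhodin")
    d = col("observed", required=False)
    out = []
    for _, row in df.iterrows():
        out.append(
            ChemostatCondition(
                glucose_uptake=float(row[g]),
                o2_uptake=float(row[o]),
                co2_production=float(row[c2]),
                actinorhodin_production=float(row[a]),
                observed_dilution_rate=float(row[d]) if d is not None else None,
            )
        )
    return out
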