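"""Synthetic fixtures: toy metabolic networks, depletion schedules, and
expression matrices with known ground truth.

The generator emulates the structure of a phosphate-limited *Streptomyces*
fermentation study: a stoichiometric model with a lumped biomass reaction,
nutrient exchanges whose uptake capacity ramps to zero as nutrients deplete
(phosphate at the 34 h switch), an antibiotic pathway whose production rate
rises after the switch, and a log2 expression matrix in which each gene's
profile is a noisy affine transform of its matched reaction's flux profile —
with injected anticorrelated (sign-flipped), constant-flux, unexpressed, and
negative-control genes.  Every product is deterministic under the seed, and
ground-truth labels are emitted alongside so the whole analysis pipeline can
be scored against known answers.

Toy network layout (per branch b with uptake capacity u_b):

    ∅ ↔ nut_b,e → nut_b,c → x_1 → ... → x_{L-1} → precursor

All branches feed one pooled precursor; the biomass reaction consumes
``biomass_demand`` units of it, so the closed-form optimal growth rate is
μ* = (Σ_active u_b − maintenance_flux) / biomass_demand.  Blocked branches
(zero uptake forever) carry provably zero flux and supply the zero-flux gene
set; a maintenance reaction with pinned flux supplies the constant-flux
genes; an antibiotic pathway (precursor → act → secreted) carries the
post-switch production.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .dynamic import (
    ConstraintSchedule,
    FluxTimeSeries,
    default_time_grid,
    run_dynamic_fba,
)
from .errors import ConfigError
from .expression import ExpressionMatrix, match_genes
from .fba import ChemostatCondition, ExchangeMap, solve_fba
from .model import MetabolicModel, Metabolite, Reaction

#: formula gives the antibiotic a molecular weight of ≈ 634.5 g/mol
ACT_FORMULA = "C32H26O14"
ACT_EXCHANGE = "EX_act_e"

_DEFAULT_NUTRIENTS = ("phosphate", "glucose", "glutamate")


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic study.

    Fractions partition the genes whose matched flux varies over time into
    correlated / anticorrelated / unexpressed (remainder: uncorrelated, flat
    expression); they must sum to ≤ 1.  ``f_constant_flux`` sizes the gene
    complement of the pinned-flux maintenance reaction.  ``noise_sd`` is the
    additive Gaussian noise on log2 expression, applied to unit-variance
    flux shapes.
    """

    n_chain_length: int = 3
    n_branches: int = 3
    n_blocked_branches: int = 1
    n_genes: int = 200
    n_times: Optional[int] = None  # None → the fermentation sampling grid
    noise_sd: float = 0.1
    f_correlated: float = 0.55
    f_anticorrelated: float = 0.15
    f_constant_flux: float = 0.045
    f_unexpressed: float = 0.05
    n_controls: int = 10
    seed: int = 0
    uptake_rate: float = 10.0
    biomass_demand: float = 2.0
    maintenance_flux: float = 0.2
    depletion_times: dict[str, float] = field(
        default_factory=lambda: {"phosphate": 34.0, "glutamate": 56.0}
    )
    switch_time: float = 34.0
    antibiotic_slope: float = 50.0  # μg/gDW/h per hour after the switch

    def __post_init__(self):
        fr = (self.f_correlated, self.f_anticorrelated,
              self.f_constant_flux, self.f_unexpressed)
        if any(f < 0 or f > 1 for f in fr) or sum(fr) > 1 + 1e-12:
            raise ConfigError("fractions must lie in [0, 1] and sum to at most 1")
        if self.n_chain_length < 1:
            raise ConfigError("n_chain_length must be >= 1")
        if self.n_branches < 1:
            raise ConfigError("need at least one active branch")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be non-negative")

    @property
    def nutrients(self) -> list[str]:
        base = list(_DEFAULT_NUTRIENTS[: self.n_branches])
        base += [f"nut{i}" for i in range(len(base) + 1, self.n_branches + 1)]
        return base

    @property
    def blocked_nutrients(self) -> list[str]:
        return [f"blk{i}" for i in range(1, self.n_blocked_branches + 1)]

    def time_grid(self) -> np.ndarray:
        if self.n_times is None:
            return default_time_grid()
        if self.n_times < 2:
            raise ConfigError("n_times must be >= 2")
        return np.linspace(20.0, 60.0, self.n_times)


@dataclass
class ToyRecord:
    """Bookkeeping emitted with the toy model: the analytic optimum and the
    structural ground truth used by recovery tests."""

    optimum: float  # closed-form μ* at full uptake
    branch_capacities: dict[str, float]
    blocked_nutrients: list[str]
    biomass_demand: float
    maintenance_flux: float
    reaction_genes: dict[str, list[str]]
    blocked_reactions: list[str]
    constant_flux_reactions: list[str]


def make_toy_model(spec: SyntheticSpec) -> tuple[MetabolicModel, ToyRecord]:
    """Build the branch/chain toy network with gene associations.

    Genes are assigned blockwise (synthetic operons: consecutive gene ids on
    the same reaction, joined as isozymes with ``or``); every tenth gene is
    additionally attached to the following reaction (multi-reaction genes),
    and reactions with ≥ 3 genes carry one two-gene ``and`` complex.  The
    returned record holds the closed-form optimal growth rate
    (Σ uptake − maintenance) / demand.
    """
    mets: list[Metabolite] = [Metabolite("prec_c", name="pooled precursor")]
    rxns: list[Reaction] = []
    gene_bearing: list[str] = []
    blocked_rxns: list[str] = []

    all_nutrients = [(n, False) for n in spec.nutrients] + [
        (n, True) for n in spec.blocked_nutrients
    ]
    for nut, blocked in all_nutrients:
        mets.append(Metabolite(f"{nut}_e", compartment="e"))
        mets.append(Metabolite(f"{nut}_c", compartment="c"))
        rxns.append(
            Reaction(
                f"EX_{nut}_e",
                {f"{nut}_e": -1.0},
                lower_bound=0.0 if blocked else -spec.uptake_rate,
                upper_bound=0.0,
                kind="exchange",
            )
        )
        branch_chain = []
        tr = Reaction(
            f"TR_{nut}", {f"{nut}_e": -1.0, f"{nut}_c": 1.0}, 0.0, 1000.0,
            kind="transport",
        )
        rxns.append(tr)
        branch_chain.append(tr.id)
        prev = f"{nut}_c"
        for i in range(1, spec.n_chain_length + 1):
            nxt = "prec_c" if i == spec.n_chain_length else f"{nut}_x{i}_c"
            if nxt != "prec_c":
                mets.append(Metabolite(nxt, compartment="c"))
            step = Reaction(
                f"CH_{nut}_{i}", {prev: -1.0, nxt: 1.0}, 0.0, 1000.0,
                kind="enzymatic",
            )
            rxns.append(step)
            branch_chain.append(step.id)
            prev = nxt
        gene_bearing.extend(branch_chain)
        if blocked:
            blocked_rxns.extend([f"EX_{nut}_e"] + branch_chain)

    # antibiotic pathway: precursor → act_c → act_e → ∅ (secretion only)
    mets.append(Metabolite("act_c", name="antibiotic", formula=ACT_FORMULA))
    mets.append(Metabolite("act_e", name="antibiotic", compartment="e",
                           formula=ACT_FORMULA))
    rxns.append(Reaction("ACT_SYN", {"prec_c": -1.0, "act_c": 1.0}, 0.0, 1000.0,
                         kind="enzymatic"))
    rxns.append(Reaction("ACT_TR", {"act_c": -1.0, "act_e": 1.0}, 0.0, 1000.0,
                         kind="transport"))
    rxns.append(Reaction(ACT_EXCHANGE, {"act_e": -1.0}, 0.0, 1000.0,
                         kind="exchange"))
    gene_bearing.extend(["ACT_SYN", "ACT_TR"])

    rxns.append(
        Reaction(
            "MNT", {"prec_c": -1.0},
            spec.maintenance_flux, spec.maintenance_flux,
            kind="maintenance",
        )
    )
    rxns.append(
        Reaction("BM", {"prec_c": -spec.biomass_demand}, 0.0, 1000.0, kind="biomass")
    )

    # ---- gene assignment -------------------------------------------------
    width = max(4, len(str(spec.n_genes)))
    genes = [f"g{i:0{width}d}" for i in range(1, spec.n_genes + 1)]
    n_constant = round(spec.f_constant_flux * spec.n_genes)
    constant_genes, pathway_genes = genes[:n_constant], genes[n_constant:]

    reaction_genes: dict[str, list[str]] = {rid: [] for rid in gene_bearing}
    reaction_genes["MNT"] = list(constant_genes)
    if pathway_genes:
        chunks = np.array_split(np.array(pathway_genes), len(gene_bearing))
        for rid, chunk in zip(gene_bearing, chunks):
            reaction_genes[rid] = list(chunk)
        for i, g in enumerate(pathway_genes):
            if (i + 1) % 10 == 0:  # multi-reaction genes
                j = next(k for k, rid in enumerate(gene_bearing)
                         if g in reaction_genes[rid])
                other = gene_bearing[(j + 1) % len(gene_bearing)]
                if g not in reaction_genes[other]:
                    reaction_genes[other].append(g)

    by_id = {r.id: r for r in rxns}
    for rid in ["MNT"] + gene_bearing:
        members = reaction_genes.get(rid, [])
        if not members:
            continue
        if len(members) >= 3:
            complex_part = f"({members[0]} and {members[1]})"
            rule = " or ".join([complex_part] + members[2:])
        else:
            rule = " or ".join(members)
        by_id[rid].gene_association = rule
    if spec.maintenance_flux == 0 and not reaction_genes["MNT"]:
        pass

    model = MetabolicModel(metabolites=mets, reactions=rxns, id="toy_switch")
    capacities = {n: spec.uptake_rate for n in spec.nutrients}
    optimum = (sum(capacities.values()) - spec.maintenance_flux) / spec.biomass_demand
    record = ToyRecord(
        optimum=optimum,
        branch_capacities=capacities,
        blocked_nutrients=list(spec.blocked_nutrients),
        biomass_demand=spec.biomass_demand,
        maintenance_flux=spec.maintenance_flux,
        reaction_genes={k: list(v) for k, v in reaction_genes.items()},
        blocked_reactions=blocked_rxns,
        constant_flux_reactions=["MNT"] if spec.maintenance_flux > 0 else [],
    )
    return model, record


def make_schedule(spec: SyntheticSpec) -> ConstraintSchedule:
    """Depletion-style schedule on the fermentation grid.

    Each nutrient with a depletion time ramps linearly from full uptake at
    the grid start to zero at depletion (hard zero after); others stay
    constant.  Blocked nutrients are pinned at zero.  The antibiotic rate is
    zero before the switch and rises linearly after.
    """
    times = spec.time_grid()
    t0 = times[0]
    exchange_bounds = {}
    for nut in spec.nutrients:
        t_dep = spec.depletion_times.get(nut)
        if t_dep is None:
            rate = np.full_like(times, spec.uptake_rate)
        else:
            if t_dep <= t0:
                raise ConfigError(
                    f"depletion time {t_dep} h for {nut} is not after the "
                    f"grid start {t0} h"
                )
            rate = spec.uptake_rate * np.clip((t_dep - times) / (t_dep - t0), 0, 1)
        exchange_bounds[f"EX_{nut}_e"] = np.column_stack(
            [-rate, np.zeros_like(rate)]
        )
    for nut in spec.blocked_nutrients:
        exchange_bounds[f"EX_{nut}_e"] = np.zeros((len(times), 2))
    act = spec.antibiotic_slope * np.clip(times - spec.switch_time, 0, None)
    return ConstraintSchedule(
        times=times,
        exchange_bounds=exchange_bounds,
        antibiotic_rates={ACT_EXCHANGE: act},
        switch_time=spec.switch_time,
    )


def essential_reactions(spec: SyntheticSpec) -> set[str]:
    """Reactions that carry non-zero flux at every scheduled time point,
    derived from the study design rather than from any solve: the chains of
    nutrients that never deplete within the grid, plus the pinned-flux
    maintenance reaction and the biomass reaction."""
    grid_end = spec.time_grid()[-1]
    out = set()
    for nut in spec.nutrients:
        t_dep = spec.depletion_times.get(nut)
        if t_dep is None or t_dep > grid_end:
            out |= {f"TR_{nut}", f"EX_{nut}_e"}
            out |= {f"CH_{nut}_{i}" for i in range(1, spec.n_chain_length + 1)}
    if spec.maintenance_flux > 0:
        out.add("MNT")
    out.add("BM")
    return out


def simulate_expression(
    flux_ts: FluxTimeSeries,
    matching: dict[str, str],
    spec: SyntheticSpec,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Expression profiles as noisy affine transforms of matched fluxes.

    Gene labels (the emitted ground truth):

    * ``zero_flux`` — matched flux identically zero; expression nonetheless
      switches on sigmoidally at the switch time (the blocked-pathway
      signature that flags model gaps).
    * ``constant_flux`` — matched flux constant non-zero (maintenance);
      expression is a declining ramp, uninformative for correlation.
    * ``correlated`` / ``anticorrelated`` — a·z + b + N(0, σ) on the
      unit-variance flux shape z, with a > 0 resp. a < 0 (sign-flip
      emulating misannotated genes).
    * ``unexpressed`` — flat noise at the control floor.
    * ``uncorrelated`` — flat noise at a gene-specific baseline.
    * ``control`` — added negative-control probes (``CTRL_*`` rows).
    """
    if flux_ts.flux_matrix.empty:
        raise ConfigError("flux time series is empty")
    rng = np.random.default_rng(spec.seed)
    times = flux_ts.times
    T = len(times)
    genes = sorted(matching)

    structural: dict[str, str] = {}
    varying: list[str] = []
    for g in genes:
        flux = flux_ts.flux_profile(matching[g])
        flux = flux[np.isfinite(flux)]
        if np.all(np.abs(flux) <= 1e-9):
            structural[g] = "zero_flux"
        elif np.std(flux) == 0:
            structural[g] = "constant_flux"
        else:
            varying.append(g)

    shuffled = list(rng.permutation(np.array(varying)))
    n_corr = round(spec.f_correlated * len(varying))
    n_anti = round(spec.f_anticorrelated * len(varying))
    n_unexpr = round(spec.f_unexpressed * len(varying))
    labels = dict(structural)
    for g in shuffled[:n_corr]:
        labels[g] = "correlated"
    for g in shuffled[n_corr:n_corr + n_anti]:
        labels[g] = "anticorrelated"
    for g in shuffled[n_corr + n_anti:n_corr + n_anti + n_unexpr]:
        labels[g] = "unexpressed"
    for g in shuffled[n_corr + n_anti + n_unexpr:]:
        labels[g] = "uncorrelated"

    floor = 4.5
    sigmoid_on = floor + 1.5 + 2.0 / (1.0 + np.exp(-(times - spec.switch_time) / 2.0))
    ramp_down = 8.0 - 2.0 * (times - times[0]) / (times[-1] - times[0])

    rows = np.empty((len(genes), T))
    slopes: dict[str, float] = {}
    for i, g in enumerate(genes):
        lab = labels[g]
        noise = rng.normal(0.0, spec.noise_sd, T)
        if lab in ("correlated", "anticorrelated"):
            flux = flux_ts.flux_profile(matching[g])
            z = (flux - np.nanmean(flux)) / np.nanstd(flux)
            a = rng.uniform(0.8, 1.5) * (1 if lab == "correlated" else -1)
            b = rng.uniform(6.0, 9.0)
            rows[i] = a * z + b + noise
            slopes[g] = a
        elif lab == "zero_flux":
            rows[i] = sigmoid_on + noise
        elif lab == "constant_flux":
            rows[i] = ramp_down + noise
        elif lab == "unexpressed":
            rows[i] = floor + noise
        else:  # uncorrelated: flat baseline
            rows[i] = rng.uniform(6.0, 9.0) + noise

    control_ids = [f"CTRL_{i:03d}" for i in range(1, spec.n_controls + 1)]
    control_rows = floor + rng.normal(0.0, spec.noise_sd, (len(control_ids), T))

    values = pd.DataFrame(
        np.vstack([rows, control_rows]) if control_ids else rows,
        index=genes + control_ids,
        columns=times,
    )
    expr = ExpressionMatrix(values=values, control_rows=set(control_ids))
    always_on = essential_reactions(spec)
    truth = pd.DataFrame(
        {
            "gene": genes + control_ids,
            "label": [labels[g] for g in genes] + ["control"] * len(control_ids),
            "slope": [slopes.get(g, np.nan) for g in genes]
            + [np.nan] * len(control_ids),
            "matched_reaction": [matching[g] for g in genes]
            + [""] * len(control_ids),
            "essential": [matching[g] in always_on for g in genes]
            + [False] * len(control_ids),
        }
    ).set_index("gene")
    return expr, truth


def make_chemostat_table(
    model: MetabolicModel,
    n: int,
    seed: int,
    exchange_id: Optional[str] = None,
) -> list[ChemostatCondition]:
    """A self-consistent chemostat panel on a toy model.

    *n* conditions with strictly increasing glucose-role uptake rates on one
    exchange (see :func:`default_exchange_map`); the observed dilution rate
    is filled with the model's own predicted μ, so prediction must match
    observation exactly when the panel is re-solved.
    """
    if n == 0:
        return []
    exchanges = default_exchange_map(model, exchange_id)
    rng = np.random.default_rng(seed)
    base = np.linspace(0.5, 1.0, n) * rng.uniform(5.0, 15.0)
    out = []
    for u in base:
        cond = ChemostatCondition(
            glucose_uptake=float(u),
            o2_uptake=0.0,
            co2_production=0.0,
            actinorhodin_production=0.0,
        )
        overrides = {exchanges.glucose: (-float(u), 0.0)}
        state = solve_fba(model, bound_overrides=overrides)
        cond.observed_dilution_rate = (
            state.objective_value if state.optimal else float("nan")
        )
        out.append(cond)
    return out


def default_exchange_map(
    model: MetabolicModel, exchange_id: Optional[str] = None
) -> ExchangeMap:
    """Pick the glucose-role exchange of a toy model: ``EX_glucose_e`` when
    present, else the lexicographically first uptake-capable exchange."""
    if exchange_id is None:
        ids = set(model.reaction_ids)
        if "EX_glucose_e" in ids:
            exchange_id = "EX_glucose_e"
        else:
            candidates = sorted(
                r.id for r in model.reactions
                if r.is_exchange and r.lower_bound < 0
            )
            if not candidates:
                raise ConfigError("model has no uptake-capable exchange reaction")
            exchange_id = candidates[0]
    return ExchangeMap(glucose=exchange_id)


@dataclass
class SyntheticBundle:
    """Everything one pipeline run consumes, generated from a single spec."""

    spec: SyntheticSpec
    model: MetabolicModel
    record: ToyRecord
    schedule: ConstraintSchedule
    flux_ts: FluxTimeSeries
    matching: dict[str, str]
    expression: ExpressionMatrix
    truth: pd.DataFrame


def make_bundle(
    spec: SyntheticSpec,
    objective_mode: str = "forced",
    parsimonious: bool = True,
) -> SyntheticBundle:
    """Generate the full study: model → schedule → dynamic FBA → matching →
    expression with truth labels.  Deterministic under ``spec.seed``."""
    model, record = make_toy_model(spec)
    schedule = make_schedule(spec)
    flux_ts = run_dynamic_fba(
        model, schedule, objective_mode=objective_mode, parsimonious=parsimonious
    )
    matching = match_genes(model, flux_ts)
    expr, truth = simulate_expression(flux_ts, matching, spec)
    return SyntheticBundle(
        spec=spec,
        model=model,
        record=record,
        schedule=schedule,
        flux_ts=flux_ts,
        matching=matching,
        expression=expr,
        truth=truth,
    )
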