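"""Independent oracles used by the test suite.

These deliberately avoid the package's LP code paths: the flux-balance
optimum is recomputed by brute-force vertex enumeration of the small LP, the
stoichiometric matrix by naive per-reaction assembly, and blocked reactions
by graph reachability from open exchanges.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.linalg import qr

from switchfba.model import MetabolicModel, Metabolite, Reaction


def assemble_S_bruteforce(model: MetabolicModel) -> np.ndarray:
    """Dense S from per-reaction maps, one entry at a time."""
    S = np.zeros((len(model.metabolites), len(model.reactions)))
    met_row = {m.id: i for i, m in enumerate(model.metabolites)}
    for j, rxn in enumerate(model.reactions):
        for met, coef in rxn.stoichiometry.items():
            S[met_row[met], j] = coef
    return S


def vertex_enumeration_optimum(
    S: np.ndarray,
    c: np.ndarray,
    lb: np.ndarray,
    ub: np.ndarray,
    feas_tol: float = 1e-7,
) -> float:
    """Max c·v s.t. S·v = 0, lb ≤ v ≤ ub, over all basic feasible solutions.

    Requires finite bounds (bounded polytope), so the optimum is attained at
    a vertex: n − rank(S) variables sit at a bound and the rest solve the
    equality system.  Exponential, fine for ≤ ~12 reactions.
    """
    S = np.asarray(S, dtype=float)
    m, n = S.shape
    assert np.all(np.isfinite(lb)) and np.all(np.isfinite(ub))
    if m == 0:
        return float(np.sum(np.where(c > 0, c * ub, c * lb)))
    # independent rows via column-pivoted QR of S^T
    _, R, piv = qr(S.T, pivoting=True)
    diag = np.abs(np.diag(R))
    r = int(np.sum(diag > 1e-10 * max(1.0, diag.max() if diag.size else 1.0)))
    Sr = S[sorted(piv[:r])]
    best = -np.inf
    k = n - r
    for nonbasic in itertools.combinations(range(n), k):
        basic = [j for j in range(n) if j not in nonbasic]
        A = Sr[:, basic]
        if r:
            if abs(np.linalg.det(A)) < 1e-12:
                continue
            lu = np.linalg.inv(A)
        for corner in itertools.product(*[(lb[j], ub[j]) for j in nonbasic]):
            v = np.zeros(n)
            v[list(nonbasic)] = corner
            if r:
                v[basic] = lu @ (-Sr[:, list(nonbasic)] @ np.array(corner))
            if (
                np.all(v >= lb - feas_tol)
                and np.all(v <= ub + feas_tol)
                and (m == 0 or np.max(np.abs(S @ v)) <= feas_tol)
            ):
                best = max(best, float(c @ v))
    assert best > -np.inf, "no feasible vertex found (should not happen: 0 ∈ box)"
    return best


def random_network(rng: np.random.Generator) -> MetabolicModel:
    """A random bounded network with ≤ 12 reactions, always feasible (0 ∈ box).

    Bounds are finite so the vertex oracle applies.
    """
    m = int(rng.integers(3, 6))
    n = int(rng.integers(6, 11))
    mets = [Metabolite(f"m{i}") for i in range(m)]
    rxns = []
    for j in range(n):
        stoich = {}
        n_entries = int(rng.integers(1, min(4, m) + 1))
        for i in rng.choice(m, size=n_entries, replace=False):
            coef = int(rng.choice([-2, -1, 1, 2]))
            stoich[f"m{i}"] = float(coef)
        lower = float(rng.choice([-10.0, -5.0, 0.0]))
        upper = float(rng.choice([5.0, 10.0]))
        rxns.append(Reaction(f"r{j:02d}", stoich, lower, upper))
    weights = rng.random(n) * (rng.random(n) < 0.5)
    if not np.any(weights):
        weights[int(rng.integers(n))] = 1.0
    objective = {f"r{j:02d}": float(w) for j, w in enumerate(weights) if w > 0}
    return MetabolicModel(metabolites=mets, reactions=rxns, objective=objective)


def reachable_reactions(model: MetabolicModel) -> set[str]:
    """Reactions that can possibly carry forward flux, by breadth-first
    propagation of producible metabolites from open uptake exchanges.

    Conservative oracle for blocked linear pathways (irreversible chains):
    a reaction with an unreachable substrate can never carry positive flux.
    """
    producible = set()
    for rxn in model.reactions:
        if rxn.is_exchange and rxn.lower_bound < 0:
            producible |= set(rxn.stoichiometry)
    changed = True
    active: set[str] = set()
    while changed:
        changed = False
        for rxn in model.reactions:
            if rxn.id in active or rxn.is_exchange:
                continue
            substrates = {mid for mid, coef in rxn.stoichiometry.items() if coef < 0}
            if rxn.upper_bound > 0 and substrates <= producible:
                active.add(rxn.id)
                new = {mid for mid, coef in rxn.stoichiometry.items() if coef > 0}
                if not new <= producible:
                    producible |= new
                    changed = True
                changed = changed or rxn.id in active
    return active
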