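import numpy as np
import pytest

from oracles import random_network, vertex_enumeration_optimum
from switchfba.errors import ConfigError, SolverError
from switchfba.fba import (
    ChemostatCondition,
    ExchangeMap,
    chemostat_panel,
    condition_overrides,
    mass_balance_residual,
    parsimonious_flux,
    read_conditions_tsv,
    solve_fba,
)
from switchfba.model import MetabolicModel, Metabolite, Reaction, stoichiometric_matrix
from switchfba.units import molecular_weight


class TestSolveFBA:
    def test_chain_analytic_optimum(self, chain_model):
        state = solve_fba(chain_model)
        assert state.optimal
        assert state.objective_value == pytest.approx(5.0, abs=1e-9)
        assert mass_balance_residual(chain_model, state) <= 1e-6

    def test_infeasible_bounds_reported(self, chain_model):
        # force biomass flux above what the uptake cap allows
        state = solve_fba(chain_model, bound_overrides={"BM": (6.0, 1000.0)})
        assert state.status == "infeasible"
        assert state.fluxes == {}

    def test_unbounded_names_a_direction(self):
        m = MetabolicModel(
            metabolites=[Metabolite("A")],
            reactions=[
                Reaction("IN", {"A": 1}, 0, float("inf")),
                Reaction("OUT", {"A": -1}, 0, float("inf")),
            ],
            objective={"OUT": 1},
        )
        state = solve_fba(m)
        assert state.status == "unbounded"
        assert state.unbounded_reaction == "OUT"

    def test_monotone_in_uptake_relaxation(self, chain_model):
        mus = [
            solve_fba(chain_model, bound_overrides={"EX_A": (-u, 0)}).objective_value
            for u in (1.0, 2.0, 5.0, 10.0, 20.0)
        ]
        assert all(b >= a - 1e-9 for a, b in zip(mus, mus[1:]))

    def test_objective_invariant_under_row_permutation(self, chain_model):
        ref = solve_fba(chain_model).objective_value
        rng = np.random.default_rng(0)
        for _ in range(5):
            perm = rng.permutation(len(chain_model.metabolites))
            shuffled = MetabolicModel(
                metabolites=[chain_model.metabolites[i] for i in perm],
                reactions=chain_model.reactions,
                objective=chain_model.objective,
            )
            assert solve_fba(shuffled).objective_value == pytest.approx(
                ref, rel=1e-9
            )

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_vertex_enumeration_oracle(self, seed):
        model = random_network(np.random.default_rng(seed))
        state = solve_fba(model)
        assert state.optimal
        S = stoichiometric_matrix(model, dense=True)
        c = np.array([model.objective.get(r.id, 0.0) for r in model.reactions])
        lb = np.array([r.lower_bound for r in model.reactions])
        ub = np.array([r.upper_bound for r in model.reactions])
        oracle = vertex_enumeration_optimum(S, c, lb, ub)
        assert state.objective_value == pytest.approx(oracle, abs=1e-8)

    def test_glpk_backend_cross_check(self, tmp_path, bundle):
        """An unrelated LP implementation must find the same optimum."""
        cobra = pytest.importorskip("cobra")
        from switchfba.sbml_io import write_sbml

        path = tmp_path / "toy.xml"
        write_sbml(bundle.model, path)
        cm = cobra.io.read_sbml_model(str(path))
        ours = solve_fba(bundle.model).objective_value
        theirs = cm.optimize().objective_value
        assert ours == pytest.approx(theirs, rel=1e-9)


class TestParsimonious:
    def test_unique_optimum_unchanged(self, chain_model):
        plain = solve_fba(chain_model)
        pars = parsimonious_flux(chain_model, optimum=plain.objective_value)
        assert pars.objective_value == pytest.approx(plain.objective_value)
        for rid in chain_model.reaction_ids:
            assert pars.fluxes[rid] == pytest.approx(plain.fluxes[rid], abs=1e-6)

    def test_internal_cycle_zeroed(self):
        m = MetabolicModel(
            metabolites=[Metabolite("A"), Metabolite("B")],
            reactions=[
                Reaction("EX_A", {"A": -1}, -10, 0, kind="exchange"),
                Reaction("R1", {"A": -1, "B": 1}, -1000, 1000),
                Reaction("R2", {"B": -1, "A": 1}, -1000, 1000),  # closes a 2-cycle
                Reaction("BM", {"B": -2}, 0, 1000, kind="biomass"),
            ],
        )
        pars = parsimonious_flux(m)
        # net A→B conversion is 10; any cycling would inflate |R1|+|R2|
        # above the minimal 10 without changing the optimum
        assert pars.fluxes["R1"] - pars.fluxes["R2"] == pytest.approx(10.0, abs=1e-6)
        assert abs(pars.fluxes["R1"]) + abs(pars.fluxes["R2"]) == pytest.approx(
            10.0, abs=1e-6
        )
        assert pars.objective_value == pytest.approx(5.0)

    def test_alternate_routes_min_total_flux(self):
        # two parallel A→B routes; route P2 spends 2 reactions, so the
        # brute-force minimum of Σ|v| puts all 10 units through P1:
        # Σ|v| = 10 (EX) + 10 (P1) + 5 (BM) = 25
        m = MetabolicModel(
            metabolites=[Metabolite("A"), Metabolite("B"), Metabolite("X")],
            reactions=[
                Reaction("EX_A", {"A": -1}, -10, 0, kind="exchange"),
                Reaction("P1", {"A": -1, "B": 1}, 0, 1000),
                Reaction("P2a", {"A": -1, "X": 1}, 0, 1000),
                Reaction("P2b", {"X": -1, "B": 1}, 0, 1000),
                Reaction("BM", {"B": -2}, 0, 1000, kind="biomass"),
            ],
        )
        pars = parsimonious_flux(m)
        total = sum(abs(v) for v in pars.fluxes.values())
        assert total == pytest.approx(25.0, abs=1e-6)
        assert pars.fluxes["P2a"] == pytest.approx(0.0, abs=1e-6)

    def test_overtight_optimum_raises(self, chain_model):
        with pytest.raises(SolverError, match="relax"):
            parsimonious_flux(chain_model, optimum=6.0)  # unattainable


ACT_MW = molecular_weight("C32H26O14")


class TestChemostatPanel:
    @pytest.fixture
    def chemostat_model(self):
        """Toy respiring model with glucose/O2 in, CO2/actinorhodin out."""
        return MetabolicModel(
            metabolites=[
                Metabolite("glc", compartment="e"),
                Metabolite("o2", compartment="e"),
                Metabolite("co2", compartment="e"),
                Metabolite("act", compartment="e", formula="C32H26O14"),
                Metabolite("x"),
            ],
            reactions=[
                Reaction("EX_glc", {"glc": -1}, -10, 0, kind="exchange"),
                Reaction("EX_o2", {"o2": -1}, -10, 0, kind="exchange"),
                Reaction("EX_co2", {"co2": -1}, 0, 1000, kind="exchange"),
                Reaction("EX_act", {"act": -1}, 0, 1000, kind="exchange"),
                Reaction("RESP", {"glc": -1, "o2": -1, "x": 1, "co2": 1}, 0, 1000),
                Reaction("ACTSYN", {"x": -1, "act": 1}, 0, 1000),
                Reaction("BM", {"x": -1}, 0, 1000, kind="biomass"),
            ],
        )

    EXCH = ExchangeMap(glucose="EX_glc", o2="EX_o2", co2="EX_co2",
                       actinorhodin="EX_act")

    def test_equality_mode_pins_productions(self, chemostat_model):
        cond = ChemostatCondition(2.0, 3.0, 2.0, 1000.0 * ACT_MW * 0.1)
        overrides = condition_overrides(chemostat_model, cond, self.EXCH)
        assert overrides["EX_glc"] == (-2.0, 0.0)
        assert overrides["EX_co2"] == (2.0, 2.0)
        lo, hi = overrides["EX_act"]
        assert lo == hi == pytest.approx(0.1)

    def test_panel_analytic(self, chemostat_model):
        # glc limited: RESP flux = 2 = co2; biomass = x − act = 2 − 0.1
        cond = ChemostatCondition(2.0, 3.0, 2.0, 1000.0 * ACT_MW * 0.1,
                                  observed_dilution_rate=1.9)
        [(_, mu)] = chemostat_panel(chemostat_model, [cond], self.EXCH)
        assert mu == pytest.approx(1.9, abs=1e-9)

    def test_empty_condition_list(self, chemostat_model):
        assert chemostat_panel(chemostat_model, [], self.EXCH) == []

    def test_single_condition_matches_direct_solve(self, chemostat_model):
        cond = ChemostatCondition(1.5, 2.0, 1.5, 0.0)
        [(_, mu)] = chemostat_panel(chemostat_model, [cond], self.EXCH)
        overrides = condition_overrides(chemostat_model, cond, self.EXCH)
        assert mu == solve_fba(chemostat_model, bound_overrides=overrides).objective_value

    def test_missing_exchange_named(self, chemostat_model):
        cond = ChemostatCondition(1.0, 1.0, 1.0, 0.0)
        with pytest.raises(ConfigError, match="oxygen"):
            condition_overrides(
                chemostat_model, cond,
                ExchangeMap(glucose="EX_glc", o2="EX_nope"),
            )

    def test_negative_printed_rate_rejected(self):
        with pytest.raises(ConfigError, match="non-negative"):
            ChemostatCondition(-1.0, 1.0, 1.0, 0.0)

    def test_conditions_tsv_roundtrip(self, tmp_path):
        path = tmp_path / "cond.tsv"
        path.write_text(
            "Glucose (mmol/g.h)\tO2 (mmol/g.h)\tCO2 (mmol/g.h)\t"
            "Actinorhodin (ug/g.h)\tObserved dilution rate D(/h)\n"
            "0.5\t1.8\t1.9\t2\t0.035\n"
            "2.1\t7.2\t7\t5\t0.128\n"
        )
        conds = read_conditions_tsv(path)
        assert len(conds) == 2
        assert conds[0].glucose_uptake == 0.5
        assert conds[1].observed_dilution_rate == 0.128
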