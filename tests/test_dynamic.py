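import numpy as np
import pandas as pd
import pytest

from switchfba.dynamic import (
    ConstraintSchedule,
    build_schedule,
    default_time_grid,
    objective_at,
    run_dynamic_fba,
)
from switchfba.errors import ConfigError, DataError
from switchfba.fba import mass_balance_residual, parsimonious_flux, FluxState
from switchfba.model import stoichiometric_matrix
from switchfba.synth import ACT_EXCHANGE, SyntheticSpec, make_schedule, make_toy_model
from switchfba.units import ug_per_h_to_mmol


def simple_table(times, rates, col="glc"):
    return pd.DataFrame({"time_h": times, col: rates})


class TestBuildSchedule:
    def test_constant_rates_give_constant_bounds(self):
        sched = build_schedule(
            simple_table([0, 5, 10], [2.0, 2.0, 2.0]), {"glc": "EX_glc"},
            switch_time=8,
        )
        np.testing.assert_allclose(sched.exchange_bounds["EX_glc"][:, 0], -2.0)
        np.testing.assert_allclose(sched.exchange_bounds["EX_glc"][:, 1], 0.0)

    def test_depleted_nutrient_bound_is_hard_zero(self):
        t = [30, 32, 34, 36, 40]
        sched = build_schedule(
            simple_table(t, [2.0, 1.0, 0.0, 0.0, 0.0], col="pho"),
            {"pho": "EX_pho"}, switch_time=34,
        )
        bounds = dict(zip(t, sched.exchange_bounds["EX_pho"][:, 0]))
        assert bounds[34] == bounds[36] == bounds[40] == 0.0
        assert bounds[30] == -2.0

    def test_linear_interpolation_midpoint(self):
        sched = build_schedule(
            simple_table([0.0, 10.0], [2.0, 0.0]), {"glc": "EX_glc"},
            times=np.array([0.0, 5.0, 10.0]), switch_time=8,
        )
        assert sched.bounds_at(5.0) == {"EX_glc": (-1.0, 0.0)}

    def test_duplicate_times_rejected(self):
        with pytest.raises(DataError, match="duplicate"):
            build_schedule(simple_table([1, 1, 2], [1, 1, 1]), {"glc": "EX_glc"})

    def test_negative_rate_names_cell(self):
        with pytest.raises(DataError, match="glc.*row 1"):
            build_schedule(simple_table([1, 2, 3], [1.0, -0.5, 1.0]),
                           {"glc": "EX_glc"})

    def test_no_extrapolation_beyond_window(self):
        with pytest.raises(ConfigError, match="extrapolat"):
            build_schedule(simple_table([10, 20], [1, 1]), {"glc": "EX_glc"},
                           times=np.array([5.0, 15.0]))


class TestSchedule:
    def test_times_strictly_increasing_required(self):
        with pytest.raises(ConfigError, match="increasing"):
            ConstraintSchedule(times=np.array([1.0, 1.0, 2.0]))

    def test_antibiotic_rates_zero_before_switch_enforced(self):
        with pytest.raises(ConfigError, match="switch"):
            ConstraintSchedule(
                times=np.array([30.0, 40.0]),
                antibiotic_rates={"EX_act": np.array([1.0, 2.0])},
                switch_time=34.0,
            )

    def test_default_grid_matches_sampling_design(self):
        grid = default_time_grid()
        assert grid[0] == 20.0 and grid[-1] == 60.0
        assert np.all(np.diff(grid[:25]) == 1.0)
        assert np.all(np.diff(grid[25:]) == 2.0)


@pytest.fixture(scope="module")
def setup():
    spec = SyntheticSpec(seed=0)
    model, _ = make_toy_model(spec)
    return model, make_schedule(spec), spec


class TestObjectiveAt:

    def test_pure_biomass_before_switch(self, setup):
        model, sched, _ = setup
        obj = objective_at(model, sched, 20.0)
        assert obj.weights == model.objective
        assert not obj.switched

    def test_zero_rates_reduce_to_biomass_after_switch(self, setup):
        model, _, spec = setup
        quiet = SyntheticSpec(seed=0, antibiotic_slope=0.0)
        sched = make_schedule(quiet)
        obj = objective_at(model, sched, 40.0)
        assert obj.switched
        assert obj.weights == model.objective

    def test_weight_equals_unit_conversion(self, setup):
        model, sched, spec = setup
        t = 40.0
        mw = 634.54
        obj = objective_at(model, sched, t, antibiotic_mw={ACT_EXCHANGE: mw},
                           weight_scale=2.0)
        rate = spec.antibiotic_slope * (t - spec.switch_time)
        expected = 2.0 * ug_per_h_to_mmol(rate, mw)
        assert obj.weights[ACT_EXCHANGE] == pytest.approx(expected)

    def test_out_of_range_time_rejected(self, setup):
        model, sched, _ = setup
        with pytest.raises(ConfigError, match="range"):
            objective_at(model, sched, 5.0)


class TestRunDynamicFBA:
    def test_constant_schedule_reproduces_static_solution_bitwise(self):
        spec = SyntheticSpec(seed=0, depletion_times={}, antibiotic_slope=0.0,
                             n_times=5)
        model, _ = make_toy_model(spec)
        sched = make_schedule(spec)
        ts = run_dynamic_fba(model, sched)
        static = parsimonious_flux(
            model, bound_overrides=sched.bounds_at(sched.times[0])
        )
        ref = np.array([static.fluxes[r] for r in model.reaction_ids])
        for t in sched.times:
            np.testing.assert_array_equal(
                ts.flux_matrix[t].to_numpy(), ref
            )

    def test_every_column_mass_balanced(self, bundle):
        S = stoichiometric_matrix(bundle.model, dense=True)
        for t in bundle.flux_ts.times:
            v = bundle.flux_ts.flux_matrix[t].to_numpy()
            assert np.max(np.abs(S @ v)) <= 1e-6

    def test_growth_tracks_depletion(self):
        spec = SyntheticSpec(seed=0, antibiotic_slope=0.0)
        model, _ = make_toy_model(spec)
        ts = run_dynamic_fba(model, make_schedule(spec))
        mu = ts.growth_curve.to_numpy()
        assert np.all(np.diff(mu) <= 1e-9)

    def test_all_depleted_end_state_zero_growth(self):
        spec = SyntheticSpec(
            seed=0, maintenance_flux=0.0, antibiotic_slope=0.0,
            depletion_times={"phosphate": 34.0, "glucose": 50.0, "glutamate": 55.0},
        )
        model, _ = make_toy_model(spec)
        ts = run_dynamic_fba(model, make_schedule(spec))
        assert ts.statuses[-1] == "optimal"
        assert ts.growth_curve.iloc[-1] == pytest.approx(0.0, abs=1e-9)

    def test_columns_equal_oneshot_resolves(self, bundle):
        """Each column must equal an independently constructed single LP."""
        sched = bundle.schedule
        for t in bundle.flux_ts.times[::7]:
            overrides = dict(sched.bounds_at(t))
            rate = sched.antibiotic_rates_at(t)[ACT_EXCHANGE]
            r_mmol = ug_per_h_to_mmol(rate, 634.54)
            overrides[ACT_EXCHANGE] = (r_mmol, r_mmol)
            one = parsimonious_flux(bundle.model, bound_overrides=overrides)
            got = bundle.flux_ts.flux_matrix[t].to_numpy()
            want = np.array([one.fluxes[r] for r in bundle.model.reaction_ids])
            np.testing.assert_allclose(got, want, atol=1e-6)

    def test_switch_continuity_with_zero_antibiotics(self):
        spec = SyntheticSpec(seed=0, antibiotic_slope=0.0,
                             depletion_times={"glutamate": 56.0})
        model, _ = make_toy_model(spec)
        sched = make_schedule(spec)
        ts = run_dynamic_fba(model, sched, objective_mode="weighted")
        mu = ts.growth_curve
        # grid is hourly around the 34 h switch; μ(t) continuous there
        before, at = mu.loc[33.0], mu.loc[34.0]
        after = mu.loc[35.0]
        assert abs(at - before) == pytest.approx(abs(after - at), abs=1e-6)

    def test_missing_exchange_fails_before_solving(self, chain_model):
        sched = ConstraintSchedule(
            times=np.array([0.0, 1.0]),
            exchange_bounds={"EX_ghost": np.array([[-1.0, 0.0], [-1.0, 0.0]])},
            switch_time=0.5,
        )
        with pytest.raises(ConfigError, match="EX_ghost"):
            run_dynamic_fba(chain_model, sched)

    def test_infeasible_timepoints_recorded_not_dropped(self, chain_model):
        sched = ConstraintSchedule(
            times=np.array([0.0, 1.0]),
            exchange_bounds={"EX_A": np.array([[-10.0, 0.0], [-10.0, 0.0]])},
            switch_time=0.5,
        )
        with pytest.warns(UserWarning, match="infeasible"):
            ts = run_dynamic_fba(chain_model, sched,
                                 extra_overrides={"BM": (6.0, 1000.0)})
        assert ts.statuses == ["infeasible", "infeasible"]
        assert ts.flux_matrix.isna().all().all()
        assert len(ts.times) == 2
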