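"""Time-resolved FBA across a fermentation.

The fermentation is modeled as a sequence of independent steady states: at
each sampled time point the measured nutrient uptake rates become exchange
bounds (the input function) and the objective is re-solved.  Before the
metabolic switch the objective is pure biomass; from the switch time on
(phosphate depletion, default 34 h) the objective is dynamically varied by
adding antibiotic-production terms whose weights track the measured
antibiotic production rates.  No biomass ODE is integrated — each column of
the result is an ordinary FBA solution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError
from .fba import FluxState, parsimonious_flux, solve_fba
from .model import MetabolicModel
from .units import ug_per_h_to_mmol

DEFAULT_SWITCH_TIME = 34.0


def default_time_grid() -> np.ndarray:
    """The fermentation sampling grid: hourly 20-44 h, two-hourly 46-60 h."""
    return np.concatenate([np.arange(20.0, 45.0, 1.0), np.arange(46.0, 61.0, 2.0)])


@dataclass
class ConstraintSchedule:
    """Time-varying exchange bounds plus antibiotic production rates.

    ``exchange_bounds`` maps exchange reaction id → array of shape (T, 2)
    holding (lower, upper) in mmol/gDW/h at each time.  ``antibiotic_rates``
    maps antibiotic exchange reaction id → length-T production rates in
    μg/gDW/h (zero before ``switch_time``).
    """

    times: np.ndarray
    exchange_bounds: dict[str, np.ndarray] = field(default_factory=dict)
    antibiotic_rates: dict[str, np.ndarray] = field(default_factory=dict)
    switch_time: float = DEFAULT_SWITCH_TIME

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        if self.times.ndim != 1 or len(self.times) == 0:
            raise ConfigError("schedule needs a non-empty 1-d time grid")
        if np.any(np.diff(self.times) <= 0):
            raise ConfigError("schedule times must be strictly increasing")
        for rid, arr in self.exchange_bounds.items():
            arr = np.asarray(arr, dtype=float)
            if arr.shape != (len(self.times), 2):
                raise ConfigError(
                    f"bounds for {rid} must have shape (n_times, 2), got {arr.shape}"
                )
            if np.any(arr[:, 0] > arr[:, 1]):
                raise ConfigError(f"bounds for {rid}: lower > upper at some time")
            self.exchange_bounds[rid] = arr
        pre = self.times < self.switch_time
        for rid, rates in self.antibiotic_rates.items():
            rates = np.asarray(rates, dtype=float)
            if rates.shape != self.times.shape:
                raise ConfigError(f"antibiotic rates for {rid} must match the grid")
            if np.any(rates < 0):
                raise ConfigError(f"antibiotic rates for {rid} must be non-negative")
            if np.any(rates[pre] != 0):
                raise ConfigError(
                    f"antibiotic rates for {rid} must be zero before the switch"
                )
            self.antibiotic_rates[rid] = rates

    def _interp(self, values: np.ndarray, t: float) -> float:
        if t < self.times[0] or t > self.times[-1]:
            raise ConfigError(
                f"time {t} outside the schedule range "
                f"[{self.times[0]}, {self.times[-1]}] (no extrapolation)"
            )
        return float(np.interp(t, self.times, values))

    def bounds_at(self, t: float) -> dict[str, tuple[float, float]]:
        """Linearly interpolated (lower, upper) per scheduled exchange."""
        return {
            rid: (self._interp(arr[:, 0], t), self._interp(arr[:, 1], t))
            for rid, arr in self.exchange_bounds.items()
        }

    def antibiotic_rates_at(self, t: float) -> dict[str, float]:
        return {
            rid: self._interp(rates, t)
            for rid, rates in self.antibiotic_rates.items()
        }


def build_schedule(
    measurements: pd.DataFrame,
    uptake_columns: dict[str, str],
    antibiotic_columns: Optional[dict[str, str]] = None,
    switch_time: float = DEFAULT_SWITCH_TIME,
    time_column: str = "time_h",
    times: Optional[np.ndarray] = None,
) -> ConstraintSchedule:
    """Assemble a :class:`ConstraintSchedule` from a measured rate table.

    Parameters
    ----------
    measurements : DataFrame
        One row per sample; a time column plus one non-negative rate column
        per constrained exchange.  Uptake rates are given as printed
        (positive); they become uptake caps (lower bound −rate, upper 0),
        and a measured rate of exactly 0 — a depleted nutrient — becomes a
        hard zero uptake bound.
    uptake_columns / antibiotic_columns : dict
        Column name → exchange reaction id.
    times : array, optional
        Model time grid; defaults to the measurement times.  Rates at grid
        times not measured are filled by linear interpolation; the grid must
        lie inside the measured window (no extrapolation).
    """
    if time_column not in measurements.columns:
        raise DataError(f"measurement table lacks time column {time_column!r}")
    t_meas = measurements[time_column].to_numpy(dtype=float)
    if len(np.unique(t_meas)) != len(t_meas):
        dupes = sorted({t for t in t_meas if list(t_meas).count(t) > 1})
        raise DataError(f"duplicate time stamps in measurement table: {dupes}")
    order = np.argsort(t_meas)
    t_meas = t_meas[order]

    antibiotic_columns = antibiotic_columns or {}
    for col in list(uptake_columns) + list(antibiotic_columns):
        if col not in measurements.columns:
            raise DataError(f"measurement table lacks column {col!r}")
        vals = measurements[col].to_numpy(dtype=float)
        bad = np.where(vals < 0)[0]
        if bad.size:
            raise DataError(
                f"negative measured rate in column {col!r}, row {bad[0]} "
                f"(value {vals[bad[0]]})"
            )

    grid = np.asarray(times, dtype=float) if times is not None else t_meas
    if grid[0] < t_meas[0] or grid[-1] > t_meas[-1]:
        raise ConfigError(
            "model time grid extends beyond the measured window; "
            "measured rates are not extrapolated"
        )

    exchange_bounds = {}
    for col, rid in uptake_columns.items():
        rates = measurements[col].to_numpy(dtype=float)[order]
        on_grid = np.interp(grid, t_meas, rates)
        exchange_bounds[rid] = np.column_stack([-on_grid, np.zeros_like(on_grid)])
    antibiotic_rates = {}
    for col, rid in antibiotic_columns.items():
        rates = measurements[col].to_numpy(dtype=float)[order]
        antibiotic_rates[rid] = np.interp(grid, t_meas, rates)
    return ConstraintSchedule(
        times=grid,
        exchange_bounds=exchange_bounds,
        antibiotic_rates=antibiotic_rates,
        switch_time=switch_time,
    )


@dataclass
class ObjectiveSpec:
    """The objective at one time point: biomass plus antibiotic weights."""

    weights: dict[str, float]
    switched: bool

    def __post_init__(self):
        if any(w < 0 for w in self.weights.values()):
            raise ConfigError("objective weights must be non-negative")


def objective_at(
    model: MetabolicModel,
    schedule: ConstraintSchedule,
    t: float,
    antibiotic_mw: Optional[dict[str, float]] = None,
    weight_scale: float = 1.0,
) -> ObjectiveSpec:
    """The dynamically varying objective at time *t*.

    Before the switch time this is the model's pure biomass objective.  From
    the switch on, each antibiotic exchange gains a weight β_k(t)
    proportional to its measured production rate at *t*, converted from
    μg/gDW/h to mmol/gDW/h via its molecular weight and scaled by
    ``weight_scale`` (the proportionality constant between observed
    production and objective weight; dimensionless, default 1).
    """
    if t < schedule.times[0] or t > schedule.times[-1]:
        raise ConfigError(
            f"time {t} outside schedule range [{schedule.times[0]}, {schedule.times[-1]}]"
        )
    weights = dict(model.objective)
    switched = t >= schedule.switch_time
    if switched:
        antibiotic_mw = antibiotic_mw or {}
        for rid, rate in schedule.antibiotic_rates_at(t).items():
            if rate == 0:
                continue
            mw = antibiotic_mw.get(rid)
            if mw is None:
                from .fba import _actinorhodin_mw_from_model

                mw = _actinorhodin_mw_from_model(model, rid)
            weights[rid] = weights.get(rid, 0.0) + weight_scale * ug_per_h_to_mmol(
                rate, mw
            )
    return ObjectiveSpec(weights=weights, switched=switched)


@dataclass
class FluxTimeSeries:
    """Per-timepoint optimal fluxes across the fermentation.

    ``flux_matrix`` is a reactions × times DataFrame (columns = hours);
    ``growth_curve`` is the biomass flux μ(t) in 1/h.  Infeasible time points
    carry NaN columns and are listed in ``statuses`` — never silently
    dropped.  ``resolution_method`` records whether columns are plain FBA
    solutions or parsimonious resolutions.
    """

    times: np.ndarray
    flux_matrix: pd.DataFrame
    growth_curve: pd.Series
    statuses: list[str]
    resolution_method: str = "parsimonious"
    objective_mode: str = "weighted"

    def flux_profile(self, reaction_id: str) -> np.ndarray:
        return self.flux_matrix.loc[reaction_id].to_numpy(dtype=float)


def run_dynamic_fba(
    model: MetabolicModel,
    schedule: ConstraintSchedule,
    objective_mode: str = "weighted",
    parsimonious: bool = True,
    antibiotic_mw: Optional[dict[str, float]] = None,
    weight_scale: float = 1.0,
    extra_overrides: Optional[dict[str, tuple[float, float]]] = None,
) -> FluxTimeSeries:
    """Solve one FBA per scheduled time point and assemble the flux matrix.

    ``objective_mode``:

    * ``"weighted"`` — antibiotic production enters the objective with
      weights β_k(t) from :func:`objective_at`.
    * ``"forced"`` — the objective stays pure biomass and each antibiotic
      exchange flux is instead pinned to its measured (molar-converted)
      production rate.

    Each solve is optionally post-processed with the parsimonious secondary
    objective (default), giving a unique, reproducible flux vector.
    """
    if objective_mode not in ("weighted", "forced"):
        raise ConfigError(f"unknown objective_mode {objective_mode!r}")
    rxn_ids = set(model.reaction_ids)
    missing = sorted(
        (set(schedule.exchange_bounds) | set(schedule.antibiotic_rates)) - rxn_ids
    )
    if missing:
        raise ConfigError(
            "schedule references exchange reactions absent from the model: "
            + ", ".join(missing)
        )

    biomass = [rid for rid, w in model.objective.items() if w > 0]
    columns: list[np.ndarray] = []
    mus: list[float] = []
    statuses: list[str] = []
    n = len(model.reactions)
    for t in schedule.times:
        overrides = dict(schedule.bounds_at(t))
        if extra_overrides:
            overrides.update(extra_overrides)
        if objective_mode == "forced":
            objective = dict(model.objective)
            antibiotic_mw = antibiotic_mw or {}
            for rid, rate in schedule.antibiotic_rates_at(t).items():
                mw = antibiotic_mw.get(rid)
                if mw is None:
                    from .fba import _actinorhodin_mw_from_model

                    mw = _actinorhodin_mw_from_model(model, rid)
                r_mmol = ug_per_h_to_mmol(rate, mw)
                overrides[rid] = (r_mmol, r_mmol)
        else:
            objective = objective_at(
                model, schedule, t, antibiotic_mw, weight_scale
            ).weights
        state = solve_fba(model, objective, overrides)
        if parsimonious and state.optimal:
            state = parsimonious_flux(
                model, objective, state.objective_value, overrides
            )
        statuses.append(state.status)
        if state.optimal:
            columns.append(np.array([state.fluxes[r.id] for r in model.reactions]))
            mus.append(sum(state.fluxes[rid] for rid in biomass))
        else:
            warnings.warn(f"time point {t} h: LP {state.status}", stacklevel=2)
            columns.append(np.full(n, np.nan))
            mus.append(np.nan)

    flux_matrix = pd.DataFrame(
        np.column_stack(columns), index=model.reaction_ids, columns=schedule.times
    )
    return FluxTimeSeries(
        times=schedule.times,
        flux_matrix=flux_matrix,
        growth_curve=pd.Series(mus, index=schedule.times, name="mu"),
        statuses=statuses,
        resolution_method="parsimonious" if parsimonious else "fba",
        objective_mode=objective_mode,
    )
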