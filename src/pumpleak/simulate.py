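"""Time integration of cell ion contents, volume and potential.

The three ion contents are advanced with a fixed-step explicit Euler scheme
(default step 0.01 min); at every internal step the membrane potential is
re-solved from the zero-charge-flux constraint and the volume from osmotic
balance, so each state on the trajectory satisfies both constraints.  The
pump coefficient decays linearly, beta(t) = max(0, beta0 - kb*t), and a
piecewise schedule can replace any membrane parameter at stated times
(stepwise, applied at the event time and not before).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .constraints import (PotentialSolveError, check_constraints,
                          initial_state, osmotic_volume, solve_potential)
from .model import (RT_F_MV, CellState, ExternalMedium, FluxTable,
                    MembraneParams, ModelError, build_flux_table,
                    compute_osor, cotransport_fluxes,
                    electrochemical_potentials, ghk_anion_flux,
                    ghk_cation_flux)

_TEPS = 1e-9  # time comparison slack, min


class StepSizeError(ModelError):
    """A concentration went non-positive; a smaller dt is required."""


def beta_at(beta0: float, kb: float, t: float) -> float:
    """Linearly decaying pump rate coefficient, clamped at zero.

    beta(t) = max(0, beta0 - kb*t); kb is the decline of beta per minute.
    """
    if beta0 < 0 or kb < 0 or t < 0:
        raise ModelError("beta0, kb and t must be >= 0")
    return max(0.0, beta0 - kb * t)


def _solve_u_or_nan(state: CellState, params: MembraneParams,
                    medium: ExternalMedium, beta: float) -> float:
    """Membrane potential for the step, or NaN for a chargeless membrane.

    With no channel permeability the charge-flux equation is independent of
    u; that is admissible only when the pump carries no net charge either
    (beta = 0, or gamma = 1, or [Na]i = 0), in which case the potential is
    indeterminate but irrelevant to the dynamics.
    """
    if params.pna > 0 or params.pk > 0 or params.pcl > 0:
        return solve_potential(state, params, medium, beta=beta,
                               guess=state.u if math.isfinite(state.u) else None)
    if beta * state.na * abs(1.0 - 1.0 / params.gamma) > 0:
        raise PotentialSolveError(
            "pump carries net charge but no channel can return it; "
            "the charge-flux equation has no solution")
    return math.nan


@dataclass
class ParamSchedule:
    """Ordered stepwise parameter overrides.

    ``events`` is a list of ``(time_min, {field: value})``; at each event
    time the named :class:`MembraneParams` fields are replaced from that time
    onward.
    """

    events: list[tuple[float, dict[str, float]]] = field(default_factory=list)

    def __post_init__(self) -> None:
        times = [t for t, _ in self.events]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ModelError("schedule times must be strictly increasing")
        for _, overrides in self.events:
            for name in overrides:
                if name not in MembraneParams.FIELDS:
                    raise ModelError(f"unknown parameter {name!r} in schedule")

    def __len__(self) -> int:
        return len(self.events)


@dataclass
class TimeCourse:
    """Sampled trajectory of the state variables.

    ``frame`` has one row per sample: t, U, na, k, cl, V (= V/A, ml mmol^-1),
    mun, muk, mucl, prna, prk, prcl (backward-difference concentration
    derivatives across the last internal step, mM min^-1; zero on the first
    row).  ``flux_tables`` holds one :class:`FluxTable` per row when flux
    recording is enabled, else only the final table.
    """

    frame: pd.DataFrame
    flux_tables: list[FluxTable | None]
    final_state: CellState
    final_params: MembraneParams

    @property
    def final_flux_table(self) -> FluxTable:
        ft = self.flux_tables[-1]
        assert ft is not None
        return ft

    def final_row(self) -> pd.Series:
        return self.frame.iloc[-1]

    def osor(self) -> float:
        """OSOR at the last sampled time point."""
        return compute_osor(self.final_flux_table)


@dataclass
class Scenario:
    """A complete, runnable model configuration."""

    medium: ExternalMedium
    na: float
    k: float
    cl: float
    params: MembraneParams
    schedule: ParamSchedule = field(default_factory=ParamSchedule)
    t_end: float = 240.0
    dt: float = 0.01
    hp: int = 100
    name: str = ""

    def with_params(self, **overrides: float) -> "Scenario":
        """Copy of the scenario with some membrane parameters replaced."""
        return replace(self, params=replace(self.params, **overrides))

    def run(self, **kwargs) -> TimeCourse:
        return simulate(self, **kwargs)


def _content_rates(na: float, k: float, cl: float, u: float,
                   params: MembraneParams, medium: ExternalMedium,
                   beta: float) -> tuple[float, float, float]:
    """Per-ml flux sums for the three content rate equations.

    dNa_i/dt = V*(J_chan,Na - beta*na + J_NC + J_NKCC)
    dK_i/dt  = V*(J_chan,K + beta*na/gamma + J_KC + J_NKCC)
    dCl_i/dt = V*(J_chan,Cl + J_NC + J_KC + 2*J_NKCC)
    """
    ct = cotransport_fluxes(params, na, k, cl, medium)
    fna = (ghk_cation_flux(params.pna, u, na, medium.na0)
           - beta * na + ct.jnc + ct.jnkcc)
    fk = (ghk_cation_flux(params.pk, u, k, medium.k0)
          + beta * na / params.gamma + ct.jkc + ct.jnkcc)
    fcl = (ghk_anion_flux(params.pcl, u, cl, medium.cl0)
           + ct.jnc + ct.jkc + 2.0 * ct.jnkcc)
    return fna, fk, fcl


def step(state: CellState, params: MembraneParams, medium: ExternalMedium,
         dt: float) -> CellState:
    """Advance the state by one explicit Euler step of length dt (min).

    Solves u at the current state, applies the content rate equations, then
    re-imposes osmotic balance on the volume and recomputes concentrations.
    """
    if dt <= 0:
        raise ModelError("dt must be > 0")
    beta = params.beta_at(state.t)
    u = _solve_u_or_nan(state, params, medium, beta)
    fna, fk, fcl = _content_rates(state.na, state.k, state.cl, u,
                                  params, medium, beta)
    na_c, k_c, cl_c = state.contents()
    scale = state.v * dt / 1000.0  # ml * min -> mmol per (umol/min/ml)
    na_c += fna * scale
    k_c += fk * scale
    cl_c += fcl * scale
    v = osmotic_volume(na_c, k_c, cl_c, state.a, medium)
    na, k, cl = (1000.0 * na_c / v, 1000.0 * k_c / v, 1000.0 * cl_c / v)
    if na <= 0 or k <= 0 or cl <= 0:
        raise StepSizeError(
            f"concentration went non-positive at t={state.t + dt:.4g} min; "
            "reduce dt")
    return CellState(t=state.t + dt, na=na, k=k, cl=cl, v=v,
                     z=state.z, a=state.a, u=u)


def _sample_row(state: CellState, params: MembraneParams,
                medium: ExternalMedium, prev: CellState | None,
                dt_last: float, record_fluxes: bool
                ) -> tuple[dict, FluxTable | None]:
    beta = params.beta_at(state.t)
    u = _solve_u_or_nan(state, params, medium, beta)
    st = replace(state, u=u)
    mu = electrochemical_potentials(st, medium)
    if prev is None or dt_last <= 0:
        prna = prk = prcl = 0.0
    else:
        prna = (st.na - prev.na) / dt_last
        prk = (st.k - prev.k) / dt_last
        prcl = (st.cl - prev.cl) / dt_last
    row = {"t": st.t, "U": st.U, "na": st.na, "k": st.k, "cl": st.cl,
           "V": st.v, "mun": mu.mun, "muk": mu.muk, "mucl": mu.mucl,
           "prna": prna, "prk": prk, "prcl": prcl, "beta": beta}
    ft = build_flux_table(st, params, medium, beta=beta) if record_fluxes else None
    return row, ft


def simulate(scenario: Scenario, *, t_end: float | None = None,
             dt: float | None = None, hp: int | None = None,
             record_fluxes: bool = True,
             check_every_sample: bool = True) -> TimeCourse:
    """Run a scenario and return the sampled time course.

    Samples are taken at t = 0, every ``hp``-th internal step, at every
    scheduled event time, and at ``t_end``.  Internal steps are cut short to
    land exactly on event times and on ``t_end``.
    """
    t_end = scenario.t_end if t_end is None else t_end
    dt = scenario.dt if dt is None else dt
    hp = scenario.hp if hp is None else hp
    if t_end < 0:
        raise ModelError("t_end must be >= 0")
    if hp < 1:
        raise ModelError("hp must be >= 1")

    medium = scenario.medium
    params = scenario.params.copy()
    events = list(scenario.schedule.events)
    state = initial_state(scenario.na, scenario.k, scenario.cl, medium)

    # events at (or before) t = 0 apply immediately
    while events and events[0][0] <= _TEPS:
        params = replace(params, **events[0][1])
        events.pop(0)

    rows: list[dict] = []
    tables: list[FluxTable | None] = []

    def emit(prev: CellState | None, dt_last: float, want_fluxes: bool) -> None:
        nonlocal state
        row, ft = _sample_row(state, params, medium, prev, dt_last, want_fluxes)
        state = replace(state, u=row["U"] / RT_F_MV)
        if check_every_sample:
            check_constraints(state, medium)
        rows.append(row)
        tables.append(ft)

    emit(None, 0.0, record_fluxes or t_end <= _TEPS)

    steps_since_sample = 0
    prev_state = state
    dt_last = 0.0
    while state.t < t_end - _TEPS:
        next_event = events[0][0] if events else math.inf
        dt_i = min(dt, t_end - state.t, next_event - state.t)
        prev_state = state
        state = step(state, params, medium, dt_i)
        dt_last = dt_i
        steps_since_sample += 1
        at_event = events and state.t >= events[0][0] - _TEPS
        at_end = state.t >= t_end - _TEPS
        if at_event or at_end or steps_since_sample >= hp:
            emit(prev_state, dt_last, record_fluxes or at_end)
            steps_since_sample = 0
        if at_event:
            params = replace(params, **events[0][1])
            events.pop(0)

    frame = pd.DataFrame(rows)
    return TimeCourse(frame=frame, flux_tables=tables,
                      final_state=state, final_params=params)


def detect_balance(timecourse: TimeCourse,
                   tol: float = 1e-3) -> tuple[bool, float | None]:
    """First sampled time where all concentration derivatives are below tol.

    The t = 0 row carries zero backward differences by convention and is
    skipped unless it is the only row.  Returns (balanced, time) with time
    ``None`` when the trajectory never settles.
    """
    frame = timecourse.frame
    if frame.empty:
        raise ModelError("empty time course")
    start = 0 if len(frame) == 1 else 1
    sub = frame.iloc[start:]
    mask = (sub[["prna", "prk", "prcl"]].abs().max(axis=1) < tol)
    if mask.any():
        return True, float(sub.loc[mask.idxmax(), "t"])
    return False, None
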