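"""Parameter identification against observed ion time courses.

The workflow mirrors how pump-leak transport coefficients are identified in
practice: candidate parameter sets are simulated, compared with the observed
(t, [Na]i, [K]i, [Cl]i) table by a sum-of-squares objective, and candidates
whose predicted OSOR (the pump's share of K+ influx, a directly measurable
ratio) falls below a user-set plausibility floor are rejected outright.  The
objective surface can be poorly conditioned, so the optimizer is
derivative-free (Nelder-Mead simplex seeded from the scenario's own values).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .model import ModelError, OSORUndefinedError, compute_osor
from .simulate import ParamSchedule, Scenario, simulate

_FREE_NAME = re.compile(r"^(?P<param>[a-z0-9]+)(?:@(?P<time>[0-9.]+))?$")

#: Penalty added to the objective for OSOR-rejected candidates, scaled so
#: the simplex is steered back toward the accepted region.
_REJECT_PENALTY = 1e6


class FitError(ModelError):
    """Invalid fitting configuration."""


@dataclass
class FitResult:
    """Outcome of :func:`fit_parameters`.

    ``params`` maps each free name to its fitted value (empty when every
    candidate was rejected by the OSOR filter); ``sse`` and ``osor`` belong
    to the best accepted candidate.  ``all_rejected`` is True when no
    candidate passed the filter.
    """

    params: dict[str, float]
    sse: float
    osor: float
    all_rejected: bool
    n_evaluations: int
    n_rejected: int
    history: pd.DataFrame = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {"params": dict(self.params), "sse": self.sse,
                "osor": self.osor, "all_rejected": self.all_rejected,
                "n_evaluations": self.n_evaluations,
                "n_rejected": self.n_rejected}


def _parse_free_name(name: str) -> tuple[str, float | None]:
    m = _FREE_NAME.match(name)
    if not m:
        raise FitError(f"bad free-parameter name {name!r}; use 'pk' or 'pk@60'")
    from .model import MembraneParams
    if m.group("param") not in MembraneParams.FIELDS:
        raise FitError(f"unknown membrane parameter {m.group('param')!r}")
    t = m.group("time")
    return m.group("param"), (float(t) if t is not None else None)


def apply_free_values(scenario: Scenario, names: list[str],
                      values: np.ndarray) -> Scenario:
    """Scenario copy with free parameters set.

    A plain name ('pk') sets the base membrane parameter; 'pk@60' sets (or
    adds) a schedule override at t = 60 min.
    """
    params = scenario.params.copy()
    events = {t: dict(o) for t, o in scenario.schedule.events}
    for name, value in zip(names, values):
        pname, at = _parse_free_name(name)
        if at is None:
            params = replace(params, **{pname: float(value)})
        else:
            events.setdefault(at, {})[pname] = float(value)
    schedule = ParamSchedule(sorted((t, o) for t, o in events.items()))
    return replace(scenario, params=params, schedule=schedule)


def _fit_sim_kwargs(observed: pd.DataFrame, scenario: Scenario) -> dict:
    """Dense-enough sampling for interpolation, fluxes only at the end."""
    tmax = float(observed["t"].max())
    if tmax > scenario.t_end + 1e-9:
        raise FitError(f"observed times reach t={tmax:g} min but the "
                       f"scenario runs only to t_end={scenario.t_end:g}")
    diffs = np.diff(np.unique(observed["t"]))
    spacing = float(diffs.min()) if len(diffs) else max(tmax, scenario.dt)
    hp = max(1, int(round(max(spacing, 4 * scenario.dt) / (4 * scenario.dt))))
    return {"hp": hp, "record_fluxes": False, "check_every_sample": False}


def sse_objective(observed: pd.DataFrame, scenario: Scenario,
                  timecourse=None) -> float:
    """Sum of squared residuals (mM^2) over observed points and the 3 ions.

    ``observed`` must have columns t, na, k, cl with times inside the
    simulated range; simulated concentrations are linearly interpolated in
    time.  A pre-computed ``timecourse`` may be passed to avoid re-running.
    """
    for col in ("t", "na", "k", "cl"):
        if col not in observed.columns:
            raise FitError(f"observed table lacks column {col!r}")
    if observed.empty:
        raise FitError("observed table is empty")
    tc = timecourse
    if tc is None:
        tc = simulate(scenario, **_fit_sim_kwargs(observed, scenario))
    frame = tc.frame
    tobs = observed["t"].to_numpy(float)
    if tobs.min() < frame["t"].iloc[0] - 1e-9 or \
       tobs.max() > frame["t"].iloc[-1] + 1e-9:
        raise FitError("observed times fall outside the simulated range")
    sse = 0.0
    for ion in ("na", "k", "cl"):
        sim = np.interp(tobs, frame["t"].to_numpy(), frame[ion].to_numpy())
        resid = observed[ion].to_numpy(float) - sim
        sse += float(resid @ resid)
    return sse


def make_synthetic_observations(scenario: Scenario, sample_times,
                                noise_sd: float = 0.0,
                                seed: int | None = None) -> pd.DataFrame:
    """Simulate a scenario and sample noisy (t, na, k, cl) observations.

    Gaussian noise of standard deviation ``noise_sd`` (mM) is added
    independently per ion and time point; deterministic for a fixed seed.
    """
    if noise_sd < 0:
        raise FitError("noise_sd must be >= 0")
    times = np.asarray(sample_times, float)
    obs_probe = pd.DataFrame({"t": times, "na": 0.0, "k": 0.0, "cl": 0.0})
    tc = simulate(scenario, **_fit_sim_kwargs(obs_probe, scenario))
    frame = tc.frame
    out = {"t": times}
    rng = np.random.default_rng(seed)
    for ion in ("na", "k", "cl"):
        vals = np.interp(times, frame["t"].to_numpy(), frame[ion].to_numpy())
        if noise_sd > 0:
            vals = vals + rng.normal(0.0, noise_sd, size=len(times))
        out[ion] = vals
    return pd.DataFrame(out)


def fit_parameters(observed: pd.DataFrame, scenario: Scenario,
                   free_names: list[str], bounds: dict[str, tuple[float, float]],
                   osor_min: float = 0.0, *, x0: dict[str, float] | None = None,
                   maxiter: int = 400, xatol: float = 1e-6,
                   fatol: float = 1e-10) -> FitResult:
    """Fit free membrane parameters to an observed ion time course.

    Derivative-free minimization of :func:`sse_objective` over the named
    parameters within finite ``bounds`` (a dict name -> (lo, hi)).  Every
    evaluated candidate is also scored by its simulated OSOR at the final
    time; candidates with OSOR < ``osor_min`` are rejected (penalized during
    the search and excluded from the result).  Returns the best accepted
    candidate, or an explicit all-rejected result when none passes.
    """
    if not free_names:
        raise FitError("free_names must be nonempty")
    for name in free_names:
        _parse_free_name(name)
        if name not in bounds:
            raise FitError(f"no bounds given for {name!r}")
        lo, hi = bounds[name]
        if not (math.isfinite(lo) and math.isfinite(hi) and lo < hi):
            raise FitError(f"bounds for {name!r} must be finite with lo < hi")

    lo = np.array([bounds[n][0] for n in free_names])
    hi = np.array([bounds[n][1] for n in free_names])
    span = hi - lo

    def start_value(name: str) -> float:
        pname, at = _parse_free_name(name)
        if x0 is not None and name in x0:
            return x0[name]
        if at is None:
            v = getattr(scenario.params, pname)
        else:
            v = dict(scenario.schedule.events).get(at, {}).get(
                pname, getattr(scenario.params, pname))
        blo, bhi = bounds[name]
        return min(max(v, blo), bhi) if blo < v < bhi else 0.5 * (blo + bhi)

    x_start = np.array([start_value(n) for n in free_names])
    sim_kwargs = _fit_sim_kwargs(observed, scenario)
    sim_kwargs["record_fluxes"] = True  # final flux table needed for OSOR

    history: list[dict] = []

    def objective(s: np.ndarray) -> float:
        # optimize in bound-scaled space; out-of-bounds -> quadratic wall
        x = lo + s * span
        overshoot = float(np.sum(np.maximum(0, lo - x) / span)
                          + np.sum(np.maximum(0, x - hi) / span))
        if overshoot > 0:
            return _REJECT_PENALTY * (1.0 + overshoot)
        cand = apply_free_values(scenario, free_names, x)
        tc = simulate(cand, **sim_kwargs)
        sse = sse_objective(observed, cand, timecourse=tc)
        try:
            osor = tc.osor()
        except OSORUndefinedError:
            osor = math.nan
        accepted = (not math.isnan(osor)) and osor >= osor_min
        if osor_min <= 0 and math.isnan(osor):
            accepted = True  # no filter requested, OSOR merely unavailable
        history.append({**{n: v for n, v in zip(free_names, x)},
                        "sse": sse, "osor": osor, "accepted": accepted})
        return sse if accepted else sse + _REJECT_PENALTY
    s0 = (x_start - lo) / span
    minimize(objective, s0, method="Nelder-Mead",
             options={"maxiter": maxiter, "xatol": xatol, "fatol": fatol})

    hist = pd.DataFrame(history)
    accepted = hist[hist["accepted"]]
    n_rej = int((~hist["accepted"]).sum())
    if accepted.empty:
        return FitResult(params={}, sse=math.inf, osor=math.nan,
                         all_rejected=True, n_evaluations=len(hist),
                         n_rejected=n_rej, history=hist)
    best = accepted.loc[accepted["sse"].idxmin()]
    return FitResult(params={n: float(best[n]) for n in free_names},
                     sse=float(best["sse"]), osor=float(best["osor"]),
                     all_rejected=False, n_evaluations=len(hist),
                     n_rejected=n_rej, history=hist)


@dataclass
class ScanResult:
    """Family of simulations from :func:`sensitivity_scan`.

    ``endpoints`` has one row per scanned value with the final-state
    variables and their deltas from the first value.
    """

    param_name: str
    values: list[float]
    timecourses: list
    endpoints: pd.DataFrame


def sensitivity_scan(scenario: Scenario, param_name: str,
                     values) -> ScanResult:
    """Repeat a simulation over trial values of one parameter.

    ``param_name`` follows the same 'pk' / 'pk@60' syntax as the fitter.
    All other inputs stay fixed; the endpoint table makes the sensitivity of
    the final state to the scanned coefficient directly comparable.
    """
    values = list(values)
    if not values:
        raise FitError("values must be nonempty")
    _parse_free_name(param_name)
    tcs, rows = [], []
    for v in values:
        cand = apply_free_values(scenario, [param_name], np.array([v]))
        tc = simulate(cand)
        tcs.append(tc)
        fin = tc.frame.iloc[-1]
        rows.append({param_name: v, "t": fin["t"], "U": fin["U"],
                     "na": fin["na"], "k": fin["k"], "cl": fin["cl"],
                     "V": fin["V"]})
    endpoints = pd.DataFrame(rows)
    for col in ("U", "na", "k", "cl", "V"):
        endpoints[f"d_{col}"] = endpoints[col] - endpoints[col].iloc[0]
    return ScanResult(param_name=param_name, values=values,
                      timecourses=tcs, endpoints=endpoints)
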