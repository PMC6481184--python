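"""The two mandatory constraints of the pump-leak model.

Macroscopic electroneutrality and osmotic balance with the medium are the
model-independent physical requirements every admissible state must satisfy:

* the impermeant-osmolyte pair (A, z) is derived once from the initial ion
  concentrations so that both constraints hold at t = 0, then held fixed;
* at every instant the membrane potential is the root of the net
  charge-flux equation (zero-capacitance formulation: the potential follows
  the fluxes instantaneously on the minute timescale of interest);
* the cell water volume follows from osmotic equilibrium with the bath.
"""

from __future__ import annotations

import math

from scipy.optimize import brentq

from .model import (CellState, ExternalMedium, MembraneParams, ModelError,
                    ghk_anion_flux, ghk_cation_flux)

#: Default search interval for the dimensionless potential u (U of about
#: -214 to +53 mV), generously wider than any physiological value.
DEFAULT_BRACKET = (-8.0, 2.0)

#: Convergence tolerance on u for the potential solve.
U_TOL = 1e-12


class PotentialSolveError(ModelError):
    """The charge-flux equation has no root in the search interval."""


def derive_impermeant(na: float, k: float, cl: float,
                      medium: ExternalMedium) -> tuple[float, float]:
    """Impermeant osmolyte concentration A/V (mM) and mean valence z.

    Osmotic balance fixes A/V = kv*(na0+k0+cl0+B0) - (na+k+cl); bulk
    electroneutrality then fixes z = (cl - na - k)/(A/V).  Both are evaluated
    from the initial state and frozen for the whole simulation.
    """
    a_conc = medium.osmolarity - (na + k + cl)
    if a_conc <= 0:
        raise ModelError(
            "internal ion osmolarity exceeds the external total; "
            "no positive impermeant osmolyte concentration exists")
    z = (cl - na - k) / a_conc
    return a_conc, z


def initial_state(na: float, k: float, cl: float, medium: ExternalMedium,
                  t: float = 0.0) -> CellState:
    """Build a constraint-consistent state from initial concentrations.

    A is normalised to 1 mmol, so the initial volume is V = 1000/(A/V) ml.
    The membrane potential field is left NaN until solved.
    """
    a_conc, z = derive_impermeant(na, k, cl, medium)
    return CellState(t=t, na=na, k=k, cl=cl, v=1000.0 / a_conc, z=z, a=1.0)


def charge_flux(u: float, na: float, k: float, cl: float,
                params: MembraneParams, medium: ExternalMedium,
                beta: float) -> float:
    """Total net charge flux carried across the membrane at potential u.

    Channels carry their ions' charges; the pump carries the unbalanced
    fraction -beta*na*(1 - 1/gamma); cotransporters are electroneutral and
    are excluded.  The physical membrane potential is the root of this
    function.
    """
    return (ghk_cation_flux(params.pna, u, na, medium.na0)
            + ghk_cation_flux(params.pk, u, k, medium.k0)
            - ghk_anion_flux(params.pcl, u, cl, medium.cl0)
            - beta * na * (1.0 - 1.0 / params.gamma))


def solve_potential(state: CellState | None, params: MembraneParams,
                    medium: ExternalMedium, *,
                    na: float | None = None, k: float | None = None,
                    cl: float | None = None, beta: float | None = None,
                    bracket: tuple[float, float] = DEFAULT_BRACKET,
                    guess: float | None = None) -> float:
    """Solve the zero-net-charge-flux equation for the dimensionless u.

    Concentrations are taken from ``state`` unless given explicitly.
    ``beta`` defaults to the decayed pump coefficient at the state's time.
    The root is located by a warm-started local bracket around ``guess``
    (progressively widened), falling back to a scan of ``bracket``, and then
    polished by Brent's method to ``U_TOL``.
    """
    if state is not None:
        na = state.na if na is None else na
        k = state.k if k is None else k
        cl = state.cl if cl is None else cl
        if beta is None:
            beta = params.beta_at(state.t)
    if na is None or k is None or cl is None:
        raise ModelError("concentrations required (state or na/k/cl)")
    if beta is None:
        beta = params.beta0

    if params.pna == 0 and params.pk == 0 and params.pcl == 0:
        raise PotentialSolveError(
            "no channel permeability: charge flux is independent of u")

    def phi(u: float) -> float:
        return charge_flux(u, na, k, cl, params, medium, beta)

    lo, hi = bracket
    if guess is not None and math.isfinite(guess):
        half = 0.05
        while half <= (hi - lo):
            a = max(lo, guess - half)
            b = min(hi, guess + half)
            fa, fb = phi(a), phi(b)
            if fa == 0.0:
                return a
            if fb == 0.0:
                return b
            if fa * fb < 0:
                return float(brentq(phi, a, b, xtol=U_TOL))
            half *= 3.0

    # full scan of the bracket for a sign change
    n = 81
    us = [lo + (hi - lo) * i / (n - 1) for i in range(n)]
    fprev = phi(us[0])
    if fprev == 0.0:
        return us[0]
    for a, b in zip(us, us[1:]):
        fb = phi(b)
        if fb == 0.0:
            return b
        if fprev * fb < 0:
            return float(brentq(phi, a, b, xtol=U_TOL))
        fprev = fb
    raise PotentialSolveError(
        f"no sign change of the charge flux on u in [{lo}, {hi}]: "
        f"phi({lo})={phi(lo):.6g}, phi({hi})={phi(hi):.6g}")


def osmotic_volume(na_content: float, k_content: float, cl_content: float,
                   a: float, medium: ExternalMedium) -> float:
    """Cell water volume (ml) from osmotic balance with the medium.

    Contents and ``a`` are in mmol (per unit A); the volume is
    1000*(Na_i + K_i + Cl_i + A)/osmolarity, so that the summed internal
    osmolyte concentration equals the effective external osmolarity.
    """
    total = na_content + k_content + cl_content + a
    if total <= 0:
        raise ModelError("total internal osmolyte content must be > 0")
    return 1000.0 * total / medium.osmolarity


def check_constraints(state: CellState, medium: ExternalMedium,
                      electro_tol: float = 1e-6,
                      osmo_tol: float = 1e-9) -> tuple[float, float]:
    """Residuals (electroneutrality, osmotic balance) in mM; raises if large."""
    electro = state.na + state.k - state.cl + state.z * state.a_conc
    osmo = state.na + state.k + state.cl + state.a_conc - medium.osmolarity
    if abs(electro) > electro_tol:
        raise ModelError(f"electroneutrality violated by {electro:.3e} mM")
    if abs(osmo) > osmo_tol:
        raise ModelError(f"osmotic balance violated by {osmo:.3e} mM")
    return electro, osmo
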