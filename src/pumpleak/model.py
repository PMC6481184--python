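"""Domain types and closed-form flux expressions for the pump-leak model.

The model describes a single animal cell exchanging Na+, K+ and Cl- with an
effectively infinite external medium through three pathways:

* electroconductive channels, with constant-field (Goldman-Hodgkin-Katz)
  flux kinetics governed by integral permeability coefficients ``pna``,
  ``pk``, ``pcl`` (min^-1) and the dimensionless membrane potential ``u``;
* the Na+/K+ pump, a first-order Na+ efflux ``-beta*[Na]i`` coupled to a K+
  influx ``beta*[Na]i/gamma`` (gamma is the Na:K stoichiometry, 3:2 = 1.5);
* electroneutral cotransporters NC (Na-Cl), KC (K-Cl) and NKCC (Na-K-2Cl),
  driven by the transmembrane difference of the products of their substrate
  concentrations.

All fluxes are expressed in umol min^-1 per ml of cell water; inward net
fluxes are positive, outward negative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: RT/F at 37 degrees C, in mV; converts the dimensionless potential u to U.
RT_F_MV = 26.7

#: Below this |u| the GHK expressions switch to their analytic u -> 0 limit.
U_SMALL = 1e-6

IONS = ("Na", "K", "Cl")
PATHWAYS = ("PUMP", "Channel", "NC", "KC", "NKCC")


class ModelError(ValueError):
    """Invalid model configuration or state."""


class OSORUndefinedError(ModelError):
    """OSOR requested while the ouabain-resistant K+ influx is zero."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExternalMedium:
    """Fixed bath composition.

    Parameters
    ----------
    na0, k0, cl0 : float
        External ion concentrations, mM.
    b0 : float
        External membrane-impermeant non-electrolyte (e.g. mannitol), mM.
    kv : float
        Ratio of "new" to "old" medium osmolarity; scales the total external
        osmolarity when the bath is changed (1.0 for an unchanged medium).
    """

    na0: float
    k0: float
    cl0: float
    b0: float = 0.0
    kv: float = 1.0

    def __post_init__(self) -> None:
        for name in ("na0", "k0", "cl0", "b0"):
            if getattr(self, name) < 0:
                raise ModelError(f"{name} must be >= 0")
        if self.kv <= 0:
            raise ModelError("kv must be > 0")
        if self.osmolarity <= 0:
            raise ModelError("total external osmolarity must be > 0")

    @property
    def osmolarity(self) -> float:
        """Effective external osmolarity kv*(na0 + k0 + cl0 + B0), mM."""
        return self.kv * (self.na0 + self.k0 + self.cl0 + self.b0)


@dataclass
class MembraneParams:
    """Transport coefficients of the membrane.

    ``beta0`` is the pump rate coefficient at t = 0 (min^-1); during a run the
    effective coefficient decays linearly, ``beta(t) = max(0, beta0 - kb*t)``,
    which models the progressive pump suppression seen in apoptosis.  ``kb``
    is therefore in units of beta per minute.  ``pna``/``pk``/``pcl`` are
    channel permeability coefficients (min^-1); ``inc``/``ikc`` are NC/KC
    cotransport rate coefficients (ml umol^-1 min^-1) and ``inkcc`` the NKCC
    coefficient (ml^3 umol^-3 min^-1).
    """

    beta0: float = 0.0
    gamma: float = 1.5
    kb: float = 0.0
    pna: float = 0.0
    pk: float = 0.0
    pcl: float = 0.0
    inc: float = 0.0
    ikc: float = 0.0
    inkcc: float = 0.0

    FIELDS = ("beta0", "gamma", "kb", "pna", "pk", "pcl", "inc", "ikc", "inkcc")

    def __post_init__(self) -> None:
        for name in self.FIELDS:
            if getattr(self, name) < 0:
                raise ModelError(f"{name} must be >= 0")
        if self.gamma <= 0:
            raise ModelError("gamma must be > 0")

    def beta_at(self, t: float) -> float:
        """Pump rate coefficient at time ``t`` (min), clamped at zero."""
        return max(0.0, self.beta0 - self.kb * t)

    def copy(self) -> "MembraneParams":
        return replace(self)


@dataclass
class CellState:
    """Intracellular state at one instant.

    Concentrations ``na``/``k``/``cl`` are per ml of cell water (mM).  ``v``
    is the cell water volume per unit of impermeant osmolyte, ml mmol^-1
    (with ``a`` normalised to 1 mmol, ``v`` equals V/A).  ``z`` is the mean
    valence of the impermeant osmolytes.  ``u`` is the dimensionless membrane
    potential; ``U`` (mV) = 26.7 * u.
    """

    t: float
    na: float
    k: float
    cl: float
    v: float
    z: float
    a: float = 1.0
    u: float = math.nan

    @property
    def U(self) -> float:
        """Membrane potential in mV."""
        return RT_F_MV * self.u

    @property
    def a_conc(self) -> float:
        """Impermeant osmolyte concentration A/V in mM (the table's A/V*1000)."""
        return 1000.0 * self.a / self.v

    def contents(self) -> tuple[float, float, float]:
        """Ion contents (mmol per unit A): concentration * volume / 1000."""
        return (self.na * self.v / 1000.0,
                self.k * self.v / 1000.0,
                self.cl * self.v / 1000.0)


@dataclass(frozen=True)
class ElectrochemicalGradients:
    """Transmembrane electrochemical potential differences, mV."""

    mun: float
    muk: float
    mucl: float


@dataclass(frozen=True)
class CotransportFluxes:
    """Net and unidirectional cotransporter fluxes (umol min^-1 ml^-1)."""

    jnc: float
    jkc: float
    jnkcc: float
    inc_influx: float
    inc_efflux: float
    ikc_influx: float
    ikc_efflux: float
    inkcc_influx: float
    inkcc_efflux: float


@dataclass
class FluxTable:
    """Per-ion, per-pathway flux decomposition (the balance-sheet of the cell).

    Rows follow :data:`IONS`, columns :data:`PATHWAYS`.  ``net``, ``influx``
    and ``efflux`` are 3x5 arrays in umol min^-1 (ml cell water)^-1; influx
    entries are >= 0, efflux entries <= 0 and net = influx + efflux cell by
    cell.  For NKCC the Cl- entries carry the factor 2 of its stoichiometry.
    """

    net: np.ndarray
    influx: np.ndarray
    efflux: np.ndarray

    def get(self, ion: str, pathway: str, kind: str = "net") -> float:
        i = IONS.index(ion)
        j = PATHWAYS.index(pathway)
        return float(getattr(self, kind)[i, j])

    def total_net(self, ion: str) -> float:
        """Sum of net fluxes over all pathways for one ion."""
        return float(self.net[IONS.index(ion)].sum())

    def to_frame(self) -> pd.DataFrame:
        """Long-format DataFrame with columns ion, pathway, net, influx, efflux."""
        rows = []
        for i, ion in enumerate(IONS):
            for j, pw in enumerate(PATHWAYS):
                rows.append({"ion": ion, "pathway": pw,
                             "net": self.net[i, j],
                             "influx": self.influx[i, j],
                             "efflux": self.efflux[i, j]})
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# flux expressions
# ---------------------------------------------------------------------------

def ghk_cation_flux(p: float, u: float, ci: float, co: float) -> float:
    """Net constant-field channel flux of a monovalent cation.

    Returns ``p*u*(ci*exp(u) - co)/g`` with ``g = 1 - exp(u)``; positive
    inward.  At |u| below :data:`U_SMALL` the analytic limit ``p*(co - ci)``
    is used to avoid the 0/0 form.
    """
    if p == 0.0:
        return 0.0
    if abs(u) < U_SMALL:
        return p * (co - ci)
    eu = math.exp(u)
    return p * u * (ci * eu - co) / (1.0 - eu)


def ghk_anion_flux(p: float, u: float, ci: float, co: float) -> float:
    """Net constant-field channel flux of a monovalent anion (valence -1).

    Returns ``p*u*(ci - co*exp(u))/g`` with ``g = 1 - exp(u)``; positive
    inward.  This is the standard valence -1 GHK form: substituting -u for u
    and swapping the roles of the concentration terms in the cation
    expression.  Same small-|u| limit ``p*(co - ci)``.
    """
    if p == 0.0:
        return 0.0
    if abs(u) < U_SMALL:
        return p * (co - ci)
    eu = math.exp(u)
    return p * u * (ci - co * eu) / (1.0 - eu)


def ghk_unidirectional(p: float, u: float, ci: float, co: float,
                       valence: int) -> tuple[float, float]:
    """Unidirectional (influx, efflux) components of the GHK channel flux.

    influx >= 0, efflux <= 0 and influx + efflux equals the net flux from
    :func:`ghk_cation_flux` / :func:`ghk_anion_flux`.  ``valence`` is +1 or
    -1.
    """
    if valence not in (+1, -1):
        raise ModelError("valence must be +1 or -1")
    if p == 0.0:
        return 0.0, 0.0
    if abs(u) < U_SMALL:
        return p * co, -p * ci
    eu = math.exp(u)
    g = 1.0 - eu
    if valence == +1:
        return (-p * u * co / g, p * u * ci * eu / g)
    return (-p * u * co * eu / g, p * u * ci / g)


def pump_fluxes(beta: float, nai: float, gamma: float) -> tuple[float, float]:
    """Na+/K+ pump fluxes: (Na+ net efflux <= 0, K+ net influx >= 0).

    Na+ efflux is first order in the internal concentration, ``-beta*nai``;
    K+ influx is ``beta*nai/gamma``.  The pump's net charge flux is
    ``-beta*nai*(1 - 1/gamma)``.
    """
    if beta < 0 or nai < 0:
        raise ModelError("beta and nai must be >= 0")
    if gamma <= 0:
        raise ModelError("gamma must be > 0")
    out = beta * nai
    return -out, out / gamma


def cotransport_fluxes(params: MembraneParams, na: float, k: float, cl: float,
                       medium: ExternalMedium) -> CotransportFluxes:
    """Electroneutral cotransporter fluxes.

    J_NC = inc*(na0*cl0 - na*cl); J_KC = ikc*(k0*cl0 - k*cl);
    J_NKCC = inkcc*(na0*k0*cl0^2 - na*k*cl^2).  Unidirectional components are
    the external-product (influx) and internal-product (efflux) terms.  Each
    carries zero net charge, so none contributes to the potential equation.
    """
    m = medium
    inc_in = params.inc * m.na0 * m.cl0
    inc_out = -params.inc * na * cl
    ikc_in = params.ikc * m.k0 * m.cl0
    ikc_out = -params.ikc * k * cl
    inkcc_in = params.inkcc * m.na0 * m.k0 * m.cl0 * m.cl0
    inkcc_out = -params.inkcc * na * k * cl * cl
    return CotransportFluxes(
        jnc=inc_in + inc_out,
        jkc=ikc_in + ikc_out,
        jnkcc=inkcc_in + inkcc_out,
        inc_influx=inc_in, inc_efflux=inc_out,
        ikc_influx=ikc_in, ikc_efflux=ikc_out,
        inkcc_influx=inkcc_in, inkcc_efflux=inkcc_out,
    )


def electrochemical_potentials(state: CellState,
                               medium: ExternalMedium) -> ElectrochemicalGradients:
    """Per-ion electrochemical potential differences (mV).

    mun = 26.7*ln(na/na0) + U, muk likewise; mucl = 26.7*ln(cl/cl0) - U
    (opposite sign of U for the anion).  Positive values drive the ion
    outward through its channels.
    """
    for val, name in ((state.na, "na"), (state.k, "k"), (state.cl, "cl"),
                      (medium.na0, "na0"), (medium.k0, "k0"), (medium.cl0, "cl0")):
        if val <= 0:
            raise ModelError(f"{name} must be > 0 for electrochemical potentials")
    U = state.U
    return ElectrochemicalGradients(
        mun=RT_F_MV * math.log(state.na / medium.na0) + U,
        muk=RT_F_MV * math.log(state.k / medium.k0) + U,
        mucl=RT_F_MV * math.log(state.cl / medium.cl0) - U,
    )


def build_flux_table(state: CellState, params: MembraneParams,
                     medium: ExternalMedium, beta: float | None = None) -> FluxTable:
    """Assemble the full 3-ion x 5-pathway flux decomposition.

    ``state.u`` must already hold the solved membrane potential.  ``beta``
    defaults to ``params.beta_at(state.t)``.
    """
    if beta is None:
        beta = params.beta_at(state.t)
    u = state.u
    net = np.zeros((3, 5))
    infl = np.zeros((3, 5))
    effl = np.zeros((3, 5))

    # pump
    na_pump, k_pump = pump_fluxes(beta, state.na, params.gamma)
    net[0, 0] = effl[0, 0] = na_pump
    net[1, 0] = infl[1, 0] = k_pump

    # channels
    for i, (p, ci, co, val) in enumerate((
            (params.pna, state.na, medium.na0, +1),
            (params.pk, state.k, medium.k0, +1),
            (params.pcl, state.cl, medium.cl0, -1))):
        fi, fe = ghk_unidirectional(p, u, ci, co, val)
        infl[i, 1], effl[i, 1] = fi, fe
        net[i, 1] = fi + fe

    # cotransporters (Cl carries 2x the NKCC turnover)
    ct = cotransport_fluxes(params, state.na, state.k, state.cl, medium)
    infl[0, 2], effl[0, 2] = ct.inc_influx, ct.inc_efflux
    infl[2, 2], effl[2, 2] = ct.inc_influx, ct.inc_efflux
    infl[1, 3], effl[1, 3] = ct.ikc_influx, ct.ikc_efflux
    infl[2, 3], effl[2, 3] = ct.ikc_influx, ct.ikc_efflux
    infl[0, 4], effl[0, 4] = ct.inkcc_influx, ct.inkcc_efflux
    infl[1, 4], effl[1, 4] = ct.inkcc_influx, ct.inkcc_efflux
    infl[2, 4], effl[2, 4] = 2 * ct.inkcc_influx, 2 * ct.inkcc_efflux
    net[:, 2:] = infl[:, 2:] + effl[:, 2:]

    return FluxTable(net=net, influx=infl, efflux=effl)


def compute_osor(flux_table: FluxTable) -> float:
    """Ratio of ouabain-sensitive to ouabain-resistant K+(Rb+) influx.

    Numerator: pump K+ influx.  Denominator: the sum of K+ unidirectional
    influxes through channels and the KC/NKCC cotransporters (all
    ouabain-resistant routes; in runs without cotransport this reduces to the
    channel influx alone).  Rb+ is assumed to trace K+, so the tracer
    concentration cancels in the ratio.
    """
    ik = IONS.index("K")
    num = flux_table.influx[ik, PATHWAYS.index("PUMP")]
    den = (flux_table.influx[ik, PATHWAYS.index("Channel")]
           + flux_table.influx[ik, PATHWAYS.index("KC")]
           + flux_table.influx[ik, PATHWAYS.index("NKCC")])
    if den <= 0.0:
        raise OSORUndefinedError(
            "ouabain-resistant K influx is zero; OSOR is undefined")
    return float(num / den)
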