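"""Packaged scenarios for the published U937-like model configurations.

Each factory returns a fresh :class:`~pumpleak.simulate.Scenario`.  All use
the standard bath (140 Na, 5.8 K, 116 Cl, 48.2 mannitol-equivalent, kv = 1,
total 310 mosM) and differ in the initial intracellular state, transport
coefficients and parameter schedule.
"""

from __future__ import annotations

from .model import ExternalMedium, MembraneParams
from .simulate import ParamSchedule, Scenario

#: The standard 310-mosM bath shared by all scenarios.
STANDARD_MEDIUM = ExternalMedium(na0=140.0, k0=5.8, cl0=116.0, b0=48.2, kv=1.0)


def table2_balance() -> Scenario:
    """Transition to the balanced state of a high-potential U937-like cell.

    Starts slightly off balance (33/152/45 mM) and converges within ~4 h to
    U about -44.7 mV, na 38, k 147, cl 45.1, V/A 12.51.
    """
    return Scenario(
        name="table2_balance",
        medium=STANDARD_MEDIUM,
        na=33.0, k=152.0, cl=45.0,
        params=MembraneParams(beta0=0.039, gamma=1.5, kb=0.0,
                              pna=0.00382, pk=0.022, pcl=0.0091,
                              inc=3e-5, ikc=0.0, inkcc=0.0),
        t_end=240.0, dt=0.01, hp=2400,
    )


def fig1_perturbations() -> Scenario:
    """Balanced high-potential cell used as the base for single-parameter
    perturbation studies (vary one coefficient with a sensitivity scan)."""
    sc = table2_balance()
    return Scenario(
        name="fig1_perturbations",
        medium=sc.medium,
        na=38.0, k=147.0, cl=45.1,
        params=sc.params.copy(),
        t_end=240.0, dt=0.01, hp=3000,
    )


def fig2_pumpstop(pcl: float = 0.0001) -> Scenario:
    """Ion redistribution after turning the pump off (beta = 0).

    ``pcl`` selects the chloride permeability variant (0.1, 0.001 or 0.0001
    in the published family); at low pcl the early phase is a nearly
    equal K+/Na+ exchange with no swelling.
    """
    return Scenario(
        name="fig2_pumpstop",
        medium=STANDARD_MEDIUM,
        na=52.6, k=144.2, cl=11.9,
        params=MembraneParams(beta0=0.0, gamma=1.5, kb=0.0,
                              pna=0.006, pk=0.06, pcl=pcl),
        t_end=240.0, dt=0.01, hp=2400,
    )


def fig3_pumpstop_fit() -> Scenario:
    """Near-complete pump block (beta 0.001, down from 0.039) fitted to
    observed K+/Na+/Cl- time courses."""
    return Scenario(
        name="fig3_pumpstop_fit",
        medium=STANDARD_MEDIUM,
        na=35.0, k=156.0, cl=70.0,
        params=MembraneParams(beta0=0.001, gamma=1.5, kb=0.0,
                              pna=0.00301, pk=0.023, pcl=0.00405,
                              inc=3.4e-5),
        t_end=240.0, dt=0.01, hp=2400,
    )


def table4_apoptosis() -> Scenario:
    """Staurosporine-type apoptotic volume decrease.

    Baseline low-potential cell (na 32, k 117, cl 40; U about -29.9 mV).  At
    t = 0 the channel permeabilities shift stepwise (pk 0.0115 -> 0.03,
    pna 0.0041 -> 0.003, pcl 0.0125 -> 0.068) and the pump starts a linear
    decay (kb = 6.8e-5: beta 0.029 -> 0.013 over 4 h); at t = 60 min pk
    drops to 0.02.
    """
    return Scenario(
        name="table4_apoptosis",
        medium=STANDARD_MEDIUM,
        na=32.0, k=117.0, cl=40.0,
        params=MembraneParams(beta0=0.029, gamma=1.5, kb=0.0,
                              pna=0.0041, pk=0.0115, pcl=0.0125,
                              inc=3e-6),
        schedule=ParamSchedule([
            (0.0, {"pk": 0.03, "pna": 0.003, "pcl": 0.068, "kb": 0.000068}),
            (60.0, {"pk": 0.02}),
        ]),
        t_end=240.0, dt=0.01, hp=1000,
    )


_TABLE5_SHIFTS = {
    "pk": {"pk": 0.03},
    "pna": {"pna": 0.003},
    "pk_pna": {"pk": 0.03, "pna": 0.003},
    "pk_pna_pcl": {"pk": 0.03, "pna": 0.003, "pcl": 0.068},
}


def table5_shifts(variant: str = "pk_pna_pcl") -> Scenario:
    """Early-apoptosis stepwise permeability shifts at constant pump rate.

    ``variant`` is one of 'pk', 'pna', 'pk_pna', 'pk_pna_pcl' and names the
    coefficients stepped at t = 0 from the same baseline as
    :func:`table4_apoptosis` (no pump decay; first hour only).
    """
    if variant not in _TABLE5_SHIFTS:
        raise KeyError(f"unknown shift variant {variant!r}; "
                       f"choose from {sorted(_TABLE5_SHIFTS)}")
    base = table4_apoptosis()
    return Scenario(
        name=f"table5_shifts[{variant}]",
        medium=base.medium,
        na=base.na, k=base.k, cl=base.cl,
        params=base.params.copy(),
        schedule=ParamSchedule([(0.0, dict(_TABLE5_SHIFTS[variant]))]),
        t_end=60.0, dt=0.01, hp=1500,
    )


FIXTURES = {
    "table2_balance": table2_balance,
    "fig1_perturbations": fig1_perturbations,
    "fig2_pumpstop": fig2_pumpstop,
    "fig3_pumpstop_fit": fig3_pumpstop_fit,
    "table4_apoptosis": table4_apoptosis,
    "table5_shifts": table5_shifts,
}


def list_fixtures() -> list[str]:
    return sorted(FIXTURES)


def get_fixture(name: str) -> Scenario:
    try:
        factory = FIXTURES[name]
    except KeyError:
        raise KeyError(f"unknown fixture {name!r}; available: "
                       f"{', '.join(list_fixtures())}") from None
    return factory()
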