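"""Conversions from raw cell-physiology measurements to model inputs.

Covers the three quantities the model consumes from the bench: cell water
content from buoyant density, the pump rate coefficient from an
ouabain-sensitive Rb+ influx assay, and per-water ion concentrations from
per-protein contents.
"""

from __future__ import annotations

import pandas as pd

from .model import ModelError


def water_from_density(rho: float, rho_dry: float = 1.38,
                       protein_frac: float = 0.72) -> float:
    """Cell water content (ml per g protein) from buoyant density.

    v = (1 - rho/rho_dry) / (protein_frac * (rho - 1)), with rho the measured
    buoyant density (g/ml), rho_dry the dry-mass density and protein_frac the
    protein share of dry mass.  Strictly decreasing in rho on (1, rho_dry).
    """
    if rho >= rho_dry:
        if rho == rho_dry:
            return 0.0
        raise ModelError("rho must be < rho_dry")
    if rho <= 1.0:
        raise ModelError("rho must be > 1 g/ml (water)")
    return (1.0 - rho / rho_dry) / (protein_frac * (rho - 1.0))


def pump_beta_from_rb(os_rb_influx: float, na_content: float,
                      rbo: float = 2.5, ko: float = 5.8,
                      gamma: float = 1.5,
                      convention: str = "total") -> float:
    """Pump rate coefficient beta from an ouabain-sensitive Rb+ influx.

    The Rb+-borne fraction of the pump cation influx is scaled to the total
    pump K+(Rb+) influx and multiplied by gamma to give the pump Na+ efflux;
    beta is that efflux divided by the cell Na+ content (same units as the
    influx times time).

    ``convention`` selects the scaling of the measured Rb+ influx:
    'total' (default) uses (rbo + ko)/rbo, treating external Rb+ and K+ as a
    single pool of pump substrate of which Rb+ is the traced fraction;
    'k_only' uses ko/rbo (the Rb+ influx reported separately from the K+
    influx).  The published examples use 2.5 mM Rb+ against 5.8 mM K+.
    """
    if os_rb_influx < 0:
        raise ModelError("os_rb_influx must be >= 0")
    if na_content <= 0:
        raise ModelError("na_content must be > 0")
    if rbo <= 0 or ko <= 0 or gamma <= 0:
        raise ModelError("rbo, ko and gamma must be > 0")
    if convention == "total":
        scale = (rbo + ko) / rbo
    elif convention == "k_only":
        scale = ko / rbo
    else:
        raise ModelError("convention must be 'total' or 'k_only'")
    pump_cation_influx = os_rb_influx * scale
    na_efflux = gamma * pump_cation_influx
    return na_efflux / na_content


def ion_content_units(content: float, water: float) -> float:
    """Concentration in cell water (mM) from per-protein content.

    content in umol per g protein, water in ml per g protein.
    """
    if water <= 0:
        raise ModelError("water must be > 0")
    return content / water


def read_measurements(path) -> pd.DataFrame:
    """Read a simple delimited table of measurements.

    Accepts comma- or whitespace-separated columns with a header row, e.g.
    (time, content, density).  Returns the table as-is; conversion to model
    units is done with the functions above.
    """
    return pd.read_csv(path, sep=None, engine="python", comment="#")
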