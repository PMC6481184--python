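"""Readers and writers for the tool's plain-text formats.

Three formats are handled:

* the DATAB.txt parameter-file dialect: two whitespace-separated records,
  ``na0 k0 cl0 B0 kv na k cl beta gamma`` and
  ``pna pk pcl inc ikc inkcc hp kb`` (scientific notation accepted);
* the RESB.txt-style three-section result report (time course of variables,
  parameter echo, flux balance with z / OSOR / A/V*1000 footer) plus a
  machine-readable CSV export of the trajectory;
* YAML scenario files declaring medium, initial state, parameters, schedule
  and run controls.
"""

from __future__ import annotations

import logging
from pathlib import Path

import yaml

from .model import (IONS, PATHWAYS, ExternalMedium, FluxTable, MembraneParams,
                    ModelError, OSORUndefinedError)
from .simulate import ParamSchedule, Scenario, TimeCourse

log = logging.getLogger("pumpleak")

DATAB_RECORD1 = ("na0", "k0", "cl0", "B0", "kv",
                 "na", "k", "cl", "beta", "gamma")
DATAB_RECORD2 = ("pna", "pk", "pcl", "inc", "ikc", "inkcc", "hp", "kb")

#: DATAB fields that must not be negative (rate/permeability coefficients).
_NONNEG = {"beta", "gamma", "pna", "pk", "pcl", "inc", "ikc", "inkcc",
           "kb", "kv", "na0", "k0", "cl0", "B0", "na", "k", "cl", "hp"}


class ParseError(ModelError):
    """Malformed input file; message names the offending field and line."""


def _parse_number(token: str, name: str, lineno: int) -> float:
    try:
        return float(token)
    except ValueError:
        raise ParseError(
            f"field {name!r} on line {lineno}: {token!r} is not a number"
        ) from None


def read_datab(path) -> tuple[ExternalMedium, dict[str, float],
                              MembraneParams, int]:
    """Parse a DATAB.txt-dialect parameter file.

    Returns (medium, initial concentrations {na,k,cl}, membrane parameters,
    hp).  The two records may share one line or be split across lines; blank
    lines and ``#`` comments are ignored.
    """
    path = Path(path)
    lines = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        text = raw.split("#", 1)[0].strip()
        if text:
            lines.append((lineno, text.split()))
    if not lines:
        raise ParseError(f"{path}: no data lines")

    n1, n2 = len(DATAB_RECORD1), len(DATAB_RECORD2)
    first_line, first_tokens = lines[0]
    if len(first_tokens) == n1 + n2 and len(lines) == 1:
        rec1, rec2 = first_tokens[:n1], first_tokens[n1:]
        line1 = line2 = first_line
    else:
        if len(first_tokens) != n1:
            raise ParseError(
                f"{path} line {first_line}: record 1 needs {n1} fields "
                f"({' '.join(DATAB_RECORD1)}), got {len(first_tokens)}")
        rec1, line1 = first_tokens, first_line
        rest = [(ln, tok) for ln, toks in lines[1:] for tok in toks]
        if len(rest) != n2:
            raise ParseError(
                f"{path}: record 2 needs {n2} fields "
                f"({' '.join(DATAB_RECORD2)}), got {len(rest)}")
        rec2 = [tok for _, tok in rest]
        line2 = rest[0][0]

    values: dict[str, float] = {}
    for name, token in zip(DATAB_RECORD1, rec1):
        values[name] = _parse_number(token, name, line1)
    for name, token in zip(DATAB_RECORD2, rec2):
        values[name] = _parse_number(token, name, line2)
    for name in _NONNEG:
        if values[name] < 0:
            raise ParseError(f"{path}: field {name!r} must be >= 0, "
                             f"got {values[name]}")

    medium = ExternalMedium(na0=values["na0"], k0=values["k0"],
                            cl0=values["cl0"], b0=values["B0"],
                            kv=values["kv"])
    initial = {"na": values["na"], "k": values["k"], "cl": values["cl"]}
    params = MembraneParams(beta0=values["beta"], gamma=values["gamma"],
                            kb=values["kb"], pna=values["pna"],
                            pk=values["pk"], pcl=values["pcl"],
                            inc=values["inc"], ikc=values["ikc"],
                            inkcc=values["inkcc"])
    hp = int(values["hp"]) if values["hp"] >= 1 else 1
    return medium, initial, params, hp


def write_datab(medium: ExternalMedium, initial: dict[str, float],
                params: MembraneParams, hp: int, path) -> None:
    """Write a DATAB.txt-dialect file (round-trips with :func:`read_datab`).

    Numbers are printed with 12 significant digits.
    """
    v1 = (medium.na0, medium.k0, medium.cl0, medium.b0, medium.kv,
          initial["na"], initial["k"], initial["cl"],
          params.beta0, params.gamma)
    v2 = (params.pna, params.pk, params.pcl, params.inc, params.ikc,
          params.inkcc, hp, params.kb)
    fmt = "%.12g"
    text = ("# " + " ".join(DATAB_RECORD1) + "\n"
            + " ".join(fmt % x for x in v1) + "\n"
            + "# " + " ".join(DATAB_RECORD2) + "\n"
            + " ".join(fmt % x for x in v2) + "\n")
    Path(path).write_text(text)


# ---------------------------------------------------------------------------
# RESB-style report
# ---------------------------------------------------------------------------

_TC_COLS = ("t", "U", "na", "k", "cl", "V", "mun", "muk", "mucl",
            "prna", "prk", "prcl")
_UNIT_NOTE = (
    "# units: t min; U, mun, muk, mucl mV; na, k, cl mM; V = V/A ml mmol-1;\n"
    "# prna, prk, prcl mM min-1; fluxes umol min-1 (ml cell water)-1;\n"
    "# outward net fluxes negative; kb in beta-units per minute;\n"
    "# OSOR = pump K influx / (channel + KC + NKCC K influx)\n")


def _flux_section(ft: FluxTable) -> str:
    out = []
    heads = {"net": ("Net flux", PATHWAYS),
             "influx": ("Influx", tuple("I" + p for p in PATHWAYS)),
             "efflux": ("Efflux", tuple("E" + p for p in PATHWAYS))}
    for kind in ("net", "influx", "efflux"):
        title, cols = heads[kind]
        out.append(("%-8s" % title) + "".join("%12s" % c for c in cols))
        arr = getattr(ft, kind)
        for i, ion in enumerate(IONS):
            out.append(("%-8s" % ion)
                       + "".join("%12.4f" % (arr[i, j] + 0.0 if arr[i, j] else 0.0)
                                 for j in range(len(PATHWAYS))))
        out.append("")
    return "\n".join(out)


def write_resb(timecourse: TimeCourse, scenario: Scenario, path,
               csv_path=None) -> None:
    """Write the three-section result report and its CSV companion.

    Section A is the sampled time course of variables, section B echoes the
    parameters in the DATAB layout, section C is the final flux balance with
    the z / OSOR / A/V*1000 footer.  The full trajectory is also written as
    CSV next to the report (or to ``csv_path``).
    """
    if timecourse.frame.empty:
        raise ModelError("cannot write a report for an empty time course")
    path = Path(path)
    csv_path = Path(csv_path) if csv_path else path.with_suffix(".csv")

    lines = [_UNIT_NOTE, "(A) TIME COURSE OF VARIABLES"]
    lines.append("".join("%10s" % c for c in _TC_COLS))
    for _, row in timecourse.frame.iterrows():
        lines.append("".join("%10.4f" % row[c] for c in _TC_COLS[:9])
                     + "".join("%10.5f" % row[c] for c in _TC_COLS[9:]))

    lines.append("")
    lines.append("(B) PARAMETER VALUES")
    m, p = scenario.medium, scenario.params
    lines.append("".join("%10s" % c for c in DATAB_RECORD1))
    lines.append("".join("%10.4g" % x for x in
                         (m.na0, m.k0, m.cl0, m.b0, m.kv, scenario.na,
                          scenario.k, scenario.cl, p.beta0, p.gamma)))
    lines.append("".join("%10s" % c for c in DATAB_RECORD2))
    lines.append("".join("%10.4g" % x for x in
                         (p.pna, p.pk, p.pcl, p.inc, p.ikc, p.inkcc,
                          scenario.hp, p.kb)))
    for t_ev, overrides in scenario.schedule.events:
        lines.append("  at t=%-8g set %s" % (
            t_ev, ", ".join(f"{k}={v:g}" for k, v in overrides.items())))

    lines.append("")
    lines.append("(C) FLUX BALANCE AT THE FINAL TIME POINT")
    lines.append(_flux_section(timecourse.final_flux_table))
    try:
        osor = "%.2f" % timecourse.osor()
    except OSORUndefinedError:
        osor = "undefined"
    st = timecourse.final_state
    lines.append("%12s%12s%12s" % ("z", "OSOR", "A/V*1000"))
    lines.append("%12.4f%12s%12.2f" % (st.z, osor, st.a_conc))
    lines.append("")

    path.write_text("\n".join(lines))
    timecourse.frame.to_csv(csv_path, index=False)
    log.info("wrote report %s and trajectory %s", path, csv_path)


# ---------------------------------------------------------------------------
# scenario files
# ---------------------------------------------------------------------------

def scenario_to_dict(scenario: Scenario) -> dict:
    p = scenario.params
    return {
        "name": scenario.name,
        "medium": {"na0": scenario.medium.na0, "k0": scenario.medium.k0,
                   "cl0": scenario.medium.cl0, "b0": scenario.medium.b0,
                   "kv": scenario.medium.kv},
        "initial": {"na": scenario.na, "k": scenario.k, "cl": scenario.cl},
        "params": {name: getattr(p, name) for name in MembraneParams.FIELDS},
        "schedule": [{"time": t, "set": dict(o)}
                     for t, o in scenario.schedule.events],
        "t_end": scenario.t_end, "dt": scenario.dt, "hp": scenario.hp,
    }


def scenario_from_dict(data: dict) -> Scenario:
    try:
        medium = ExternalMedium(**data["medium"])
        initial = data["initial"]
        params = MembraneParams(**data.get("params", {}))
        schedule = ParamSchedule([(float(ev["time"]), dict(ev["set"]))
                                  for ev in data.get("schedule", [])])
        return Scenario(medium=medium, na=float(initial["na"]),
                        k=float(initial["k"]), cl=float(initial["cl"]),
                        params=params, schedule=schedule,
                        t_end=float(data.get("t_end", 240.0)),
                        dt=float(data.get("dt", 0.01)),
                        hp=int(data.get("hp", 100)),
                        name=str(data.get("name", "")))
    except (KeyError, TypeError) as exc:
        raise ParseError(f"bad scenario structure: {exc}") from exc


def load_scenario(path) -> Scenario:
    """Load a YAML scenario file."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ParseError(f"{path}: scenario file must be a mapping")
    return scenario_from_dict(data)


def save_scenario(scenario: Scenario, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(scenario_to_dict(scenario), fh, sort_keys=False)
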