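import pytest

import pumpleak as pl
from pumpleak.fixtures import table2_balance, table4_apoptosis


@pytest.fixture(scope="session")
def medium():
    return pl.STANDARD_MEDIUM


@pytest.fixture(scope="session")
def table2_tc():
    """Full 240-min balanced-state run at the default step."""
    return pl.simulate(table2_balance())


@pytest.fixture(scope="session")
def table2_endpoints_by_dt(table2_tc):
    """Final rows of the balanced-state run at three integration steps."""
    out = {0.01: table2_tc.frame.iloc[-1]}
    for dt in (0.02, 0.005):
        tc = pl.simulate(table2_balance(), dt=dt, record_fluxes=False)
        out[dt] = tc.frame.iloc[-1]
    return out


@pytest.fixture(scope="session")
def table4_tc():
    """Full 240-min apoptosis run with the scheduled permeability changes."""
    return pl.simulate(table4_apoptosis())


@pytest.fixture(scope="session")
def table2_converged_state(table2_tc):
    """Constraint-consistent state at the end of the balanced-state run."""
    st = table2_tc.final_state
    sc = table2_balance()
    u = pl.solve_potential(st, sc.params, sc.medium)
    from dataclasses import replace
    return replace(st, u=u)
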