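"""Closed-form flux expressions against published flux-balance values."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import pumpleak as pl
from pumpleak.fixtures import table2_balance

# dimensionless potential of the published balanced state (U = -44.7 mV)
U_BAL = -44.7 / 26.7

concs = st.floats(0.1, 300.0)
perms = st.floats(1e-5, 1.0)
pots = st.floats(-6.0, 2.0).filter(lambda u: abs(u) > 1e-6)


class TestGHKNet:
    @pytest.mark.parametrize("p,u,ci,co,expected,rel", [
        # cation: Na channel flux of the balanced state (rounded table inputs)
        (0.00382, U_BAL, 38.0, 140.0, 1.0451, 5e-3),
        # high-precision closed-form oracle value
        (0.01, -1.0, 100.0, 140.0, 1.6328, 1e-4),
    ])
    def test_cation_examples(self, p, u, ci, co, expected, rel):
        assert pl.ghk_cation_flux(p, u, ci, co) == pytest.approx(expected, rel=rel)

    def test_cation_zero_at_equilibrium(self):
        assert pl.ghk_cation_flux(0.5, 0.0, 120.0, 120.0) == 0.0

    @pytest.mark.parametrize("p,u,ci,co,expected,rel", [
        # anion: Cl channel net flux of the balanced state
        (0.0091, U_BAL, 45.1, 116.0, -0.4363, 5e-3),
    ])
    def test_anion_examples(self, p, u, ci, co, expected, rel):
        assert pl.ghk_anion_flux(p, u, ci, co) == pytest.approx(expected, rel=rel)

    def test_anion_nernst_equilibrium(self):
        u = -1.2
        ci = 116.0 * math.exp(u)
        assert pl.ghk_anion_flux(0.01, u, ci, 116.0) == pytest.approx(0.0, abs=1e-15)

    def test_anion_zero_potential_limit(self):
        assert pl.ghk_anion_flux(1.0, 0.0, 100.0, 140.0) == pytest.approx(40.0)

    @given(p=perms, u=pots, ci=concs, co=concs)
    @settings(max_examples=100, derandomize=True)
    def test_cation_flip_symmetry(self, p, u, ci, co):
        left = pl.ghk_cation_flux(p, u, ci, co)
        right = -pl.ghk_cation_flux(p, -u, co, ci)
        assert left == pytest.approx(right, rel=1e-10, abs=1e-12)

    @given(p=perms, ci=concs, co=concs, sign=st.sampled_from([-1.0, 1.0]))
    @settings(max_examples=50, derandomize=True)
    def test_small_u_branch_continuous_with_full_expression(self, p, ci, co,
                                                            sign):
        # the full GHK form deviates from its u->0 limit by at most the
        # first-order Taylor term, so the branch switch is seamless
        limit = p * (co - ci)
        for u in (sign * 1e-4, sign * 2e-6):
            for flux in (pl.ghk_cation_flux, pl.ghk_anion_flux):
                full = flux(p, u, ci, co)
                assert abs(full - limit) <= p * abs(u) * (ci + co) + 1e-12

    def test_switch_point_deviation_negligible_at_physiological_gradient(self):
        # at the 1e-6 switch the discarded terms are < 1e-5 relative for a
        # typical transmembrane gradient
        full = pl.ghk_cation_flux(0.01, 1.5e-6, 100.0, 140.0)
        limit = 0.01 * 40.0
        assert full == pytest.approx(limit, rel=1e-5)


class TestGHKUnidirectional:
    @pytest.mark.parametrize("p,ci,co,val,infl,effl", [
        (0.022, 147.0, 5.8, +1, 0.2627, -1.2505),   # K channel
        (0.0091, 45.1, 116.0, -1, 0.4082, -0.8445),  # Cl channel
    ])
    def test_balanced_state_components(self, p, ci, co, val, infl, effl):
        i, e = pl.ghk_unidirectional(p, U_BAL, ci, co, val)
        assert i == pytest.approx(infl, rel=5e-3)
        assert e == pytest.approx(effl, rel=5e-3)

    def test_zero_permeability(self):
        assert pl.ghk_unidirectional(0.0, -1.0, 10.0, 10.0, +1) == (0.0, 0.0)

    @given(p=perms, u=pots, ci=concs, co=concs,
           val=st.sampled_from([+1, -1]))
    @settings(max_examples=100, derandomize=True)
    def test_components_sum_to_net_with_signs(self, p, u, ci, co, val):
        i, e = pl.ghk_unidirectional(p, u, ci, co, val)
        net = (pl.ghk_cation_flux if val == +1 else pl.ghk_anion_flux)(p, u, ci, co)
        assert i >= 0 and e <= 0
        assert i + e == pytest.approx(net, rel=1e-12, abs=1e-14)


class TestPump:
    def test_balanced_state_fluxes(self):
        na_net, k_net = pl.pump_fluxes(0.039, 38.0, 1.5)
        assert na_net == pytest.approx(-1.4811, rel=5e-3)
        assert k_net == pytest.approx(0.9874, rel=5e-3)

    def test_zero_beta(self):
        assert pl.pump_fluxes(0.0, 50.0, 1.5) == (0.0, 0.0)

    def test_electroneutral_limit_gamma_one(self):
        na_net, k_net = pl.pump_fluxes(0.03, 40.0, 1.0)
        assert na_net == -k_net


class TestCotransport:
    def test_nc_balanced_state(self, medium):
        params = pl.MembraneParams(inc=3e-5)
        ct = pl.cotransport_fluxes(params, 38.0, 147.0, 45.1, medium)
        assert ct.jnc == pytest.approx(0.4359, rel=5e-3)
        assert ct.inc_influx == pytest.approx(0.4872, rel=5e-3)
        assert ct.inc_efflux == pytest.approx(-0.0513, rel=5e-3)

    def test_all_zero_coefficients(self, medium):
        ct = pl.cotransport_fluxes(pl.MembraneParams(), 30, 100, 40, medium)
        assert all(getattr(ct, f) == 0.0 for f in ct.__dataclass_fields__)

    def test_product_equilibrium(self, medium):
        na = 100.0
        cl = medium.na0 * medium.cl0 / na
        ct = pl.cotransport_fluxes(pl.MembraneParams(inc=1e-4), na, 1.0, cl, medium)
        assert ct.jnc == pytest.approx(0.0, abs=1e-12)

    @given(inc=st.floats(0, 1e-3), ikc=st.floats(0, 1e-3),
           inkcc=st.floats(0, 1e-7), na=concs, k=concs, cl=concs)
    @settings(max_examples=50, derandomize=True)
    def test_cotransporters_carry_no_charge(self, medium, inc, ikc, inkcc,
                                            na, k, cl):
        params = pl.MembraneParams(inc=inc, ikc=ikc, inkcc=inkcc)
        state = pl.CellState(t=0, na=na, k=k, cl=cl, v=10.0, z=-1.0, u=-1.0)
        ft = pl.build_flux_table(state, params, medium, beta=0.0)
        for pw in ("NC", "KC", "NKCC"):
            charge = (ft.get("Na", pw) + ft.get("K", pw) - ft.get("Cl", pw))
            assert charge == pytest.approx(0.0, abs=1e-12)


class TestElectrochemicalPotentials:
    def test_balanced_state_row(self, medium):
        state = pl.CellState(t=240, na=38.0, k=147.0, cl=45.1, v=12.51,
                             z=-1.75, u=U_BAL)
        mu = pl.electrochemical_potentials(state, medium)
        assert mu.mun == pytest.approx(-79.5, abs=0.1)
        assert mu.mucl == pytest.approx(19.4, abs=0.1)

    def test_zero_at_equal_concentration_and_zero_potential(self, medium):
        state = pl.CellState(t=0, na=medium.na0, k=medium.k0, cl=medium.cl0,
                             v=10.0, z=0.0, u=0.0)
        mu = pl.electrochemical_potentials(state, medium)
        assert (mu.mun, mu.muk, mu.mucl) == (0.0, 0.0, 0.0)

    def test_nonpositive_concentration_rejected(self, medium):
        state = pl.CellState(t=0, na=0.0, k=100.0, cl=40.0, v=10.0, z=0.0, u=0.0)
        with pytest.raises(pl.ModelError):
            pl.electrochemical_potentials(state, medium)


class TestFluxTableAndOSOR:
    def test_balanced_state_table(self, medium):
        state = pl.CellState(t=0, na=38.0, k=147.0, cl=45.1, v=12.51,
                             z=-1.75, u=U_BAL)
        params = table2_balance().params
        ft = pl.build_flux_table(state, params, medium, beta=0.039)
        assert ft.get("Na", "PUMP") == pytest.approx(-1.4811, rel=5e-3)
        assert ft.get("Na", "Channel") == pytest.approx(1.0451, rel=5e-3)
        assert ft.get("Na", "NC") == pytest.approx(0.4359, rel=5e-3)
        assert ft.get("K", "Channel") == pytest.approx(-0.9878, rel=5e-3)
        assert ft.get("Cl", "Channel") == pytest.approx(-0.4363, rel=5e-3)
        # identity: net = influx + efflux in all 15 cells
        np.testing.assert_allclose(ft.net, ft.influx + ft.efflux,
                                   rtol=1e-12, atol=1e-14)
        assert (ft.influx >= 0).all() and (ft.efflux <= 0).all()
        # pump stoichiometry link between the K and Na pump entries
        assert ft.get("K", "PUMP", "influx") == pytest.approx(
            -ft.get("Na", "PUMP", "efflux") / params.gamma, rel=1e-12)
        assert pl.compute_osor(ft) == pytest.approx(3.76, abs=0.02)

    def test_charge_balance_at_truly_converged_state(self, medium,
                                                     table2_converged_state):
        # channel charge fluxes cancel the pump's unbalanced charge at the
        # solved potential of the converged state
        st = table2_converged_state
        params = table2_balance().params
        ft = pl.build_flux_table(st, params, medium, beta=0.039)
        charge = (ft.get("Na", "Channel") + ft.get("K", "Channel")
                  - ft.get("Cl", "Channel")
                  - 0.039 * st.na * (1 - 1 / params.gamma))
        assert abs(charge) < 1e-3

    def test_all_zero_parameters_give_zero_table(self, medium):
        state = pl.CellState(t=0, na=30.0, k=100.0, cl=40.0, v=10.0,
                             z=-1.0, u=math.nan)
        ft = pl.build_flux_table(state, pl.MembraneParams(), medium, beta=0.0)
        assert not ft.net.any() and not ft.influx.any() and not ft.efflux.any()

    def test_osor_zero_when_pump_off(self, medium):
        state = pl.CellState(t=0, na=30.0, k=100.0, cl=40.0, v=10.0,
                             z=-1.0, u=-1.0)
        ft = pl.build_flux_table(state, pl.MembraneParams(pk=0.02), medium,
                                 beta=0.0)
        assert pl.compute_osor(ft) == 0.0

    def test_osor_undefined_without_resistant_influx(self, medium):
        state = pl.CellState(t=0, na=30.0, k=100.0, cl=40.0, v=10.0,
                             z=-1.0, u=-1.0)
        ft = pl.build_flux_table(state, pl.MembraneParams(beta0=0.03, pna=0.004),
                                 medium, beta=0.03)
        with pytest.raises(pl.OSORUndefinedError):
            pl.compute_osor(ft)


class TestTypeInvariants:
    def test_medium_rejects_negative_and_zero_kv(self):
        with pytest.raises(pl.ModelError):
            pl.ExternalMedium(na0=-1, k0=5.8, cl0=116)
        with pytest.raises(pl.ModelError):
            pl.ExternalMedium(na0=140, k0=5.8, cl0=116, kv=0.0)

    def test_params_reject_negative_rates_and_zero_gamma(self):
        with pytest.raises(pl.ModelError):
            pl.MembraneParams(pna=-0.001)
        with pytest.raises(pl.ModelError):
            pl.MembraneParams(gamma=0.0)

    def test_state_unit_links(self):
        state = pl.CellState(t=0, na=33.0, k=152.0, cl=45.0, v=12.5,
                             z=-1.75, u=-1.0)
        assert state.U == pytest.approx(-26.7)
        assert state.a_conc == pytest.approx(80.0)
        na_c, k_c, cl_c = state.contents()
        assert na_c == pytest.approx(33.0 * 12.5 / 1000.0)
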