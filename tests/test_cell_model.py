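"""Cell model: steady states vs an integration oracle, fluxes, growth law."""

import math

import numpy as np
import pytest
from scipy.integrate import solve_ivp

import colimit as cl
from colimit.cell import _system


def integrate_to_steady_state(cell, env, chem, rtol=1e-12):
    """Independent oracle: explicit time integration of the two ODEs from zero."""
    A, b, *_ = _system(cell, env, chem)
    eigs = np.linalg.eigvals(A)
    t_end = 40.0 / min(e.real for e in eigs)
    sol = solve_ivp(
        lambda t, x: b - A @ x,
        (0.0, t_end),
        [0.0, 0.0],
        method="Radau",
        rtol=rtol,
        atol=1e-10,
    )
    return sol.y[:, -1]


class TestSteadyState:
    def test_no_sources_or_sinks_equilibrates_with_outside(self, chem):
        # all couplings off, passive exchange only, pH_in == pH_out:
        # the pools sit exactly at the boundary concentrations
        cell = cl.CellParams(gamma=0.0, delta=0.0, chi=0.0, phi=0.0)
        env = cl.Environment(pCO2=0.01)
        ss = cl.steady_state(cell, env, chem)
        assert ss.C_in == pytest.approx(ss.C_out, rel=1e-12)
        assert ss.H_in == pytest.approx(ss.H_out, rel=1e-12)

    def test_naive_depletion_matches_closed_form(self):
        # alpha = 1e4, gamma = 1e3, interconversion negligible:
        # C_in/C_out -> alpha/(alpha+gamma) = 10/11 > 0.9
        chem = cl.CarbonateParams(k_h=1e-12)
        cell = cl.CellParams(P_C=0.3, sa_v=1e4 / 0.3, gamma=1e3, delta=0.0, chi=0.0)
        env = cl.Environment(pCO2=0.0004)
        ss = cl.steady_state(cell, env, chem)
        assert ss.C_in / ss.C_out == pytest.approx(1e4 / 1.1e4, rel=1e-6)
        assert ss.C_in / ss.C_out > 0.9

    def test_matches_integration_oracle(self, random_cells, ambient, chem):
        for cell in random_cells:
            ss = cl.steady_state(cell, ambient, chem)
            c_ode, h_ode = integrate_to_steady_state(cell, ambient, chem)
            assert ss.C_in == pytest.approx(c_ode, rel=1e-6)
            assert ss.H_in == pytest.approx(h_ode, rel=1e-6)

    def test_singular_system_raises(self, ambient):
        # no removal path for HCO3-: beta = phi = delta = 0 and a pH so high
        # that spontaneous dehydration vanishes -> singular with chi input
        chem = cl.CarbonateParams(k_h=0.037, pK1_eff=5.01)
        cell = cl.CellParams(P_H=0.0, phi=0.0, delta=0.0, chi=1.0)
        env = cl.Environment(pCO2=0.0004, pH_in=10.0, pH_out=7.0)
        # push K_eq to ~1e5 so k_d underflows the singularity threshold: use
        # an explicit tiny k_h instead
        chem = cl.CarbonateParams(k_h=1e-300, pK1_eff=6.35)
        with pytest.raises(cl.DegenerateParameterError):
            cl.steady_state(cell, env, chem)

    def test_nonnegative_solution(self, random_cells, ambient, chem):
        for cell in random_cells[:25]:
            ss = cl.steady_state(cell, ambient, chem)
            assert ss.C_in >= 0 and ss.H_in >= 0


class TestFluxes:
    def test_conservation(self, random_cells, ambient, chem):
        # J_chi - J_L,tot = J_rub + J_bic for every parameter set
        for cell in random_cells:
            fr = cl.fluxes(cl.steady_state(cell, ambient, chem), cell)
            scale = max(abs(fr.J_chi), abs(fr.J_L_tot), fr.J_B)
            assert abs(fr.J_chi - fr.J_L_tot - fr.J_B) <= 1e-9 * scale

    def test_passive_influx_without_uptake(self, ambient, chem, default_cell):
        # no pump: carboxylation is balanced by net diffusive entry
        fr = cl.fluxes(cl.steady_state(default_cell, ambient, chem), default_cell)
        assert fr.J_chi == 0.0
        assert fr.J_L_C < 0.0
        assert fr.J_L_tot == pytest.approx(-fr.J_B, rel=1e-9)

    def test_all_activities_zero_all_fluxes_zero(self, ambient, chem):
        cell = cl.CellParams(gamma=0.0, delta=0.0, chi=0.0, phi=0.0)
        fr = cl.fluxes(cl.steady_state(cell, ambient, chem), cell)
        for name in ("J_rub", "J_bic", "J_B", "J_L_C", "J_L_H", "J_L_tot", "J_chi"):
            assert getattr(fr, name) == pytest.approx(0.0, abs=1e-9)

    def test_extreme_coexpression_reaches_hundredfold_leakage(self, ambient, chem):
        cell = cl.CellParams(delta=1e6, chi=1e6)
        fr = cl.fluxes(cl.steady_state(cell, ambient, chem), cell)
        assert fr.leak_ratio >= 100.0


class TestCANeutrality:
    def test_ca_preserves_equilibrium(self, ambient, chem):
        # with no consumption or uptake, a CA must not shift the pools
        base = cl.CellParams(gamma=0.0, chi=0.0, phi=0.0, delta=1e-6)
        boosted = base.with_rates(delta=1.0)  # 1e6-fold more CA
        ss0 = cl.steady_state(base, ambient, chem)
        ss1 = cl.steady_state(boosted, ambient, chem)
        assert ss1.C_in == pytest.approx(ss0.C_in, rel=1e-9)
        assert ss1.H_in == pytest.approx(ss0.H_in, rel=1e-9)

    def test_large_delta_locks_pools_to_equilibrium_ratio(self, ambient, chem):
        for cell in (
            cl.CellParams(gamma=100.0, phi=1.0),
            cl.CellParams(gamma=1000.0, phi=5.0, chi=10.0),
        ):
            big = cell.with_rates(delta=1e4 * max(cell.gamma, cell.phi, chem.k_h))
            ss = cl.steady_state(big, ambient, chem)
            keq = cl.equilibrium_ratio(ambient.pH_in, chem)
            assert ss.H_in / ss.C_in == pytest.approx(keq, rel=0.01)


class TestGrowth:
    def test_liebig_minimum_and_regimes(self, default_cell):
        fr_bic0 = cl.FluxReport(
            J_rub=10.0, J_bic=0.0, J_B=10.0, J_L_C=0, J_L_H=0, J_L_tot=-10.0,
            J_chi=0.0, leak_ratio=-1.0,
        )
        gp = cl.growth_rate(fr_bic0, default_cell)
        assert gp.growth_rate == 0.0
        assert gp.limiting_regime == "bicarboxylation_limited"
        assert math.isinf(gp.doubling_time)

    def test_tie_breaks_to_rubisco(self, default_cell):
        f = default_cell.f_H
        q = cl.cell.DEFAULT_QC_UM
        # construct exact tie: J_rub/(1-f) == J_bic/f
        fr = cl.FluxReport(
            J_rub=(1 - f) * q, J_bic=f * q, J_B=q, J_L_C=0, J_L_H=0,
            J_L_tot=-q, J_chi=0.0, leak_ratio=-1.0,
        )
        gp = cl.growth_rate(fr, default_cell)
        assert gp.limiting_regime == "rubisco_limited"

    def test_doubling_time_identity(self, ambient, chem, default_cell):
        _, _, gp = cl.evaluate(default_cell, ambient, chem)
        assert gp.doubling_time == pytest.approx(math.log(2) / gp.growth_rate)

    def test_qc_scale_equivariance(self, ambient, chem, default_cell):
        _, fr, _ = cl.evaluate(default_cell, ambient, chem)
        g1 = cl.growth_rate(fr, default_cell, q_C_uM=1e7).growth_rate
        g2 = cl.growth_rate(fr, default_cell, q_C_uM=2e7).growth_rate
        assert g2 == pytest.approx(g1 / 2.0, rel=1e-12)

    def test_rejects_nonpositive_demand(self, ambient, chem, default_cell):
        _, fr, _ = cl.evaluate(default_cell, ambient, chem)
        with pytest.raises(ValueError):
            cl.growth_rate(fr, default_cell, q_C_uM=0.0)

    def test_monotone_in_co2(self, chem, default_cell):
        rates = [
            cl.evaluate(default_cell, cl.Environment(pCO2=p), chem)[2].growth_rate
            for p in cl.ASSAY_PCO2
        ]
        assert all(b > a for a, b in zip(rates, rates[1:]))

    def test_monotone_in_delta_up_to_plateau(self, ambient, chem):
        # growth rises with CA activity while bicarboxylation limited and is
        # flat to ~1e-3 relative in the rubisco-limited plateau (CA hydration
        # consumes a little CO2 there)
        cell = cl.CellParams(gamma=100.0)
        deltas = np.geomspace(1e-3, 1e6, 40)
        rates = np.array(
            [cl.evaluate(cell.with_rates(delta=d), ambient, chem)[2].growth_rate for d in deltas]
        )
        drops = (rates[:-1] - rates[1:]) / rates.max()
        assert drops.max() <= 1e-3


class TestClosedForms:
    @pytest.mark.parametrize(
        "alpha, gamma, expected",
        [(1e4, 1e3, 10 / 11), (123.0, 0.0, 1.0), (1e3, 1e3, 0.5)],
    )
    def test_naive_depletion_ratio(self, alpha, gamma, expected):
        assert cl.naive_depletion_ratio(alpha, gamma) == pytest.approx(expected)

    def test_naive_depletion_rejects_bad_alpha(self):
        with pytest.raises(ValueError):
            cl.naive_depletion_ratio(0.0, 1.0)

    @pytest.mark.parametrize(
        "fraction, total, mass, expected_mM",
        [(0.2, 300.0, 60.0, 1.0), (0.0, 300.0, 60.0, 0.0), (0.1, 300.0, 60.0, 0.5)],
    )
    def test_rubisco_site_budget(self, fraction, total, mass, expected_mM):
        assert cl.max_rubisco_site_concentration(fraction, total, mass) == pytest.approx(
            expected_mM
        )

    def test_percell_fixation_order_of_magnitude(self, chem):
        # alpha ~ 1e4, gamma = 1e3, C_out = 15 uM, 1 fL cell:
        # ~1e10 CO2 fixed per hour, doubling a 1e10-carbon cell in < 2 h
        cell = cl.CellParams(P_C=0.3, sa_v=1e4 / 0.3, gamma=1e3)
        env = cl.Environment(pCO2=15e-6 / chem.K_H)
        rate, doubling = cl.percell_fixation_rate(cell, env, chem, demand_molecules=1e10)
        assert 1e10 <= rate <= 1e11
        assert doubling <= 2.0

    def test_percell_fixation_zero_rubisco(self, ambient, chem):
        rate, doubling = cl.percell_fixation_rate(
            cl.CellParams(gamma=0.0), ambient, chem
        )
        assert rate == 0.0 and math.isinf(doubling)


class TestValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"gamma": -1.0},
            {"f_H": 0.0},
            {"f_H": 0.6},
            {"volume_L": 0.0},
            {"uptake_substrate": "glucose"},
        ],
    )
    def test_bad_cell_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            cl.CellParams(**kwargs)

    def test_alpha_beta_derived_from_permeabilities(self):
        cell = cl.CellParams(P_C=0.5, P_H=1e-5, sa_v=2e4)
        assert cell.alpha == pytest.approx(1e4)
        assert cell.beta == pytest.approx(0.2)

    def test_uptake_substrate_switch(self, ambient, chem):
        # HCO3--importing (SbtA-like) uptake sees the larger external pool
        co2_cell = cl.CellParams(chi=1.0, uptake_substrate="co2")
        hco3_cell = cl.CellParams(chi=1.0, uptake_substrate="hco3")
        fr_c = cl.fluxes(cl.steady_state(co2_cell, ambient, chem), co2_cell)
        fr_h = cl.fluxes(cl.steady_state(hco3_cell, ambient, chem), hco3_cell)
        keq = cl.equilibrium_ratio(ambient.pH_out, chem)
        assert fr_h.J_chi == pytest.approx(fr_c.J_chi * keq, rel=1e-12)
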