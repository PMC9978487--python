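"""Unit and property tests for the bacterial box model."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bacclim.model_core import (
    BacterialState,
    EnvForcing,
    ModelParams,
    doc_uptake,
    grazing,
    integrate,
    mortality,
    partition_biomass,
    poc_uptake,
    respiration,
    steady_state_biomass,
    temperature_factor,
    tendency,
)

pos = st.floats(min_value=0.0, max_value=1e3, allow_nan=False)
conc = st.floats(min_value=0.0, max_value=100.0, allow_nan=False)


class TestTemperatureFactor:
    def test_unity_at_reference(self):
        assert temperature_factor(10.0, 2.95, 10.0) == pytest.approx(1.0)

    def test_one_decade_above(self):
        assert temperature_factor(20.0, 2.95, 10.0) == pytest.approx(2.95)

    def test_below_reference(self):
        assert temperature_factor(0.0, 2.0, 10.0) == pytest.approx(0.5)

    def test_invalid_q10(self):
        with pytest.raises(ValueError):
            temperature_factor(10.0, 0.0)
        with pytest.raises(ValueError):
            temperature_factor(10.0, -1.0)

    @given(st.floats(-2, 35), st.floats(-2, 35))
    def test_monotone_in_T_for_q10_above_one(self, t1, t2):
        if t1 > t2:
            t1, t2 = t2, t1
        assert temperature_factor(t1, 2.95) <= temperature_factor(t2, 2.95)


class TestPartition:
    def test_symmetric_pools(self):
        s = partition_biomass(10.0, 100.0, 100.0)
        assert s.B_DOC == pytest.approx(5.0)
        assert s.B_POC == pytest.approx(5.0)

    def test_doc_rich(self):
        s = partition_biomass(30.0, 2350.0, 323.0)
        assert s.phi_DOC == pytest.approx(0.87917, abs=1e-4)
        assert s.B_DOC == pytest.approx(26.37, abs=0.01)
        assert s.B_POC == pytest.approx(3.62, abs=0.01)

    def test_single_pool(self):
        s = partition_biomass(7.0, 5.0, 0.0)
        assert s.phi_DOC == 1.0
        assert s.B_POC == 0.0

    def test_degenerate_substrate(self, caplog):
        s = partition_biomass(3.0, 0.0, 0.0)
        assert s.phi_DOC == 0.0
        assert s.B_DOC == 0.0
        assert s.B_POC == 3.0

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            partition_biomass(-1.0, 1.0, 1.0)

    @given(pos, conc, conc)
    def test_closure_at_ulp_level(self, B, DOC, POC):
        s = partition_biomass(B, DOC, POC)
        assert abs(s.B_DOC + s.B_POC - s.B) <= 1e-15 * s.B
        assert 0.0 <= s.phi_DOC <= 1.0


class TestDocUptake:
    def test_half_saturation(self, params):
        s = partition_biomass(2.0, params.X_DOC, 0.0)
        f = EnvForcing(T=params.T_ref, DOC=params.X_DOC, POC=0.0)
        assert doc_uptake(s, f, params) == pytest.approx(0.5 * params.mu_max * s.B_DOC)

    def test_saturation_limit(self, params):
        s = partition_biomass(2.0, 100 * params.X_DOC, 0.0)
        f = EnvForcing(T=params.T_ref, DOC=100 * params.X_DOC, POC=0.0)
        expect = params.mu_max * s.B_DOC
        assert doc_uptake(s, f, params) == pytest.approx(expect, rel=1e-4)

    def test_worked_example(self):
        p = ModelParams(mu_max=2.0, Q10_B=2.95, X_DOC=5.0)
        s = BacterialState(B=1.0, B_DOC=1.0, B_POC=0.0, phi_DOC=1.0)
        f = EnvForcing(T=20.0, DOC=10.0, POC=0.0)
        assert doc_uptake(s, f, p) == pytest.approx(2 * 2.95 * 8 / 9, rel=1e-6)

    @given(st.floats(0, 50), st.floats(0, 50), st.floats(0, 30), st.floats(0, 30))
    def test_monotone_in_doc_and_temperature(self, d1, d2, t1, t2):
        p = ModelParams()
        f1 = EnvForcing(T=t1, DOC=d1, POC=0.0)
        f2 = EnvForcing(T=t2, DOC=d2, POC=0.0)
        s = BacterialState(B=1.0, B_DOC=1.0, B_POC=0.0, phi_DOC=1.0)
        if d1 <= d2 and t1 <= t2:
            assert doc_uptake(s, f1, p) <= doc_uptake(s, f2, p) + 1e-12

    def test_saturation_bound(self, params):
        s = partition_biomass(5.0, 30.0, 3.0)
        f = EnvForcing(T=22.0, DOC=30.0, POC=3.0)
        f_T = temperature_factor(22.0, params.Q10_B)
        assert doc_uptake(s, f, params) <= params.mu_max * f_T * s.B_DOC + 1e-12


class TestPocUptake:
    def test_depth_factor_at_reference(self, params):
        s = partition_biomass(2.0, 0.0, 10.0)
        f_ref = EnvForcing(T=params.T_ref, DOC=0.0, POC=10.0, z=params.z0)
        f_surf = EnvForcing(T=params.T_ref, DOC=0.0, POC=10.0, z=0.0)
        assert poc_uptake(s, f_ref, params) == pytest.approx(poc_uptake(s, f_surf, params))

    def test_contois_half_saturation(self, params):
        B_POC = 4.0
        poc = params.X_POC * B_POC
        s = BacterialState(B=B_POC, B_DOC=0.0, B_POC=B_POC, phi_DOC=0.0)
        f = EnvForcing(T=params.T_ref, DOC=0.0, POC=poc, z=params.z0)
        assert poc_uptake(s, f, params) == pytest.approx(0.5 * params.mu_max * B_POC)

    def test_depth_halving(self):
        p = ModelParams(b_exp=-1.0)
        B_POC = 1.0
        s = BacterialState(B=B_POC, B_DOC=0.0, B_POC=B_POC, phi_DOC=0.0)
        f_deep = EnvForcing(T=p.T_ref, DOC=0.0, POC=1e6, z=2 * p.z0)
        f_ref = EnvForcing(T=p.T_ref, DOC=0.0, POC=1e6, z=p.z0)
        ratio = poc_uptake(s, f_deep, p) / poc_uptake(s, f_ref, p)
        assert ratio == pytest.approx(0.5, rel=1e-6)

    def test_zero_when_empty(self, params):
        s = partition_biomass(0.0, 0.0, 10.0)
        f = EnvForcing(T=15.0, DOC=0.0, POC=10.0, z=10.0)
        assert poc_uptake(s, f, params) == 0.0
        s2 = partition_biomass(5.0, 10.0, 0.0)
        f2 = EnvForcing(T=15.0, DOC=10.0, POC=0.0, z=10.0)
        assert poc_uptake(s2, f2, params) == 0.0

    def test_surface_no_division_error(self, params):
        s = partition_biomass(1.0, 0.0, 5.0)
        f = EnvForcing(T=10.0, DOC=0.0, POC=5.0, z=0.0)
        v = poc_uptake(s, f, params)
        assert np.isfinite(v) and v > 0


class TestRespiration:
    def test_oxic_limit(self, params, state_factory):
        s = state_factory(B=2.0)
        f = EnvForcing(T=params.T_ref, DOC=10.0, POC=5.0, DO=1e4)
        R, f_O = respiration(s, f, params, BCD=10.0)
        assert f_O == pytest.approx(1.0, abs=1e-6)
        assert R == pytest.approx(params.b_B * s.B + params.gamma_a * 10.0, rel=1e-5)

    def test_oxygen_half_saturation(self, params, state_factory):
        f = EnvForcing(T=15.0, DOC=1.0, POC=1.0, DO=params.h_o)
        _, f_O = respiration(state_factory(), f, params, BCD=1.0)
        assert f_O == pytest.approx(0.5)

    def test_worked_example(self):
        p = ModelParams(b_B=0.01, gamma_a=0.5, gamma_o=0.2)
        s = BacterialState(B=50.0, B_DOC=25.0, B_POC=25.0, phi_DOC=0.5)
        f = EnvForcing(T=p.T_ref, DOC=10.0, POC=10.0, DO=1e5)
        R, _ = respiration(s, f, p, BCD=10.0)
        assert R == pytest.approx(5.5, rel=1e-6)
        assert 1 - R / 10.0 == pytest.approx(0.45, rel=1e-5)

    def test_low_oxygen_modes_differ(self, state_factory):
        s = state_factory(B=1.0)
        f = EnvForcing(T=15.0, DOC=5.0, POC=5.0, DO=1.0)  # anoxic-ish
        p_default = ModelParams(oxygen_mode="low_oxygen_extra")
        p_printed = ModelParams(oxygen_mode="as_printed")
        R_default, _ = respiration(s, f, p_default, BCD=4.0)
        R_printed, _ = respiration(s, f, p_printed, BCD=4.0)
        # default: extra cost at low oxygen; printed form barely adds anything
        assert R_default > R_printed

    @given(conc, st.floats(0, 30), st.floats(0, 500), st.floats(0, 20))
    def test_floor_is_basal_respiration(self, B, T, DO, BCD):
        p = ModelParams()
        s = partition_biomass(B, 1.0, 1.0)
        f = EnvForcing(T=T, DOC=1.0, POC=1.0, DO=DO)
        R, f_O = respiration(s, f, p, BCD=BCD)
        f_T = temperature_factor(T, p.Q10_B)
        assert R >= p.b_B * f_T * B - 1e-12
        assert 0.0 <= f_O <= 1.0


class TestGrazing:
    def test_no_prey(self, params):
        s = partition_biomass(0.0, 1.0, 1.0)
        f = EnvForcing(T=15.0, DOC=1.0, POC=1.0, Z=2.0, P=0.0)
        G, F_c, e = grazing(s, f, params)
        assert G == 0.0

    def test_half_saturation_of_total_uptake(self):
        p = ModelParams(mu_Z=0.0, h_ZF=1.0, delta_ZB=1.0, r_Z0=2.0)
        # with mu_Z = 0 capture efficiency is 1 and F_c = B
        s = partition_biomass(1.0, 1.0, 1.0)  # F_c = h_ZF
        f = EnvForcing(T=p.T_ref, DOC=1.0, POC=1.0, Z=3.0, P=0.0)
        G, F_c, e = grazing(s, f, p)
        assert F_c == pytest.approx(1.0)
        assert G == pytest.approx(0.5 * p.r_Z0 * f.Z)

    def test_worked_example(self):
        p = ModelParams(r_Z0=2.0, delta_ZB=1.0, mu_Z=1.0, h_ZF=0.5)
        s = partition_biomass(1.0, 1.0, 0.0)
        f = EnvForcing(T=p.T_ref, DOC=1.0, POC=0.0, Z=1.0, P=0.0)
        G, F_c, e = grazing(s, f, p)
        assert e == pytest.approx(0.5)
        assert F_c == pytest.approx(0.5)
        assert G == pytest.approx(1.0)

    @given(conc, st.floats(0, 20), st.floats(0, 20))
    def test_bounded_by_potential_ingestion(self, B, Z1, Z2):
        p = ModelParams()
        s = partition_biomass(B, 1.0, 1.0)
        f1 = EnvForcing(T=12.0, DOC=1.0, POC=1.0, Z=Z1, P=0.5)
        f2 = EnvForcing(T=12.0, DOC=1.0, POC=1.0, Z=Z2, P=0.5)
        f_T_Z = temperature_factor(12.0, p.Q10_Z)
        G1, _, _ = grazing(s, f1, p)
        G2, _, _ = grazing(s, f2, p)
        assert G1 <= p.r_Z0 * f_T_Z * Z1 + 1e-12
        if Z1 <= Z2:
            assert G1 <= G2 + 1e-12


class TestMortality:
    def test_zero_biomass(self, params):
        s = partition_biomass(0.0, 1.0, 1.0)
        assert mortality(s, EnvForcing(T=20.0, DOC=1.0, POC=1.0), params) == 0.0

    def test_reference_temperature(self, params):
        s = partition_biomass(8.0, 1.0, 1.0)
        f = EnvForcing(T=params.T_ref, DOC=1.0, POC=1.0)
        assert mortality(s, f, params) == pytest.approx(params.d_B * 8.0)

    def test_worked_example(self):
        p = ModelParams(d_B=0.05, Q10_B=2.0)
        s = partition_biomass(40.0, 1.0, 1.0)
        f = EnvForcing(T=20.0, DOC=1.0, POC=1.0)  # f_T = 2
        assert mortality(s, f, p) == pytest.approx(4.0)


class TestTendency:
    def test_all_zero_at_zero_biomass(self, params):
        s = partition_biomass(0.0, 5.0, 5.0)
        f = EnvForcing(T=15.0, DOC=5.0, POC=5.0, Z=1.0, P=1.0, z=10.0)
        d = tendency(s, f, params)
        for name in ("BCD", "R", "BP", "G", "M", "dBdt"):
            assert getattr(d, name) == pytest.approx(0.0)
        assert np.isnan(d.BGE)

    def test_composed_against_pieces(self, params, oxic_forcing):
        s = partition_biomass(3.0, oxic_forcing.DOC, oxic_forcing.POC)
        d = tendency(s, oxic_forcing, params)
        bcd_doc = doc_uptake(s, oxic_forcing, params)
        bcd_poc = poc_uptake(s, oxic_forcing, params)
        R, _ = respiration(s, oxic_forcing, params, bcd_doc + bcd_poc)
        G, _, _ = grazing(s, oxic_forcing, params)
        M = mortality(s, oxic_forcing, params)
        assert d.BCD == pytest.approx(bcd_doc + bcd_poc, rel=1e-12)
        assert d.BP == pytest.approx(bcd_doc + bcd_poc - R, rel=1e-12)
        assert d.dBdt == pytest.approx(d.BP - G - M, rel=1e-12)

    @given(pos, conc, conc, st.floats(0, 30), conc, conc, st.floats(0, 200))
    @settings(max_examples=150)
    def test_conservation_identities(self, B, DOC, POC, T, Z, P, z):
        p = ModelParams()
        s = partition_biomass(B, DOC, POC)
        f = EnvForcing(T=T, DOC=DOC, POC=POC, DO=250.0, Z=Z, P=P, z=z)
        d = tendency(s, f, p)
        scale = max(abs(float(d.BCD)), 1.0)
        assert abs(float(d.BCD) - float(d.BCD_DOC) - float(d.BCD_POC)) <= 1e-10 * scale
        assert abs(float(d.BP) - (float(d.BCD) - float(d.R))) <= 1e-10 * scale
        assert abs(float(d.dBdt) - (float(d.BP) - float(d.G) - float(d.M))) <= 1e-10 * scale
        for factor in (d.f_DOC, d.f_POC, d.f_depth, d.f_O, d.e_ZB, d.e_ZP):
            assert -1e-12 <= float(factor) <= 1 + 1e-12

    def test_production_split_proportional_to_demand(self, params, oxic_forcing):
        s = partition_biomass(2.0, oxic_forcing.DOC, oxic_forcing.POC)
        d = tendency(s, oxic_forcing, params)
        assert float(d.BP_DOC) == pytest.approx(float(d.BGE) * float(d.BCD_DOC))
        assert float(d.BP_POC) == pytest.approx(float(d.BGE) * float(d.BCD_POC))
        assert float(d.BP_DOC) + float(d.BP_POC) == pytest.approx(float(d.BP))

    def test_vectorized_matches_scalar(self, params):
        T = np.array([5.0, 15.0, 25.0])
        DOC = np.array([1.0, 3.0, 9.0])
        POC = np.array([8.0, 4.0, 2.0])
        s = partition_biomass(np.full(3, 2.0), DOC, POC)
        f = EnvForcing(T=T, DOC=DOC, POC=POC, DO=250.0, Z=0.5, P=1.0, z=20.0)
        d = tendency(s, f, params)
        for i in range(3):
            si = partition_biomass(2.0, DOC[i], POC[i])
            fi = EnvForcing(T=T[i], DOC=DOC[i], POC=POC[i], DO=250.0, Z=0.5, P=1.0, z=20.0)
            di = tendency(si, fi, params)
            assert float(np.asarray(d.dBdt)[i]) == pytest.approx(float(di.dBdt), rel=1e-12)


class TestIntegrate:
    def test_to_steady_reaches_balance(self, params, oxic_forcing):
        s0 = partition_biomass(0.5, oxic_forcing.DOC, oxic_forcing.POC)
        res = integrate(s0, oxic_forcing, params, dt=0.1, mode="to_steady")
        assert res.converged
        d = res.final_diagnostics
        assert abs(float(d.BP) - float(d.G) - float(d.M)) < 1e-4

    def test_no_sinks_strictly_increasing(self, oxic_forcing):
        p = ModelParams(d_B=0.0)
        f = EnvForcing(T=15.0, DOC=1.0, POC=10.0, DO=250.0, Z=0.0, P=0.0, z=25.0)
        s0 = partition_biomass(0.5, f.DOC, f.POC)
        res = integrate(s0, [f] * 50, p, dt=0.1, mode="transient")
        traj = [float(s.B) for s in res.states]
        assert all(b2 > b1 for b1, b2 in zip(traj, traj[1:]))

    def test_dt_refinement(self, params, oxic_forcing):
        s0 = partition_biomass(0.5, oxic_forcing.DOC, oxic_forcing.POC)
        b_coarse = float(integrate(s0, oxic_forcing, params, dt=0.1,
                                   mode="to_steady").final_state.B)
        b_fine = float(integrate(s0, oxic_forcing, params, dt=0.05,
                                 mode="to_steady").final_state.B)
        assert abs(b_fine - b_coarse) / b_coarse < 1e-3

    def test_nonconvergence_flagged(self, params):
        # abundant DOC: free-living growth is supercritical, no steady state
        f = EnvForcing(T=25.0, DOC=50.0, POC=5.0, DO=250.0, Z=0.1, P=0.1, z=10.0)
        s0 = partition_biomass(0.5, f.DOC, f.POC)
        res = integrate(s0, f, params, dt=0.1, mode="to_steady",
                        max_steps=200, B_cap=100.0)
        assert not res.converged

    def test_bad_arguments(self, params, oxic_forcing, state_factory):
        with pytest.raises(ValueError):
            integrate(state_factory(), oxic_forcing, params, dt=0.0)
        with pytest.raises(ValueError):
            integrate(state_factory(), [], params)
        with pytest.raises(ValueError):
            integrate(state_factory(), oxic_forcing, params, mode="bogus")


class TestSteadyStateSolver:
    def test_matches_euler(self, params, oxic_forcing):
        B, conv = steady_state_biomass(oxic_forcing, params)
        assert conv
        s0 = partition_biomass(0.5, oxic_forcing.DOC, oxic_forcing.POC)
        res = integrate(s0, oxic_forcing, params, dt=0.02, mode="to_steady")
        assert float(B) == pytest.approx(float(res.final_state.B), rel=1e-3)

    def test_supercritical_flagged(self, params):
        f = EnvForcing(T=25.0, DOC=50.0, POC=5.0, DO=250.0, Z=0.1, P=0.1, z=10.0)
        B, conv = steady_state_biomass(f, params, B_cap=50.0)
        assert not conv
        assert float(B) == 50.0

    def test_oxic_bge_identity(self, params, oxic_forcing):
        B, conv = steady_state_biomass(oxic_forcing, params)
        assert conv
        s = partition_biomass(B, oxic_forcing.DOC, oxic_forcing.POC)
        d = tendency(s, oxic_forcing, params)
        f_T = temperature_factor(oxic_forcing.T, params.Q10_B)
        expect = 1.0 - params.gamma_a - params.b_B * f_T * float(B) / float(d.BCD)
        # the residual low-oxygen term at DO = 250 is O(1e-5) of BGE
        assert float(d.BGE) == pytest.approx(expect, abs=1e-4)


class TestParamValidation:
    def test_respiration_fractions(self):
        with pytest.raises(ValueError):
            ModelParams(gamma_a=0.7, gamma_o=0.4)

    def test_negative_rate(self):
        with pytest.raises(ValueError):
            ModelParams(d_B=-0.1)

    def test_positive_depth_exponent(self):
        with pytest.raises(ValueError):
            ModelParams(b_exp=0.5)

    def test_bad_oxygen_mode(self):
        with pytest.raises(ValueError):
            ModelParams(oxygen_mode="sometimes")
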