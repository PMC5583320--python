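"""Patient-model right-hand sides: oracle cross-checks and conservation."""

import numpy as np
import pytest

import pbutkin as pk
from pbutkin import presets
from pbutkin.patient import (FlowSettings, PatientState, ToxinParameters,
                             UreaParameters, UreaState, patient_rhs_array,
                             urea_rhs_array)
from pbutkin.simulator import _simulate_patient_only
from pbutkin.units import InvalidParameterError


def oracle_rhs(y, V_ic, G_mg, mw, kip_ml, kic_ml, k1, k2, qp_ml, quf_ml, inlet):
    """Independent mass-balance oracle, written as explicit d(V*C)/dt
    bookkeeping and converted to concentration form at the end."""
    T_pl, PT_pl, P_pl, T_is, PT_is, P_is, T_ic, V_pl, V_is = y
    T_out, PT_out, P_out = inlet
    qp, quf = qp_ml / 1e3, quf_ml / 1e3
    kip, kic = kip_ml / 1e3, kic_ml / 1e3
    g = G_mg / (1e3 * mw)
    a = V_is / (V_is + V_pl)

    assoc_pl = k1 * P_pl * T_pl * V_pl
    dissoc_pl = k2 * PT_pl * V_pl
    assoc_is = k1 * P_is * T_is * V_is
    dissoc_is = k2 * PT_is * V_is

    dm = {
        "T_pl": -qp * T_pl + (qp - quf) * T_out + kip * (T_is - T_pl)
                + a * quf * T_is - assoc_pl + dissoc_pl,
        "PT_pl": -qp * PT_pl + (qp - quf) * PT_out + assoc_pl - dissoc_pl,
        "P_pl": -qp * P_pl + (qp - quf) * P_out - assoc_pl + dissoc_pl,
        "T_is": kic * (T_ic - T_is) - kip * (T_is - T_pl) - a * quf * T_is
                - assoc_is + dissoc_is,
        "PT_is": assoc_is - dissoc_is,
        "P_is": -assoc_is + dissoc_is,
        "T_ic": g - kic * (T_ic - T_is),
    }
    dV_pl, dV_is = -(1 - a) * quf, -a * quf
    return np.array([
        (dm["T_pl"] - T_pl * dV_pl) / V_pl,
        (dm["PT_pl"] - PT_pl * dV_pl) / V_pl,
        (dm["P_pl"] - P_pl * dV_pl) / V_pl,
        (dm["T_is"] - T_is * dV_is) / V_is,
        (dm["PT_is"] - PT_is * dV_is) / V_is,
        (dm["P_is"] - P_is * dV_is) / V_is,
        dm["T_ic"] / V_ic,
        dV_pl, dV_is,
    ])


class TestPatientRHS:
    def test_matches_independent_oracle_on_random_states(self):
        rng = np.random.default_rng(7)
        mw = 213.21
        for _ in range(20):
            y = np.concatenate([rng.uniform(1e-7, 1e-3, 6),
                                rng.uniform(1e-7, 1e-3, 1),
                                rng.uniform(1.0, 5.0, 1),
                                rng.uniform(5.0, 15.0, 1)])
            inlet = tuple(rng.uniform(0, 1e-3, 3))
            G, kip, kic = rng.uniform(0, 0.1), rng.uniform(0, 2000), rng.uniform(0, 500)
            k1, ka = rng.uniform(1e2, 1e7), rng.uniform(1e1, 1e6)
            qp, quf = rng.uniform(50, 400), rng.uniform(0, 15)
            params = ToxinParameters(G=G, K_ip_T=kip, K_ic_T=kic,
                                     binding=pk.BindingParameters.from_k1_KA(k1, ka))
            sp = pk.Species("x", molecular_weight=mw, binding_degree_0=0.5,
                            c_total_0=1.0)
            got = patient_rhs_array(y, 25.9, params, sp,
                                    FlowSettings(Q_p=qp, Q_uf=quf), inlet)
            want = oracle_rhs(y, 25.9, G, mw, kip, kic, k1, k1 / ka, qp, quf, inlet)
            np.testing.assert_allclose(got, want, rtol=1e-12, atol=1e-20)

    def test_equilibrium_state_is_stationary(self, albumin):
        # G=0, no UF, dialyzer bypassed, binding equilibrated and free
        # concentration uniform: every derivative vanishes
        st0 = presets.calibrated_patient_state("IS")
        params = presets.calibrated_parameters("IS")
        params = ToxinParameters(G=0.0, K_ip_T=params.K_ip_T,
                                 K_ic_T=params.K_ic_T, binding=params.binding)
        sp = presets.calibrated_species("IS")
        dy = pk.patient_rhs(st0, params, sp, FlowSettings(Q_p=189.0, Q_uf=0.0))
        scale = max(st0.T_pl, st0.PT_pl, st0.P_pl)
        assert abs(dy.T_pl) < 1e-12 * scale
        assert abs(dy.PT_is) < 1e-9 * scale
        assert abs(dy.T_ic) < 1e-12 * scale
        assert dy.V_pl == 0.0 and dy.V_is == 0.0

    def test_negative_concentration_guard(self):
        st0 = presets.calibrated_patient_state("IS")
        st0.T_pl = -1e-9
        params = presets.calibrated_parameters("IS")
        sp = presets.calibrated_species("IS")
        with pytest.raises(InvalidParameterError):
            pk.patient_rhs(st0, params, sp, FlowSettings(Q_p=189.0))


class TestVolumeRHS:
    def test_no_uf_is_static(self):
        st0 = presets.calibrated_patient_state("pCG")
        assert pk.volume_rhs(st0, 0.0) == (0.0, 0.0)

    def test_reference_split(self):
        # V_pl 2.4, V_is 10.5 -> alpha = 10.5/12.9; at Quf 8.3 mL/min
        # plasma loses (1-alpha)*Quf ~ 1.545e-3 L/min
        st0 = presets.calibrated_patient_state("pCG")
        dvpl, dvis = pk.volume_rhs(st0, 8.3)
        alpha = 10.5 / 12.9
        assert dvpl == pytest.approx(-(1 - alpha) * 8.3e-3, rel=1e-12)
        assert dvis == pytest.approx(-alpha * 8.3e-3, rel=1e-12)

    def test_total_volume_loss_equals_uf(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            st0 = presets.calibrated_patient_state("IS")
            st0.V_pl, st0.V_is = rng.uniform(1, 5), rng.uniform(5, 15)
            quf = rng.uniform(0, 20)
            dvpl, dvis = pk.volume_rhs(st0, quf)
            assert dvpl + dvis == pytest.approx(-quf / 1e3, rel=1e-12)

    def test_alpha_is_constant_along_the_uf_trajectory(self):
        # dV_is/dV_pl = alpha/(1-alpha) = V_is/V_pl, so the ratio (and
        # hence alpha) is invariant under the volume dynamics
        st = presets.calibrated_patient_state("pCG")
        ratio0 = st.V_is / st.V_pl
        quf = 2000.0 / 240.0
        dt = 0.5
        for _ in range(480):
            dvpl, dvis = pk.volume_rhs(st, quf)
            st.V_pl += dvpl * dt
            st.V_is += dvis * dt
        assert st.V_is / st.V_pl == pytest.approx(ratio0, rel=1e-9)
        assert st.V_pl + st.V_is == pytest.approx(12.9 - 2.0, rel=1e-9)


class TestMassConservation:
    def test_closed_patient_conserves_toxin_mass(self):
        # dialyzer bypass, G=0, Quf=0: whole-body toxin and albumin
        # amounts are integrals of motion over a 240-min integration
        sp = presets.calibrated_species("pCS")
        p = presets.calibrated_parameters("pCS")
        params = ToxinParameters(G=0.0, K_ip_T=p.K_ip_T, K_ic_T=p.K_ic_T,
                                 binding=p.binding)
        st0 = presets.calibrated_patient_state("pCS")
        st0.T_ic *= 2.0  # perturb so the run is not trivially stationary
        res = _simulate_patient_only(st0, params, sp, 240.0)
        m = res.toxin_mass_series()
        np.testing.assert_allclose(m, m[0], rtol=1e-8)
        alb = [res.patient_state(i).albumin_mass() for i in (0, len(res.t) - 1)]
        assert alb[1] == pytest.approx(alb[0], rel=1e-10)

    def test_relaxation_restores_equilibrium_in_both_pools(self):
        sp = presets.calibrated_species("IS")
        p = presets.calibrated_parameters("IS")
        params = ToxinParameters(G=0.0, K_ip_T=p.K_ip_T, K_ic_T=p.K_ic_T,
                                 binding=p.binding)
        st0 = presets.calibrated_patient_state("IS")
        st0.T_pl *= 0.5   # knock plasma off equilibrium
        res = _simulate_patient_only(st0, params, sp, 2000.0)
        end = res.final_state
        ka = params.binding.K_A
        assert end.PT_pl / (end.P_pl * end.T_pl) == pytest.approx(ka, rel=1e-8)
        assert end.PT_is / (end.P_is * end.T_is) == pytest.approx(ka, rel=1e-8)
        assert end.T_pl == pytest.approx(end.T_is, rel=1e-6)
        assert end.T_pl == pytest.approx(end.T_ic, rel=1e-6)


class TestUreaModel:
    def test_equilibrated_idle_state_is_stationary(self):
        params = UreaParameters(G=0.0, K_ic_T=363.0, K_D=224.0)
        y = np.array([800.0, 800.0, 12.9])
        dy = urea_rhs_array(y, 25.9, params, 0.0, dialysis_on=False)
        np.testing.assert_allclose(dy, 0.0, atol=1e-14)

    def test_fast_exchange_limit_matches_single_pool_decay(self):
        # K_ic -> large collapses the two pools to one with clearance
        # K_D: C(t) = C0 * exp(-K_D*t/V_total) at Quf = 0
        params = UreaParameters(G=0.0, K_ic_T=1e7, K_D=224.0)
        st0 = UreaState(C_ex=1000.0, C_ic=1000.0, V_ex=12.9, V_ic=25.9)
        from dataclasses import replace
        cfg = replace(presets.DEFAULT_SESSION, UF_volume=0.0)
        res = pk.simulate_urea_session(st0, params, cfg)
        v_tot = 12.9 + 25.9
        expected = 1000.0 * np.exp(-0.224 * res.t / v_tot)
        np.testing.assert_allclose(res.C_ex, expected, rtol=1e-5)

    def test_two_pool_lag_extracellular_falls_faster(self):
        params = presets.calibrated_urea_parameters()
        res = pk.simulate_urea_session(presets.urea_state(900.0), params,
                                       presets.DEFAULT_SESSION)
        assert res.C_ex[-1] < res.C_ic[-1]
        assert np.all(np.diff(res.C_ex[:60]) < 0)

    def test_generation_compartment_is_selectable(self):
        with pytest.raises(InvalidParameterError):
            UreaParameters(G=1.0, K_ic_T=363.0, K_D=224.0,
                           generation_compartment="plasma")
        p_ic = UreaParameters(G=8.17, K_ic_T=363.0, K_D=224.0,
                              generation_compartment="intracellular")
        y = np.array([800.0, 800.0, 12.9])
        dy = urea_rhs_array(y, 25.9, p_ic, 0.0, dialysis_on=False)
        assert dy[1] > 0 and dy[0] == pytest.approx(0.0, abs=1e-14)
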