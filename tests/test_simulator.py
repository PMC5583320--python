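"""Coupled session, rebound, inter-dialytic and reservoir simulations."""

from dataclasses import replace

import numpy as np
import pytest

import pbutkin as pk
from pbutkin import presets
from conftest import run_calibrated_session


class TestSession:
    def test_plasma_total_falls_and_removal_accumulates(self, pcg_session):
        tot = pcg_session.plasma_total
        assert np.all(np.diff(tot) < 0)
        assert np.all(np.diff(pcg_session.removed_mg) >= 0)
        assert np.all(pcg_session.patient >= -1e-12)

    def test_free_rr_exceeds_total_rr_once_circuit_equilibrates(self, pcg_session):
        # the toxin-free primed dialyzer transiently dilutes plasma
        # albumin and lowers the bound fraction; past that transient the
        # free-concentration RR stays above the total-concentration RR
        i = pcg_session.at_time(120.0)
        rr_t = pk.rr_series(pcg_session)
        rr_f = pk.rr_series(pcg_session, free=True)
        assert np.all(rr_f[i:] >= rr_t[i:])

    def test_bound_fraction_increases_over_the_session(self, is_session):
        bf = pk.bound_fraction_series(is_session)
        assert bf[-1] > bf[0]
        assert np.all(np.diff(bf[5:]) > -1e-10)

    def test_albumin_is_conserved_while_its_concentration_rises(self, pcg_session):
        cfg = pcg_session.config
        op = pk.DialyzerOperator(pcg_session.geometry, cfg.Q_p, cfg.Q_d,
                                 cfg.Q_uf, n_x=cfg.n_x,
                                 binding=pcg_session.params.binding)
        alb0 = pcg_session.initial_state.albumin_mass()
        alb1 = (pcg_session.final_state.albumin_mass()
                + op.protein_holdup_mass(pcg_session.dialyzer_state(-1)))
        assert alb1 == pytest.approx(alb0, rel=1e-8)
        # protein is non-dialyzable: UF concentrates it
        p_tot = pcg_session.patient[:, 1] + pcg_session.patient[:, 2]
        assert p_tot[-1] > p_tot[0]

    def test_mass_audit_closes(self, pcg_session):
        audit = pk.mass_audit(pcg_session)
        assert audit["relative_error"] < 5e-3

    def test_no_removal_when_membrane_is_closed(self):
        sp = presets.calibrated_species("pCG")
        p = presets.calibrated_parameters("pCG")
        st0 = presets.calibrated_patient_state("pCG")
        geom = pk.dialyzer_preset("F180NR", koa=1e-9)
        cfg = replace(presets.DEFAULT_SESSION, UF_volume=0.0, n_x=15,
                      duration=60.0)
        res = pk.simulate_session(st0, p, sp, geom, cfg)
        # generation is the only mass source; plasma only accrues it
        m = res.toxin_mass_series()
        g_mol = p.G / (1000.0 * sp.molecular_weight)
        holdup = pk.DialyzerOperator(geom, cfg.Q_p, cfg.Q_d, 0.0, 15,
                                     binding=p.binding).holdup_mass(
            res.dialyzer_state(-1))
        assert m[-1] + holdup - m[0] == pytest.approx(g_mol * 60.0, rel=1e-3)
        assert res.removed_mg[-1] == pytest.approx(0.0, abs=1e-9)

    def test_trajectories_are_bit_identical_across_runs(self, session_cfg):
        a = run_calibrated_session("IAA", session_cfg)
        b = run_calibrated_session("IAA", session_cfg)
        np.testing.assert_array_equal(a.patient, b.patient)
        np.testing.assert_array_equal(a.removed_mg, b.removed_mg)

    def test_rr_monotone_in_koa_qd_qb(self):
        sp = presets.calibrated_species("IS")
        p = presets.calibrated_parameters("IS")
        st0 = presets.calibrated_patient_state("IS")
        base = replace(presets.DEFAULT_SESSION, n_x=15, duration=120.0)

        def rr(koa=600.0, qb=300.0, qd=700.0):
            geom = pk.dialyzer_preset("F180NR", koa=koa)
            cfg = replace(base, Q_b=qb, Q_d=qd)
            res = pk.simulate_session(st0, p, sp, geom, cfg)
            return pk.rr_series(res)[-1]

        r0 = rr()
        assert rr(koa=900.0) > r0
        assert rr(qd=900.0) > r0
        assert rr(qb=400.0) > r0


class TestReboundAndInterval:
    def test_equilibrated_state_without_generation_stays_put(self):
        sp = presets.calibrated_species("IS")
        p = presets.calibrated_parameters("IS")
        p0 = pk.ToxinParameters(G=0.0, K_ip_T=p.K_ip_T, K_ic_T=p.K_ic_T,
                                binding=p.binding)
        st0 = presets.calibrated_patient_state("IS")
        res = pk.simulate_rebound(st0, p0, sp, duration=60.0)
        np.testing.assert_allclose(res.plasma_total,
                                   res.plasma_total[0], rtol=1e-9)

    def test_pcg_plasma_rebounds_sharply_and_mass_is_accounted(self, pcg_session):
        p = pcg_session.params
        sp = pcg_session.species
        reb = pk.simulate_rebound(pcg_session.final_state, p, sp, duration=120.0)
        assert reb.plasma_total[-1] > 1.2 * reb.plasma_total[0]
        m = reb.toxin_mass_series()
        g_mol = p.G / (1000.0 * sp.molecular_weight)
        assert m[-1] - m[0] == pytest.approx(g_mol * reb.t[-1], rel=1e-6)

    def test_interval_restores_volumes_after_matching_intake(self, pcg_session):
        nxt = pk.simulate_interdialytic(pcg_session.final_state,
                                        pcg_session.params,
                                        pcg_session.species,
                                        interval=44.0 * 60.0, intake_volume=2.0)
        st0 = pcg_session.initial_state
        assert nxt.V_pl + nxt.V_is == pytest.approx(st0.V_pl + st0.V_is, rel=1e-9)

    def test_interval_without_generation_only_dilutes(self):
        sp = presets.calibrated_species("pCG")
        p = presets.calibrated_parameters("pCG")
        p0 = pk.ToxinParameters(G=0.0, K_ip_T=p.K_ip_T, K_ic_T=p.K_ic_T,
                                binding=p.binding)
        st0 = presets.calibrated_patient_state("pCG")
        m0 = st0.toxin_mass()
        nxt = pk.simulate_interdialytic(st0, p0, sp, interval=600.0,
                                        intake_volume=1.5)
        assert nxt.toxin_mass() == pytest.approx(m0, rel=1e-7)
        assert nxt.plasma_total < st0.plasma_total


class TestInVitroReservoir:
    def test_closed_membrane_keeps_reservoir_flat(self):
        sp = pk.Species("x", molecular_weight=354.38, binding_degree_0=0.0,
                        c_total_0=20.0)
        params = pk.ToxinParameters(G=0.0, K_ip_T=0.0, K_ic_T=0.0, binding=None)
        geom = pk.dialyzer_preset("F6", koa=1e-9)
        cfg = pk.SessionConfig(duration=60.0, Q_b=200.0, Q_d=300.0,
                               UF_volume=0.0, hematocrit=0.0,
                               mode="in_vitro_reservoir", n_x=15)
        res = pk.simulate_in_vitro_reservoir((sp.c_total_0_molar, 0.0, 0.0),
                                             4.5, params, sp, geom, cfg)
        # after the primed circuit fills (a ~70 mL blood-side holdup),
        # the reservoir concentration is flat and nothing is removed
        np.testing.assert_allclose(res.plasma_total[5:], res.plasma_total[5],
                                   rtol=1e-8)
        # KoA = 1e-9 mL/min still leaks ~KoA*C*t ~ 1e-9 mg; bound covers it
        assert res.removed_mg[-1] == pytest.approx(0.0, abs=1e-8)

    def test_unbound_solute_decays_like_single_pool_clearance(self):
        # no binding: reservoir follows C0*exp(-Cl*t/V) with Cl the
        # dialyzer's steady clearance at the same discretization
        from pbutkin.dialyzer import steady_state_clearance
        sp = pk.Species("x", molecular_weight=100.0, binding_degree_0=0.0,
                        c_total_0=10.0)
        params = pk.ToxinParameters(G=0.0, K_ip_T=0.0, K_ic_T=0.0, binding=None)
        geom = pk.dialyzer_preset("F6", koa=300.0)
        n_x = 60
        cfg = pk.SessionConfig(duration=120.0, Q_b=200.0, Q_d=300.0,
                               UF_volume=0.0, hematocrit=0.0,
                               mode="in_vitro_reservoir", n_x=n_x)
        res = pk.simulate_in_vitro_reservoir((sp.c_total_0_molar, 0.0, 0.0),
                                             4.5, params, sp, geom, cfg)
        cl = steady_state_clearance(geom, 200.0, 300.0, 0.0, n_x=n_x,
                                    settle_min=10.0)
        # the ~0.23 L circuit holdup acts as extra distribution volume,
        # so the single-pool closed form holds to a few percent
        expected = res.plasma_total[0] * np.exp(-cl / 1000.0 * res.t / 4.5)
        np.testing.assert_allclose(res.plasma_total[5:], expected[5:], rtol=3e-2)
        cl_cf = pk.clearance_from_koa(1.0, 200.0, 300.0, 300.0)
        assert cl == pytest.approx(cl_cf, rel=1e-2)
        # the decay slope over a late window pins the clearance tightly
        i1, i2 = res.at_time(60.0), res.at_time(120.0)
        slope = np.log(res.plasma_total[i1] / res.plasma_total[i2]) / 60.0
        assert slope == pytest.approx(cl / 1000.0 / 4.5, rel=6e-2)


class TestSweep:
    def test_single_point_grid_matches_direct_session(self, session_cfg):
        sp = presets.calibrated_species("IAA")
        p = presets.calibrated_parameters("IAA")
        st0 = presets.calibrated_patient_state("IAA")
        geom = pk.dialyzer_preset("F180NR")
        cfg = replace(session_cfg, n_x=15, duration=120.0)
        grid = pk.sweep_flows(st0, p, sp, geom, cfg, [300.0], [700.0])
        assert len(grid) == 1
        res = pk.simulate_session(st0, p, sp, geom, cfg)
        assert grid.rr_total.iloc[0] == pytest.approx(pk.rr_series(res)[-1],
                                                      rel=1e-12)
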