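"""End-to-end preset scenarios.

Each preset resolves to a complete, self-contained simulation study
using the calibrated reference-patient presets — no external data — and
returns a bundle of tidy DataFrames plus a metrics dict.  Presets:

``calibration_baseline``
    One four-hour session per PBUT plus the two-pool urea comparator;
    reduction ratios and relative removal per solute.
``binding_dynamics``
    Intra-dialytic plasma bound-fraction time courses, run at the
    clinical low/mid/high initial bound fractions per toxin.
``inlet_outlet_binding``
    Bound fraction at the dialyzer blood inlet vs outlet at 120 min.
``rr_time_course``
    Reduction-ratio time courses for free and total concentration.
``invitro_phenolred``
    Bench reservoir runs of phenol red through small/large dialyzers at
    two dialysate flows (KoA inverted from measured clearances).
``profiles_rebound``
    Compartmental concentration profiles during dialysis and 120 min of
    post-dialysis rebound.
``flow_sweep``
    Total-concentration RR over a (Q_b, Q_d) grid per toxin.
``pcg_counterfactual``
    pCG with its intracellular mass transfer coefficient raised to the
    urea value (363 mL/min).
"""

from __future__ import annotations

import json
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import presets
from .binding import BindingParameters
from .dialyzer import dialyzer_preset
from .metrics import (inlet_outlet_binding, koa_from_clearance, relative_removal,
                      rr_series, session_metrics, urea_reduction_ratio,
                      urea_relative_removal)
from .calibration import SAMPLE_TIMES, urea_predialysis_for_generation
from .patient import ToxinParameters
from .simulator import (SessionConfig, simulate_in_vitro_reservoir,
                        simulate_rebound, simulate_session,
                        simulate_urea_session, sweep_flows)
from .species import Species

SCENARIO_NAMES = (
    "calibration_baseline", "binding_dynamics", "inlet_outlet_binding",
    "rr_time_course", "invitro_phenolred", "profiles_rebound",
    "flow_sweep", "pcg_counterfactual",
)

#: Bench phenol-red runs: (dialyzer preset, Q_d mL/min, measured
#: phenol-red clearance mL/min), labelled a-d in order of clearance.
PHENOL_RED_RUNS = {
    "a": ("F6", 300.0, 11.0),
    "b": ("F200NR", 300.0, 14.0),
    "c": ("F6", 750.0, 16.0),
    "d": ("F200NR", 750.0, 23.0),
}
PHENOL_RED_FREE_FRACTION = 0.06
PHENOL_RED_KA = 2.8e4            # M^-1
PHENOL_RED_QB = 200.0            # bench blood-side (plasma) flow, mL/min
PHENOL_RED_C0 = 20.0             # mg/L, bench pool loading
PHENOL_RED_DURATION = 120.0      # min
RESERVOIR_VOLUME = 4.5           # L


def _session_cfg(n_x: int, **overrides) -> SessionConfig:
    return replace(presets.DEFAULT_SESSION, n_x=n_x, **overrides)


def _run_pbut_session(name: str, n_x: int, binding_degree=None, K_ic_T=None,
                      **session_overrides):
    sp = presets.calibrated_species(name, binding_degree)
    params = presets.calibrated_parameters(name, binding_degree=binding_degree,
                                           K_ic_T=K_ic_T)
    state0 = presets.calibrated_patient_state(name, binding_degree=binding_degree)
    geom = dialyzer_preset("F180NR")
    cfg = _session_cfg(n_x, **session_overrides)
    return simulate_session(state0, params, sp, geom, cfg)


def run_scenario(name: str, out_dir: str | Path | None = None,
                 n_x: int = 100, **kwargs) -> dict:
    """Run one preset scenario; optionally write CSV/JSON outputs.

    Returns ``{"tables": {label: DataFrame}, "metrics": dict}``.
    """
    if name not in SCENARIO_NAMES:
        raise KeyError(f"unknown scenario {name!r}; choose from {SCENARIO_NAMES}")
    bundle = _SCENARIOS[name](n_x=n_x, **kwargs)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for label, df in bundle["tables"].items():
            df.to_csv(out / f"{name}_{label}.csv", index=False)
        (out / f"{name}_metrics.json").write_text(
            json.dumps(bundle["metrics"], indent=2))
    return bundle


def _calibration_baseline(n_x: int = 100) -> dict:
    metrics: dict = {}
    frames = []
    for name in presets.PBUT_NAMES:
        res = _run_pbut_session(name, n_x)
        metrics[name] = session_metrics(res)
        frames.append(res.to_dataframe())
    urea_params = presets.calibrated_urea_parameters()
    cfg = _session_cfg(n_x)
    c0 = urea_predialysis_for_generation(
        urea_params, cfg, interval=presets.INTERDIALYTIC_INTERVAL_MIN,
        intake_volume=presets.INTERDIALYTIC_INTAKE_L)
    ures = simulate_urea_session(presets.urea_state(c0), urea_params, cfg)
    metrics["urea"] = {
        "predialysis_mg_per_L": c0,
        "rr_total": urea_reduction_ratio(ures),
        "relative_removal": urea_relative_removal(ures),
    }
    return {"tables": {"trajectories": pd.concat(frames, ignore_index=True)},
            "metrics": metrics}


def _binding_dynamics(n_x: int = 100) -> dict:
    rows = []
    for name in presets.PBUT_NAMES:
        lo, hi = presets.TOXIN_PRESETS[name]["binding_range"]
        for bd in (lo, 0.5 * (lo + hi), hi):
            res = _run_pbut_session(name, n_x, binding_degree=bd)
            bf = np.interp(SAMPLE_TIMES, res.t, res.plasma_bound_fraction)
            for t, v in zip(SAMPLE_TIMES, bf):
                rows.append({"toxin": name, "binding_degree_0": bd,
                             "time_min": t, "bound_fraction": v})
    df = pd.DataFrame(rows)
    return {"tables": {"bound_fraction": df},
            "metrics": {"n_runs": int(df.groupby(["toxin", "binding_degree_0"]).ngroups)}}


def _inlet_outlet_binding(n_x: int = 100) -> dict:
    rows = []
    for name in presets.PBUT_NAMES:
        lo, hi = presets.TOXIN_PRESETS[name]["binding_range"]
        for bd in (lo, 0.5 * (lo + hi), hi):
            res = _run_pbut_session(name, n_x, binding_degree=bd)
            inlet, outlet = inlet_outlet_binding(res, 120.0)
            rows.append({"toxin": name, "binding_degree_0": bd,
                         "inlet_bound_fraction": inlet,
                         "outlet_bound_fraction": outlet})
    df = pd.DataFrame(rows)
    return {"tables": {"inlet_outlet": df},
            "metrics": {"outlet_exceeds_inlet": bool(
                (df.outlet_bound_fraction > df.inlet_bound_fraction).all())}}


def _rr_time_course(n_x: int = 100) -> dict:
    rows = []
    for name in presets.PBUT_NAMES:
        res = _run_pbut_session(name, n_x)
        rr_t = np.interp(SAMPLE_TIMES, res.t, rr_series(res))
        rr_f = np.interp(SAMPLE_TIMES, res.t, rr_series(res, free=True))
        for t, a, b in zip(SAMPLE_TIMES, rr_t, rr_f):
            rows.append({"toxin": name, "time_min": t,
                         "rr_total": a, "rr_free": b})
    return {"tables": {"rr": pd.DataFrame(rows)}, "metrics": {}}


def phenol_red_setup(run: str) -> tuple[Species, ToxinParameters, tuple, float]:
    """Species, parameters, initial reservoir triple and KoA for one
    bench phenol-red run (KoA inverted from the measured clearance)."""
    preset_name, qd, cl = PHENOL_RED_RUNS[run]
    koa = koa_from_clearance(cl, PHENOL_RED_FREE_FRACTION, PHENOL_RED_QB, qd)
    sp = Species(name="phenol_red", molecular_weight=354.38,
                 binding_degree_0=1.0 - PHENOL_RED_FREE_FRACTION,
                 c_total_0=PHENOL_RED_C0)
    t_tot = sp.c_total_0_molar
    T0 = PHENOL_RED_FREE_FRACTION * t_tot
    PT0 = t_tot - T0
    p_free = (1.0 - PHENOL_RED_FREE_FRACTION) / (PHENOL_RED_FREE_FRACTION
                                                 * PHENOL_RED_KA)
    # k1 borrowed from pCS (similar bound fraction); k2 from K_A
    params = ToxinParameters(
        G=0.0, K_ip_T=0.0, K_ic_T=0.0,
        binding=BindingParameters.from_k1_KA(presets.TOXIN_PRESETS["pCS"]["k1"],
                                             PHENOL_RED_KA))
    return sp, params, (T0, PT0, p_free), koa


def _invitro_phenolred(n_x: int = 100, runs=tuple(PHENOL_RED_RUNS)) -> dict:
    rows = []
    removal_120: dict[str, float] = {}
    for run in runs:
        preset_name, qd, cl = PHENOL_RED_RUNS[run]
        sp, params, triple, koa = phenol_red_setup(run)
        geom = dialyzer_preset(preset_name, koa=koa)
        cfg = SessionConfig(duration=PHENOL_RED_DURATION, Q_b=PHENOL_RED_QB,
                            Q_d=qd, UF_volume=0.0, hematocrit=0.0,
                            mode="in_vitro_reservoir", n_x=n_x,
                            reservoir_volume=RESERVOIR_VOLUME)
        res = simulate_in_vitro_reservoir(triple, RESERVOIR_VOLUME, params,
                                          sp, geom, cfg)
        tot = res.plasma_total
        removal_120[run] = float((tot[0] - tot[-1]) / tot[0])
        for t, c in zip(res.t, tot / tot[0]):
            rows.append({"run": run, "dialyzer": preset_name, "Q_d": qd,
                         "KoA": koa, "time_min": t, "c_rel": c})
    return {"tables": {"reservoir_decay": pd.DataFrame(rows)},
            "metrics": {"fractional_removal_120min": removal_120}}


def _profiles_rebound(n_x: int = 100, rebound_min: float = 120.0) -> dict:
    rows = []
    metrics = {}
    for name in presets.PBUT_NAMES:
        res = _run_pbut_session(name, n_x)
        reb = simulate_rebound(res.final_state, res.params, res.species,
                               duration=rebound_min)
        c0_tot = res.plasma_total[0]
        c0_free = res.plasma_free[0]
        for src, t_off in ((res, 0.0), (reb, res.t[-1])):
            for i, t in enumerate(src.t):
                st = src.patient_state(i)
                rows.append({
                    "toxin": name, "time_min": t + t_off,
                    "plasma_total_rel": st.plasma_total / c0_tot,
                    "interstitial_total_rel": (st.T_is + st.PT_is) / c0_tot,
                    "plasma_free_rel": st.T_pl / c0_free,
                    "interstitial_free_rel": st.T_is / c0_free,
                    "intracellular_free_rel": st.T_ic / c0_free,
                })
        end_session = res.plasma_total[-1]
        end_rebound = reb.plasma_total[-1]
        metrics[name] = {
            "rebound_rise_fraction": float((end_rebound - end_session)
                                           / end_session),
        }
    return {"tables": {"profiles": pd.DataFrame(rows)}, "metrics": metrics}


def _flow_sweep(n_x: int = 100, toxins=presets.PBUT_NAMES,
                Qb_range=(300.0, 400.0, 500.0),
                Qd_range=(500.0, 650.0, 800.0)) -> dict:
    frames = []
    metrics = {}
    geom = dialyzer_preset("F180NR")
    for name in toxins:
        sp = presets.calibrated_species(name)
        params = presets.calibrated_parameters(name)
        state0 = presets.calibrated_patient_state(name)
        grid = sweep_flows(state0, params, sp, geom, _session_cfg(n_x),
                           Qb_range, Qd_range)
        grid.insert(0, "toxin", name)
        frames.append(grid)
        # normalized full-range effects at the mid point of the other axis
        qb_mid, qd_mid = Qb_range[len(Qb_range) // 2], Qd_range[len(Qd_range) // 2]
        g = grid.set_index(["Q_b", "Q_d"]).rr_total
        eff_qb = g[(Qb_range[-1], qd_mid)] - g[(Qb_range[0], qd_mid)]
        eff_qd = g[(qb_mid, Qd_range[-1])] - g[(qb_mid, Qd_range[0])]
        metrics[name] = {"delta_rr_over_Qb_range": float(eff_qb),
                         "delta_rr_over_Qd_range": float(eff_qd)}
    return {"tables": {"rr_grid": pd.concat(frames, ignore_index=True)},
            "metrics": metrics}


def _pcg_counterfactual(n_x: int = 100, K_ic_T: float = 363.0) -> dict:
    base = _run_pbut_session("pCG", n_x)
    cf = _run_pbut_session("pCG", n_x, K_ic_T=K_ic_T)
    metrics = {
        "relative_removal_baseline": float(relative_removal(base)),
        "relative_removal_counterfactual": float(relative_removal(cf)),
        "K_ic_T_counterfactual": K_ic_T,
    }
    return {"tables": {}, "metrics": metrics}


_SCENARIOS = {
    "calibration_baseline": _calibration_baseline,
    "binding_dynamics": _binding_dynamics,
    "inlet_outlet_binding": _inlet_outlet_binding,
    "rr_time_course": _rr_time_course,
    "invitro_phenolred": _invitro_phenolred,
    "profiles_rebound": _profiles_rebound,
    "flow_sweep": _flow_sweep,
    "pcg_counterfactual": _pcg_counterfactual,
}
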