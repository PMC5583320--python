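"""Coupled patient-dialyzer simulations.

Modes:

* in-vivo session: three-compartment patient feeding the spatially
  resolved dialyzer at Qp, blood outlet returning at Qp - Quf,
* rebound: patient only, dialyzer bypassed, generation on,
* inter-dialytic interval: patient only, fluid ingestion reversing the
  session's volume loss,
* in-vitro reservoir: a well-mixed plasma pool replaces the patient
  (the bench configuration used for phenol-red validation),
* two-pool urea session (conventional fixed-clearance dialyzer),
* blood/dialysate flow sweeps.

The coupled ODE/PDE system is integrated as one stiff system (BDF with
a supplied Jacobian sparsity pattern); there is no hidden randomness,
identical configurations yield identical trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.sparse import lil_matrix

from .dialyzer import DialyzerGeometry, DialyzerOperator, DialyzerState
from .patient import (FlowSettings, PatientState, ToxinParameters, UreaParameters,
                      UreaState, patient_rhs_array, urea_rhs_array)
from .species import Species
from .units import (InvalidParameterError, ML_PER_L, MIN_PER_H,
                    generation_to_molar_rate, molar_to_mass,
                    plasma_flow_from_blood)

NPAT = 9  # dynamic patient variables


class IntegrationError(RuntimeError):
    """The stiff integrator failed; carries the solver message."""


@dataclass(frozen=True)
class SessionConfig:
    """One hemodialysis session (or bench run) configuration.

    duration : min; Q_b, Q_d : blood and dialysate flow, mL/min;
    UF_volume : total ultrafiltration volume, L (removed at constant
    rate); hematocrit : fraction; n_x : axial cells in the dialyzer
    grid; reservoir_volume : L (in-vitro mode).  rtol/atol are the
    stiff-integrator tolerances (atol applies to molar concentrations).
    """

    duration: float = 240.0
    Q_b: float = 300.0
    Q_d: float = 700.0
    UF_volume: float = 2.0
    hematocrit: float = 0.37
    mode: str = "in_vivo"
    n_x: int = 100
    reservoir_volume: float = 4.5
    intake_volume: float = 2.0
    output_dt: float = 1.0
    rtol: float = 1e-8
    atol: float = 1e-12

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise InvalidParameterError("duration must be > 0")
        if self.mode not in ("in_vivo", "in_vitro_reservoir", "rebound", "interdialytic"):
            raise InvalidParameterError(f"unknown mode {self.mode!r}")

    @property
    def Q_uf(self) -> float:
        """Constant ultrafiltration rate, mL/min."""
        return self.UF_volume * ML_PER_L / self.duration

    @property
    def Q_p(self) -> float:
        """Plasma flow entering the dialyzer, mL/min."""
        if self.mode == "in_vitro_reservoir":
            return self.Q_b  # artificial plasma: no cells
        return plasma_flow_from_blood(self.Q_b, self.hematocrit)

    def output_grid(self) -> np.ndarray:
        t = np.arange(0.0, self.duration + 0.5 * self.output_dt, self.output_dt)
        if t[-1] < self.duration:
            t = np.append(t, self.duration)
        return t


@dataclass
class SimulationResult:
    """Time-stamped trajectories of a coupled simulation.

    ``patient`` has one row per output time and columns
    [T_pl, PT_pl, P_pl, T_is, PT_is, P_is, T_ic, V_pl, V_is] (molar, L);
    for reservoir runs the interstitial/intracellular slots mirror the
    reservoir (see :func:`simulate_in_vitro_reservoir`).  Dialyzer
    fields are (n_t, n_x) arrays; ``removed_mg`` is the cumulative
    toxin mass carried out with spent dialysate.
    """

    t: np.ndarray
    patient: np.ndarray
    V_ic: float
    dialyzer_T: np.ndarray | None
    dialyzer_PT: np.ndarray | None
    dialyzer_P: np.ndarray | None
    dialyzer_Td: np.ndarray | None
    removed_mg: np.ndarray
    species: Species
    params: ToxinParameters
    config: SessionConfig | None
    geometry: DialyzerGeometry | None
    solver_stats: dict = field(default_factory=dict)

    def patient_state(self, i: int) -> PatientState:
        return PatientState.from_array(self.patient[i], self.V_ic)

    @property
    def initial_state(self) -> PatientState:
        return self.patient_state(0)

    @property
    def final_state(self) -> PatientState:
        return self.patient_state(-1)

    # -- plasma series ------------------------------------------------------
    @property
    def plasma_free(self) -> np.ndarray:
        return self.patient[:, 0]

    @property
    def plasma_total(self) -> np.ndarray:
        return self.patient[:, 0] + self.patient[:, 1]

    @property
    def plasma_total_mg_per_l(self) -> np.ndarray:
        return molar_to_mass(self.plasma_total, self.species.molecular_weight)

    @property
    def plasma_bound_fraction(self) -> np.ndarray:
        tot = self.plasma_total
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(tot > 0, self.patient[:, 1] / tot, np.nan)

    def dialyzer_state(self, i: int) -> DialyzerState:
        if self.dialyzer_T is None:
            raise ValueError("run had no dialyzer attached")
        return DialyzerState(T=self.dialyzer_T[i], PT=self.dialyzer_PT[i],
                             P=self.dialyzer_P[i], T_d=self.dialyzer_Td[i])

    def toxin_mass_series(self) -> np.ndarray:
        """Whole-body (or reservoir) toxin amount over time, mol."""
        return np.array([self.patient_state(i).toxin_mass()
                         for i in range(len(self.t))])

    def at_time(self, t_query: float) -> int:
        return int(np.argmin(np.abs(self.t - t_query)))

    def to_dataframe(self) -> pd.DataFrame:
        """Tidy long-format trajectory (time, variable, value)."""
        cols = ["T_pl", "PT_pl", "P_pl", "T_is", "PT_is", "P_is", "T_ic",
                "V_pl", "V_is"]
        df = pd.DataFrame(self.patient, columns=cols)
        df.insert(0, "time_min", self.t)
        df["removed_mg"] = self.removed_mg
        df["toxin"] = self.species.name
        return df.melt(id_vars=["time_min", "toxin"], var_name="variable",
                       value_name="value")


# ---------------------------------------------------------------------------
# Coupled session
# ---------------------------------------------------------------------------

def _coupled_sparsity(n_x: int) -> lil_matrix:
    """Jacobian sparsity of [patient(9) | T | PT | P | Td | removed]."""
    n = n_x
    size = NPAT + 4 * n + 1
    S = lil_matrix((size, size), dtype=np.int8)
    bT, bPT, bP, bTd = NPAT, NPAT + n, NPAT + 2 * n, NPAT + 3 * n
    # patient block: dense, plus dependence on the three outlet cells
    S[0:NPAT, 0:NPAT] = 1
    for col in (bT + n - 1, bPT + n - 1, bP + n - 1):
        S[0:NPAT, col] = 1
    for j in range(n):
        blood_cols = [bT + j, bPT + j, bP + j]
        # blood cells: reaction couples T/PT/P locally; transfer couples Td
        for row in blood_cols:
            for col in blood_cols:
                S[row, col] = 1
        S[bT + j, bTd + j] = 1
        if j > 0:
            S[bT + j, bT + j - 1] = 1
            S[bPT + j, bPT + j - 1] = 1
            S[bP + j, bP + j - 1] = 1
        else:
            S[bT, 0] = S[bPT, 1] = S[bP, 2] = 1  # inlet from plasma
        # dialysate cells
        S[bTd + j, bTd + j] = 1
        S[bTd + j, bT + j] = 1
        if j < n - 1:
            S[bTd + j, bTd + j + 1] = 1
    S[size - 1, bTd] = 1  # removed mass <- dialysate outlet cell
    return S


def _atol_vector(cfg: SessionConfig, n_states: int) -> np.ndarray:
    atol = np.full(n_states, cfg.atol)
    atol[7:9] = 1e-8          # volumes, L scale
    atol[-1] = cfg.atol       # cumulative removal, mol
    return atol


def _integrate(rhs, t_span, y0, cfg: SessionConfig, sparsity, t_eval):
    sol = solve_ivp(rhs, t_span, y0, method="BDF", t_eval=t_eval,
                    rtol=cfg.rtol, atol=_atol_vector(cfg, len(y0)),
                    jac_sparsity=sparsity)
    if not sol.success:
        raise IntegrationError(f"stiff integration failed: {sol.message}")
    return sol


def simulate_session(patient0: PatientState, params: ToxinParameters,
                     species: Species, geom: DialyzerGeometry,
                     cfg: SessionConfig) -> SimulationResult:
    """Simulate one in-vivo HD session for a single protein-bound toxin.

    The patient starts at pre-dialysis binding equilibrium; the dialyzer
    starts toxin-free.  Returns trajectories on the configured output
    grid.
    """
    n = cfg.n_x
    op = DialyzerOperator(geom, cfg.Q_p, cfg.Q_d, cfg.Q_uf, n_x=n,
                          binding=params.binding)
    flows = FlowSettings(Q_p=cfg.Q_p, Q_uf=cfg.Q_uf)
    V_ic = patient0.V_ic

    y0 = np.concatenate([patient0.as_array(), DialyzerState.zeros(n).as_array(), [0.0]])
    bT, bPT, bP = NPAT, NPAT + n, NPAT + 2 * n

    def rhs(t, y):
        y_p = y[:NPAT]
        d = DialyzerState.from_array(y[NPAT:NPAT + 4 * n], n)
        outlet = (y[bT + n - 1], y[bPT + n - 1], y[bP + n - 1])
        dy_p = patient_rhs_array(y_p, V_ic, params, species, flows, outlet)
        dd = op.rhs(d, (y_p[0], y_p[1], y_p[2]))
        return np.concatenate([dy_p, dd.as_array(), [op.dialysate_outflow(d)]])

    t_eval = cfg.output_grid()
    sol = _integrate(rhs, (0.0, cfg.duration), y0, cfg, _coupled_sparsity(n), t_eval)

    Y = sol.y.T
    mw = species.molecular_weight
    return SimulationResult(
        t=sol.t, patient=Y[:, :NPAT], V_ic=V_ic,
        dialyzer_T=Y[:, bT:bT + n], dialyzer_PT=Y[:, bPT:bPT + n],
        dialyzer_P=Y[:, bP:bP + n], dialyzer_Td=Y[:, NPAT + 3 * n:NPAT + 4 * n],
        removed_mg=Y[:, -1] * mw * ML_PER_L,
        species=species, params=params, config=cfg, geometry=geom,
        solver_stats={"nfev": sol.nfev, "njev": sol.njev, "steps": len(sol.t)},
    )


def mass_audit(result: SimulationResult) -> dict:
    """Global toxin mass balance over a coupled session.

    initial + generated == final + dialyzer holdup + removed, all mol.
    Returns the terms and the relative discrepancy (on initial+generated).
    """
    cfg = result.config
    op = DialyzerOperator(result.geometry, cfg.Q_p, cfg.Q_d, cfg.Q_uf,
                          n_x=cfg.n_x, binding=result.params.binding)
    m0 = result.initial_state.toxin_mass()
    m_end = result.final_state.toxin_mass()
    generated = generation_to_molar_rate(result.params.G,
                                         result.species.molecular_weight) * result.t[-1]
    holdup = op.holdup_mass(result.dialyzer_state(-1))
    removed = result.removed_mg[-1] / (result.species.molecular_weight * ML_PER_L)
    residual = m0 + generated - m_end - holdup - removed
    return {
        "initial_mol": m0, "generated_mol": generated, "final_mol": m_end,
        "holdup_mol": holdup, "removed_mol": removed,
        "relative_error": abs(residual) / (m0 + generated),
    }


# ---------------------------------------------------------------------------
# Patient-only phases (rebound, inter-dialytic interval)
# ---------------------------------------------------------------------------

def _simulate_patient_only(state0: PatientState, params: ToxinParameters,
                           species: Species, duration: float,
                           intake_volume: float = 0.0,
                           rtol: float = 1e-8, atol: float = 1e-12,
                           output_dt: float = 1.0) -> SimulationResult:
    V_ic = state0.V_ic
    q_in = intake_volume * ML_PER_L / duration  # mL/min
    flows = FlowSettings(Q_p=0.0, Q_uf=0.0)

    def rhs(t, y):
        dy = patient_rhs_array(y, V_ic, params, species, flows, (y[0], y[1], y[2]))
        if q_in > 0.0:
            # fluid ingestion: volume gain split like UF loss, diluting
            # concentrations (solute-free fluid)
            alpha = y[8] / (y[8] + y[7])
            dV_pl = (1.0 - alpha) * q_in / ML_PER_L
            dV_is = alpha * q_in / ML_PER_L
            dy = dy.copy()
            dy[0:3] -= y[0:3] * dV_pl / y[7]
            dy[3:6] -= y[3:6] * dV_is / y[8]
            dy[7] += dV_pl
            dy[8] += dV_is
        return dy

    t_eval = np.arange(0.0, duration + 0.5 * output_dt, output_dt)
    if t_eval[-1] < duration:
        t_eval = np.append(t_eval, duration)
    S = lil_matrix((NPAT, NPAT), dtype=np.int8)
    S[:, :] = 1
    sol = solve_ivp(rhs, (0.0, duration), state0.as_array(), method="BDF",
                    t_eval=t_eval, rtol=rtol,
                    atol=np.array([atol] * 7 + [1e-8, 1e-8]), jac_sparsity=S)
    if not sol.success:
        raise IntegrationError(f"patient-only integration failed: {sol.message}")
    Y = sol.y.T
    return SimulationResult(
        t=sol.t, patient=Y, V_ic=V_ic,
        dialyzer_T=None, dialyzer_PT=None, dialyzer_P=None, dialyzer_Td=None,
        removed_mg=np.zeros(len(sol.t)), species=species, params=params,
        config=None, geometry=None,
        solver_stats={"nfev": sol.nfev, "steps": len(sol.t)},
    )


def simulate_rebound(state_end: PatientState, params: ToxinParameters,
                     species: Species, duration: float = 120.0) -> SimulationResult:
    """Post-dialysis rebound: dialyzer bypassed, generation on, no UF."""
    return _simulate_patient_only(state_end, params, species, duration)


def simulate_interdialytic(state_end: PatientState, params: ToxinParameters,
                           species: Species, interval: float = 44.0 * MIN_PER_H,
                           intake_volume: float = 2.0) -> PatientState:
    """Inter-dialytic interval with fluid ingestion; returns the next
    pre-dialysis state."""
    res = _simulate_patient_only(state_end, params, species, interval,
                                 intake_volume=intake_volume, output_dt=interval)
    return res.final_state


# ---------------------------------------------------------------------------
# In-vitro reservoir (bench validation configuration)
# ---------------------------------------------------------------------------

def simulate_in_vitro_reservoir(reservoir0: tuple[float, float, float],
                                reservoir_volume: float,
                                params: ToxinParameters, species: Species,
                                geom: DialyzerGeometry,
                                cfg: SessionConfig) -> SimulationResult:
    """Well-mixed reservoir (artificial plasma pool) through the dialyzer.

    ``reservoir0`` is the initial (T, PT, P) molar triple (build it with
    :func:`pbutkin.binding.partition_equilibrium`).  Binding kinetics are
    active in the reservoir and along the fiber.  The returned result
    stores the reservoir triple in the plasma slots; interstitial and
    intracellular slots are zero.
    """
    n = cfg.n_x
    op = DialyzerOperator(geom, cfg.Q_p, cfg.Q_d, cfg.Q_uf, n_x=n,
                          binding=params.binding)
    qp = cfg.Q_p / ML_PER_L
    quf = cfg.Q_uf / ML_PER_L
    if params.binding is not None:
        k1, k2 = params.binding.k1, params.binding.k2
    else:
        k1 = k2 = 0.0

    bT, bPT, bP = 4, 4 + n, 4 + 2 * n  # reservoir occupies slots 0..3

    def rhs(t, y):
        T_r, PT_r, P_r, V_r = y[0], y[1], y[2], y[3]
        d = DialyzerState.from_array(y[4:4 + 4 * n], n)
        T_out, PT_out, P_out = d.outlet
        r = k1 * P_r * T_r - k2 * PT_r
        qr = qp - quf
        dV = -quf
        m_T = -qp * T_r + qr * T_out - r * V_r
        m_PT = -qp * PT_r + qr * PT_out + r * V_r
        m_P = -qp * P_r + qr * P_out - r * V_r
        dd = op.rhs(d, (T_r, PT_r, P_r))
        return np.concatenate([
            [(m_T - T_r * dV) / V_r, (m_PT - PT_r * dV) / V_r,
             (m_P - P_r * dV) / V_r, dV],
            dd.as_array(), [op.dialysate_outflow(d)],
        ])

    size = 4 + 4 * n + 1
    S = lil_matrix((size, size), dtype=np.int8)
    S[0:4, 0:4] = 1
    for col in (bT + n - 1, bPT + n - 1, bP + n - 1):
        S[0:4, col] = 1
    inner = _coupled_sparsity(n)  # reuse dialyzer block pattern
    S[4:, 4:] = inner[NPAT:, NPAT:]
    for j, col in ((bT, 0), (bPT, 1), (bP, 2)):
        S[j, col] = 1

    y0 = np.concatenate([[reservoir0[0], reservoir0[1], reservoir0[2],
                          reservoir_volume],
                         DialyzerState.zeros(n).as_array(), [0.0]])
    t_eval = cfg.output_grid()
    atol = np.full(size, cfg.atol)
    atol[3] = 1e-8
    sol = solve_ivp(rhs, (0.0, cfg.duration), y0, method="BDF", t_eval=t_eval,
                    rtol=cfg.rtol, atol=atol, jac_sparsity=S)
    if not sol.success:
        raise IntegrationError(f"reservoir integration failed: {sol.message}")

    Y = sol.y.T
    n_t = len(sol.t)
    patient = np.zeros((n_t, NPAT))
    patient[:, 0:3] = Y[:, 0:3]
    patient[:, 7] = Y[:, 3]              # V_pl slot carries reservoir volume
    patient[:, 8] = 1e-300               # keep alpha well-defined, unused
    mw = species.molecular_weight
    return SimulationResult(
        t=sol.t, patient=patient, V_ic=0.0,
        dialyzer_T=Y[:, bT:bT + n], dialyzer_PT=Y[:, bPT:bPT + n],
        dialyzer_P=Y[:, bP:bP + n], dialyzer_Td=Y[:, 4 + 3 * n:4 + 4 * n],
        removed_mg=Y[:, -1] * mw * ML_PER_L,
        species=species, params=params, config=cfg, geometry=geom,
        solver_stats={"nfev": sol.nfev, "steps": len(sol.t)},
    )


# ---------------------------------------------------------------------------
# Two-pool urea session
# ---------------------------------------------------------------------------

@dataclass
class UreaResult:
    """Trajectory of the conventional two-pool urea model (mg/L, L)."""

    t: np.ndarray
    C_ex: np.ndarray
    C_ic: np.ndarray
    V_ex: np.ndarray
    V_ic: float
    params: UreaParameters

    @property
    def final_state(self) -> UreaState:
        return UreaState(C_ex=self.C_ex[-1], C_ic=self.C_ic[-1],
                         V_ex=self.V_ex[-1], V_ic=self.V_ic)

    def mass_series(self) -> np.ndarray:
        return self.V_ex * self.C_ex + self.V_ic * self.C_ic


def simulate_urea_session(urea0: UreaState, params: UreaParameters,
                          cfg: SessionConfig) -> UreaResult:
    """One dialysis session of the two-pool urea model (fixed clearance
    K_D, no dialyzer PDE)."""
    V_ic = urea0.V_ic

    def rhs(t, y):
        return urea_rhs_array(y, V_ic, params, cfg.Q_uf, dialysis_on=True)

    t_eval = cfg.output_grid()
    sol = solve_ivp(rhs, (0.0, cfg.duration), urea0.as_array(), method="BDF",
                    t_eval=t_eval, rtol=1e-10, atol=1e-10)
    if not sol.success:
        raise IntegrationError(f"urea integration failed: {sol.message}")
    return UreaResult(t=sol.t, C_ex=sol.y[0], C_ic=sol.y[1], V_ex=sol.y[2],
                      V_ic=V_ic, params=params)


def simulate_urea_interdialytic(state_end: UreaState, params: UreaParameters,
                                interval: float = 44.0 * MIN_PER_H,
                                intake_volume: float = 2.0) -> UreaState:
    V_ic = state_end.V_ic
    q_in = intake_volume * ML_PER_L / interval

    def rhs(t, y):
        return urea_rhs_array(y, V_ic, params, 0.0, dialysis_on=False,
                              intake_rate=q_in)

    sol = solve_ivp(rhs, (0.0, interval), state_end.as_array(), method="BDF",
                    rtol=1e-10, atol=1e-10)
    if not sol.success:
        raise IntegrationError(f"urea interval integration failed: {sol.message}")
    return UreaState(C_ex=sol.y[0, -1], C_ic=sol.y[1, -1], V_ex=sol.y[2, -1],
                     V_ic=V_ic)


# ---------------------------------------------------------------------------
# Flow sweeps
# ---------------------------------------------------------------------------

def sweep_flows(patient0: PatientState, params: ToxinParameters,
                species: Species, geom: DialyzerGeometry, cfg: SessionConfig,
                Qb_range, Qd_range) -> pd.DataFrame:
    """Total-concentration reduction ratio over a (Q_b, Q_d) grid.

    Returns a tidy DataFrame with columns Q_b, Q_d, rr_total, rr_free.
    """
    rows = []
    for qb in Qb_range:
        for qd in Qd_range:
            c = replace(cfg, Q_b=float(qb), Q_d=float(qd))
            res = simulate_session(patient0, params, species, geom, c)
            tot = res.plasma_total
            free = res.plasma_free
            rows.append({"Q_b": float(qb), "Q_d": float(qd),
                         "rr_total": (tot[0] - tot[-1]) / tot[0],
                         "rr_free": (free[0] - free[-1]) / free[0]})
    return pd.DataFrame(rows)
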