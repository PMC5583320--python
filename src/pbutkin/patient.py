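"""Three-compartment patient model and the two-pool urea comparator.

A protein-bound toxin distributes over plasma, interstitial and
intracellular water.  Free toxin (T) exchanges between all three pools;
albumin (P) and the albumin-toxin complex (PT) live in plasma and
interstitium only and do not cross the capillary endothelium.  Toxin is
generated at a constant rate in the intracellular pool.  Ultrafiltration
shrinks plasma and interstitial volumes in proportion to their share of
extracellular water; intracellular volume is constant.

The governing balances (molar, per compartment), with Qp the plasma
flow to the dialyzer, Quf the ultrafiltration rate and *_out the
dialyzer blood-outlet concentrations:

    d(V_pl*T_pl)/dt  = -Qp*T_pl + (Qp-Quf)*T_out + K_ip*(T_is-T_pl)
                       + alpha*Quf*T_is + (-k1*P_pl*T_pl + k2*PT_pl)*V_pl
    d(V_pl*PT_pl)/dt = -Qp*PT_pl + (Qp-Quf)*PT_out + (k1*P_pl*T_pl - k2*PT_pl)*V_pl
    d(V_pl*P_pl)/dt  = -Qp*P_pl + (Qp-Quf)*P_out + (-k1*P_pl*T_pl + k2*PT_pl)*V_pl
    d(V_is*T_is)/dt  = K_ic*(T_ic-T_is) - K_ip*(T_is-T_pl) - alpha*Quf*T_is
                       + (-k1*P_is*T_is + k2*PT_is)*V_is
    d(V_is*PT_is)/dt = (k1*P_is*T_is - k2*PT_is)*V_is
    d(V_is*P_is)/dt  = -(k1*P_is*T_is - k2*PT_is)*V_is
    d(V_ic*T_ic)/dt  = G - K_ic*(T_ic-T_is)
    dV_pl/dt = -(1-alpha)*Quf,   dV_is/dt = -alpha*Quf,
    alpha = V_is/(V_is+V_pl)

The integrator state is kept in concentration form,
dC/dt = (mass-balance RHS - C*dV/dt)/V, which is algebraically
equivalent and better scaled.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .binding import BindingParameters, bound_pool_for_free
from .species import AlbuminModel, Species
from .units import InvalidParameterError, generation_to_molar_rate, ML_PER_L


@dataclass(frozen=True)
class ToxinParameters:
    """Per-toxin kinetic parameters.

    G : generation rate, mg/min.
    K_ip_T : plasma<->interstitial free-toxin mass transfer coefficient, mL/min.
    K_ic_T : intracellular<->interstitial mass transfer coefficient, mL/min.
    binding : mass-action constants, or None for an unbound solute.
    """

    G: float
    K_ip_T: float
    K_ic_T: float
    binding: BindingParameters | None

    def __post_init__(self) -> None:
        if self.G < 0 or self.K_ip_T < 0 or self.K_ic_T < 0:
            raise InvalidParameterError("G, K_ip_T and K_ic_T must be >= 0")


@dataclass(frozen=True)
class FlowSettings:
    """Extracorporeal flows seen by the patient model (mL/min)."""

    Q_p: float
    Q_uf: float = 0.0

    def __post_init__(self) -> None:
        if self.Q_uf < 0:
            raise InvalidParameterError("Q_uf must be >= 0")
        if self.Q_p < self.Q_uf:
            raise InvalidParameterError("Q_p must be >= Q_uf")


@dataclass
class PatientState:
    """Concentrations (M) and volumes (L) of the three compartments."""

    T_pl: float
    PT_pl: float
    P_pl: float
    T_is: float
    PT_is: float
    P_is: float
    T_ic: float
    V_pl: float
    V_is: float
    V_ic: float

    NVAR = 9  # dynamic entries (V_ic is constant)

    @property
    def alpha(self) -> float:
        return self.V_is / (self.V_is + self.V_pl)

    def as_array(self) -> np.ndarray:
        return np.array([self.T_pl, self.PT_pl, self.P_pl,
                         self.T_is, self.PT_is, self.P_is,
                         self.T_ic, self.V_pl, self.V_is], dtype=float)

    @classmethod
    def from_array(cls, y: np.ndarray, V_ic: float) -> "PatientState":
        return cls(T_pl=y[0], PT_pl=y[1], P_pl=y[2],
                   T_is=y[3], PT_is=y[4], P_is=y[5],
                   T_ic=y[6], V_pl=y[7], V_is=y[8], V_ic=V_ic)

    def copy(self) -> "PatientState":
        return replace(self)

    # -- derived quantities -------------------------------------------------
    @property
    def plasma_total(self) -> float:
        """Total (free+bound) plasma toxin concentration, M."""
        return self.T_pl + self.PT_pl

    @property
    def plasma_bound_fraction(self) -> float:
        tot = self.plasma_total
        return self.PT_pl / tot if tot > 0 else float("nan")

    def toxin_mass(self) -> float:
        """Whole-body toxin amount, mol (free+bound, free-only in IC)."""
        return (self.V_pl * (self.T_pl + self.PT_pl)
                + self.V_is * (self.T_is + self.PT_is)
                + self.V_ic * self.T_ic)

    def albumin_mass(self) -> float:
        """Whole-body albumin amount (free + complexed), mol."""
        return self.V_pl * (self.P_pl + self.PT_pl) + self.V_is * (self.P_is + self.PT_is)


def initialize_equilibrium_state(species: Species, albumin: AlbuminModel,
                                 volumes: tuple[float, float, float]) -> PatientState:
    """Pre-dialysis equilibrium state for one toxin.

    Plasma free/bound split is set by the measured bound fraction; the
    free concentration is equal across all three pools; the interstitial
    bound pool follows from local albumin (40/60 plasma/interstitial
    mass split) at the same K_A; the intracellular pool holds free toxin
    only.

    Parameters
    ----------
    volumes : (V_pl0, V_is0, V_ic) in L.  Note V_is0 = V_ex0 - V_pl0
        when starting from an extracellular volume.
    """
    V_pl0, V_is0, V_ic = volumes
    if min(V_pl0, V_is0, V_ic) <= 0:
        raise InvalidParameterError("volumes must be positive")
    T_tot = species.c_total_0_molar
    PT_pl = species.binding_degree_0 * T_tot
    T_free = T_tot - PT_pl
    P_tot_pl = albumin.plasma_molar_0
    P_pl = P_tot_pl - PT_pl
    if P_pl <= 0:
        raise InvalidParameterError("bound toxin exceeds plasma albumin")
    if species.binding_degree_0 == 0.0:
        K_A = 0.0
        PT_is = 0.0
        P_tot_is = albumin.interstitial_molar_0(V_pl0, V_is0)
    else:
        K_A = PT_pl / (P_pl * T_free)
        P_tot_is = albumin.interstitial_molar_0(V_pl0, V_is0)
        PT_is = bound_pool_for_free(T_free, P_tot_is, K_A)
    return PatientState(
        T_pl=T_free, PT_pl=PT_pl, P_pl=P_pl,
        T_is=T_free, PT_is=PT_is, P_is=P_tot_is - PT_is,
        T_ic=T_free, V_pl=V_pl0, V_is=V_is0, V_ic=V_ic,
    )


# ---------------------------------------------------------------------------
# Right-hand sides
# ---------------------------------------------------------------------------

def patient_rhs_array(y: np.ndarray, V_ic: float, params: ToxinParameters,
                      species: Species, flows: FlowSettings,
                      inlet_return: tuple[float, float, float]) -> np.ndarray:
    """Concentration-form derivatives of the 9 dynamic patient variables.

    ``inlet_return`` is the dialyzer blood-outlet triple (T_out, PT_out,
    P_out); pass the plasma concentrations themselves to bypass the
    dialyzer.
    """
    T_pl, PT_pl, P_pl, T_is, PT_is, P_is, T_ic, V_pl, V_is = y
    T_out, PT_out, P_out = inlet_return

    qp = flows.Q_p / ML_PER_L       # L/min
    quf = flows.Q_uf / ML_PER_L
    kip = params.K_ip_T / ML_PER_L
    kic = params.K_ic_T / ML_PER_L
    g_mol = generation_to_molar_rate(params.G, species.molecular_weight)
    alpha = V_is / (V_is + V_pl)

    if params.binding is not None:
        k1, k2 = params.binding.k1, params.binding.k2
    else:
        k1 = k2 = 0.0
    r_pl = k1 * P_pl * T_pl - k2 * PT_pl    # net association rate, M/min
    r_is = k1 * P_is * T_is - k2 * PT_is

    qr = qp - quf                            # return flow
    # mass balances, mol/min
    m_T_pl = -qp * T_pl + qr * T_out + kip * (T_is - T_pl) + alpha * quf * T_is - r_pl * V_pl
    m_PT_pl = -qp * PT_pl + qr * PT_out + r_pl * V_pl
    m_P_pl = -qp * P_pl + qr * P_out - r_pl * V_pl
    m_T_is = kic * (T_ic - T_is) - kip * (T_is - T_pl) - alpha * quf * T_is - r_is * V_is
    m_PT_is = r_is * V_is
    m_P_is = -r_is * V_is
    m_T_ic = g_mol - kic * (T_ic - T_is)

    dV_pl = -(1.0 - alpha) * quf
    dV_is = -alpha * quf

    return np.array([
        (m_T_pl - T_pl * dV_pl) / V_pl,
        (m_PT_pl - PT_pl * dV_pl) / V_pl,
        (m_P_pl - P_pl * dV_pl) / V_pl,
        (m_T_is - T_is * dV_is) / V_is,
        (m_PT_is - PT_is * dV_is) / V_is,
        (m_P_is - P_is * dV_is) / V_is,
        m_T_ic / V_ic,
        dV_pl,
        dV_is,
    ])


def patient_rhs(state: PatientState, params: ToxinParameters, species: Species,
                flows: FlowSettings,
                inlet_return: tuple[float, float, float] | None = None) -> PatientState:
    """Dataclass wrapper around :func:`patient_rhs_array`.

    Returns the time-derivatives packed in a :class:`PatientState`
    (V_ic slot carries 0).  Raises on negative concentrations, the
    integrator-level validity guard.
    """
    y = state.as_array()
    if np.any(y[:7] < 0):
        raise InvalidParameterError("negative concentration in patient state")
    if inlet_return is None:
        inlet_return = (state.T_pl, state.PT_pl, state.P_pl)
    dy = patient_rhs_array(y, state.V_ic, params, species, flows, inlet_return)
    return PatientState(*dy, V_ic=0.0)


def volume_rhs(state: PatientState, Q_uf: float) -> tuple[float, float]:
    """(dV_pl/dt, dV_is/dt) in L/min under ultrafiltration Q_uf (mL/min)."""
    if Q_uf < 0:
        raise InvalidParameterError("Q_uf must be >= 0")
    alpha = state.alpha
    quf = Q_uf / ML_PER_L
    return -(1.0 - alpha) * quf, -alpha * quf


# ---------------------------------------------------------------------------
# Conventional two-pool urea model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class UreaParameters:
    """Two-pool urea kinetics.

    G : generation rate, mg/min.
    K_ic_T : intracellular<->extracellular mass transfer coefficient, mL/min.
    K_D : conventional (whole-dialyzer) urea clearance, mL/min.
    generation_compartment : where G enters; the conventional choice is
        the extracellular pool.
    """

    G: float
    K_ic_T: float
    K_D: float
    generation_compartment: str = "extracellular"

    def __post_init__(self) -> None:
        if self.G < 0 or self.K_ic_T <= 0 or self.K_D < 0:
            raise InvalidParameterError("urea parameters must be positive")
        if self.generation_compartment not in ("extracellular", "intracellular"):
            raise InvalidParameterError("generation_compartment must be "
                                        "'extracellular' or 'intracellular'")


@dataclass
class UreaState:
    """Urea concentrations (mg/L) and volumes (L)."""

    C_ex: float
    C_ic: float
    V_ex: float
    V_ic: float

    def as_array(self) -> np.ndarray:
        return np.array([self.C_ex, self.C_ic, self.V_ex], dtype=float)

    @classmethod
    def from_array(cls, y: np.ndarray, V_ic: float) -> "UreaState":
        return cls(C_ex=y[0], C_ic=y[1], V_ex=y[2], V_ic=V_ic)

    def mass(self) -> float:
        """Total body urea, mg."""
        return self.V_ex * self.C_ex + self.V_ic * self.C_ic


def urea_rhs_array(y: np.ndarray, V_ic: float, params: UreaParameters,
                   Q_uf: float, dialysis_on: bool,
                   intake_rate: float = 0.0) -> np.ndarray:
    """Two-pool urea derivatives in concentration form.

    ``intake_rate`` (mL/min) models inter-dialytic fluid ingestion into
    the extracellular pool (dilution without solute).
    """
    C_ex, C_ic, V_ex = y
    kic = params.K_ic_T / ML_PER_L
    kd = (params.K_D / ML_PER_L) if dialysis_on else 0.0
    quf = Q_uf / ML_PER_L if dialysis_on else 0.0
    qin = intake_rate / ML_PER_L

    g_ex = params.G if params.generation_compartment == "extracellular" else 0.0
    g_ic = params.G - g_ex

    m_ex = g_ex - kd * C_ex + kic * (C_ic - C_ex)   # mg/min
    m_ic = g_ic - kic * (C_ic - C_ex)
    dV_ex = -quf + qin
    return np.array([
        (m_ex - C_ex * dV_ex) / V_ex,
        m_ic / V_ic,
        dV_ex,
    ])


def urea_rhs(state: UreaState, params: UreaParameters, Q_uf: float,
             dialysis_on: bool, intake_rate: float = 0.0) -> UreaState:
    dy = urea_rhs_array(state.as_array(), state.V_ic, params, Q_uf,
                        dialysis_on, intake_rate)
    return UreaState(C_ex=dy[0], C_ic=dy[1], V_ex=dy[2], V_ic=0.0)
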