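"""Derived removal metrics and the free-fraction clearance relation.

Reduction ratio (RR) is the relative pre-to-post drop of a plasma
concentration (what clinical sampling measures); relative removal is
the fraction of the total body load (all compartments) removed in one
session.  The closed-form counter-current clearance with a free
fraction f,

    Cl = Qp * (1 - (f - theta)/(Theta*f - theta)),
    Theta = exp(KoA*(f/Qp - 1/Qd)),  theta = Qp/Qd,

reduces to the classic urea clearance formula at f = 1 and is used both
to invert bench clearances into KoA values and as an independent check
on the discretized dialyzer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .patient import PatientState
from .simulator import SimulationResult, UreaResult
from .units import InvalidParameterError


@dataclass(frozen=True)
class ClearanceRelation:
    """Inputs of the free-fraction counter-current clearance formula."""

    f: float
    Q_p: float
    Q_d: float
    KoA: float

    def __post_init__(self) -> None:
        if not 0.0 < self.f <= 1.0:
            raise InvalidParameterError("free fraction must be in (0, 1]")
        if min(self.Q_p, self.Q_d, self.KoA) <= 0:
            raise InvalidParameterError("flows and KoA must be > 0")

    @property
    def theta(self) -> float:
        return self.Q_p / self.Q_d

    @property
    def Theta(self) -> float:
        return math.exp(self.KoA * (self.f / self.Q_p - 1.0 / self.Q_d))

    @property
    def clearance(self) -> float:
        return clearance_from_koa(self.f, self.Q_p, self.Q_d, self.KoA)


def clearance_from_koa(f: float, Q_p: float, Q_d: float, KoA: float) -> float:
    """Diffusive clearance of a solute with free fraction f, mL/min."""
    if not 0.0 < f <= 1.0:
        raise InvalidParameterError("free fraction must be in (0, 1]")
    if min(Q_p, Q_d) <= 0 or KoA < 0:
        raise InvalidParameterError("flows must be > 0 and KoA >= 0")
    if KoA == 0.0:
        return 0.0
    theta = Q_p / Q_d
    z = KoA * (f / Q_p - 1.0 / Q_d)
    if z > 50.0:
        # transport-limited regime; divide through by e^z to avoid overflow
        return Q_p * f / (f + (f - theta) * math.exp(-z))
    em1 = math.expm1(z)
    denom = f * em1 + (f - theta)
    if denom == 0.0 or z == 0.0:
        # removable singularity at f*Qd == Qp: limit form
        return Q_p * f / (f + Q_p / KoA)
    return Q_p * f * em1 / denom


def koa_from_clearance(Cl: float, f: float, Q_p: float, Q_d: float) -> float:
    """Invert the clearance relation for KoA by bracketed root finding.

    Raises if Cl is outside the attainable range (0, Cl_max) where
    Cl_max is the transport-limited bound at KoA -> infinity.
    """
    if Cl <= 0:
        raise InvalidParameterError("clearance must be > 0")
    cl_max = clearance_from_koa(f, Q_p, Q_d, 1e9)
    if Cl >= cl_max:
        raise InvalidParameterError(
            f"clearance {Cl} mL/min not attainable (bound {cl_max:.3f} mL/min)")

    def g(koa: float) -> float:
        return clearance_from_koa(f, Q_p, Q_d, koa) - Cl

    koa = brentq(g, 1e-9, 1e9, xtol=1e-12, rtol=1e-14)
    assert abs(g(koa)) < 1e-9
    return koa


def in_vivo_koa_correction(koa_in_vitro: float, reduction: float = 0.20) -> float:
    """De-rate a bench-measured KoA for in-vivo use (default -20%)."""
    if koa_in_vitro <= 0:
        raise InvalidParameterError("KoA must be > 0")
    return koa_in_vitro * (1.0 - reduction)


# ---------------------------------------------------------------------------
# Removal metrics
# ---------------------------------------------------------------------------

def reduction_ratio(c0: float, ct: float) -> float:
    """(c0 - ct)/c0 on any consistent concentration scale."""
    if c0 <= 0:
        raise InvalidParameterError("pre-dialysis concentration must be > 0")
    return (c0 - ct) / c0


def rr_series(result: SimulationResult, free: bool = False) -> np.ndarray:
    """Reduction-ratio time series on plasma total (or free) concentration."""
    c = result.plasma_free if free else result.plasma_total
    return (c[0] - c) / c[0]


def relative_removal(result: SimulationResult) -> float:
    """Fraction of the pre-dialysis whole-body toxin load removed.

    The removed load is the toxin mass actually carried out with spent
    dialysate over the session, expressed against the initial
    (all-compartment) body load.  It differs from the net load change
    (:func:`load_reduction`) by intra-session generation and by the
    small toxin holdup resident in the dialyzer at session end.
    """
    m0 = result.initial_state.toxin_mass()
    if m0 <= 0:
        raise InvalidParameterError("initial toxin mass must be > 0")
    m0_mg = m0 * result.species.molecular_weight * 1000.0
    return result.removed_mg[-1] / m0_mg


def load_reduction(state0: PatientState, state_end: PatientState) -> float:
    """Net relative change of the whole-body load,
    (initial - final)/initial."""
    m0 = state0.toxin_mass()
    if m0 <= 0:
        raise InvalidParameterError("initial toxin mass must be > 0")
    return (m0 - state_end.toxin_mass()) / m0


def urea_reduction_ratio(result: UreaResult) -> float:
    return reduction_ratio(result.C_ex[0], result.C_ex[-1])


def urea_relative_removal(result: UreaResult) -> float:
    """Removed urea mass (dialytic clearance integral, recovered from
    the mass balance m0 + G*t - m_end) over the initial body load."""
    m = result.mass_series()
    generated = result.params.G * result.t[-1]
    return (m[0] + generated - m[-1]) / m[0]


def urea_load_reduction(result: UreaResult) -> float:
    m = result.mass_series()
    return (m[0] - m[-1]) / m[0]


# ---------------------------------------------------------------------------
# Bound fractions
# ---------------------------------------------------------------------------

def bound_fraction_series(result: SimulationResult) -> np.ndarray:
    """Plasma bound fraction PT/(PT+T) per output time."""
    return result.plasma_bound_fraction


def bound_fraction_profile(result: SimulationResult, t_query: float = 120.0
                           ) -> np.ndarray:
    """Axial bound-fraction profile along the blood side at ``t_query``."""
    i = result.at_time(t_query)
    return result.dialyzer_state(i).bound_fraction_profile()


def inlet_outlet_binding(result: SimulationResult, t_query: float = 120.0
                         ) -> tuple[float, float]:
    """(inlet, outlet) blood-side bound fractions at ``t_query`` min."""
    profile = bound_fraction_profile(result, t_query)
    i = result.at_time(t_query)
    # inlet = plasma mix entering the fiber at that instant
    st = result.patient_state(i)
    return st.plasma_bound_fraction, float(profile[-1])


def session_metrics(result: SimulationResult) -> dict:
    """Summary metrics JSON-able dict for one toxin session."""
    rr_tot = rr_series(result)
    rr_fr = rr_series(result, free=True)
    inlet, outlet = (float("nan"), float("nan"))
    if result.dialyzer_T is not None and result.t[-1] >= 120.0:
        inlet, outlet = inlet_outlet_binding(result, 120.0)
    return {
        "toxin": result.species.name,
        "rr_total": float(rr_tot[-1]),
        "rr_free": float(rr_fr[-1]),
        "relative_removal": float(relative_removal(result)),
        "load_reduction": float(load_reduction(result.initial_state,
                                               result.final_state)),
        "bound_fraction_t0": float(result.plasma_bound_fraction[0]),
        "bound_fraction_tEnd": float(result.plasma_bound_fraction[-1]),
        "inlet_outlet_binding_at_120": [float(inlet), float(outlet)],
        "removed_mg": float(result.removed_mg[-1]),
    }
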