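"""Calibrated parameter presets for the reference patient.

Kinetic constants, generation rates and compartment volumes were
calibrated against intra-dialytic concentration time courses of a
representative hemodialysis patient; pre-dialysis concentrations and
bound fractions are 10-patient clinical averages.  These presets make
every scenario in the package runnable without external data.
"""

from __future__ import annotations

from dataclasses import dataclass

from .binding import BindingParameters, association_constant_for_species
from .patient import (PatientState, ToxinParameters, UreaParameters, UreaState,
                      initialize_equilibrium_state)
from .simulator import SessionConfig
from .species import AlbuminModel, Species, default_species

#: Shared compartment volumes of the reference patient, L.
V_PL0 = 2.4      # initial plasma volume
V_EX0 = 12.9     # initial extracellular fluid volume
V_IC = 25.9      # intracellular fluid volume (constant)
V_IS0 = V_EX0 - V_PL0   # interstitial = extracellular minus plasma

#: Per-toxin calibrated kinetics: generation rate G (mg/min),
#: plasma<->interstitial K_ip_T (mL/min), intracellular<->interstitial
#: K_ic_T (mL/min), association rate k1 (M^-1 min^-1); plus pre-dialysis
#: plasma total concentration (mg/L), mean bound fraction and the
#: clinical range of bound fractions.
TOXIN_PRESETS: dict[str, dict] = {
    "IAA": dict(G=0.0053, K_ip_T=1366.0, K_ic_T=160.0, k1=1.5e3,
                c_total_0=2.1, binding_degree_0=0.73, binding_range=(0.63, 0.80)),
    "IS": dict(G=0.0285, K_ip_T=1210.0, K_ic_T=103.0, k1=3.6e7,
               c_total_0=15.1, binding_degree_0=0.93, binding_range=(0.90, 0.95)),
    "pCG": dict(G=0.0136, K_ip_T=1148.0, K_ic_T=67.0, k1=1.9e6,
                c_total_0=3.5, binding_degree_0=0.13, binding_range=(0.09, 0.19)),
    "pCS": dict(G=0.0277, K_ip_T=1060.0, K_ic_T=98.0, k1=4.0e7,
                c_total_0=30.6, binding_degree_0=0.95, binding_range=(0.93, 0.97)),
}

PBUT_NAMES = tuple(TOXIN_PRESETS)

#: Calibrated two-pool urea kinetics: G (mg/min), K_ic_T (mL/min) and
#: the conventional dialyzer urea clearance K_D (mL/min).
UREA_PRESET = dict(G=8.17, K_ic_T=363.0, K_D=224.0)

DEFAULT_ALBUMIN = AlbuminModel()        # 4 g/dL, 40% of mass in plasma
DEFAULT_SESSION = SessionConfig()       # 240 min, Qb 300, Qd 700, UF 2 L, Hct 0.37

#: Inter-dialytic defaults used with the 95% periodicity condition.
INTERDIALYTIC_INTERVAL_MIN = 44.0 * 60.0
INTERDIALYTIC_INTAKE_L = 2.0


def calibrated_species(name: str, binding_degree: float | None = None) -> Species:
    p = TOXIN_PRESETS[name]
    bd = p["binding_degree_0"] if binding_degree is None else binding_degree
    return default_species(name, binding_degree_0=bd, c_total_0=p["c_total_0"])


def calibrated_parameters(name: str, albumin: AlbuminModel = DEFAULT_ALBUMIN,
                          binding_degree: float | None = None,
                          K_ic_T: float | None = None) -> ToxinParameters:
    """Calibrated :class:`ToxinParameters`; k2 follows from k1 and the
    K_A implied by the pre-dialysis bound fraction.

    ``K_ic_T`` overrides the preset (counterfactual studies).
    """
    p = TOXIN_PRESETS[name]
    sp = calibrated_species(name, binding_degree)
    K_A = association_constant_for_species(sp, albumin)
    return ToxinParameters(
        G=p["G"], K_ip_T=p["K_ip_T"],
        K_ic_T=p["K_ic_T"] if K_ic_T is None else K_ic_T,
        binding=BindingParameters.from_k1_KA(p["k1"], K_A),
    )


def calibrated_patient_state(name: str, albumin: AlbuminModel = DEFAULT_ALBUMIN,
                             binding_degree: float | None = None) -> PatientState:
    sp = calibrated_species(name, binding_degree)
    return initialize_equilibrium_state(sp, albumin, (V_PL0, V_IS0, V_IC))


def calibrated_urea_parameters() -> UreaParameters:
    return UreaParameters(**UREA_PRESET)


def urea_state(c_predialysis: float) -> UreaState:
    """Equilibrated pre-dialysis two-pool urea state (mg/L)."""
    return UreaState(C_ex=c_predialysis, C_ic=c_predialysis,
                     V_ex=V_EX0, V_ic=V_IC)
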