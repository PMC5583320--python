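"""Mass-action albumin-toxin binding.

The reversible reaction P + T <-> PT is modelled with a single binding
site per albumin molecule and no competition between toxins: each toxin
sees its own independent equilibrium

    K_A = k1/k2 = PT0 / (P0 * T0)

evaluated from the pre-dialysis plasma state.  The module also builds
the pre-dialysis multi-compartment equilibrium patient state: free
toxin concentration equal across plasma, interstitium and intracellular
water; bound pools set by the local albumin concentration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .species import AlbuminModel, Species
from .units import InvalidParameterError


@dataclass(frozen=True)
class BindingParameters:
    """Kinetic constants of the P + T <-> PT equilibrium.

    k1 : association rate constant, M^-1 min^-1.
    k2 : dissociation rate constant, min^-1.
    K_A : equilibrium association constant, M^-1 (== k1/k2).
    """

    k1: float
    k2: float

    def __post_init__(self) -> None:
        if self.k1 <= 0 or self.k2 <= 0:
            raise InvalidParameterError("k1 and k2 must be positive")

    @property
    def K_A(self) -> float:
        return self.k1 / self.k2

    @classmethod
    def from_k1_KA(cls, k1: float, K_A: float) -> "BindingParameters":
        return cls(k1=k1, k2=dissociation_rate(k1, K_A))

    @classmethod
    def none(cls) -> None:
        """Marker for unbound solutes (urea): no binding parameters."""
        return None


def equilibrium_association_constant(PT0: float, P0: float, T0: float) -> float:
    """K_A = PT0 / (P0 * T0), all concentrations molar."""
    if PT0 <= 0 or P0 <= 0 or T0 <= 0:
        raise InvalidParameterError("PT0, P0 and T0 must all be positive")
    return PT0 / (P0 * T0)


def dissociation_rate(k1: float, K_A: float) -> float:
    """k2 = k1 / K_A from the definition of the association constant."""
    if k1 <= 0 or K_A <= 0:
        raise InvalidParameterError("k1 and K_A must be positive")
    return k1 / K_A


def association_constant_for_species(species: Species, albumin: AlbuminModel) -> float:
    """K_A implied by the pre-dialysis plasma bound fraction.

    Returns 0 for an unbound species (binding_degree_0 == 0).
    """
    f_bound = species.binding_degree_0
    if f_bound == 0.0:
        return 0.0
    T_tot = species.c_total_0_molar
    PT0 = f_bound * T_tot
    T0 = T_tot - PT0
    P0 = albumin.plasma_molar_0 - PT0
    if P0 <= 0:
        raise InvalidParameterError(
            "bound toxin exceeds available albumin; check concentrations"
        )
    return equilibrium_association_constant(PT0, P0, T0)


def partition_equilibrium(T_total: float, P_total: float, K_A: float
                          ) -> tuple[float, float, float]:
    """Split totals into (T_free, PT, P_free) at mass-action equilibrium.

    Solves K_A * (P_total - PT) * (T_total - PT) = PT for the unique
    root with 0 <= PT <= min(P_total, T_total), via the numerically
    stable quadratic root form with a bisection fallback.
    """
    if T_total < 0 or P_total < 0 or K_A < 0:
        raise InvalidParameterError("totals and K_A must be >= 0")
    if K_A == 0.0 or T_total == 0.0 or P_total == 0.0:
        return T_total, 0.0, P_total
    # K_A*PT^2 - (1 + K_A*(P+T))*PT + K_A*P*T = 0
    a = K_A
    b = -(1.0 + K_A * (P_total + T_total))
    c = K_A * P_total * T_total
    disc = b * b - 4.0 * a * c
    if disc < 0:  # only reachable through rounding; fall back to bisection
        return _partition_bisect(T_total, P_total, K_A)
    sq = math.sqrt(disc)
    # b < 0 always, so the stable root pair is q/a (small) and c/q:
    q = -0.5 * (b - sq)
    PT = c / q  # the smaller root, the physical one
    upper = min(P_total, T_total)
    if not 0.0 <= PT <= upper * (1.0 + 1e-12):
        return _partition_bisect(T_total, P_total, K_A)
    PT = min(PT, upper)
    return T_total - PT, PT, P_total - PT


def _partition_bisect(T_total: float, P_total: float, K_A: float
                      ) -> tuple[float, float, float]:
    def g(PT: float) -> float:
        return K_A * (P_total - PT) * (T_total - PT) - PT

    lo, hi = 0.0, min(P_total, T_total)
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if g(mid) > 0:
            lo = mid
        else:
            hi = mid
    PT = 0.5 * (lo + hi)
    return T_total - PT, PT, P_total - PT


def bound_pool_for_free(T_free: float, P_total: float, K_A: float) -> float:
    """PT at equilibrium when the FREE toxin concentration is prescribed.

    Solves PT = K_A * (P_total - PT) * T_free, the construction used for
    the interstitial pool where free toxin equals the plasma free
    concentration pre-dialysis.
    """
    if T_free < 0 or P_total < 0 or K_A < 0:
        raise InvalidParameterError("inputs must be >= 0")
    denom = 1.0 + K_A * T_free
    return K_A * P_total * T_free / denom
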