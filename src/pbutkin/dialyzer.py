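"""Counter-current hollow-fiber dialyzer: geometry, fluxes, PDE.

Blood (plasma) flows in +x inside each fiber, dialysate flows in -x in
the annulus around it.  Free toxin crosses the membrane by diffusion
(KoA-driven) and convection (ultrafiltration, Peclet-weighted in-membrane
concentration); the complex and albumin are non-dialyzable and simply
advect while being concentrated by water removal.  Mass-action binding
is active along the fiber.

Blood side (per fiber, concentrations molar):

    dT/dt  = -(1/(N*A)) d(Qp*T)/dx - (1/(N*A*L)) * (KoA*(T-Td) + Quf*Tbar)
             + (-k1*P*T + k2*PT)
    dPT/dt = -(1/(N*A)) d(Qp*PT)/dx + (k1*P*T - k2*PT)
    dP/dt  = -(1/(N*A)) d(Qp*P)/dx + (-k1*P*T + k2*PT)

Dialysate side:

    dTd/dt = +(1/(N*A_d)) d(Qd*Td)/dx + (1/(N*A_d*L)) * (KoA*(T-Td) + Quf*Tbar)

with Tbar = T*(1-phi) + Td*phi, phi = 1/Pe - 1/(e^Pe - 1),
Pe = Quf/KoA.  Plasma flow decreases linearly along the fiber
(Qp(x) = Qpi - (x/L)*Quf), dialysate flow increases by the same amount
(Qd(x) = Qdi + ((L-x)/L)*Quf); there is no back-filtration.

Spatial discretization is method-of-lines with first-order upwinding in
the local flow direction on n_x cells; plug flow, no axial diffusion
beyond the upwind scheme's numerical diffusion.  Fresh dialysate
(Td = 0) enters at x = L; blood-outlet values are read at the last cell.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .binding import BindingParameters
from .units import InvalidParameterError, ML_PER_L


class GeometryError(ValueError):
    """Fiber bundle does not fit the stated housing."""


def fiber_flow_area(r_f: float) -> float:
    """Inner cross-sectional (blood flow) area of one fiber, m^2."""
    if r_f <= 0:
        raise InvalidParameterError("fiber radius must be > 0")
    return math.pi * r_f ** 2


def dialysate_annulus_area(D_h: float, N: int, r_f: float, t_f: float) -> float:
    """Per-fiber dialysate flow area, m^2.

    The housing cross-section is shared equally by the N fibers; each
    fiber (outer radius r_f + t_f) occupies part of its share:
    A_d = pi*D_h^2/(4N) - pi*(r_f + t_f)^2.
    """
    a_d = math.pi * D_h ** 2 / (4.0 * N) - math.pi * (r_f + t_f) ** 2
    if a_d < 0:
        raise GeometryError("fibers do not fit housing: annulus area < 0")
    return a_d


@dataclass(frozen=True)
class DialyzerGeometry:
    """Hollow-fiber dialyzer geometry and transport capacity.

    N : fiber count; L : fiber length (m); r_f : fiber inner radius (m);
    t_f : membrane wall thickness (m); D_h : housing diameter (m);
    KoA : overall mass transfer-area coefficient (mL/min), lumping
    blood-side, membrane and dialysate-side resistances.
    """

    N: int
    L: float
    r_f: float
    t_f: float
    D_h: float
    KoA: float

    def __post_init__(self) -> None:
        if min(self.N, self.L, self.r_f, self.t_f, self.D_h) <= 0 or self.KoA <= 0:
            raise InvalidParameterError("all dialyzer dimensions and KoA must be > 0")
        dialysate_annulus_area(self.D_h, self.N, self.r_f, self.t_f)  # geometry check

    @property
    def A(self) -> float:
        """Per-fiber blood flow area, m^2."""
        return fiber_flow_area(self.r_f)

    @property
    def A_d(self) -> float:
        """Per-fiber dialysate annulus area, m^2."""
        return dialysate_annulus_area(self.D_h, self.N, self.r_f, self.t_f)

    def with_koa(self, koa: float) -> "DialyzerGeometry":
        return replace(self, KoA=koa)


#: Fresenius dialyzer presets; fiber dimensions shared, fiber count sets
#: the membrane surface area (F180NR 1.8 m^2, F6 1.3 m^2, F200NR 2.0 m^2).
#: KoA default is the in-vivo value used for the PBUT simulations.
_F_SHARED = dict(L=0.23, r_f=105e-6, t_f=35e-6, D_h=0.04, KoA=600.0)
DIALYZER_PRESETS: dict[str, DialyzerGeometry] = {
    "F180NR": DialyzerGeometry(N=12300, **_F_SHARED),
    "F6": DialyzerGeometry(N=8800, **_F_SHARED),
    "F200NR": DialyzerGeometry(N=13660, **_F_SHARED),
}


def dialyzer_preset(name: str, koa: float | None = None) -> DialyzerGeometry:
    geom = DIALYZER_PRESETS[name]
    return geom.with_koa(koa) if koa is not None else geom


# ---------------------------------------------------------------------------
# Membrane flux terms
# ---------------------------------------------------------------------------

def peclet(Q_uf: float, KoA: float) -> float:
    """Peclet number Pe = Quf/KoA, convective over diffusive transport."""
    if KoA <= 0:
        raise InvalidParameterError("KoA must be > 0")
    if Q_uf < 0:
        raise InvalidParameterError("Q_uf must be >= 0")
    return Q_uf / KoA


def phi_weight(Pe: float) -> float:
    """Convective weighting phi = 1/Pe - 1/(e^Pe - 1).

    phi -> 1/2 as Pe -> 0 (series 1/2 - Pe/12 + Pe^3/720 - ...); a
    series fallback avoids catastrophic cancellation at small Pe.
    """
    if Pe < 0:
        raise InvalidParameterError("Pe must be >= 0")
    if Pe < 1e-6:
        return 0.5 - Pe / 12.0
    return 1.0 / Pe - 1.0 / math.expm1(Pe)


def membrane_concentration(T, T_d, Pe: float):
    """In-membrane concentration Tbar = T*(1-phi) + Td*phi."""
    phi = phi_weight(Pe)
    return T * (1.0 - phi) + T_d * phi


# ---------------------------------------------------------------------------
# Flow profiles (per fiber)
# ---------------------------------------------------------------------------

def plasma_flow_profile(x, Q_pi: float, Q_uf: float, L: float):
    """Per-fiber plasma flow qp(x) = Qpi - (x/L)*Quf, mL/min.

    Raises if ultrafiltration would exhaust the blood-side flow.
    """
    if Q_pi - Q_uf <= 0:
        raise InvalidParameterError("ultrafiltration exceeds per-fiber plasma flow")
    return Q_pi - (np.asarray(x) / L) * Q_uf


def dialysate_flow_profile(x, Q_di: float, Q_uf: float, L: float):
    """Per-fiber dialysate flow qd(x) = Qdi + ((L-x)/L)*Quf, mL/min."""
    return Q_di + ((L - np.asarray(x)) / L) * Q_uf


# ---------------------------------------------------------------------------
# Discretized state and RHS
# ---------------------------------------------------------------------------

@dataclass
class DialyzerState:
    """Axial concentration fields on n_x cells over [0, L].

    Blood-side T, PT, P and dialysate-side T_d, all molar.  Cell j is
    centred at (j + 1/2) * L/n_x.  The stated initial condition is
    all-zero fields (dialyzer primed with toxin-free fluid).
    """

    T: np.ndarray
    PT: np.ndarray
    P: np.ndarray
    T_d: np.ndarray

    @classmethod
    def zeros(cls, n_x: int) -> "DialyzerState":
        return cls(*(np.zeros(n_x) for _ in range(4)))

    @property
    def n_x(self) -> int:
        return len(self.T)

    def as_array(self) -> np.ndarray:
        return np.concatenate([self.T, self.PT, self.P, self.T_d])

    @classmethod
    def from_array(cls, y: np.ndarray, n_x: int) -> "DialyzerState":
        return cls(T=y[0:n_x], PT=y[n_x:2 * n_x],
                   P=y[2 * n_x:3 * n_x], T_d=y[3 * n_x:4 * n_x])

    @property
    def outlet(self) -> tuple[float, float, float]:
        """Blood-outlet triple (T, PT, P) at x = L."""
        return self.T[-1], self.PT[-1], self.P[-1]

    def bound_fraction_profile(self) -> np.ndarray:
        tot = self.T + self.PT
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(tot > 0, self.PT / tot, np.nan)


class DialyzerOperator:
    """Precomputed discretization of the dialyzer PDE.

    Holds grid geometry, face flows and unit conversions so that the
    right-hand side evaluation inside the stiff integrator is a handful
    of vectorized operations.
    """

    def __init__(self, geom: DialyzerGeometry, Q_p: float, Q_d: float,
                 Q_uf: float, n_x: int = 100,
                 binding: BindingParameters | None = None):
        if n_x < 3:
            raise InvalidParameterError("n_x must be >= 3")
        self.geom = geom
        self.n_x = n_x
        self.binding = binding
        self.Q_p, self.Q_d, self.Q_uf = Q_p, Q_d, Q_uf

        N = geom.N
        L = geom.L
        dx = L / n_x
        x_faces = np.linspace(0.0, L, n_x + 1)
        # per-fiber flows at cell faces, L/min
        self.qp_faces = plasma_flow_profile(x_faces, Q_p / N, Q_uf / N, L) / ML_PER_L
        self.qd_faces = dialysate_flow_profile(x_faces, Q_d / N, Q_uf / N, L) / ML_PER_L
        # per-fiber cell volumes, L
        self.vb = geom.A * dx * ML_PER_L
        self.vd = geom.A_d * dx * ML_PER_L
        # per-cell transmembrane coefficients, L/min (total KoA/Quf spread
        # evenly over N fibers and n_x cells)
        self.koa_cell = geom.KoA / ML_PER_L / (N * n_x)
        self.quf_cell = Q_uf / ML_PER_L / (N * n_x)
        self.Pe = peclet(Q_uf, geom.KoA)
        self.phi = phi_weight(self.Pe)

    # -- advection (first-order upwind) -------------------------------------
    def _blood_advect(self, C: np.ndarray, inlet: float) -> np.ndarray:
        """d(mass)/dt per cell from +x advection, mol/min."""
        up = np.empty(self.n_x + 1)
        up[0] = inlet
        up[1:] = C
        flux = self.qp_faces * up          # mol/min through each face
        return flux[:-1] - flux[1:]

    def _dialysate_advect(self, T_d: np.ndarray, inlet: float = 0.0) -> np.ndarray:
        """d(mass)/dt per cell from -x advection, mol/min."""
        up = np.empty(self.n_x + 1)
        up[:-1] = T_d
        up[-1] = inlet                     # fresh dialysate at x = L
        flux = self.qd_faces * up
        return flux[1:] - flux[:-1]

    def rhs(self, state: DialyzerState,
            inlet_blood: tuple[float, float, float],
            inlet_dialysate: float = 0.0) -> DialyzerState:
        """Field time-derivatives given the blood-inlet triple at x=0.

        ``inlet_dialysate`` is the fresh-dialysate concentration entering
        at x=L (0 in every operating mode; overridable for diagnostics).
        """
        T, PT, P, T_d = state.T, state.PT, state.P, state.T_d
        T_in, PT_in, P_in = inlet_blood

        # transmembrane free-toxin transfer per cell, mol/min
        T_bar = T * (1.0 - self.phi) + T_d * self.phi
        s = self.koa_cell * (T - T_d) + self.quf_cell * T_bar

        if self.binding is not None:
            k1, k2 = self.binding.k1, self.binding.k2
            r = k1 * P * T - k2 * PT       # M/min
        else:
            r = 0.0

        dT = (self._blood_advect(T, T_in) - s) / self.vb - r
        dPT = self._blood_advect(PT, PT_in) / self.vb + r
        dP = self._blood_advect(P, P_in) / self.vb - r
        dT_d = (self._dialysate_advect(T_d, inlet_dialysate) + s) / self.vd

        out = DialyzerState(T=dT, PT=dPT, P=dP, T_d=dT_d)
        if not np.all(np.isfinite(dT)):
            raise FloatingPointError("dialyzer RHS produced non-finite values")
        return out

    def rhs_array(self, y: np.ndarray,
                  inlet_blood: tuple[float, float, float]) -> np.ndarray:
        state = DialyzerState.from_array(y, self.n_x)
        return self.rhs(state, inlet_blood).as_array()

    def dialysate_outflow(self, state: DialyzerState) -> float:
        """Toxin mass flow leaving with spent dialysate at x=0, mol/min
        (all N fibers)."""
        return self.geom.N * self.qd_faces[0] * state.T_d[0]

    def holdup_mass(self, state: DialyzerState) -> float:
        """Toxin amount resident in the dialyzer (blood T+PT and
        dialysate T_d), mol, all N fibers."""
        blood = self.vb * np.sum(state.T + state.PT)
        dial = self.vd * np.sum(state.T_d)
        return self.geom.N * (blood + dial)

    def protein_holdup_mass(self, state: DialyzerState) -> float:
        """Albumin amount (free + complexed) resident in the blood side,
        mol, all N fibers."""
        return self.geom.N * self.vb * np.sum(state.P + state.PT)

    def blood_outflow(self, state: DialyzerState) -> float:
        """Total toxin (T+PT) mass flow leaving the blood side at x=L,
        mol/min, all N fibers."""
        return self.geom.N * self.qp_faces[-1] * (state.T[-1] + state.PT[-1])


def steady_state_clearance(geom: DialyzerGeometry, Q_p: float, Q_d: float,
                           Q_uf: float = 0.0, n_x: int = 100,
                           binding: BindingParameters | None = None,
                           inlet: tuple[float, float, float] = (1e-5, 0.0, 0.0),
                           settle_min: float = 30.0) -> float:
    """Whole-dialyzer clearance (mL/min) at a constant blood inlet.

    Integrates the discretized fields to steady state and reports the
    blood-side total (T+PT) mass removal over the inlet total
    concentration, the quantity a bench clearance measurement yields.
    """
    from scipy.integrate import solve_ivp

    op = DialyzerOperator(geom, Q_p, Q_d, Q_uf, n_x=n_x, binding=binding)
    y0 = DialyzerState.zeros(n_x).as_array()
    sol = solve_ivp(lambda t, y: op.rhs_array(y, inlet), (0.0, settle_min), y0,
                    method="BDF", rtol=1e-10, atol=1e-16)
    if not sol.success:
        raise FloatingPointError(f"clearance settling failed: {sol.message}")
    st = DialyzerState.from_array(sol.y[:, -1], n_x)
    c_in = inlet[0] + inlet[1]
    inflow = geom.N * op.qp_faces[0] * c_in
    outflow = op.blood_outflow(st)
    return (inflow - outflow) / c_in * ML_PER_L
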