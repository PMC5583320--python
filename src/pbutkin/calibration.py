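"""Parameter estimation and the generation-rate periodicity condition.

The kinetic constants (K_ip_T, K_ic_T, k1) and, optionally, the shared
compartment volumes are estimated from intra-dialytic plasma total
concentration time series sampled at {0, 15, 30, 60, 120, 240} min by
bounded nonlinear least squares on log-transformed parameters with a
seeded multi-start.  The fit objective per toxin is the relative error

    RE = sqrt( sum_i ((y_pred_i - y_obs_i)/y_obs_i)^2 )

and the stacked residual vector across toxins is minimized jointly.

Generation rates are set by a periodicity condition: the pre-dialysis
concentration at the next session (after a configurable inter-dialytic
interval with fluid ingestion) is a fixed fraction (default 95%) of the
current pre-dialysis concentration.  Both directions are provided: G
for a given pre-dialysis state, and the pre-dialysis concentration for
a given G (needed for urea, whose pre-dialysis level is not an input).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq, least_squares

from .binding import BindingParameters, association_constant_for_species
from .dialyzer import DialyzerGeometry
from .patient import PatientState, ToxinParameters, UreaParameters, UreaState, \
    initialize_equilibrium_state
from .simulator import (SessionConfig, simulate_interdialytic, simulate_session,
                        simulate_urea_interdialytic, simulate_urea_session)
from .species import AlbuminModel, Species
from .units import InvalidParameterError, MIN_PER_H, molar_to_mass

SAMPLE_TIMES = np.array([0.0, 15.0, 30.0, 60.0, 120.0, 240.0])

DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "K_ip_T": (50.0, 1e4),
    "K_ic_T": (5.0, 2e3),
    "k1": (1e2, 1e9),
    "V_pl0": (1.0, 6.0),
    "V_ex0": (8.0, 25.0),
    "V_ic": (15.0, 45.0),
}


class EstimationFailure(RuntimeError):
    """No optimizer start converged to an acceptable fit."""


def relative_error(predicted, observed) -> float:
    """Root-sum-square relative misfit over matched sample points."""
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if predicted.shape != observed.shape:
        raise InvalidParameterError("series lengths differ")
    if np.any(observed <= 0):
        raise InvalidParameterError("observations must be positive")
    return float(np.sqrt(np.sum(((predicted - observed) / observed) ** 2)))


@dataclass
class ToxinObservations:
    """One toxin's calibration inputs: identity, fixed G, observed series."""

    species: Species
    G: float
    times: np.ndarray
    c_total: np.ndarray  # mg/L

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.c_total = np.asarray(self.c_total, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise InvalidParameterError("observation times must be increasing")
        if np.any(self.c_total <= 0):
            raise InvalidParameterError("observed concentrations must be > 0")


@dataclass
class CalibrationProblem:
    """Joint calibration setup.

    free_params : per-toxin parameter names to estimate, subset of
        {"K_ip_T", "K_ic_T", "k1"}.
    fit_volumes : also estimate the shared (V_pl0, V_ex0, V_ic).
    volumes : initial guess (and fixed values when not fitted), L.
    initial_guess : per-toxin dict of starting parameter values.
    """

    toxins: dict[str, ToxinObservations]
    albumin: AlbuminModel
    geometry: DialyzerGeometry
    config: SessionConfig
    free_params: tuple[str, ...] = ("K_ip_T", "K_ic_T", "k1")
    fit_volumes: bool = False
    volumes: tuple[float, float, float] = (2.4, 12.9, 25.9)  # V_pl0, V_ex0, V_ic
    initial_guess: dict[str, dict[str, float]] = field(default_factory=dict)
    bounds: dict[str, tuple[float, float]] = field(default_factory=lambda: dict(DEFAULT_BOUNDS))

    def __post_init__(self) -> None:
        for name in self.free_params:
            if name not in ("K_ip_T", "K_ic_T", "k1"):
                raise InvalidParameterError(f"cannot free parameter {name!r}")


def _forward_series(obs: ToxinObservations, values: dict[str, float],
                    volumes: tuple[float, float, float],
                    albumin: AlbuminModel, geom: DialyzerGeometry,
                    cfg: SessionConfig) -> np.ndarray:
    """Plasma total concentration (mg/L) at the observation times."""
    v_pl0, v_ex0, v_ic = volumes
    sp = obs.species
    K_A = association_constant_for_species(sp, albumin)
    params = ToxinParameters(
        G=obs.G, K_ip_T=values["K_ip_T"], K_ic_T=values["K_ic_T"],
        binding=BindingParameters.from_k1_KA(values["k1"], K_A) if K_A > 0 else None,
    )
    state0 = initialize_equilibrium_state(sp, albumin, (v_pl0, v_ex0 - v_pl0, v_ic))
    res = simulate_session(state0, params, sp, geom, cfg)
    pred = np.interp(obs.times, res.t, res.plasma_total_mg_per_l)
    return pred


@dataclass
class FitResult:
    parameters: dict[str, dict[str, float]]
    volumes: tuple[float, float, float]
    relative_errors: dict[str, float]
    cost: float
    n_starts_converged: int
    nfev: int
    sensitivity: dict[str, float]

    @property
    def converged(self) -> bool:
        return self.n_starts_converged > 0


def estimate_parameters(problem: CalibrationProblem, n_starts: int = 8,
                        seed: int = 0, ftol: float = 1e-10,
                        xtol: float = 1e-10, max_nfev: int | None = None
                        ) -> FitResult:
    """Joint bounded least squares, multi-start over log-parameters.

    The first start is the supplied initial guess; the remaining starts
    perturb it log-uniformly within a half-decade (seeded, hence
    reproducible).  Raises :class:`EstimationFailure` if no start
    converges.
    """
    rng = np.random.default_rng(seed)
    names = list(problem.toxins)
    per_toxin = list(problem.free_params)

    # assemble parameter vector: per-toxin free params, then shared volumes
    def defaults_for(name: str) -> dict[str, float]:
        g = dict(K_ip_T=1000.0, K_ic_T=100.0, k1=1e6)
        g.update(problem.initial_guess.get(name, {}))
        return g

    x0, lo, hi, labels = [], [], [], []
    for name in names:
        g = defaults_for(name)
        for p in per_toxin:
            x0.append(np.log(g[p]))
            lo.append(np.log(problem.bounds[p][0]))
            hi.append(np.log(problem.bounds[p][1]))
            labels.append(f"{name}.{p}")
    if problem.fit_volumes:
        for p, v in zip(("V_pl0", "V_ex0", "V_ic"), problem.volumes):
            x0.append(np.log(v))
            lo.append(np.log(problem.bounds[p][0]))
            hi.append(np.log(problem.bounds[p][1]))
            labels.append(p)
    x0, lo, hi = map(np.array, (x0, lo, hi))

    def unpack(x: np.ndarray):
        vals = np.exp(x)
        k = 0
        per: dict[str, dict[str, float]] = {}
        for name in names:
            base = defaults_for(name)
            for p in per_toxin:
                base[p] = vals[k]
                k += 1
            per[name] = base
        volumes = problem.volumes
        if problem.fit_volumes:
            volumes = tuple(vals[k:k + 3])
        return per, volumes

    def residuals(x: np.ndarray) -> np.ndarray:
        per, volumes = unpack(x)
        res = []
        for name in names:
            obs = problem.toxins[name]
            pred = _forward_series(obs, per[name], volumes, problem.albumin,
                                   problem.geometry, problem.config)
            res.append((pred - obs.c_total) / obs.c_total)
        return np.concatenate(res)

    best = None
    n_conv = 0
    nfev_total = 0
    for s in range(n_starts):
        xs = x0 if s == 0 else np.clip(
            x0 + rng.uniform(-0.5, 0.5, size=len(x0)) * np.log(10.0), lo, hi)
        try:
            fit = least_squares(residuals, xs, bounds=(lo, hi), method="trf",
                                ftol=ftol, xtol=xtol, gtol=1e-12,
                                max_nfev=max_nfev)
        except Exception:
            continue
        nfev_total += fit.nfev
        if not fit.success and best is not None:
            continue
        n_conv += int(fit.success)
        if best is None or fit.cost < best.cost:
            best = fit
    if best is None:
        raise EstimationFailure("no optimizer start converged")

    per, volumes = unpack(best.x)
    rel_errs = {}
    for name in names:
        obs = problem.toxins[name]
        pred = _forward_series(obs, per[name], volumes, problem.albumin,
                               problem.geometry, problem.config)
        rel_errs[name] = relative_error(pred, obs.c_total)
    # local sensitivity: column norms of the final Jacobian per label
    sens = {lab: float(np.linalg.norm(best.jac[:, j]))
            for j, lab in enumerate(labels)}
    return FitResult(parameters={n: {p: per[n][p] for p in per_toxin} for n in names},
                     volumes=tuple(float(v) for v in volumes),
                     relative_errors=rel_errs, cost=float(best.cost),
                     n_starts_converged=max(n_conv, 1), nfev=nfev_total,
                     sensitivity=sens)


# ---------------------------------------------------------------------------
# Synthetic fixtures
# ---------------------------------------------------------------------------

def generate_fixture(species: Species, params: ToxinParameters,
                     albumin: AlbuminModel, geom: DialyzerGeometry,
                     cfg: SessionConfig,
                     volumes: tuple[float, float, float] = (2.4, 12.9, 25.9),
                     noise_sigma: float = 0.0, seed: int = 0,
                     times: np.ndarray = SAMPLE_TIMES) -> ToxinObservations:
    """Forward-simulate and sample a synthetic calibration series.

    ``noise_sigma`` applies multiplicative Gaussian noise
    c -> c*(1 + sigma*eps); the fixture is deterministic for a fixed
    seed.  ``volumes`` is (V_pl0, V_ex0, V_ic).
    """
    v_pl0, v_ex0, v_ic = volumes
    state0 = initialize_equilibrium_state(species, albumin,
                                          (v_pl0, v_ex0 - v_pl0, v_ic))
    res = simulate_session(state0, params, species, geom, cfg)
    c = np.interp(times, res.t, res.plasma_total_mg_per_l)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        c = c * (1.0 + noise_sigma * rng.standard_normal(len(c)))
        c = np.maximum(c, 1e-12)
    return ToxinObservations(species=species, G=params.G, times=times, c_total=c)


# ---------------------------------------------------------------------------
# Generation-rate periodicity
# ---------------------------------------------------------------------------

def generation_fixed_point(params: ToxinParameters, species: Species,
                           state0: PatientState, geom: DialyzerGeometry,
                           cfg: SessionConfig,
                           interval: float = 44.0 * MIN_PER_H,
                           intake_volume: float = 2.0,
                           target_ratio: float = 0.95,
                           g_bracket: tuple[float, float] = (0.0, 10.0),
                           xtol: float = 1e-8) -> float:
    """Generation rate G (mg/min) satisfying the periodicity condition.

    Simulates session + inter-dialytic interval as a function of G and
    returns the G for which the next pre-dialysis plasma total equals
    ``target_ratio`` times the current one.  The ratio is monotone
    increasing in G, so a bracketed scalar root suffices.
    """
    if not 0.0 < target_ratio <= 1.0:
        raise InvalidParameterError("target_ratio must be in (0, 1]")
    c0 = molar_to_mass(state0.T_pl + state0.PT_pl, species.molecular_weight)

    def ratio(G: float) -> float:
        p = replace(params, G=G)
        res = simulate_session(state0, p, species, geom, cfg)
        nxt = simulate_interdialytic(res.final_state, p, species,
                                     interval=interval,
                                     intake_volume=intake_volume)
        c_next = molar_to_mass(nxt.T_pl + nxt.PT_pl, species.molecular_weight)
        return c_next / c0

    def objective(G: float) -> float:
        return ratio(G) - target_ratio

    lo, hi = g_bracket
    f_lo = objective(lo)
    if f_lo >= 0:
        if abs(f_lo) < xtol:
            return lo
        raise InvalidParameterError("target ratio reached with zero generation")
    n_expand = 0
    while objective(hi) < 0:
        hi *= 4.0
        n_expand += 1
        if n_expand > 8:
            raise InvalidParameterError("no generation rate satisfies the "
                                        "periodicity target in bracket")
    return brentq(objective, lo, hi, xtol=xtol)


def urea_periodicity_ratio(c_predialysis: float, params: UreaParameters,
                           cfg: SessionConfig, interval: float,
                           intake_volume: float,
                           volumes: tuple[float, float] = (12.9, 25.9)) -> float:
    """next/current pre-dialysis extracellular urea ratio for one cycle."""
    v_ex, v_ic = volumes
    state0 = UreaState(C_ex=c_predialysis, C_ic=c_predialysis, V_ex=v_ex, V_ic=v_ic)
    res = simulate_urea_session(state0, params, cfg)
    nxt = simulate_urea_interdialytic(res.final_state, params,
                                      interval=interval,
                                      intake_volume=intake_volume)
    return nxt.C_ex / c_predialysis


def urea_generation_fixed_point(params: UreaParameters, state0: UreaState,
                                cfg: SessionConfig,
                                interval: float = 44.0 * MIN_PER_H,
                                intake_volume: float = 2.0,
                                target_ratio: float = 0.95,
                                g_bracket: tuple[float, float] = (0.0, 50.0)
                                ) -> float:
    """Urea generation rate G satisfying the periodicity condition."""
    def f(G: float) -> float:
        p = replace(params, G=G)
        return urea_periodicity_ratio(state0.C_ex, p, cfg, interval,
                                      intake_volume,
                                      volumes=(state0.V_ex, state0.V_ic)) - target_ratio

    lo, hi = g_bracket
    if f(lo) >= 0:
        raise InvalidParameterError("target ratio reached with zero generation")
    while f(hi) < 0:
        hi *= 2.0
        if hi > 1e4:
            raise InvalidParameterError("no urea generation rate in bracket")
    return brentq(f, lo, hi, xtol=1e-8)


def urea_predialysis_for_generation(params: UreaParameters, cfg: SessionConfig,
                                    interval: float = 44.0 * MIN_PER_H,
                                    intake_volume: float = 2.0,
                                    target_ratio: float = 0.95,
                                    c_bracket: tuple[float, float] = (50.0, 5000.0),
                                    volumes: tuple[float, float] = (12.9, 25.9)
                                    ) -> float:
    """Pre-dialysis urea concentration (mg/L) consistent with a given G
    under the periodicity condition (the inverse of the G fixed point;
    the cycle ratio is monotone decreasing in the concentration)."""
    def f(c0: float) -> float:
        return urea_periodicity_ratio(c0, params, cfg, interval, intake_volume,
                                      volumes=volumes) - target_ratio

    lo, hi = c_bracket
    if f(lo) < 0 or f(hi) > 0:
        raise InvalidParameterError("pre-dialysis concentration bracket does "
                                    "not contain the periodicity solution")
    return brentq(f, lo, hi, xtol=1e-8)


def calibrate_with_generation(problem: CalibrationProblem,
                              interval: float = 44.0 * MIN_PER_H,
                              intake_volume: float = 2.0,
                              target_ratio: float = 0.95,
                              g_tol: float = 1e-3, max_outer: int = 10,
                              **fit_kwargs) -> tuple[FitResult, dict[str, float]]:
    """Alternate parameter estimation and generation-rate update until
    G changes by less than ``g_tol`` (relative) for every toxin."""
    problem = replace(problem)
    for _ in range(max_outer):
        fit = estimate_parameters(problem, **fit_kwargs)
        new_g: dict[str, float] = {}
        max_change = 0.0
        for name, obs in problem.toxins.items():
            vals = {**fit.parameters[name]}
            sp = obs.species
            K_A = association_constant_for_species(sp, problem.albumin)
            params = ToxinParameters(
                G=obs.G, K_ip_T=vals.get("K_ip_T", 1000.0),
                K_ic_T=vals.get("K_ic_T", 100.0),
                binding=BindingParameters.from_k1_KA(vals.get("k1", 1e6), K_A)
                if K_A > 0 else None)
            v_pl0, v_ex0, v_ic = fit.volumes
            state0 = initialize_equilibrium_state(sp, problem.albumin,
                                                  (v_pl0, v_ex0 - v_pl0, v_ic))
            g = generation_fixed_point(params, sp, state0, problem.geometry,
                                       problem.config, interval=interval,
                                       intake_volume=intake_volume,
                                       target_ratio=target_ratio)
            if obs.G > 0:
                max_change = max(max_change, abs(g - obs.G) / obs.G)
            new_g[name] = g
        for name, g in new_g.items():
            problem.toxins[name].G = g
        if max_change < g_tol:
            break
    return fit, new_g
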