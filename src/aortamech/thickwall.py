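"""Extension-inflation of the residually stressed thick-walled HGO cylinder.

The artery is an incompressible homogeneous cylinder.  Residual stress is
encoded by the opening-angle construction: the stress-free reference is a
cut-open sector with radii rho_i <= rho <= rho_o and parameter
k = pi / (pi - Phi0).  For opening angles beyond 180 degrees the cut ring
everts (curls inside-out); k is then formally negative and the sector's
*outer* surface becomes the lumen of the closed vessel.  Writing kappa = |k|,
the mapping to the deformed configuration is

    normal:   r(rho) = sqrt(ri^2 + (rho^2 - rho_i^2) / (kappa lam_z)),
    everted:  r(rho) = sqrt(ri^2 + (rho_o^2 - rho^2) / (kappa lam_z)),

with lam_theta = kappa r / rho, lam_z = lam, lam_r = 1/(lam_theta lam_z).
The only non-trivial equilibrium equation (radial) integrates to the
pressure-radius relation P = int_{ri}^{ro} (sigma_theta - sigma_r)/r dr over
the isochoric stress difference, and the reaction (constraint) stress is

    p(r) = P + sigma_r(r) - int_{ri}^{r} (sigma_theta(q) - sigma_r(q))/q dq.

The tabulated geometry (R, H) describes the *unloaded closed* ring: the
sector inner radius rho_i is recovered once per artery by requiring the
closed, axially unstretched ring to be in equilibrium at zero pressure.

Wall integrals use fixed-order Gauss-Legendre quadrature in the reference
radial coordinate; transmural profiles use a dense uniform reference grid
with cumulative trapezoidal integration for p(r).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.optimize import brentq

from .datasets import (MN_PER_N, PressureRadiusSeries, RunConfig, SilicoArtery,
                       StressSeries, pressure_grid)
from .hgo import PrincipalStretches, isochoric_stress

__all__ = [
    "DeformedState", "TransmuralProfile", "residual_stress_parameter",
    "stress_free_sector", "solve_inner_radius", "pressure_sweep",
    "transmural_profile", "transmural_gradient", "reduced_axial_force",
    "silico_load_fraction", "midwall_stress_series", "reaction_stress_at",
    "add_measurement_noise",
]


@dataclass(frozen=True)
class DeformedState:
    """One solved extension-inflation state of a thick-walled artery.

    ``k`` is stored as the positive magnitude kappa; ``everted`` records
    whether the stress-free sector closes inside-out (opening angle beyond
    180 degrees), in which case the sector outer radius rho_o maps to the
    deformed inner radius ri.
    """

    P: float  # kPa
    ri: float  # mm
    ro: float  # mm
    h: float  # mm
    k: float  # |residual-stress parameter|
    everted: bool
    lam_z: float
    rho_i: float  # stress-free sector inner radius, mm
    rho_o: float  # stress-free sector outer radius, mm

    @property
    def r_mid(self) -> float:
        """Mid-wall radius ri + h/2 in the deformed configuration."""
        return self.ri + 0.5 * self.h

    def radius_at(self, rho) -> np.ndarray:
        """Deformed radius of the material circle at reference radius rho."""
        if self.everted:
            num = self.rho_o**2 - np.square(rho)
        else:
            num = np.square(rho) - self.rho_i**2
        return np.sqrt(self.ri**2 + num / (self.k * self.lam_z))

    def reference_radius_at(self, r) -> np.ndarray:
        """Inverse map: reference radius of the deformed circle at r."""
        shift = self.k * self.lam_z * (np.square(r) - self.ri**2)
        if self.everted:
            return np.sqrt(self.rho_o**2 - shift)
        return np.sqrt(self.rho_i**2 + shift)


@dataclass
class TransmuralProfile:
    """Through-thickness stress state at one pressure level (all in kPa).

    Arrays are ordered by increasing deformed radius (lumen first).
    """

    P: float
    r_grid: np.ndarray  # deformed radii, mm
    rho_grid: np.ndarray  # reference radii, mm
    iso_theta: np.ndarray
    aniso_theta: np.ndarray
    total_theta: np.ndarray
    iso_z: np.ndarray
    aniso_z: np.ndarray
    total_z: np.ndarray
    reaction_p: np.ndarray
    sigma_rr: np.ndarray  # total radial stress


def residual_stress_parameter(phi0_deg: float, convention: str = "full") -> float:
    """Signed residual-stress parameter k from the tabulated opening angle.

    Under the 'full' (Fung-type) convention k = pi/(pi - Phi0): the sector
    spans 2(pi - Phi0), a flat strip corresponds to Phi0 = 180 degrees
    (singular), and Phi0 > 180 describes an everted ring with k < 0.  Under
    the 'half' convention the tabulated angle is twice the kinematic one,
    k = 2 pi/(2 pi - Phi0) > 0 for all admissible angles.
    """
    if not 0.0 <= phi0_deg < 360.0:
        raise ValueError(f"opening angle {phi0_deg} outside [0, 360) deg")
    phi0 = np.deg2rad(phi0_deg)
    if convention == "half":
        return float(2.0 * np.pi / (2.0 * np.pi - phi0))
    if convention != "full":
        raise ValueError(f"unknown opening-angle convention {convention!r}")
    if phi0_deg == 180.0:
        raise ValueError("opening angle 180 deg (flat strip) is singular "
                         "under the 'full' convention")
    return float(np.pi / (np.pi - phi0))


def _kappa_everted(artery: SilicoArtery, config: RunConfig) -> tuple[float, bool]:
    k = residual_stress_parameter(artery.Phi0, config.opening_angle_convention)
    return abs(k), k < 0.0


@lru_cache(maxsize=None)
def _gauss_nodes(n: int) -> tuple[np.ndarray, np.ndarray]:
    return np.polynomial.legendre.leggauss(n)


def _map_radius(rho, ri, rho_i, rho_o, kappa, lam_z, everted):
    num = (rho_o**2 - np.square(rho)) if everted else (np.square(rho) - rho_i**2)
    return np.sqrt(ri**2 + num / (kappa * lam_z))


def _stress_diff(rho, ri, rho_i, rho_o, kappa, lam_z, everted, artery):
    """(sigma_theta - sigma_r)(rho) of the isochoric stress, and r(rho)."""
    r = _map_radius(rho, ri, rho_i, rho_o, kappa, lam_z, everted)
    lam_th = kappa * r / rho
    s = isochoric_stress(PrincipalStretches.plane(lam_th, lam_z),
                         artery.c, artery.k1, artery.k2, artery.beta)
    return (s.iso_theta + s.aniso_theta) - s.iso_r, r


def _luminal_pressure(ri, rho_i, rho_o, kappa, lam_z, everted, artery, n_quad):
    """P required to hold inner radius ri: the wall quadrature of equilibrium."""
    x, w = _gauss_nodes(n_quad)
    mid, half = 0.5 * (rho_o + rho_i), 0.5 * (rho_o - rho_i)
    rho = mid + half * x
    diff, r = _stress_diff(rho, ri, rho_i, rho_o, kappa, lam_z, everted, artery)
    # |dr| = rho / (kappa lam_z r) d(rho); integrand (sig_th - sig_r)/r dr
    return float(np.sum(w * diff * rho / (kappa * lam_z * np.square(r))) * half)


def _bracket_root(fun, lo, hi, what: str):
    """Bracket a root of an increasing function; +inf means 'beyond range'."""

    def safe(x):
        try:
            return fun(x)
        except FloatingPointError:
            return np.inf

    f_lo = safe(lo)
    for _ in range(80):
        if f_lo < 0.0:
            break
        hi = lo
        lo *= 0.7
        f_lo = safe(lo)
    else:
        raise RuntimeError(f"{what}: no lower bracket endpoint found")
    f_hi = safe(hi)
    for _ in range(80):
        if f_hi >= 0.0:
            break
        lo = hi
        hi *= 1.4
        f_hi = safe(hi)
    else:
        raise RuntimeError(f"{what}: no upper bracket endpoint found")
    for _ in range(80):
        if np.isfinite(f_hi):
            break
        mid = 0.5 * (lo + hi)
        f_mid = safe(mid)
        if f_mid < 0.0:
            lo = mid
        else:
            hi, f_hi = mid, f_mid
    else:
        raise RuntimeError(f"{what}: could not shrink bracket to finite values")
    return lo, hi


@lru_cache(maxsize=None)
def stress_free_sector(artery: SilicoArtery, config: RunConfig) -> tuple[float, float]:
    """Radii (rho_i, rho_o) of the cut-open stress-free sector.

    Under the default 'unloaded' geometry interpretation the tabulated (R, H)
    are the inner radius and thickness of the unloaded closed ring; rho_i is
    found so that this ring (lam_z = 1, P = 0) is in radial equilibrium, with
    rho_o fixed by incompressibility.  Under 'sector' the tabulated values are
    the sector radii themselves.
    """
    kappa, everted = _kappa_everted(artery, config)
    if config.geometry_interpretation == "sector":
        return artery.R, artery.R + artery.H
    if artery.Phi0 == 0.0:
        return artery.R, artery.R + artery.H

    ro_u = artery.R + artery.H
    area = kappa * (ro_u**2 - artery.R**2)  # rho_o^2 - rho_i^2 at lam_z = 1

    def residual(rho_i: float) -> float:
        rho_o = np.sqrt(rho_i**2 + area)
        # decreasing in rho_i; negate to feed the increasing-function bracketer
        return -_luminal_pressure(artery.R, rho_i, rho_o, kappa, 1.0, everted,
                                  artery, config.n_quad)

    center = kappa * artery.R  # lam_theta(rho_i) = 1 there
    lo, hi = _bracket_root(residual, 0.7 * center, 1.4 * center,
                           f"set {artery.set_id} stress-free sector")
    rho_i = brentq(residual, lo, hi, xtol=1e-12, rtol=8.9e-16)
    return float(rho_i), float(np.sqrt(rho_i**2 + area))


def solve_inner_radius(artery: SilicoArtery, P: float,
                       config: RunConfig | None = None) -> DeformedState:
    """Solve the deformed inner radius at luminal pressure P (kPa)."""
    config = config or RunConfig()
    if P < 0:
        raise ValueError("P must be non-negative")
    kappa, everted = _kappa_everted(artery, config)
    rho_i, rho_o = stress_free_sector(artery, config)
    lam_z = artery.lam

    def residual(ri: float) -> float:
        return _luminal_pressure(ri, rho_i, rho_o, kappa, lam_z, everted,
                                 artery, config.n_quad) - P

    lo, hi = _bracket_root(residual, 0.8 * artery.R, 3.0 * artery.R,
                           f"set {artery.set_id} at P = {P} kPa")
    ri = brentq(residual, lo, hi, xtol=1e-13, rtol=8.9e-16)
    ro = float(np.sqrt(ri**2 + (rho_o**2 - rho_i**2) / (kappa * lam_z)))
    return DeformedState(P=float(P), ri=float(ri), ro=ro, h=ro - float(ri),
                         k=kappa, everted=everted, lam_z=lam_z,
                         rho_i=rho_i, rho_o=rho_o)


def pressure_sweep(artery: SilicoArtery, config: RunConfig | None = None
                   ) -> tuple[PressureRadiusSeries, list[DeformedState]]:
    """Solve every pressure level of the grid; the in silico 'measurement'."""
    config = config or RunConfig()
    states = []
    for P in pressure_grid(config):
        try:
            states.append(solve_inner_radius(artery, P, config))
        except RuntimeError as err:
            raise RuntimeError(f"pressure level {P} kPa failed: {err}") from err
    series = PressureRadiusSeries(
        P=np.array([s.P for s in states]),
        ri=np.array([s.ri for s in states]),
        h=np.array([s.h for s in states]))
    return series, states


def _stresses_on(rho, state: DeformedState, artery: SilicoArtery):
    r = state.radius_at(rho)
    lam_th = state.k * r / rho
    s = isochoric_stress(PrincipalStretches.plane(lam_th, state.lam_z),
                         artery.c, artery.k1, artery.k2, artery.beta)
    return s, r


def transmural_profile(state: DeformedState, artery: SilicoArtery,
                       config: RunConfig | None = None) -> TransmuralProfile:
    """Through-thickness stress components and the reaction stress p(r)."""
    config = config or RunConfig()
    rho = np.linspace(state.rho_i, state.rho_o, config.n_profile)
    s, r = _stresses_on(rho, state, artery)
    diff = (s.iso_theta + s.aniso_theta) - s.iso_r
    integrand = diff * rho / (state.k * state.lam_z * np.square(r))
    accum = cumulative_trapezoid(integrand, rho, initial=0.0)
    if state.everted:  # integration from the lumen starts at the rho_o end
        accum = accum[-1] - accum
    p = state.P + s.iso_r - accum
    fields = dict(
        iso_theta=s.iso_theta, aniso_theta=s.aniso_theta,
        total_theta=s.iso_theta + s.aniso_theta - p,
        iso_z=s.iso_z, aniso_z=s.aniso_z,
        total_z=s.iso_z + s.aniso_z - p,
        reaction_p=p, sigma_rr=s.iso_r - p)
    if state.everted:  # store lumen-first
        rho, r = rho[::-1], r[::-1]
        fields = {key: val[::-1] for key, val in fields.items()}
    return TransmuralProfile(P=state.P, r_grid=r, rho_grid=rho, **fields)


def transmural_gradient(profile: TransmuralProfile, direction: str) -> float:
    """Total stress at the outer wall minus at the inner wall (kPa)."""
    series = profile.total_theta if direction == "theta" else profile.total_z
    return float(series[-1] - series[0])


def reaction_stress_at(state: DeformedState, artery: SilicoArtery, r_eval: float,
                       config: RunConfig | None = None) -> float:
    """Reaction stress p at deformed radius r_eval, by wall quadrature."""
    config = config or RunConfig()
    rho_eval = float(state.reference_radius_at(r_eval))
    x, w = _gauss_nodes(config.n_quad)
    # integrate (sig_th - sig_r)/q dq from the lumen radius to r_eval
    if state.everted:
        a, b = rho_eval, state.rho_o
    else:
        a, b = state.rho_i, rho_eval
    mid, half = 0.5 * (a + b), 0.5 * (b - a)
    rho = mid + half * x
    s, r = _stresses_on(rho, state, artery)
    diff = (s.iso_theta + s.aniso_theta) - s.iso_r
    accum = float(np.sum(w * diff * rho / (state.k * state.lam_z * np.square(r))) * half)
    s_eval, _ = _stresses_on(np.array([rho_eval]), state, artery)
    return state.P + float(s_eval.iso_r[0]) - accum


def reduced_axial_force(state: DeformedState, artery: SilicoArtery,
                        config: RunConfig | None = None) -> float:
    """Reduced axial force F_red = pi int (2 sig_z - sig_th - sig_r) r dr, in N.

    The reaction stress cancels in the integrand, so only isochoric components
    enter; the kPa*mm^2 result is converted to newtons.
    """
    config = config or RunConfig()
    x, w = _gauss_nodes(config.n_quad)
    mid, half = 0.5 * (state.rho_o + state.rho_i), 0.5 * (state.rho_o - state.rho_i)
    rho = mid + half * x
    s, r = _stresses_on(rho, state, artery)
    integrand = (2.0 * (s.iso_z + s.aniso_z) - (s.iso_theta + s.aniso_theta)
                 - s.iso_r)
    # |r dr| = rho / (kappa lam_z) d(rho)
    force = np.pi * float(np.sum(w * integrand * rho) * half) / (state.k * state.lam_z)
    return force / MN_PER_N


def silico_load_fraction(state: DeformedState, artery: SilicoArtery,
                         direction: str, config: RunConfig | None = None) -> float:
    """Collagen load-bearing fraction: wall integrals of aniso/(iso+aniso)."""
    config = config or RunConfig()
    x, w = _gauss_nodes(config.n_quad)
    mid, half = 0.5 * (state.rho_o + state.rho_i), 0.5 * (state.rho_o - state.rho_i)
    rho = mid + half * x
    s, r = _stresses_on(rho, state, artery)
    if direction == "theta":
        aniso, iso = s.aniso_theta, s.iso_theta
    elif direction == "z":
        aniso, iso = s.aniso_z, s.iso_z
    else:
        raise ValueError(f"unknown direction {direction!r}")
    # |dr| = rho / (kappa lam_z r) d(rho); the constant prefactor cancels
    jac = rho / r
    num = float(np.sum(w * aniso * jac))
    den = float(np.sum(w * (iso + aniso) * jac))
    if den == 0.0:
        raise ZeroDivisionError("degenerate material: zero total directional stress")
    return num / den


def midwall_stress_series(artery: SilicoArtery, states: list[DeformedState],
                          config: RunConfig | None = None) -> StressSeries:
    """Mid-wall stress components and wall-averaged load fractions per level."""
    config = config or RunConfig()
    n = len(states)
    out = {name: np.empty(n) for name in
           ("iso_th", "aniso_th", "tot_th", "iso_z", "aniso_z", "tot_z",
            "p", "psi_th", "psi_z")}
    for i, st in enumerate(states):
        rho_m = float(st.reference_radius_at(st.r_mid))
        s, _ = _stresses_on(np.array([rho_m]), st, artery)
        p = reaction_stress_at(st, artery, st.r_mid, config)
        out["iso_th"][i] = s.iso_theta[0]
        out["aniso_th"][i] = s.aniso_theta[0]
        out["tot_th"][i] = s.iso_theta[0] + s.aniso_theta[0] - p
        out["iso_z"][i] = s.iso_z[0]
        out["aniso_z"][i] = s.aniso_z[0]
        out["tot_z"][i] = s.iso_z[0] + s.aniso_z[0] - p
        out["p"][i] = p
        out["psi_th"][i] = silico_load_fraction(st, artery, "theta", config)
        out["psi_z"][i] = silico_load_fraction(st, artery, "z", config)
    return StressSeries(
        P=np.array([s.P for s in states]),
        sigma_iso_theta=out["iso_th"], sigma_aniso_theta=out["aniso_th"],
        sigma_total_theta=out["tot_th"], sigma_iso_z=out["iso_z"],
        sigma_aniso_z=out["aniso_z"], sigma_total_z=out["tot_z"],
        reaction_p=out["p"], psi_aniso_theta=out["psi_th"],
        psi_aniso_z=out["psi_z"], model="silico")


def add_measurement_noise(series: PressureRadiusSeries, sd_radius_mm: float,
                          seed: int) -> PressureRadiusSeries:
    """Emulate ultrasound radius noise: i.i.d. Gaussian perturbation of ri.

    The wall thickness is recomputed from the unperturbed state's conserved
    cross-section area h (2 ri + h), so the noisy series stays kinematically
    admissible.  Deterministic for a given seed.
    """
    if sd_radius_mm < 0:
        raise ValueError("noise sd must be non-negative")
    if sd_radius_mm == 0.0:
        return PressureRadiusSeries(series.P.copy(), series.ri.copy(), series.h.copy())
    rng = np.random.default_rng(seed)
    ri = series.ri + rng.normal(0.0, sd_radius_mm, size=len(series))
    area = series.h * (2.0 * series.ri + series.h)
    h = -ri + np.sqrt(np.square(ri) + area)
    return PressureRadiusSeries(series.P.copy(), ri, h)
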