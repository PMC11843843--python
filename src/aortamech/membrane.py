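"""The constitutive membrane (thin-wall) model used for in vivo identification.

Two stress sets are computed from a measured (P, ri, h) signal:

* equilibrium stresses from global force balance,
      sigma_theta_eq = (ri/h + alpha) P,
      sigma_z_eq     = (pi ri^2 P + Fred) / (pi h (2 ri + h)),
      sigma_r_eq     = 0,
  with the reduced axial force replaced in vivo by the estimate
      Fred_est = Pmap pi [ (gamma/2) (2 ri + h)^2 - ri^2 ]
  built from the assumption sigma_z/sigma_theta = gamma at mean pressure;

* constitutive stresses from the HGO law at the mid-wall membrane stretches
      lam_theta_m = (2 ri + h) / (Ri + sqrt(Ri^2 + lam h (2 ri + h))),
      lam_z_m = lam,  lam_r_m = 1/(lam_theta_m lam_z_m),
  measured from the unloaded configuration with inner radius Ri (the square
  root is the unloaded outer radius under incompressibility), with the
  reaction stress p_mod = 2 c lam_r_m^2 enforcing zero radial stress.

The identification (see :mod:`aortamech.identify`) minimizes the squared
difference between the two sets over the pressure sweep.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datasets import (MN_PER_N, MembraneParams, PressureRadiusSeries,
                       RunConfig, StressSeries, pressure_grid)
from .hgo import PrincipalStretches, isochoric_stress

__all__ = ["MembraneState", "equilibrium_stresses", "estimate_reduced_axial_force",
           "membrane_stretches", "membrane_constitutive_stresses",
           "membrane_load_fraction", "membrane_stress_series", "synthetic_series"]


@dataclass
class MembraneState:
    """Membrane kinematics at one or more pressure levels (vectorized)."""

    P: np.ndarray
    ri: np.ndarray
    h: np.ndarray
    lam_th_m: np.ndarray
    lam_z_m: np.ndarray
    lam_r_m: np.ndarray


def equilibrium_stresses(ri, h, P, Fred_N: float, alpha: float = 0.5):
    """Membrane equilibrium stresses (sigma_theta, sigma_z, sigma_r) in kPa.

    ``Fred_N`` is the reduced axial force in newtons (converted internally to
    kPa*mm^2); radial stress is neglected against the membrane stresses.
    """
    ri = np.asarray(ri, dtype=float)
    h = np.asarray(h, dtype=float)
    P = np.asarray(P, dtype=float)
    if np.any(h <= 0) or np.any(ri <= 0):
        raise ValueError("invalid geometry: ri and h must be positive")
    fred = Fred_N * MN_PER_N
    sig_th = (ri / h + alpha) * P
    sig_z = (np.pi * np.square(ri) * P + fred) / (np.pi * h * (2.0 * ri + h))
    return sig_th, sig_z, np.zeros_like(sig_th)


def estimate_reduced_axial_force(ri_map: float, h_map: float,
                                 config: RunConfig | None = None) -> float:
    """Estimated reduced axial force (N) from the gamma-ratio assumption.

    ``ri_map`` and ``h_map`` are the measured inner radius and thickness at
    mean arterial pressure.
    """
    config = config or RunConfig()
    g = config.gamma
    fred = config.P_map * np.pi * (0.5 * g * (2.0 * ri_map + h_map) ** 2 - ri_map**2)
    return float(fred) / MN_PER_N


def membrane_stretches(ri, h, Ri: float, lam: float) -> MembraneState:
    """Mid-wall membrane stretches from measured geometry and unloaded Ri."""
    ri = np.asarray(ri, dtype=float)
    h = np.asarray(h, dtype=float)
    if Ri <= 0 or lam <= 0:
        raise ValueError("Ri and lam must be positive")
    span = 2.0 * ri + h
    lam_th = span / (Ri + np.sqrt(Ri**2 + lam * h * span))
    lam_z = np.full_like(lam_th, lam)
    return MembraneState(P=np.zeros_like(lam_th), ri=ri, h=h,
                         lam_th_m=lam_th, lam_z_m=lam_z,
                         lam_r_m=1.0 / (lam_th * lam_z))


def membrane_constitutive_stresses(state: MembraneState, params: MembraneParams):
    """Constitutive membrane stresses per direction.

    Returns a dict with keys 'iso_theta', 'aniso_theta', 'total_theta',
    'iso_z', 'aniso_z', 'total_z', 'pmod' (all kPa).  The reaction stress
    pmod = 2 c lam_r_m^2 enforces zero total radial stress exactly.
    """
    s = isochoric_stress(
        PrincipalStretches(state.lam_r_m, state.lam_th_m, state.lam_z_m),
        params.c, params.k1, params.k2, params.beta)
    pmod = 2.0 * params.c * np.square(state.lam_r_m)
    return {
        "iso_theta": s.iso_theta, "aniso_theta": s.aniso_theta,
        "total_theta": s.iso_theta + s.aniso_theta - pmod,
        "iso_z": s.iso_z, "aniso_z": s.aniso_z,
        "total_z": s.iso_z + s.aniso_z - pmod,
        "pmod": pmod,
    }


def membrane_load_fraction(stresses: dict, direction: str):
    """Collagen load-bearing fraction aniso/(iso+aniso), pointwise."""
    iso = stresses[f"iso_{direction}"]
    aniso = stresses[f"aniso_{direction}"]
    den = iso + aniso
    if np.any(den == 0.0):
        raise ZeroDivisionError("zero directional stress: fraction undefined")
    return aniso / den


def membrane_stress_series(series: PressureRadiusSeries, params: MembraneParams,
                           config: RunConfig | None = None) -> StressSeries:
    """Constitutive membrane predictions along a measured pressure sweep."""
    config = config or RunConfig()
    state = membrane_stretches(series.ri, series.h, params.Ri, params.lam)
    st = membrane_constitutive_stresses(state, params)
    return StressSeries(
        P=series.P.copy(),
        sigma_iso_theta=st["iso_theta"], sigma_aniso_theta=st["aniso_theta"],
        sigma_total_theta=st["total_theta"], sigma_iso_z=st["iso_z"],
        sigma_aniso_z=st["aniso_z"], sigma_total_z=st["total_z"],
        reaction_p=st["pmod"],
        psi_aniso_theta=membrane_load_fraction(st, "theta"),
        psi_aniso_z=membrane_load_fraction(st, "z"),
        model="membrane")


def _geometry_from_stretch(s: float, h: float, Ri: float, lam: float):
    """Invert the mid-wall stretch relation: (ri, span=2ri+h) for given s, h.

    With S = 2 ri + h the stretch reads s = S/(Ri + sqrt(Ri^2 + lam h S));
    eliminating the square root gives a quadratic for it, solved here.
    """
    u = 0.5 * (s * lam * h
               + np.sqrt((s * lam * h) ** 2 + 4.0 * (Ri**2 + lam * h * s * Ri)))
    S = s * (Ri + u)
    return 0.5 * (S - h), S


def synthetic_series(params: MembraneParams, config: RunConfig | None = None,
                     max_iter: int = 60, tol: float = 1e-12) -> PressureRadiusSeries:
    """Generate the (P, ri, h) signal of an exact membrane artery.

    At every pressure level both membrane equilibrium equations are satisfied
    by the constitutive stresses, with the axial force taken as the
    gamma-ratio estimate computed self-consistently from the series at mean
    pressure (fixed-point iteration).  On such a series the identification
    objective vanishes exactly at ``params``.
    """
    from scipy.optimize import brentq

    config = config or RunConfig()
    P_levels = pressure_grid(config)

    def residual_pair(s, h, P, fred_N):
        ri, _ = _geometry_from_stretch(s, h, params.Ri, params.lam)
        st = membrane_constitutive_stresses(
            membrane_stretches(ri, h, params.Ri, params.lam), params)
        sth_eq, sz_eq, _ = equilibrium_stresses(ri, h, P, fred_N, config.alpha)
        return float(st["total_theta"] - sth_eq), float(st["total_z"] - sz_eq)

    def thickness_on_circ_balance(s, P, fred_N):
        """h at which the circumferential equation holds, for given stretch."""
        r1 = lambda h: residual_pair(s, h, P, fred_N)[0]
        # cap the search at thin-wall thicknesses; beyond lies a second,
        # unphysical thick-branch root of the same equation
        lo, hi, cap = 1e-4, 0.2 * params.Ri, 0.6 * params.Ri
        f_hi = r1(hi)
        while r1(lo) * f_hi > 0.0:
            if hi >= cap:
                return None
            hi = min(hi * 1.5, cap)
            f_hi = r1(hi)
        return brentq(r1, lo, hi, xtol=1e-14)

    def solve_level(P, fred_N, s_warm=None):
        # nested 1-D solves: the axial residual along the circumferential
        # balance curve is monotone decreasing in the stretch
        def g(s):
            h = thickness_on_circ_balance(s, P, fred_N)
            if h is None:
                return None
            return residual_pair(s, h, P, fred_N)[1]

        def refine(a, b):
            s_root = brentq(g, a, b, xtol=1e-14)
            return s_root, thickness_on_circ_balance(s_root, P, fred_N)

        if s_warm is not None:
            try:  # walk from the previous level's solution
                a, fa = s_warm, g(s_warm)
                for _ in range(200):
                    if fa is None:
                        break
                    b = a * (1.003 if fa > 0 else 1 / 1.003)
                    fb = g(b)
                    if fb is None:
                        break
                    if fa * fb <= 0.0:
                        return refine(*sorted((a, b)))
                    a, fa = b, fb
            except (FloatingPointError, ValueError):
                pass

        grid = np.concatenate([
            np.linspace(0.4, 1.0, 20, endpoint=False),
            1.0 + 1e-3 + np.concatenate([[0.0], np.geomspace(1e-3, 4.0, 60)])])
        prev_s, prev_g = None, None
        for s in grid:
            try:
                val = g(float(s))
            except (FloatingPointError, ValueError):
                val = None
            if val is None:
                prev_s, prev_g = None, None
                continue
            if prev_g is not None and prev_g * val <= 0.0:
                return refine(prev_s, float(s))
            prev_s, prev_g = float(s), val
        raise RuntimeError(f"membrane forward solve failed at P = {P} kPa")

    # initial axial-force guess from the identified value or a Laplace scale
    fred = params.Fred_est if params.Fred_est is not None else 0.5
    ri = np.empty_like(P_levels)
    h = np.empty_like(P_levels)
    for _ in range(max_iter):
        s = None
        for j, P in enumerate(P_levels):
            s, hh = solve_level(float(P), fred, s_warm=s)
            ri[j] = _geometry_from_stretch(s, hh, params.Ri, params.lam)[0]
            h[j] = hh
        series = PressureRadiusSeries(P_levels, ri, h)
        fred_new = estimate_reduced_axial_force(
            *series.at_pressure(config.P_map), config)
        if abs(fred_new - fred) < tol:
            break
        fred = fred_new
    return PressureRadiusSeries(P_levels, ri, h)
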