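"""Holzapfel-Gasser-Ogden constitutive kernel.

The strain energy is the sum of a neo-Hookean matrix part,
Psi_iso = c (I1 - 3), and an exponential collagen part carried by two
mechanically equivalent fiber families arranged symmetrically around the
circumferential direction at pitch angle beta,

    Psi_aniso = (k1 / 2 k2) (exp(k2 (I4 - 1)^2) + exp(k2 (I6 - 1)^2) - 2),

with I4 = I6 = lam_theta^2 cos^2(beta) + lam_z^2 sin^2(beta).  Fibers are
tension-only: the anisotropic stress vanishes for I4 < 1.  For diagonal
deformation gradients the push-forward 2 F (dPsi/dC) F^T gives the isochoric
Cauchy stress components implemented here:

    sigma_iso_d   = 2 c lam_d^2,
    sigma_aniso_theta = 4 k1 (I4 - 1) e^{k2 (I4-1)^2} lam_theta^2 cos^2(beta),
    sigma_aniso_z     = 4 k1 (I4 - 1) e^{k2 (I4-1)^2} lam_z^2 sin^2(beta),
    sigma_aniso_r     = 0,

where the factor 4 = 2 (push-forward) x 2 (fiber families); the off-diagonal
theta-z terms of the two families cancel by symmetry.  All functions are
vectorized over stretch arrays.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PrincipalStretches", "IsochoricStress", "fiber_invariant",
           "isochoric_stress", "strain_energy"]

# exp argument beyond which the fiber exponential is numerically meaningless
_EXP_LIMIT = 500.0


@dataclass(frozen=True)
class PrincipalStretches:
    """Incompressible principal stretches (radial, circumferential, axial)."""

    lam_r: np.ndarray | float
    lam_th: np.ndarray | float
    lam_z: np.ndarray | float

    @classmethod
    def plane(cls, lam_th, lam_z) -> "PrincipalStretches":
        """Construct from the in-plane pair; lam_r follows from det F = 1."""
        lam_th, lam_z = np.broadcast_arrays(np.asarray(lam_th, dtype=float),
                                            np.asarray(lam_z, dtype=float))
        if np.any(lam_th <= 0) or np.any(lam_z <= 0):
            raise ValueError("stretches must be positive")
        return cls(1.0 / (lam_th * lam_z), lam_th, lam_z)


@dataclass(frozen=True)
class IsochoricStress:
    """Isochoric Cauchy stress components (kPa) and the fiber invariant."""

    iso_r: np.ndarray | float
    iso_theta: np.ndarray | float
    iso_z: np.ndarray | float
    aniso_r: np.ndarray | float
    aniso_theta: np.ndarray | float
    aniso_z: np.ndarray | float
    I4: np.ndarray | float


def fiber_invariant(lam_th, lam_z, beta_deg):
    """I4 = I6 = lam_theta^2 cos^2(beta) + lam_z^2 sin^2(beta)."""
    b = np.deg2rad(beta_deg)
    return np.square(lam_th) * np.cos(b) ** 2 + np.square(lam_z) * np.sin(b) ** 2


def strain_energy(stretches: PrincipalStretches, c, k1, k2, beta_deg):
    """Psi = Psi_iso + Psi_aniso per unit reference volume (kPa)."""
    I1 = (np.square(stretches.lam_r) + np.square(stretches.lam_th)
          + np.square(stretches.lam_z))
    psi = c * (I1 - 3.0)
    I4 = fiber_invariant(stretches.lam_th, stretches.lam_z, beta_deg)
    e = I4 - 1.0
    active = e > 0.0
    psi_fib = np.where(active, k1 / (2.0 * k2)
                       * 2.0 * (np.exp(k2 * np.square(np.where(active, e, 0.0))) - 1.0),
                       0.0)
    return psi + psi_fib


def isochoric_stress(stretches: PrincipalStretches, c, k1, k2, beta_deg) -> IsochoricStress:
    """Isochoric Cauchy stress of the HGO law at the given principal stretches.

    Raises
    ------
    FloatingPointError
        If the fiber exponent k2 (I4-1)^2 exceeds the overflow guard, which
        indicates stretches or parameters far outside the physical range.
    """
    lam_r = np.square(stretches.lam_r)
    lam_th = np.square(stretches.lam_th)
    lam_z = np.square(stretches.lam_z)
    iso_r, iso_th, iso_z = 2.0 * c * lam_r, 2.0 * c * lam_th, 2.0 * c * lam_z

    I4 = fiber_invariant(stretches.lam_th, stretches.lam_z, beta_deg)
    e = np.asarray(I4, dtype=float) - 1.0
    arg = k2 * np.square(e)
    if np.any(arg > _EXP_LIMIT):
        raise FloatingPointError(
            f"fiber exponential overflow: k2 (I4-1)^2 = {np.max(arg):.3g} "
            f"(I4 max {np.max(I4):.6g}); stretches/parameters out of physical range")
    b = np.deg2rad(beta_deg)
    gain = np.where(e > 0.0, 4.0 * k1 * e * np.exp(arg), 0.0)
    aniso_th = gain * lam_th * np.cos(b) ** 2
    aniso_z = gain * lam_z * np.sin(b) ** 2
    return IsochoricStress(iso_r, iso_th, iso_z,
                           np.zeros_like(np.asarray(aniso_th, dtype=float)),
                           aniso_th, aniso_z, I4)
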