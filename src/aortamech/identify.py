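"""In vivo parameter identification from a pressure-radius series.

Six membrane parameters theta = (Ri, c, k1, k2, beta, lam) are identified by
minimizing the sum over pressure levels and both in-plane directions of the
squared difference between the membrane equilibrium stresses (computed from
the measured geometry, with the reduced axial force replaced by its
gamma-ratio estimate at mean pressure) and the constitutive membrane
stresses.  The problem is non-convex; a seeded Latin-hypercube multi-start
of bounded trust-region least-squares keeps the best local solution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import qmc

from .datasets import MembraneParams, PressureRadiusSeries, RunConfig
from .membrane import (equilibrium_stresses, estimate_reduced_axial_force,
                       membrane_constitutive_stresses, membrane_stretches)

__all__ = ["ParameterBounds", "IdentificationResult", "objective", "identify"]

_PENALTY = 1e6  # finite residual magnitude for non-finite stress evaluations

_NAMES = ("Ri", "c", "k1", "k2", "beta", "lam")


@dataclass(frozen=True)
class ParameterBounds:
    """Box bounds for theta; defaults cover every tabulated identified set."""

    Ri: tuple[float, float] = (1.0, 20.0)  # mm
    c: tuple[float, float] = (0.01, 200.0)  # kPa
    k1: tuple[float, float] = (0.01, 200.0)  # kPa
    k2: tuple[float, float] = (0.01, 200.0)
    beta: tuple[float, float] = (1.0, 89.0)  # deg
    lam: tuple[float, float] = (1.0, 6.0)

    def arrays(self) -> tuple[np.ndarray, np.ndarray]:
        pairs = [getattr(self, n) for n in _NAMES]
        return (np.array([p[0] for p in pairs]),
                np.array([p[1] for p in pairs]))


@dataclass
class StartRecord:
    x0: np.ndarray
    x: np.ndarray
    cost: float
    status: int


@dataclass
class IdentificationResult:
    params: MembraneParams
    objective_value: float  # kPa^2
    fred_est: float  # N, the estimate used in the axial equilibrium stress
    n_starts: int
    converged_fraction: float
    starts: list[StartRecord] = field(default_factory=list)


def _residuals(theta, series: PressureRadiusSeries, fred_est_N: float,
               config: RunConfig, normalize: bool) -> np.ndarray:
    Ri, c, k1, k2, beta, lam = theta
    sig_th_eq, sig_z_eq, _ = equilibrium_stresses(
        series.ri, series.h, series.P, fred_est_N, config.alpha)
    try:
        state = membrane_stretches(series.ri, series.h, Ri, lam)
        st = membrane_constitutive_stresses(
            state, MembraneParams(set_id="_", Ri=Ri, c=c, k1=k1, k2=k2,
                                  beta=beta, lam=lam))
    except (FloatingPointError, ValueError):
        return np.full(2 * len(series), _PENALTY)
    res = np.concatenate([st["total_theta"] - sig_th_eq,
                          st["total_z"] - sig_z_eq])
    if normalize:
        scales = np.concatenate([np.full(len(series), np.mean(np.abs(sig_th_eq))),
                                 np.full(len(series), np.mean(np.abs(sig_z_eq)))])
        res = res / np.maximum(scales, 1e-12)
    if not np.all(np.isfinite(res)):
        return np.full_like(res, _PENALTY)
    return res


def objective(theta, series: PressureRadiusSeries,
              config: RunConfig | None = None, *,
              fred_est_N: float | None = None,
              normalize: bool = False) -> float:
    """Sum of squared stress differences over levels and directions (kPa^2).

    The reduced axial force estimate is computed once from the series at mean
    arterial pressure unless supplied.  ``normalize`` switches to
    per-direction mean-stress scaling (dimensionless objective) for
    sensitivity studies.
    """
    config = config or RunConfig()
    if fred_est_N is None:
        fred_est_N = estimate_reduced_axial_force(
            *series.at_pressure(config.P_map), config)
    res = _residuals(np.asarray(theta, dtype=float), series, fred_est_N,
                     config, normalize)
    return float(np.dot(res, res))


def identify(series: PressureRadiusSeries, config: RunConfig | None = None,
             seed: int = 0, *, n_starts: int = 64,
             bounds: ParameterBounds | None = None,
             normalize: bool = False, set_id: str = "") -> IdentificationResult:
    """Multi-start bounded least-squares identification of theta.

    Start points are drawn from a seeded Latin hypercube over the bounds;
    each start runs a trust-region-reflective least-squares solve, and the
    lowest final objective wins.  Deterministic for a given seed.
    """
    config = config or RunConfig()
    if len(series) < 6:
        raise ValueError("need at least 6 pressure levels for 6 unknowns")
    bounds = bounds or ParameterBounds()
    lo, hi = bounds.arrays()
    fred_est_N = estimate_reduced_axial_force(
        *series.at_pressure(config.P_map), config)

    sampler = qmc.LatinHypercube(d=len(_NAMES), seed=seed)
    # geometric spread for the stiffness-like parameters, linear for the rest
    unit = sampler.random(n_starts)
    x0s = np.empty_like(unit)
    for j, name in enumerate(_NAMES):
        if name in ("c", "k1", "k2"):
            x0s[:, j] = lo[j] * (hi[j] / lo[j]) ** unit[:, j]
        else:
            x0s[:, j] = lo[j] + (hi[j] - lo[j]) * unit[:, j]

    starts: list[StartRecord] = []
    for x0 in x0s:
        try:
            with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
                sol = least_squares(
                    _residuals, x0, bounds=(lo, hi),
                    args=(series, fred_est_N, config, normalize),
                    method="trf", xtol=1e-14, ftol=1e-14, gtol=1e-14,
                    max_nfev=400)
            starts.append(StartRecord(x0=x0.copy(), x=sol.x.copy(),
                                      cost=2.0 * float(sol.cost),
                                      status=int(sol.status)))
        except Exception:  # noqa: BLE001 - keep the multi-start going
            starts.append(StartRecord(x0=x0.copy(), x=x0.copy(),
                                      cost=np.inf, status=-1))
    ok = [s for s in starts if np.isfinite(s.cost)]
    if not ok:
        raise RuntimeError(
            "identification failed for every start point; statuses: "
            + ", ".join(str(s.status) for s in starts))
    best = min(ok, key=lambda s: s.cost)
    params = MembraneParams(set_id=set_id or "identified",
                            Ri=best.x[0], c=best.x[1], k1=best.x[2],
                            k2=best.x[3], beta=best.x[4], lam=best.x[5],
                            Fred_est=fred_est_N)
    return IdentificationResult(
        params=params, objective_value=best.cost, fred_est=fred_est_N,
        n_starts=n_starts,
        converged_fraction=sum(s.status > 0 for s in starts) / len(starts),
        starts=starts)
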