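"""Domain types, run configuration, and packaged parameter fixtures.

Unit conventions
----------------
All stresses are held in kPa and all lengths in mm throughout the package.
Forces therefore arise internally in kPa*mm^2 (= mN) and are converted to
newtons (factor 1/1000) exactly once, at the I/O boundary where tabulated
values are in N.  Angles are stored in degrees as tabulated and converted
to radians at the point of use.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from importlib import resources
from typing import Literal

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "SilicoArtery",
    "MembraneParams",
    "RunConfig",
    "PressureRadiusSeries",
    "StressSeries",
    "MetricPair",
    "ComparisonMetrics",
    "load_fixture_tables",
    "load_clinic_row",
    "pressure_grid",
    "MN_PER_N",
]

#: forces are accumulated in kPa*mm^2 = mN; divide by this to report newtons
MN_PER_N = 1000.0


@dataclass(frozen=True)
class SilicoArtery:
    """One thick-walled in silico abdominal aorta.

    ``R`` and ``H`` are the inner radius and wall thickness of the *unloaded,
    closed* configuration (residually stressed, load-free ring); the
    stress-free cut-open sector is recovered from them and the opening angle
    by the simulator.  ``Fred_mean_ref`` is the tabulated mean reduced axial
    force of the reference simulation and is carried as an oracle value only.
    """

    set_id: str
    group: str  # one of {"hg", "lc", "cs"}
    R: float  # mm
    H: float  # mm
    Phi0: float  # opening angle, degrees
    c: float  # kPa
    k1: float  # kPa
    k2: float  # dimensionless
    beta: float  # fiber pitch angle, degrees
    lam: float  # in vivo axial pre-stretch
    Fred_mean_ref: float  # N
    label: str = ""

    def __post_init__(self) -> None:
        if not (self.R > 0 and self.H > 0):
            raise ValueError(f"set {self.set_id}: R and H must be positive")
        if not (self.c > 0 and self.k1 > 0 and self.k2 > 0):
            raise ValueError(f"set {self.set_id}: material parameters must be positive")
        if not 0.0 <= self.beta < 90.0:
            raise ValueError(f"set {self.set_id}: beta must lie in [0, 90) deg")
        if self.lam < 1.0:
            raise ValueError(f"set {self.set_id}: lam must be >= 1")
        if not 0.0 <= self.Phi0 < 360.0:
            raise ValueError(f"set {self.set_id}: Phi0 must lie in [0, 360) deg")


@dataclass(frozen=True)
class MembraneParams:
    """One identified parameter set of the constitutive membrane model."""

    set_id: str
    Ri: float  # unloaded inner radius, mm
    c: float  # kPa
    k1: float  # kPa
    k2: float  # dimensionless
    beta: float  # degrees
    lam: float  # identified axial stretch
    Fred_est: float | None = None  # estimated reduced axial force, N
    group: str = ""
    label: str = ""

    def __post_init__(self) -> None:
        if self.Ri <= 0:
            raise ValueError(f"set {self.set_id}: Ri must be positive")
        if not (self.c > 0 and self.k1 > 0 and self.k2 > 0):
            raise ValueError(f"set {self.set_id}: material parameters must be positive")
        if not 0.0 <= self.beta < 90.0:
            raise ValueError(f"set {self.set_id}: beta must lie in [0, 90) deg")
        if self.lam < 1.0:
            raise ValueError(f"set {self.set_id}: lam must be >= 1")


@dataclass(frozen=True)
class RunConfig:
    """Study conditions: pressure window, membrane constants, and numerics.

    Defaults are the conditions of the evaluation study: diastolic-to-systolic
    sweep 9.3-16 kPa at 101 uniform levels, mean arterial pressure 13.3 kPa,
    mid-wall evaluation parameter alpha = 0.5, and axial-to-circumferential
    stress ratio gamma = 0.59 at mean pressure.
    """

    P_dbp: float = 9.3  # kPa
    P_sbp: float = 16.0  # kPa
    P_map: float = 13.3  # kPa
    n_levels: int = 101
    alpha: float = 0.5
    gamma: float = 0.59
    opening_angle_convention: Literal["half", "full"] = "full"
    geometry_interpretation: Literal["unloaded", "sector"] = "unloaded"
    quadrature_tol: float = 1e-10
    root_tol: float = 1e-10
    n_quad: int = 80  # Gauss-Legendre nodes for wall integrals
    n_profile: int = 2001  # reference-grid points for transmural profiles

    def __post_init__(self) -> None:
        if not (self.P_dbp < self.P_map < self.P_sbp):
            raise ValueError("require P_dbp < P_map < P_sbp")
        if self.n_levels < 2:
            raise ValueError("n_levels must be >= 2")
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError("alpha must lie in (0, 1]")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def with_(self, **kwargs) -> "RunConfig":
        return replace(self, **kwargs)


@dataclass
class PressureRadiusSeries:
    """Per-pressure (P, ri, h): the 'measured' in vivo signal."""

    P: np.ndarray  # kPa
    ri: np.ndarray  # mm
    h: np.ndarray  # mm

    def __post_init__(self) -> None:
        self.P = np.asarray(self.P, dtype=float)
        self.ri = np.asarray(self.ri, dtype=float)
        self.h = np.asarray(self.h, dtype=float)
        if not (self.P.shape == self.ri.shape == self.h.shape):
            raise ValueError("P, ri, h must have equal lengths")
        if np.any(np.diff(self.P) <= 0):
            raise ValueError("P must be strictly increasing")
        if np.any(self.h <= 0):
            raise ValueError("h must be positive")

    def __len__(self) -> int:
        return len(self.P)

    def at_pressure(self, P: float) -> tuple[float, float]:
        """(ri, h) at pressure ``P`` by linear interpolation within the sweep."""
        if not (self.P[0] <= P <= self.P[-1]):
            raise ValueError(f"P={P} outside series range [{self.P[0]}, {self.P[-1]}]")
        return (float(np.interp(P, self.P, self.ri)),
                float(np.interp(P, self.P, self.h)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"P_kPa": self.P, "ri_mm": self.ri, "h_mm": self.h})

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PressureRadiusSeries":
        return cls(df["P_kPa"].to_numpy(), df["ri_mm"].to_numpy(), df["h_mm"].to_numpy())


@dataclass
class StressSeries:
    """Per-pressure stress components of one model, both directions, in kPa.

    ``psi_aniso_*`` are the collagen load-bearing fractions.  The invariant
    total = iso + aniso - reaction_p holds componentwise in each direction.
    """

    P: np.ndarray
    sigma_iso_theta: np.ndarray
    sigma_aniso_theta: np.ndarray
    sigma_total_theta: np.ndarray
    sigma_iso_z: np.ndarray
    sigma_aniso_z: np.ndarray
    sigma_total_z: np.ndarray
    reaction_p: np.ndarray
    psi_aniso_theta: np.ndarray
    psi_aniso_z: np.ndarray
    model: str = ""

    def component(self, direction: str, component: str) -> np.ndarray:
        """Fetch a series by direction ('theta'|'z') and component name."""
        if component == "reaction":
            return self.reaction_p
        if component == "fraction":
            return getattr(self, f"psi_aniso_{direction}")
        return getattr(self, f"sigma_{component}_{direction}")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "P_kPa": self.P,
            "sigma_iso_theta_kPa": self.sigma_iso_theta,
            "sigma_aniso_theta_kPa": self.sigma_aniso_theta,
            "sigma_total_theta_kPa": self.sigma_total_theta,
            "sigma_iso_z_kPa": self.sigma_iso_z,
            "sigma_aniso_z_kPa": self.sigma_aniso_z,
            "sigma_total_z_kPa": self.sigma_total_z,
            "reaction_p_kPa": self.reaction_p,
            "psi_aniso_theta": self.psi_aniso_theta,
            "psi_aniso_z": self.psi_aniso_z,
        })
        df.insert(0, "model", self.model)
        return df


@dataclass(frozen=True)
class MetricPair:
    """Agreement between a predicted and a reference curve.

    ``delta_max`` is the signed difference of maximum magnitude; ``r_hat_sq``
    the offset-corrected coefficient of determination clipped to [0, 1], or
    ``None`` when the reference curve is constant and the measure undefined.
    """

    delta_max: float
    r_hat_sq: float | None


@dataclass
class ComparisonMetrics:
    """One full per-set comparison row: metrics keyed by (direction, component).

    Directions are 'theta' and 'z' for components 'iso', 'aniso', 'total' and
    'fraction'; the reaction stress is direction-free and keyed ('', 'reaction').
    """

    set_id: str
    group: str
    metrics: dict[tuple[str, str], MetricPair] = field(default_factory=dict)

    def to_records(self) -> list[dict]:
        out = []
        for (direction, component), m in self.metrics.items():
            out.append({
                "set_id": self.set_id, "group": self.group,
                "direction": direction, "component": component,
                "delta_max": m.delta_max,
                "r_hat_sq": np.nan if m.r_hat_sq is None else m.r_hat_sq,
            })
        return out


# ---------------------------------------------------------------------------
# fixtures

_SILICO_COLS = ["set_id", "label", "group", "R_mm", "H_mm", "Phi0_deg", "c_kPa",
                "k1_kPa", "k2", "beta_deg", "lam", "Fred_mean_N"]
_MEMBRANE_COLS = ["set_id", "label", "group", "Ri_mm", "c_kPa", "k1_kPa", "k2",
                  "beta_deg", "lam", "Fred_est_N"]


def _read_fixture(name: str, required: list[str]) -> pd.DataFrame:
    ref = resources.files("aortamech.data") / name
    with resources.as_file(ref) as path:
        df = pd.read_csv(path, dtype={"set_id": str, "label": str})
    missing = [col for col in required if col not in df.columns]
    if missing:
        raise ValueError(f"fixture {name} is corrupted: missing columns {missing}")
    return df


def load_fixture_tables() -> tuple[list[SilicoArtery], list[MembraneParams]]:
    """Load the 21 thick-wall parameter sets and their identified counterparts.

    Returns the in silico sets (groups hg: 1-6, lc: 7-14, cs: 15-21) and the
    21 identified membrane parameter sets, aligned by ``set_id``.  The clinical
    cohort summary row is excluded here; see :func:`load_clinic_row`.
    """
    sil = _read_fixture("silico_sets.csv", _SILICO_COLS)
    mem = _read_fixture("membrane_sets.csv", _MEMBRANE_COLS)
    arteries = [
        SilicoArtery(
            set_id=row.set_id, label="" if pd.isna(row.label) else row.label,
            group=row.group, R=row.R_mm, H=row.H_mm, Phi0=row.Phi0_deg,
            c=row.c_kPa, k1=row.k1_kPa, k2=row.k2, beta=row.beta_deg,
            lam=row.lam, Fred_mean_ref=row.Fred_mean_N,
        )
        for row in sil.itertuples()
    ]
    membranes = [
        MembraneParams(
            set_id=row.set_id, label="" if pd.isna(row.label) else row.label,
            group=row.group, Ri=row.Ri_mm, c=row.c_kPa, k1=row.k1_kPa,
            k2=row.k2, beta=row.beta_deg, lam=row.lam,
            Fred_est=None if pd.isna(row.Fred_est_N) else row.Fred_est_N,
        )
        for row in mem.itertuples() if row.group != "clinic"
    ]
    if len(arteries) != len(membranes):
        raise ValueError("fixture tables are inconsistent: set counts differ")
    return arteries, membranes


def load_clinic_row() -> MembraneParams:
    """The clinical-cohort summary parameter row (not runnable as a thick wall)."""
    mem = _read_fixture("membrane_sets.csv", _MEMBRANE_COLS)
    row = mem[mem.group == "clinic"].iloc[0]
    return MembraneParams(
        set_id=str(row.set_id), group="clinic", Ri=row.Ri_mm, c=row.c_kPa,
        k1=row.k1_kPa, k2=row.k2, beta=row.beta_deg, lam=row.lam, Fred_est=None,
    )


def pressure_grid(config: RunConfig) -> np.ndarray:
    """Uniform pressure levels from diastolic to systolic, inclusive (kPa)."""
    return np.linspace(config.P_dbp, config.P_sbp, config.n_levels)
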