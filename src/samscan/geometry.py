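"""Per-orientation observables and desk-scale estimates.

Covers the quantities used to rationalize how an adsorbed redox enzyme
couples to an electrode: the molecular dipole moment (magnitude and
angle to the surface normal), directional statistics of a dipole
pseudo-trajectory, perpendicular cofactor-to-surface distances,
optimal-superposition (Kabsch) RMSD as a structural-integrity check,
and two independent monolayer surface-coverage estimators.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Optional, Sequence, Union

import numpy as np
from scipy.spatial.transform import Rotation

from .constants import AVOGADRO, EA_TO_DEBYE
from .model import MolecularModel
from .surface import SurfaceModel

__all__ = [
    "DipoleRecord",
    "TrajectoryStats",
    "CoverageEstimate",
    "dipole_moment",
    "trajectory_dipole_stats",
    "estimate_vmf_kappa",
    "surface_distance",
    "kabsch_rmsd",
    "coverage_hex_packing",
    "coverage_de_feijter",
]


@dataclasses.dataclass
class DipoleRecord:
    """Dipole vector in Debye with its origin convention.

    For a charged species the dipole depends on the reference point, so
    the origin and the net charge are recorded alongside the vector.
    ``angle_to_normal`` is measured against +z (the surface normal).
    """

    vector: np.ndarray
    magnitude: float
    angle_to_normal: float
    origin: str
    net_charge: float

    def validate(self) -> None:
        if abs(self.magnitude - np.linalg.norm(self.vector)) > 1e-9:
            raise ValueError("magnitude inconsistent with vector")
        if not 0.0 <= self.angle_to_normal <= 180.0:
            raise ValueError("angle_to_normal outside [0, 180]")


@dataclasses.dataclass
class TrajectoryStats:
    """Directional statistics of a dipole pseudo-trajectory."""

    n_frames: int
    mean_direction: np.ndarray
    angular_spread: float        # degrees, circular SD √(−2 ln R̄)
    magnitude_mean: float        # Debye
    magnitude_sd: float          # Debye
    mean_resultant_length: float


@dataclasses.dataclass
class CoverageEstimate:
    """Monolayer coverage with the method and inputs that produced it."""

    molar_coverage: float        # pmol/cm²
    mass_coverage: float         # ng/cm²
    method: str
    inputs: dict


# ----------------------------------------------------------------------
# Dipole moment
# ----------------------------------------------------------------------

def _origin_point(
    model: MolecularModel, origin: Union[str, Sequence[float]]
) -> tuple[np.ndarray, str]:
    if isinstance(origin, str):
        if origin == "center_of_mass":
            return model.center_of_mass(), origin
        if origin == "center_of_geometry":
            return model.center_of_geometry(), origin
        raise ValueError(f"unknown origin convention {origin!r}")
    return np.asarray(origin, dtype=float), "custom"


def dipole_moment(
    model: MolecularModel, origin: Union[str, Sequence[float]] = "center_of_mass"
) -> DipoleRecord:
    """μ⃗ = 4.8032 × Σ q_i (r⃗_i − r⃗_origin), charges in e, positions in
    Å, result in Debye. The default origin is the center of mass (unit
    masses where elements are unknown); the origin is recorded because
    the result is origin-dependent for net-charged species."""
    point, label = _origin_point(model, origin)
    vec = EA_TO_DEBYE * (
        model.charges[:, None] * (model.positions - point)
    ).sum(axis=0)
    mag = float(np.linalg.norm(vec))
    if mag > 1e-12:
        cosang = np.clip(vec[2] / mag, -1.0, 1.0)
        angle = math.degrees(math.acos(cosang))
    else:
        angle = 0.0
    rec = DipoleRecord(
        vector=vec,
        magnitude=mag,
        angle_to_normal=angle,
        origin=label,
        net_charge=float(model.charges.sum()),
    )
    rec.validate()
    return rec


def trajectory_dipole_stats(
    frames: Sequence[MolecularModel],
    origin: Union[str, Sequence[float]] = "center_of_mass",
) -> TrajectoryStats:
    """Per-frame dipoles of an ensemble, summarized as a mean direction,
    a circular standard deviation √(−2 ln R̄) (degrees) of the dipole
    direction about that mean, and the magnitude mean/SD in Debye."""
    if len(frames) < 2:
        raise ValueError("need at least 2 frames")
    n_atoms = len(frames[0])
    if any(len(f) != n_atoms for f in frames):
        raise ValueError("inconsistent atom counts across frames")
    vecs = np.array([dipole_moment(f, origin).vector for f in frames])
    mags = np.linalg.norm(vecs, axis=1)
    if np.any(mags < 1e-12):
        raise ValueError("zero dipole frame: direction undefined")
    units = vecs / mags[:, None]
    resultant = units.mean(axis=0)
    rbar = float(np.linalg.norm(resultant))
    mean_dir = resultant / rbar if rbar > 1e-12 else np.array([0.0, 0.0, 1.0])
    spread = math.degrees(math.sqrt(max(0.0, -2.0 * math.log(min(rbar, 1.0))))) \
        if rbar > 0 else float("inf")
    return TrajectoryStats(
        n_frames=len(frames),
        mean_direction=mean_dir,
        angular_spread=spread,
        magnitude_mean=float(mags.mean()),
        magnitude_sd=float(mags.std()),
        mean_resultant_length=rbar,
    )


def estimate_vmf_kappa(rbar: float, dim: int = 3) -> float:
    """Banerjee approximation κ̂ = R̄(d − R̄²)/(1 − R̄²) for the
    von Mises–Fisher concentration from a mean resultant length."""
    if not 0.0 <= rbar < 1.0:
        raise ValueError("mean resultant length must lie in [0, 1)")
    return rbar * (dim - rbar**2) / (1.0 - rbar**2)


# ----------------------------------------------------------------------
# Distances and superposition
# ----------------------------------------------------------------------

def surface_distance(
    model: MolecularModel,
    selection: str,
    surface: SurfaceModel,
    reference: str = "sam_top",
) -> float:
    """Perpendicular (z) distance from the centroid of the selected
    atoms to the reference plane: ``sam_top`` (topmost SAM heavy atom)
    or ``au_top`` (gold layer)."""
    idx = model.select(selection)
    if len(idx) == 0:
        raise ValueError(f"selection {selection!r} matches no atoms")
    if reference == "sam_top":
        plane_z = surface.top_z
    elif reference == "au_top":
        gold = surface.atoms.tagged("gold")
        if len(gold) == 0:
            raise ValueError("surface has no gold layer")
        plane_z = float(surface.atoms.positions[gold, 2].max())
    else:
        raise ValueError(f"unknown reference plane {reference!r}")
    centroid_z = float(model.positions[idx, 2].mean())
    return centroid_z - plane_z


def kabsch_rmsd(
    reference: MolecularModel,
    mobile: MolecularModel,
    selection: Optional[str] = None,
) -> float:
    """Minimal RMSD after optimal least-squares superposition (rotation
    + translation, proper rotations only)."""
    if selection is not None:
        ri = reference.select(selection)
        mi = mobile.select(selection)
        if len(ri) == 0 or len(mi) == 0:
            raise ValueError(f"selection {selection!r} matches no atoms")
        p = reference.positions[ri]
        q = mobile.positions[mi]
    else:
        p = reference.positions
        q = mobile.positions
    if p.shape != q.shape:
        raise ValueError("selected atom counts differ between models")
    p0 = p - p.mean(axis=0)
    q0 = q - q.mean(axis=0)
    rot, _ = Rotation.align_vectors(p0, q0)
    diff = p0 - rot.apply(q0)
    return float(np.sqrt((diff**2).sum() / len(p0)))


# ----------------------------------------------------------------------
# Surface coverage
# ----------------------------------------------------------------------

def coverage_hex_packing(
    diameter: float, molecular_weight: Optional[float] = None
) -> CoverageEstimate:
    """Molar coverage of a hexagonally close-packed monolayer of disks
    of the given *diameter* (nm): Γ = 1 / (N_A · (√3/2)·d²), returned
    in pmol/cm². Each molecule occupies the hexagonal unit cell area
    (√3/2)·d²."""
    if diameter <= 0:
        raise ValueError("diameter must be positive")
    d_cm = diameter * 1e-7
    area = (math.sqrt(3.0) / 2.0) * d_cm**2          # cm² per molecule
    molar = 1.0 / (AVOGADRO * area)                   # mol/cm²
    molar_pmol = molar * 1e12
    mw = molecular_weight or 0.0
    mass_ng = molar * mw * 1e9
    return CoverageEstimate(
        molar_coverage=molar_pmol,
        mass_coverage=mass_ng,
        method="hex_packing",
        inputs={"diameter_nm": diameter, "molecular_weight": molecular_weight},
    )


def coverage_de_feijter(
    thickness: float,
    n_film: float,
    n_ambient: float,
    dn_dc: float,
    molecular_weight: float,
) -> CoverageEstimate:
    """de Feijter estimate from ellipsometry: adsorbed mass
    Γ = t·(n_film − n_ambient)/(dn/dc) with the thickness in nm and
    dn/dc in cm³/g; molar coverage is Γ/MW. Raises if the film index is
    below the ambient index (nonphysical film)."""
    if dn_dc <= 0:
        raise ValueError("dn/dc must be positive")
    if thickness < 0:
        raise ValueError("thickness must be non-negative")
    if n_film < n_ambient:
        raise ValueError("film refractive index below ambient: nonphysical")
    t_cm = thickness * 1e-7
    mass = t_cm * (n_film - n_ambient) / dn_dc        # g/cm²
    molar = mass / molecular_weight                   # mol/cm²
    est = CoverageEstimate(
        molar_coverage=molar * 1e12,
        mass_coverage=mass * 1e9,
        method="de_feijter",
        inputs={
            "thickness_nm": thickness,
            "n_film": n_film,
            "n_ambient": n_ambient,
            "dn_dc_cm3_per_g": dn_dc,
            "molecular_weight": molecular_weight,
        },
    )
    if molecular_weight > 0 and mass > 0:
        assert abs(est.molar_coverage - est.mass_coverage * 1e3 / molecular_weight) \
            <= 1e-9 * est.molar_coverage
    return est
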