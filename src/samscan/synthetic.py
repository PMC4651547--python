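"""Synthetic bodies, landscapes, and dipole pseudo-trajectories.

Every generator is deterministic for a fixed seed and has a closed-form
ground truth, so each pipeline stage can be tested end to end without
any external structure file: a ±q dumbbell with an analytic dipole, a
patchy sphere whose charged cap fixes the preferred orientation over a
charged slab, a two-basin toy landscape with planted minima, and a
von Mises–Fisher dipole trajectory with prescribed mean direction and
concentration.

These toys emulate the coarse electrostatic features that drive the
orientation screen — net charge, charge patches, macrodipoles — not
realistic protein folds or sequence-derived charge distributions.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np

from .model import AtomRecord, MolecularModel
from .scan import EnergyLandscape, ScanConfig

__all__ = [
    "make_dumbbell",
    "make_patchy_sphere",
    "make_random_blob",
    "make_two_basin_landscape",
    "make_vmf_dipole_trajectory",
    "sample_vmf",
]

#: Toy LJ parameters; small so electrostatics dominates patch tests.
TOY_LJ = (0.1, 2.0)


def make_dumbbell(q: float, separation: float) -> MolecularModel:
    """Two point charges +q and −q on the z axis, center of geometry at
    the origin: analytic dipole 4.8032·q·separation Debye along +z and
    zero net charge."""
    if separation <= 0:
        raise ValueError("separation must be positive")
    h = separation / 2.0
    atoms = [
        AtomRecord("QP", "C", "DUM", 1, "X", np.array([0.0, 0.0, +h]),
                   charge=+q, lj_epsilon=TOY_LJ[0], lj_rmin_half=TOY_LJ[1]),
        AtomRecord("QM", "C", "DUM", 1, "X", np.array([0.0, 0.0, -h]),
                   charge=-q, lj_epsilon=TOY_LJ[0], lj_rmin_half=TOY_LJ[1]),
    ]
    return MolecularModel("dumbbell", atoms)


def fibonacci_sphere(n: int) -> np.ndarray:
    """Quasi-uniform unit-sphere point set (Fibonacci lattice)."""
    i = np.arange(n)
    golden = (1.0 + math.sqrt(5.0)) / 2.0
    z = 1.0 - (2.0 * i + 1.0) / n
    phi = 2.0 * math.pi * i / golden
    r = np.sqrt(np.clip(1.0 - z**2, 0.0, 1.0))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def make_patchy_sphere(
    n_atoms: int,
    radius: float,
    cap_half_angle: float,
    cap_charge: float,
    seed: int = 0,
) -> MolecularModel:
    """Sphere of *n_atoms* pseudo-atoms with a charged polar cap.

    Atoms within *cap_half_angle* degrees of +z share *cap_charge*
    equally; the rest are neutral. All atoms carry identical small LJ
    parameters, so the preferred orientation over an oppositely charged
    slab is cap-toward-surface — the known ground truth for scan tests.
    The ``cap`` selection tags the charged atoms.
    """
    if n_atoms < 10:
        raise ValueError("need at least 10 atoms")
    points = radius * fibonacci_sphere(n_atoms)
    cos_cap = math.cos(math.radians(cap_half_angle))
    in_cap = points[:, 2] / radius >= cos_cap - 1e-12
    n_cap = int(in_cap.sum())
    if n_cap == 0:
        raise ValueError("cap_half_angle too small: no atoms in cap")
    atoms = []
    for i, p in enumerate(points):
        q = cap_charge / n_cap if in_cap[i] else 0.0
        atoms.append(
            AtomRecord(
                f"P{i % 100}", "C", "TOY", i + 1, "X", p,
                charge=q, lj_epsilon=TOY_LJ[0], lj_rmin_half=TOY_LJ[1],
                tags={"cap"} if in_cap[i] else set(),
            )
        )
    model = MolecularModel("patchy_sphere", atoms)
    model.set_selection("cap", np.flatnonzero(in_cap))
    return model


def make_random_blob(
    n_atoms: int, radius: float, net_charge: float, seed: int
) -> MolecularModel:
    """Random cloud of charged pseudo-atoms inside a sphere; per-atom
    charges are uniform draws rescaled to sum to *net_charge*."""
    rng = np.random.default_rng(seed)
    pos = rng.normal(size=(n_atoms, 3))
    pos *= radius * rng.uniform(0, 1, n_atoms)[:, None] ** (1 / 3) \
        / np.linalg.norm(pos, axis=1)[:, None]
    q = rng.uniform(-1.0, 1.0, n_atoms)
    q += (net_charge - q.sum()) / n_atoms
    atoms = [
        AtomRecord(f"B{i % 100}", "C", "TOY", i + 1, "X", pos[i],
                   charge=float(q[i]), lj_epsilon=TOY_LJ[0],
                   lj_rmin_half=TOY_LJ[1])
        for i in range(n_atoms)
    ]
    return MolecularModel("random_blob", atoms)


def _wrapped_sq_distance(grid: np.ndarray, center: float) -> np.ndarray:
    d = np.abs(grid - center) % 360.0
    return np.minimum(d, 360.0 - d) ** 2


def make_two_basin_landscape(
    basin_centers: Sequence[tuple[float, float]],
    depths: Sequence[float] = (10.0, 8.0),
    width: float = 10.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    config: Optional[ScanConfig] = None,
) -> EnergyLandscape:
    """Two wrapped negative Gaussian wells plus seeded Gaussian noise on
    the default 36 × 36 grid. With zero noise the argmin is exactly the
    deeper planted center; the planted minima are the ground truth for
    basin-selection tests."""
    if len(basin_centers) != 2:
        raise ValueError("exactly two basin centers required")
    (t1, p1), (t2, p2) = basin_centers
    sep = max(
        min(abs(t1 - t2) % 360, 360 - abs(t1 - t2) % 360),
        min(abs(p1 - p2) % 360, 360 - abs(p1 - p2) % 360),
    )
    if sep < 2 * width:
        raise ValueError("basin centers closer than 2×width on the torus")
    config = config or ScanConfig()
    thetas = config.theta_values
    psis = config.psi_values
    energies = np.zeros((len(thetas), len(psis)))
    for (tc, pc), depth in zip(basin_centers, depths):
        dt = _wrapped_sq_distance(thetas, tc)[:, None]
        dp = _wrapped_sq_distance(psis, pc)[None, :]
        energies -= depth * np.exp(-(dt + dp) / (2.0 * width**2))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        energies += rng.normal(0.0, noise_sd, energies.shape)
    out = EnergyLandscape(
        theta_values=thetas,
        psi_values=psis,
        energies=energies,
        config=config,
        provenance={
            "generator": "two_basin",
            "basin_centers": list(map(list, basin_centers)),
            "depths": list(depths),
            "width_deg": width,
            "noise_sd": noise_sd,
            "seed": seed,
        },
    )
    out.validate()
    return out


def sample_vmf(
    mean_direction: Sequence[float], kappa: float, n: int, seed: int
) -> np.ndarray:
    """Draw *n* unit vectors from a von Mises–Fisher distribution on S²
    by inversion of the exact marginal of the polar cosine
    (w = 1 + κ⁻¹·ln[u + (1−u)·e^(−2κ)]) with a uniform azimuth — the
    standard Wood-style construction. The spread-recovery oracle in the
    tests uses the closed-form estimator instead, keeping the check
    independent of this sampler."""
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    mu = np.asarray(mean_direction, dtype=float)
    mu = mu / np.linalg.norm(mu)
    rng = np.random.default_rng(seed)
    u = rng.uniform(size=n)
    w = 1.0 + np.log(u + (1.0 - u) * math.exp(-2.0 * kappa)) / kappa
    phi = rng.uniform(0.0, 2.0 * math.pi, n)
    # orthonormal frame around mu
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, mu)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = ref - np.dot(ref, mu) * mu
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(mu, e1)
    s = np.sqrt(np.clip(1.0 - w**2, 0.0, 1.0))
    return (
        w[:, None] * mu
        + s[:, None] * (np.cos(phi)[:, None] * e1 + np.sin(phi)[:, None] * e2)
    )


def make_vmf_dipole_trajectory(
    n_frames: int,
    mean_direction: Sequence[float],
    kappa: float,
    magnitude: float,
    seed: int,
) -> list[MolecularModel]:
    """Dipole pseudo-trajectory: each frame is a ±0.5 e dumbbell whose
    axis is a von Mises–Fisher draw about *mean_direction* with
    concentration κ, scaled so every frame's dipole magnitude is exactly
    *magnitude* Debye."""
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    from .constants import EA_TO_DEBYE

    directions = sample_vmf(mean_direction, kappa, n_frames, seed)
    q = 0.5
    separation = magnitude / (EA_TO_DEBYE * q)
    frames = []
    for k, d in enumerate(directions):
        h = (separation / 2.0) * d
        atoms = [
            AtomRecord("QP", "C", "DUM", 1, "X", +h, charge=+q),
            AtomRecord("QM", "C", "DUM", 1, "X", -h, charge=-q),
        ]
        frames.append(MolecularModel(f"vmf_frame_{k}", atoms))
    return frames
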