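"""SAM-on-gold surface slab builder.

Models a 6-amino-1-hexanethiol self-assembled monolayer chemisorbed on
Au(111): thiol sulfurs on a (√3×√3)R30° overlayer (spacing 4.995 Å),
each chain an untilted all-trans pseudo-atom stack topped by an amino
headgroup, above a single hexagonal gold layer that interacts only
through Lennard-Jones terms (no image charges — polarization is
neglected throughout). A configurable fraction of the amino headgroups
is protonated (–NH₃⁺, +1 e); at pH 7 against the thiol's surface pKa
of ≈6 that fraction is about 8%, the default here.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import numpy as np

from .model import AtomRecord, MolecularModel

__all__ = [
    "ChainSite",
    "SurfaceSpec",
    "SurfaceModel",
    "protonated_fraction",
    "assign_protonation",
    "build_sam_surface",
]

#: Au(111) nearest-neighbor distance, Å.
AU_SPACING = 2.884
#: Vertical offset of the Au plane below the thiol sulfurs, Å.
AU_Z_OFFSET = -2.0
#: Au LJ parameters (charge is always zero).
AU_LJ = (0.10, 1.65)


@dataclasses.dataclass(frozen=True)
class ChainSite:
    """One pseudo-atom of the per-site thiol chain."""

    name: str
    element: str
    z_offset: float          # Å above the sulfur anchor
    charge: float            # e (neutral-chain value)
    lj_epsilon: float
    lj_rmin_half: float


def _default_chain() -> tuple[ChainSite, ...]:
    """6-amino-1-hexanethiol: S anchor, six CH₂ pseudo-carbons at 1.25 Å
    z-increments, amino nitrogen headgroup on top."""
    sites = [ChainSite("S", "S", 0.0, 0.0, 0.45, 2.0)]
    sites += [
        ChainSite(f"C{k}", "C", 1.25 * k, 0.0, 0.08, 2.0) for k in range(1, 7)
    ]
    sites.append(ChainSite("N", "N", 1.25 * 7, 0.0, 0.20, 1.85))
    return tuple(sites)


@dataclasses.dataclass
class SurfaceSpec:
    """Parameters of the SAM slab.

    Defaults give a 25 × 29-site slab (≈122 Å × 121 Å, 725 chains) with
    exactly 8% of the amino headgroups protonated — the fraction
    appropriate for pH 7 against a surface pKa near 6 — so a protein
    footprint of ~100 Å stays inside the slab.
    """

    nx: int = 25
    ny: int = 29
    thiol_spacing: float = 4.995
    chain: Sequence[ChainSite] = dataclasses.field(default_factory=_default_chain)
    protonation_fraction: float = 0.08
    headgroup_charge_protonated: float = 1.0
    seed: int = 1
    gold_layers: int = 1

    def validate(self) -> None:
        if self.nx < 1 or self.ny < 1:
            raise ValueError("nx and ny must be ≥ 1")
        if self.thiol_spacing <= 0:
            raise ValueError("thiol_spacing must be positive")
        if not 0.0 <= self.protonation_fraction <= 1.0:
            raise ValueError("protonation_fraction must lie in [0, 1]")
        if self.gold_layers < 0:
            raise ValueError("gold_layers must be non-negative")


@dataclasses.dataclass
class SurfaceModel:
    """Built slab: atoms plus the metadata the scan needs."""

    atoms: MolecularModel
    top_z: float
    normal: np.ndarray
    protonated_indices: np.ndarray     # chain indices, 0 .. n_chains-1
    net_charge: float
    extent_x: float
    extent_y: float
    n_chains: int
    spec: Optional[SurfaceSpec] = None

    def validate(self) -> None:
        spec = self.spec or SurfaceSpec()
        expected = len(self.protonated_indices) * spec.headgroup_charge_protonated
        if abs(self.net_charge - expected) > 1e-6:
            raise ValueError("surface net charge inconsistent with protonation")
        sam = [
            z for z, tags in zip(self.atoms.positions[:, 2], self.atoms.tags)
            if "sam" in tags
        ]
        if sam and max(sam) > self.top_z + 1e-9:
            raise ValueError("SAM atom above top_z")


def protonated_fraction(pH: float, pKa: float) -> float:
    """Henderson–Hasselbalch fraction of protonated (–NH₃⁺) headgroups,
    ``1 / (1 + 10**(pH − pKa))``. Returns 0.5 at pH = pKa."""
    return 1.0 / (1.0 + 10.0 ** (pH - pKa))


def assign_protonation(n_chains: int, fraction: float, seed: int) -> np.ndarray:
    """Choose ``round(fraction × n_chains)`` distinct chain indices,
    uniformly without replacement from a seeded generator."""
    if n_chains < 1:
        raise ValueError("n_chains must be ≥ 1")
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    k = int(round(fraction * n_chains))
    rng = np.random.default_rng(seed)
    idx = rng.choice(n_chains, size=k, replace=False)
    return np.sort(idx)


def build_sam_surface(spec: Optional[SurfaceSpec] = None) -> SurfaceModel:
    """Build the SAM-coated Au slab described by *spec*.

    Thiol anchors sit on a hexagonal lattice with the given spacing;
    protonated chains carry +1 e (by default) on the amino headgroup,
    neutral chains are uncharged; a hexagonal Au pseudo-layer (LJ only)
    lies beneath the anchors. The slab is finite: no periodic images
    enter any energy sum, so a protein footprint should stay well inside
    the extents.
    """
    spec = spec or SurfaceSpec()
    spec.validate()
    a = spec.thiol_spacing
    row_h = a * np.sqrt(3.0) / 2.0

    n_chains = spec.nx * spec.ny
    protonated = assign_protonation(
        n_chains, spec.protonation_fraction, spec.seed
    )
    protonated_set = set(int(i) for i in protonated)

    atoms: list[AtomRecord] = []
    chain_idx = 0
    head_name = spec.chain[-1].name
    for j in range(spec.ny):
        for i in range(spec.nx):
            x = i * a + (j % 2) * a / 2.0
            y = j * row_h
            is_prot = chain_idx in protonated_set
            for site in spec.chain:
                charge = site.charge
                tags = {"sam"}
                if site.name == head_name:
                    tags.add("headgroup")
                    if is_prot:
                        charge = charge + spec.headgroup_charge_protonated
                        tags.add("protonated")
                atoms.append(
                    AtomRecord(
                        atom_name=site.name,
                        element=site.element,
                        residue_name="SAM",
                        residue_number=chain_idx + 1,
                        chain_id="S",
                        position=np.array([x, y, site.z_offset]),
                        charge=charge,
                        lj_epsilon=site.lj_epsilon,
                        lj_rmin_half=site.lj_rmin_half,
                        tags=tags,
                    )
                )
            chain_idx += 1

    top_z = max(site.z_offset for site in spec.chain)
    extent_x = (spec.nx - 1) * a + a / 2.0
    extent_y = (spec.ny - 1) * row_h

    # gold underlayer: hexagonal, LJ-only, spanning the SAM footprint
    gold_serial = 0
    for layer in range(spec.gold_layers):
        z = AU_Z_OFFSET - layer * AU_SPACING * np.sqrt(2.0 / 3.0)
        au_row = AU_SPACING * np.sqrt(3.0) / 2.0
        nyy = int(np.ceil(extent_y / au_row)) + 1
        nxx = int(np.ceil(extent_x / AU_SPACING)) + 1
        for j in range(nyy):
            for i in range(nxx):
                x = i * AU_SPACING + (j % 2) * AU_SPACING / 2.0
                y = j * au_row
                gold_serial += 1
                atoms.append(
                    AtomRecord(
                        atom_name="AU",
                        element="AU",
                        residue_name="AUL",
                        residue_number=gold_serial,  # unique per atom so PDB round-trips
                        chain_id="Z",
                        position=np.array([x, y, z]),
                        charge=0.0,
                        lj_epsilon=AU_LJ[0],
                        lj_rmin_half=AU_LJ[1],
                        tags={"gold"},
                    )
                )

    mm = MolecularModel("sam_surface", atoms)
    net = len(protonated) * spec.headgroup_charge_protonated
    surf = SurfaceModel(
        atoms=mm,
        top_z=top_z,
        normal=np.array([0.0, 0.0, 1.0]),
        protonated_indices=protonated,
        net_charge=float(net),
        extent_x=extent_x,
        extent_y=extent_y,
        n_chains=n_chains,
        spec=spec,
    )
    surf.validate()
    return surf
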