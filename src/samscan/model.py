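"""Core molecular containers.

A :class:`MolecularModel` is an ordered collection of atoms — a protein,
a cofactor set, a SAM slab, or a toy body — stored as parallel numpy
arrays for fast pairwise-energy work, with per-atom metadata (names,
residues, tags) kept as Python lists. :class:`AtomRecord` is the
single-atom construction/view convenience.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import numpy as np

from .constants import element_mass

__all__ = ["AtomRecord", "MolecularModel"]


@dataclasses.dataclass
class AtomRecord:
    """One atom: identity, position (Å), charge (e) and LJ parameters.

    ``lj_epsilon`` (kcal/mol) and ``lj_rmin_half`` (Å) are non-negative;
    zero means "no Lennard-Jones interaction".
    """

    atom_name: str
    element: str
    residue_name: str
    residue_number: int
    chain_id: str
    position: np.ndarray
    charge: float = 0.0
    lj_epsilon: float = 0.0
    lj_rmin_half: float = 0.0
    tags: set = dataclasses.field(default_factory=set)

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise ValueError("position must be a 3-vector")
        if not np.all(np.isfinite(self.position)):
            raise ValueError("position components must be finite")
        if self.lj_epsilon < 0 or self.lj_rmin_half < 0:
            raise ValueError("LJ parameters must be non-negative")
        self.tags = set(self.tags)


class MolecularModel:
    """Ordered atom collection with vectorized numeric columns.

    Attributes
    ----------
    name : str
    atom_names, elements, residue_names, chain_ids : list of str
    residue_numbers : list of int
    positions : (N, 3) float array, Å
    charges : (N,) float array, e
    lj_epsilon, lj_rmin_half : (N,) float arrays
    tags : list of set of str
    selections : dict mapping label -> index array
    net_charge : float — declared net charge; recomputed by
        parameterization, checked against the charge sum.
    """

    def __init__(self, name: str = "model", atoms: Iterable[AtomRecord] = ()):
        atoms = list(atoms)
        self.name = name
        self.atom_names = [a.atom_name for a in atoms]
        self.elements = [a.element for a in atoms]
        self.residue_names = [a.residue_name for a in atoms]
        self.residue_numbers = [a.residue_number for a in atoms]
        self.chain_ids = [a.chain_id for a in atoms]
        self.positions = (
            np.array([a.position for a in atoms], dtype=float)
            if atoms
            else np.zeros((0, 3))
        )
        self.charges = np.array([a.charge for a in atoms], dtype=float)
        self.lj_epsilon = np.array([a.lj_epsilon for a in atoms], dtype=float)
        self.lj_rmin_half = np.array([a.lj_rmin_half for a in atoms], dtype=float)
        self.tags = [set(a.tags) for a in atoms]
        self.selections: dict[str, np.ndarray] = {}
        self.net_charge = float(self.charges.sum())

    # -- basic protocol ------------------------------------------------
    def __len__(self) -> int:
        return len(self.atom_names)

    def atom(self, i: int) -> AtomRecord:
        """Materialize atom *i* as an :class:`AtomRecord`."""
        return AtomRecord(
            atom_name=self.atom_names[i],
            element=self.elements[i],
            residue_name=self.residue_names[i],
            residue_number=self.residue_numbers[i],
            chain_id=self.chain_ids[i],
            position=self.positions[i].copy(),
            charge=float(self.charges[i]),
            lj_epsilon=float(self.lj_epsilon[i]),
            lj_rmin_half=float(self.lj_rmin_half[i]),
            tags=set(self.tags[i]),
        )

    def atoms(self) -> list[AtomRecord]:
        return [self.atom(i) for i in range(len(self))]

    def copy(self) -> "MolecularModel":
        m = MolecularModel(self.name)
        m.atom_names = list(self.atom_names)
        m.elements = list(self.elements)
        m.residue_names = list(self.residue_names)
        m.residue_numbers = list(self.residue_numbers)
        m.chain_ids = list(self.chain_ids)
        m.positions = self.positions.copy()
        m.charges = self.charges.copy()
        m.lj_epsilon = self.lj_epsilon.copy()
        m.lj_rmin_half = self.lj_rmin_half.copy()
        m.tags = [set(t) for t in self.tags]
        m.selections = {k: np.array(v, dtype=int) for k, v in self.selections.items()}
        m.net_charge = self.net_charge
        return m

    def append(self, atom: AtomRecord) -> None:
        self.atom_names.append(atom.atom_name)
        self.elements.append(atom.element)
        self.residue_names.append(atom.residue_name)
        self.residue_numbers.append(atom.residue_number)
        self.chain_ids.append(atom.chain_id)
        self.positions = (
            np.vstack([self.positions, atom.position[None, :]])
            if len(self.positions)
            else atom.position[None, :].astype(float)
        )
        self.charges = np.append(self.charges, atom.charge)
        self.lj_epsilon = np.append(self.lj_epsilon, atom.lj_epsilon)
        self.lj_rmin_half = np.append(self.lj_rmin_half, atom.lj_rmin_half)
        self.tags.append(set(atom.tags))
        self.net_charge = float(self.charges.sum())

    # -- selections and tags -------------------------------------------
    def set_selection(self, label: str, indices: Sequence[int]) -> None:
        idx = np.asarray(indices, dtype=int)
        if len(idx) and (idx.min() < 0 or idx.max() >= len(self)):
            raise IndexError(f"selection {label!r} references invalid atom indices")
        self.selections[label] = idx

    def select(self, label: str) -> np.ndarray:
        """Indices for *label*: an explicit selection, or all atoms tagged with it."""
        if label in self.selections:
            return self.selections[label]
        idx = np.array([i for i, t in enumerate(self.tags) if label in t], dtype=int)
        return idx

    def tagged(self, tag: str) -> np.ndarray:
        return np.array([i for i, t in enumerate(self.tags) if tag in t], dtype=int)

    # -- geometry ------------------------------------------------------
    @property
    def masses(self) -> np.ndarray:
        return np.array([element_mass(e) for e in self.elements])

    def center_of_geometry(self) -> np.ndarray:
        if not len(self):
            raise ValueError("empty model has no center")
        return self.positions.mean(axis=0)

    def center_of_mass(self) -> np.ndarray:
        if not len(self):
            raise ValueError("empty model has no center")
        m = self.masses
        return (self.positions * m[:, None]).sum(axis=0) / m.sum()

    def translate(self, shift) -> "MolecularModel":
        out = self.copy()
        out.positions = out.positions + np.asarray(shift, dtype=float)
        return out

    def validate(self) -> None:
        """Check the container invariants; raise ValueError on violation."""
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("non-finite coordinates")
        if np.any(self.lj_epsilon < 0) or np.any(self.lj_rmin_half < 0):
            raise ValueError("negative LJ parameters")
        if abs(self.net_charge - self.charges.sum()) > 1e-6:
            raise ValueError("declared net_charge inconsistent with atom charges")
        for label, idx in self.selections.items():
            if len(idx) and (idx.min() < 0 or idx.max() >= len(self)):
                raise ValueError(f"selection {label!r} out of range")

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<MolecularModel {self.name!r}: {len(self)} atoms, "
            f"net charge {self.net_charge:+.3f} e>"
        )
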