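"""Structure I/O and parameterization.

Reads and writes PDB (wwPDB v3.3 columns, via gemmi, multi-MODEL aware)
and PQR (whitespace-delimited, charge and radius after the coordinates).
Assigns per-atom charges and Lennard-Jones parameters from a packaged
residue-level table, and extends a chain C-terminus with an ideal
α-helical Cα trace for segments unresolved in a crystal structure.

The packaged table is a deliberately minimal, heavy-atom united-charge
model: every hydrogen's charge is folded into its parent heavy atom, and
per-residue sums equal the formal charge at pH 7 (Asp/Glu −1, Lys/Arg +1,
His neutral). It is suitable for coarse electrostatic screening of
protein–surface orientations, not for quantitative force-field work.
"""

from __future__ import annotations

import csv
import logging
import math
from importlib import resources
from pathlib import Path
from typing import Mapping, Optional, Sequence

import gemmi
import numpy as np

from .model import AtomRecord, MolecularModel

logger = logging.getLogger(__name__)

__all__ = [
    "ParseError",
    "ForceFieldTable",
    "load_default_table",
    "read_structure",
    "read_models",
    "write_structure",
    "parameterize",
    "append_cterm_helix",
    "STANDARD_RESIDUES",
]


class ParseError(ValueError):
    """A structure file violated the named standard."""


STANDARD_RESIDUES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}

#: Residue-name aliases folded onto the packaged table's names.
RESIDUE_ALIASES = {
    "HSD": "HIS", "HSE": "HIS", "HSP": "HIS",
    "HID": "HIS", "HIE": "HIS", "HIP": "HIS",
    "CYX": "CYS", "MSE": "MET",
}

#: HETATM residue names recognized as FeS clusters (3RGW-style naming).
FES_RESIDUES = {"SF4", "F3S", "FS4", "FES", "FS3"}


# ----------------------------------------------------------------------
# Force-field table
# ----------------------------------------------------------------------

class ForceFieldTable:
    """Map (residue_name, atom_name) → (charge, lj_epsilon, lj_rmin_half).

    A ``("*", "*")`` row supplies the fallback for unmatched atoms.
    """

    def __init__(
        self,
        entries: Mapping[tuple[str, str], tuple[float, float, float]],
        default_entry: tuple[float, float, float] = (0.0, 0.05, 2.0),
        provenance: str = "",
    ):
        self.entries = dict(entries)
        self.default_entry = tuple(default_entry)
        self.provenance = provenance
        for res in STANDARD_RESIDUES:
            if not any(r == res for r, _ in self.entries):
                raise ValueError(f"table lacks entries for standard residue {res}")

    def lookup(self, residue_name: str, atom_name: str):
        res = RESIDUE_ALIASES.get(residue_name, residue_name)
        hit = self.entries.get((res, atom_name))
        if hit is not None:
            return hit, True
        hit = self.entries.get((res, "*"))
        if hit is not None:
            return hit, True
        return self.default_entry, False

    def residue_charge(self, residue_name: str) -> float:
        """Summed charge of all non-OXT entries for a residue."""
        return sum(
            q for (r, a), (q, _, _) in self.entries.items()
            if r == residue_name and a != "OXT"
        )

    def residue_names(self) -> set[str]:
        return {r for r, _ in self.entries}

    @classmethod
    def from_csv(cls, path, provenance: str = "") -> "ForceFieldTable":
        entries = {}
        default = (0.0, 0.05, 2.0)
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                key = (row["residue_name"], row["atom_name"])
                val = (
                    float(row["charge"]),
                    float(row["lj_epsilon"]),
                    float(row["lj_rmin_half"]),
                )
                if key == ("*", "*"):
                    default = val
                else:
                    entries[key] = val
        return cls(entries, default, provenance or str(path))


def load_default_table() -> ForceFieldTable:
    """The packaged united heavy-atom residue table."""
    ref = resources.files("samscan.data") / "residue_params.csv"
    with resources.as_file(ref) as path:
        return ForceFieldTable.from_csv(path, provenance="samscan packaged table")


# ----------------------------------------------------------------------
# Reading
# ----------------------------------------------------------------------

def _validate_pdb_lines(path: Path) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(("ATOM  ", "HETATM")):
                if len(line.rstrip("\n")) < 54:
                    raise ParseError(f"{path}:{lineno}: truncated coordinate record")
                try:
                    for lo, hi in ((30, 38), (38, 46), (46, 54)):
                        float(line[lo:hi])
                except ValueError:
                    raise ParseError(
                        f"{path}:{lineno}: unparseable coordinates in {line[:26]!r}"
                    ) from None


def _model_from_gemmi(gmodel: "gemmi.Model", name: str) -> MolecularModel:
    atoms = []
    for chain in gmodel:
        for residue in chain:
            het = residue.het_flag == "H"
            for atom in residue:
                tags = set()
                if het:
                    tags.add("hetero")
                    elem = atom.element.name.upper()
                    if elem == "NI" or residue.name in {"NFU", "NFE"}:
                        tags.add("cofactor:NiFe")
                    if residue.name in FES_RESIDUES:
                        tags.add("cofactor:FeS")
                atoms.append(
                    AtomRecord(
                        atom_name=atom.name,
                        element=atom.element.name,
                        residue_name=residue.name,
                        residue_number=residue.seqid.num,
                        chain_id=chain.name,
                        position=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                        tags=tags,
                    )
                )
    return MolecularModel(name, atoms)


def _read_pqr(path: Path) -> MolecularModel:
    atoms = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.startswith(("ATOM", "HETATM")):
                continue
            fields = line.split()
            # ATOM serial name resName [chain] resNum x y z charge radius
            if len(fields) == 11:
                chain = fields[4]
                rest = fields[5:]
            elif len(fields) == 10:
                chain = ""
                rest = fields[4:]
            else:
                raise ParseError(f"{path}:{lineno}: malformed PQR record")
            try:
                resnum = int(rest[0])
                x, y, z, charge, radius = (float(v) for v in rest[1:6])
            except ValueError:
                raise ParseError(f"{path}:{lineno}: malformed PQR record") from None
            name = fields[2]
            atoms.append(
                AtomRecord(
                    atom_name=name,
                    element=_guess_element(name),
                    residue_name=fields[3],
                    residue_number=resnum,
                    chain_id=chain,
                    position=np.array([x, y, z]),
                    charge=charge,
                    lj_rmin_half=radius,
                    tags={"hetero"} if line.startswith("HETATM") else set(),
                )
            )
    return MolecularModel(Path(path).stem, atoms)


def _guess_element(atom_name: str) -> str:
    stripped = atom_name.strip().lstrip("0123456789")
    if not stripped:
        return ""
    two = stripped[:2].upper()
    if two in {"FE", "NI", "AU", "ZN", "MG", "SE", "CL", "NA"}:
        return two
    return stripped[0].upper()


def _infer_format(path: Path, format: Optional[str]) -> str:
    if format:
        fmt = format.upper()
    else:
        fmt = path.suffix.lstrip(".").upper() or "PDB"
    if fmt not in {"PDB", "PQR"}:
        raise ValueError(f"unsupported structure format: {fmt}")
    return fmt


def read_structure(path, format: Optional[str] = None) -> MolecularModel:
    """Read a PDB or PQR file into a :class:`MolecularModel`.

    Atom order is preserved; coordinates are Å. PDB atoms carry zero
    charge until :func:`parameterize` runs; PQR atoms carry the charge
    and radius columns. HETATM records are kept and tagged ``hetero``.
    For multi-MODEL PDB files only the first model is returned (use
    :func:`read_models` for ensembles). The first alternate location is
    kept; others are dropped with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _infer_format(path, format)
    if fmt == "PQR":
        model = _read_pqr(path)
    else:
        _validate_pdb_lines(path)
        try:
            st = gemmi.read_pdb(str(path))
        except (RuntimeError, ValueError) as exc:
            raise ParseError(f"{path}: {exc}") from exc
        if any(a.altloc not in ("", "\0", "A") for m in st for c in m
               for r in c for a in r):
            logger.warning("%s: alternate locations present; keeping first", path)
        st.remove_alternative_conformations()
        if len(st) == 0:
            raise ParseError(f"{path}: empty structure")
        model = _model_from_gemmi(st[0], path.stem)
    if len(model) == 0:
        raise ParseError(f"{path}: empty structure")
    return model


def read_models(path, format: Optional[str] = None) -> list[MolecularModel]:
    """Read every MODEL of a multi-model PDB (e.g. a pose ensemble or
    coordinate pseudo-trajectory) as a list of models."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt != "PDB":
        return [read_structure(path, format)]
    _validate_pdb_lines(path)
    st = gemmi.read_pdb(str(path))
    st.remove_alternative_conformations()
    if len(st) == 0:
        raise ParseError(f"{path}: empty structure")
    return [
        _model_from_gemmi(m, f"{path.stem}[{i}]") for i, m in enumerate(st)
    ]


# ----------------------------------------------------------------------
# Writing
# ----------------------------------------------------------------------

def _gemmi_model(model: MolecularModel, num: int) -> "gemmi.Model":
    gm = gemmi.Model(num)
    chain_map: dict[str, gemmi.Chain] = {}
    res_key = None
    residue = None
    for i in range(len(model)):
        cid = model.chain_ids[i] or "A"
        if cid not in chain_map:
            chain_map[cid] = gemmi.Chain(cid)
            gm.add_chain(chain_map[cid])
        chain = gm[cid]
        key = (cid, model.residue_numbers[i], model.residue_names[i])
        if key != res_key:
            residue = gemmi.Residue()
            residue.name = model.residue_names[i]
            residue.seqid = gemmi.SeqId(model.residue_numbers[i], " ")
            residue.het_flag = "H" if "hetero" in model.tags[i] else "A"
            chain.add_residue(residue)
            res_key = key
            residue = chain[-1]
        atom = gemmi.Atom()
        atom.name = model.atom_names[i]
        atom.element = gemmi.Element(model.elements[i] or "X")
        x, y, z = model.positions[i]
        atom.pos = gemmi.Position(x, y, z)
        atom.occ = 1.0
        atom.b_iso = 0.0
        residue.add_atom(atom)
    return gm


def write_structure(model, path, format: Optional[str] = None) -> None:
    """Write a model — or a sequence of models as a multi-MODEL PDB
    ensemble — to *path* in PDB or PQR format."""
    path = Path(path)
    models = list(model) if isinstance(model, (list, tuple)) else [model]
    if not models or any(len(m) == 0 for m in models):
        raise ValueError("refusing to write an empty structure")
    fmt = _infer_format(path, format)
    if fmt == "PQR":
        if len(models) > 1:
            raise ValueError("PQR output does not support multi-model ensembles")
        _write_pqr(models[0], path)
        return
    st = gemmi.Structure()
    st.name = models[0].name
    for num, m in enumerate(models, start=1):
        st.add_model(_gemmi_model(m, num))
    with open(path, "w") as fh:
        fh.write(st.make_pdb_string())


def _write_pqr(model: MolecularModel, path: Path) -> None:
    with open(path, "w") as fh:
        for i in range(len(model)):
            rec = "HETATM" if "hetero" in model.tags[i] else "ATOM"
            x, y, z = model.positions[i]
            fh.write(
                f"{rec:<6s}{i + 1:>5d} {model.atom_names[i]:<4s} "
                f"{model.residue_names[i]:<4s}{model.chain_ids[i] or 'A':>1s} "
                f"{model.residue_numbers[i]:>4d} "
                f"{x:>10.4f}{y:>10.4f}{z:>10.4f} "
                f"{model.charges[i]:>8.4f} {model.lj_rmin_half[i]:>7.4f}\n"
            )
        fh.write("END\n")


# ----------------------------------------------------------------------
# Parameterization
# ----------------------------------------------------------------------

def parameterize(
    model: MolecularModel,
    table: Optional[ForceFieldTable] = None,
    charged_termini: bool = True,
    cofactor_charges: Optional[Mapping[str, Mapping[str, float]]] = None,
) -> MolecularModel:
    """Assign charges and LJ parameters to every atom from *table*.

    Unmatched atoms receive the table's default entry and are counted in
    ``result.param_report`` (never fatal). ``cofactor_charges`` maps a
    HETATM residue name to per-atom charges, for metal sites and FeS
    clusters that no residue table covers; untreated cofactors stay at
    the default (zero) charge with a logged warning. With
    ``charged_termini`` each protein chain gets +1 e on its first
    backbone N and −1 e on its last backbone carboxylate (OXT when
    present, else O). The declared net charge is recomputed; applying
    the same table twice is a no-op.
    """
    if len(model) == 0:
        raise ValueError("cannot parameterize an empty model")
    table = table or load_default_table()
    cofactor_charges = cofactor_charges or {}
    out = model.copy()
    defaulted: list[str] = []
    known = table.residue_names() | set(RESIDUE_ALIASES)

    for i in range(len(out)):
        res = out.residue_names[i]
        name = out.atom_names[i]
        if res in cofactor_charges:
            q = float(cofactor_charges[res].get(name, 0.0))
            _, eps, rmin = table.default_entry
            out.charges[i], out.lj_epsilon[i], out.lj_rmin_half[i] = q, eps, rmin
            continue
        (q, eps, rmin), matched = table.lookup(res, name)
        out.charges[i], out.lj_epsilon[i], out.lj_rmin_half[i] = q, eps, rmin
        if not matched:
            defaulted.append(f"{res}{out.residue_numbers[i]}:{name}")

    if charged_termini:
        _apply_charged_termini(out, known)

    untreated = sorted(
        {
            out.residue_names[i]
            for i in range(len(out))
            if "hetero" in out.tags[i]
            and out.residue_names[i] not in cofactor_charges
            and out.residue_names[i] not in known
        }
    )
    if untreated:
        logger.warning(
            "cofactor groups without supplied charges (left at default): %s",
            ", ".join(untreated),
        )
    if defaulted:
        logger.info("%d atoms parameterized from the default entry", len(defaulted))
    out.net_charge = float(out.charges.sum())
    out.param_report = {
        "n_defaulted": len(defaulted),
        "defaulted_atoms": defaulted,
        "untreated_cofactors": untreated,
        "table": table.provenance,
    }
    return out


def _apply_charged_termini(model: MolecularModel, known_residues: set[str]) -> None:
    """+1 e on the first backbone N, −1 e on the last OXT/O, per chain."""
    chains: dict[str, list[int]] = {}
    for i in range(len(model)):
        if model.residue_names[i] in known_residues and "hetero" not in model.tags[i]:
            chains.setdefault(model.chain_ids[i], []).append(i)
    for idx in chains.values():
        first_res = (model.residue_numbers[idx[0]], model.residue_names[idx[0]])
        for i in idx:
            if (model.residue_numbers[i], model.residue_names[i]) == first_res \
                    and model.atom_names[i] == "N":
                model.charges[i] += 1.0
                break
        last_res = (model.residue_numbers[idx[-1]], model.residue_names[idx[-1]])
        last = [i for i in idx
                if (model.residue_numbers[i], model.residue_names[i]) == last_res]
        oxt = [i for i in last if model.atom_names[i] == "OXT"]
        o = [i for i in last if model.atom_names[i] == "O"]
        if oxt:
            model.charges[oxt[0]] -= 1.0
        elif o:
            model.charges[o[0]] -= 1.0


# ----------------------------------------------------------------------
# C-terminal helix extension
# ----------------------------------------------------------------------

ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}

HELIX_RADIUS = 2.3      # Å, Cα distance from the helix axis
HELIX_RISE = 1.5        # Å per residue along the axis
HELIX_TWIST = 100.0     # degrees per residue


def append_cterm_helix(
    model: MolecularModel,
    sequence: str,
    anchor: tuple[str, int] | int,
) -> MolecularModel:
    """Append *sequence* as an ideal α-helical Cα trace after *anchor*.

    The anchor is ``(chain_id, residue_number)`` or a bare residue
    number; it must have a Cα atom. One Cα pseudo-atom per residue is
    placed on a cylinder of radius 2.3 Å with 1.5 Å rise and 100° twist
    per residue, the axis following the anchor's local chain direction
    (anchor Cα minus the preceding Cα; +z if there is none). Appended
    atoms are tagged ``modeled`` and parameterize like any residue.
    An empty sequence returns the model unchanged.
    """
    if not sequence:
        return model.copy()
    if isinstance(anchor, tuple):
        chain_id, resnum = anchor
    else:
        chain_id, resnum = None, int(anchor)

    ca_idx = [
        i for i in range(len(model))
        if model.atom_names[i] == "CA"
        and model.residue_numbers[i] == resnum
        and (chain_id is None or model.chain_ids[i] == chain_id)
    ]
    if not ca_idx:
        raise ValueError(f"anchor residue {resnum} has no CA atom")
    ai = ca_idx[0]
    chain_id = model.chain_ids[ai]
    anchor_pos = model.positions[ai]

    prev = [
        i for i in range(len(model))
        if model.atom_names[i] == "CA"
        and model.chain_ids[i] == chain_id
        and model.residue_numbers[i] < resnum
    ]
    if prev:
        prev_i = max(prev, key=lambda i: model.residue_numbers[i])
        axis = anchor_pos - model.positions[prev_i]
        nrm = np.linalg.norm(axis)
        axis = axis / nrm if nrm > 1e-9 else np.array([0.0, 0.0, 1.0])
    else:
        axis = np.array([0.0, 0.0, 1.0])

    # orthonormal frame (u, v, axis); the anchor Cα sits on the cylinder
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, axis)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = ref - np.dot(ref, axis) * axis
    u /= np.linalg.norm(u)
    v = np.cross(axis, u)
    origin = anchor_pos - HELIX_RADIUS * u

    out = model.copy()
    twist = math.radians(HELIX_TWIST)
    for k, letter in enumerate(sequence, start=1):
        res3 = ONE_TO_THREE.get(letter.upper())
        if res3 is None:
            raise ValueError(f"unknown one-letter residue code {letter!r}")
        phi = k * twist
        pos = (
            origin
            + HELIX_RISE * k * axis
            + HELIX_RADIUS * (math.cos(phi) * u + math.sin(phi) * v)
        )
        out.append(
            AtomRecord(
                atom_name="CA",
                element="C",
                residue_name=res3,
                residue_number=resnum + k,
                chain_id=chain_id,
                position=pos,
                tags={"modeled"},
            )
        )
    return out
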