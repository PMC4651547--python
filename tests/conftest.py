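"""Shared fixtures and independent oracles.

The oracle implementations here are deliberately naive (explicit loops,
no chunking, no masking tricks) so they stay independent of the package
code paths they check.
"""

import math

import numpy as np
import pytest

import samscan as ss
from samscan.model import AtomRecord, MolecularModel


def naive_interaction_energy(a, b, dielectric=1.0, cutoff=math.inf):
    """Brute-force O(N²) Coulomb + LJ double loop (test oracle)."""
    ke = 332.0636 / dielectric
    total = 0.0
    for i in range(len(a)):
        pi = a.positions[i]
        for j in range(len(b)):
            r = math.dist(pi, b.positions[j])
            if r > cutoff:
                continue
            total += ke * a.charges[i] * b.charges[j] / r
            eps = math.sqrt(a.lj_epsilon[i] * b.lj_epsilon[j])
            if eps > 0:
                rmin = a.lj_rmin_half[i] + b.lj_rmin_half[j]
                s6 = (rmin / r) ** 6
                total += eps * (s6 * s6 - 2 * s6)
    return total


def toroidal_cheb(a, b):
    """Wrap-aware Chebyshev distance between two (θ, ψ) pairs."""
    def d(x, y):
        v = abs(x - y) % 360.0
        return min(v, 360.0 - v)
    return max(d(a[0], b[0]), d(a[1], b[1]))


def single_atom(pos, charge=0.0, eps=0.0, rmin_half=0.0):
    return MolecularModel(
        "atom",
        [AtomRecord("X", "C", "TOY", 1, "A", np.asarray(pos, float),
                    charge=charge, lj_epsilon=eps, lj_rmin_half=rmin_half)],
    )


@pytest.fixture(scope="session")
def default_table():
    return ss.load_default_table()


@pytest.fixture(scope="session")
def small_surface():
    """10×10 slab, 8% protonated → net +8 e."""
    return ss.build_sam_surface(
        ss.SurfaceSpec(nx=10, ny=10, protonation_fraction=0.08, seed=1)
    )


@pytest.fixture(scope="session")
def patchy_sphere():
    from samscan import synthetic
    return synthetic.make_patchy_sphere(
        n_atoms=100, radius=10.0, cap_half_angle=40.0, cap_charge=-1.0, seed=1
    )


@pytest.fixture
def tripeptide_pdb(tmp_path):
    """Hand-written Gly-Ala-Lys fragment with backbone + side chains."""
    lines = [
        "ATOM      1  N   GLY A   1       0.000   0.000   0.000  1.00  0.00           N",
        "ATOM      2  CA  GLY A   1       1.458   0.000   0.000  1.00  0.00           C",
        "ATOM      3  C   GLY A   1       2.009   1.420   0.000  1.00  0.00           C",
        "ATOM      4  O   GLY A   1       1.251   2.390   0.000  1.00  0.00           O",
        "ATOM      5  N   ALA A   2       3.332   1.536   0.000  1.00  0.00           N",
        "ATOM      6  CA  ALA A   2       3.988   2.837   0.000  1.00  0.00           C",
        "ATOM      7  CB  ALA A   2       3.671   3.602   1.287  1.00  0.00           C",
        "ATOM      8  C   ALA A   2       5.496   2.663   0.000  1.00  0.00           C",
        "ATOM      9  O   ALA A   2       6.021   1.551   0.000  1.00  0.00           O",
        "ATOM     10  N   LYS A   3       6.235   3.770   0.000  1.00  0.00           N",
        "ATOM     11  CA  LYS A   3       7.694   3.710   0.000  1.00  0.00           C",
        "ATOM     12  CB  LYS A   3       8.280   5.122   0.000  1.00  0.00           C",
        "ATOM     13  CG  LYS A   3       9.806   5.140   0.000  1.00  0.00           C",
        "ATOM     14  CD  LYS A   3      10.370   6.556   0.000  1.00  0.00           C",
        "ATOM     15  CE  LYS A   3      11.893   6.583   0.000  1.00  0.00           C",
        "ATOM     16  NZ  LYS A   3      12.441   7.956   0.000  1.00  0.00           N",
        "ATOM     17  C   LYS A   3       8.222   2.929  -1.203  1.00  0.00           C",
        "ATOM     18  O   LYS A   3       7.581   2.845  -2.253  1.00  0.00           O",
        "ATOM     19  OXT LYS A   3       9.342   2.409  -1.104  1.00  0.00           O",
        "END",
    ]
    path = tmp_path / "gak.pdb"
    path.write_text("\n".join(lines) + "\n")
    return path
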