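# Methods

## Scope and model

`samscan` is a coarse electrostatic screen for the adsorption
orientation of a charged protein on an amino-alkanethiol SAM-coated
gold electrode. It deliberately stops where molecular dynamics begins:
the protein and the monolayer are rigid, solvent and ions are absent,
and the score is a bare Coulomb + Lennard-Jones pair sum. The screen's
job is to rank orientations and expose the electrostatically preferred
binding modes, not to predict absolute adsorption energies. Ensembles
produced elsewhere (e.g. MD trajectories saved as multi-MODEL PDB) can
be analyzed with the same observable machinery, but no dynamics is run
here.

## Surface model

* Thiol sulfurs on a hexagonal (√3×√3)R30° overlayer of Au(111),
  spacing 4.995 Å (Au nearest-neighbor 2.884 Å). Chains are untilted
  all-trans stacks of seven pseudo-atoms (S, 6×CH₂ at 1.25 Å
  z-increments) topped by the amino nitrogen at 8.75 Å.
* Headgroup protonation: a fraction *f* of chains carries +1 e on the
  nitrogen. *f* follows Henderson–Hasselbalch,
  f = 1/(1+10^(pH−pKa)); with pH 7 and a surface pKa near 6 this gives
  ≈ 8%, the packaged default. Protonated sites are drawn uniformly
  without replacement from a seeded generator — the real lateral
  distribution on an electrode is unknown, and determinism is required
  for reproducible screens.
* Default slab: 25 × 29 sites (725 chains, extents 122.4 Å × 121.1 Å).
  The site count is a multiple of 25 so that round(0.08·n) is *exactly*
  8%, and both extents exceed 120 Å so a ~100 Å protein footprint stays
  inside the finite patch. There are no periodic images; the finite-
  patch bias is what the lateral-translation check quantifies (below).
* The gold layer is a single hexagonal plane 2 Å beneath the sulfurs
  with Lennard-Jones parameters only. Zero charge is a modelling
  statement, not an omission: the screen neglects polarization, so
  image-charge attraction is out of scope by construction.

## Charge model

The packaged residue table is a united heavy-atom model: every
hydrogen's charge is folded into its parent heavy atom, backbone atoms
carry a small N⁻/CA⁺/C⁺/O⁻ polarity that sums to zero, polar side
chains carry local dipoles, and ionizable side chains carry their pH-7
formal charge on the terminal group (Asp/Glu −1, Lys/Arg +1, His
neutral). Per-residue sums therefore equal the formal charge exactly,
which is the property the screen actually uses. Free termini get ±1 e
(toggleable). Lennard-Jones parameters are assigned per element
(C 0.08/2.00, N 0.20/1.85, O 0.12/1.70, S 0.45/2.00 kcal/mol / Å).

Metal cofactors ([NiFe] site, FeS clusters) have no standard residue
parameters; they are accepted as per-atom charge maps in the config and
default to zero with a logged warning. Consequently any absolute dipole
computed for a metalloprotein reflects the protein charges plus
whatever cofactor charges were supplied.

The unresolved C-terminal tail can be appended as an ideal α-helical
Cα trace (radius 2.3 Å, rise 1.5 Å/residue, twist 100°/residue) along
the anchor's local chain direction. A Cα-only trace is enough because
the tail enters the screen only through coarse charges and sterics.

## Scan protocol

* Orientations are R = R_y(ψ)·R_x(θ) about the protein's center of
  geometry, on the half-open grid [0°, 360°)² in 10° steps (36 × 36 =
  1296 orientations by default). The composition order and the
  center-of-geometry pivot are conventions, fixed and documented here.
* After each rotation the protein is re-placed so its lowest atom sits
  exactly 5 Å (the `gap`) above the topmost SAM heavy atom, centered
  laterally over the slab.
* Energy: ε_r = 1 (vacuum), k = 332.0636 kcal·Å·mol⁻¹·e⁻², LJ combining
  ε_ij = √(ε_iε_j), Rmin_ij = rmin½_i + rmin½_j. Pair truncation at
  30 Å with no switching function; `cutoff: inf` gives exact sums. The
  kernel is an exact chunked double sum — there is no neighbor-list
  approximation to validate, and the tests still compare it against an
  independently written naive loop.
* Overlapping atoms (r = 0 with non-zero interaction) raise an error
  rather than returning ±inf.

## Candidate selection and the field term

`select_minima` greedily takes the lowest grid points whose wrap-aware
Chebyshev distance max(Δθ, Δψ) to all previously selected points is
≥ 30°, until k = 2 poses are found; ties break by (θ, ψ) ascending.
Two candidates with a 30° exclusion zone mirror the screening protocol
this package implements.

The interfacial-field re-ranking adds weight × (−μ⃗·E⃗) to each grid
point, at 4.8032 kcal/mol per Debye·(V/Å) (the e·Å-based convention,
fixed in `constants.py`). The field points along +z above the potential
of zero charge (default PZC −0.25 V) and flips sign below it, which is
the mechanism by which a negative applied potential can re-orient an
adsorbed enzyme. Field strength and weight are user inputs: the screen
makes no claim about their physical magnitude.

## Observables

* Dipole: μ⃗ = 4.8032 Σ qᵢ(r⃗ᵢ − r⃗₀) Debye, origin defaulting to the
  center of mass; the origin and net charge are recorded because the
  dipole of a charged species is origin-dependent.
* Trajectory statistics: per-frame dipole directions are summarized by
  the normalized vector mean and the circular standard deviation
  √(−2 ln R̄) in degrees, with R̄ the mean resultant length; the vMF
  concentration is recovered with the Banerjee estimator
  κ̂ = R̄(3−R̄²)/(1−R̄²).
* Distances are perpendicular (z) distances from a selection centroid
  to either the SAM top plane or the gold plane — both conventions are
  offered because "distance to the electrode" is ambiguous between
  them.
* RMSD uses proper-rotation least-squares superposition
  (`scipy.spatial.transform.Rotation.align_vectors`).
* Coverage: hexagonal close packing Γ = 1/(N_A·(√3/2)d²) from a
  molecular footprint d, and de Feijter
  Γ = t·(n_film − n_ambient)/(dn/dc) from an ellipsometric thickness.
  Both are order-of-magnitude estimators whose inputs (footprint,
  refractive indices, dn/dc) dominate the result.

## Synthetic generators and what the tests show

The generators provide analytic ground truth: a ±q dumbbell (dipole
4.8032·q·d), a Fibonacci-lattice patchy sphere whose charged cap fixes
the preferred orientation, a two-basin landscape with planted minima
(default well width 10°, depths 10 and 8 kcal/mol — wells one grid step
wide, so the planted centers are recoverable at noise up to a tenth of
the shallower depth; broader or noisier wells degrade exact-gridpoint
recovery, which is a property of the landscape, not of the selector),
and a von Mises–Fisher dipole trajectory sampled by inversion of the
exact polar-cosine marginal.

These toys exercise every code path under known truth, but they are
not proteins: passing tests demonstrate the correctness of the kernels
and the selection logic, not the realism of any particular charge
model. Two measured caveats are worth recording:

* With randomly scattered protonated sites the surface charge field is
  not lattice-periodic, so a one-lattice-vector shift of the protein
  changes the energy by tens of percent; on a uniformly protonated
  (homogeneous) slab the same shift changes it by < 10⁻⁸ relative.
  The lateral-invariance test therefore runs on the homogeneous slab,
  where it isolates genuine finite-patch/edge bias.
* Over the randomly protonated default surface, the patchy-sphere
  minimum is always cap-toward-surface but can tilt one 10° grid step
  away from the ideal (180°, 0°)/(0°, 180°) pair, because the seeded
  site placement breaks the symmetry. Tests assert agreement with an
  independent exhaustive oracle plus the cap-down geometry, and the
  exact antipodal pair on the symmetric (fully protonated) surface.

## Problem sizes

The shipped tests and the acceptance script use toy bodies of 30–500
atoms and slabs of 36–725 chains; a full 36 × 36 scan at these sizes
takes seconds. The same code paths accept full-size proteins (~10⁴
atoms) and the default slab; a complete 1296-orientation scan then
takes minutes on one core, scaling linearly in atom-pair count.

## Known limitations

Rigid bodies (no side-chain relaxation, no SAM flexibility), no
solvent or ions, no gold polarization/image charges, residue-level
charges (no hydrogen placement or pKa prediction), two-angle sampling
rather than full SO(3), and finite-slab electrostatics without
periodic images. The per-orientation energies are screening scores;
only their ranking is meaningful.
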