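# Methods

This note documents the models, conventions and numerical choices behind
`stdgem`, and what the synthetic benchmarks do and do not demonstrate.

## STD quantification

The fractional STD effect of a resonance is `(I0 − Isat)/I0`, computed
exactly as written (no rearrangement); absolute STD % is 100× that.
Input is an already-integrated peak table — no spectral processing
(Fourier transform, phasing, baseline correction, peak picking) is in
scope, and no K_D estimation is attempted.  One record per resolved
resonance is assumed; how overlapping or degenerate protons were
integrated upstream is the caller's responsibility.

Conventions worth stating explicitly:

* **Negative STD** (`Isat > I0`) indicates a phasing or subtraction
  artefact.  It is kept and flagged, never clipped: silently zeroing it
  would hide exactly the pathology it reveals.
* **Relative STD %** divides by the compound's maximum absolute STD; the
  argmax proton is assigned exactly 100 (first occurrence wins on ties)
  and the ratio is computed as `100·(x/max)` so no other proton can
  exceed 100 by a floating-point ulp.
* **Colour classes** use strict thresholds: above 80 → dark red, above
  40 → orange, otherwise lime, with the maximum proton in its own class
  (black dot).  Exactly 80 and exactly 40 therefore fall downward; the
  convention is strict "over" at both boundaries.
* **Reporting bins**: the two open-ended ranges (>1%, <0.2%) compare the
  raw value strictly; the interior ranges have one-decimal printed
  bounds with gaps (e.g. 0.8–0.9), closed by rounding the value to one
  decimal before assignment.  Rounding is half-away-from-zero via
  `floor(10·x + 0.5)/10`, which is platform-stable and free of the
  bankers'-rounding surprises of built-in `round`.
* **Noise floor**: 0.05% absolute STD by default, configurable.  No
  experimental detection limit is assumed; the default is simply a small
  value well below typical reported intensities (0.1–1.5%).  A binder is
  any compound with at least one proton strictly above the floor;
  non-binders get no relative values or classes.  Per-compound bin
  counts include only above-floor protons, so row sums equal the number
  of interacting protons.

## Interaction fingerprints

Hydrogen-bond donors and acceptors on the protein come from residue
templates for the 20 standard amino acids (backbone N donates except in
proline; backbone O accepts; the usual side-chain sets).  Ligand atoms —
and any non-standard residue, including the pseudo-residues of the
synthetic toys — fall back to an element rule: every N/O accepts, and
donates when it carries a covalently attached hydrogen (bonds inferred
geometrically from covalent radii × 1.25).  If a partition is modelled
without hydrogens entirely, its N/O atoms are kept as potential donors
and the criterion downgrades to heavy-atom distance only, with a logged
notice.

Default geometric cutoffs are not taken from any specific study (the
workflow this generalises relied on visual inspection); they follow
common structural-biology practice and are all configuration-exposed:

| contact      | criterion                                   | default |
|--------------|---------------------------------------------|---------|
| hydrogen bond| D···A distance; best D–H···A angle at H     | ≤ 3.5 Å; ≥ 120° |
| hydrophobic  | apolar-C···apolar-C distance                | ≤ 4.5 Å |
| cation-π     | cation–ring-centroid distance; angle to ring normal | ≤ 6.0 Å; ≤ 45° |

Apolar means a carbon with no bonded N/O.  Hydrophobic contacts are
deduplicated to one per (residue, ligand atom) pair at minimal distance.
The cation centre is the centroid of the Arg guanidinium atoms
(NE/CZ/NH1/NH2) or Lys NZ; ring planes are SVD fits to the declared
aromatic atoms, and the angle uses the absolute normal projection so
ring orientation is irrelevant.  π-π stacking, halogen bonds, charge
assignment and scoring-function energies are out of scope.

**Per-proton projection.**  A contact is attributed to a proton when it
touches the proton's bonded heavy atom or a heavy atom one covalent bond
away.  This is the minimal rule that reproduces "proton near contact"
without a distance-weighted model; a cation-π contact touches every atom
of its ring, so it projects to all ring protons.  Consequently one
contact may count for several protons, and projected sums can exceed the
number of contacts — intended, since STD saturation also spreads beyond
a single proton.

## Superposition, clustering, state assignment

Superposition is the closed-form least-squares rigid fit (Kabsch via
SVD) with the determinant correction that forbids reflections.  Inputs
must have ≥ 3 atoms and non-degenerate geometry; collinear point sets
are rejected because the rotation about the axis is undetermined.  The
RMSD matrix superposes every pair independently — the most literal
reading of "clustered with respect to RMSD" — and is therefore not
guaranteed to satisfy the triangle inequality; violations are warned
about, not repaired.

Clustering is k-medoids (PAM) on that matrix, chosen over centroid
methods because representatives must be actual frames.  Greedy BUILD
initialisation plus ten seeded random restarts, each refined by
best-improvement swaps; ties break to the lowest frame index, so results
are bit-reproducible given the seed.  On every tested instance with
n ≤ 10 and k ≤ 3 this reaches the exhaustive-enumeration optimum.  k
defaults to 10 representative structures; heavy atoms only by default.
Whether k = 10 is imposed or emergent in the workflows this mirrors is
unknowable from the outside, so it is treated as configuration.

State assignment labels a structure by the nearer of two reference
conformations under superposed RMSD, with the margin reported; a margin
within 1e-6 Å is an unresolvable tie (`UNASSIGNED`).

## Concordance and state selection

Absolute STD % and contact counts live on incommensurate scales and the
comparison is inherently ordinal, so agreement is Spearman's ρ with
average ranks for ties, over the protons present on both sides (missing
protons are listed, never imputed).  ρ is undefined — reported as null,
with the per-proton table still emitted — when fewer than three protons
are shared or either variable is constant.

Pose location is decided by ligand-centroid burial: the fraction of
protein atoms within 8 Å of the ligand centroid, interior when above
0.15.  Both numbers are configurable; they formalise a qualitative
"deep in the pocket vs external surface" distinction and were chosen to
separate the two planted pose types cleanly.  Binder call × pose
location gives the 2×2 agreement classification.  State selection takes
the mean ρ over compounds per state and returns the maximum, breaking
exact ties to the lexicographically first state id with a warning.

## Synthetic data: what it emulates, what it does not

The generator encodes the screening conditions as defaults: 400 µM
ligand against 0.4 µM protein (the 1000:1 excess that suppresses
rebinding distortion of epitope maps; the config validates the ratio
arithmetic), a 2.94 s saturation train, and a 13-compound panel with one
planted non-binder (12 of 13 binding).

The transfer model is
`f = S · (1 − exp(−t_sat/T)) · Σ_atoms (r0/r)^m`, clipped to [0, 0.99],
with multiplicative log-normal noise (CV default 0.05) so integrals stay
positive.  Parameter choices, made once:

| parameter | default | why |
|-----------|---------|-----|
| m (transfer exponent) | 6 | inverse-sixth-power dipolar kernel; the standard distance dependence of cross-relaxation |
| r0 (transfer scale) | 4.0 Å | puts typical proton–protein distances (3–7 Å) on the steep part of the kernel |
| S (saturation efficiency) | 0.002 | scales simulated absolute STD into the experimentally reported 0.1–1.5% range |
| T (build-up constant) | 1.5 s | gives build-up-like behaviour over the 0.98–2.94 s saturation range |
| noise CV | 0.05 | typical integral reproducibility for well-resolved 1D peaks |

This is *not* a relaxation-matrix (CORCEMA-type) simulation: no spin
diffusion, no exchange kinetics, no rebinding, no NOE build-up curves.
Passing recovery tests therefore shows the analysis correctly inverts a
monotone distance-dependent transfer under multiplicative noise — not
that it would quantitatively reproduce a real spectrometer's output.

Panel poses place a chain ligand over a slab of apolar pseudo-residue
carbons with a smooth per-proton burial ramp (one end inserted, one
exposed, random direction per compound).  The smoothness matters: both
the transfer sum and the one-bond contact projection average over chain
neighbours, so a spatially incoherent epitope would be washed out by
both observables — real poses are spatially coherent in the same way.
Inconsistent-state poses shuffle the burial depths; non-binders get zero
transfer before noise and a ligand displaced 25 Å from the protein
surface.  The toy pocket for fingerprint tests plants one contact of
each kind with geometry well inside the default cutoffs (2.9 Å/180°
H-bond, 4.0 Å C···C, 4.2 Å on-axis cation-π) among glycine filler
residues in a 20–80-atom shell.

Two-state ensembles scale a random displacement so the references'
superposed RMSD hits the requested separation (5 Å default) exactly
(fixed-point iteration, 8 rounds), then alternate frames between states
with isotropic Gaussian noise (σ = 0.2 Å default) and random rigid
motions.  A separation/noise ratio below 3 warns that label recovery is
not guaranteed.

All generation is driven by `numpy.random.default_rng` with order-stable
iteration: a fixed seed reproduces coordinates bit for bit.

## Problem sizes

The bundled benchmarks use 13- and 20-compound panels with 10 protons
per compound, 40-frame ensembles of 30 atoms, and toy complexes of ≤ 80
atoms — sizes at which every brute-force oracle (all-pairs contact
scans, exhaustive medoid enumeration for n ≤ 10/k ≤ 3, dense rotation
grids of ~1.4·10⁴ samples) is itself exact and fast, so implementation
and oracle can be compared at tight tolerances (1e-3 Å for
superposition, exact set equality for contacts).

## Known limitations

* Donor/acceptor typing covers the 20 standard amino acids plus an
  element fallback; modified residues get the fallback, not a template.
* Bond inference is geometric; severely distorted input coordinates can
  mis-type apolar carbons or miss attached hydrogens.
* The RMSD matrix costs O(n²) superpositions; ensembles of thousands of
  frames would need subsampling.
* ρ with ≤ 5 protons is a coarse statistic; reports carry `n_protons`
  so downstream consumers can filter.
* Residue-level biology of any specific target (which arginine, which
  asparagine) is outside what synthetic recovery can validate.
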