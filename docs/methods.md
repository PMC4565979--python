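# Methods

This note records the models, conventions, numerical choices and known
limitations behind `tetherloc`.  It documents what the code computes;
every empirical number quoted here is produced by the test suite or by
`scripts/acceptance.py`.

## Geometry and structure handling

All geometry is Cα-level: cross-link distances are Euclidean Cα–Cα
distances in Å, and density is rasterized from Cα positions.  Full-atom
content read from PDB files is carried opaquely and written back, but never
interpreted.  Residue numbering is the author (1-based) numbering of the
input file; nothing is renumbered.  Rigid transforms are proper
(det R = +1); reflections are forbidden everywhere except the density
module's explicit `mirror` operation, so superposition can never silently
flip a hand.  Superposition is the Kabsch SVD solution with the determinant
correction; the test suite checks it against an independent Horn-quaternion
implementation.

A residue without a Cα atom is *unmappable*: distance queries involving it
return NaN (never a silent zero), cross-link records touching it are
retained and flagged rather than dropped, and violation scoring excludes
them while reporting the exclusion count once.  Proxy coordinates — e.g.
loop lysines absent from a crystal structure but placeable from a
homologous structure — may be supplied per site and yield a distinct
`proxy-mapped` status.

## Cross-link bookkeeping

A cross-link is an unordered residue-site pair; records are normalized at
ingest (lexicographically smaller site first) and duplicate rows merge by
summing counts.  "Total" counts include redundant detections of the same
pair (miss-cleaved peptides); "non-redundant" collapses to unique pairs,
either per dataset or pooled across datasets — both scopes are exposed
because published tables do not always state which was used.  Region
categorization assigns each record exactly one category from its endpoint
regions; a scheme may declare lobe regions so that pairs inside a RecA-fold
ATPase are reported as intralobe/interlobe.  The bundled Mot1 region scheme
places the RecA1/RecA2 boundary at residue 1010; this boundary is not
structurally annotated for this organism and is a working choice that
users should replace for other proteins (all known RecA1-side sites fall at
or below 1008 and RecA2-side sites at or above 1013, so the exact split
does not affect the bundled analysis).

## Conformer-state discrimination

Each inter-lobe linkage carries one distance per candidate conformer and
one detection count per nucleotide dataset.  The comparison cutoff defaults
to 30 Å, the maximum Cα–Cα span bridgeable by a short lysine-reactive
cross-linker plus two lysine side chains, and is **inclusive**: a distance
of exactly 30 Å is compatible, reading the cutoff as the maximum feasible
span.  A linkage compatible with every model (or with none) does not
distinguish them; a linkage detected in every dataset cannot tell datasets
apart and is flagged non-informative.  The per-dataset verdict is the
intersection of compatible-model sets over the informative, discriminating
linkages detected in that dataset — all-sites reasoning, not majority vote.
An empty support yields "all models" (the data cannot narrow the state, as
for the ADP dataset in the bundled table); a non-empty support with an
empty intersection reports "no single model consistent" instead of failing.

## Tethered-ensemble localization

The disordered linker is never built; it acts purely as a distance bound
between the core-side and mobile-side anchor residues,
(n_linker + 1) × 3.8 Å (8 linker residues ⇒ 34.2 Å).  Placements are
rejection-sampled: uniform random orientation (via uniformly distributed
rotations), anchor target uniform in the tether ball, no core–mobile Cα
pair closer than 4.0 Å.  "Compact" mode adds a centroid-radius bound
(core Rg + mobile Rg + tether maximum) as a crude stand-in for the
compactness bias of linker-aware ensemble generators; only relative
violation scores matter downstream, so the precise form of this bound is
not critical and it is configurable.

Scoring uses the non-redundant cross-link set; links internal to either
body are placement-invariant and excluded.  A member's score is the number
of mapped inter-body links with distance strictly above the cutoff
(boundary inclusive, matching the conformer module), with the summed
restraint distance as tie-break and the member index as final,
deterministic tie-break.  Selection returns the top-k (k = 12 by default,
the number of best-scoring models one typically inspects); convergence
between datasets is the Jaccard overlap of selected member indices, and
placement spread reports pairwise mobile-domain RMSD and the maximum
pairwise rotation angle.

**Information limit.** With ~20 links at a 30 Å cutoff the satisfied region
is large: on the synthetic benchmark (150-residue core, 50-residue mobile
domain, contact-docked truth, n = 5,000) the violation-minimizing member's
centroid lands 10–30 Å from the planted centroid depending on the link
draw, and the top-12 membership is sensitive to which links a dataset
contains (Jaccard ≈ 0.15–0.35 between fully independent 20-link draws,
rising to ≈ 0.85 when the two datasets are detection-subsets of one
underlying link pool).  Selection robustly *concentrates* — top-12 spread
is far below ensemble-wide spread — but exact best-list identity between
independent datasets is not a reproducible property of the method at this
restraint density, and the package reports overlap rather than asserting
identity.

## Density operations

Maps are voxel grids (isotropic spacing, physical origin) read and written
as CCP4/MRC mode-2 float through gemmi, with voxel size and origin
preserved bit-exactly.

*Rasterization.* A model becomes density as a sum of unit-integral
isotropic Gaussians centered on Cα positions with FWHM equal to the nominal
resolution.  Unit integral makes the grid sum count residues; it implies
the peak scales as FWHM⁻³ (doubling the resolution divides the peak by 8),
which the tests pin down.

*Filtering.* The low-pass filter attenuates in the frequency domain with
half-maximum at 1/resolution and preserves the mean; its impulse response
is tested against the closed-form Gaussian kernel.  The standalone
Laplacian is the 6-neighbor stencil (Å⁻²) with zero-flux boundaries.
Inside the fitting search both the map and the probe density pass through
the *circular* (spectral) Laplacian instead, so that the FFT-accelerated
score equals a direct-space correlation exactly (verified to 1e-6 and
observed at ~1e-15); filtering both sides is required for the score to be
a true correlation of identically filtered signals.

*Exhaustive fitting.* Orientations come from a Fibonacci-sphere × in-plane
grid, sized so nearest-neighbor spacing stays at or below the angular step
(10° default, per standard practice for low-resolution docking), with the
identity always included.  Per orientation the probe is deposited by
trilinear cloud-in-cell weights, convolved spectrally with the point-spread
Gaussian, and all translations are scored at once by FFT cross-correlation,
normalized to an affine-invariant correlation coefficient.  Peaks merging
within one voxel and one angular step are collapsed; survivors are
re-scored with exact (direct Gaussian) rasterization, and the best few are
refined off-lattice by Powell search over a rotation-vector and sub-voxel
translation — the standard grid-then-refine scheme.  On a 22 Å synthetic
map this recovers a planted placement to ≪1° and ≪1 voxel with ccc ≈ 1.00.

*Handedness.* Particles are full-frame noisy copies of the map (white
Gaussian noise at a stated variance-ratio SNR; optionally rotated).  For
each particle, ΔCCC is the best correlation against the map minus the best
against its mirrored version, searching rotations at a coarse step and all
translations; the clean reference (not the noisy particle) is the side that
is rotated, because interpolating the particle would smooth its noise and
bias the comparison.  A two-sided sign test summarizes significance.  A
quasi-globular blob is nearly achiral at 20–25 Å, so the handedness
benchmark uses a C-shaped solenoid (a helical coil wound along an arc,
emulating an α-helical repeat horseshoe) whose chirality survives
low-pass filtering; with n = 40 particles at SNR 0.5 the test yields every
ΔCCC positive (p ≈ 2 × 10⁻¹²) and flips sign when the particles are
generated from the mirrored map.

*FSC and contouring.* Fourier shell correlation uses one-voxel-wide shells
and reports the resolution at the first downward crossing of the threshold
(0.5 by default) with linear interpolation; two half-maps simulated at
25 Å with independent noise read back ≈ 22 Å.  Volume contouring returns
the threshold whose enclosed volume is the largest value not exceeding the
target; the theoretical model volume uses 110 Da per residue and
1.21 Å³/Da, conventional constants for protein partial specific volume.
Residual segmentation masks above-threshold voxels farther than
1.5 × (resolution/2) from any fitted Cα and reports the largest connected
component.

## Synthetic data: what it emulates, and what it does not

Toy domains are self-avoiding Cα walks (3.8 Å steps, 4.0 Å exclusion) with
a centripetal step bias chosen so the radius of gyration follows the
empirical globular scaling ≈ 2.2·n^0.38 Å.  The true placement of the
mobile domain is contact-docked (4–6 Å closest approach): tethered domains
pack against their partner, and in the motivating system the mobile
domain's density segment directly abuts the core.  Coordinates are
quantized to 0.001 Å so PDB round-trips are exact.  The bilobed
ATPase stand-in joins two such globules on one chain at a touching,
non-interpenetrating interface, and conformers are generated by rotating
the second lobe about a hinge axis chosen (from a deterministic candidate
scan) to open the inter-lobe angle without clashes — lobe-internal geometry
is preserved to 1e-9 Å.

Simulated cross-links draw true pairs uniformly from residue pairs within
the cross-linkable distance on the generating structure and false positives
from pairs beyond it; per-dataset detection counts are 1 + Poisson(1)
truncated at 3, with an optional per-dataset Bernoulli detection
probability (the bundled reference table has zero counts in 11/39 dataset
cells, i.e. a per-dataset detection rate ≈ 0.72, which the strictly
positive count law alone cannot emulate).  Every simulated link is detected
in at least one dataset.

The generators deliberately omit most physics of the real experiments:
no lysine specificity or reactivity, no peptide-level detectability, no
negative-stain flattening, CTF or tomographic missing wedge, and particles
for the handedness test are map copies plus white noise.  Green tests
therefore demonstrate the *pipeline's* correctness and the method's
behavior under controlled noise, not its performance on real micrographs
or spectra.

## Problem sizes and defaults

The shipped analyses use a 150-residue core with a 50-residue mobile domain
(ensemble n = 5,000, cutoff 30 Å, k = 12), 22 Å maps on 2.5–3.5 Å voxels,
10° fitting steps, and 40 particles at SNR 0.5 for the handedness test —
sizes chosen so the complete pipeline and its acceptance script run in
minutes on a single CPU while keeping every stage's statistical behavior
visible.  All stage seeds derive from one top-level seed, and identical
configs reproduce identical output bytes.
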