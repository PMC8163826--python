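# Methods

`latticectx` analyzes pleomorphic capsid-like particles (CLPs) assembled
from a retroviral capsid protein (CA).  Such particles are closed or
tubular lattices of CA hexamers; closure of a hexagonal surface requires
exactly 12 pentagonal defects, so every closed particle carries 12 CA
pentamers among a variable number of hexamers.  Because each particle has
a different global shape, conventional subtomogram averaging of the whole
lattice is limited by local geometric heterogeneity; the method
implemented here classifies each *unit pair* (two adjacent hexamers or a
hexamer and a pentamer) by its local pentamer context and refines poses
by a per-neighbor *consensus alignment*.

## Pose conventions

Orientations are intrinsic ZXZ Euler triplets (phi, theta, psi) in
degrees, `R = Rz(phi) Rx(theta) Rz(psi)`, theta canonicalized to
[0, 180], phi and psi to [0, 360).  A unit's outward normal is
`R·(0,0,1)`; psi is the in-plane spin about the normal, which the normal
itself does not constrain.  Positions are kept in voxels with the voxel
size (Å) carried explicitly; all physical thresholds are in Å.  The
processing lineage this convention mirrors does not pin down tilt/twist
definitions in its public record; the operational definitions used here
are:

* **tilt** — angle between the two outward normals (identical to the
  connectivity criterion "normal difference");
* **twist** — signed angle between the two units' in-plane x axes after
  parallel transport (minimal rotation) of one frame onto the other's
  tangential plane; antisymmetric under operand swap;
* **curvature** — angle of the center-to-center vector below the first
  unit's tangential plane, *positive* for a convex-outward surface.  The
  accepted window (−15°, +40°) is asymmetric precisely because real
  particles are predominantly convex.  The criterion is evaluated from
  both units' planes and both must pass (a symmetric, stricter reading
  of a one-sided rule).

## Synthetic lattices

The generators provide ground truth for every downstream stage.  Unit
spacing defaults to 80 Å, the center of the 60–110 Å window the
connectivity criteria accept.

* **Tubes** — a triangular lattice rolled on a cylinder, `n_around`
  units per ring, pitch `spacing·√3/2`, radially outward normals, the
  in-plane x axis along the tube axis.  All units are C2 hexamers.
* **T=1 / T=3 icosahedra** — Caspar–Klug placement: pentamers at the 12
  icosahedron vertices; for T=3 additionally 20 hexamers at the face
  centers, all scaled to a common sphere with hexamer–hexamer chord =
  spacing (pentamer–hexamer ≈ 0.90·spacing, inside the window).
* **Random closed polyhedrons** — a capped-tube fullerene: a body of
  10-unit rings closed by two caps, each an apex pentamer plus a
  5-hexamer ring, leaving 5 pentamers alternating in each boundary body
  ring (capped armchair-nanotube combinatorics).  Exactly 12 pentamers
  by construction; the Euler characteristic of the dual triangulation is
  asserted in tests.  Achievable sizes are 32, 42, 52, … units;
  requested sizes are rounded to the nearest (the 62-unit polyhedron
  stands in for a "60-unit" study).  The seed fixes ring twists and a
  small (1.2 Å) positional jitter; `elongation` stretches the body
  pitch within the spacing window.  Vertex normals are area-weighted
  incident-face normals of the triangulation.  The minimal 32-unit
  polyhedron is squatter than the icosahedral ideal and its largest
  pair tilts exceed the 45° connectivity window; from 42 units upward
  all generated pairs satisfy every criterion, and `build_icosahedron(3)`
  covers the 32-unit morphology exactly.

**Density model.**  Units are rendered as Gaussian pseudo-atom
templates: an outer ring of CTD-like blobs (radius 30 Å for hexamers,
24 Å for pentamers, σ = 7 Å) plus an inner ring of weaker NTD-like
blobs lifted 12 Å along the outward normal.  The inner ring serves two
purposes a real CA lattice also exhibits: it distinguishes a unit
center from the empty three-fold holes of the blob honeycomb (otherwise
template matching and alignment can lock onto the dual lattice), and it
makes the unit *polar*, so matching can recover the sign of the normal.
The C2 hexamer carries a twofold weight modulation (1.4/0.8) on the
outer ring.  Templates are coarse blobs, not atomic models; accuracy
targets are set accordingly.

**Acquisition model.**  A binary missing-wedge mask in Fourier space
(default ±60° about x, approximating a −66°/+63° single-axis tilt
range) and additive white Gaussian noise, both seed-reproducible.  No
CTF or dose model: those corrections are performed upstream of this
kind of analysis by dedicated reconstruction tools.

## Template matching

Volume and template are band-pass filtered with the same isotropic
window (default 425–30 Å, soft edges).  The template is scanned over a
Fibonacci net of normal directions (arc ≈ `other_step`, default 15°)
crossed with in-plane angles every `phi_step` (default 10°) over
360°/n for a Cn template.  Correlation is locally normalized: the
rotated, masked, zero-mean template is correlated by FFT and divided by
the local standard deviation of the volume under a spherical mask, so
the score is invariant to local intensity scale and offset and bounded
by 1.  The local σ is floored at 2% of its maximum to suppress
spurious correlations in the empty regions of noise-free synthetic
volumes.  Peaks are local maxima separated by at least the minimum unit
spacing, extracted greedily by descending cc with linear-voxel-index
tie-breaks — fully deterministic.

## Connectivity networks

Candidate pairs pass if spacing ∈ [60, 110] Å, curvature from both
sides ∈ [−15°, 40°], and normal difference ≤ 45° (boundaries
inclusive).  Connected components of the resulting graph are the
candidate particles; only networks with **more than 20** units are
retained (21 is the smallest surviving size).  "Maximum-connectivity
network" is read as connected component, not clique.

## Context classification

Neighbor slots of each unit in a pair are numbered 1–6
counterclockwise viewed from outside, slot 1 = the partner; slots 2/6
are the two neighbors shared by both units (so 2′ names the same unit
as 6″), and slots 3–5 touch one unit only.  Six general groups follow
from the pentamer occupancy (see the module docstring for the full
rules).  Rules are evaluated most-constrained-first in the order
1, 2, 6, 3, 4, 5, with group 3 reading "both units have at least one
pentamer at slots 3–5": this ordering is total over *every* consistent
slot configuration (an exhaustive sweep is part of the test suite),
which a literal "exactly one pentamer each" group 3 would not be, and
agrees with the published group definitions on every configuration they
enumerate.

Pairs unconstrained by pentamers are subclassified by their orientation
to the local tube axis: the axis is the near-null singular direction of
the neighborhood's normals (cylinder normals are all perpendicular to
the axis; if the smallest singular value exceeds 20% of the largest the
region is spherical and no class is assigned).  The signed in-plane
angle between edge and axis, folded to (−90°, 90°], falls into one of
three hexagonal edge families; labels are canonical (largest |angle| =
circumferential = class 1, then by sign), making them invariant under
rigid motion and axis-sign flips.

Local hexamer symmetry: three alternating pentamer neighbors → C3; two
antipodal → C2; none → tube-like C2; anything else (including
non-antipodal two-pentamer arrangements) → C1.

## Consensus alignment

Each unit is aligned once per direct neighbor against a two-unit masked
reference (central unit + that neighbor), yielding N measurements with
correlation weights.  The consensus position is the cc-weighted mean;
the consensus normal is the cc-weighted, renormalized vector sum.
Measurements with cc ≤ 0 are dropped; a unit whose measurements are all
flagged keeps its prior pose.  The normal leaves the in-plane angle
free; it is combined as a cc-weighted circular mean after transporting
each measured frame onto the consensus normal (carrying the single
best measurement's angle is available behind a switch).  With equal
weights both equations reduce exactly to arithmetic means, and on
measurements with isotropic Gaussian position noise the consensus error
contracts as 1/√N — both are asserted in tests, the latter by
Monte-Carlo on a 62-unit polyhedron.

The per-pair search is a bounded two-stage rotation net (default ±8°
in 4° steps, then ±4° in 2° steps about the best candidate) crossed
with FFT translation search and parabolic sub-voxel refinement.  On a
noise-free isolated pair with a truth reference it recovers 2-voxel /
8° perturbations to within 0.5 voxel / 2°.

**Class-geometry optimization.**  Per class (group, subclass), the mean
and standard deviation of pair tilt/twist/distance are computed; unit
poses are then nudged by a greedy pattern search (±0.5 voxel, ±2° per
axis by default) accepting only steps that decrease the summed z-scored
deviation of the unit's pairs.  z-scoring makes Å and degrees
commensurable; a 0.5-unit floor on each std keeps singleton classes
finite.  The objective is non-increasing by construction and pairs at
their class mean are fixed points.

**Interface-centered averages.**  Final class averages are built from
boxes re-extracted at pair midpoints and rotated into the pair frame
(x along the in-plane center-to-center direction, z along the mean
normal); classes with fewer than 3 members are skipped.

## Subtomogram averaging and resolution

The tube pipeline seeds poses from the cylinder parametrization of the
annotated tube (axis and radius by PCA), oversampled ~4× in surface
density, then iterates: align each subtomogram to the current average
over a bounded rotation/translation net, drop subvolumes below an
absolute cc threshold and below 0.75× the stack median (subvolumes that
did not align), remove duplicates that converged onto the same lattice
site (greedy by descending cc within a 40 Å cutoff), and re-average
with C2 symmetry.  The default schedule is three rounds at bin 2 and
two at bin 1 with shrinking search ranges; binning is by Fourier
cropping and box sizes are fixed in physical extent.  Reference-based
alignment leaves one gauge freedom — a common offset of all positions
along the unit normal — which is irrelevant to the average itself and
fixed explicitly when comparing against rendered ground truth.

Half-sets are split even/odd (for tubes) or at the particle level (for
mixed data, `split_half_sets`).  Orientation anisotropy is compensated
by wedge-weighted averaging: each subtomogram's spectrum contributes
only inside its pose-rotated binary wedge support, and the accumulated
spectrum is divided by the coverage (floored at 0.5; uncovered voxels
zeroed and reported).  FSC uses Gaussian-softened spherical masks and
reports the resolution at the 0.143 criterion by linear interpolation
at the first downward crossing after the curve has been above
threshold (the near-DC shell of mean-free maps carries no signal); a
curve that never crosses returns Nyquist with a flag.  The
phase-randomization component of fully mask-corrected FSC is not
implemented — a documented limitation; soft masks keep the mask bias
small at desk scale.

## Model analysis

Superposition is least-squares rigid (Kabsch via
`scipy.spatial.transform.Rotation.align_vectors`), atoms paired by
(chain, residue, atom name), C-alpha by default; an independent
closed-form quaternion-eigenvalue solution serves as the oracle in
tests (agreement to 1e-9 Å).  Interface RMSD between class models:
superpose on the fixed-domain selection, then measure RMSD over the
measured domain(s) *without re-fitting*; the matrix is symmetric, has a
zero diagonal, and is invariant under rigid motion of any input model.
Comparisons against deposited pentamer models are possible with
downloaded coordinates but are not part of the test suite, which is
self-contained.

## Problem sizes and study conditions

Desk-scale defaults used by the tests and the acceptance script: 42-unit
polyhedron rendered at 4 Å/voxel in a 144³ box for the full
pipeline (matching with a 20° direction net and 30° in-plane step);
10×5-unit tubes at 4–6 Å/voxel for matching and averaging studies;
50 trials for consensus statistics; 64³ volumes for FSC calibration.
These sizes keep each study in the minutes range on a single CPU while
leaving every acceptance property far from its decision boundary.

## What the synthetic data does and does not show

The generators emulate lattice geometry, missing-wedge sampling and
additive noise, but not CTF modulation, dose-dependent damage, gold
fiducials, crowding, or atomic-detail density.  Passing tests therefore
demonstrate the correctness of the geometry, classification, consensus
and averaging machinery under controlled conditions — not that the
pipeline reaches any particular resolution on real tomograms, where
annotation quality and CTF handling dominate.

## Known limitations

* The polyhedron generator produces one (capped-tube) family of
  fullerene topologies; isolated pentamer defects in flat regions and
  conical morphologies are out of its range.
* Matching cost grows linearly with the orientation net; the default
  10°/15° net is accurate but slow for large volumes — the pipeline
  default uses a 20° net, adequate for the 60–110 Å lattice regime.
* The wedge model is binary single-axis; per-tilt exposure weighting is
  not modelled.
* In-plane consensus is this package's own completion of the
  normal-vector consensus; both behaviors (weighted circular mean /
  best-measurement) are available.
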