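# Methods

`npcfit` reconstructs, at desk scale and on fully synthetic data, the
computational chain used to infer the scaffold architecture of a
C8-symmetric nuclear pore complex (NPC) from cryo-electron tomography:
subtomogram averaging of wedge-corrupted particles, exhaustive rigid-body
fitting of subcomplex models into ring densities with empirical-null
significance assessment, difference-map and copy-number analysis, and a
nucleoporin co-expression analysis. Every stage is exercised against
phantoms with known ground truth, so recovery can be checked exactly.

## Conventions

Grids are cubes of isotropic voxels; array axes 0/1/2 are physical x/y/z
with the pore (C8) axis along z, and the physical coordinate of voxel
`(i, j, k)` is `origin + voxel_size * (i, j, k)` (voxel centres, nm
everywhere at the API surface). Rigid transforms are intrinsic ZYZ Euler
rotations in degrees about the grid centre followed by a translation
(`Pose`); resampling is trilinear, with an exact integer-lattice path for
axis-permutation rotations. Maps are read and written as MRC2014 mode-2
volumes (header lengths in Å, the API in nm).

## Phantoms

Subcomplexes are weighted pseudo-atom (bead) models: at the 3–6 nm
resolutions relevant here, fitting is driven by a subcomplex's shape
envelope, not atomic detail, and beads keep every experiment cheap. The
Y-complex stand-in is a chiral, ~40 nm two-armed shape (25 nm stem, 15 nm
long arm, a shorter out-of-plane second arm breaks mirror symmetry so
orientation recovery is unambiguous); the inner-ring protomer is a
seeded anisotropic bead cluster (~9 nm); a double-Y model pairs two
Y-copies with the exact relative pose of the stock nuclear ring.

The stock algal-NPC layout (`crnpc_spec`) places, per C8 ring:

| ring | subunit | copies | radius (nm) | z (nm) | phase |
|---|---|---|---|---|---|
| CR | Y-complex | 8 | 47 | +23 | 0° |
| NR-outer | Y-complex | 8 | 47 | −23 | 0° |
| NR-inner | Y-complex | 8 | 33 | −27 | 8° |
| IR (4 rings) | protomer | 4×8 | 35 / 43 | ±4 / ±12 | 0–10° |

so the cytoplasmic ring carries 8 Y-copies, the nuclear ring 16 (the
inner ring of the pair duplicated radially inward with a small azimuthal
and axial offset, as in the real complex), and the inner ring 32
protomers in 8 spokes of 4. The `hsnpc_like_spec` variant has 16
Y-copies on both sides, a taller scaffold and a narrower channel, for
contrast experiments. Copies are placed tangentially at equal angular
spacing; ring radii, heights and tilts are configuration, not code.

Density rendering sums isotropic Gaussians (FWHM = stated resolution)
per bead; the map integral equals the total bead weight, so map "mass"
is meaningful. Particles are simulated by a random pose (uniform
in-plane angle, small normal tilt and shift), a binary missing-wedge
mask in Fourier space (single tilt axis, ±60° default), and white
Gaussian noise scaled to a stated signal-to-noise ratio. Expression
phantoms draw per-module latent sample profiles and mix them with
independent noise so within-module Pearson correlation equals the
requested value on the log scale, then exponentiate onto a non-negative
FPKM-like scale.

The default study conditions for the reproduction experiments are 3 nm
voxels, a 132 nm box (44³), 6 nm rendering resolution, ±60° wedge, snr
1, and a 24° orientation grid. These sizes keep a full copy-number
census under two minutes on one CPU.

## Subtomogram averaging

Alignment maximizes the constrained cross-correlation — correlation over
the Fourier region sampled by both volumes' (possibly rotated) wedges,
DC excluded — over an in-plane rotation grid with a quarter-step local
refinement and an FFT translation search. Averages are
wedge-compensated: aligned Fourier data are summed and divided by the
summed wedge coverage, floored at 10 % of the mean coverage, and voxels
never sampled by any wedge are zeroed rather than amplified. Each
iteration ends by imposing the rotational symmetry. Initial orientations
come from a reference (the phantoms' analogue of manual
pre-orientation); full ab-initio alignment is out of scope. Asymmetric
units are extracted by rotating each aligned particle through the
symmetry angles and cropping a cube at the ring mid-radius on +x, with
the wedge orientation tracked per unit. Focused (masked) refinement
re-aligns units against a masked reference and only ever changes the map
inside the mask's support.

## Systematic fitting

Every pose on a quasi-uniform SO(3) grid (golden-spiral directions ×
in-plane sweep, one direction per step² of solid angle) and every
translation on the voxel lattice is scored:

* `cc` — Pearson correlation between model and map over the voxels of
  the transformed model envelope;
* `overlap` — fraction of those voxels inside the map's own envelope;
* `score = cc × overlap`, penalizing high-correlation fits that hang
  outside the density.

The translational scan runs via FFT cross-correlations and matches
direct per-pose evaluation to 1e−5 (tested). Envelope isovalues default
to Otsu's threshold for the model and, for the map, to the isovalue
enclosing the map's expected molecular volume, calibrated
mass-proportionally from the model envelope (rendering preserves mass,
and zero-mean noise cancels in the mass estimate). Evaluations whose
overlap is below one envelope voxel or whose local map variance sits at
FFT round-off are snapped to exact zero — they carry no information.

### Significance

The tested hypotheses are the local maxima of the score over the
translation lattice (per orientation), restricted to maxima with
overlap ≥ 0.3 — placements that do not engage the map envelope are not
comparable hypotheses. p-values are upper-tail probabilities under an
empirical null:

* For maps whose support fills the grid, the null sample is the maxima
  distribution obtained by running the same search against a
  **phase-randomized surrogate** of the target (identical amplitude
  spectrum, scrambled phases, hence no structure). This null calibrates
  itself to the map's noise: on pure-noise maps the significant-cluster
  rate stays at or below the nominal level (verified over 20 seeds).
* For region-masked ring maps no structure-free surrogate with
  comparable statistics exists (randomized phases spread the band's
  power over the whole box), so the null falls back to a normal law
  fitted to the (q10, q50) quantiles of the observed maxima — genuine
  placements live only in the upper tail and cannot contaminate a
  lower-quantile fit.

Multiple testing follows the clustered-hypotheses view: raw grid maxima
are massively dependent (one physical placement surfaces as many
neighbouring maxima), so Benjamini–Hochberg runs over the greedy
best-first clusters (absorption within a rotation tolerance, default
1.5× the angular step, and a translation tolerance, default 6 nm), and
clusters with q ≤ α are significant.

### From significant clusters to copy counts

Counting copies requires placements to be unique and mutually
exclusive. Acceptance visits significant clusters best-first and
enforces, in order: a relative overlap floor (a countable copy should be
about as embedded in the map envelope as the best fits — 0.75× the
median overlap of the top five clusters); a per-model minimum centre
separation below the closest physical copy spacing (12 nm for the Y,
8 nm for the protomer); and, for elongated models that tile
quasi-continuous rings head-to-tail, sequential density claiming: an
accepted placement claims the voxels where its own placed density
reaches the map threshold (exactly the density it explains), those
voxels are zeroed in a working copy, and a later candidate is kept only
if it retains at least half of its score against the residual. A
spurious "bridge" placement straddling two genuine copies loses its
entire support once they are accepted; a genuine neighbour loses only
the contact region. Claiming is disabled for the compact protomer,
whose stacking distance is below its own blur radius at 6 nm — there,
plain non-maximum suppression is the correct guard. A bounded
trust-region pose polish (≤ 0.75 angular step, ≤ 0.75 voxel) is
available to relieve grid quantization but is not needed for the stock
experiments and is off by default.

The hierarchical assignment fits models in order (largest first),
accepts placements, removes the claimed density (masking by default,
subtraction by flag) and continues on the residual; `count_copies`
attributes each accepted placement to the ring region (cytoplasmic /
inner / nuclear, split at |z| = 17 nm, midway between the outer-ring and
inner-ring subunit planes) containing its centre.

### Reproduction experiments

`experiments.crnpc_copy_census` builds the algal-NPC phantom, simulates
one corrupted particle, imposes C8 symmetry (the cheap stand-in for a
converged average), cuts the three ring maps, and runs the census: Y
into CR and NR, protomer into IR. At the study conditions with phantom
seed 42 it reports CR 8, NR 16 (24 Y-copies in total) and IR 32; across
other seeds counts vary by at most a few copies. The difference
experiment subtracts the 8-copy ring from the 16-copy ring (built on a
common plane and simulated with a shared noise realization, as both
rings come from the same reconstruction), rescales the positive
difference to the rendering scale and counts Y placements — eight. The
double-Y experiment fits the paired model into both outer-ring maps of
the noise-free phantom (pair discrimination probes the converged,
high-SNR average, not a single particle) and additionally requires both
Y-copies of a candidate pair to be embedded in ring density; pairs are
found only in the 16-copy nuclear ring, none in the 8-copy cytoplasmic
ring.

## Architectural measurements

Difference maps z-score both inputs inside a common mask before
subtracting (exactly antisymmetric). Ring geometry comes from
cylindrically averaged radial and axial profiles thresholded at half
maximum (a scale-free convention; the measurement threshold of the
original analysis is not public): inner/outer diameter from the first
and last above-threshold radius, axial extent from the axial profile
span. Rotational register folds azimuthal offsets into the symmetry
unit (45° for C8) and declares register below a 5° median offset — one
eighth of the unit, comfortably separating in-register from staggered
placements at phantom SNRs. Head-to-tail adjacency connects a copy's
head bead to a neighbour's tail bead within a contact distance; a
closed ring yields one cycle.

## Co-expression

The pipeline is log2(FPKM + 1) → quantile normalization (sorted values
replaced by cross-sample mean order statistics; ties get rank-averaged
targets, the de-facto standard) → per-gene mean centering → all-pairs
Pearson correlation with two-sided t-distribution p-values (the
conventional choice at hundreds of samples), masking entries above the
p ≤ 0.01 threshold → complete-linkage hierarchical ordering on 1 − PCC →
within/between-module PCC distributions with normal-reference Gaussian
kernel densities and the spread of within-module medians as the
separation statistic. With few genes, quantile normalization couples
genes through shared order statistics; the planted-module tests
therefore use a few hundred background genes, as any real compendium
would provide.

## What the phantoms do and do not show

The generators emulate ring-arranged shape envelopes, missing-wedge
corruption, stationary white noise, and block-correlated expression
modules. They do not emulate membrane density, molecular crowding, CTF
effects, conformational heterogeneity, structured (correlated) noise, or
the diurnal structure of real expression compendia. Passing the
planted-recovery suites therefore demonstrates that the inference chain
is correct and calibrated under its stated model, not that it would
reach the same resolution or discrimination on real tomograms.

## Numerical choices and limitations

Low-pass filtering uses a raised-cosine edge one frequency shell wide
ending exactly at the cutoff (no power beyond it; a second pass only
re-attenuates that shell). The FSC resolution criterion defaults to the
0.143 crossing with 0.5 available; the source analysis does not state
which criterion produced its headline resolution. Fourier wedge masks
are binary; constrained correlations exclude DC and error out on empty
overlap. Degenerate inputs (all-zero maps, constant score distributions,
empty masks, constant genes) raise informative errors rather than
returning silent zeros. The double-Y discrimination is resolution
limited: at 6 nm rendering with snr 1 on a single particle it becomes
marginal, which is why the experiment probes the noise-free (averaged)
regime. Counts on seeds other than the documented study seed can vary
by one to three copies in the 16- and 32-copy rings; the cytoplasmic
ring count of eight is stable across all seeds tested.
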