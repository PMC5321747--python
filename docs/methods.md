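# Methods

## Scope and model

`tomodiff` implements a subtomogram-analysis workflow for single-axis
cryo-electron tomography at the scale of a workstation: particles are small
3D volumes whose Fourier content is confined to the region sampled by the
tilt series (everything outside the ±60° wedge is unmeasured), corrupted by
additive white Gaussian noise.  The workflow estimates per-particle rigid
poses, averages with missing-wedge compensation, sorts compositional
heterogeneity (subunit present/absent) with focused classification, and
localizes missing density between two averages with a σ-normalized
difference map.

Subtomograms are *simulated directly* as rotate → wedge filter → noise.
Tomographic projection, weighted back-projection, CTF and dose-dependent
damage are not modelled: the missing-wedge filter is the property that all
downstream wedge-aware machinery responds to, and it is applied exactly.

## Conventions

- In-memory grids are float32 indexed `(x, y, z)`, the axis order gemmi
  uses for MRC/CCP4 grids; files round-trip bit-exactly in mode 2.
- Voxel size is isotropic (Å); the map origin (Å) lives in MRC header
  words 50–52.
- Rotations are intrinsic ZYZ Euler triplets in degrees; shifts are voxels.
  A pose maps the particle frame to the reference frame.  Rotation center
  is voxel `floor(N/2)` on each axis; centered Fourier grids put DC at the
  same index.
- Density is positive (more density = larger values); a CLI flag inverts
  depositions with the opposite convention.

## The phantom

A caricature of the ER membrane-bound ribosome–translocon complex on a 48³
grid at 5 Å/voxel: a large Gaussian body (sd 60 Å) for the 80S ribosome
above a soft-edged membrane slab (40 Å thick), plus small Gaussian blobs
for Sec61 and the accessory complexes — TRAPα/β (lumenal, sd 12 Å), TRAPγ
(reaching the cytosolic face, sd 10 Å), TRAPδ (at the OST-facing periphery,
sd 10 Å) and OST (sd 18 Å).  Geometry mirrors the qualitative membrane
topology of the complex; it claims no structural fidelity.  Component
amplitudes and positions are configurable; omitting a component subtracts
exactly its analytic field, which is what makes planted-deletion tests
exact.

Dataset simulation draws uniform SO(3) rotations (normalized Gaussian
quaternions, avoiding Euler-angle bias), uniform shifts in ±4 voxels,
independent Bernoulli occupancy flags per component group, and per-particle
noise seeds, all from one dataset seed — regeneration is bit-identical.
SNR is defined as wedge-filtered signal variance inside the particle
region (phantom > 10% of max) over noise variance; box padding would
otherwise deflate the signal term.

Default study conditions: 200 particles at SNR 0.7 with OST present on
58% of complexes and the TRAP core on 76% (so ~24% of the OST-containing
class lacks TRAP); the synthetic "patient" dataset additionally lacks TRAPδ
throughout.  What passing tests show is that the *method* recovers planted
fractions, poses and deletions under wedge + noise; they cannot show
robustness to CTF, non-white noise, crowding, or conformational (rather
than compositional) heterogeneity, none of which the generator emulates.

## Scoring and alignment

The pairwise kernel is a constrained cross-correlation: volumes are
(optionally) masked in real space, Fourier transformed, and correlated over
the intersection of their wedge supports with DC excluded.  Excluding DC
makes the full-support case collapse exactly to Pearson correlation of
voxel values, which the tests exploit as a brute-force oracle.  The score
is invariant to positive affine intensity changes of either input.

Alignment searches a deterministic ZYZ grid (φ, ψ over [0°, 360°), θ over
[0°, 180°], pole rows deduplicated); per orientation the reference is
rotated into the particle frame, wedge- and band-filtered identically to
the particle, and the translation is the arg-max of the FFT
cross-correlation within a shift cap (6 voxels default).  Ties resolve to
the lowest grid index.  Shifts are integer-voxel; sub-voxel refinement is
deliberately out of scope at these grid sizes.

The iterative schedule defaults to one global pass at 30° on 2× binned
volumes followed by two local 3×3×3 refinements (15°, 7.5°) at full
sampling, re-averaging after each pass.  Local neighborhoods always include
the incumbent pose, so a particle's score cannot degrade within a pass.
Band limits during scoring are configurable; the pipeline low-passes scoring
to 20 Å, which suppresses white noise while keeping all discriminative
phantom features (a high-pass at 50 Å was considered and rejected: the
phantom's alignment signal is concentrated at low spatial frequency).

Averaging divides the sum of pose-rotated particle transforms by the sum of
rotated wedge supports, clamped from below at `0.1·n` to keep barely
sampled voxels from amplifying noise.

Template matching filters the tomogram and each rotated template with the
wedge and a 50 Å low-pass (matching against a coarse reference), computes
locally normalized cross-correlation under a spherical mask of the template
radius, and applies greedy non-maximum suppression with that radius.  Its
locality is reliable when particle spacing exceeds the particle diameter;
overlapping particles inflate the local variance estimate and bias peaks.

## Focused classification

The spec-level idea — classify aligned particles from a focus-masked,
wedge-aware pairwise correlation matrix — is sharpened in one important
way: particles are compared as **residuals against a wedge-matched
reprojection of the reference** (reference rotated into the particle frame,
wedge-filtered, rotated back, subtracted before masking).  Correlating raw
aligned particles turns out to be dominated by wedge-orientation variance
of the shared density, burying occupancy signal; correlating residuals
cancels the shared term within each pair's support intersection, leaving
occupancy and noise.  Particles that deviate the same way (same missing
subunit) correlate strongly; conforming particles contribute near-zero
entries — a block structure.

The matrix is double-centered (Gower), eigen-decomposed, embedded in the
top 4 coordinates scaled by √eigenvalue, and clustered by k-means (k = 2,
10 restarts, fixed seed).  The retained class per round is the one with the
higher mean density inside the focus mask (the "present" class).  When the
leading eigenvalue does not stand out from the bulk spectrum (λ₁ < 2·λ₂),
the matrix carries no detectable heterogeneity and a single class is
returned rather than splitting noise; the factor 2 sits well clear of both
the null (λ₁/λ₂ ≈ 1.1 in homogeneous simulations) and genuine splits
(≥ 5).  A pairwise low-pass (20 Å default in the pipeline) restricts the
kernel to a Fourier ball, which is both a large speed win (the matrix
reduces to three dense matrix products) and a robustness win.

## Resolution

FSC uses 1-Fourier-voxel shells (maximum curve granularity at 48³–64³);
the crossing below threshold is located by linear interpolation in
frequency and reported as 1/frequency, with a flag (and the Nyquist value
2·voxel) when the curve never crosses.  Half-set FSC averages the two
halves of a seeded shuffle split using the *final* poses — the halves are
not refined independently, a known optimistic bias accepted for a
desk-scale tool and stated here.  Cross-resolution against an external
reference is read at FSC = 0.33; half-set resolution at FSC = 0.5.  No
soft-mask or phase-randomization corrections are applied — they would
change the numbers and are out of scope.

## Difference mapping

Pipeline order is fixed: low-pass both maps to the target resolution
(raised-cosine edge of 2 Fourier voxels — a hard cutoff would ring into the
difference), resample the reference onto the study grid, rigid-fit unless
the maps share an averaging frame, apply the exclusion mask (if any) to
both, normalize both to mean 0 / std 1 over the analysis region, subtract,
and divide by the standard deviation σ of the difference over that region.
σ is the std of the *difference map* (not of either input) — the most
direct reading of "a feature at kσ", and the alternative is one
normalization call away.  Convention: the first argument is the map under
study, so density it lacks relative to the reference is a negative
"reduction".

Components are 26-connected voxel sets beyond ±kσ; those smaller than a
(1.5 nm)³ cube are dropped as noise specks; a component is "localized" when
its bounding-box diagonal is ≤ 8 nm (the qualitative term needs a number to
be testable).  The analysis region defaults to the whole box; a particle
mask option exists because empty padding dilutes σ (making features look
more significant) — the default mirrors plain whole-box normalization and
is stated in the component table's params.

Numerical guard: after normalization both inputs have unit variance, so a
difference σ below 10⁻⁵ is float32 quantization, not signal; such pairs are
flagged `identical_maps` with an empty component table (σ-normalizing
quantization noise would otherwise manufacture arbitrary-looking "features").

## Pipeline and reproducibility

The YAML config is schema-validated (unknown keys rejected); every run
writes the resolved config, a manifest with the config hash and seed, and
per-stage tables with fixed float formatting — two runs at one seed are
byte-identical.  Problem sizes (48³ boxes, 200 particles, the 30°/15°/7.5°
schedule) are chosen so the full workflow and the test suite complete in
minutes on one CPU while keeping every recovery property measurable;
scaling up is a config change, not a code change.

## Known limitations

- No CTF, dose weighting, or colored noise in simulation or scoring.
- Integer-voxel shifts only; angular accuracy bounded by the final grid step.
- Half-set FSC without independent refinement is optimistic.
- Classification assumes compositional (not conformational) heterogeneity
  and a reasonable reference; a grossly wrong reference biases residuals.
- Template matching assumes non-overlapping particles; in crowded fields
  the local normalization window mixes neighbours.
- The phantom is a geometric caricature; none of its dimensions should be
  read as structural measurements.
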