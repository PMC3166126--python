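# Methods

## The measurement problem

Lens fiber cells pack crystallins at 600–800 mg/ml, and how
αA-crystallin (a ~20 kDa chaperone) is arranged in that cytoplasm is
read out here from 3D density maps: conical electron tomograms of
fiber cells either labeled with anti-αA antibody/gold conjugates or
unlabeled.  The pipeline quantifies where the label (or the protein
density itself) sits: particle positions, sizes, pairwise spacings,
and recurring geometric arrangements.  All distances are Euclidean in
nm; volumes are consumed as already-reconstructed 8-bit density maps
(0–255) with cubic voxels, 0.8 nm by default.

## Segmentation

Foreground is defined by a single intensity threshold (defaults: 200
for gold maps, where colloidal gold's amplitude contrast saturates the
8-bit range; 120 for protein density).  The foreground is partitioned
by a marker-based 3D watershed on the inverted, Gaussian-smoothed
intensity (smoothing 0.8 nm ≈ 1 voxel), with markers at local maxima
at least 2 voxels apart; any foreground component left without a
marker receives one at its brightest voxel.  Regions below
`min_voxels` (default 4) are dropped.  Per region we record the voxel
count, volume `V = n·a³`, equivalent-sphere diameter
`d = (6V/π)^{1/3}`, peak intensity, and the intensity-weighted
centroid ("mass center") in physical coordinates.  The partition is
exact: region volumes sum to the retained foreground volume, and
raising the threshold can only shrink the foreground.

Diameters of small particles are resolution-limited: a 3 nm sphere
blurred to ~2 nm resolution and thresholded at half its apparent peak
measures within ~15%, but below ~2 nm the apparent size is set by the
point-spread function, not the particle.  This is why the labeled
classification rules in the original workflow lean on peak intensity
as well as diameter.

## Classification

Labeled mode reproduces the two-class OR rules (yellow: d > 4 nm or
peak > 200; blue: d > 2 nm or peak > 150) with yellow evaluated first —
the blue rule alone would accept every yellow particle, so sequential
precedence is the only reading that yields disjoint classes.  For
synthetic volumes the gold is rendered saturating (see below), making
peak intensity uninformative; a `labeled_diameter_only` preset sets the
intensity thresholds to 255 (unreachable for 8-bit data) so membership
is decided by diameter alone.  Unlabeled mode classifies purely by
diameter band — blue (2, 3.5) nm, yellow (3.5, 7) nm, aggregates
> 7 nm — with an alternative (3.5, 5) nm yellow preset, since both
upper bounds appear in the source workflow.  Aggregates can be excluded
geometrically (configurable corner octant of the analysis box) or by
connection-graph degree (above a fixed cutoff or the 98th percentile).

## Connection networks and spacing models

Every unordered pair of blue/yellow particles with center distance
strictly below its class-pair cutoff becomes a connection (all pairs,
not only nearest neighbors; a k-nearest restriction is optional).
Distance samples per pair type are summarized as 1–2 Gaussian
components reported as center ± HWHM.  Three fitting routes:

* **Histogram least squares** (default for the standalone fit
  operation): sum-of-Gaussians least squares against the 1-nm-binned
  histogram — the classic curve-fitting workflow.
* **Truncated-mixture maximum likelihood** (pipeline default):
  unbinned likelihood with the support truncated at (0, cutoff).
  Truncation matters: a 7.5 nm spacing with HWHM 3.5 loses ~25% of its
  mass above the 10 nm blue–blue cutoff, and an untruncated fit would
  bias the center low.  Optimization is Nelder–Mead from quantile-based
  multi-starts plus seeded jitter (deterministic given the seed);
  component count can be fixed or chosen by BIC.  An optional
  random-pair background component with density `3r²/c³` — the
  distance law for uniformly scattered particles inside the cutoff
  `c` — absorbs coincidental cross-assembly pairs.  Its weight can be
  fitted, but the pipeline default fixes it at the
  complete-spatial-randomness expectation computed from the observed
  class counts and box volume, `E[pairs] = N_pairs·(4π/3)c³/V_box`,
  which removes a weakly identified parameter and stabilizes the
  center estimates at realistic sample sizes (tens to low hundreds of
  connections).
* **Windowed peak fit**: locate the dominant histogram peak (after a
  1-2-1 smoothing), fit a single Gaussian within ±1.5 FWHM of it, and
  iterate the window.  This estimates "the center of the fundamental
  spacing peak" robustly when contamination sits away from the peak —
  notably the lower tail of the doubled repeat leaking under the
  blue–blue cutoff — at the cost of modeling exactly one component.

The spacing-multiple report divides each fitted center by the
blue–blue fundamental and gives the deviation from the nearest integer
in {1, 2, 3}: dimers that skip one or two decoration sites double or
triple the basic repeat, so centers of 7.5 / 14 / 24 nm yield ratios
1 : 1.87 : 3.2.

## Tether measurement

Antibody tethers link each gold particle to its antigen on a filament
or bead.  The measurement is a geodesic: starting at the gold center,
Dijkstra through 26-connected voxels above a path threshold (55),
ending at the first voxel of an assembly — density above the protein
threshold (120) outside the blur halo of any gold (gold mask dilated
by 2 nm) — plus half the filament core diameter (1.25 nm) to reach the
axis.  The length is therefore defined center-to-axis, matching the
generator's definition of tether length as |gold center − site|.
Tethers shorter than the gold radius plus the ~2 nm halo are below the
method's resolution floor; chamfer discretization overestimates path
lengths by up to ~5%.  In crowded fields the nearest reachable
assembly may not be the tethered one, which biases individual
measurements low; the measurement is intended for sparse subvolumes
around isolated conjugates (the 128×128×50-voxel extraction default).

## Synthetic scenes

The generator emulates the structural model the analysis assumes, so
parameter recovery can be tested against exact ground truth:

* **Filaments**: random polylines with bounded curvature (direction
  jitter 8°/nm by default), reflected at the box walls; straight when
  curvature is zero.
* **Decoration**: arc-length increments ~N(7 nm, 1.7 nm) between
  sites; dimer modes occupy every 2nd or 3rd site (center-to-center
  14 / 21 nm).  The default 1.7 nm increment jitter reproduces a
  blue–blue spacing HWHM of ~2 nm.
* **Beads**: a configurable fraction of sites become 4-member clusters
  at the vertices of a randomly oriented square or regular tetrahedron
  with 15 nm circumscribed diameter.
* **Gold**: two diameter populations, N(3.0, 0.6) and N(7, 1.5) nm
  (truncated at 1 nm), attached at tether distance ~N(14, 3) nm.
  Tether directions are correlated within a filament (5° cone around a
  per-filament direction) and the length spread is split into
  within-filament (sd 1 nm) and between-filament components.  This
  local correlation is what preserves the site repeat in the gold–gold
  distances — with independent 14 nm tethers the label spacing would
  not mirror the 7 nm decoration spacing, whereas labeled-cell data
  show that it does.  Independent tethers are available via
  parameters.
* **Rendering**: protein at amplitude 180, filament cores 180, tethers
  120, background 30; gold painted bright enough that its post-PSF
  peak reaches ≥250 (amplitude contrast; sub-resolution gold gets a
  compensating boost, including for sub-voxel center offsets).  The
  scene is convolved with an isotropic Gaussian PSF (σ 0.85 nm ≈ 2 nm
  FWHM resolution), offset, degraded with Gaussian noise (sd 8), then
  clipped to [0, 255] and quantized.  Identical parameters (including
  the seed) give bit-identical volumes.

What the generator does *not* emulate: missing-cone/conical-tilt
anisotropy, CTF oscillations, membranes and gap junctions, stain
granularity, or spatially varying background.  Passing recovery tests
therefore demonstrates correctness of the measurement chain under the
assumed geometry and noise, not performance on raw experimental maps.

## Problem sizes and tolerances in the verification suite

The acceptance checks use: 20 spheres of 5–10 nm diameter for the
segmentation oracle (exact count, sub-voxel centers, volumes within
10%); 500 random points against an O(n²) scan for the network; 20
replicates of n=214 truncated-mixture draws (median center error
< 0.7 nm per component); end-to-end monomer (7.5 nm repeat, 150 nm
box, 14 filaments) and dimer-skip-1 (10 filaments) tomograms with
recovery tolerances of 1.0 and 1.5 nm — the acceptance script pools
three replicate tomograms per condition and reports the median, as the
original analyses pooled several tomograms; 50 isolated straight
tethers (mean within 1.5 nm of 14); and a 300-particle two-population
classification (confusion < 10%).  The dimer fundamental is fitted
under the tighter 24 nm mixed-pair window (single component + CSR
background), which excludes the doubled 30 nm repeat; the monomer
fundamental uses the windowed peak fit.  Scene sizes were chosen to
keep the full suite under a few minutes on one CPU while giving each
estimate at least ~30–100 connections.

## Known limitations

* Mode-0 MRC output stores intensities shifted by −128 (signed 8-bit);
  readers other than `read_volume` see the shifted values.
* Foreign MRC files with permuted axis order (MAPC/MAPR/MAPS) are not
  re-oriented.
* Unlabeled-mode diameters of near-resolution particles are biased by
  partial-volume effects; the diameter bands apply to the measured,
  not the physical, diameter.
* The motif detector enumerates within the connection graph only;
  arrangements whose edges exceed the cutoffs are invisible by design.
* Mass estimates assume the fixed protein density 0.0013 nm³/Da and
  that segmented volume equals molecular volume; both are rough for
  small, blurred particles.
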