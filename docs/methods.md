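# Methods

This note documents the models, algorithms and numerical choices behind
`guvstack`: what each stage computes, which parameters matter, what the
virtual-image simulator does and does not emulate, and where the design was
genuinely open.

## Problem setting

Giant unilamellar vesicles (GUVs) are micrometer-scale spherical lipid
bilayers imaged by confocal fluorescence microscopy as z-stacks: each
optical section shows a vesicle as a bright circular contour (the membrane)
whose radius follows the sphere geometry
`rho(z) = sqrt(R^2 - (z - z0)^2)`.  Three analyses are automated:

1. **Membrane binding** — how much of a second fluorescent species (channel
   B) sits on the membrane, using geometry detected in the lipid channel A.
2. **Protein droplet intensity** — the same machinery applied to globular
   liquid-liquid phase-separated droplets, measuring the full interior disc
   instead of the perimeter band.
3. **Phase-separation state** — whether a vesicle's membrane shows one
   uniform reporter level (homogeneous) or two coexisting levels
   (domain-separated), decided per section and aggregated per vesicle.

Three pipeline variants differ in who makes selection and state decisions:
program 1 is pure pixel computation; program 2 replaces per-circle
selection with a 4-class CNN; program 3 additionally replaces the state
decision with a 2-class CNN trained entirely on simulated images.

## Segmentation

Each section is first reduced to a binary mask with a triangle-method
threshold: a 256-bin histogram of the observed intensity range, the line
from the peak bin to the farthest non-empty tail bin, and the threshold at
the bin maximizing the perpendicular distance from histogram to line.  For
integer-valued data (16-bit camera counts) the bin width is kept at or
above one intensity unit; finer bins produce an empty-bin comb between
discrete levels that distorts the triangle geometry badly enough to move
the threshold from the tail to the histogram peak on background-only
sections.

Circles are detected with a circular Hough transform over a configured
radius range (default 20–120 px, covering typical GUV sizes at the default
calibration of 127.3 µm / 1,024 px).  The edge map is the gradient
magnitude of the binary mask (masking markedly improves behavior at low
signal-to-noise ratio; a Canny path on the raw image is selectable).  The
accumulator (scikit-image's `hough_circle`) is normalized so a fully voted
circle scores 1; peaks above `1 - sensitivity` become candidates, so the
0–1 `sensitivity` knob admits progressively weaker circles.  Two
suppression rules follow, strongest score first: near-duplicates (center
distance < 2 px and radius difference < 2 px) and concentric re-detections
(candidate center inside 0.75× the radius of a kept circle).  Because the
mask boundary lies a few pixels outside the blurred membrane crest, every
kept circle's radius is refined to the argmax of the circularly averaged
radial intensity profile of the *raw* image, with a parabolic sub-pixel
fit.  On noiseless rendered rings this brings center and radius errors
below 1 px.

## 3-D assembly and selection

Circles are grouped in ascending z.  Within one section, circles and open
entities are matched nearest-first against each entity's most recent
center, with a 10 px default tolerance — small enough that adjacent
vesicles (radius ≥ 20 px) cannot merge, and tracking the latest center
tolerates slow drift.  Matching is globally nearest-first within a section,
so the grouping does not depend on detection order.  Two selection stages
follow:

* per circle, an edge-contrast filter: mean intensity per pixel over the
  rim annulus `(r - band, r]` (default band 3 px) versus the interior disc;
  pass iff rim/interior ≥ 1.5.  This removes filled or multilamellar-like
  sections and the near-pole "cap" sections where the shell appears as a
  blob rather than a ring;
* per entity, a minimum-section rule (≥ 3 sections; one or two sections do
  not establish a 3-D object) and rejection of any entity whose bounding
  square leaves the frame.

## Intensity quantification

For droplet samples, note that the detection channel shows *filled* discs
rather than rings; the rim/interior contrast criterion that rejects
multilamellar vesicles would also reject droplets at its default, so
droplet analyses should set `min_edge_ratio` near zero (the filter then
only removes edge-touching and empty detections).

All measurements are background-corrected: `I_net = I_raw - I_background`,
with the background per section estimated as the mean of the pixels at or
below that section's triangle threshold (the dark part of the image).
Membrane binding sums channel B over pixels with center distance in
`(r - n, r]` (user-set `n`, default 3); droplets average over the full disc
`d <= r`.  Per-vesicle means weight sections by pixel count, giving a
representative value for the whole sphere; negative nets are reported
as-is so condition means stay unbiased.  Condition summaries average
per-stack means and report the between-stack standard deviation (n−1).

## Phase-state determination (contour statistic)

The perimeter is divided into N = 36 angular segments of the annulus
`(r - Δr, r]` (Δr = 3 px); each segment's net mean intensity forms the
contour profile.  Sorting the segments, the value at the 20th-percentile
rank from the top (bottom) defines the high (low) domain level — a rank,
not an extremum, so single-segment outliers cannot define a level — and
`mid = (high + low)/2`.  Discontinuities are counted by a cyclic two-state
hysteresis traversal: the trace is HIGH after exceeding `mid·(1 + p/100)`,
LOW after dropping below `mid·(1 − p/100)`, and each HIGH↔LOW transition is
one domain boundary.  Hysteresis means a swing must span the full ±p band:
single-threshold crossing counting would double-count noise wiggles.  A
closed contour yields an even count; a section is *separated* at ≥ 2.  A
vesicle is separated when at least 40% of its analyzed sections are
(boundary inclusive).

Two choices here deserve emphasis:

* **Band placement.** The pipeline measures the profile at radius
  `r_hat + Δr/2`, so the annulus brackets the detected intensity crest
  symmetrically.  Anchoring the band's outer edge exactly at `r_hat` would
  sample only the inner tail of the point-spread-widened membrane, roughly
  doubling the angular noise of segment means.
* **The p parameter tracks the reporter.** p is the minimum relative swing
  that counts as a domain boundary and should be set from the reporter's
  partition coefficient: strongly partitioned reporters (large
  bright/dim contrast) warrant a larger p so that noise on homogeneous
  contours stays inside the dead band.  The package default is p = 20%;
  the simulation benchmarks use p = 35% because the simulated reporter's
  dim-domain level is at most 45% of the bright level (see below).

## The virtual confocal simulator

Scenes are analytic: vesicles are perfect spheres (center, radius R,
membrane level, optional interior level); a membrane domain is the portion
of the shell inside a secondary *domain sphere*, rendered at its own
(usually dimmer) level.  A section at height z draws the exact geometry —
a 1-px-wide ring of radius `sqrt(R^2 - (z - z0)^2)`, domain arcs where the
ring enters a domain sphere, the interior disc — then convolves with an
in-plane Gaussian PSF (σ 1.2–2 px) and adds Gaussian noise (default σ = 5%
of the membrane level, approximating confocal read plus shot noise).
Ground truth never requires rendering: per-section centers, ring radii and
phase labels (separated iff the ring crosses a domain sphere over a
nonzero arc) come from the scene alone, which is what makes recall and
accuracy measurable exactly.

Default intensity scales: membrane 400–800, background 20–50, interior
0–20, domain level 15–45% of the parent membrane level (a strongly
partitioned reporter), domain cap half-angles 30–150° in-plane (section
arcs of 60–300°).  Training patches are rendered directly at 50×50 px with
ring radii 14–22 px and ±2 px center jitter, matching what `prepare_patch`
produces from detected circles at margin 1.2.

What the simulator does **not** emulate: axial (z) PSF blur — each section
is blurred only in-plane; photobleaching; polarization-dependent
excitation around the contour; membrane fluctuations or deformation
(vesicles are perfect spheres); multi-channel crosstalk.  Passing
simulation benchmarks therefore demonstrates correctness of the
*computation* under idealized confocal geometry, not robustness to every
artifact of real microscopes.

## The two CNN classifiers

Both networks share one family: 50×50×1 inputs with zerocenter
normalization (the training-set mean image is stored and subtracted at
inference), three conv(3×3, same padding)→batch-norm→ReLU blocks, 2×2
stride-2 max-pools after blocks one and two (spatial flow 50→25→12), a
fully connected layer and softmax.  The selection filter uses 16/32/64
filters with 4 outputs (C1 typical unilamellar, C2 multilamellar, C3
overlapping, C4 hazy; only C1 passes); the state classifier uses 8/16/32
filters with 2 outputs (homogeneous vs separated) and operates on
background-zeroed patches — zeroing sub-threshold pixels (not binarizing)
removes background variation that otherwise dominates what the small
network learns.

The engine is a compact CPU implementation (im2col convolutions as BLAS
matrix multiplies, float32 NCHW); at ~10^5 parameters, training on tens of
thousands of patches takes minutes on one core.  Training is stochastic
gradient descent with momentum 0.9 at the fixed recipe: initial learning
rate 0.01, at most 4 epochs, validation every 30 iterations.  Two defaults
were genuinely open and are set as follows:

* **Batch size 32.** With the epoch budget fixed at 4, the batch size
  controls the number of SGDM updates; 32 (vs the conventional 128)
  quadruples the update count and consistently raises held-out accuracy of
  the state classifier by 1–2 points at 5,000 patches per class.
* **Best-validation checkpoint.** At learning rate 0.01 the final iterate
  wobbles 1–2% between validation checkpoints; the trainer returns the
  weights of the best validation checkpoint (an option the usual deep
  learning trainers expose as "output network: best validation"), and the
  reported accuracy scores that delivered network.

Loss is cross-entropy on the softmax outputs by default; an MSE-on-softmax
option is provided.  Weight init is He-normal; batch-norm uses running
statistics (momentum 0.1) at inference.  Training is deterministic for a
fixed seed in single-threaded execution.  Augmentation replicates the
training set under random scaling (0.9–1.1) and position shifts (±3 px);
the ranges must contain the identity.

## Problem sizes used in validation

The test suite and the reproduction script run entirely on simulated data
at desk scale, chosen to exercise each claim while staying cheap: the
virtual-training experiment uses 5,000 patches per class (plus a disjoint
750-per-class validation draw and 2× augmentation); segmentation recall
uses 50 isolated rings spanning the full 20–120 px radius range;
phase-state accuracy uses 200 single-vesicle mini-stacks (half homogeneous,
half with equatorial-belt domain caps of 3-D half-angle 40–110°, noise 5%)
evaluated on ground-truth geometry so the state methods are isolated from
segmentation error; binding-contrast recovery uses paired conditions with
a true 20:1 channel-B ratio over three stacks each.  Full-frame pipeline
tests use 128–256 px frames rather than 1,024 px; nothing in the method
depends on the frame size.

## Known limitations

* Only circular cross-sections are segmented; strongly deformed or tubular
  membranes are out of scope (they are rejected rather than measured).
* Grouping links by center proximity between nearby sections; two vesicles
  stacked almost exactly above one another in z would merge.
* The contour statistic needs the dim domain to remain detectable after
  thresholding; reporters with near-unity partition coefficients require a
  small p, where noise robustness degrades — the CNN state classifier is
  the intended remedy for such samples.
* CNNs trained on the simulator transfer to data with similar optics and
  labeling; for real microscopes, retraining on images from the matching
  setup is recommended.
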