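# Methods

## Scope and data model

`angiolume` quantifies tumor vascular morphology and oxygenation in
three-channel 3D fluorescence volumes: a vessel-wall channel (endothelial
marker), an autofluorescence (AF) channel, and a hypoxia-reporter
channel. All stages operate on `ImageVolume` — a `(z, y, x)` voxel grid
with per-axis spacing in µm — so physical quantities (radii, lengths,
volumes, distances) are always derived from the stored spacing. Typical
light-sheet acquisitions are anisotropic (e.g. 1×1 µm in-plane, 3 µm
z-step); all distance-based computation (graph radii, the lumen weight
map) happens after nearest-neighbor super-sampling along z to an
isotropic grid.

## Autofluorescence correction

AF appears in every channel with the same spatial distribution at
channel-specific intensity, superimposed on global intensity gradients
that defeat any global subtraction. The correction is therefore local:

* local mean and SD are box-kernel statistics of radius *k* (default 32
  voxels), computed with reflect (edge-repeating) padding — reflect
  avoids the edge dimming a zero-padded filter would cause; the SD uses
  E[x²] − E[x]², clipped at 0 against rounding;
* AF peaks are voxels exceeding local mean + *f*·local SD with
  *f* ∈ [0.05, 0.4], a per-volume choice the package exposes but does not
  auto-tune;
* within the peak mask the AF signal is standardized by its local mean
  and SD, rescaled by the *target channel's* local SD (the symmetric
  local choice; an `amplify` factor of 1.2 is available for severe AF)
  and subtracted; results are clamped at 0, since negative photon counts
  are meaningless; voxels outside the mask are never touched;
* connected components above the 0.999 intensity quantile with ≥ 1000
  voxels (haemorrhage-like saturation) become an exclusion mask honored
  by region assignment downstream.

## Vessel segmentation

### Losses

Three terms, combined as L = (1−β)((1−α)L_Dice + αL_clDice) + βL_Lumen
with α = β = 0.5 by default (a convex combination, so L ∈ [0, 1]):

* **Dice** — soft Dice with smoothing constant 1.0 in numerator and
  denominator (prevents 0/0; empty∩empty scores 0).
* **clDice** — harmonic mean of topology precision and sensitivity on
  soft skeletons obtained by iterated soft morphological opening
  (axis-separable 3-point min/max pools). The ground-truth skeleton is
  computed from the binary mask without gradients; the prediction is
  skeletonized differentiably. The iteration count (default 10) must
  exceed the largest expected vessel radius in voxels.
* **Lumen** — each ground-truth voxel receives weight
  σ(min(EDT, r) − (r−5)) with σ the logistic and EDT the distance to the
  nearest background voxel (so background weight is σ(5−r) ≈ 0.0067 and
  deep lumen saturates at σ(5) ≈ 0.9933 for r = 10). The loss is Dice
  with these per-voxel weights entering each term once:
  1 − (2Σ w·p·g + s)/(Σ w·p + Σ w·g + s). Applying the weight once (not
  to both factors of the product) is the form in which a perfect
  prediction scores exactly 0 while errors are charged in proportion to
  their lumen weight; weighting prediction and truth separately would
  penalize even perfect overlap wherever w < 1.

### Network and training

A plain 3D U-Net: per level two 3³ convolutions, each followed by
per-channel instance normalization (affine) and ReLU; 2× max-pooling
down, nearest-neighbor upsampling + 3³ convolution up, skip
concatenation, 1³ sigmoid output head. Channels start at 8 and double per
level for 5 levels, giving 1,620,201 trainable parameters;
`UNet3D.layer_list()` emits every tensor so the count is auditable. The
normalization is what makes small-batch Dice-family training stable; its
omission leaves the network stuck in all-foreground or all-background
regimes.

Training uses adaptive-moment gradient descent (Adam) with linear warmup
over 5 epochs to the initial rate 1e-4, then 0.99 exponential decay per
epoch, 150 epochs, on 128³ chunks. Augmentations: random contrast
(gamma), additive Gaussian noise, and for 75% of samples a random linear
multiplicative bias field; every applied augmentation is logged so tests
can audit the stream. All weights and the data order derive from one
integer seed. Binary cross entropy is deliberately not part of the vessel
loss; it is the tumor-region model's loss only.

### Inference and post-processing

Whole volumes are predicted on chunks with 50% overlap, blended with a
separable periodic Hann window sampled at half-integer offsets — at this
overlap the shifted windows sum to exactly 1 along each axis, so an
identity model reproduces its input to float precision. Borders are
reflect-padded by half a chunk and cropped after stitching. The
probability map is thresholded at 0.5 and enclosed cavities are filled.

A model-free bootstrap segmentation (local-mean normalization followed by
hysteresis thresholding) seeds annotation and serves as a fast fallback
path. It traces walls but cannot fill the lumen of large hollow vessels —
recovering those is exactly what the lumen loss exists for.

## Vascular graph

3D thinning (`skimage.morphology.skeletonize`) produces a one-voxel
centerline. Skeleton voxels with ≥ 3 skeleton neighbors (26-connectivity)
cluster into branch nodes placed at the cluster centroid; single-neighbor
voxels are end nodes; node-to-node chains become segments. Closed loops
without branch points receive one anchor node carrying a self-segment.
Terminal spurs shorter than `bulge_size` × the radius at their attachment
are treated as surface bulges and pruned (default bulge size 1), after
which pass-through (degree-2) nodes are dissolved by concatenating their
two segments. Per-point radius is the distance transform at the skeleton
voxel; every foreground voxel is assigned to the segment owning its
nearest centerline voxel, so voxel counts are conserved exactly.

Features per segment: arc length (sum of consecutive point distances);
volume (assigned voxels × voxel volume); average cross-section =
volume/length; min/avg/max radius; curveness = arc length / endpoint
chord (≥ 1; for self-loops the chord is floored at one voxel length).
Segments with < 2 centerline points or no assigned voxels are flagged
degenerate and excluded from feature tables. Kissing vessels merged by
voxelization are accepted as merged topology.

Voxelization biases worth knowing: skeleton endpoints retract from the
mask surface by roughly one radius, which shortens measured lengths by a
few percent and inflates curveness of strongly curved short segments by
up to ~5%.

## Regions and hypoxia

The tumor mask is the union of up to three sources: a U-Net segmenting
tumor tissue from vessel morphology alone (trained with BCE on the 2×
mean-downscaled vessel channel, mask upscaled back), a reporter-based
mask, and manual add/remove corrections ingested as mask files. The
reporter-based path thresholds the σ=2-smoothed reporter at a
high-expression core level (default 0.25) and applies a metric closing
(default 18 µm) to bridge the normoxic rims interleaved between hypoxic
cores — keying on the unambiguous strong signal rather than the subtle
baseline elevation, which drowns in the textured parenchyma background;
reporter-dim tumors are the morphology model's job.

The hypoxia threshold is healthy-tissue mean + 1.5 SD of the reporter
channel, where "healthy tissue" is all non-tumor, non-excluded specimen
voxels. Classification compares the threshold against a lightly smoothed
(σ = 0.5 voxel) reporter, suppressing per-voxel shot noise so the rule
acts on local mean intensity as it does on high-SNR microscopy data.
Labels partition the volume into background / healthy / normoxic-tumor /
hypoxic-tumor / excluded; raising the σ-factor can only shrink the
hypoxic set.

## Region-conditioned, lumen-weighted statistics

Segments are assigned to the region containing both endpoint nodes; when
endpoints disagree, the majority region along the centerline decides.
Segments with an endpoint within ~1.5 voxels + one local radius of the
volume border are excluded (the radius allowance compensates skeleton end
retraction), as are segments mostly inside the exclusion mask. Each
included segment's lumen weight is its assigned voxel count over the
specimen total (weights sum to 1 per specimen). Histograms give each
segment its lumen weight — % of total lumen per bin, summing to 100 — so
a single large vessel counts as much vasculature as many equal-volume
capillaries; bin widths come from the weighted Freedman–Diaconis rule on
the pooled control distribution.

Scalar summaries per animal: tumor/hypoxic/normoxic volume (mm³),
hypoxia ratio (hypoxic/normoxic), vessel volume per tumor volume, and the
vascularization index (segments per mm³ of region). Groups are compared
against the control with Welch's unequal-variance t-test (Satterthwaite
degrees of freedom, two-tailed; stars ns / * ≤ 0.05 / ** ≤ 0.01 /
*** ≤ 0.001, no multiple-testing correction — noted in output metadata).
Pooled lumen-weighted feature distributions (animals pooled per group,
weights kept) are compared with a weighted two-sample Kolmogorov–Smirnov
test: D is the sup distance of the weighted ECDFs in double precision;
the p-value uses the asymptotic Kolmogorov distribution with effective
sample sizes (Σw)²/Σw² per side. With unit weights this reduces exactly
to the classical statistic; the p-value approximation is swappable for a
permutation scheme.

## The phantom generator

The generator emulates the study conditions with full ground truth:

* **Vessels** — cubic-spline paths through jittered control points;
  healthy vessels traverse the volume, tumor-anchored vessels are
  confined to ~2.5 tumor radii and carry sinusoidal transverse waviness
  (the tortuosity control) and larger radii. Anchor rejection sampling
  makes the tumor bed `tumor_vessel_boost`× denser than healthy tissue.
  Tubes are rasterized as spheres swept along the centerline; the voxel
  nearest each centerline point is always foreground.
* **Wall-only rendering** — vessels above the hollow-radius threshold
  contribute signal only within a 2 µm wall; their lumen is dark. This
  reproduces the large-vessel failure mode the lumen loss addresses.
* **Hypoxia** — exactly the tumor voxels whose Euclidean distance to the
  nearest vessel exceeds a threshold; `hypoxic_fraction_target` instead
  pins the distance quantile so the generative hypoxic fraction is exact.
* **Reporter channel** — parenchyma AF floor (0.05) with spatially
  correlated texture (SD 0.05, correlation ~4 voxels) present in healthy
  tissue (myelinated parenchyma is textured in this band; tumor displaces
  it), a small normoxic-tumor overshoot (0.07) from promoter background
  expression, and 0.5 inside hypoxia — i.e. the normoxic mode lies below
  the healthy mean + 1.5 SD threshold and the hypoxic mode far above it.
  The hypoxia front is rendered with half the optical blur of the vessel
  channel, since it is a tissue property, not an optical one.
* **AF** — Gaussian blobs added to *all* channels at channel-specific
  ratios; a multiplicative linear bias field and additive Gaussian noise
  complete the rendering. All randomness flows from one seed through
  `SeedSequence`, so identical spec + seed is bit-identical.

What the phantom does **not** model: oxygen diffusion physics, staining
chemistry, scattering or depth-dependent PSFs, vessels *inside* hypoxic
tissue (phantom hypoxia is avascular by construction, so hypoxic-region
segment samples are sparse), or empty space around the specimen. Passing
tests therefore demonstrate correctness of the computational pipeline
under controlled geometry, not biological fidelity of any particular
number.

## Experiment problem sizes

Chosen once as the package's study conditions:

* **Lumen-benefit contrast** — 32³ isotropic phantoms with thin filled
  capillaries (r 1.5–2.5 µm) and thick wall-only tumor vessels
  (r 6–9 µm, noise SD 0.04); tiny U-Nets (base 4, 3 levels), 10 training
  chunks, 12 epochs at rate 1e-3 (warmup 2), skeleton iterations 10,
  lumen clip r = 10; β = 0.5 vs β = 0 at α = 0.5, three seeds, five
  held-out phantoms each. Readout: interior fill fraction — the share of
  true deep-lumen voxels (EDT > 3.5 voxels) predicted vessel. The vessel
  sizes and noise keep the task hard enough that neither model saturates
  within twelve epochs (an easy draw lets both models reach full interior
  fill and the contrast collapses to a tie); the scaled-down learning
  rate is what lets the tiny model leave initialization within a dozen
  epochs, and the full-scale schedule remains the default configuration.
* **Region recovery** — 24×72×72 µm phantom, 6 uniformly placed vessels,
  tumor fraction 0.25, pinned hypoxic fraction 0.6; recovery is measured
  through the full AF-correction → threshold → classification chain.
  Residual bias (+0.03…+0.05) is the blur halo at the hypoxic boundary, a
  surface-to-volume artifact of the small scale.
* **Treatment cohort** — 32×112×112 voxels at 1×1×3 µm, 26 vessels, tumor
  fraction 0.28 (boost 6), hypoxic fraction 2/3 (the untreated
  condition); treated group: tumor volume × 0.1, tumor caliber × 0.5;
  n = 5 per group. Vessels are rendered solid here: the pathway under
  study is graph-feature and volume recovery through the model-free
  segmentation; lumen reconstruction has its own experiment. Readouts:
  Welch test on recovered tumor volume, weighted KS on the pooled
  lumen-weighted average cross-section of tumor vessels, treated vs
  control.

## Known limitations

* The graph extraction approximates the reference thinning-based
  algorithm; exact numerical agreement with other implementations is not
  expected, and kissing vessels are not split.
* The weighted-KS p-value rests on an effective-sample-size plug-in; for
  heavily concentrated weights it is conservative.
* The autodiff core is sized for small networks on CPU; the default
  5-level model trains, but slowly — the package's experiments use the
  scaled-down configurations above.
* Hysteresis bootstrap segmentation does not recover lumina; quantitative
  caliber statistics through that path understate large-vessel
  cross-sections unless vessels are filled.
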