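# Methods

`cryopick` implements a self-supervised particle-picking loop for
single-particle cryo-EM: an ab initio intensity-based picker proposes
candidate particles, reference-free 2D class averaging filters them by a
class-quality score, and a small CNN is trained on the filtered set,
picked with, and re-filtered until the picks stabilize.  No labeled data
or pre-trained weights enter the loop at any point; the only prior
knowledge is the particle diameter in pixels.

## The ab initio picker

A micrograph is integer-binned (block means, default bin 9), min-max
normalized to [0, 1], and thresholded against its local mean: a pixel
enters the detection mask when

    image[p] − mean(window centered at p) > threshold,

with the window tied to the binned particle diameter (rounded up to
odd) and mirror-reflected boundaries.  8-connected mask components
become candidates; each contributes a deviation-weighted centroid.  Two
cleanups follow: components smaller than a tenth of the binned particle
footprint (floor 2 px) are dropped as single-pixel noise excursions, and
surviving centroids closer than one particle diameter are resolved
greedily in favor of the larger component.  Centroids map back to the
unbinned frame as `x·bin + bin/2`.

The threshold is the picker's main data-dependent knob.  On real
micrographs, whose dynamic range is dominated by large-scale structure,
useful values are around 1e-3 to 1.5e-3 on the normalized scale.  On the
white-noise synthetic scenes of this package's test bench the normalized
noise deviation is orders of magnitude larger, so a fixed tiny threshold
admits half of all pixels.  The picker therefore also accepts an
automatic threshold anchored to the robust noise scale of the deviation
image, `k · 1.4826 · MAD`, with `k = 2` as the bench operating point:
bright contaminants compress the normalized signal (they stretch the
min-max range), and noise and signal compress together, so a
noise-anchored threshold adapts where any fixed value fails.  Dark-
on-bright particles are handled by an invert flag.

Intensity-based detection cannot distinguish particles from crystalline
ice: bright contaminants are picked at this stage by design, and their
removal is the job of the downstream class filter and CNN.

## 2D class averaging and the %/Res filter

Particles are extracted (box, by default, 1.5x the particle diameter in
the workflow), block-binned by 4, resampled bilinearly to 64x64 and
standardized per crop to zero mean, unit variance.

The built-in classifier is hard-assignment k-means over normalized
cross-correlation, marginalized over a grid of in-plane rotations
(8 angles) and integer shifts (±2 px).  Each class is seeded from a
*single* random particle rather than a partition average: partition
averages are all template-dominated and leave no asymmetry, whereas a
single-particle seed lets junk-dominated classes emerge, and because a
noise member correlates with its own class average like 1/sqrt(M), junk
then drains away from the clean classes round by round.  Empty classes
are re-seeded from the particle worst matched anywhere, which also tends
to be junk.  The classifier exists to make the selection loop run
deterministically offline; production users can instead feed class
metadata (distribution + estimated resolution per class) from an
external class-averaging program through `classes_from_metadata`.

Per class, the quality score is

    %/Res = (percent of all particles in the class) / (estimated resolution in Å),

and classes with %/Res strictly above 0.1 are kept.  Resolution is the
1/f at the first FRC = 0.5 crossing (linearly interpolated) between
even/odd half-set averages; a never-crossing FRC reports Nyquist, and
classes with fewer than two members are unresolved (score 0).  The FRC
is computed from the **unaligned** member images: aligning pure noise
against a shared reference imprints coherent structure on it (the
Einstein-from-noise effect), which in testing inflated junk-class
resolutions from the box limit (~300 Å) to 100-200 Å and pushed their
%/Res above the cutoff.  Unaligned half-averages are unbiased for junk
and merely conservative for asymmetric templates, and the selection
rule only needs a quality proxy that orders junk below real classes.

Selection iterates: classify the current set into `max(2, round(N/200))`
classes, keep members of passing classes, and stop once at least 90% of
a round's input survives.  A ten-round cap with a warning guards
pathological inputs.  The survivor set is non-increasing by
construction.

The 0.1 cutoff discriminates only when resolutions carry physical
units: a junk class of fraction p can never resolve beyond the box size
in Å, so rejecting it requires `100·p < 0.1 · box_Å`.  The synthetic
bench therefore keeps physical dimensions realistic (5 Å/px with 60 px
particles — a 300 Å particle, i.e. ribosome-scale geometry sampled ~5x
coarser than typical micrographs so scenes stay small).

## The CNN picker

Architecture: 64x64x1 input, three blocks of 3x3 convolution (32, 64,
128 filters, ReLU) each followed by 2x2 max pooling, a 128-unit dense
layer, and a 2-way softmax head trained with cross-entropy.  Weights use
He initialization from an explicit seed; the optimizer is Adam at 1e-3,
batch size 64, 30 epochs by default.  The network is implemented
directly in numpy (im2col + BLAS GEMM in float32, channels-last, with
persistent scratch buffers); a 30-epoch run on 2000 crops takes a few
minutes on one CPU core and is bit-reproducible given the seed.

Training data: positives are the class-filtered particles (label 1);
negatives are sampled uniformly from areas at least one particle
diameter from every known particle (label 0), one per positive by
default, resampled fresh each workflow iteration.  Contaminated areas
are *not* excluded from negative sampling — ice regions enter the
negative pool in proportion to their area, which is how the picker
learns to reject them.  Below 100 positives a warning is emitted;
training proceeds.  The training portion (stratified 80/20 split) is
re-augmented every epoch: rotation uniform in ±20°, then horizontal and
vertical flips with probability 0.5 each.  Train accuracy/loss are
accumulated from the training minibatches (i.e. on augmented crops,
before each update); validation metrics come from a clean full pass per
epoch.

Picking slides a window of the extraction box over the micrograph at a
stride of a quarter particle diameter (any stride up to half a diameter
keeps every center within the de-duplication radius of a window),
extracts each window through the identical crop pipeline as training,
and keeps windows with particle probability ≥ 0.9.  Overlapping
detections closer than one particle diameter are resolved greedily by
probability, ties broken by (x, y) so the result is independent of
input order.

## The workflow

1. **Initialize**: ab initio picks (or user-supplied manual coordinates)
   on a 20-40 micrograph subset, then the iterative %/Res filter.
2. **Iterate**: train the CNN from scratch on the current particles,
   pick the subset, classify the picks, and keep qualified ones.  The
   *qualified fraction* is the share of CNN picks landing in classes
   with %/Res > 0.1; at ≥ 70% the loop declares convergence, and after
   3 iterations without convergence the last model is used regardless.
   Retraining from scratch (rather than fine-tuning) keeps every
   iteration a pure function of its particle set.
3. **Production**: the final model picks all micrographs, one
   coordinate STAR per micrograph, resumable across runs, with
   unreadable inputs logged and skipped.

Every stage seed derives deterministically from the master seed, so a
run's ledger is bit-reproducible.

## The synthetic bench

`simdata` generates micrographs with unit-variance Gaussian background
noise, soft-edged disk/ring/rod templates stamped at random rotations
with peak amplitude equal to the requested SNR (peak contrast over noise
sd — low values emulate low-defocus imaging), and irregular bright
contaminants (unions of random ellipses) at a multiple (default 3x) of
the particle amplitude.  Particle centers keep one diameter of
separation, a diameter of edge margin, and by default a particle radius
of clearance from contaminants.  Everything derives from a seed;
datasets regenerate bit-identically from their manifest.

What the bench does *not* model: CTF oscillations and defocus-dependent
contrast inversion (the SNR knob stands in for defocus), structured
ice gradients, beam-induced motion, detector MTF, particle aggregation
and orientation preference.  Passing tests therefore demonstrate the
correctness of the decision rules and the closed-loop behavior
(contaminant exclusion, junk filtering, convergence) — not picking
performance on real micrographs.

Pick quality is scored by greedy one-to-one center matching within a
tolerance radius (half a particle diameter in the tests): precision =
matched/picked, recall = matched/truth.

## Problem sizes and numerical choices

The shipped test bench uses: five 1024² scenes of 30 disks for picker
recovery; a 700 template + 300 noise stack for the selection loop; 2000
balanced crops, 30 epochs for the training check (its label-shuffle
control runs 10 epochs — the no-leakage property it checks does not
depend on epoch count); and twenty 1024² scenes of 40 particles + 3 ice
blobs for the end-to-end run (training at 10 epochs, scan stride d/3).
These sizes keep a complete run in the tens of minutes on one CPU core
while leaving each decision rule with clear statistical margin.

Degenerate inputs: flat crops standardize to zeros; constant images
produce empty masks; empty coordinate sets round-trip as empty files;
classification refuses K > N; selection that empties the particle set
raises with advice to lower the cutoff.  Max-pool gradient ties are
split evenly among the tied inputs, which keeps training deterministic.

## Known limitations

* The built-in classifier is a correlation k-means, not a
  maximum-likelihood classifier; it is CTF-blind and intended for the
  offline loop and the bench, not as a replacement for a production
  class-averaging program.
* The local-threshold picker assumes additive bright (or, inverted,
  dark) particle contrast; phase-plate-like contrast is out of scope.
* Scanning is dense sliding-window scoring on one CPU; large production
  sets are processed serially.
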