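# Methods

This note records the models implemented by `neurostim`, the choices made
where the design was genuinely open, and what the synthetic validation
does and does not establish.

## The fwRF encoding model

A region's scalar response to an image is modeled in three stages.

**Feature bank.** Images (side S pixels, default 64, covering an
8.4° × 8.4° field of view) are convolved ("same" linear convolution, FFT
implementation in float32 with cached filter transforms) with a fixed,
seeded bank of oriented Gabor patches and center-surround
difference-of-Gaussian kernels; responses are rectified at zero and
block-averaged to per-level map sides (default: 16 channels at 16×16,
12 at 8×8, 4 global 1×1 channels; 32 channels total). The bank is fully
determined by its configuration, so model files only store the
configuration. A `deepnet_scale_bank()` preset declares the concatenated
map shapes of a deep-network backbone — (256, 27, 27), (896, 13, 13),
(1536, 1, 1) — for shape plumbing; it carries no trained weights and
cannot extract features.

**Channel selection.** Where a level has more channels than the cap K
(512 at full scale), the channels with the highest spatial variance per
image, averaged over images, are kept; ties break toward the lower channel
index. The alternative reading — variance across images of the spatially
averaged map — is available as `criterion="across_images"`.

**Pooling and readout.** Each channel map is collapsed by an isotropic
Gaussian pooling field. Coordinates put the origin at the field center
(x rightward, y upward); grid weights are evaluated at cell centers and
renormalized to sum to one per resolution level, so edge truncation can
never break normalization; 1×1 maps pass through. The pooling radius is
expressed as a fraction of the field extent: the classical 0.04–0.4 grid
is far too small to be degrees on an 8.4° field, and 0.04 · 8.4° ≈ 0.34°
matches plausible receptive-field sizes. The readout is ridge regression
with an unpenalized intercept on centered features; λ = 0 falls back to
minimum-norm least squares.

**Grid search.** Candidate centers form a square lattice (spacing 1.4°,
clipped to the field → 49 centers), radii and penalties are log-spaced
(8 radii in [0.04, 0.4]; 9 penalties — [1e3, 1e7] at full scale, [1e−6,
1e2] in the desk preset, matching the synthetic feature magnitudes). Every
combination is fitted on the training set (one SVD per pooling field
serves all penalties) and scored by Pearson r on the validation set; ties
break deterministically by lower radius index, then penalty index, then
lexicographic center. With noiseless data generated by the same
functional form at an on-grid field, recovery is exact and validation
r = 1 (asserted in tests).

**Group model.** The arithmetic mean of several subjects' model
predictions. Group, single and ensemble models all linearize to a
weighted sum of plain fwRF readouts, which lets prediction and its
analytic pixel gradient share one convolution pass.

## Stimulus selection and synthesis

Max sets take the top-N candidates by predicted activation (descending;
ties by image id); Avg sets rank by ascending `|prediction|` — meaningful
because models are fitted to z-scored responses, so zero prediction means
an average response. Within a session, Avg sets are selected from the
pool minus the Max set, and the regions' natural sets are kept disjoint
from one another: at desk-scale pool sizes cross-region collisions are
likely, and a session's manifest and trial table require unique image
ids (at the 72,000-image scale this constraint is almost never binding).

The generator is a seeded, differentiable stand-in for a conditional
GAN: each class has a smooth template from the same parametric family as
the natural stimuli, and the noise vector modulates the amplitudes of
fixed smooth spatial modes before a logistic squash into [0, 1] — so
pixels are bounded for any noise and the render map is affine in `z`
before the squash, giving a cheap analytic Jacobian. Synthesis follows
the two-step procedure: (1) probe every class with the same seeded noise
vectors (default 100 per class) and rank classes by mean predicted
activation (Max: descending; Avg: ascending magnitude); (2) spread the N
optimizations evenly over the best classes (default 10 retained;
remainder to the better classes) and minimize the Max or Avg loss with
`λ_z‖z‖²` regularization (default λ_z = 0.01) by projected gradient
descent (default 200 steps of size 0.05, truncation `|z_i| ≤ 2`) or by
seeded random search. The best-so-far iterate is returned, which makes
the best-loss curve non-increasing by construction. Because torch is not
a dependency, the gradient of the full model∘render chain is derived by
hand (pooling adjoint → rectification mask → correlation with the
filters via conjugate FFT multiplication) and is verified against finite
differences in the tests. The pipeline's desk configuration uses 60
steps of size 0.3: the synthetic loss surface has small gradients, and
at that setting the optimized image beats its class-probe mean in 20/20
seeded runs.

## Personalization

A novel subject's predictor is `ŷ = Σ w_i base_i(I) + b` over B frozen
base models (B = 8 at full scale), fitted by ordinary least squares with
an unpenalized intercept (minimum-norm under rank deficiency; optional
ridge for ill-conditioned cases; no sign or sum constraints). Training
pairs are a seeded stratified sample per (condition × designed-region)
cell of Session 1 — 32 × 4 × 3 = 384 images at the full design — with
image responses averaged over repeats before fitting, matching the
accuracy-evaluation convention.

## Statistics

All response comparisons use image-level means of within-(subject,
region) z-scored trials. The z-score uses the divide-by-n standard
deviation.

The condition contrast is a random-intercept LME, `y = Xβ + Zα + ε`.
Because the only random effect is a subject intercept, `V(θ) = I + θZZᵀ`
(θ the variance ratio σ_α²/σ_ε²) is block diagonal and every REML
quantity reduces to closed forms in per-subject sums. θ is profiled on a
log grid (θ = 0 plus 57 points over 1e−8…1e6) with local refinement to a
relative tolerance of 1e−8; fixed effects are the GLS solution at the
optimum. The implementation agrees with an independent mixed-model
package to ~1e−8 on β in tests, and with a dense-matrix GLS oracle
exactly at fixed θ.

Permutation inference re-draws the condition labels within subject
(preserving subject exchangeability; a global scheme is available),
refits the model for each of n_perm = 1000 draws, and reports the
fraction of permuted coefficients at least as large in magnitude as the
observed one — denominator exactly n_perm, so the smallest attainable p
is 0. The permutation refits run vectorized across all draws (the same
per-subject sufficient statistics, with a shrinking-bracket refinement of
each draw's θ), which makes a 1000-permutation test take tens of
milliseconds; the vectorized coefficients equal per-draw scalar refits to
1e−7. The observed coefficient is computed through the same estimator,
which also supports the single-subject case. Under a simulated global
null (subject offsets present, no condition effect) the test rejects at
α = 0.05 at a rate of ~0.05 (asserted within [0.03, 0.07] over 1000
simulations), with power ≥ 0.9 at an effect of 0.8 σ_ε.

Multiple comparisons use Benjamini–Hochberg FDR (step-up at q = 0.05,
applied per region), effect sizes are Cohen's d with the pooled n−1 SD
and Max − Avg sign, encoding accuracy is the Pearson r between predicted
and repeat-averaged measured responses over images seen at least twice,
and inter-subject similarity matrices carry across-subject correlations
off the diagonal and test–retest (repeat-1 vs repeat-2) reliability on
it. The accuracy–modulation association pools (accuracy, d) pairs across
regions and sources and permutes the pairing; the hierarchy-trend LME
regresses per-subject t statistics on an integer region level and the
contrast type, with a within-subject permutation p for the level
coefficient.

## The synthetic world

Virtual subjects are ground-truth fwRF models: response =
gain · Σ_k w*_k · pool_k(image) + ε with i.i.d. Gaussian noise per
(image, repeat). This is deliberately the same functional form the
estimator assumes, making parameter recovery a well-posed test.
Choices that matter:

* **Stimuli** are parametric grayscale patterns (two Gaussian blobs plus
  a windowed oriented grating) whose orientation, frequency, contrast and
  layout vary by an integer class and are jittered per image. On a
  10-class, 50-images-per-class pool, between-class variance of pooled
  features exceeds within-class variance for well over 90% of channels,
  which is what makes class probing meaningful. Pools are lazy: a
  73,000-image pool (8 × 9000 unique + 1000 shared) enumerates in about a
  second and renders pixels on first access, deterministically per seed.
* **Tuning structure.** Each region has one canonical pooling field
  shared by all its subjects (regional retinotopy is consistent across
  people; without this a group model carries no information about a novel
  subject) and one shared tuning direction mixed with per-subject
  idiosyncratic directions, `w = f·w_common + (1−f)·w_idio`, unit
  normalized (default f = 0.5 for both cohorts). Both the shared and the
  idiosyncratic directions are drawn shaped by the pooled-feature
  covariance of the stimulus family: the parametric images span a
  low-rank feature manifold, and isotropic directions can land nearly
  orthogonal to it, making inter-subject signal correlation a coin flip;
  with only the shared direction on the manifold the group model becomes
  near-perfect and personalization has no headroom. Shaping both
  reproduces the regime the method addresses — reliable group transfer
  *and* a reliable personalization gain.
* **Noise.** Gains are calibrated so the noise-free signal has unit SD
  over a calibration sample; noise_sd is then interpretable as
  1/reliability − 1 in variance units, and the empirical split-half
  correlation matches v/(v+σ²) within 0.05 over 2000 images (tested).
  Novel subjects receive a noise ladder (0.35–1.2) so encoding accuracy
  varies across subjects, which is what powers the accuracy-vs-modulation
  correlation.
* **Sessions.** Session 1 uses 2 repeats per image (the minimum
  consistent with "at least two measurements"; configurable). Responses
  are in arbitrary units, z-scored downstream; no hemodynamics, voxels or
  trial timing are simulated.

What passing tests show: the estimator recovers its own generative form;
selection/synthesis/statistics behave as specified; and the full loop
produces the expected qualitative result (d(Max, Avg) > 0 in both
sources, accuracy–modulation r > 0, personalized ≥ group for most
subjects). What they cannot show: performance on real fMRI data, where
the encoding model is misspecified, noise is structured, and image
statistics are natural.

## Pipeline scale and reproducibility

The pipeline's desk-scale defaults preserve the experimental arithmetic —
40-image condition sets (480 Session-1 images, 128 Session-2 images per
subject, 384 training pairs), 8 base and 6 novel subjects, the 49 × 8 × 9
hypergrid, 100 probe images per class, 1000 permutations — over a reduced
image pool (80 unique images per base subject + 40 shared), a 32-channel
bank and a small generator (8 classes, 6 noise dimensions). A full run
takes about four minutes on one CPU. Every stage derives its seeds from
the master seed, writes outputs atomically, and records SHA-256 content
hashes in a run manifest; re-running a configuration reproduces the
hashes bit for bit. Session-2 assembly keeps each subject's 128 image ids
unique by drawing Other images from unused members of the other subjects'
(oversized, 52-image) Self sets and backfilling the Group portion from an
extended group ranking.

## Known limitations

* The feature bank is fixed and shallow; it stands in for a pretrained
  deep backbone structurally (multi-resolution, rectified, channel-capped)
  but not semantically — there are no object-category channels.
* The generator's class templates come from the same pattern family as
  the natural pool, so "synthetic" and "natural" images differ less here
  than GAN samples differ from photographs.
* The LME supports a single random intercept per subject (the form used
  throughout); images are not modeled as a random effect, so conclusions
  need not generalize to out-of-sample images.
* Avg selection uses raw model outputs; with models fitted on z-scored
  responses this approximates "closest to average", exactly as intended,
  but models fitted to uncentered responses would need explicit centering.
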