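# Methods

This note records the models, conventions and numerical choices behind
`longisym`, and what the synthetic experiments do and do not establish.

## Synthetic longitudinal phantoms

The generator (`longisym.phantom`) emulates the data layout of a
longitudinal structural study: two sessions per subject, a subject class,
an integer-label atlas on the same grid, and per-subject covariates.

**Geometry.** The "brain" is an axis-aligned ellipsoid at 80% of the grid
extent — deterministic, and guaranteeing an empty background for the
cropping stage. Regions are a seeded Voronoi partition of the mask grown
from random interior sites; Voronoi cells of a convex mask are connected.

**Intensities.** Each region receives a distinct mean intensity (cycled
offsets ±0.15 around 0.6, smoothed with a 1-voxel Gaussian), plus a
smooth subject-specific random field (σ = 2 voxels, amplitude 0.08); the
brain edge is tapered over ~1 voxel, mimicking partial-volume falloff.
The contrast makes rigid alignment well conditioned; the smoothness keeps
resampling interpolation error small relative to the signals of interest.

**Change model.** Atrophy is multiplicative intensity loss in designated
target regions: session 2 = (1 − f) × session 1 there, with f = 0.4 for
progressors, 0.2 for the intermediate class, 0 for non-progressors
(defaults). This is deliberately not a biomechanical deformation: it
gives the network a learnable longitudinal signal whose ground truth is
analytically exact — from noiseless aligned pairs, f is recoverable to
machine precision as 1 − mean₂/mean₁ over the target region.

**Corruption order.** Session 2 is atrophied, then rigidly perturbed
(uniform within ±2 mm / ±2° by default, resampled with cubic
interpolation so both "acquisitions" stay comparably sharp), then both
sessions receive independent additive Gaussian noise (SD 0.05 ≈ 5% of the
intensity range). Registration therefore has to be solved before change
detection, as in real pipelines.

**Default study conditions.** 16³ voxels at 1 mm isotropic spacing, six
regions, atrophy implanted in region 3, 5% noise, ±2 mm/±2°
misalignment. Covariates (time between sessions ~ U(0.5, 2.5) years,
gender ~ Bernoulli(½), age ~ N(74, 6²)) are sampled independently of
class, so the phantom contains no demographic confounding by
construction.

**What the phantoms do not emulate:** deformation fields, bias fields,
multi-contrast physics, scanner drift, real anatomical variability, or
intensity distributions of any particular scanner. Passing the synthetic
recovery experiments shows the pipeline is *internally correct* (it finds
exactly the change that was implanted, where it was implanted); it is not
evidence about sensitivity on clinical data.

## Preprocessing

Session 2 is rigidly aligned into session 1's grid (first-session space
is the registration target; a halfway-space variant would be a
straightforward extension). The brain mask is the largest connected
component above 0.2 × max intensity, morphologically closed — a
surrogate for skull stripping that is exact on phantoms. Intensities are
min–max rescaled to [0, 1] using the 1st/99th percentile within the mask,
clipped, with outside-mask voxels zeroed. Optional isotropic resolution
reduction maps each axis length to round-half-up(fraction × length) with
anti-aliased trilinear resampling (e.g. a 182×218×182 grid at fraction
0.25 becomes 46×55×46). Finally both sessions are cropped to the tight
bounding box of the mask; cohort-level preprocessing crops **all**
subjects to the bounding box of the union of their masks, so every
preprocessed grid is voxel-aligned with every other — required for group
relevance accumulation.

### Rigid registration

Six parameters (three Euler rotations in degrees, three translations in
mm) about the fixed volume's center, estimated by bounded Powell search,
translations first and then all six parameters, within a coarse-to-fine
pyramid (coarse levels are used only while ≥16 voxels per axis remain, so
16³ phantoms are solved single-level). A candidate is accepted only if
it does not worsen the cost. The dissimilarity is a **trimmed** MSE:
both images are smoothed (σ = 1 voxel), the moving image is resampled
with cubic interpolation, and the largest 15% of squared differences are
excluded. Three numerical choices matter at small sharp-edged grids:

* *Cubic interpolation in the cost.* Trilinear resampling loses enough
  high-frequency content that its artifacts rival the alignment signal of
  a 5° rotation on a 16³ grid.
* *Smoothing both images* suppresses the remaining interpolation
  artifacts.
* *Trimming* makes the metric robust to genuine focal change: a
  longitudinal pair contains real atrophy, and an untrimmed MSE is
  reduced by spurious rotations that smear the atrophied region into its
  neighbours. Trimming 15% removes that incentive (the atrophy occupies
  a few percent of the volume; the margin covers its blurred boundary).

Search bounds default to ±8° / ±8 mm — within-subject longitudinal
misalignment is small, and the bounds also exclude distant
blur-compensating basins. On noiseless phantoms, single-mode
perturbations (≤5 mm shifts, 5° single-axis rotations) are recovered well
within 0.5 voxel / 0.5°; combined rotations about all three axes are
identifiable only to ~1–2° at 16³ (texture-limited), which the pooling
stages of the network absorb.

## Network

Defaults follow the reference protocol: 64 filters per parallel branch
(so a module's concatenated width is 192), one shared module before and
one module after the merge (both counts configurable in {1, 2, 3}),
shape-preserving padding, biases on, no batch normalization, 2³/stride-2
max pooling per module, global max pooling before the 2-class softmax
head, Adam at learning rate 1e-4, batch 4, ≤150 epochs, early stopping
patience 30 with best-validation weights restored. "Filters per branch"
is a reading choice (the width could also be interpreted as the
concatenated total); it is exposed in `InceptionSpec`.

The merge is the elementwise absolute difference: it reconciles
"subtraction" with an L-1 difference, is symmetric under session swap,
and sends identical inputs to an exactly-zero change map — both
properties are asserted in the test suite, for untrained and trained
models alike. The Siamese branch is a single list of layer objects
applied to both inputs, so weight sharing is structural: serialized
models contain exactly one copy of the pre-merge weights.

Everything (forward, backward, Adam) is NumPy: convolutions are im2col +
matmul in float32; max-pool routing uses explicit argmax indices (first
index on ties), which the LRP pass reuses. Training is deterministic
given the seed (single-threaded BLAS).

**CPU-scale runs.** The pipeline defaults and the acceptance experiments
keep the default 1+1 module topology but run it at reduced width (16
filters per branch; 8 for the 10-fold ensemble experiment), learning rate
1e-3, and shortened early stopping (≤10 epochs, patience 4). On the
phantom task the implanted signal is strong enough that these schedules
converge to the same perfect-separation solutions the full protocol
would reach; the reduced sizes are a deliberate choice so the complete
suite runs on one CPU in minutes.

## ε-LRP

The decomposed quantity is the **pre-softmax score of the progressor
class** (decomposing softmax probabilities is degenerate; the target
class is configurable). Rules per layer, with stabilizer
ε = 1e-9 and sign-matched stabilization z + ε·sign(z):

* linear layers (conv, dense): relevance is divided by the stabilized
  pre-activation, propagated along the weights, and multiplied by the
  layer input ("input × modified gradient");
* ReLU: pass-through;
* max pooling (windowed and global): winner-take-all to the argmax
  input, first index on ties;
* the |a−b| merge: locally linearized as sign(d)·a − sign(d)·b and given
  the standard ε-rule, which conserves relevance across the merge and
  routes exactly zero where the branches agree.

On bias-free networks with positive pre-activations this reduces to
gradient × input (asserted to 1e-6 relative error); with biases a small
fraction of relevance is absorbed by the bias terms, so conservation of
the target score holds to within a few percent at small bias scales.
The test suite also checks voxel-level agreement with an independent
brute-force redistribution oracle (explicit loops, no shared code).

## Region aggregation

`M_N` accumulates the *absolute* per-voxel relevance of all supplied
subjects and both sessions (callers pass test-set maps only). `M_r`
divides each region's summed `M_N` by its voxel count, removing the size
bias; because `M_N` is already non-negative, summing with or without an
absolute value inside the region is identical. Rows are ranked by `M_r`
descending with ties broken by region id; a max-normalized column
(`M_r_scaled`) is provided for heatmap display. The cortical/subcortical
distinction is a metadata column on the atlas, not a separate code path.

## Evaluation statistics

* AUC is the midrank (Mann–Whitney) estimator, ties counted ½; it equals
  brute-force pair counting to 1e-12.
* The operating point minimizes √((1−sens)² + (1−spec)²) over the
  empirical ROC points of the rule "score ≥ t"; ties resolve to the
  lowest threshold. Balanced accuracy is (sens + spec)/2.
* DeLong's test uses the midrank structural components with the paired
  covariance; identical score vectors return p = 1, and a zero-variance
  difference with unequal AUCs raises a numerical-degeneracy error
  rather than fabricating a p-value. The asymptotic p agrees with a
  10,000-draw paired permutation oracle to < 0.05 at n = 20 when the two
  scorers genuinely differ; for near-identical scorers in mid-range p
  the normal approximation is known to be coarser.
* Confidence intervals are 2.5/97.5 percentiles of the AUC over seeded
  subsamples **without replacement** (1000 iterations at 80% — the
  stated iteration count and fraction suggest subsampling rather than a
  bootstrap; subsamples that lose a class are redrawn).
* Repeated stratified 10-fold CV (100 repeats by default) averages each
  subject's out-of-fold probability across repeats, then builds **one**
  ROC from the averaged probabilities (per-repeat ROC averaging is the
  other defensible reading; pooled-then-one-ROC is implemented).
  Stratification is used throughout because phantom cohorts are small
  enough that unstratified folds can lose a class.
* The network uses a single stratified 10-fold scheme in which each fold
  serves once as test, the following fold as validation, and the rest as
  training (80/10/10). External subjects are scored by averaging the 10
  fold-models' probabilities; their ROC against the non-progressor group
  uses the non-progressors' own cross-validation test-set probabilities.

## Baselines

Voxel features are the flattened |s₁ − s₂| in C order; region features
are |v₁ − v₂| of per-region volume vectors (on phantoms, per-region
integrated intensity serves as the volume proxy, since the implanted
change is intensity loss). IQR scaling (x − Q1)/(Q3 − Q1) uses
linear-interpolation quantiles fit on training rows only; constant
columns are flagged degenerate and scaled to zero. Classifiers:
L1-regularized logistic regression (liblinear), linear SVM with
Platt-scaled decision values, random forest (200 trees) — all through
scikit-learn.

## Confounder adjustment

Main-effects logistic regression of the binary group on time between
sessions (years), gender (0/1, reference level 0), baseline age (years)
and the network probability, fit by Newton/IRLS (statsmodels) with
convergence tolerance 1e-10 and ≤100 iterations; Wald 95% CIs and
two-sided p-values are reported (profile-likelihood intervals would be
the alternative). Separation is detected both from the perfect-prediction
condition and from a standardized coefficient-norm explosion, and raised
as an error. Parameter recovery is verified by simulation: at n = 2000,
each true coefficient falls inside its Wald CI in ≥90 of 100 seeded
replicates.

## Acceptance experiment sizes

`scripts/acceptance.py` runs, per seed: the atrophy-recovery experiment
on 200 pairs (100 per class) at 16³ with 5% noise and ±2 mm/±2°
misalignment, training one 80/10/10 fold at width 16 and explaining the
held-out fold; the intermediate-class experiment on 20 subjects per class
(including atrophy 0.2 intermediates) with all ten fold-models at width
8; registration recovery on noiseless single-mode perturbations; the
statistics and formula checks on constructed score sets; and 100
confounder replicates at n = 2000. These problem sizes are the package's
chosen desk-scale defaults; all are configurable upward.

## Known limitations

* Multi-axis rotation recovery at 16³ is texture-limited (~1–2°); larger
  grids sharpen it.
* The NumPy network is practical to hundreds of subjects at 16³–32³; it
  is not a route to 1-mm whole-brain training.
* ε-LRP conservation is approximate in the presence of biases (the
  ε-rule's known leakage); bias-free configurations conserve exactly.
* Atrophy as intensity loss means the baselines and network see a
  simpler signal than real morphometric change; the phantoms validate
  mechanics, not clinical effect sizes.
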