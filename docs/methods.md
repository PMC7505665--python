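# Methods

`sharedrep` implements a multivariate decoding workflow for asking
whether two ways of evoking the same mental state — here, vicarious pain
evoked by viewing noxious stimulation of limbs (NS) versus painful
facial expressions (FE) — rest on shared or distinct neural
representations, and whether the shared part is specific to pain rather
than generic arousal.  This note records the model assumptions, the
defaults and why they were chosen, and what the synthetic data do and do
not establish.

## Decoding model

Features are per-subject condition-average images restricted to an
analysis mask and linearized in a fixed x-fastest order.  The decoder is
a linear soft-margin SVM (hinge loss, penalty C = 1) on features
affinely scaled per voxel so the training set spans [-1, 1]; test images
reuse the training scaler and may exceed that range.  Voxels constant in
training are mapped to 0 for train and test alike.  The SVM is solved by
libsvm with tolerance 1e-6, tight enough that decision values agree with
an independent quadratic-program solution to better than 1e-4 on small
problems (tested).

Evaluation conventions:

* **2AFC accuracy** — per subject, the member of the (pain, control)
  pair with the larger pattern expression w·x is called pain; exact ties
  score 0.5.  Offsets cancel in the pairwise difference, so 2AFC is
  invariant to adding any constant image to both pair members.
* **Single-interval accuracy** — sign of w·x + b against the label; a
  zero decision value scores 0.5.
* **Significance** — exact one-tailed binomial test of the per-subject
  2AFC outcomes against chance 0.5 (strict wins counted).  One-tailed
  because the scientific claim is above-chance classification.
* **Effect size** — Cohen's d of the paired expression differences,
  mean(Δ)/sd(Δ); reported as ±inf when sd(Δ) = 0 with nonzero mean.

Cross-validation assigns whole subjects to folds (pairs never split),
fold sizes differing by at most one, and repeats the random partition
(default 10 folds × 10 repeats).  Per repeat, subject outcomes are
pooled across folds; accuracies, p values and d are then arithmetically
averaged across repeats.  Averaging p values across repeats is
statistically unconventional but is retained deliberately as the
aggregation rule of the workflow being reproduced.  Between-modality
cross-prediction reuses the identical fold partitions: the model trained
on modality A pairs of the training folds is scored on modality B pairs
of the held-out subjects, so within- and between-modality accuracies are
directly comparable.  With train = test modality the code path reduces
exactly to within-modality CV (tested).

The modality-general decoder pools NS and FE pain-versus-control images
from all subjects (scaler fit on the pooled set).  It is used only for
transfer analyses, never for within-sample accuracy claims.

## Pattern expression and transfer

Pattern expression is the raw dot product w·x, offset excluded.  On
transfer data (different paradigm or acquisition) the training scaler is
*never* applied — the units of an independent dataset bear no relation
to the training min/max; scaling remains available as an option for
within-paradigm use.  Expression–covariate correlations on the thermal
set are pooled across subject × level rows (33 × 6 gives df = 196); a
within-subject variant can be computed by grouping the returned series.
Level-contrast 2AFC averages expressions within the low and high level
sets per subject before the paired comparison, and excludes (with a
warning) subjects missing a required level.

Specificity applies the pain decoder, under its own fold structure, to
the held-out subjects' negative-vs-neutral contrast via raw dot
products.  Chance accuracy there, combined with above-chance thermal
transfer, is the double dissociation that separates a pain-specific
representation from an arousal response.

## Map-level statistics

* Group t-maps: voxel-wise one-sample t (df n−1, two-tailed); zero-
  variance voxels get t = 0, p = 1, flagged.
* FDR: Benjamini–Hochberg step-up at q = 0.05 over the two-tailed p of
  |t| (one joint correction, not per tail).
* Extent: connected components under 18-connectivity (faces + edges,
  the SPM lineage convention); components below 100 mm³ are removed —
  at 2 mm isotropic voxels, 12-voxel clusters go, 13-voxel clusters
  stay.
* Permutation spatial similarity: condition labels are swapped within
  subject; the null pools both shuffle directions (A-side and B-side, n
  permutations each) with per-direction p also reported.  The add-one
  rule p = (1 + hits)/(1 + 2n) avoids p = 0.  Two-sided on |r| by
  default, one-sided available.
* Bootstrap reliability: subjects resampled with replacement, decoder
  retrained per sample; z = mean(w*)/sd(w*), two-tailed normal p (a
  percentile variant is a natural extension; the normal form is what
  z-map thresholding implies), then FDR + extent.  Zero-sd voxels get
  p = 1 when the mean is 0 and are flagged extreme otherwise.
* Octants: both weight maps are z-scored across voxels; each voxel's
  angle θ = atan2(z_y, z_x) selects one of eight 45°-wide sectors
  centred on the axes and diagonals (O2/O6 are the shared-positive/
  shared-negative diagonals).  Sector boundaries belong to the
  counterclockwise neighbour — an explicit convention; ties have
  measure zero for continuous weights.  Exact-zero pairs are excluded
  and counted.  SSD per octant sums z_x² + z_y².

## Searchlight

Spheres are integer lattice points within a Euclidean radius given in
voxel units or mm (via the voxel size; radius 3 voxels equals 6 mm on a
2 mm grid); out-of-mask voxels are dropped, no padding.  Every centre
reuses one shared fold partition — re-drawing folds per centre would
confound spatial structure with partition luck — and defaults to a
single repeat for tractability (configurable).  Centre significance is
a subject-level binomial test on pooled outcomes; each of the four maps
(two within, two between) is FDR-corrected across centres, and the
conjunction keeps centres significant on all four.  Decoder failures at
degenerate centres leave that centre at chance rather than aborting the
map.

## Synthetic data

The generator draws condition images as

    image(s, m, c) = subject_effect(s) + Σ_k a(c, k)·pattern_k + ε,

with ε i.i.d. Gaussian (sd 1 by default) per voxel and a per-subject
Gaussian intercept image (sd 0.5) shared across that subject's
conditions — the within-subject pairing that forced-choice evaluation
exploits.  The four component patterns (shared pain, NS-unique,
FE-unique, arousal) occupy disjoint random supports, are Gram–Schmidt
orthogonalized in that fixed order and unit-normalized, making recovery
tests unambiguous.  Default amplitudes (in noise-sd units): shared 1.5,
modality-unique 0.8, arousal-on-pain 0.4, arousal-on-negative 1.5.
They were chosen once to place the default configuration in the
qualitative regime of interest — within-modality decoding well above
chance, between-modality transfer intermediate (shared signal dominates
unique), weak arousal leakage into the pain decoder — not to reproduce
any empirical per-voxel effect size, which is unknown.

The thermal set gives each subject one image per stimulation level with
shared-pattern loading slope × level and a rating linear in level plus
Gaussian noise (sd 1) — the simplest monotone stimulus–response model
the correlation analyses need.  The default slope 0.75 was calibrated
once on the reference configuration (6³ grid, 60 training subjects) so
that pooled expression–level correlations and high-vs-low 2AFC land in
the regime the workflow is designed to detect (r ≈ 0.5, accuracy ≈
0.95).

Block-design runs are boxcars (16 s blocks) convolved with the Glover
canonical HRF projecting each condition's mean pattern into voxel
space, plus low-order cosine drift, a motion-coupled nuisance signal
driven by random-walk motion parameters, and white noise.  Cleaning
regresses the 24-column motion expansion (parameters, squares, backward
differences with a leading zero, squared differences), per-outlier
indicators, a linear trend and discrete-cosine drift regressors
(periods > 128 s) out of the signal in a single simultaneous pass;
block averages then span round(16 s / TR) volumes starting 3 TRs after
the onset volume (onset mapped to the nearest earlier volume).  Outlier
volumes are regressed but retained in block averages by default
(exclusion is a flag).

What the generator does **not** emulate: spatial autocorrelation and
smoothness, physiological noise spectra, field inhomogeneity,
inter-stimulus variance within blocks, and any surface geometry.
Passing tests therefore establish the statistical machinery — chance
calibration, shared-versus-unique separation, resampling behaviour —
under idealized voxel-independent noise, not performance on real fMRI
data, whose headline accuracies additionally depend on sample size and
real signal topology.

## Numerical and design choices

* Masked vectors use Fortran (x-fastest) linearization everywhere;
  voxel indices are 0-based; mm coordinates appear only in NIfTI
  affines at I/O boundaries.
* Rank-deficient nuisance designs fall back to least squares on the
  pseudo-inverse with a warning.
* The repeated-CV scheme derives all partitions from one seed;
  pipeline runs are byte-deterministic given the config, whose hash is
  recorded in the run log.
* Desk-scale problem sizes used by the test suite: 6³–8³ grids,
  20–60 subjects, 1000 bootstrap samples, 200 permutations per side for
  calibration studies; these are the package's reference configurations
  for property checks.
* The pipeline entry point runs every stage except the searchlight,
  which is exposed as a library call (`searchlight_crosspred`) and
  sized by its caller.

## Known limitations

Voxel-independent noise makes decoding easier per unit amplitude than
on spatially smooth data; amplitudes are therefore regime-calibrated,
not physically meaningful.  Averaging p values across CV repeats
(retained for fidelity) has no clean sampling interpretation; treat
aggregated p as descriptive and rely on the per-repeat results when a
calibrated test is needed.  The bootstrap z normal approximation is
anti-conservative for very small subject counts; the implementation
refuses n < 10.
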