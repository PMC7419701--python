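# Methods

This note documents the models, parameter choices, and known limitations of
`langmap`. Everything quantitative stated here is computed by the test suite
or `scripts/acceptance.py`.

## The phantom generator

The pipeline's statistical premise is that voxels of one resting-state
network share a latent low-frequency signal. The generator makes that premise
literal so every downstream stage can be verified against known ground truth.

**Geometry.** A spherical "brain" is inscribed in an isotropic grid (default
24³ voxels of 3 mm). Parcels are spherical blobs (default radius 2 voxels)
placed on a lattice whose spacing exceeds one blob diameter, so disjointness
holds by construction; blobs may be clipped at the brain edge. Network 1 is
the language analog: its first parcel (Broca-like) is placed left-anterior,
its second (Wernicke-like) left-posterior; remaining language parcels prefer
the right hemisphere, standing in for homologs. Two leftover lattice sites
become white-matter and CSF stand-in compartments for nuisance extraction.
The left hemisphere is the lower-x half of the grid; anterior is higher y.
Requests that cannot be packed raise a capacity error rather than degrade.

**Signals.** Each network carries one latent signal: white Gaussian noise
low-pass filtered below 0.1 Hz (the band the preprocessing retains) and
standardized. A parcel voxel's series is
`baseline + a_sig * latent + a_noise * white noise + drift`, with
`a_sig² = snr/(snr+1)` and `a_noise² = 1/(snr+1)` so total fluctuation
variance is 1 regardless of SNR; background brain voxels carry the noise and
drift terms only. Baseline intensity is 1000, fluctuations are ~0.1 % of it,
drift is a per-voxel random linear slope (scale 0.3 units). Defaults:
`snr = 5` (within-network voxel-pair correlation ≈ 0.83), TR 2.2 s, two
160-frame rest runs, one 100-frame task run — the patient acquisition
timing. The paper-scale protocol prints no effect sizes, so the SNR and drift
defaults are this package's choices of a plausibly clean clinical acquisition;
they are fixed study conditions, not tuning knobs.

**Motion spikes** are whole-volume intensity offsets of 2.5 % of the baseline
(5× the censoring threshold), not geometric displacement — realignment is out
of scope, so the spike-indicator regressor and its temporal derivative stand
in for motion parameters in the nuisance set.

**Degenerate zero-noise regime.** With exactly zero noise the in-brain data
matrix has rank K (one latent per network). Regressing three nuisance
waveforms (global, white matter, CSF — each a mixture of the latents via
spatial smoothing) then collapses the residuals to rank ≈ 1, making all
between-network correlations ±1 and the classes inseparable. This is a
faithful property of rank-deficient data, not a bug; "effectively noise-free"
checks therefore use `snr = 100`, which keeps the data full-rank while
leaving within-network correlations at 0.99.

**Task runs** add `amplitude × regressor` (block boxcar convolved with the
hemodynamic kernel) to responsive parcels on top of a rest run with the same
seed. Spontaneous network activity is a genuine confound for the GLM — it
biases the amplitude estimate by its chance correlation with the regressor —
so exact-recovery checks use `include_spontaneous=False`, which zeroes the
latent signals. The default experiment drives all language parcels (the
Wernicke analog at 0.4× amplitude) and co-activates two task-general
networks, emulating an expressive task's non-specific responses; these ratios
are fixed design choices of the phantom.

**Meta-analytic maps** place Gaussian blobs (peak Z = 8, 9 mm FWHM) on the
two language-analog parcel centers over small background noise (sd 0.2), with
an optional smaller-extent distractor blob (peak 5, 4.5 mm FWHM) to exercise
cluster-size ranking.

**Cohort table.** The 35-patient clinical/demographic table ships as a
tab-separated fixture (one row per lesion; two patients have two lesions).
Its per-patient totals give mean 43.85 mL and maximum 207 mL; the smallest
per-patient total in the table is 0.4 mL, although the patient whose total is
1.4 mL (RS_005, 1.2 + 0.2) is the conventional range floor. The summary
reports the table as-is.

## Preprocessing

Stages, applied identically to rest and task runs: per-voxel least-squares
detrending; zero-phase low-pass (second-order Butterworth run
forward-backward — the band, not the filter family, is prescribed, and a
zero-phase IIR is the standard phase-preserving choice; the squared response
passes ≥ 0.94 at 0.05 Hz and ≤ 0.06 at 0.2 Hz for TR 2.2 s); separable
Gaussian smoothing with sigma = FWHM/(2√(2 ln 2)) per axis, reflective
boundary (intensity-conserving); nuisance regression of white-matter mean,
CSF mean, global mean, and the spike regressors, with an intercept —
residuals are orthogonal to every column, constant columns are dropped, and
rank-deficient designs raise an error naming the collinear columns.

Frame censoring computes, per frame, the RMS over brain voxels of the
intensity change from the previous frame, as a percentage of the whole-brain
mean intensity, and excludes frames above 0.5 %. It is evaluated on the raw
intensities (after detrending the mean is ~0 and a relative criterion is
meaningless) and the kept-frame mask is enforced by every downstream
correlation and GLM computation rather than by deleting frames. An isolated
spike flags two frames — itself and its successor — because both transitions
exceed the threshold; frame 0 is always kept. Matching the task acquisition
length uses the first 100 kept frames of the pooled rest runs ("contiguous"
is interpreted as the earliest contiguous block of kept frames).

## Features

A training example is the whole-brain Fisher-z correlation volume of one
parcel-mean seed, labeled with the seed's network; at inference the same
representation is computed with each in-mask voxel as its own seed (raster
order), which reduces classification to voxelwise network scoring. The
Fisher transform is variance-stabilizing; correlations are clamped to
|r| ≤ 1 − 1e-7 before atanh. Zero-variance voxels yield z = 0 and, as seeds,
are flagged so the classifier assigns uniform 1/K probabilities. A
correlation requires at least 30 kept frames (configurable). The 70/30 split
shuffles example ids with a seeded generator and takes
`round(n × 0.3)` validation ids — for 268,000 examples, 187,600/80,400.

## Classifier

Architecture: an average-pooling input reduction (applied while the grid is
≥ 16 voxels per axis — correlation volumes are spatially smooth, so little is
lost), a 3-cubic stem convolution, a second pooling (grid ≥ 12), then dense
blocks in which each layer is BatchNorm → ReLU → convolution producing
`growth_rate` channels concatenated onto the block's running feature stack,
with kernel edges cycling through {3, 5} within each block. Between blocks, a
transition (BatchNorm → ReLU → 1-cubic compression convolution → average
pool) halves channels. The head is BatchNorm → ReLU → global average pool →
fully connected softmax over the K networks.

Layer accounting, embedded in every model's manifest: learnable convolutions
plus the fully connected head,
`total = 1 stem + Σ layers-per-block + (blocks − 1) transitions + 1 head`.
The reference configuration (3 blocks × 15 layers) counts 49; the desk-scale
default (2 blocks, layers 1 and 2, growth 6, stem 8) counts 6 and trains in
seconds. All layers are implemented directly on numpy with explicit
backward passes (im2col convolutions, batch normalization with running
statistics, exact gradient routing through the dense concatenations),
verified against numerical differentiation in the test suite.

Training minimizes softmax cross-entropy with Adam at a fixed step
(3 × 10⁻³), batch 16, validating every 2 epochs and stopping once validation
accuracy has not improved for 3 consecutive validations; the best-validation
weights are restored. All stochastic stages take explicit seeds;
single-threaded CPU execution is the reference mode.

Probability-map smoothing is two-stage. Stage 1 (stride-1 mode filter): the
winner-take-all label volume is replaced by its modal label in a 3³ window
(in-mask voxels only; count ties resolve to the lowest class index), and each
voxel's probability vector becomes the mean over neighborhood voxels carrying
that modal label. Stage 2: a separable length-3 box filter per class,
restricted to the mask, then per-voxel renormalization. Both stages preserve
the per-voxel sum of 1 (within 1e-5) and are independently toggleable, since
whether the original filters operated on labels or probabilities is an open
interpretation. Under count ties the class-index tie-break makes the mode
stage non-equivariant to class permutation; in tie-free configurations
equivariance is exact (tested).

## Task GLM

Design matrix: intercept plus the boxcar convolved with a gamma-variate
kernel (shape 6, scale 1 s → peak near 5 s, unit sum; the kernel family is
this package's choice — only "standard GLM methods" is prescribed). Per-voxel
least squares on kept frames; beta is the task coefficient and
t = beta/SE with dof = kept frames − columns. A design with no blocks
degrades to intercept-only with zero beta/t maps. Post-processing smooths at
10 mm and masks extra-cranial voxels; no clustering or thresholding. The
score fed to ROC is the t-statistic volume (beta maps are also emitted); ROC
is rank-based, so any order-preserving statistic choice is equivalent.

## Ground-truth ROIs

The five-step construction is implemented exactly as listed in the module
docstring. Decisions where the recipe is ambiguous: the 3.7 threshold is
applied in Z units (it is a Z-score); since tanh is order-preserving,
thresholding the tanh map at tanh(3.7) selects identical voxels (asserted by
a dual-path test), and the tanh map is kept as the probability annotation.
Connectivity defaults to 26-neighborhood (configurable to 6). Re-binarization
after the 3 mm smooth is at 0.5. A size tie for the second-largest cluster is
broken by larger peak Z. Cluster search is restricted to the left half-grid,
and the anterior (higher-y centroid) ROI is named Broca-like. Every output
asserts disjointness and carries a provenance record (thresholds, cluster
census, centers of mass).

## Group evaluation

Group maps are voxelwise arithmetic means of per-subject maps, min-max
normalized within the brain mask (order-preserving, so AUC is unchanged).
AUC is the concordant-pair fraction with ties ½, computed by the rank
formula and verified against an exhaustive O(n²) oracle. The bootstrap ROC
resamples voxels (cases) with replacement — the group maps collapse subjects
before the ROC, so the voxel is the sampling unit — computes each
replicate's ROC by threshold sweep over unique scores, interpolates linearly
onto a 101-point FPR grid, and reports the vertically averaged TPR with
percentile bands and a percentile AUC interval (10,000 replicates,
alpha 0.05 by default; the test suite uses 1,000). A degenerate resample
(single-class) is redrawn once, then falls back to the chance diagonal. Note
the replicate mean can legitimately lie outside a percentile band when the
replicate distribution is strongly skewed (e.g. TPR pinned at 1).

The negative class for each ROI's ROC is the left-hemisphere brain mask
excluding the other language ROI (whole-mask negatives are configurable);
evaluating within the left hemisphere matches the ground truth's hemisphere
restriction.

## The default experiment

12 subjects, 24³ grid, 6 networks × 4 parcels, snr 5, two 160-frame rest
runs and one 100-frame task run per subject, two injected spike frames per
run. The classifier is trained on the cohort's parcel-seed examples (70/30
split) and then applied per voxel to the same subjects at two data lengths
(all kept frames vs the first 100). Phantom subjects are exchangeable draws
from one generator, so a separate normal-training cohort would only relabel
seeds; the original study trained on separate normal cohorts. Subject maps
are averaged first; one group-level ROC is computed per (ROI, method). The
experiment runs in about 4 minutes on one CPU; problem sizes were chosen so
the whole suite plus the acceptance script stay desk-scale.

What passing shows — and does not. The phantom realizes exactly the
correlation structure the classifier assumes: success demonstrates that the
implementation recovers planted topography through the full chain (including
censoring, pooled runs, and limited data), not that the method attains any
particular accuracy on clinical data. Real acquisitions add registration
error, physiological noise, spatially varying SNR, and tumor mass effects,
none of which are simulated.

## Known limitations

- No slice-timing, odd-even intensity, or rigid-body motion correction, and
  no atlas registration: phantom modalities are generated in register.
- Motion is modeled as intensity spikes only.
- The numpy CNN targets desk-scale volumes; it is single-threaded BLAS-bound
  and does not scale to the full 2,795-subject training regime.
- Bootstrap inference treats voxels as exchangeable; spatial autocorrelation
  (induced by smoothing) makes the CIs optimistic, as with any voxel-level
  case bootstrap.
- Laterality indices, surface rendering, and tractography are out of scope.
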