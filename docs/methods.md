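# Methods

This document records what each stage of the package computes, the numerical
choices that are not visible from the API, what the synthetic generator does
and does not emulate, and known limitations.

## RDM conventions

An RDM over `n` conditions is stored either as an `n × n` symmetric matrix
with zero diagonal or as a length `n(n−1)/2` vector in **lower-triangle
row-major order over i > j**: `(1,0), (2,0), (2,1), (3,0), …`. All vector
forms in the package (neural, model, searchlight) use this order;
`strsa.rdm.vectorize` / `unvectorize` convert and validate. Note that
`scipy.spatial.distance.pdist` uses the upper-triangle order, which is a
different permutation — convert through `squareform` + `vectorize` rather
than comparing raw vectors.

Model RDMs are normalized to mean 0, **population** standard deviation 1
(`ddof=0`; the choice only rescales regression betas and leaves correlations
unchanged). VIFs come from the inverse of the model correlation matrix
(`vif_scores`), equivalent to `1/(1−R²)` of each model regressed on the
others.

## Time-resolved decoding

Epochs are binned with `bin_samples` (default: width 1 at the input rate;
wider bins average samples and are assigned the center-sample time; stride 1
gives sliding bins). Per time bin and condition pair, a linear SVM (C = 1)
is trained and tested with leave-one-chunk-out cross-validation over 6
chunks; trials within a fold are balanced by subsampling, and features are
z-scored using training-fold statistics only. Accuracies (chance 0.5) fill
the neural RDM.

The SVM is a liblinear-style dual coordinate-descent solver for the hinge
loss, compiled with numba, with the bias handled as a regularized augmented
feature and a deterministic cyclic update order. A standard library SVM at
this problem size costs milliseconds per fit; the recovery benchmarks need
on the order of a million fits, which made an in-package solver necessary.
The test suite pins it against `sklearn.svm.LinearSVC` (weights) and
`sklearn.svm.SVC` (fold-level accuracies through the full decoding path).

## RSA

* **Standard RSA**: per subject and bin, Spearman correlation between the
  neural RDM vector and a model vector, Fisher z-transformed immediately;
  all aggregation happens on the z scale. Rank-degenerate bins contribute
  z = 0 with a warning.
* **Multiple-regression RSA**: per subject and bin, OLS of the raw neural
  vector on `[1, model vectors]`. The design must be full rank; reduce by
  VIF first.
* **Noise ceiling**: per bin, leave-one-out lower bound (each subject's RDM
  vs the mean of the others) and upper bound (vs the grand mean), averaged
  on the z scale, reported in r units. The lower bound is ≤ the upper bound
  at every bin by construction (the grand mean contains the left-out
  subject).

## Cluster permutation statistics

One-sample cluster tests use sign flips of subject time courses, a
cluster-forming threshold from the t distribution (`alpha_form`, df =
number of exchangeability units − 1), cluster mass = summed t, and the
max-cluster-mass null. When `2^k ≤ n_perm` for `k` exchangeability units the
full sign-flip set is enumerated and p-values are exact (`hits / 2^k`);
otherwise Monte-Carlo draws use the add-one estimator
`(hits + 1) / (n_draws + 1)`. The `groups` argument defines exchangeability
blocks that flip together — bootstrap replicates that duplicate a subject
must share that subject's sign, and the threshold df shrinks accordingly.

Spatiotemporal (fusion) clusters use the Kronecker product of the voxel
adjacency graph (face/edge/corner neighbors on the output grid) with
temporal contiguity, and `scipy.sparse.csgraph.connected_components`.

Onset = first bin of the first significant positive cluster inside the test
window. Bootstrap onset CIs resample subjects with replacement, rerun the
cluster test with `groups` set to the resample pattern, and take the
2.5/97.5 percentiles over replicates that produced a significant cluster;
the fraction that produced none is reported as `missing_fraction`.

## Model RDMs from images

The pluggable feature-extractor interface ships a GIST-style descriptor:
one-sided log-Gabor filters, 4 scales × 8 orientations, energy pooled on a
4 × 4 grid (512 dimensions). Binary attribute RDMs (e.g. 1-vs-2 people) and
generic feature RDMs (Euclidean or correlation distance, exemplar averaging
either of features or of pairwise distances) complete the set.
`reduce_by_vif` drops the worst member (ties and infinities first) until all
VIFs pass the threshold.

## Synthetic generator

The generator emulates the structure of the study the package reimplements:
a delayed match-to-sample design (every stimulus twice as S1; action /
location / actor probes balanced within ±1 trial; location probes draw S2
from the same action; ISIs from the study's set), and EEG/fMRI data with
planted representational geometry.

* **Geometry embedding**: a target RDM vector is embedded as latent
  condition patterns whose distances reproduce the target's rank order
  *exactly* — classical MDS with an additive constant for the Euclidean
  (EEG) case, a shrunk unit-diagonal Gram matrix for the correlation-metric
  (fMRI searchlight) case.
* **EEG**: per subject, a seeded orthonormal projection maps latent patterns
  to channels; the planted window is gated by a raised-cosine envelope with
  10 ms ramps; i.i.d. Gaussian sensor noise on top. Subject heterogeneity:
  per-subject lognormal amplitude gains (`subject_amp_sd`) and optional
  geometry jitter.
* **fMRI**: latent patterns (correlation-metric embedding, zero-mean
  projections so searchlight 1−Spearman is preserved) are written into a
  voxel ROI with per-voxel amplitude variation; Gaussian noise elsewhere.
* **Correlated model RDMs**: `make_correlated_model_rdms` reproduces a
  target Pearson correlation matrix between model vectors *exactly* (whiten
  a seeded Gaussian basis, recolor by the Cholesky factor). With
  `decorrelate_transforms=True` the basis is additionally shaped by a damped
  joint iteration so that (a) low-order polynomial transforms and pairwise
  products of each model, beyond their own linear part, have strongly
  suppressed chance correlations with the other models, and (b) Spearman
  correlations approach the target too. Decoding maps planted distances
  through a compressive nonlinearity, so chance transform alignments become
  subject-shared spurious signal; suppressing them makes latency recovery a
  test of the pipeline rather than of one basis draw. Residuals are an
  order of magnitude below chance level, not zero.

What the generator does **not** emulate: realistic EEG spectra or
autocorrelated noise, volume conduction, eye/muscle artifacts, hemodynamic
convolution or physiological fMRI noise, behavioral response generation, or
any preprocessing stage (the package consumes epoched/beta-level data by
design).

## Frozen benchmark protocols

`strsa.protocols` freezes two end-to-end recovery benchmarks that the test
suite and the analysis scripts share. Scales are reduced relative to the
emulated study (which used 27 conditions, 24 EEG / 20 fMRI subjects, 63
channels, 500 Hz, 10 000 permutations) so each benchmark runs in minutes on
one CPU:

* **Latency-order recovery**: 16 conditions, 18 exemplars × 2 repetitions,
  8 subjects, 16 channels, 100 Hz, five models with the published
  correlation structure planted at 80/120/180/200/280 ms (60 ms windows),
  graded amplitudes 2.2–2.8 (later models onset inside earlier models'
  windows, where the accuracy sigmoid has spent part of its sensitive
  range), 200 bootstrap replicates. A replicate passes when the five 95%
  onset CIs are non-overlapping and in planted order.
* **Fusion recovery**: the same design with one planted model and four
  foils; 20³ voxels at 2 mm with a 10³ ROI, 8 fMRI subjects with geometry
  jitter 0.35, searchlight radius 6 mm, output grid 4 mm, 300 permutations.
  Scored by Jaccard overlap between the biggest significant spatiotemporal
  cluster and the ground truth (ROI dilated by the searchlight sphere ×
  planted window bins), plus planted-vs-foil identification at FDR < .05.

## Limitations

* **Onset CIs are fragile at 8 subjects.** With 200 bootstrap resamples of
  8 subjects, the 2.5th percentile of the onset distribution is set by a
  handful of replicates; a single resample in which a spurious pre-onset
  cluster reaches significance drags the CI lower bound far below the
  planted onset. With two planted onsets only 20 ms apart (gist/people at a
  10 ms bin width), the latency benchmark therefore orders all five CIs in
  most but not all replicates. This is a property of small-sample bootstrap
  onset estimation, not of the implementation; the emulated study used
  three times as many subjects.
* The cluster-forming threshold uses a t quantile although decoding
  accuracies are bounded; calibration is verified empirically (the
  family-wise error test in the acceptance suite), not assumed.
* Exact Pearson / suppressed-transform model bases exist only up to finite-n
  limits; structural correlations between transforms of correlated models
  are preserved by design and bound what decorrelation can achieve.
* The GIST-style descriptor is a stand-in for the original pretrained-CNN
  features (out of scope); it is deterministic and tested, but not a
  numerical reproduction of any published descriptor.
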