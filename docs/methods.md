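# Methods

This note records the model, the numerical choices, and the limits of what
the synthetic experiments can show.  It is written for a reader who wants to
know *why* the package behaves as it does, not just what it computes.

## The statistical model

A subject's preprocessed resting-state series is treated as a noisy linear
mixture of K spatial sources (network maps) with smooth time courses.  The
method asks, per component and per patient: *is this patient's expression of
network i inside the network's own territory compatible with the
healthy-control distribution?*  The test statistic is the cosine similarity
between the mask-restricted template and subject maps; it deliberately mixes
topography and strength, because a network can be abnormal by displacement,
by shrinkage, or by weakening, and all three reduce CS.

The null distribution is empirical (control CS values), and the decision
rule is a subsampled exceedance test: draw a subsample of controls without
replacement, ask whether the patient lies more than 3 subsample-SDs from the
subsample mean (two-sided, strict inequality), and call the component
altered when this holds in at least `1 − α` (95%) of 50 000 subsamples.
The subsampling exists because a fraction of the controls also built the
template and are therefore biased toward high CS; drawing ~65% of the
cohort per iteration dilutes that bias.  The coupling of the 3-SD rule with
the 95%-of-iterations requirement uses both printed constants of the
decision rule without inventing a third; the exceedance is two-sided because
components *more* template-like than every control are also anomalies.

## Template estimation

* Two-stage PCA: subjects are reduced in time (default: K + 5 components),
  concatenated, and reduced again; the group matrix is whitened with
  voxel-mean-free rows and exact identity covariance.
* Infomax uses the logistic nonlinearity and full-batch natural-gradient
  ascent.  Learning rate: `0.005 / ln(K)`, annealed by ×0.98 whenever the
  update direction turns by more than 60°; convergence is declared on the
  learning-rate-independent gradient magnitude `‖GW‖/‖W‖ < 1e-6` (a
  step-size-based criterion can "converge" spuriously after aggressive
  annealing — this was observed and is why the gradient magnitude is used).
* After convergence the unmixing matrix is symmetrically decorrelated.
  Sources of one run are then *exactly* uncorrelated, which gives the
  stability index clean identities: duplicate runs produce Iq = 1 to
  machine precision, and high-SNR phantoms give Iq ≈ 1.  The projection
  onto orthonormal unmixing costs a bias of order ρ²/8 in map recovery when
  true maps are correlated at ρ; phantom maps are constructed with
  |ρ| < 0.3 (typically < 0.1), so recovery stays above 0.99.
* Map orientation: positive skewness (activation is positive), then
  Z-scoring over mask voxels.  ICASSO similarity is |Pearson r|; clustering
  is average-linkage agglomerative cut at K clusters; the centrotype
  maximizes summed intra-cluster similarity with ties broken by lowest run
  index.

## Guided back-reconstruction

The subject objective `F(w) = λ·J(y) + (1−λ)·ρ(y, t)²` is maximized on the
unit sphere of the subject's whitened spatial basis by gradient ascent with
backtracking line search and doubling restarts; the iterate starts at the
normalized projection of the template onto the basis, which is also the
exact maximizer of the λ→0 limit.  Defaults: λ = 0.5, log-cosh contrast,
tol 1e-6 on the (sign-invariant) step norm, 1000 iterations, no
orthogonalization across components (subject components may overlap).  The
λ→0 solution agrees with an independent dual-regression estimate to map
correlation > 0.99 on well-conditioned phantoms; the phantom generator
equalizes component energies (unit RMS per component map) precisely so that
the eigenvalue weighting that separates projection from dual regression is
negligible.

A negative final correspondence triggers a sign flip (logged).  Negentropy
is reported as `(E[G(y)] − E[G(ν)])²` with the Gaussian baseline integrated
numerically at import; log-cosh is evaluated in its overflow-safe form
`|x| + log1p(exp(−2|x|)) − log 2`.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `z_thresh` | 1.0 | template Z threshold for component masks (tolerant, absorbs lesion-induced spatial shifts) |
| `min_cluster_voxels` | 200 (full scale); 10 on 12³ phantoms | minimum connected cluster extent, face connectivity |
| `n_perm` | 50 000 | permutation iterations; flagged-fraction Monte-Carlo error < 0.01 |
| `subsample` | 200 (→ ⌈0.65·n⌉ when fewer controls) | controls drawn per iteration, without replacement |
| `sd_mult`, `alpha` | 3.0, 0.05 | exceedance threshold and iteration-fraction level |
| `lambda_weight` | 0.5 | negentropy vs correspondence trade-off |
| `head_radius_mm` | 50 | rotation-to-arc-length conversion for FD |
| `n_boot` | 1000 | case-resampling bootstrap for coefficient CVs |

## The phantom: what it emulates, what it does not

The generator plants K maps (2–5 Gaussian nodes each, FWHM 2.5 voxels,
pairwise |r| < 0.3, unit RMS) inside an ellipsoidal brain on a 12³–14³
grid, with an inferior "cerebellum" cap for exclusion-mask logic.  Time
courses are band-limited Gaussian processes, Gram–Schmidt-orthogonalized
for ICA identifiability at small T.  Lesions multiply the spatial weight of
selected nodes (0 = deleted); by default the *proximal* node (node 0, where
the tumour-core ball is placed) survives and distal nodes are attenuated —
the disconnection phenomenology in which cortex over the lesion keeps its
synchronization while remote nodes lose it.  Oedema is one binary dilation
of the core.  Behaviour scores follow a planted sparse non-negative linear
model on the standardized network distances.  Voxel noise is i.i.d.
Gaussian (`noise_sd` 0.6 against unit-RMS signal).

Not emulated: haemodynamics, physiological/motion artifacts, spatial noise
correlation, realistic tumour growth or mass effects, registration error.
Consequently the phantom's control CS distributions are far tighter than
clinical ones (σ ~ 1e-4), planted deletions sit thousands of SDs from the
null, and passing detection tests demonstrates the *logic* and calibration
of the decision rule, not clinical effect sizes.

## Study sizes used by the tests and acceptance script

Desk-scale sizes keep the full suite within minutes on one CPU: template
cohorts of 8–20 controls, K = 3–5, T = 100–120, 12³–14³ grids, 2 000–50 000
permutation iterations depending on the precision the check needs, 8–20
replicate cohorts for calibration/power experiments, and n = 22, p = 45
(with 200 replicates, 200 bootstrap resamples) for the regression null
calibration.  The null-calibration experiment keeps the cohort proportions
of the intended use case: just under half of the distribution controls also
build the template, and pseudo-patients are held out of both.

## Numerical and degenerate-input conventions

* Grids never resample; any shape/affine mismatch is an error.
* Vectorization is Fortran raster order (first axis fastest), masks are
  strictly binary, statistics run over mask voxels only.
* Zero-variance voxels, zero-norm CS vectors, σ = 0 control distributions,
  and empty component masks are all explicit unusable/error states, never
  silent NaNs.
* Sample SDs use the n−1 denominator throughout.
* Cluster extent uses "at least" semantics (a cluster exactly at the
  minimum survives); the exclusion mask is applied *after* cluster
  filtering.
* CS is computed on the template-derived mask only.  An automated report of
  the fraction of subject suprathreshold voxels outside that mask
  (`outside_mask_fraction`) replaces the manual displaced-component check.
* Spearman p-values are exact (full enumeration of pairings) for n ≤ 10,
  asymptotic above; the rank-sum test is exact for small tie-free samples.
* All randomness flows from explicit seeds through
  `numpy.random.default_rng`; permutation substreams derive from one seed,
  and two runs of the same configuration produce bit-identical manifests.

## Design choices where the design was open

* **CV of constrained estimates**: no closed-form covariance exists for
  sign-constrained least squares, so coefficient CVs come from a
  case-resampling bootstrap over patients; a support coefficient that is
  zero in more than half of the resamples gets CV = ∞ and blocks
  acceptance.  This makes the acceptance rule aggressive against unstable
  supports: under planted signal with moderate noise, spurious small
  support coefficients frequently fail the CV gate, so "accepted" is a
  high-precision, low-recall label.  Jackknife or asymptotic alternatives
  were not pursued.
* **Intercept**: always included and unconstrained (domain scores are not
  centred); demographics enter as +/− column pairs so one non-negative
  solver expresses free signs.
* **Atlas combination**: with several atlases the per-network overlap is
  the maximum across atlases; ties at the argmax break lexicographically.
* **Oedema**: recovered as the set difference of the tumour+oedema and
  tumour-core masks.

## Known limitations

* The flagged-fraction of the subsampled exceedance test saturates sharply:
  once a patient sits ≳ 4.5 control SDs out, essentially every subsample
  exceeds the 3-SD bound.  Dose-response experiments on attenuation grids
  therefore see a step-like flagged-fraction (graded information lives in
  `ΔCSσ`, which never saturates).
* One-unit back-reconstruction with λ = 0.5 inherits the template's spatial
  prior; a component truly absent in a subject still returns a map (with
  low correspondence), by design.
* The behaviour module reports in-sample fit only; no cross-validated
  prediction claims are made, mirroring the intended use.
* Network labelling of low-overlap components is only flagged
  (`low_confidence`), the literature-based resolution being out of scope.
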