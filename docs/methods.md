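# Methods

This note documents the models, estimators and numerical choices behind
`dlradiomics`, and what its synthetic-data tests do and do not demonstrate.

## Problem and endpoint

The package predicts, from the pre-treatment planning CT alone, whether a
head-and-neck gross tumor volume (primary GTVp or nodal GTVn) will belong to
the fast-regressing half of a cohort during early radiotherapy. The endpoint
per patient is the regression rate

    rate = 100 · (V_init − V_boost) / V_init / treatment_days   [% per day],

where V_init and V_boost are the contoured GTV volumes on the initial and
boost planning CTs and treatment_days counts fractions delivered before the
boost scan. Binary labels come from a strict median split (rate > median →
regression class; a rate exactly at the threshold goes to nonregression, a
deterministic choice the median split itself leaves open). Explicit
thresholds are accepted for sweep analyses; typical clinical sweep lists are
0.46–3.2 %/day (GTVp) and 1.4–4.1 %/day (GTVn).

## Imaging chain

All preprocessing is deterministic; identical inputs give bit-identical
crops.

* **Resampling.** Nearest-neighbor to 1×1×1 mm³. The output grid is
  anchored at the input origin and covers the input physical extent
  (`n_out = round(n·s/t)` voxels per axis); output voxel centers at
  `(j+0.5)·t` are filled from the input cell containing that position.
  Toolkits differ in these conventions, so they are fixed here explicitly
  and the resampler is a few lines of index arithmetic rather than a
  wrapped library call.
* **Slice choice.** The axial slice with the maximum foreground pixel count;
  ties go to the lowest index. The choice depends on the mask only.
* **Cropping.** 100×100 px at 1 mm/px, centered on the in-plane center of
  gravity of the slice mask (the crop is 2D, so the COG is computed in 2D).
  COG coordinates round to the nearest voxel with half-way ties toward the
  lower index. If the initial patch holds more than one 8-connected
  foreground component, the patch is re-centered once on the centroid of the
  largest in-patch component. Out-of-volume regions are padded with the
  background fill.
* **Background and windowing.** Non-GTV pixels are set to the global minimum
  of the resampled volume (per-volume rather than per-crop, so the fill is
  stable across crops of one patient). Intensities are windowed at level
  50 HU, width 350 HU: [−125, 225] HU maps linearly onto [0, 1] with
  clipping. The [0, 1] range is the package contract; backbone adapters own
  any further channel normalization.
* **Model input.** The windowed patch is bilinearly resized to the
  backbone's input edge (a per-backbone configuration value, not a property
  of the method) and replicated into three identical channels.

## Deep features

Backbones sit behind a registry: a backbone is any callable mapping an
(H, W, 3) image in [0, 1] to a fixed-length vector. The sixteen
ImageNet-pretrained CNN names are accepted as adapter identities (three of
them — SqueezeNet, DarkNet19, DarkNet53 — are declared as tapped at the
layer before the final softmax since they have no terminal fully connected
layer); their weights are never distributed with the package. The reference
backend used throughout the tests is a **deterministic stub**: tanh of a
seeded Gaussian random projection of the flattened image (projection and
bias depend only on the seed and image size). The stub is pure, injective
with high probability, and sensitive to intensity scale — enough structure
to exercise every downstream stage without pretrained weights.

Features are z-scored per column over the full analysis cohort before any
resampling, using the n−1 sample SD. Computing the statistics on the full
cohort matches the internal-validation workflow this design reproduces and
carries the same optimistic bias; results should be read as internal
validation, not external performance. Constant columns map to zeros with a
warning rather than failing.

The handcrafted catalogue (107 features: 14 shape, 18 first-order, 24 GLCM,
16 GLRLM, 14 GLDM, 16 GLSZM, 5 NGTDM) is computed by a built-in IBSI-style
backend: fixed 25 HU bin width anchored at the ROI minimum, 1 mm isotropic
resampling, GLCM/GLRLM aggregated over the 13 unique 3D directions with
feature-level averaging, 26-connected zones and dependencies, and a GLDM
dependence index that counts the center voxel (so it is always ≥ 1). Shape
features mesh the mask with marching cubes after slight Gaussian smoothing
(σ = 0.8 voxels, applied only for ROIs ≥ 64 voxels), which suppresses the
staircase bias that otherwise deflates sphericity by ~8% on a 10 mm sphere.
External IBSI extractors can be registered under the same backend contract.

## Feature selection

* **Robustness.** Each feature's subjects × raters table over alternative
  segmentations is scored with the two-way mixed-effects,
  absolute-agreement, single-measurement ICC (McGraw–Wong "Case 3A"
  convention), computed from the two-way ANOVA mean squares:
  (MSR − MSE) / (MSR + (k−1)·MSE + (k/n)(MSC − MSE)). Features are kept iff
  ICC strictly exceeds 0.7; undefined ICCs (zero total variance) drop the
  feature.
* **Redundancy.** Offending pairs are those with |Spearman ρ| strictly
  above 0.8 (absolute value: anti-correlated duplicates are equally
  redundant). The most-correlated offending pair is resolved first; the
  member with the higher mean |ρ| against all other retained features is
  dropped, ties going to the higher column index; correlations among the
  survivors are then re-examined. The loop removes one feature per step, so
  it terminates, and the post-condition (no retained pair above threshold)
  is verified by exhaustive scan in the tests.
* **Rankers.** Five filter methods produce descending score orders with
  ties broken by original feature index:
  * CHSQ — chi-square independence statistic of class vs the feature
    discretized into 10 quantile bins; score −log₁₀ p.
  * WLCX — two-sample rank-sum (normal approximation); score −log₁₀ p.
  * NCA — diagonal neighborhood component analysis: weights w maximize the
    expected leave-one-out stochastic-neighbor accuracy with distance
    Σ w_r²|x_ir − x_jr| and ridge penalty λ = 1/n, L-BFGS from an all-ones
    start; scores are w².
  * ReliefF — expected margin over k = 10 nearest hits/misses for every
    instance, Manhattan distance, miss terms weighted by class priors.
  * infFS — path-integral centrality: row sums of S = (I − rA)⁻¹ − I with
    adjacency a_ij = α·max(s_i, s_j) + (1−α)(1 − |ρ_S(i,j)|), α = 0.5 and
    r = 0.9/spectral-radius(A). The per-feature relevance prior s_i is the
    Fisher-type standardized class separation |μ₁−μ₀|/√(sd₁²+sd₀²) rescaled
    to [0, 1], as in the supervised variant of the algorithm: a class-blind
    spread prior carries no information on z-scored cohorts, where every
    feature has unit total variance.

Clinical factors (ordinal-coded, one column per factor, with a dedicated
"not applicable" HPV level) skip the ICC and redundancy steps and go
straight to the rankers — with ~a dozen factors there is no dimensionality
problem to mitigate.

## Classifiers

Five scikit-learn estimators behind a uniform contract: RF (100 trees,
√p features per split), SVM (RBF, C = 1, γ = 1/(p·var)), KNN (k = 5,
Euclidean), Gaussian NB, LDA (lsqr solver with automatic shrinkage). The
published experiment's exact hyperparameters are not public, so these
defaults are ordinary textbook settings, all overridable per algorithm.
Scores are class-1 probabilities where available, decision-function values
otherwise — AUC is rank-based, so the distinction is immaterial for the
estimator; the sensitivity/specificity operating point is the classifier's
default threshold (0.5 on probabilities, 0 on decision values), a choice
the evaluation design leaves open.

## 0.632+ bootstrap evaluation

Per feature subset the apparent AUC(X, X) is computed once (it does not
depend on the replicate). Each of B bootstrap replicates trains on an
in-bag multiset of size N drawn uniformly with replacement and tests on the
out-of-bag complement:

* AUC′ = max{0.5, AUC_oob};
* R(b) = 1 if AUC_oob ≤ 0.5; (AUC_app − AUC_oob)/(AUC_app − 0.5) if
  AUC_app > AUC_oob > 0.5; else 0;
* a(b) = 0.632/(1 − 0.368·R(b)) ∈ [0.632, 1];
* replicate value (1 − a(b))·AUC_app + a(b)·AUC′; the estimate is the mean
  over replicates.

Replicates whose in-bag or out-of-bag set is single-class (or whose in-bag
is too degenerate to fit) are skipped and counted; the effective B is
reported. Sensitivity and specificity blend out-of-bag and apparent values
with the same a(b) weights. AUC itself is the Mann–Whitney statistic with
midrank tie handling.

Forward selection is greedy with strict-improvement acceptance (no epsilon;
ties do not extend the subset) and evaluates all candidate subsets on the
same bootstrap splits — common random numbers remove between-candidate
bootstrap noise and make the procedure deterministic given the master seed.

The 5×5 grid runs forward selection per (ranker top-10, classifier) cell
and summarizes with the mean and SD over the 25 AUCs; failed cells are
excluded from the mean with a warning.

The corrected resampled paired t-test uses
t = mean(d)/√((1/K + n_test/n_train)·s_d²), df = K−1, one-tailed in the
direction "first pipeline better". Because bootstrap train/test sizes vary
per replicate, the correction uses the average sizes over the repetitions
(for cohorts of 96 and 79 those averages are 61/35 and 50/29). Zero
variance with nonzero mean is reported as a degenerate result with p → 0
(or 1) rather than an exception.

The threshold sweep relabels the cohort at each rate threshold, balances
classes by down-sampling the majority without replacement to the minority
size, and averages the 0.632+ AUC over 100 draws (configurable downward;
balanced thresholds short-circuit to a single evaluation). Selected
features are additionally screened against tumor volume with Spearman ρ,
since volume-correlated features add no information beyond the trivially
available volume.

## Synthetic data

* **Phantoms** — ellipsoidal masks on a constant −1000 HU background with
  smoothed Gaussian texture inside (mean 60 HU, SD 40 HU, smoothing scale
  1.5 mm): realistic enough in intensity statistics to drive windowing,
  texture matrices and the stub backbone, with no claim of anatomical
  realism.
* **Perturbed segmentations** — the signed distance field of a mask plus
  smoothed surface noise, re-thresholded; nine raters by default. Overlap
  (Dice) decreases monotonically with the noise magnitude, giving
  ground-truth-controlled ICC behavior.
* **Feature cohorts** — informative features are unit-variance Gaussians
  with between-class mean shift δ (so the single-feature oracle AUC is
  Φ(δ/√2)); redundant features are parent + scaled noise with the noise
  scale found by bisection on the empirical Spearman correlation (no closed
  form survives the rank transform); the rest is independent noise. Labels
  are assigned at the configured class balance and shuffled.

Because the cohorts are Gaussian with independent noise features, passing
tests demonstrate correct machinery and calibration — not that deep
features of real tumors carry this much signal. Cohort-level AUCs from real
data cannot be reproduced here (the patient data is private); the tests
instead verify parameter recovery (estimate ≈ Φ(δ/√2) within ±0.05 at
n = 200), null calibration (mean estimate in [0.45, 0.55] at δ = 0, t-test
type-I rate ≤ nominal), and exact agreement with independent oracles (ANOVA
mean squares for ICC, exhaustive pair enumeration for AUC, truncated power
series for infFS).

## Problem sizes and determinism

The test suite and examples run at desk scale: B = 15–200 bootstrap
replicates, cohorts of 50–200 samples, 8–51 features, and 20-seed
Monte-Carlo loops — sizes chosen so the full suite completes in a few
minutes on one CPU while keeping Monte-Carlo error well inside the asserted
tolerances. Results bundles label runs with B < 1000 or U < 100 as
"reduced". All randomness flows from a master seed through named
substreams (`numpy.random.SeedSequence`); a rerun with the same config and
seed reproduces the results JSON byte for byte at a fixed thread count.

## Known limitations

* The stub backbone is a random projection: it validates plumbing and
  statistics, not transfer-learning performance; pretrained adapters must
  be registered by the user.
* z-scoring before resampling leaks cohort statistics into the bootstrap —
  kept deliberately to mirror the workflow this package reproduces, and
  flagged above.
* The built-in handcrafted backend follows IBSI definitions but is not
  benchmarked against a reference extractor value-for-value; counts,
  families and limit cases (sphere sphericity, uniform-ROI degeneracies)
  are tested.
* Handcrafted texture features on very large ROIs (≫10⁵ voxels) are
  computed with dense direction scans and will be slow.
* No registration between initial and boost CT, no dose modeling, no
  DICOM-RT parsing; masks arrive as NIfTI.
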