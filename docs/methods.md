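# Methods

## Problem and approach

Gastrointestinal stromal tumors (GIST) grow beneath the gastric mucosa, so
surface inspection cannot delineate them.  Near-infrared hyperspectral
imaging (NIR-HSI) records a full reflectance spectrum (1000–2350 nm, 6.3 nm
steps, 215 bands) at every pixel of a resected specimen; because NIR light
penetrates millimetres of tissue, the spectrum of a pixel over a covered
lesion carries a depth-attenuated tumor contribution.  The package
classifies every pixel as *gist* or *normal* with a kernel SVM trained on
box-annotated pixels, and evaluates the result at the specimen level with
leave-one-out cross-validation against a pathologist-drawn boundary line.

The processing chain per specimen:

1. **Reflectance calibration** — R = (raw − dark)/(white − dark) against
   white-standard and shutter-closed reference frames.  Positions where
   white ≤ dark are flagged unusable instead of propagating NaNs;
   reflectance above 1.5 is clipped and counted.
2. **Absorbance** — A = −log10(max(R, floor)), floor 1e−4.  Absorbance is
   used because stacked tissue layers contribute approximately additively
   there (Beer–Lambert); shadow pixels that would hit the floor are masked
   anyway.
3. **Band selection** — wavelengths above 1600 nm are dropped (96 of 215
   bands remain): detector sensitivity is low and water absorption strong
   above the cut.
4. **Highlight/shadow masking** — pixels whose reflectance at the band
   nearest 1300 nm is above 0.70 (specular highlight) or below 0.10
   (shadow) are removed.  The thresholds themselves retain (the rule is
   "over"/"below"); this matters only for measure-zero boundary cases.
5. **SNV** — each spectrum is standardized, z = (x − mean x)/std x, which
   removes per-pixel multiplicative scatter gain and additive baseline
   offset exactly.  std is the population standard deviation (SNV
   convention; the sample variant differs by a constant per-spectrum factor
   and is available via `ddof=1`).  SNV runs after the band cut, so the
   statistics are computed over the analysis bands only.
6. **Classification** — RBF-kernel SVM, C = 1, bandwidth σ² set to the
   median of pairwise squared distances among the training spectra.
7. **Evaluation** — per-pixel confusion counts over the evaluation domain
   (valid ∧ outside the boundary-exclusion corridor ∧ tissue), pooled by
   summing counts across specimens (count-weighted, never macro-averaged):

       Specificity [%] = TN/(FP+TN)·100
       Sensitivity [%] = TP/(TP+FN)·100
       Accuracy    [%] = (TP+TN)/(TP+TN+FP+FN)·100

   Specimens without a normal region leave FPR/specificity undefined; the
   report renders those cells as "–".  Tables round to one decimal, half
   away from zero.

## The SVM and its solver

The formulation is the multiclass hinge objective
minimize ½Σₙ‖wₙ‖² + (C/m)Σᵢξᵢ subject to
⟨xᵢ,w_{yᵢ}⟩ − ⟨xᵢ,wₙ⟩ ≥ (1 − δ_{yᵢ,n}) − ξᵢ, decision argmaxₙ⟨x,wₙ⟩.
With k = 2 classes only the difference w = w₁ − w₂ is constrained and the
optimum has w₁ = −w₂ = w/2, so the problem is exactly the *bias-free*
soft-margin binary SVM with penalty C′ and signs sᵢ = ±1.  Its dual is a
box-constrained concave QP with **no equality constraint** (no intercept),
so the decomposition solver takes exact Newton steps on one dual coordinate
at a time, always the maximal KKT violator, until the largest violation on
kernel scores drops below 1e−3 (cap 10⁷ updates).  This is equivalent to
SMO-style pairwise working sets on this dual but simpler, since pairs are
only needed to preserve an equality constraint that does not exist here.
A brute-force QP solution (L-BFGS-B on the dual) serves as an independent
oracle in the tests; objectives agree to 1e−6 relative on random small
instances and predictions agree exactly.

**C convention.** Two readings of "C = 1" are implemented:

* `c_mode="per-sample"` applies the objective literally: the binary
  reduction gets C′ = 2C/m.  With per-pixel training sets (m ≈ 2000) this
  makes C′ ≈ 10⁻³; every dual variable then sits at its bound and the
  decision function degenerates to a difference of class kernel means.
  That estimator is extremely sensitive to any aggregate asymmetry between
  the two training clouds: in a no-signal experiment all leave-one-out
  folds (which share 10/11 of their data) collapse to the *same* class and
  pooled accuracy lands on a class share rather than at chance.
* `c_mode="absolute"` uses C′ = C, the convention of decomposition-method
  SVM libraries — i.e. what actually runs when such a tool is invoked with
  C = 1.  This fits a genuine maximum-margin boundary, behaves at chance
  (≈50%) under the no-signal control, and is the pipeline default.

`svm_core.train` keeps the literal per-sample default so the objective can
be studied as written; the pipeline overrides it.

**Training-set balance.** The pipeline caps training data at 1000 pixels
per class per fold (seeded stratified subsample).  Besides bounding the
kernel matrix, the cap equalizes class counts: the bias-free kernel
expansion sums one term per training pixel, so class imbalance (tumor-only
specimens contribute tumor boxes only) shifts every decision value toward
the majority class — precisely in the regime where the spectra carry
little information.

**Determinism.** The solver has no random path; training rows are
canonicalized (sorted by specimen, then pixel) before optimization, so
results do not depend on fold-assembly order.  Ties in argmax prediction go
to the lexicographically first class code ("gist").

## Ground truth, exclusion corridor, geometry conventions

Coordinates are 0-based (row, col) with the band axis last; pixel centers
sit at integer coordinates with no half-pixel offset.  Polygon membership
uses the even-odd rule at pixel centers (pixels inside the boundary are
tumor, outside-but-on-tissue normal, the rest background).  Training boxes
are half-open [r0,r1)×[c0,c1).

Because the boundary line is freehand, its thickness t is doubled on both
sides for accuracy accounting: a pixel is excluded iff its center lies
within Euclidean distance 2t of the boundary polyline.  The distance-based
rule (rather than a morphological dilation with a structuring element) was
chosen because the uncertainty of a freehand line is isotropic around the
drawn curve; with t = 0 only pixels on the line are excluded.

## Synthetic specimens

No public NIR-HSI dataset of submucosal tumors exists, so the pipeline is
exercised end to end on simulated cohorts.  Per specimen:

* **Geometry** — 64×64 pixels; tissue extent with a 2 px stage margin; the
  lesion is a rotated ellipse (semi-axes 16–22 px) whose margin is the
  boundary polyline (t = 2 px); tumor-only specimens (last 2 of 12) have a
  boundary containing the whole extent.  Two 8×8 training boxes per
  available class are auto-placed clear of the exclusion corridor.
* **Spectra** — layered Beer–Lambert mixing.  Each pixel is a mucosa layer
  (depth 0.4–2.5 mm over the lesion, the measured range for covered
  lesions) on a deep layer (2–4 mm).  Inside the lesion the deep layer uses
  the tumor absorptivity curve, outside the normal curve:
  A = d_muc·ε_muc + d_deep·ε_gist (tumor) vs (d_muc+d_deep)·ε_muc (normal).
  Both classes share the same per-specimen thickness fields, so overall
  optical depth carries no class label information — this makes the
  zero-separation null exact by construction.
* **Endmembers** — smooth Gaussian-band absorptivity curves sharing the
  1450 nm water band; the tumor curve is the normal curve times a smooth
  multiplicative perturbation sized by bisection so the post-SNV L2
  distance over the analysis bands equals the requested separation δ
  (default 1.2 over 96 bands, i.e. deliberately *similar* spectra —
  SNV-normalized spectra have norm ≈ √96 ≈ 9.8, so δ = 1.2 is a ~12%
  relative difference).  δ = 0 yields identical curves.
* **Artifacts and noise** — per-pixel gain U(0.85, 1.15) and offset
  U(−0.05, 0.05) applied in absorbance (exactly the artifacts SNV removes),
  Gaussian absorbance noise sd 0.015, and 1% each of planted specular
  highlight (R ≈ 0.75–0.95) and shadow (R ≈ 0.01–0.08) pixels.
  The defaults were fixed by a matched-filter signal calculation — at
  δ = 1.2 the per-band class separation is several times the SNV-scaled
  noise projection, so a working pipeline should classify nearly all
  pixels correctly, while δ = 0 must sit at chance.
* **Calibration path** — optionally each specimen carries a raw/white/dark
  count triplet whose calibration reproduces the stored reflectance.

What the simulator does **not** emulate: within-class biochemical
heterogeneity, wavelength-dependent scattering and its depth dependence,
specimen-edge thinning, instrument point-spread, and detector nonlinearity.
Real-tissue accuracy is therefore *not* predicted by these runs: the
synthetic cohort is near-perfectly classified (≈100% pooled accuracy),
whereas the ex-vivo study this pipeline reimplements reports 86.1%.
Passing the synthetic end-to-end check shows the pipeline is correct and
leak-free (chance under the null), not that the clinical problem is easy.

## Problem sizes and runtime

Default desk-scale runs use 12 specimens of 64×64 pixels on the full
215-band grid (96 analysis bands), ≈2000 training rows per fold after the
per-class cap, and ≈31k evaluated pixels per cohort; a full LOOCV cohort
evaluation takes well under a minute on one CPU.  The tests use 32×32
specimens with 4 px boxes and a 1 px boundary for the same chain at lower
cost.

## Known limitations

* The ENVI reader supports the dialect the package writes (BSQ/BIL/BIP,
  byte order 0, header offset 0); exotic headers are out of scope.
* `median_sigma2` materializes all m(m−1)/2 pairwise distances; fine for
  m ≤ ~20k, not for whole-image training sets (use the per-class cap).
* The boundary-exclusion corridor uses exact Euclidean distance to the
  polyline via vectorized geometry predicates; cost is O(pixels ×
  segments), acceptable at these grid sizes.
* Metrics are pixel-pooled; no per-specimen confidence intervals or ROC
  analysis are provided.
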