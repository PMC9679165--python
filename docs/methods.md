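# Methods

This note documents the models and procedures implemented in `fcdsurf`,
the parameters that matter, the synthetic data the tests run on, and the
numerical choices made where the design was genuinely open.

## Geometry

All geometry lives on a bilaterally symmetric template: two triangle
meshes with identity vertex correspondence and identical cortex masks, so
interhemispheric subtraction is a single index-aligned difference.

* **Geodesic distance** is the shortest path on the edge graph with
  Euclidean edge weights (multi-source Dijkstra via
  `scipy.sparse.csgraph`), restricted to the cortex subgraph. This is the
  practical surface-neuroimaging convention; exact polyhedral geodesics
  (MMP, heat method) are out of scope. Graph geodesics overestimate true
  surface distance by a few percent on coarse meshes, which is immaterial
  for 20/40 mm border zones.
* **Connected components** of a flagged vertex set use flagged-path
  connectivity along mesh edges; components never span hemispheres.
* **Gaussian smoothing** computes, per vertex,
  Σⱼ wⱼxⱼ / Σⱼ wⱼ with wⱼ = exp(−dⱼ²/2σ²) over geodesic neighbours with
  dⱼ ≤ 3σ (under 1% of kernel mass is truncated). Kernel sizes are
  interpreted as FWHM (σ = FWHM/2.355), the convention of the standard
  cortical-surface tools; `kernel_is_fwhm=False` switches to raw σ. A
  kernel too small to reach any neighbour warns and returns the input.
  Medial-wall vertices carry 0 and are excluded from every neighbourhood,
  every statistic and every cluster.

## Quality control

Per subject × feature × region (regions from a cortical parcellation;
on the synthetic template a 34-region-per-hemisphere geodesic Voronoi
parcellation grown from farthest-point seeds), the regional mean is
compared with the cohort's per-region distribution. A feature is an
outlier when |regional mean − cohort mean| > 2.7 cohort SD in strictly
more than 10 non-lesional regions; subjects with ≥2 such features
(T1-only) or ≥3 (FLAIR available) are excluded. Cohort statistics include
the candidate subject (no leave-one-out); under a Gaussian null the
exclusion rate is far below 1%, so the inclusion bias is negligible.

## ComBat harmonization

Standard parametric empirical-Bayes ComBat fitted per (feature, vertex):
least-squares estimation of intercept, covariate coefficients (age, sex,
disease status) and per-site locations; standardization by the pooled
residual SD; normal/inverse-gamma EB shrinkage of per-site location and
scale; adjustment y\* = σ(z − γ\*ₛ)/δ\*ₛ + α + Xβ. Implementation choices:

* FLAIR availability varies by subject, so the model is fit as two
  complete blocks (T1 features on everyone, FLAIR features on the FLAIR
  subcohort). Each block requires ≥2 subjects per site.
* Site scale estimates use ddof=0, making a cohort with no batch effect an
  exact fixed point of harmonization (with ddof=1 the output shrinks
  residuals by √((n−1)/n)). At realistic n the difference is far below
  the EB shrinkage itself.
* Constant covariate columns (e.g. disease status in a controls-only
  reference) are dropped; they are absorbed by the intercept.
* `eb=False` gives direct per-site location/scale standardization — the
  closed-form oracle used by the tests; grand-mean preservation and
  new-site idempotence are exact in this mode and approximate under EB.
* A new site is harmonized to a frozen reference: α, β and the pooled SD
  stay fixed, only the new site's γ, δ are estimated (with EB priors
  moment-matched on the new site's own per-feature estimates) and removed.
  Zero-variance measurements are skipped and returned unchanged.

## Three-stage normalization

Stage 1 z-scores each feature within subject across all cortex vertices of
both hemispheres (pooling hemispheres; the statistics are global shifts,
so age/sex offsets drop out). Stage 2 forms asymmetry maps
asym_left = left − right and asym_right = −asym_left exactly. Stage 3
z-scores stage-1 and stage-2 outputs per vertex by the control reference
(mean/SD over healthy controls; train-cohort controls when a split is
given, preventing test leakage). The control SD is floored at 1e-3 to
avoid blow-ups at near-constant vertices. Re-running normalization on the
same store is refused rather than silently double-applied.

The classifier consumes 33 features per vertex:
`[combat | normalized | asymmetry]`, each block in the fixed 11-feature
registry order. The combat block is itself scaled per vertex by the
control reference ("combat_z") so that **all** inputs are dimensionless
z-scores and the zero vector means "control average". This makes the 0
imputation for missing FLAIR principled (it is the control mean) and makes
the zero baseline of integrated gradients interpretable; with raw-scale
combat values (FLAIR ≈ 100 a.u.) both would be meaningless.

## Lesion masks and border zones

Masks are closed by five one-ring dilations followed by five erosions
(vertex-graph morphological closing; original vertices are never removed).
Geodesic rings at (0, 20] and (20, 40] mm from the closed mask absorb the
uncertainty of manual mask borders: mask ∪ rings is excluded from all
training; a cluster touching the 20 mm ring counts for sensitivity+.
Interrater overlap is |B ∩ dilate(A, border)| / |B| (direction-ambiguous
in common usage, so the symmetrized mean is also available) and is
non-decreasing in the border radius.

## Classifier

A 33→40→10→1 fully-connected network, rectifier activations, logistic
output, dropout 0.4 on the input layer, explicit numpy forward/backward
passes, Adam (lr 1e-3, β 0.9/0.999), batch size 512. The focal loss
FL(p_t) = −α(1−p_t)^γ log p_t uses γ=2, α=0.5 by default (γ=0, α=1
recovers cross-entropy exactly); probabilities are clipped at 1e-7.

Per epoch, each patient contributes exactly 2000 lesional draws (with
replacement only when the mask is smaller than the quota) and 2000
non-lesional draws from cortex outside the 0–40 mm exclusion zone;
controls contribute 2000 non-lesional draws (`include_controls=True`).
Each (member, epoch, subject) draw has its own RNG stream keyed by a
stable hash of the subject id, so sampling is invariant to subject
ordering and fully replayable — the test suite audits a training run by
regenerating every draw and checking the exclusion contract.

Default ensemble: 10 folds × 5 initializations = 50 members, mean-averaged
probability; training runs up to 100 epochs with early stopping (patience
10) on held-out-fold focal loss. The decision threshold scans
0.01…0.99 in steps of 0.01 and keeps the smallest maximizer of the pooled
vertex Dice score over train patients (exclusion-zone vertices omitted).
Reduced configurations (2 folds × 2 inits, 20 epochs) are used throughout
the tests; they already saturate detection of strong planted lesions.

## Evaluation

Clusters are per-hemisphere connected components of the thresholded
prediction; components under 100 vertices are discarded (the boundary is
inclusive: exactly 100 is kept). "Overlap" means at least one shared
vertex. Specificity counts controls with zero post-filter clusters.
Detection-factor analysis fits logistic regression by IRLS (verified
against `statsmodels.Logit` to 1e-6), obtains two-sided permutation
p-values by permuting the detection outcome —
p = (1 + #{|β_perm| ≥ |β_obs|})/(1 + n_perm) — and applies
Benjamini–Hochberg across factors at q = 0.05. Quasi-separation is
detected (|β| > 20) and flagged rather than iterated to divergence.

## Interpretation

Integrated gradients use the zero baseline and a right-endpoint Riemann
sum, IGᵢ = xᵢ·(1/m)Σₖ ∂F/∂xᵢ((k/m)x), m = 256 by default; ensemble
attribution is the mean over members. Because the quadrature error is
O(1/m) and strongly lesional inputs traverse the saturated region of the
output sigmoid, report generation doubles m (up to 32×) until the
completeness residual |ΣIG − (F(x) − F(0))| is within 1% of the response;
a report is never emitted with a violated completeness axiom.

Lesion phenotyping averages the T1-derived normalized features within each
lesion mask (size-matched random geodesic discs on controls for
comparison), embeds the summaries with UMAP (15 neighbours, min_dist 0.1,
fixed seed) and clusters the 2-D coordinates with a 3-component Gaussian
mixture (argmax responsibility). On synthetic cohorts with the three
planted archetypes the adjusted Rand index against the planted labels
is ≈1.

## Synthetic cohort

The generator emulates the statistical structure the pipeline assumes,
not MRI physics. Template: two mirrored icospheres (level *n* has
10·4ⁿ+2 vertices; default level 5 = 10242), radius 60 mm, with a polar cap
marked non-cortex as a medial-wall stand-in. At level 5 this gives
≈4.4 mm²/vertex, so default lesions (geodesic discs, radius 15–30 mm)
comfortably exceed the 100-vertex cluster filter while 20/40 mm border
zones stay local — coarser than real cortical meshes (≈0.5 mm²/vertex)
but the same regime of lesion-to-filter ratio.

Per subject and feature: value = smooth population mean map + age·slope +
sex·offset + site additive shift + ε·σ·site scale, with ε unit-variance
spatially correlated noise (white noise smoothed with a 15 mm kernel and
re-standardized per vertex). The population mean maps are shared across
cohorts through a separate `anatomy_seed`, so independent cohorts sample
one population — required for new-site harmonization experiments. The
spatial-pattern amplitude is 30% of the noise SD, keeping the
across-vertex (intrasubject) and per-vertex (control-reference) SD scales
commensurate, so a lesion planted at k SD remains ≈k SD after both
normalizations. Principal curvatures k₁, k₂ are generated directly with a
deterministic folding-like sinusoidal base plus smooth noise; the
curvature features are derived through the same combinators the pipeline
uses. Defaults: age ~ U(3, 60) years, sex ~ Bernoulli(0.5), thickness age
slope −0.01 mm/yr, FLAIR available for 60–80% of subjects per site.

Lesions: hemisphere by fair coin, seed uniform over cortex, one geodesic
disc per patient, archetype offsets added inside the mask in units of the
subject's across-cortex feature SD. The three archetypes mirror the known
FCD phenotype groups: group 1 (+2 thickness, +2 intrinsic curvature,
−2 contrast, +1.5 WM FLAIR), group 2 (−2 contrast, −1.5 intracortical
FLAIR, +1 intrinsic curvature), group 3 (heterogeneous, all |offsets|
< 0.5 SD — near the detection floor by design). Effect sizes are
testability choices, not measurements; no quantitative lesional effect
sizes exist to copy.

**What passing tests show** — that each stage implements its definition
exactly (oracle agreement), that planted parameters (site effects, age
slopes, lesion effects, archetype structure) are recovered end-to-end, and
that the training contracts (exclusion zones, sampling quotas,
reproducibility) hold. **What they do not show** — performance on real
MRI: real features have anatomy-correlated noise, registration error,
mask errors and lesion heterogeneity far beyond three archetypes, and the
synthetic group-3 regime (near-null lesions) is exactly where real
detection degrades.

## Problem sizes and determinism

Unit tests run on level-2/3 templates (162/642 vertices); the end-to-end
checks and `scripts/acceptance.py` use the full default template
(level 5, 10242 vertices, 200 subjects) with the reduced 2×2 ensemble.
All randomness flows from explicit integer seeds through
`numpy.random.SeedSequence`; the same seed reproduces cohorts
bit-identically and network weights exactly.

## Known limitations

* Graph geodesics, not exact surface geodesics; distances are mesh-
  resolution dependent.
* ComBat assumes Gaussian site effects shared across subjects; scanner
  upgrades mid-study (batch drift) are not modelled.
* The 33-feature input treats missing FLAIR as exactly control-average,
  which slightly biases T1-only subjects toward "healthy" at FLAIR-driven
  lesions.
* The permutation regression permutes outcomes, which tests the global
  null per factor; factor-conditional exchangeability is assumed.
* UMAP is an external component; only seed-level determinism is
  guaranteed, not stability of the embedding under library upgrades.
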