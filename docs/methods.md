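# Methods

## Scope and assumptions

The package quantifies and reports acute ischemic stroke lesions that are
already in a common template space: a binary infarct-core mask, parcellation
atlases (arterial territories, classical structures, optionally an ASPECTS
scheme and lateral-ventricle sub-regions) and an optional ADC map must all
share one grid, checked by `grids_compatible` (equal shapes, affines within
1e-4 mm). No registration or resampling is performed; supplying unregistered
inputs is an error, not a silent fix. Voxel indices are 0-based, world space
is RAS, and world x > 0 is the right hemisphere.

Empty lesion masks are rejected everywhere (the log-volume feature is
undefined and a report without a detected infarct is meaningless).

## Quantitative feature vector

For each ROI *r* of a scheme, `QFV_r = lesioned voxels in r / voxels in r`,
an exact integer ratio kept at full precision; display uses round-half-up at
2 decimals. The lesion volume is `voxel count × voxel volume / 1000` ml and
enters the feature vector as its natural log (the "log ml" convention is
configurable only in the sense that the raw ml value is also reported).
Lesion voxels outside every labeled ROI count toward the volume but no
fraction; their number is surfaced as `unassigned_voxels`. ROIs are
bilateral (one label covers both homologues), so fractions are
hemisphere-agnostic while the report's laterality comes from the mask
geometry.

Two exact identities are enforced by tests: conservation
(Σ_r QFV_r·|r| + unassigned = lesion voxels) and equality with a
brute-force per-voxel counting oracle.

The quality-control index is the Dice overlap of the subject's brain mask
against the atlas brain, flagged below a configurable threshold (default
0.90). This is the package's own stand-in formulation for an
atlas-agreement index; it is not derived from any published formula.

## Ventricular ratio features

The five lateral-ventricle sub-regions are merged, then two strips of
`width` voxel layers (default 5) are built with a box (Chebyshev)
structuring element: OLV = dilation minus the ventricles, ILV = ventricles
minus their erosion. With the CSF threshold t = 0.0018 mm²/s:

- `γ_OLVR = #{v ∈ OLV : ADC(v) < t} / |OLV|` — tissue fraction just outside
  the template ventricles; enlargement pushes CSF into OLV and lowers it;
- `γ_ILVR = #{v ∈ ILV : ADC(v) > t} / |ILV|` — CSF fraction just inside;
  compression or shift replaces ventricle with displaced tissue and lowers it.

Both inequalities are strict, so a voxel exactly at the threshold counts as
neither CSF nor tissue. Cohort-relative flags use strict `<` against the
cohort means. A unit guard rejects ADC maps whose 99th percentile exceeds
1.0 (likely a ×10⁻⁶ scaled integer map); callers must rescale explicitly.

Binary hydrocephalus classification uses the feature triple
`[γ_OLVR, γ_ILVR, log volume]` with the same model families; this feature
set is a package design choice. The BT family carries no hydrocephalus head
because there is no single QFV component to threshold.

## Classification models

One independent binary classifier per ROI over the full concatenated
feature vector (both schemes' fractions, log volume, the two γ ratios).
Families: BT, LDA, QDA, RF, KNN, SVM (probability-calibrated SVC), MLP,
all via scikit-learn except BT.

**BT.** The prediction rule is `QFV_r ≥ θ_r → injured`. θ_r is the smallest
grid value (default grid 0.00–1.00, step 0.01) maximizing the mean
cross-validated BACC + F1; ties go to the smaller threshold ("the minimal
level achieving the highest score"). Folds are stratified on the ROI label;
when a class cannot populate two folds the score degrades to
resubstitution.

**Hyperparameter selection.** Stage 1: one 5-fold CV pass over the whole
grid, scored by mean-over-folds BACC + F1 (mean over ROIs unless a single
ROI is requested). Stage 2: 10-repeat 5-fold CV over the stage-1 top three;
the stage-2 winner is returned, ties resolved by grid order. A grid point
that is infeasible for the fold size (e.g. a KNN neighborhood larger than
the training fold) scores −∞ rather than aborting the search. Default
grids are package choices declared in `DEFAULT_GRIDS`.

**Degenerate ROIs.** A region with fewer than two training examples of a
class becomes a constant predictor at the training prevalence and is listed
in the model card's `constant_rois` — severe imbalance is flagged, never
hidden.

**Metrics.** sensitivity = TP/(TP+FN), precision = TP/(TP+FP),
BACC = (sensitivity+specificity)/2, F1 = harmonic mean, Cohen's κ with
marginal-product chance agreement. Undefined ratios return 0 with a
warning. ICC3 (two-way mixed, single rater, consistency) is computed from
the ANOVA decomposition
`(MS_rows − MS_error) / (MS_rows + (k−1)·MS_error)`; tests cross-check it
against pingouin's ICC(C,1).

## Explanations

MDI importance refits `n_models` (default 100) independently re-seeded
forests and reports the mean and SD of the normalized impurity decreases.
Permutation importance is the mean drop in BACC (default) over `n_iter`
(default 100) shuffles of one column, computable on training or testing
data.

Per-case Shapley values are interventional: the value of a coalition S is
the mean model output with the features in S fixed at the case's values and
the rest drawn from a background sample (default 100 training cases). With
at most 12 features the attribution is computed exactly by coalition
enumeration; above that, by antithetic permutation sampling. Both routes
satisfy efficiency — `base + Σφ = predicted probability` — exactly (the
permutation estimator's marginal contributions telescope), so the 1e-6
tolerance in `Explanation` only absorbs floating-point accumulation; any
residual drift is spread uniformly before validation. Null features receive
exactly 0 and duplicated symmetric features equal shares under the exact
route. The estimator is model-agnostic; tree-path-specific shortcuts are
deliberately not used so every family is explained by the same procedure.

## Report

The template is a fixed, injective function of the structured fields, so
`parse_report_text` inverts it exactly (volumes are printed at 3 decimals;
round-trip identity holds on 3-decimal volumes).

- **Hemisphere**: lesion voxel fractions on each side of world x = 0;
  "bilateral" when the minor side holds ≥ 10% (configurable), strict
  midline voxels counting to neither side.
- **Territories**: positive predictions with probability ≥ 0.70 are
  asserted ("in the territory of the middle cerebral artery"); below the
  band they are qualified ("possibly Lateral Lenticulostriate"). The band
  is calibrated so the worked example reproduces and is configurable.
- **Structures** are listed in atlas-table order.
- **MCA-ASPECTS** = 10 − #{ASPECTS regions with fraction ≥ τ}, τ = 0.05 by
  default. The involvement rule and τ are package design choices; the
  ASPECTS parcellation shipped by the phantom module is synthetic geometry,
  and clinical use requires a real ASPECTS atlas.

## Synthetic phantoms: what they emulate and what they do not

`make_phantom_atlas` builds an ellipsoidal brain partitioned by a
centroidal (Lloyd-relaxed) Voronoi tessellation of mirrored seed pairs:
each bilateral ROI is one label with two mirror-symmetric components, plus
an unpaired midline brainstem analogue, and a five-part central ventricle
box. Lloyd relaxation keeps ROI volumes comparable, mirroring real
parcellations whose homologous ROIs have approximately equal volume.
`make_lesion` grows a connected region by stochastic dilation until each
targeted ROI's overlap fraction is within ±0.02 of its target, bridging
disconnected targets along in-brain shortest paths and finishing with a
mild (3%) spillover pass so lesions coalesce across boundaries the way
infarcts do; untargeted ROIs stay at or below the tolerance.

The default cohort (`PhantomSpec`): 48³ grid at 1 mm, 8 arterial pairs, 6
structural pairs + brainstem, per-ROI structural prevalence 0.45 with
target fractions drawn uniformly from [0.10, 0.30] (mean lesion ≈ 4 ml,
the clinical median scale), labels `fraction ≥ 0.05` flipped with 5%
noise, and an ADC phantom whose ventricular CSF zone scales per case
(scale > 1.25 defines the hydrocephalus label). Near-balanced prevalences
are deliberate: with 5% label noise the noise-limited BACC ceiling is
highest for balanced classes (~0.95) and degrades sharply for rare or
near-universal labels, which would make parameter-recovery checks
uninformative at desk scale. Arterial involvement is not drawn directly —
it emerges from lesion geometry, as clinically.

What passing tests on these phantoms shows: the arithmetic, protocols and
code paths are correct under known ground truth, class imbalance and label
noise. What they do not show: performance on clinical cohorts — phantom
lesions are texture-free stochastic blobs, the parcellation adjacency is
Voronoi rather than vascular anatomy, ADC has no pathology other than the
ventricle scaling, and registration error does not exist. Published
clinical performance tables are therefore out of reach at desk scale and
are replaced by property-based checks (oracle identities, recovery floors,
monotonicity, additivity, determinism).

## Problem sizes used by the test suite and acceptance script

Cohort n = 400 (200 train / 200 held out; an even split halves the variance
of the per-ROI held-out estimate relative to a 75/25 split at this n); BT
oracle checks on 120 cases; MDI with 25 forests of 100 trees on 150 cases;
Shapley with 8 permutations against a 40-case background (efficiency is
exact regardless of the permutation count); determinism on a 32³ phantom
with n = 20. API defaults (100 forests, 100 permutation iterations, 200
Shapley permutations) are unchanged by these choices.

## Known limitations

- The QCI is a Dice stand-in, not a validated atlas-agreement index.
- The ASPECTS involvement rule (τ = 0.05) is an assumption; no published
  rule is implemented.
- Probabilities are not calibrated; the 0.70 "possibly" band is a prose
  convention, not a calibrated confidence.
- Per-hemisphere QFVs are not computed (ROIs are bilateral by design).
- The permutation-sampling Shapley estimate has Monte-Carlo variance in its
  individual attributions (efficiency is still exact); increase
  `n_samples` for publication-grade attribution values.
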