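# Methods

This note describes the models and procedures implemented in `bprm`, the
design choices behind them, and what the synthetic validation does and does
not demonstrate.

## Problem setting

In COPD, airflow limitation measured by spirometry (FEV1/FVC%) arises from
two structurally distinct processes: emphysematous destruction, visible as
low attenuation on inspiratory CT, and functional small airway disease
(fSAD), visible only as air trapping on expiratory CT. The package
quantifies both from a paired inspiratory/expiratory scan, regresses
FEV1/FVC% on the size- and region-resolved burden of each lesion type, and
redistributes the fitted model back onto the lung as a grid-level severity
map (the bullous parametric response map, BPRM) intended to flag the least
functional regions — candidate targets for bronchoscopic lung volume
reduction.

## Densitometry and PRM

Lesion masks are strict thresholdings (`HU < t`) of the parenchyma: mild
emphysema at −920 HU and severe emphysema at −950 HU on inspiration, air
trapping at −856 HU on expiration. LAV% is the lesion fraction of the
parenchyma (lung minus airway — the airway is always removed before any
density is computed). One published variant uses −930 HU for mild emphysema;
−920 is the default here because the tabulated measure names use it, and
−930 is available through `Thresholds.emph_mild`. The strict inequality is a
single documented convention; a voxel exactly at the threshold is *not*
lesion.

The PRM classifies each parenchyma voxel of the co-registered pair. Two
emphysema rules are implemented:

* `strict_both` (default): emphysema ⇔ HU < −950 on *both* phases;
  fSAD ⇔ expiratory HU < −856 and not emphysema.
* `classic`: emphysema ⇔ inspiratory < −950 and expiratory < −856;
  fSAD ⇔ inspiratory ≥ −950 and expiratory < −856.

Classes are mutually exclusive and, together with `normal`, cover the valid
parenchyma exactly — that partition is asserted in tests. Voxels whose
warped position falls outside the expiratory field of view are excluded and
counted separately rather than classified.

## Segmentation

The airway is grown from a trachea seed by threshold stepping: the
threshold rises from −960 HU in 20 HU steps and a step is rejected when the
seeded component's volume jumps by more than a factor of 2 (leak into the
parenchyma). This leak-guarded stepping is our concrete reading of
"adaptive" seeded growth; the step, bound and leak factor are configurable.
The lung mask is then every `HU < −200` component touching the airway, with
vessels re-included by morphological closing (radius 2 voxels) plus hole
filling, and the airway subtracted. A bound of +200 HU — meaningful when
the initial mask marks everything darker than soft tissue — is available in
the config, but −200 is the default because region growing *from an airway
seed* under +200 would flood the mediastinum.

Left/right separation erodes the mask until it falls into two sizeable
components, then reassigns every lung voxel to the nearest seed by geodesic
(in-mask) breadth-first growth; ties go to the smaller label. Sides are
named by centroid x in RAS coordinates (patient left = smaller x).

Lobe grouping uses a single surface per lung: fissure candidates are voxels
whose Hessian (Gaussian scale 2 mm) has a dominant negative eigenvalue and
plateness score `S = |λ1|·(1 − |λ2|/|λ1|)` above threshold, non-maximum
suppressed along the plate normal. A regularized thin plate spline
`z = f(x, y)` through those points separates upper from lower; with fewer
than six usable points the fallback is a horizontal plane at 0.55 of the
cranio-caudal extent (logged). The right middle lobe belongs to the lower
group by definition, which is why one surface per lung suffices.

## Registration

The expiratory lung is aligned to the inspiratory lung per side, in three
steps:

1. **Moment affine.** An axis-aligned affine (centroid shift plus per-axis
   scale from the full masks' first and second moments) absorbs the bulk of
   expiratory contraction. Respiratory motion at this scale is dominated by
   a near-affine contraction, so this step alone removes most of the
   displacement, without any correspondence estimation.
2. **Coherent point drift.** Surface points sampled on a deterministic
   6 mm physical grid are matched by non-rigid CPD: an isotropic Gaussian
   mixture on the moved floating points with uniform outlier mass
   (w = 0.1), EM-iterated with a motion-coherence prior — the displacement
   field lives in the span of a Gaussian kernel (β = 45 mm) and is shrunk
   by the regularization weight λ = 8. Two numerical choices matter and are
   deliberate:
   * The EM runs on points normalized to zero mean and unit RMS radius.
     The standard outlier constant `(2πσ²)^{3/2}·w/(1−w)·M/N` implicitly
     assumes roughly unit-scale data; on raw millimeter coordinates it
     swamps the posteriors and the registration stalls.
   * The mixture SD is floored at half the sampling pitch. Without the
     floor, σ² collapses below the pitch, every floating sample locks onto
     its nearest reference *sample* (not the nearest surface point), and
     the EM overfits sampling quantization into a biased smooth field.
   The stiff prior (λ = 8) reflects that after the affine step the residual
   is small and smooth; β, λ, pitch, w, the floor, iteration cap (300) and
   tolerance (1e−7) are all configurable.
3. **Landmark warp.** Interior points pushed through affine + CPD become
   landmarks; the dense displacement field on the inspiratory grid is the
   scattered linear interpolation of the landmark displacements (nearest-
   landmark extension outside the hull), and the expiratory HU volume is
   pulled back by trilinear interpolation. Out-of-field voxels get −1024
   and are flagged invalid.

On the synthetic phantom (96³ voxels, 1.5 mm) this recovers the known
deformation with a mean target-registration error of ≈1.2 mm against an
unregistered baseline of ≈3.8 mm; registering a point set to itself is the
identity to below 1e−6 mm.

## Low attenuation clusters

Connected low-attenuation components often merge several bullae through
thin necks. Iterative erosion with the full 3³ element gives each voxel a
depth (the number of erosion rounds it survives; equivalently the chessboard
distance to the background minus one, which the tests use as an independent
oracle). Bulla cores are connected plateaus of locally maximal depth with
depth ≥ `min_core_depth` (default 2 — a core must survive at least two
erosions, so single-voxel noise cannot split a cluster). Every lesion voxel
is assigned to exactly one core by marker-based watershed on the negated
depth; components without a qualifying core stay whole. `min_core_depth=∞`
reduces exactly to plain connected-component labeling, which is tested.
Clusters below 8 voxels are kept but flagged `small`.

Each cluster's LAD is voxel count over parenchyma count, so the LADs of one
mask sum *exactly* to LAV%/100 — an identity asserted to 1e−12. Expiratory
air-trapping clusters are classified by emphysema predominance: if more
than `ratio_cut` (default 0.5, "predominant" read as majority) of a
cluster's voxels are PRM-emphysema it is excluded from the fSAD predictors;
otherwise its effective density counts only its PRM-fSAD voxels. Cluster
region (side, lobe group) is the majority of its voxels, ties toward lower.

## Size scales and the airflow model

Pooled cluster LADs are clustered into k = 10 size scales by exact
dynamic-programming univariate k-means (contiguous clusters in sorted
order, globally minimal within-cluster sum of squares; verified against
exhaustive enumeration for every n ≤ 12, k ≤ 4). Scale boundaries are
midpoints between adjacent cluster extremes, so assigning the training pool
by boundary lookup reproduces the optimal partition exactly; new values
clamp to the outer scales. Pools larger than 3,000 are thinned to an even
quantile subsample before the O(kn²) DP. Inspiratory emphysema LADs and
expiratory fSAD LADs are pooled and scaled separately by default (a joint
mode exists), since the two lesion types have different size laws.

The predictor vector has 40 entries: summed LAD% per (scale 1–10) ×
(upper/lower) × (emphysema-950/fSAD). Summing a subject's predictors over
scales reproduces the regional LAV% identically — conservation is asserted
exactly. The response model is ordinary least squares of FEV1/FVC% on all
40 predictors followed by backward selection: repeatedly drop the
highest-p predictor (ties broken by largest column index, making the result
invariant to column order) and refit, until every retained term has
p < 0.05. Rank-deficient columns are dropped with a warning before the full
fit. Evaluation is repeated stratified 5-fold cross-validation (folds
stratified by response quintile, a seeded shuffle per repeat, Pearson r on
pooled out-of-fold predictions per repeat). Two CV modes exist:

* `reselect=True` (default): selection is re-run inside every training
  fold — the fully honest protocol.
* `reselect=False`: selection is performed once on the complete data set
  and only the coefficients are refitted per fold. This mirrors the common
  clinical-literature protocol of deriving one final model on the full
  cohort and quoting its repeated-CV correlation, and it is the mode the
  acceptance checks use; it reports a higher r than per-fold reselection
  because the support is stable across folds.

## The severity map

A cluster whose (scale, group, type) term survived selection contributes
`β · LAD%` to the predicted FEV1/FVC% deviation from the intercept; that
contribution is spread uniformly over the cluster's voxels, so voxel sums
reproduce the cluster total exactly and the whole-lung sum plus the
intercept equals the subject-level prediction to 1e−9 relative — this
conservation identity is the *definition* of severity here, and it is
preserved under grid refinement. Cells (default 20 mm isotropic, anchored
at the lung bounding-box corner for determinism) are ranked most negative
first; the export paints each voxel with its cell severity (float32 NIfTI)
and writes the ranked cell table with per-cell class composition.

## The synthetic phantom

The imaging phantom emulates exactly the quantities the pipeline measures:
two ellipsoidal lungs (inspiratory parenchyma ≈ N(−850, 30) HU, expiratory
≈ N(−760, 30)) in a soft-tissue body (+40 HU), an enclosed airway tree
(−1000 HU) reaching both lungs, spherical bullae (N(−980, 10) in both
phases), air-trap spheres (N(−900, 15) in both phases — above −950 on
inspiration, below −856 on expiration, with ≥3 SD margins to every
threshold), and one oblique bright fissure plane per lung. The expiratory
volume is the inspiratory geometry pushed through a known analytic map:
8% contraction toward the carina plus a 2 mm low-frequency sinusoid
(invertible; inverted by fixed-point iteration to <1e−6 mm). A single seed
drives all draws through independent child streams per tissue class, so
adding lesions never changes the parenchyma noise — regeneration is
bit-identical and lesion-count-independent.

What the phantom does *not* emulate: scanner noise texture and
reconstruction kernels, airway trees beyond three tubes, real fissure
geometry, vessels, and sliding motion at the pleura. Passing tests
therefore demonstrate the correctness of the algorithms under controlled
conditions — exact bookkeeping, threshold logic, recovery of a smooth known
deformation — not clinical segmentation or registration accuracy.

## The synthetic cohort

The cohort generator emulates only the statistical layer. Per subject,
cluster count ~ Poisson(150); cluster LADs are i.i.d. log-normal
(μ = ln 5e−4, σ = 1.3 — a stand-in law, configurable, since no cohort-level
cluster-size distribution is published); each cluster is uniformly assigned
a lobe group and lesion type; scales are fixed decile boundaries of the
size law; predictors are the per-bin LAD% sums. The response is
`intercept + Xβ + N(0, noise_sd)`, clipped to [10, 95] (clipping never
triggers at the defaults).

The default truth has 16 nonzero coefficients — scales 6–9 in every
(type, group) block, with scale 10 deliberately null, echoing the finding
that giant bullae contribute less to airflow limitation than medium ones.
Coefficient magnitudes are inversely proportional to each bin's natural
LAD%-sum variability under the size law (estimated once from a large probe
draw and frozen as constants), so every true term carries an equal share of
signal variance: at n = 100 each term has t ≈ 3.6, large enough for
backward selection to see it, while the total signal corresponds to
population R² ≈ 0.67 at the default noise SD of 3 (`tune_noise_for_r2`
recalibrates the noise exactly for any requested R²). The intercept of 88
puts the response at ≈55 ± 5, a realistic obstructed-cohort mean. An
optional log-normal per-subject severity factor (`severity_sigma`, default
0) can induce the between-subject burden correlation seen in real cohorts;
it is off by default because it trades per-term identifiability for
predictive ease.

Under these conditions the pipeline recovers the sign of ≈99% of the true
coefficients (sign of the selected-model estimate, falling back to the
full-model estimate for dropped terms), and fixed-selection repeated 5-fold
CV gives mean r ≈ 0.78–0.82.

## Determinism and provenance

Every stage is deterministic given its seed: grid-anchored point sampling,
seeded CV shuffles, counter-based phantom streams. Reports contain no
wall-clock state; re-running a subject or cohort with identical inputs and
seeds reproduces the output files bit-for-bit (asserted in tests). Each run
writes a provenance record (config, inputs, package version, content hash);
`run_subject` reuses cached outputs when the stored hash matches.

## Problem sizes used in validation

The test-suite phantoms are 48³ voxels at 2 mm (with one 96³ session
fixture at 1.5 mm for registration and PRM properties); synthetic cohorts
have 60–100 subjects; the acceptance script runs the 96³ phantom, 30-seed
sign recovery, a 30-repeat CV and duplicate pipeline runs. These sizes keep
the complete validation under a few minutes on one core while exercising
every code path at the study scale.

## Known limitations

* Lobe grouping fits one surface per lung; lungs with incomplete or
  supernumerary fissures will fall back to the fractional-height plane.
* The registration is mask-driven; it cannot recover motion components
  tangential to the lung surface beyond what the smoothness prior implies
  (the phantom's sinusoid is near-affine within a lung, which such a scheme
  can recover; strongly non-affine tangential motion would not be).
* LAC splitting reconstructs a published idea — cores at erosion-depth
  maxima — whose original details are not fully public; the watershed
  interpretation here is explicit and swappable.
* The HU −920 vs −930 discrepancy for mild emphysema is supported both
  ways, not arbitrated.
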