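# Methods

## Statistical model

Each analysis is a mass-univariate ordinary-least-squares regression of the
per-voxel lesion value on seven regressors: the composite naming score
(mean of spoken and written picture-naming T-scores), four nuisance task
T-scores (nonword repetition, semantic associations, spoken word
comprehension, writing copy), lesion volume, and an intercept. Predictors
are mean-centered (the intercept absorbs means; t-statistics are
unaffected — verified by test). The contrast of interest puts weight −1 on
the composite and is tested one-sided: greater abnormality associated with
lower naming ability. Z-equivalents are standard-normal quantiles of
1 − p_unc, for reporting.

The search volume is restricted to voxels whose *binary* lesion indicator
(fuzzy value > U, U = 0.3, strict) is positive in at least `min_overlap = 5`
patients. Overlap maps and volumes always use the binary indicators, even
in the fuzzy pipeline; the GLM and the exclusion fractions use whichever
image kind the pipeline is configured for.

### Family-wise error control

We use the permutation distribution of the maximum statistic rather than
random field theory: it is assumption-light, testable exactly against
enumeration, and targets the same corrected threshold. Nuisance covariates
are handled with the Freedman–Lane scheme: fit the nuisance-only model,
permute its residuals across patients, add them back to the nuisance
fit, refit the full model, and record (a) the maximum t over the mask and
(b) the maximum supra-threshold cluster extent at the forming threshold
(one-sided p < 0.001, i.e. t over the Student quantile; 26-connectivity by
default). Corrected p-values use the add-one rule
(1 + #exceedances)/(n_perm + 1), which bounds p away from zero; when the
number of distinct permutations n! does not exceed the requested n_perm the
null is enumerated exhaustively and p-values are exact (the identity
permutation is then part of its own null). Voxel- and cluster-level
inference share one permutation stream.

Degenerate voxels (zero residual variance) get t = ±∞ by the sign of the
contrast estimate, with p ∈ {0, 1}.

### Iterative exclusion

After each analysis, significant regions are extracted and every patient
with a damage fraction strictly above 0.25 to *any* region found so far is
excluded (exactly 25% is retained — the retention band is 0–25% inclusive).
Damage fraction is the lesioned proportion of the region for binary images
and the mean abnormality for fuzzy ones; the continuous analogue is the
natural reading when no thresholded count is defined, and both pipelines
are supported. Regions accumulate across iterations, so iteration k
excludes on the union of everything found in iterations 1..k. The loop
stops on: no significant voxels; an empty analysis mask; or the cohort
falling below a floor (default 30) under which permutation inference is
vacuous. Each iteration draws an independent permutation stream from a
child of the master seed; the whole trace is reproducible bit-for-bit.

**Region rule.** Significant regions are, by default, all voxels of
clusters significant at the cluster level (α = 0.05 FWE); connected
components of voxel-level FWE-significant voxels are available as
`roi_rule="voxel"`. Cluster extent is the more sensitive test for spatially
extended regions — in the motivating data the frontal region was marginal
at voxel level and secure at cluster level — and under the default
synthetic scenario it is what lets both cortical regions surface in the
first pass. This default is a deliberate design choice of this package.

### Power maps

At a voxel lesioned in k of n patients, the most favourable configuration
assigns the k lowest composite scores to the lesioned group; the voxel is
"powered" when the resulting two-sample pooled-variance t reaches the
caller's corrected critical value (e.g. the 95th percentile of the maxT
null). This is an operational definition: it bounds what the lesion
sampling could ever show at that voxel, and is exact for the best-case
assignment (proved by enumeration in the tests). It is not claimed to match
any external power-map implementation bit-for-bit.

## Post-hoc analyses

Patients are assigned to five groups from their damage fractions to the
frontal (f_F) and temporal (f_T) first-pass regions: Group 1 f_F ≥ 0.75 ∧
f_T ≤ 0.25; Group 2 mirrored; Group 3 both ≥ 0.75; Group 5 both ≤ 0.25;
Group 4 is the complement (the "partial damage" band — defining it as the
complement makes the five groups a true partition, which a literal 26–74%
reading would not). Incidence tables report impaired / not-impaired counts
and integer-rounded percentages per group. Group-vs-group incidence is
tested with the Pearson chi-square on the 2×2 table *without* continuity
correction — with Yates' correction the published worked-example statistics
(13.95, 23.3, 81.4) are not reproduced. Severity is an ANCOVA: composite ~
group + lesion volume, partial F for the group factor against the
volume-only model, pairwise adjusted-mean contrasts Bonferroni-corrected
over the number of pairs; groups with fewer than two members are dropped
with a warning. The smallest-lesion report gives, per region, the minimum
lesion volume among impaired patients with damage fraction above 0.25, and
whether that lesion extends beyond the region.

## Synthetic cohort generator

The generator builds the world in which pooled mass-univariate mapping
fails: a 32×32×32 grid at 2 mm isotropic with three disjoint critical
boxes — T (posterior, 8³ voxels), F (anterior, 8³), P (deep, 4³, displaced
off the cortical axis) — and a four-component lesion mixture:

| territory | weight | behaviour |
|---|---|---|
| posterior | 0.30 | ellipsoid on T, elongated along the anterior–posterior axis (radii ≈ 4.3 × 11 × 4.3 voxels, log-normal σ 0.25) |
| anterior  | 0.30 | the mirror image, on F |
| deep      | 0.15 | small lesion (radius ≈ 3) centred on P; damages P above θ in ~60% of draws and essentially never reaches T or F |
| large     | 0.25 | whole-territory infarct (radius ≈ 13, nearly constant) covering all three boxes |

Lesions are fuzzy: value = sigmoid(−signed distance to the ellipsoid
surface / border width), border width 1 voxel, clipped to [0, 1].

A patient carries the latent deficit D when any critical region's mean
abnormality exceeds θ = 0.5. Task scores are Gaussian around
`cutoff + 9 − 12·D` for the two naming tasks and `cutoff + 9 − coupling·
(region fraction)` for the nuisance tasks (repetition and copy couple to F
with slopes 3 and 2; comprehension and associations to T with 3 and 2),
minus 0.0005 T-points per lesioned voxel, with noise sd 3. Anchoring each
baseline at its own cut-off plus a 9-point healthy margin makes the spoken
naming baseline 70 and puts deficit carriers ~3 points below both naming
cut-offs (≈84% per-task impairment probability); a single common baseline
would make written naming (cut-off 54) almost never impaired and the
deficit-of-interest undetectable by construction. The coupling slopes are
deliberately symmetric between T and F: asymmetric couplings measurably
bias which cortical region is detected first, because a nuisance regressor
coupled to a region's damage partials that region's composite association
away.

**Why this geometry.** Three features carry the phenomenon. (i) The
*large* territory makes deep damage co-occur with cortical damage; its
patients' deficit is almost fully absorbed by the lesion-volume regressor
(their volumes are near-constant and extreme), so they contribute little
information anywhere. (ii) The *deep* territory is small (15%) and only
moderately penetrant, while most deficit carriers owe the deficit to T or
F — those carriers dilute P's marginal association below the corrected
threshold in the pooled pass. After excluding everyone with >25% cortical
damage, the survivors are mostly deep-territory cases and spared patients,
and P's association is strong. (iii) The *elongation* of cortical lesions
makes T and F damage co-occur, so the two cortical regions reinforce
rather than dilute each other and both surface in the first pass; with
independent compact cortical territories the first pass typically finds
only one of them (we verified this variant and rejected it).

Calibration targets (checked by tests at n = 1000): deep draws damage P
above θ in a majority of draws; patients with P damage but no cortical
damage are ~5–15% of the cohort; large lesions cover all three boxes; deep
lesions essentially never reach T/F. A consequence of the fixed mixture
weights plus the penetrance the masking phenomenon needs is a pooled
deficit incidence of ~0.65–0.75 — higher than is typical of real aphasia
cohorts (~0.3); the generator trades marginal realism of the incidence for
the exact co-occurrence structure under study.

Null cohorts reuse the identical lesion model but draw every score as
baseline + noise, independent of the lesions. They drive the
false-positive-rate study: over 50 replicates (n = 150, 250 permutations)
the share of cohorts with any FWE-significant voxel must stay inside the
exact binomial 95% band around 0.05, and no null may produce a productive
second iteration.

**What a green test does and does not establish.** The simulator emulates
the co-occurrence and OR-causation structure, fuzzy borders, and cut-off
behaviour of real data. It does not emulate anatomical lesion shapes,
registration error, scanner effects, score ceilings/floors (T-scores are
not truncated), or missing data. Green tests establish that the machinery
detects and recovers the planted structure and controls false positives
under the stated null — not that any particular real-data result would
replicate.

## Numerical choices and edge cases

- OLS via one QR decomposition per analysis; per-permutation cost is two
  matrix products (p×n×v), no refactorisation.
- Permutation p-values: add-one rule for Monte-Carlo, exact counts for
  exhaustive enumeration; ties counted with ≥.
- Cluster connectivity default 26 (configurable 6/18/26).
- Binarization is strict (> U) and idempotent; exactly-U voxels are intact.
- Rank-deficient designs raise immediately, naming a constant column when
  one exists; n ≤ p raises.
- Empty ROI sets are valid analysis outcomes, never errors; an empty
  analysis mask is a recorded stop reason.
- Missing behavioural scores are a hard error; no imputation anywhere.
- Cohort assembly validates shared grid/affine and never resamples.
- Master seed → per-iteration child seeds via `numpy.random.SeedSequence`;
  all child seeds are < 2³¹.

## Known limitations

- Permutation inference assumes exchangeability of nuisance-model
  residuals; heteroscedastic behavioural noise across lesion-size strata
  would weaken exactness.
- The cluster-extent null is computed at a fixed forming threshold; no
  threshold-free variant (e.g. TFCE) is provided.
- The power map is a best-case bound, not a calibrated power estimate.
- The five-group post-hoc workflow presumes exactly two first-pass regions
  of interest (frontal/temporal roles); with a single merged region the
  single-region groups are empty and their contrasts are not testable.
- Mass-univariate throughout; no multivariate or machine-learning mapping.
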