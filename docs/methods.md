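# Methods

This note documents the models, conventions, and design choices behind
`msburden`, and what the synthetic-data tests do and do not establish.

## EMR anxiety phenotyping

Anxiety is underdiagnosed and undertreated in medical populations, so the
stratification leans on prescribing behaviour rather than diagnosis codes
alone. Three structured EMR fields are combined:

* **severe anxiety** — an anxiety diagnosis code *and* an anxiolytic order:
  psychopathology prominent enough to be both coded and treated;
* **mild anxiety** — exactly one of the two;
* **no anxiety** — no psychiatric (F-chapter) diagnosis, no psychotropic
  medication, and at least one PHQ-2 or PHQ-9 observation, all with score 0.
  Psych-free patients with no PHQ on file, or a nonzero PHQ, are excluded:
  the absence of a code does not establish the absence of symptoms.

Consequences worth knowing:

* The no-anxiety group's mean PHQ-2 is exactly 0 by construction. This is an
  analytic property of the rules, not an empirical finding, and is used as an
  end-to-end pipeline check.
* Anxiety-code matching is case-insensitive prefix matching; the default
  dictionary uses the **F40 and F41** blocks, since F41 (generalized anxiety,
  panic) is the dominant anxiety billing code. The depression ruleset
  (F32/F33 or an antidepressant, binary) shares the asymptomatic comparator.
* All dictionaries (anxiolytics, antidepressants, psychotropic superset,
  prefixes) are configuration (`data/dictionaries.yaml`), not code: formulary
  lists are site-specific.
* When a patient has several PHQ observations, *all* must be zero for the
  no-anxiety label — the stricter reading. No time window around the MRI is
  applied by default; PHQ and PROMIS observations of any date are eligible,
  with per-domain PROMIS selection taking the observation most proximal to
  the (chronologically first) MRI.

## Streamline-filtering lesion burden

Inputs are a binary lesion mask on a voxel grid with a 4×4 index→world-mm
affine, and bilateral tract bundles as polylines in world mm, both already in
a common template space (registration is out of scope; only affine frames are
checked).

Conventions, fixed for bit-reproducibility:

* **Point-in-voxel rule**: voxel centers sit at integer continuous indices;
  a world point maps to the nearest index with exact halves rounded **away
  from zero**. Out-of-grid points are flagged, never clamped.
* **Resampling**: each polyline segment is subdivided so consecutive samples
  are at most half the smallest voxel edge apart, keeping original vertices.
  This guarantees no voxel is skipped along straight segments at 1 mm; the
  sampled-vertex convention (rather than exact segment–voxel intersection) is
  the one commonly used by tractography tools, and is validated against a
  brute-force per-sample oracle in the tests.
* **Volumes**: the volume of a streamline set is |union of traversed in-grid
  voxels| × voxel volume — a set union, not a per-streamline sum. With this
  definition injured voxels are always a subset of canonical voxels, so the
  burden ratio is provably in [0, 1] and monotone under lesion growth.
* **Burden**: a streamline is injured when any sample maps to a lesion voxel.
  Burden = mean(injured volume left, right) / mean(canonical volume left,
  right). Hemispheres are averaged before the ratio; a missing side
  contributes zero volume but still counts in the two-side mean. Both
  canonical volumes zero is an error.

## Statistical layer

* **GAM**: Gaussian `outcome ~ predictor + sex + total_brain_volume + s(age)`
  fitted with statsmodels `GLMGam`; the age smooth is a cubic B-spline with
  basis dimension 4 and penalty weight selected by AIC (`select_penweight`).
  The reported T and two-sided p are the Wald statistics of the parametric
  predictor term. Total brain volume is standardized internally for
  conditioning only — the predictor's T is invariant to that scaling.
  Anxiety severity enters as an ordinal 0/1/2 slope (a single parametric
  comparison across the three groups); the diagnosis contrast uses only the
  none/severe extremes. Each included group must have at least 10 rows.
* **Forced-linear mode** (`age_spline="linear"`): an unpenalized spline of
  dimension 2 is exactly a linear function of age, so this mode enters age as
  a linear column; the fit then reproduces OLS coefficients to 1e-6, which is
  asserted in the tests.
* **Effect size**: Cohen's f² = (R²_full − R²_reduced)/(1 − R²_full), with the
  reduced model dropping the predictor but keeping all covariates and the
  same smoothing weight. R² is 1 − RSS/TSS on the fitted values. The CI is a
  percentile bootstrap over patients (default B = 1000, seeded), holding the
  smoothing weight at the full-fit value for stability. On the OLS special
  case f² equals t²/df_resid exactly; that identity is tested.
* **BH-FDR**: the step-up is implemented directly (adjusted
  p₍ᵢ₎ = min over j ≥ i of m·p₍ⱼ₎/j, capped at 1) and checked against both a
  brute-force enumeration over rejection thresholds and statsmodels. The two
  hypothesis-driven UF models use unadjusted α = .05; FDR applies within the
  sensitivity suite and within the PROMIS contrast family.
* **Batteries**: one-way ANOVA for continuous demographics, Pearson χ² for
  categorical (race is tested as a demographic but is not a model covariate);
  Shapiro–Wilk normality per group/measure, unpaired t (severe vs none) and
  paired t (emotional vs physical within group) for PROMIS summaries, each
  with Cohen's d (pooled-SD for unpaired, mean/SD of differences for paired).
  A zero-variance paired difference is reported as t = 0 rather than NaN.

## Synthetic-data generator

The generator emulates the *structure* the analysis assumes, at configurable
sizes. Defaults are the study conditions the package targets:

| parameter | default | meaning |
| --- | --- | --- |
| `n_patients` | 372 | cohort size |
| `group_props` | 99/372, 249/372, 24/372 | none/mild/severe anxiety split |
| `burden_means` | 0.02, 0.05, 0.10 | planted UF burden by group |
| `burden_noise_sd` | 0.02 | between-patient burden SD (truncated to [0,1]) |
| `fornix_burden_mean` | 0.04 | group-independent fornix overlap |
| `total_lesion_extra` | 4000, 7000, 10000 mm³ | background lesion volume by group |
| `grid_shape`, `voxel_size_mm` | 48³, 1.0 | template grid |
| `phq2_means` | 0.57, 1.16 | mild/severe PHQ-2 means (truncated Poisson 0–6) |
| `promis_effect` | 4.0 | emotional T-score drop per severity level (physical: half) |
| `phq_missing_rate` | 0.1 | chance a no-anxiety patient lacks a confirming PHQ |
| `depression_rate` | 0.8 | chance an anxious patient also carries depression |

EMR events are written so the phenotyper recovers the latent group exactly
when no PHQ is missing: no-anxiety patients are psychiatrically clean with a
recorded PHQ of 0; mild patients carry exactly one of {F40/F41 code,
anxiolytic}; severe patients carry both. Age (47.7 ± 11.4 y), sex (80%
female), race and total brain volume are drawn balanced across groups.

**Toy tracts** are parametric circular arcs jittered per streamline —
hook-shaped (UF analog, anterior/inferior) and arch-shaped (fornix analog,
posterior/superior) — mirror-symmetric about the mid-sagittal plane. Their
placement guarantees disjoint voxelizations (verified at construction; grids
that cannot hold them apart raise a sizing error), so lesions planted on one
tract can never injure the other.

**Lesion planting** ranks tract voxels by how many streamlines traverse them
and adds them fewest-first, tracking the burden the filtering module would
recompute after each prefix. Adding the least-shared voxels first makes the
burden trajectory grow in the finest increments the tract offers; the
trajectory is monotone and deterministic, so planting a target reduces to a
prefix lookup, and the recomputed burden equals the trajectory value by
construction (asserted through the burden module in tests). A target farther
than 0.05 (configurable) from any achievable value raises an error naming the
granularity. Background lesions are drawn uniformly outside all tract voxels.
The burden quantum scales with (single-streamline volume)/(bundle union
volume), so small grids need enough streamlines and jitter: ≥ 40 voxels per
axis with ≥ 30 streamlines/side keeps the quantum comfortably below the
default tolerance; the 16-voxel minimum is a hard floor, not a recommendation.

What the generator does **not** emulate: realistic lesion morphology
(lesions are scattered voxels, not confluent blobs), anatomy of real tracts,
longitudinal change, scanner/site effects, or EMR noise such as
miscoded diagnoses. Passing tests therefore establish the correctness of the
rules, geometry, and statistics under the planted structure — not clinical
validity on real cohorts. Two further honest caveats: the planted effects are
deliberately strong (Monte-Carlo power of the severity GAM is ~100% at the
defaults, far above real-world effect sizes), and because depression is
generated nested within the anxiety groups while UF burden is planted by
anxiety group, the UF~depression sensitivity model *does* detect an
association in synthetic cohorts — the structure, not the null result, is
what the suite mirrors there.

## Simulation sizes and determinism

All randomness flows from a single seed through named substreams (groups,
covariates, EMR, burdens, masks), so cohorts are byte-identical across reruns
after serialization. Monte-Carlo checks use 100 regenerated cohorts (n = 400,
table-level, no voxel planting) for power and 500 for type-I error; cohorts
are generated at the table level there because the quantity under test is the
GAM, with the full imaging path exercised separately by the burden tests and
the end-to-end demo (200 patients on a 48³ grid). A rare cohort draw whose
smallest group falls below the model's minimum is skipped and replaced by the
next seed. The bundled demo enriches the severe group (30/50/20%) so all
contrasts are estimable at n = 200.

## Known limitations

* Voxel membership is decided at sampled vertices; a segment that clips a
  voxel corner between two samples (possible only for oblique segments) can
  miss it. Exact refinement stability holds for axis-aligned segments.
* The GAM smoothing weight is selected by AIC, not REML; parametric-term
  inference at these sample sizes is insensitive to the difference (an
  independent cross-check against R mgcv with REML is included in the tests).
* Wald p-values from the Gaussian GLM machinery are normal-based rather than
  t-based; at n ≥ ~100 the difference is negligible, and the empirical type-I
  error of the full procedure is verified to sit in [0.03, 0.07].
* Nonlinear registration, lesion segmentation, and tractography are upstream
  of this package and out of scope; masks and bundles must already share a
  template space.
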