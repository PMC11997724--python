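# msburden

White-matter tract lesion burden and EMR-based anxiety phenotyping in
multiple sclerosis (MS).

Anxiety affects a majority of people with MS over their lifetime, and one
candidate mechanism is demyelinating injury to the uncinate fasciculus (UF) —
the tract connecting the orbitofrontal cortex with the amygdala, two core
nodes of anxiety and stress circuitry. `msburden` packages the full analysis
needed to test that hypothesis at cohort scale from routine clinical data:

1. **phenotype** — rule-based stratification of patients from structured EMR
   fields into *MS without anxiety*, *mild anxiety* (an F40/F41 diagnosis code
   **or** an anxiolytic prescription), and *severe anxiety* (both), with a
   PHQ-2/PHQ-9 screen of 0 required to confirm the asymptomatic comparator;
   plus a binary depression stratification and PROMIS physical/emotional
   functioning summary scores.
2. **burden** — streamline-filtering lesion burden. Given a binary lesion
   mask in template space and an atlas bundle (TRK/TCK), a streamline is
   *injured* if any point of its trajectory passes through a lesion voxel, and

   ```
   burden = mean(V_injured_L, V_injured_R) / mean(V_canonical_L, V_canonical_R)
   ```

   where each V is the volume of the union of voxels traversed by the
   relevant streamline set. Burden is dimensionless in [0, 1].
3. **stats** — Gaussian GAMs `burden ~ anxiety + sex + TBV + s(age)` with a
   penalized cubic spline of age, Wald T and two-sided p for the anxiety term
   (binary severe-vs-none diagnosis, or ordinal 0/1/2 severity), Cohen's
   f² = (R²_full − R²_reduced)/(1 − R²_full) with a percentile-bootstrap CI,
   an ANOVA/χ² demographic battery, Shapiro–Wilk + t-test PROMIS comparisons
   with Cohen's d, Benjamini–Hochberg FDR, and a specificity suite (fornix
   control tract, depression comparator, total lesion volume).
4. **synth** — a synthetic-cohort generator (EMR events, toy bilateral
   tract analogs, lesion masks planted to hit target burden values) so the
   whole pipeline is testable without patient data.
5. **pipeline** — end-to-end orchestration with a reproducibility manifest.

It is aimed at neuroimaging/biostatistics researchers who have lesion
segmentations and atlas bundles in a common template space and want a tested,
scriptable implementation of this burden metric and its statistical analysis.

## Worked example

The bundled demo generates a 200-patient synthetic cohort (enriched for
severe anxiety so every contrast is estimable at this size), plants a
positive UF burden–severity gradient, a null fornix overlap, and a
general-psychopathology gradient in total lesion volume, then runs every
stage:

```bash
msburden pipeline run-all --config src/msburden/data/demo_run.yaml
```

Output (`demo_out/report.txt`, abridged):

```
Anxiety strata: {"mild": 104, "none": 53, "severe": 37}
Mean PHQ-2 by stratum: {"mild": 0.567308, "none": 0.0, "severe": 1.148649}

Hypothesis models (unadjusted alpha = .05)
  uf_vs_anxiety_diagnosis: T = 17.92, P = 8.21e-72, Cohen f2 = 3.869 [95% CI 2.964-5.621], n = 90
  uf_vs_anxiety_severity: T = 15.15, P = 7.44e-52, Cohen f2 = 1.228 [95% CI 0.944-1.612], n = 194

Sensitivity models (BH-FDR within suite)
  fornix_burden ~ diagnosis_binary: T = 0.65, P(FDR) = 0.616, significant = False
  fornix_burden ~ severity_ordinal: T = 0.33, P(FDR) = 0.744, significant = False
  ...
  total_lesion_volume ~ depression_binary: T = 12.25, P(FDR) = 3.38e-34, significant = True
```

Reading the numbers: the no-anxiety group's mean PHQ-2 is exactly 0.00 — the
classification rule *requires* a zero screen, so this is forced, and it is a
useful end-to-end sanity check. The planted UF–severity effect is recovered
with a positive T at p < .05; the fornix (where no group effect was planted)
stays null; total lesion volume associates with anxiety and depression alike,
mirroring a general-psychopathology signal. Effect sizes are much larger than
in real cohorts because the generator's planted separation is deliberately
strong relative to its noise.

Each stage is also exposed on its own (`msburden synth make-cohort`,
`msburden phenotype classify`, `msburden burden score`, `msburden stats run`),
reading/writing CSV, NIfTI, and TRK/TCK; see `--help` on any verb.

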