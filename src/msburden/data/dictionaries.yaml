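# Default code/medication dictionaries for EMR phenotyping.
# These are configuration, not code: sites should replace them with their own
# formulary. Medication names are generic, lower-case.
anxiety_dx_prefixes: [F40, F41]
anxiolytic_meds:
  - alprazolam
  - buspirone
  - chlordiazepoxide
  - clonazepam
  - clorazepate
  - diazepam
  - hydroxyzine
  - lorazepam
  - oxazepam
  - temazepam
psych_dx_prefixes: [F]
# psych_meds is a superset used only for the "psychiatrically asymptomatic"
# criterion; anxiolytics and antidepressants are merged in automatically.
psych_meds:
  - aripiprazole
  - haloperidol
  - lamotrigine
  - lithium
  - olanzapine
  - quetiapine
  - risperidone
  - valproate
  - ziprasidone
depression_dx_prefixes: [F32, F33]
antidepressant_meds:
  - amitriptyline
  - bupropion
  - citalopram
  - desvenlafaxine
  - duloxetine
  - escitalopram
  - fluoxetine
  - mirtazapine
  - nortriptyline
  - paroxetine
  - sertraline
  - venlafaxine
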