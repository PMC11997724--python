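"""EMR rule-based psychiatric phenotyping for an MS cohort.

Anxiety is stratified into three groups from structured EMR fields, exploiting
known physician undercoding behaviour: an anxiety diagnosis code (F40/F41
block) *or* an anxiolytic prescription indicates some anxiety burden (mild);
the presence of *both* indicates psychopathology severe enough to be diagnosed
and treated (severe). Patients free of any psychiatric code or medication form
the no-anxiety comparator only when a PHQ-2 or PHQ-9 screen of 0 confirms the
absence of psychopathology; psych-free patients without such confirmation are
excluded. A binary depression stratification (F32/F33 or antidepressant) uses
the same asymptomatic comparator.

The code/medication dictionaries are configuration, not code: they ship as a
YAML default and can be replaced wholesale.
"""

from __future__ import annotations

import datetime as dt
import re
from dataclasses import dataclass, field
from importlib import resources
from statistics import fmean

import yaml

__all__ = [
    "PatientRecord",
    "CodeDictionaries",
    "AnxietyStratum",
    "PromisSummary",
    "PHYSICAL_DOMAINS",
    "EMOTIONAL_DOMAINS",
    "classify_anxiety",
    "classify_depression",
    "promis_summaries",
    "select_first_mri",
    "classify_table",
]

# PROMIS domains entering each summary score. Quality of life counts as
# emotional: it tracks psychiatric rather than physical impairment.
PHYSICAL_DOMAINS = (
    "physical_health",
    "physical_activities",
    "fatigue",
    "physical_impairment",
)
EMOTIONAL_DOMAINS = (
    "mental_health",
    "emotional_problems",
    "quality_of_life",
    "social_satisfaction",
    "social_activities",
    "mental_impairment",
)

_ICD10_RE = re.compile(r"^[A-Z][0-9][0-9A-Z](\.[0-9A-Z]{1,4})?$")

SEVERITY_CODE = {"none": 0, "mild": 1, "severe": 2}


class MalformedCodeError(ValueError):
    """One or more ICD-10 code strings do not parse."""


@dataclass
class PatientRecord:
    """One patient's structured EMR extract."""

    patient_id: str
    icd10_codes: set[str] = field(default_factory=set)
    medications: set[str] = field(default_factory=set)
    #: (instrument "PHQ2" | "PHQ9", integer score, date)
    phq_obs: list[tuple[str, int, dt.date]] = field(default_factory=list)
    #: (domain label, score, date)
    promis_obs: list[tuple[str, float, dt.date]] = field(default_factory=list)
    mri_dates: list[dt.date] = field(default_factory=list)
    age: float | None = None
    sex: str | None = None
    race: str | None = None
    total_brain_volume: float | None = None

    def __post_init__(self) -> None:
        self.icd10_codes = {str(c).strip().upper() for c in self.icd10_codes}
        self.medications = {str(m).strip().lower() for m in self.medications}
        for inst, score, _date in self.phq_obs:
            hi = 6 if inst.upper() == "PHQ2" else 27
            if not 0 <= int(score) <= hi:
                raise ValueError(
                    f"{self.patient_id}: {inst} score {score} outside [0, {hi}]"
                )


@dataclass
class CodeDictionaries:
    """Configurable ICD-10 prefix lists and medication name sets."""

    anxiety_dx_prefixes: list[str]
    anxiolytic_meds: set[str]
    psych_dx_prefixes: list[str]
    psych_meds: set[str]
    depression_dx_prefixes: list[str]
    antidepressant_meds: set[str]

    def __post_init__(self) -> None:
        self.anxiety_dx_prefixes = [p.upper() for p in self.anxiety_dx_prefixes]
        self.psych_dx_prefixes = [p.upper() for p in self.psych_dx_prefixes]
        self.depression_dx_prefixes = [p.upper() for p in self.depression_dx_prefixes]
        self.anxiolytic_meds = {m.lower() for m in self.anxiolytic_meds}
        self.psych_meds = {m.lower() for m in self.psych_meds} | self.anxiolytic_meds
        self.antidepressant_meds = {m.lower() for m in self.antidepressant_meds}
        self.psych_meds |= self.antidepressant_meds
        for name in ("anxiety_dx_prefixes", "psych_dx_prefixes", "depression_dx_prefixes"):
            vals = getattr(self, name)
            if not vals:
                raise ValueError(f"{name} must be non-empty")
            bad = [p for p in vals if not p.isalnum()]
            if bad:
                raise ValueError(f"{name}: non-alphanumeric prefixes {bad}")

    @classmethod
    def default(cls) -> "CodeDictionaries":
        """Dictionaries shipped with the package (data/dictionaries.yaml)."""
        text = resources.files("msburden.data").joinpath("dictionaries.yaml").read_text()
        return cls.from_mapping(yaml.safe_load(text))

    @classmethod
    def from_mapping(cls, m: dict) -> "CodeDictionaries":
        return cls(
            anxiety_dx_prefixes=list(m["anxiety_dx_prefixes"]),
            anxiolytic_meds=set(m["anxiolytic_meds"]),
            psych_dx_prefixes=list(m["psych_dx_prefixes"]),
            psych_meds=set(m.get("psych_meds", [])),
            depression_dx_prefixes=list(m["depression_dx_prefixes"]),
            antidepressant_meds=set(m["antidepressant_meds"]),
        )

    @classmethod
    def from_yaml(cls, path) -> "CodeDictionaries":
        with open(path) as fh:
            return cls.from_mapping(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        m = {
            "anxiety_dx_prefixes": sorted(self.anxiety_dx_prefixes),
            "anxiolytic_meds": sorted(self.anxiolytic_meds),
            "psych_dx_prefixes": sorted(self.psych_dx_prefixes),
            "psych_meds": sorted(self.psych_meds),
            "depression_dx_prefixes": sorted(self.depression_dx_prefixes),
            "antidepressant_meds": sorted(self.antidepressant_meds),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(m, fh, sort_keys=False)


@dataclass(frozen=True)
class AnxietyStratum:
    """Anxiety label plus the rule firings that produced it."""

    label: str  # none | mild | severe | excluded
    has_anx_dx: bool
    has_anxiolytic: bool
    psych_free: bool
    phq_zero_confirmed: bool


def _validate_codes(codes: set[str]) -> None:
    bad = sorted(c for c in codes if not _ICD10_RE.match(c))
    if bad:
        raise MalformedCodeError(f"malformed ICD-10 codes: {bad}")


def _matches_any(codes: set[str], prefixes: list[str]) -> bool:
    return any(c.startswith(p) for c in codes for p in prefixes)


def _phq_state(record: PatientRecord) -> tuple[bool, bool]:
    """(has any PHQ observation, all observed PHQ scores are zero)."""
    scores = [s for _inst, s, _d in record.phq_obs]
    return bool(scores), bool(scores) and all(s == 0 for s in scores)


def classify_anxiety(record: PatientRecord, dicts: CodeDictionaries) -> AnxietyStratum:
    """Stratify one patient: none / mild / severe / excluded.

    severe <=> anxiety diagnosis AND anxiolytic; mild <=> exactly one of the
    two; none requires a psychiatrically clean record (no F-chapter code, no
    psychotropic medication) plus at least one PHQ-2/PHQ-9 observation, all
    with score 0. Psych-free patients without PHQ confirmation (or with a
    nonzero PHQ) are excluded, as are patients with non-anxiety psychiatric
    codes or medications.
    """
    _validate_codes(record.icd10_codes)
    has_dx = _matches_any(record.icd10_codes, dicts.anxiety_dx_prefixes)
    has_med = bool(record.medications & dicts.anxiolytic_meds)
    psych_free = not _matches_any(record.icd10_codes, dicts.psych_dx_prefixes) and not (
        record.medications & dicts.psych_meds
    )
    _has_phq, phq_zero = _phq_state(record)

    if has_dx and has_med:
        label = "severe"
    elif has_dx or has_med:
        label = "mild"
    elif psych_free and phq_zero:
        label = "none"
    else:
        label = "excluded"
    return AnxietyStratum(label, has_dx, has_med, psych_free, phq_zero)


def classify_depression(record: PatientRecord, dicts: CodeDictionaries) -> str:
    """Binary depression stratification: depression / no_depression / excluded.

    Depression if a depression diagnosis code (F32/F33 by default) or an
    antidepressant is present (both also count). The no-depression comparator
    uses the same psychiatrically-asymptomatic criteria as the anxiety "none"
    group, including the PHQ = 0 confirmation.
    """
    _validate_codes(record.icd10_codes)
    has_dx = _matches_any(record.icd10_codes, dicts.depression_dx_prefixes)
    has_med = bool(record.medications & dicts.antidepressant_meds)
    if has_dx or has_med:
        return "depression"
    psych_free = not _matches_any(record.icd10_codes, dicts.psych_dx_prefixes) and not (
        record.medications & dicts.psych_meds
    )
    _has_phq, phq_zero = _phq_state(record)
    if psych_free and phq_zero:
        return "no_depression"
    return "excluded"


@dataclass(frozen=True)
class PromisSummary:
    physical: float | None
    emotional: float | None
    n_physical_domains: int
    n_emotional_domains: int


def promis_summaries(record: PatientRecord, mri_date: dt.date) -> PromisSummary:
    """Physical and emotional functioning summaries from PROMIS domains.

    Per domain, the observation most proximal in time to the MRI is used
    (ties broken toward the earlier observation). The physical summary is the
    mean over 4 physical domains, the emotional summary the mean over 6
    emotional domains; absent domains are skipped and counted. A summary with
    zero contributing domains is None.
    """
    if not record.promis_obs:
        raise ValueError(f"{record.patient_id}: no PROMIS observations")
    best: dict[str, tuple[float, dt.date]] = {}
    for domain, score, date in record.promis_obs:
        key = (abs((date - mri_date).days), date)
        if domain not in best or key < best[domain][1]:
            best[domain] = ((float(score)), key)  # type: ignore[assignment]
    # best maps domain -> (score, sort-key); unpack scores
    chosen = {d: v[0] for d, v in best.items()}
    phys = [chosen[d] for d in PHYSICAL_DOMAINS if d in chosen]
    emot = [chosen[d] for d in EMOTIONAL_DOMAINS if d in chosen]
    return PromisSummary(
        physical=fmean(phys) if phys else None,
        emotional=fmean(emot) if emot else None,
        n_physical_domains=len(phys),
        n_emotional_domains=len(emot),
    )


def select_first_mri(record: PatientRecord) -> dt.date:
    """Chronologically earliest MRI date (patients may have several scans)."""
    if not record.mri_dates:
        raise ValueError(f"{record.patient_id}: no MRI dates")
    return min(record.mri_dates)


def classify_table(records: list[PatientRecord], dicts: CodeDictionaries | None = None):
    """Per-patient phenotype table as a pandas DataFrame.

    Columns: patient_id, stratum, anxiety_severity_code (0/1/2, NaN when
    excluded), depression, phq2_mean, promis_physical, promis_emotional, age,
    sex, race, total_brain_volume.
    """
    import numpy as np
    import pandas as pd

    dicts = dicts or CodeDictionaries.default()
    rows = []
    for rec in records:
        stratum = classify_anxiety(rec, dicts)
        dep = classify_depression(rec, dicts)
        phq2 = [s for inst, s, _d in rec.phq_obs if inst.upper() == "PHQ2"]
        phys = emot = None
        if rec.promis_obs and rec.mri_dates:
            summ = promis_summaries(rec, select_first_mri(rec))
            phys, emot = summ.physical, summ.emotional
        rows.append(
            {
                "patient_id": rec.patient_id,
                "stratum": stratum.label,
                "anxiety_severity_code": SEVERITY_CODE.get(stratum.label, np.nan),
                "depression": dep,
                "phq2_mean": fmean(phq2) if phq2 else np.nan,
                "promis_physical": phys,
                "promis_emotional": emot,
                "age": rec.age,
                "sex": rec.sex,
                "race": rec.race,
                "total_brain_volume": rec.total_brain_volume,
            }
        )
    return pd.DataFrame(rows)
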