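"""File formats: EMR event CSV, covariates CSV, NIfTI masks, TRK/TCK bundles.

The EMR extract is a long-format CSV, one row per patient-event:

    patient_id, event_type, code_or_name, value, date

with event_type in {icd10, medication, phq2, phq9, promis_domain, mri}.
Covariates travel in a separate CSV keyed by patient_id. Masks are NIfTI-1
(qform/sform honoured); bundles are TRK or TCK with streamlines in world mm.
"""

from __future__ import annotations

import datetime as dt
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from nibabel.streamlines import TckFile, Tractogram, TrkFile

from .burden import LesionMask, TractBundle, VoxelGrid
from .phenotype import PatientRecord

EMR_EVENT_TYPES = ("icd10", "medication", "phq2", "phq9", "promis_domain", "mri")
EMR_COLUMNS = ("patient_id", "event_type", "code_or_name", "value", "date")
COVARIATE_COLUMNS = ("patient_id", "age", "sex", "race", "total_brain_volume_mm3")


class EmrSchemaError(ValueError):
    """EMR CSV does not conform to the long-event schema."""


def _parse_date(s) -> dt.date:
    return dt.date.fromisoformat(str(s))


def write_emr_csv(records: list[PatientRecord], path) -> None:
    rows = []
    for rec in records:
        pid = rec.patient_id
        for code in sorted(rec.icd10_codes):
            rows.append((pid, "icd10", code, "", ""))
        for med in sorted(rec.medications):
            rows.append((pid, "medication", med, "", ""))
        for inst, score, date in rec.phq_obs:
            rows.append((pid, inst.lower(), "", score, date.isoformat()))
        for domain, score, date in rec.promis_obs:
            rows.append((pid, "promis_domain", domain, score, date.isoformat()))
        for date in rec.mri_dates:
            rows.append((pid, "mri", "", "", date.isoformat()))
    pd.DataFrame(rows, columns=EMR_COLUMNS).to_csv(path, index=False)


def write_covariates_csv(records: list[PatientRecord], path) -> None:
    rows = [
        (r.patient_id, r.age, r.sex, r.race, r.total_brain_volume) for r in records
    ]
    pd.DataFrame(rows, columns=COVARIATE_COLUMNS).to_csv(path, index=False)


def validate_emr_frame(df: pd.DataFrame) -> list[str]:
    """Schema diagnostics for an EMR event frame; empty list means clean."""
    diags = []
    missing = [c for c in EMR_COLUMNS if c not in df.columns]
    if missing:
        return [f"missing columns: {missing}"]
    bad = df.loc[~df["event_type"].isin(EMR_EVENT_TYPES)]
    for i, row in bad.iterrows():
        diags.append(f"row {i}: unknown event_type {row['event_type']!r}")
    return diags


def read_emr_csv(emr_path, covariates_path=None) -> list[PatientRecord]:
    """Read the long-event EMR CSV (and optional covariates) into records."""
    df = pd.read_csv(emr_path, dtype={"patient_id": str}, keep_default_na=False)
    diags = validate_emr_frame(df)
    if diags:
        raise EmrSchemaError("; ".join(diags[:20]))
    cov = None
    if covariates_path is not None:
        cov = pd.read_csv(covariates_path, dtype={"patient_id": str}).set_index(
            "patient_id"
        )
    records = []
    for pid, g in df.groupby("patient_id", sort=True):
        rec = PatientRecord(patient_id=pid)
        for _, row in g.iterrows():
            et = row["event_type"]
            if et == "icd10":
                rec.icd10_codes.add(row["code_or_name"])
            elif et == "medication":
                rec.medications.add(row["code_or_name"])
            elif et in ("phq2", "phq9"):
                rec.phq_obs.append(
                    (et.upper(), int(float(row["value"])), _parse_date(row["date"]))
                )
            elif et == "promis_domain":
                rec.promis_obs.append(
                    (row["code_or_name"], float(row["value"]), _parse_date(row["date"]))
                )
            elif et == "mri":
                rec.mri_dates.append(_parse_date(row["date"]))
        rec.mri_dates.sort()
        if cov is not None and pid in cov.index:
            c = cov.loc[pid]
            rec.age = float(c["age"])
            rec.sex = str(c["sex"])
            rec.race = str(c.get("race", "")) or None
            rec.total_brain_volume = float(c["total_brain_volume_mm3"])
        # re-run validation from __post_init__
        PatientRecord.__post_init__(rec)
        records.append(rec)
    return records


# ---------------------------------------------------------------- imaging IO


def save_mask(mask: LesionMask, path) -> None:
    img = nib.Nifti1Image(mask.grid.astype(np.uint8), mask.affine)
    img.header.set_xyzt_units("mm")
    nib.save(img, str(path))


def load_mask(path) -> LesionMask:
    img = nib.load(str(path))
    return LesionMask(grid=np.asarray(img.get_fdata() > 0.5), affine=img.affine)


def save_bundle(bundle: TractBundle, path, grid: VoxelGrid | None = None) -> None:
    """Write a bundle as TRK or TCK (by extension); streamlines in world mm."""
    path = Path(path)
    sls = [s.astype(np.float32) for s in bundle.streamlines]
    tg = Tractogram(sls, affine_to_rasmm=np.eye(4))
    if path.suffix == ".trk":
        header = {}
        if grid is not None:
            header = {
                "voxel_to_rasmm": grid.affine.astype(np.float32),
                "voxel_sizes": tuple(
                    np.linalg.norm(grid.affine[:3, :3], axis=0).astype(np.float32)
                ),
                "dimensions": tuple(int(s) for s in grid.shape),
            }
        TrkFile(tg, header=header).save(str(path))
    elif path.suffix == ".tck":
        TckFile(tg).save(str(path))
    else:
        raise ValueError(f"unsupported bundle format: {path.suffix}")


def load_bundle(path, name: str | None = None) -> TractBundle:
    path = Path(path)
    if path.suffix not in (".trk", ".tck"):
        raise ValueError(f"unsupported bundle format: {path.suffix}")
    tf = nib.streamlines.load(str(path))  # streamlines come back in rasmm
    sls = [np.asarray(s, dtype=float) for s in tf.tractogram.streamlines]
    return TractBundle(name=name or path.stem, streamlines=sls)
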