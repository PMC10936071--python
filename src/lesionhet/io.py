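"""Cohort serialization: NIfTI lesion volumes plus CSV tables.

Layout written by :func:`save_cohort` (and read back by
:func:`load_cohort`)::

    out/
      images/<patient>/<lesion>_{ct,suv,mask}.nii.gz
      manifest.csv     # patient_id, lesion_id, region, spacing, paths
      clinical.csv     # covariates, one row per patient
      outcomes.csv     # pfs_time, pfs_event, os_time, os_event
      stains.csv       # weak/moderate/strong % per marker (scored patients)
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .types import (
    IMPLANT_REGIONS,
    LNM_SITES,
    ClinicalCovariates,
    LesionVOI,
    PatientCase,
    SurvivalOutcome,
    VoxelGrid,
)


def _affine(spacing: tuple[float, float, float]) -> np.ndarray:
    return np.diag(list(spacing) + [1.0])


def save_cohort(patients: list[PatientCase], out_dir: str | Path) -> Path:
    """Write lesion volumes and cohort tables under ``out_dir``."""
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    manifest_rows = []
    clinical_rows = {}
    outcome_rows = {}
    stain_rows = {}
    for p in patients:
        pdir = out / "images" / p.patient_id
        pdir.mkdir(exist_ok=True)
        for lesion in p.lesions:
            paths = {}
            arrays = {"ct": lesion.ct.values, "suv": lesion.suv.values,
                      "mask": lesion.mask.astype(np.uint8)}
            for kind, arr in arrays.items():
                path = pdir / f"{lesion.lesion_id}_{kind}.nii.gz"
                nib.save(nib.Nifti1Image(np.asarray(arr), _affine(lesion.spacing)), path)
                paths[kind] = str(path.relative_to(out))
            manifest_rows.append(
                {
                    "patient_id": p.patient_id,
                    "lesion_id": lesion.lesion_id,
                    "region": lesion.region,
                    "dx": lesion.spacing[0],
                    "dy": lesion.spacing[1],
                    "dz": lesion.spacing[2],
                    **{f"{k}_path": v for k, v in paths.items()},
                }
            )
        c = p.covariates
        row = {
            "age": c.age, "ca125": c.ca125, "figo_stage": c.figo_stage,
            "sur_status": c.sur_status, "ascites_volume": c.ascites_volume,
            "ascites_character": c.ascites_character, "n_implants": c.n_implants,
            "invasion_pattern": c.invasion_pattern, "solid_ratio": c.solid_ratio,
        }
        row.update({f"lnm_{s}": int(c.lnm[s]) for s in LNM_SITES})
        row.update({f"implant_{r}": int(c.implant_locations[r]) for r in IMPLANT_REGIONS})
        clinical_rows[p.patient_id] = row
        outcome_rows[p.patient_id] = {
            "pfs_time": p.pfs.time, "pfs_event": p.pfs.event,
            "os_time": p.os.time, "os_event": p.os.event,
        }
        if p.stain_fractions:
            srow = {}
            for marker, (w, m, s) in p.stain_fractions.items():
                key = marker.replace("-", "").lower()
                srow.update({f"{key}_weak": w, f"{key}_moderate": m, f"{key}_strong": s})
            stain_rows[p.patient_id] = srow
    pd.DataFrame(manifest_rows).to_csv(out / "manifest.csv", index=False)
    pd.DataFrame.from_dict(clinical_rows, orient="index").rename_axis("patient_id").to_csv(
        out / "clinical.csv"
    )
    pd.DataFrame.from_dict(outcome_rows, orient="index").rename_axis("patient_id").to_csv(
        out / "outcomes.csv"
    )
    if stain_rows:
        pd.DataFrame.from_dict(stain_rows, orient="index").rename_axis("patient_id").to_csv(
            out / "stains.csv"
        )
    return out


def load_cohort(cohort_dir: str | Path) -> list[PatientCase]:
    """Reconstruct :class:`PatientCase` objects from a saved cohort."""
    root = Path(cohort_dir)
    manifest = pd.read_csv(root / "manifest.csv")
    clinical = pd.read_csv(root / "clinical.csv", index_col="patient_id")
    outcomes = pd.read_csv(root / "outcomes.csv", index_col="patient_id")
    stains_path = root / "stains.csv"
    stains = pd.read_csv(stains_path, index_col="patient_id") if stains_path.exists() else None
    patients = []
    for patient_id, group in manifest.groupby("patient_id", sort=True):
        lesions = []
        for _, row in group.iterrows():
            spacing = (row["dx"], row["dy"], row["dz"])
            ct = np.asanyarray(nib.load(root / row["ct_path"]).dataobj, dtype=float)
            suv = np.asanyarray(nib.load(root / row["suv_path"]).dataobj, dtype=float)
            mask = np.asanyarray(nib.load(root / row["mask_path"]).dataobj) > 0
            lesions.append(
                LesionVOI(
                    lesion_id=row["lesion_id"], region=row["region"],
                    ct=VoxelGrid(ct, spacing), suv=VoxelGrid(suv, spacing), mask=mask,
                )
            )
        crow = clinical.loc[patient_id]
        covariates = ClinicalCovariates(
            age=float(crow["age"]),
            ca125=float(crow["ca125"]),
            figo_stage=str(crow["figo_stage"]),
            sur_status=str(crow["sur_status"]),
            ascites_volume=float(crow["ascites_volume"]),
            ascites_character=str(crow["ascites_character"]),
            lnm={s: bool(crow[f"lnm_{s}"]) for s in LNM_SITES},
            n_implants=int(crow["n_implants"]),
            implant_locations={r: bool(crow[f"implant_{r}"]) for r in IMPLANT_REGIONS},
            invasion_pattern=int(crow["invasion_pattern"]),
            solid_ratio=float(crow["solid_ratio"]),
        )
        orow = outcomes.loc[patient_id]
        stain_fractions = None
        if stains is not None and patient_id in stains.index:
            srow = stains.loc[patient_id]
            stain_fractions = {}
            for marker, key in (("p53", "p53"), ("Ki-67", "ki67")):
                cols = [f"{key}_weak", f"{key}_moderate", f"{key}_strong"]
                if all(c in srow.index for c in cols) and not srow[cols].isna().any():
                    stain_fractions[marker] = tuple(float(srow[c]) for c in cols)
            stain_fractions = stain_fractions or None
        patients.append(
            PatientCase(
                patient_id=str(patient_id),
                lesions=lesions,
                covariates=covariates,
                pfs=SurvivalOutcome(float(orow["pfs_time"]), int(orow["pfs_event"])),
                os=SurvivalOutcome(float(orow["os_time"]), int(orow["os_event"])),
                stain_fractions=stain_fractions,
            )
        )
    return patients
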