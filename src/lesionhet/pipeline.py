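"""Patient- and cohort-level feature extraction.

Glue between the per-lesion operators and the modeling layer: applies the
VOI inclusion rules, computes the 8 conventional measurements per lesion,
and assembles the 107-entry patient heterogeneity vector (104 cross-lesion
statistics + cSE, cluDev, cluDiss).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .measurements import filter_vois, measure_lesion
from .stats import ALL_METRIC_NAMES, CONVENTIONAL_METRIC_NAMES, conventional_heterogeneity
from .texture import TextureConfig, texture_heterogeneity_vector
from .types import LesionVOI, PatientCase, PatientExclusionError, VoxelGrid


def lesion_measurement_table(patients: list[PatientCase], apply_filter: bool = True) -> pd.DataFrame:
    """Per-lesion conventional measurements (one row per kept lesion)."""
    rows = []
    for p in patients:
        lesions = filter_vois(p.lesions) if apply_filter else p.lesions
        for lesion in lesions:
            row = {"patient_id": p.patient_id, "lesion_id": lesion.lesion_id, "region": lesion.region}
            row.update(measure_lesion(lesion).as_dict())
            rows.append(row)
    return pd.DataFrame(rows)


def heterogeneity_vector(
    patient: PatientCase,
    texture_config: TextureConfig | None = None,
    include_texture: bool = True,
) -> pd.Series:
    """The named heterogeneity metrics of one patient.

    Raises :class:`PatientExclusionError` if fewer than two lesions pass
    the VOI filter (inter-tumor metrics need the primary plus >= 1 implant).
    """
    kept = filter_vois(patient.lesions)
    if len(kept) < 2:
        raise PatientExclusionError(
            f"{patient.patient_id}: fewer than 2 lesions pass the VOI filter"
        )
    values = conventional_heterogeneity([measure_lesion(l) for l in kept])
    if include_texture:
        values.update(texture_heterogeneity_vector(kept, texture_config).as_dict())
        names = ALL_METRIC_NAMES
    else:
        names = CONVENTIONAL_METRIC_NAMES
    return pd.Series([values[n] for n in names], index=list(names), name=patient.patient_id)


def heterogeneity_table(
    patients: list[PatientCase],
    texture_config: TextureConfig | None = None,
    include_texture: bool = True,
) -> pd.DataFrame:
    """Patient x metric heterogeneity table for a cohort."""
    return pd.DataFrame(
        [heterogeneity_vector(p, texture_config, include_texture) for p in patients]
    )


def reextract_with_perturbed_masks(
    patients: list[PatientCase],
    magnitude_mm: float,
    seed: int = 0,
    texture_config: TextureConfig | None = None,
    include_texture: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Test-retest harness: extract, perturb every mask, extract again.

    Emulates a second observer re-delineating every lesion with boundary
    noise of the given magnitude; returns the (original, re-extracted)
    heterogeneity tables for reliability screening.
    """
    from .synthetic import perturb_segmentation  # local import to avoid a cycle

    run1 = heterogeneity_table(patients, texture_config, include_texture)
    rng = np.random.default_rng(seed)
    perturbed = []
    for p in patients:
        lesions = [
            LesionVOI(
                lesion_id=l.lesion_id,
                region=l.region,
                ct=VoxelGrid(l.ct.values, l.spacing),
                suv=VoxelGrid(l.suv.values, l.spacing),
                mask=perturb_segmentation(l.mask, magnitude_mm, l.spacing, rng),
            )
            for l in p.lesions
        ]
        perturbed.append(
            PatientCase(
                patient_id=p.patient_id,
                lesions=lesions,
                covariates=p.covariates,
                pfs=p.pfs,
                os=p.os,
                stain_fractions=p.stain_fractions,
            )
        )
    run2 = heterogeneity_table(perturbed, texture_config, include_texture)
    return run1, run2
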