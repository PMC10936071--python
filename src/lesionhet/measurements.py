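"""Conventional per-lesion measurements and VOI inclusion rules.

Each lesion passing the size filter yields eight conventional measurements:
voxel count (Pixel_number), major/minor axis length in mm (Maj, Min), mean
CT value in HU, SUVmax, SUVmean, SUVpeak and total lesion glycolysis
(TLG = SUVmean x metabolic volume in mL).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .types import LesionVOI, PatientExclusionError, as_bool_array

#: Minimum bounding-box extent (strict, per dimension) for a VOI, mm.
MIN_VOI_EXTENT_MM = 5.0
#: Radius of the 1 cm^3 SUVpeak sphere, mm.
PEAK_SPHERE_RADIUS_MM = (3.0 / (4.0 * np.pi) * 1000.0) ** (1.0 / 3.0)  # ~6.2 mm


@dataclass
class ConventionalMeasurements:
    """The eight conventional measurements of one VOI."""

    pixel_number: int
    maj: float
    min: float
    hu: float
    suv_max: float
    suv_mean: float
    suv_peak: float
    tlg: float

    FIELDS = ("pixel_number", "maj", "min", "hu", "suv_max", "suv_mean", "suv_peak", "tlg")

    def as_dict(self) -> dict[str, float]:
        return {name: float(getattr(self, name)) for name in self.FIELDS}


def _bbox_extent_mm(mask: np.ndarray, spacing: tuple[float, float, float]) -> np.ndarray:
    """Axis-aligned bounding-box extent of the mask in mm per dimension."""
    idx = np.nonzero(mask)
    return np.array(
        [(idx[d].max() - idx[d].min() + 1) * spacing[d] for d in range(3)], dtype=float
    )


def filter_vois(lesions: list[LesionVOI]) -> list[LesionVOI]:
    """Apply the VOI inclusion rules.

    A lesion is kept only if its mask bounding box exceeds 5 mm in every
    dimension (strict), and within each region code only the lesion with
    the largest voxel count survives.  The primary lesion is subject to
    the same size rule.

    Raises
    ------
    PatientExclusionError
        If no lesion passes, mirroring cohort exclusion of patients
        without measurable disease.
    """
    sized = [
        l
        for l in lesions
        if np.all(_bbox_extent_mm(l.mask, l.spacing) > MIN_VOI_EXTENT_MM)
    ]
    by_region: dict[str, LesionVOI] = {}
    for lesion in sized:
        best = by_region.get(lesion.region)
        if best is None or pixel_number(lesion.mask) > pixel_number(best.mask):
            by_region[lesion.region] = lesion
    kept = [l for l in lesions if by_region.get(l.region) is l]
    if not kept:
        raise PatientExclusionError("no lesion passes the VOI inclusion rules")
    return kept


def pixel_number(mask: np.ndarray) -> int:
    """Number of voxels in the mask."""
    mask = as_bool_array(mask)
    n = int(np.count_nonzero(mask))
    if n == 0:
        raise ValueError("empty mask")
    return n


def axis_lengths(mask: np.ndarray, spacing: tuple[float, float, float]) -> tuple[float, float]:
    """Major and minor axis lengths (mm) of the masked voxel cloud.

    Principal axes come from the eigen-decomposition of the physical
    coordinate covariance; an axis length is reported as ``2 * sqrt(5 *
    eigenvalue)``, which is exact for a solid ellipsoid (a uniform ball of
    diameter d has coordinate variance d^2/20 along every axis).
    """
    mask = as_bool_array(mask)
    coords = np.argwhere(mask).astype(float) * np.asarray(spacing, dtype=float)
    if coords.shape[0] < 2:
        warnings.warn("single-voxel mask: axis lengths degenerate to 0", stacklevel=2)
        return 0.0, 0.0
    cov = np.cov(coords, rowvar=False, ddof=0)
    eig = np.clip(np.linalg.eigvalsh(cov), 0.0, None)
    lengths = 2.0 * np.sqrt(5.0 * eig)
    return float(lengths.max()), float(lengths.min())


def _sphere_kernel(spacing: tuple[float, float, float], radius_mm: float) -> np.ndarray:
    half = [int(np.floor(radius_mm / s)) for s in spacing]
    grids = np.meshgrid(
        *[np.arange(-h, h + 1) * s for h, s in zip(half, spacing)], indexing="ij"
    )
    dist2 = sum(g**2 for g in grids)
    return (dist2 <= radius_mm**2).astype(float)


def suv_peak(
    suv: np.ndarray,
    mask: np.ndarray,
    spacing: tuple[float, float, float],
    radius_mm: float = PEAK_SPHERE_RADIUS_MM,
) -> float:
    """SUVpeak: the maximal mean SUV within a 1 cm^3 sphere centred on a
    masked voxel, the sphere being clipped to the mask."""
    mask = as_bool_array(mask)
    if not mask.any():
        raise ValueError("empty mask")
    suv = np.asarray(suv, dtype=float)
    kernel = _sphere_kernel(spacing, radius_mm)
    m = mask.astype(float)
    num = signal.fftconvolve(suv * m, kernel, mode="same")
    den = signal.fftconvolve(m, kernel, mode="same")
    with np.errstate(invalid="ignore", divide="ignore"):
        sphere_mean = num / den
    return float(np.nanmax(sphere_mean[mask]))


def tlg(suv: np.ndarray, mask: np.ndarray, spacing: tuple[float, float, float]) -> float:
    """Total lesion glycolysis: SUVmean x metabolic volume (mL)."""
    mask = as_bool_array(mask)
    if not mask.any():
        raise ValueError("empty mask")
    voxel_ml = float(np.prod(spacing)) / 1000.0
    values = np.asarray(suv, dtype=float)[mask]
    return float(values.mean() * values.size * voxel_ml)


def measure_lesion(lesion: LesionVOI) -> ConventionalMeasurements:
    """Compute all eight conventional measurements for one lesion."""
    mask = lesion.mask
    spacing = lesion.spacing
    ct_vals = lesion.ct.values[mask]
    suv_vals = lesion.suv.values[mask]
    maj, mn = axis_lengths(mask, spacing)
    return ConventionalMeasurements(
        pixel_number=pixel_number(mask),
        maj=maj,
        min=mn,
        hu=float(ct_vals.mean()),
        suv_max=float(suv_vals.max()),
        suv_mean=float(suv_vals.mean()),
        suv_peak=suv_peak(lesion.suv.values, mask, spacing),
        tlg=tlg(lesion.suv.values, mask, spacing),
    )
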