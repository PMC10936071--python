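"""Core domain containers for multi-lesion PET/CT heterogeneity analysis.

A patient carries one primary ovarian lesion plus 1-9 peritoneal metastatic
implants, each delineated as a volume of interest (VOI) on co-registered
CT (Hounsfield units) and PET (standardized uptake value, SUV) grids.
Implant locations are encoded with the 9-zone abdominopelvic code
AR-0 ... AR-8; the primary lesion carries the special code ``primary``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

#: 9-zone abdominopelvic location code for metastatic implants.
IMPLANT_REGIONS: tuple[str, ...] = tuple(f"AR-{i}" for i in range(9))
#: Region code reserved for the primary ovarian lesion.
PRIMARY_REGION: str = "primary"
#: All allowed region codes.
ALL_REGIONS: tuple[str, ...] = IMPLANT_REGIONS + (PRIMARY_REGION,)

FIGO_STAGES: tuple[str, ...] = ("IIB", "IIIA", "IIIB", "IIIC", "IVA", "IVB")
SUR_STATUSES: tuple[str, ...] = ("R0", "R1", "R2")
ASCITES_CHARACTERS: tuple[str, ...] = ("none", "bloody", "non-bloody")
LNM_SITES: tuple[str, ...] = ("pelvic", "middle_abdominal", "upper_abdominal", "distant")


class PatientExclusionError(RuntimeError):
    """Raised when a patient cannot enter the analysis (e.g. no VOI passes
    the size filter, or fewer than two lesions remain)."""


@dataclass(eq=False)
class VoxelGrid:
    """A 3-D image block with physical voxel spacing in millimetres."""

    values: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3 or self.values.size == 0:
            raise ValueError("VoxelGrid requires a non-empty 3-D array")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be three positive lengths (mm)")

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))


@dataclass(eq=False)
class LesionVOI:
    """One delineated lesion: CT and SUV sub-volumes plus a binary mask.

    ``ct``, ``suv`` and ``mask`` share shape and spacing; the mask marks the
    solid lesion component on which all measurements operate.
    """

    lesion_id: str
    region: str
    ct: VoxelGrid
    suv: VoxelGrid
    mask: np.ndarray

    def __post_init__(self) -> None:
        if self.region not in ALL_REGIONS:
            raise ValueError(f"unknown region code {self.region!r}")
        self.mask = np.asarray(self.mask).astype(bool)
        if not (self.ct.values.shape == self.suv.values.shape == self.mask.shape):
            raise ValueError("ct, suv and mask must share one shape")
        if self.ct.spacing != self.suv.spacing:
            raise ValueError("ct and suv must share voxel spacing")
        if not self.mask.any():
            raise ValueError("lesion mask is empty")

    @property
    def spacing(self) -> tuple[float, float, float]:
        return self.ct.spacing


@dataclass
class ClinicalCovariates:
    """Baseline clinical description of one patient."""

    age: float
    ca125: float
    figo_stage: str
    sur_status: str
    ascites_volume: float
    ascites_character: str
    lnm: dict[str, bool]
    n_implants: int
    implant_locations: dict[str, bool]
    invasion_pattern: int
    solid_ratio: float

    def __post_init__(self) -> None:
        if self.figo_stage not in FIGO_STAGES:
            raise ValueError(f"unknown FIGO stage {self.figo_stage!r}")
        if self.sur_status not in SUR_STATUSES:
            raise ValueError(f"unknown surgical status {self.sur_status!r}")
        if self.ascites_character not in ASCITES_CHARACTERS:
            raise ValueError(f"unknown ascites character {self.ascites_character!r}")
        if set(self.lnm) != set(LNM_SITES):
            raise ValueError("lnm must carry the four nodal-site flags")
        if set(self.implant_locations) != set(IMPLANT_REGIONS):
            raise ValueError("implant_locations must carry the nine AR flags")
        if not 0.0 <= self.solid_ratio <= 1.0:
            raise ValueError("solid_ratio must lie in [0, 1]")
        if self.n_implants < 1:
            raise ValueError("inter-tumor analysis requires >= 1 implant")
        if not 0 <= int(self.invasion_pattern) <= 4:
            raise ValueError("invasion_pattern is ordinal 0-4")


@dataclass
class SurvivalOutcome:
    """Follow-up time in days and an event indicator (1 = event observed)."""

    time: float
    event: int

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError("survival time must be >= 0")
        self.event = int(self.event)
        if self.event not in (0, 1):
            raise ValueError("event must be 0 or 1")


@dataclass(eq=False)
class PatientCase:
    """All per-patient inputs: lesions, covariates, outcomes, optional stains.

    ``stain_fractions`` maps a marker name (``p53``, ``Ki-67``) to a
    (weak %, moderate %, strong %) staining triple.
    """

    patient_id: str
    lesions: list[LesionVOI]
    covariates: ClinicalCovariates
    pfs: SurvivalOutcome
    os: SurvivalOutcome
    stain_fractions: dict[str, tuple[float, float, float]] | None = None

    def __post_init__(self) -> None:
        if len(self.lesions) < 2:
            raise ValueError("a patient needs the primary plus >= 1 implant")
        regions = [l.region for l in self.lesions]
        if len(set(regions)) != len(regions):
            raise ValueError("at most one lesion per region code")
        if regions.count(PRIMARY_REGION) != 1:
            raise ValueError("exactly one primary lesion is required")

    @property
    def primary(self) -> LesionVOI:
        return next(l for l in self.lesions if l.region == PRIMARY_REGION)


@dataclass
class SimulationConfig:
    """Knobs of the synthetic phantom cohort.

    The planted linear predictor is
    ``sum_m beta_m z(metric_m) + sum_c gamma_c z(covariate_c)`` with
    z-scores taken over the generated cohort; event times are exponential
    with rate ``baseline_rate * exp(lp)`` and censoring is the minimum of a
    uniform dropout draw and an administrative horizon.
    """

    n_train: int = 200
    n_test: int = 80
    lesions_per_patient: tuple[int, int] = (1, 9)  # number of implants
    lesion_diameter: tuple[float, float] = (8.0, 22.0)  # implant diameter, mm
    primary_diameter: tuple[float, float] = (20.0, 40.0)  # primary diameter, mm
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)  # isotropic grid, mm
    heterogeneity_effect: dict[str, float] = field(
        default_factory=lambda: {"SUVmean_Std_dev": 0.7, "TLG_CV": 0.5}
    )
    clinical_effect: dict[str, float] = field(
        default_factory=lambda: {"figo_stage": 0.4, "sur_status": 0.35, "ca125": 0.3}
    )
    baseline_rate: float = float(np.log(2) / 650.0)  # PFS events/day
    baseline_rate_os: float = float(np.log(2) / 1020.0)  # OS events/day
    censor_admin: float = 2200.0  # administrative horizon, days
    dropout_upper: float = 6600.0  # uniform dropout upper bound, days
    rho_target: float = 0.85  # Spearman target for H-score vs risk
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_train < 1 or self.n_test < 0:
            raise ValueError("cohort sizes must be positive")
        lo, hi = self.lesions_per_patient
        if not (1 <= lo <= hi <= 9):
            raise ValueError("implants per patient must lie in [1, 9]")
        if self.baseline_rate <= 0 or self.baseline_rate_os <= 0:
            raise ValueError("baseline rates must be > 0")
        if not -1.0 <= self.rho_target <= 1.0:
            raise ValueError("rho_target must lie in [-1, 1]")
        if self.censor_admin < 0 or self.dropout_upper < 0:
            raise ValueError("censoring horizons must be >= 0")


def as_bool_array(mask: np.ndarray | Sequence) -> np.ndarray:
    """Coerce a mask-like input to a boolean ndarray."""
    return np.asarray(mask).astype(bool)
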