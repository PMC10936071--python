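"""Synthetic phantom cohort with known ground truth.

Emulates the study conditions the pipeline is designed for: each patient
carries one primary ovarian lesion plus 1-9 peritoneal implants placed in
the 9-zone abdominopelvic code, lesion intensities with controllable
between-lesion dispersion, clinical covariates drawn from published
category frequencies, exponential-baseline survival driven by a planted
linear predictor, and immunohistochemistry H-scores coupled to risk
through a Gaussian copula at a configurable Spearman target.

Every generator is a pure function of (config, seed); a single global seed
is expanded into per-patient substreams by a counter-based spawn-key
scheme so cohorts are reproducible under any generation order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.special import ndtri
from scipy.stats import norm, rankdata

from . import stats as het_stats
from .measurements import filter_vois, measure_lesion
from .texture import TextureConfig, texture_heterogeneity_vector
from .types import (
    ASCITES_CHARACTERS,
    FIGO_STAGES,
    IMPLANT_REGIONS,
    LNM_SITES,
    PRIMARY_REGION,
    SUR_STATUSES,
    ClinicalCovariates,
    LesionVOI,
    PatientCase,
    SimulationConfig,
    SurvivalOutcome,
    VoxelGrid,
)

# Default clinical category frequencies (training-cohort marginals of the
# emulated study population).
FIGO_PROBS = dict(zip(FIGO_STAGES, (0.0144, 0.0288, 0.0962, 0.5721, 0.1587, 0.1298)))
SUR_STATUS_PROBS = dict(zip(SUR_STATUSES, (0.5721, 0.2019, 0.2260)))
ASCITES_PROBS = dict(zip(ASCITES_CHARACTERS, (0.0433, 0.3029, 0.6538)))
LNM_PROBS = dict(zip(LNM_SITES, (0.3558, 0.3029, 0.2933, 0.1250)))
INVASION_PROBS = (0.1106, 0.2019, 0.2452, 0.2500, 0.1923)


def _normalized(probs: dict[str, float]) -> tuple[list[str], np.ndarray]:
    keys = list(probs)
    p = np.array([probs[k] for k in keys], dtype=float)
    return keys, p / p.sum()


@dataclass
class LesionIntensity:
    """Target intensity statistics of one lesion."""

    hu_mean: float = 40.0
    suv_mean: float = 5.0
    hu_sd: float = 12.0
    suv_sd: float = 1.0


@dataclass
class LesionTexture:
    """Spatial correlation scale (mm) of the within-lesion noise texture."""

    correlation_mm: float = 2.0


def _correlated_field(rng: np.random.Generator, shape, sigma_vox, mask=None) -> np.ndarray:
    """Unit-SD spatially correlated Gaussian field; the SD is normalized
    over ``mask`` (when given) so masked statistics hit their target."""
    white = rng.standard_normal(shape)
    smooth = ndimage.gaussian_filter(white, sigma=sigma_vox)
    ref = smooth if mask is None else smooth[mask]
    sd = ref.std()
    return smooth / sd if sd > 0 else smooth


def generate_lesion_phantom(
    region: str,
    diameter_mm: float,
    intensity_params: LesionIntensity | None = None,
    texture_params: LesionTexture | None = None,
    seed: int | np.random.Generator = 0,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    lesion_id: str = "lesion",
) -> LesionVOI:
    """An ellipsoidal lesion filled with spatially correlated Gaussian noise.

    CT and SUV grids are drawn around the requested means with the
    requested SDs (the realized field is renormalized so its global SD
    matches exactly); the mask is the inscribed ellipsoid of the requested
    diameter.  Deterministic given the seed.
    """
    if diameter_mm <= 0:
        raise ValueError("diameter must be > 0")
    intensity = intensity_params or LesionIntensity()
    texture = texture_params or LesionTexture()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    spacing = tuple(float(s) for s in spacing)
    radii_vox = np.array([diameter_mm / 2.0 / s for s in spacing])
    pad = 3
    shape = tuple(int(np.ceil(2 * r)) + 2 * pad + 1 for r in radii_vox)
    center = np.array([(n - 1) / 2.0 for n in shape])
    grids = np.meshgrid(*[np.arange(n) for n in shape], indexing="ij")
    rho2 = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, center, radii_vox))
    mask = rho2 <= 1.0
    sigma_vox = [texture.correlation_mm / s for s in spacing]
    ct = intensity.hu_mean + intensity.hu_sd * _correlated_field(rng, shape, sigma_vox, mask)
    suv = intensity.suv_mean + intensity.suv_sd * _correlated_field(rng, shape, sigma_vox, mask)
    suv = np.clip(suv, 0.0, None)
    return LesionVOI(
        lesion_id=lesion_id,
        region=region,
        ct=VoxelGrid(ct, spacing),
        suv=VoxelGrid(np.asarray(suv, dtype=float), spacing),
        mask=mask,
    )


def _patient_rng(seed: int, patient_index: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(patient_index, stream)))


def _draw_covariates(rng: np.random.Generator, implant_regions: list[str]) -> ClinicalCovariates:
    figo_keys, figo_p = _normalized(FIGO_PROBS)
    sur_keys, sur_p = _normalized(SUR_STATUS_PROBS)
    asc_keys, asc_p = _normalized(ASCITES_PROBS)
    ascites_character = rng.choice(asc_keys, p=asc_p)
    ascites_volume = 0.0 if ascites_character == "none" else float(
        np.exp(rng.normal(np.log(1500.0), 1.1))
    )
    return ClinicalCovariates(
        age=float(np.clip(rng.normal(54.0, 9.4), 18.0, 95.0)),
        ca125=float(np.exp(rng.normal(np.log(867.0), 0.9))),
        figo_stage=str(rng.choice(figo_keys, p=figo_p)),
        sur_status=str(rng.choice(sur_keys, p=sur_p)),
        ascites_volume=ascites_volume,
        ascites_character=str(ascites_character),
        lnm={site: bool(rng.random() < LNM_PROBS[site]) for site in LNM_SITES},
        n_implants=len(implant_regions),
        implant_locations={r: r in implant_regions for r in IMPLANT_REGIONS},
        invasion_pattern=int(rng.choice(5, p=np.asarray(INVASION_PROBS) / np.sum(INVASION_PROBS))),
        solid_ratio=float(rng.beta(5.0, 2.0)),
    )


def generate_patient(
    config: SimulationConfig,
    patient_index: int,
    seed: int | None = None,
    linear_predictor: float = 0.0,
) -> PatientCase:
    """One phantom patient: lesions, covariates and survival outcomes.

    The per-patient substream is derived from (seed, patient_index), so a
    cohort is reproducible patient by patient.  ``linear_predictor`` scales
    the event hazard; cohort-level generation replaces it with the planted
    cohort-standardized predictor (see :func:`generate_cohort`).
    """
    seed = config.seed if seed is None else seed
    rng = _patient_rng(seed, patient_index, 0)
    lo, hi = config.lesions_per_patient
    k = int(rng.integers(lo, hi + 1))
    regions = list(rng.choice(IMPLANT_REGIONS, size=k, replace=False))

    # patient-level latents: intensity bases and a between-lesion
    # dispersion multiplier driving true inter-tumor heterogeneity
    dispersion = float(rng.lognormal(0.0, 0.5))
    hu_base = float(rng.normal(45.0, 10.0))
    suv_base = float(max(1.5, rng.normal(6.0, 2.0)))

    lesions = []
    for j, region in enumerate([PRIMARY_REGION] + regions):
        if region == PRIMARY_REGION:
            diameter = float(rng.uniform(*config.primary_diameter))
        else:
            diameter = float(rng.uniform(*config.lesion_diameter))
        intensity = LesionIntensity(
            hu_mean=hu_base + float(rng.normal(0.0, 8.0 * dispersion)),
            suv_mean=float(max(0.5, suv_base + rng.normal(0.0, 1.2 * dispersion))),
            hu_sd=float(rng.uniform(8.0, 16.0)),
            suv_sd=float(rng.uniform(0.5, 1.5)),
        )
        lesions.append(
            generate_lesion_phantom(
                region,
                diameter,
                intensity,
                LesionTexture(correlation_mm=float(rng.uniform(1.5, 3.0))),
                seed=rng,
                spacing=config.spacing,
                lesion_id=f"P{patient_index:04d}-L{j}",
            )
        )
    covariates = _draw_covariates(rng, regions)
    pfs = simulate_survival(
        linear_predictor, config.baseline_rate, config.censor_admin,
        _patient_rng(seed, patient_index, 1), dropout_upper=config.dropout_upper,
    )
    osv = simulate_survival(
        linear_predictor, config.baseline_rate_os, config.censor_admin,
        _patient_rng(seed, patient_index, 2), dropout_upper=config.dropout_upper,
    )
    return PatientCase(
        patient_id=f"P{patient_index:04d}",
        lesions=lesions,
        covariates=covariates,
        pfs=pfs,
        os=osv,
    )


def simulate_survival(
    linear_predictor: float,
    baseline_rate: float,
    censor_admin: float,
    seed: int | np.random.Generator,
    dropout_upper: float | None = None,
) -> SurvivalOutcome:
    """Exponential event time with rate ``baseline_rate * exp(lp)``,
    censored at the minimum of a uniform dropout draw and the
    administrative horizon."""
    if baseline_rate <= 0:
        raise ValueError("baseline_rate must be > 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if dropout_upper is None:
        dropout_upper = 3.0 * censor_admin
    rate = baseline_rate * float(np.exp(linear_predictor))
    t_event = rng.exponential(1.0 / rate)
    t_censor = min(rng.uniform(0.0, dropout_upper) if dropout_upper > 0 else 0.0, censor_admin)
    event = int(t_event <= t_censor)
    return SurvivalOutcome(time=min(t_event, t_censor), event=event)


def simulate_h_scores(
    risk_scores, rho_target: float, seed: int | np.random.Generator
) -> np.ndarray:
    """Staining triples whose H-score tracks risk at a Spearman target.

    A Gaussian copula couples the normal scores of the risk ranks to a
    latent stain variable; the latent Pearson correlation is pre-warped by
    ``2 sin(pi rho/6)`` so the *Spearman* correlation converges to
    ``rho_target``.  The latent variable maps monotonically to an H-score
    in [0, 300], which is then decomposed into a random but consistent
    (weak %, moderate %, strong %) triple with weak+moderate+strong <= 100.
    """
    if not -1.0 <= rho_target <= 1.0:
        raise ValueError("rho_target must lie in [-1, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    risk = np.asarray(risk_scores, dtype=float)
    n = risk.size
    u = (rankdata(risk) - 0.5) / n
    z_risk = ndtri(u)
    rho_latent = float(np.clip(2.0 * np.sin(np.pi * rho_target / 6.0), -1.0, 1.0))
    z_h = rho_latent * z_risk + np.sqrt(1.0 - rho_latent**2) * rng.standard_normal(n)
    h = 300.0 * norm.cdf(z_h)
    # feasible stained-fraction total S lies in [h/3, min(100, h)]
    s_total = h / 3.0 + rng.uniform(size=n) * (np.minimum(100.0, h) - h / 3.0)
    st_lo = np.maximum(0.0, h - 2.0 * s_total)
    st_hi = (h - s_total) / 2.0
    strong = st_lo + rng.uniform(size=n) * (st_hi - st_lo)
    moderate = h - s_total - 2.0 * strong
    weak = s_total - moderate - strong
    return np.column_stack([weak, moderate, strong])


def perturb_segmentation(
    mask: np.ndarray,
    magnitude_mm: float,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Randomly dilate/erode boundary patches by up to ``magnitude_mm``.

    A smooth random field perturbs the signed Euclidean distance to the
    lesion surface; displacements are clipped at the magnitude.  Magnitude
    0 returns the mask unchanged; a perturbation that would empty the mask
    is retried at half magnitude with a warning.
    """
    if magnitude_mm < 0:
        raise ValueError("magnitude must be >= 0")
    mask = np.asarray(mask).astype(bool)
    if magnitude_mm == 0:
        return mask.copy()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    spacing = tuple(float(s) for s in spacing)
    # voxel centres sit half a voxel from the surface, so shift the signed
    # distance by h/2 to make boundary voxels reachable by ~h perturbations
    h = min(spacing)
    d_in = ndimage.distance_transform_edt(mask, sampling=spacing)
    d_out = ndimage.distance_transform_edt(~mask, sampling=spacing)
    signed = np.where(mask, d_in - 0.5 * h, -(d_out - 0.5 * h))
    sigma_vox = [3.0 / s for s in spacing]
    field = _correlated_field(rng, mask.shape, sigma_vox)
    mag = magnitude_mm
    while True:
        shift = np.clip(field * mag, -mag, mag)
        new_mask = (signed + shift) > 0
        if new_mask.any():
            return new_mask
        mag /= 2.0
        warnings.warn(
            f"perturbation emptied the mask; magnitude reduced to {mag:.3g} mm",
            stacklevel=2,
        )


@dataclass
class Cohort:
    """A generated cohort plus its planted ground truth."""

    patients: list[PatientCase]
    config: SimulationConfig
    linear_predictor: pd.Series  # planted per-patient log-hazard shift
    train_ids: list[str]
    test_ids: list[str]
    metrics: pd.DataFrame | None = None  # heterogeneity metrics computed while planting

    def outcome_frame(self, endpoint: str) -> pd.DataFrame:
        if endpoint not in ("pfs", "os"):
            raise ValueError("endpoint must be 'pfs' or 'os'")
        rows = {
            p.patient_id: {
                "time": getattr(p, endpoint).time,
                "event": getattr(p, endpoint).event,
            }
            for p in self.patients
        }
        return pd.DataFrame.from_dict(rows, orient="index")

    def clinical_frame(self) -> pd.DataFrame:
        return clinical_frame(self.patients)


_CLINICAL_ENCODERS = {
    "age": lambda c: c.age,
    "ca125": lambda c: c.ca125,
    "figo_stage": lambda c: FIGO_STAGES.index(c.figo_stage),
    "sur_status": lambda c: SUR_STATUSES.index(c.sur_status),
    "ascites_volume": lambda c: c.ascites_volume,
    "n_implants": lambda c: c.n_implants,
    "invasion_pattern": lambda c: c.invasion_pattern,
    "solid_ratio": lambda c: c.solid_ratio,
}


def clinical_frame(patients: list[PatientCase]) -> pd.DataFrame:
    """Clinical covariates of a cohort as a tidy table (one row/patient)."""
    rows = {}
    for p in patients:
        c = p.covariates
        row = {
            "age": c.age,
            "ca125": c.ca125,
            "figo_stage": c.figo_stage,
            "sur_status": c.sur_status,
            "ascites_volume": c.ascites_volume,
            "ascites_character": c.ascites_character,
            "n_implants": c.n_implants,
            "invasion_pattern": c.invasion_pattern,
            "solid_ratio": c.solid_ratio,
        }
        row.update({f"lnm_{site}": int(c.lnm[site]) for site in LNM_SITES})
        row.update({f"implant_{r}": int(c.implant_locations[r]) for r in IMPLANT_REGIONS})
        rows[p.patient_id] = row
    return pd.DataFrame.from_dict(rows, orient="index")


def _planted_predictor(
    config: SimulationConfig, patients: list[PatientCase]
) -> tuple[pd.Series, pd.DataFrame]:
    """Planted log-hazard: cohort-z-scored metric and covariate effects."""
    needs_texture = any(
        name in het_stats.TEXTURE_METRIC_NAMES for name in config.heterogeneity_effect
    )
    metric_rows = {}
    for p in patients:
        kept = filter_vois(p.lesions)
        metrics = het_stats.conventional_heterogeneity([measure_lesion(l) for l in kept])
        if needs_texture:
            metrics.update(
                texture_heterogeneity_vector(kept, TextureConfig(seed=config.seed)).as_dict()
            )
        metric_rows[p.patient_id] = metrics
    metric_df = pd.DataFrame.from_dict(metric_rows, orient="index")

    lp = pd.Series(0.0, index=metric_df.index)
    for name, beta in config.heterogeneity_effect.items():
        col = metric_df[name]
        sd = col.std(ddof=0)
        lp += beta * (col - col.mean()) / (sd if sd > 0 else 1.0)
    if config.clinical_effect:
        for name, gamma in config.clinical_effect.items():
            vals = pd.Series(
                {p.patient_id: _CLINICAL_ENCODERS[name](p.covariates) for p in patients}
            )
            sd = vals.std(ddof=0)
            lp += gamma * (vals - vals.mean()) / (sd if sd > 0 else 1.0)
    return lp, metric_df


def generate_cohort(
    config: SimulationConfig, stain_fraction: float = 0.31
) -> Cohort:
    """Generate a full phantom cohort with planted survival signal.

    Patients are generated from per-patient substreams; the planted linear
    predictor is then computed from the *extracted* heterogeneity metrics
    (z-scored over the cohort) plus clinical terms, outcomes are
    re-simulated under it, and H-scores are attached to a random subset of
    patients (default ~31%, the typical immunohistochemistry coverage).
    """
    n = config.n_train + config.n_test
    patients = [generate_patient(config, i) for i in range(n)]
    lp, metric_df = _planted_predictor(config, patients)
    for i, p in enumerate(patients):
        p.pfs = simulate_survival(
            lp[p.patient_id], config.baseline_rate, config.censor_admin,
            _patient_rng(config.seed, i, 1), dropout_upper=config.dropout_upper,
        )
        p.os = simulate_survival(
            lp[p.patient_id], config.baseline_rate_os, config.censor_admin,
            _patient_rng(config.seed, i, 2), dropout_upper=config.dropout_upper,
        )
    stain_rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(0, 99)))
    for marker in ("p53", "Ki-67"):
        triples = simulate_h_scores(lp.to_numpy(), config.rho_target, stain_rng)
        scored = stain_rng.random(n) < stain_fraction
        for i, p in enumerate(patients):
            if scored[i]:
                if p.stain_fractions is None:
                    p.stain_fractions = {}
                p.stain_fractions[marker] = tuple(triples[i])
    ids = [p.patient_id for p in patients]
    return Cohort(
        patients=patients,
        config=config,
        linear_predictor=lp,
        train_ids=ids[: config.n_train],
        test_ids=ids[config.n_train :],
        metrics=metric_df,
    )


def make_clone_patient(
    n_lesions: int = 4,
    diameter_mm: float = 14.0,
    seed: int = 0,
    patient_id: str = "CLONE",
) -> PatientCase:
    """A degenerate patient whose lesions are content-identical clones.

    Useful as a null control: every dispersion statistic and every texture
    heterogeneity metric must vanish on such a patient.
    """
    if not 2 <= n_lesions <= 10:
        raise ValueError("clone patient supports 2-10 lesions")
    template = generate_lesion_phantom(PRIMARY_REGION, diameter_mm, seed=seed)
    lesions = [template]
    for j in range(n_lesions - 1):
        lesions.append(
            LesionVOI(
                lesion_id=f"{patient_id}-L{j + 1}",
                region=IMPLANT_REGIONS[j],
                ct=VoxelGrid(template.ct.values.copy(), template.spacing),
                suv=VoxelGrid(template.suv.values.copy(), template.spacing),
                mask=template.mask.copy(),
            )
        )
    rng = np.random.default_rng(seed)
    covariates = _draw_covariates(rng, [l.region for l in lesions[1:]])
    return PatientCase(
        patient_id=patient_id,
        lesions=lesions,
        covariates=covariates,
        pfs=SurvivalOutcome(time=365.0, event=0),
        os=SurvivalOutcome(time=365.0, event=0),
    )
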