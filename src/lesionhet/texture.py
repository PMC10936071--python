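"""CT-texture-derived inter-tumor heterogeneity metrics.

The pipeline follows six steps per patient:

1. masked CT voxels are linearly rescaled to 256 integer grey values and
   discretized with a bin width of 32, giving G = 8 grey levels;
2. a 3-D grey-level co-occurrence matrix (GLCM; 13 unique unit offsets,
   symmetric, merged over offsets) is built per lesion;
3. four Haralick features (energy, entropy, contrast, homogeneity) are
   computed from each GLCM and logged as per-lesion intermediates;
4. each lesion is partitioned into k texture subregions by k-means over
   per-voxel features (grey level, 3x3x3 local mean, 3x3x3 local SD),
   standardized within the lesion; the sorted cluster centroids form the
   lesion's texture signature;
5. pairwise Euclidean distances between the lesions' signatures give a
   dissimilarity matrix whose binned distance frequencies define the
   cluster site entropy (cSE, bits);
6. a grey level distance zone matrix (GLDZM; zones = 26-connected
   equal-level components indexed by grey level x border-distance band)
   is built per lesion, and the pairwise distances between the lesions'
   normalized GLDZM vectors define the cluster dissimilarity (cluDiss,
   mean) and cluster standard deviation (cluDev, population SD).

All three patient-level metrics are zero exactly when the lesions are
texture-identical clones, and grow with between-lesion texture contrast.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from sklearn.cluster import KMeans

from .types import LesionVOI, as_bool_array

#: 13 unique 3-D direction offsets at Chebyshev distance 1 (half of the
#: 26-neighbourhood; the other half is covered by symmetrization).
GLCM_OFFSETS: tuple[tuple[int, int, int], ...] = tuple(
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) > (0, 0, 0)
)

_CONN26 = np.ones((3, 3, 3), dtype=int)


@dataclass
class TextureConfig:
    """Parameters of the texture-heterogeneity extraction."""

    rescale_levels: int = 256  # grey values after min-max rescaling
    bin_width: int = 32  # discretization bin width -> G = 256/32 = 8
    n_subregions: int = 3  # k of the per-lesion k-means
    n_restarts: int = 10  # k-means restarts
    entropy_bins: int = 10  # equal-width bins for cSE
    distance_bands: int = 4  # relative border-distance bands of the GLDZM
    seed: int = 0  # shared k-means seed (same for every lesion)

    @property
    def n_levels(self) -> int:
        return self.rescale_levels // self.bin_width


@dataclass
class GrayVolume:
    """Discretized lesion: integer levels in 1..G on the masked voxels."""

    levels: np.ndarray
    mask: np.ndarray
    n_levels: int


@dataclass
class GLCMatrix:
    p: np.ndarray  # G x G, normalized to sum 1, symmetric


@dataclass
class HaralickFeatures:
    energy: float
    entropy: float  # bits
    contrast: float
    homogeneity: float

    def as_dict(self) -> dict[str, float]:
        return {
            "energy": self.energy,
            "entropy": self.entropy,
            "contrast": self.contrast,
            "homogeneity": self.homogeneity,
        }


@dataclass
class SubregionSet:
    """k texture-subregion signatures of one lesion plus voxel labels."""

    signatures: np.ndarray  # k x 3 sorted centroid rows (padded if collapsed)
    labels: np.ndarray  # per masked voxel, in 0..k_eff-1
    k_effective: int

    @property
    def signature_vector(self) -> np.ndarray:
        return self.signatures.ravel()


@dataclass
class GLDZMatrix:
    """Zone counts by (grey level, relative border-distance band)."""

    z: np.ndarray  # G x n_bands counts
    n_zones: int

    @property
    def normalized_vector(self) -> np.ndarray:
        return self.z.ravel() / float(self.n_zones)


@dataclass
class TextureHeterogeneity:
    cSE: float
    cluDev: float
    cluDiss: float

    def as_dict(self) -> dict[str, float]:
        return {"cSE": self.cSE, "cluDev": self.cluDev, "cluDiss": self.cluDiss}


def discretize_ct(ct: np.ndarray, mask: np.ndarray, config: TextureConfig | None = None) -> GrayVolume:
    """Min-max rescale masked HU to 0..255 and bin with width 32 -> levels 1..8."""
    config = config or TextureConfig()
    mask = as_bool_array(mask)
    if not mask.any():
        raise ValueError("empty mask")
    vals = np.asarray(ct, dtype=float)[mask]
    lo, hi = vals.min(), vals.max()
    levels = np.zeros(mask.shape, dtype=int)
    if hi == lo:
        warnings.warn("constant lesion: all voxels map to grey level 1", stacklevel=2)
        levels[mask] = 1
    else:
        scaled = np.rint((vals - lo) / (hi - lo) * (config.rescale_levels - 1))
        levels[mask] = (scaled // config.bin_width).astype(int) + 1
    return GrayVolume(levels=levels, mask=mask, n_levels=config.n_levels)


def _pair_slices(off: tuple[int, int, int], shape: tuple[int, ...]):
    """Index windows (base, shifted) so base[i] pairs with array[i + off]."""
    base, shifted = [], []
    for d in range(3):
        o = off[d]
        base.append(slice(max(0, -o), shape[d] - max(0, o)))
        shifted.append(slice(max(0, o), shape[d] - max(0, -o)))
    return tuple(base), tuple(shifted)


def glcm(gray: GrayVolume) -> GLCMatrix:
    """Symmetric 3-D GLCM merged over the 13 unit offsets, normalized."""
    g = gray.n_levels
    counts = np.zeros((g, g), dtype=float)
    levels, mask = gray.levels, gray.mask
    for off in GLCM_OFFSETS:
        sl_base, sl_shift = _pair_slices(off, levels.shape)
        valid = mask[sl_base] & mask[sl_shift]
        if not valid.any():
            continue
        i = levels[sl_base][valid] - 1
        j = levels[sl_shift][valid] - 1
        np.add.at(counts, (i, j), 1.0)
        np.add.at(counts, (j, i), 1.0)
    total = counts.sum()
    if total == 0:
        raise ValueError("no in-mask voxel pair at distance 1; lesion too small")
    return GLCMatrix(p=counts / total)


def haralick(p: GLCMatrix | np.ndarray) -> HaralickFeatures:
    """Energy, entropy (bits), contrast and homogeneity of a normalized GLCM."""
    mat = p.p if isinstance(p, GLCMatrix) else np.asarray(p, dtype=float)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ValueError("GLCM must be square")
    if np.any(mat < 0) or not np.isclose(mat.sum(), 1.0, atol=1e-8):
        raise ValueError("GLCM must be normalized to sum 1 with entries >= 0")
    g = mat.shape[0]
    i, j = np.meshgrid(np.arange(g), np.arange(g), indexing="ij")
    nz = mat > 0
    entropy = float(-(mat[nz] * np.log2(mat[nz])).sum())
    return HaralickFeatures(
        energy=float((mat**2).sum()),
        entropy=entropy,
        contrast=float(((i - j) ** 2 * mat).sum()),
        homogeneity=float((mat / (1.0 + np.abs(i - j))).sum()),
    )


def _local_moments(levels: np.ndarray, mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Masked 3x3x3 local mean and SD of the grey levels, per masked voxel."""
    m = mask.astype(float)
    v = levels.astype(float) * m
    cnt = ndimage.uniform_filter(m, size=3, mode="constant") * 27.0
    s1 = ndimage.uniform_filter(v, size=3, mode="constant") * 27.0
    s2 = ndimage.uniform_filter(v * levels, size=3, mode="constant") * 27.0
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = s1 / cnt
        var = np.clip(s2 / cnt - mean**2, 0.0, None)
    return mean[mask], np.sqrt(var[mask])


def subregion_cluster(gray: GrayVolume, k: int = 3, seed: int = 0, n_restarts: int = 10) -> SubregionSet:
    """Partition a lesion into k texture subregions by seeded k-means.

    Per-voxel features are (grey level, 3x3x3 local mean, 3x3x3 local SD),
    each z-scored within the lesion (zero-variance features map to 0).  If
    the lesion offers fewer distinct feature rows than k, k is reduced with
    a warning and the sorted centroid list is padded by repetition so the
    signature dimension stays k x 3.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    mask = gray.mask
    glv = gray.levels[mask].astype(float)
    lmean, lsd = _local_moments(gray.levels, mask)
    feats = np.column_stack([glv, lmean, lsd])
    sd = feats.std(axis=0)
    mu = feats.mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, (feats - mu) / sd, 0.0)
    n_unique = np.unique(z, axis=0).shape[0]
    k_eff = min(k, n_unique, z.shape[0])
    if k_eff < k:
        warnings.warn(f"lesion supports only {k_eff} distinct subregions (k={k})", stacklevel=2)
    if k_eff == 1:
        centroids = z.mean(axis=0, keepdims=True)
        labels = np.zeros(z.shape[0], dtype=int)
    else:
        km = KMeans(n_clusters=k_eff, n_init=n_restarts, random_state=seed)
        labels = km.fit_predict(z)
        centroids = km.cluster_centers_
    order = np.lexsort(centroids.T[::-1])
    centroids = centroids[order]
    relabel = np.empty(k_eff, dtype=int)
    relabel[order] = np.arange(k_eff)
    labels = relabel[labels]
    padded = centroids[np.minimum(np.arange(k), k_eff - 1)]
    return SubregionSet(signatures=padded, labels=labels, k_effective=k_eff)


def dissimilarity_matrix(signatures: list[np.ndarray]) -> np.ndarray:
    """Pairwise Euclidean distances between signature vectors."""
    if len(signatures) < 2:
        raise ValueError("need >= 2 signatures")
    vecs = [np.asarray(s, dtype=float).ravel() for s in signatures]
    dim = vecs[0].size
    if any(v.size != dim for v in vecs):
        raise ValueError("signatures must share one dimension")
    stack = np.stack(vecs)
    diff = stack[:, None, :] - stack[None, :, :]
    return np.sqrt((diff**2).sum(axis=2))


def cluster_site_entropy(d: np.ndarray, n_bins: int = 10) -> float:
    """Entropy (bits) of the binned pairwise-distance frequencies.

    Upper-triangle distances are histogrammed into ``n_bins`` equal-width
    bins over [0, max]; all-zero distances give 0 by convention.
    """
    d = np.asarray(d, dtype=float)
    iu = np.triu_indices_from(d, k=1)
    vals = d[iu]
    if vals.size < 1:
        raise ValueError("need at least one off-diagonal distance")
    dmax = vals.max()
    if dmax <= 0:
        return 0.0
    idx = np.clip((vals / dmax * n_bins).astype(int), 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins).astype(float)
    p = counts[counts > 0] / vals.size
    return float(-(p * np.log2(p)).sum())


def gldzm(gray: GrayVolume, n_bands: int = 4) -> GLDZMatrix:
    """Grey level distance zone matrix with relative distance bands.

    Zones are 26-connected components of equal grey level inside the mask;
    each zone is indexed by its grey level and the minimum Chebyshev voxel
    distance of the zone to the mask border (border voxels have distance 1,
    voxels outside the image count as border).  Distances are aggregated
    into ``n_bands`` relative bands (quarters of the lesion's maximum
    border distance) so vectors are comparable across lesion sizes.
    """
    mask = gray.mask
    if not mask.any():
        raise ValueError("empty mask")
    padded = np.pad(mask, 1)
    dist = ndimage.distance_transform_cdt(padded, metric="chessboard")
    dist = dist[1:-1, 1:-1, 1:-1].astype(float)
    dmax = dist[mask].max()
    z = np.zeros((gray.n_levels, n_bands), dtype=float)
    n_zones = 0
    for level in range(1, gray.n_levels + 1):
        sel = mask & (gray.levels == level)
        if not sel.any():
            continue
        lab, n = ndimage.label(sel, structure=_CONN26)
        for comp in range(1, n + 1):
            zone_dist = dist[lab == comp].min()
            band = min(n_bands - 1, int(np.ceil(zone_dist / dmax * n_bands)) - 1)
            z[level - 1, band] += 1.0
            n_zones += 1
    return GLDZMatrix(z=z, n_zones=n_zones)


def cluster_dev_diss(gldzm_vectors: list[np.ndarray]) -> tuple[float, float]:
    """(cluDev, cluDiss) from the lesions' normalized GLDZM vectors.

    cluDiss is the mean and cluDev the population SD of the upper-triangle
    entries of the inter-lesion Euclidean dissimilarity matrix.
    """
    if len(gldzm_vectors) < 2:
        raise ValueError("need >= 2 lesions")
    d = dissimilarity_matrix(gldzm_vectors)
    vals = d[np.triu_indices_from(d, k=1)]
    return float(vals.std(ddof=0)), float(vals.mean())


def texture_heterogeneity_vector(
    lesions: list[LesionVOI],
    config: TextureConfig | None = None,
    return_intermediates: bool = False,
):
    """The 3 texture heterogeneity metrics (cSE, cluDev, cluDiss) of a patient.

    Expects the lesions to have passed the VOI filter.  With
    ``return_intermediates`` the per-lesion Haralick features, subregion
    signatures and GLDZM matrices are returned alongside.
    """
    config = config or TextureConfig()
    if len(lesions) < 2:
        raise ValueError("texture heterogeneity needs >= 2 lesions")
    signatures = []
    gldzm_vecs = []
    intermediates = []
    for lesion in lesions:
        gray = discretize_ct(lesion.ct.values, lesion.mask, config)
        features = haralick(glcm(gray))
        sub = subregion_cluster(
            gray, k=config.n_subregions, seed=config.seed, n_restarts=config.n_restarts
        )
        zones = gldzm(gray, n_bands=config.distance_bands)
        signatures.append(sub.signature_vector)
        gldzm_vecs.append(zones.normalized_vector)
        intermediates.append(
            {"lesion_id": lesion.lesion_id, "haralick": features, "subregions": sub, "gldzm": zones}
        )
    cse = cluster_site_entropy(dissimilarity_matrix(signatures), n_bins=config.entropy_bins)
    clu_dev, clu_diss = cluster_dev_diss(gldzm_vecs)
    result = TextureHeterogeneity(cSE=cse, cluDev=clu_dev, cluDiss=clu_diss)
    if return_intermediates:
        return result, intermediates
    return result
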