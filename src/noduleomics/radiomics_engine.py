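"""107-feature radiomics engine for intensity volumes with binary ROIs.

Computes the "original" (unfiltered-image) feature set used throughout
quantitative CT nodule analysis: 14 shape features, 18 first-order
intensity statistics and 75 gray-level texture-matrix features (24 GLCM,
16 GLRLM, 16 GLSZM, 14 GLDM, 5 NGTDM), for a total of 107 named features
per ROI.

Extraction contract
-------------------
* Features are computed on the native grid (no resampling); shape math is
  spacing-aware (mm).
* Gray levels are discretized with a fixed bin width (default 25 HU),
  each ROI over its own intensity range:
  ``level = floor(x / w) - floor(min(x) / w) + 1``.
* GLCM: symmetric, Chebyshev distance 1, the 13 unique 3-D directions,
  features averaged over directions.
* GLRLM: runs along the same 13 directions, features averaged.
* GLSZM: zones are 26-connected components of constant gray level.
* GLDM: similarity threshold alpha = 0, 26-neighbourhood; the dependence
  index of a voxel is ``1 +`` the number of in-ROI neighbours with the
  same gray level (the voxel itself counts as dependent on itself).
* NGTDM: 26-neighbourhood; only voxels with at least one in-ROI
  neighbour contribute.
* Degenerate inputs never yield NaN: each feature has a documented limit
  value (e.g. GLCM Correlation -> 1 for a constant ROI) and every
  occurrence is logged.

Feature names follow the ``family_FeatureName_role`` schema, e.g.
``shape_Sphericity_intra`` or ``gldm_DependenceNonUniformityNormalized_peri``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import ConvexHull, QhullError
from scipy import ndimage
from skimage.measure import marching_cubes, mesh_surface_area

from .volume_io import ImageVolume, RoiMask

logger = logging.getLogger("noduleomics.radiomics")

_EPS = np.spacing(1.0)

# ---------------------------------------------------------------------------
# Configuration and feature census
# ---------------------------------------------------------------------------

@dataclass
class DiscretizationConfig:
    """Gray-level discretization settings.

    bin_width_hu : fixed bin width in HU (default 25); levels are defined
    per ROI from its own intensity range.
    """

    bin_width_hu: float = 25.0

    def __post_init__(self) -> None:
        if self.bin_width_hu <= 0:
            raise ValueError("bin_width_hu must be > 0")


SHAPE_FEATURES = (
    "MeshVolume", "VoxelVolume", "SurfaceArea", "SurfaceVolumeRatio",
    "Sphericity", "Maximum3DDiameter", "Maximum2DDiameterSlice",
    "Maximum2DDiameterColumn", "Maximum2DDiameterRow", "MajorAxisLength",
    "MinorAxisLength", "LeastAxisLength", "Elongation", "Flatness",
)
FIRSTORDER_FEATURES = (
    "Energy", "TotalEnergy", "Entropy", "Minimum", "10Percentile",
    "90Percentile", "Maximum", "Mean", "Median", "InterquartileRange",
    "Range", "MeanAbsoluteDeviation", "RobustMeanAbsoluteDeviation",
    "RootMeanSquared", "Skewness", "Kurtosis", "Variance", "Uniformity",
)
GLCM_FEATURES = (
    "Autocorrelation", "JointAverage", "ClusterProminence", "ClusterShade",
    "ClusterTendency", "Contrast", "Correlation", "DifferenceAverage",
    "DifferenceEntropy", "DifferenceVariance", "JointEnergy", "JointEntropy",
    "Imc1", "Imc2", "Idm", "Idmn", "Id", "Idn", "InverseVariance",
    "MaximumProbability", "SumAverage", "SumEntropy", "SumSquares", "MCC",
)
GLRLM_FEATURES = (
    "ShortRunEmphasis", "LongRunEmphasis", "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized", "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized", "RunPercentage", "GrayLevelVariance",
    "RunVariance", "RunEntropy", "LowGrayLevelRunEmphasis",
    "HighGrayLevelRunEmphasis", "ShortRunLowGrayLevelEmphasis",
    "ShortRunHighGrayLevelEmphasis", "LongRunLowGrayLevelEmphasis",
    "LongRunHighGrayLevelEmphasis",
)
GLSZM_FEATURES = (
    "SmallAreaEmphasis", "LargeAreaEmphasis", "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized", "SizeZoneNonUniformity",
    "SizeZoneNonUniformityNormalized", "ZonePercentage", "GrayLevelVariance",
    "ZoneVariance", "ZoneEntropy", "LowGrayLevelZoneEmphasis",
    "HighGrayLevelZoneEmphasis", "SmallAreaLowGrayLevelEmphasis",
    "SmallAreaHighGrayLevelEmphasis", "LargeAreaLowGrayLevelEmphasis",
    "LargeAreaHighGrayLevelEmphasis",
)
GLDM_FEATURES = (
    "SmallDependenceEmphasis", "LargeDependenceEmphasis",
    "GrayLevelNonUniformity", "DependenceNonUniformity",
    "DependenceNonUniformityNormalized", "GrayLevelVariance",
    "DependenceVariance", "DependenceEntropy", "LowGrayLevelEmphasis",
    "HighGrayLevelEmphasis", "SmallDependenceLowGrayLevelEmphasis",
    "SmallDependenceHighGrayLevelEmphasis",
    "LargeDependenceLowGrayLevelEmphasis",
    "LargeDependenceHighGrayLevelEmphasis",
)
NGTDM_FEATURES = ("Coarseness", "Contrast", "Busyness", "Complexity", "Strength")

FAMILY_FEATURES = {
    "shape": SHAPE_FEATURES,
    "firstorder": FIRSTORDER_FEATURES,
    "glcm": GLCM_FEATURES,
    "glrlm": GLRLM_FEATURES,
    "glszm": GLSZM_FEATURES,
    "gldm": GLDM_FEATURES,
    "ngtdm": NGTDM_FEATURES,
}
N_FEATURES = sum(len(v) for v in FAMILY_FEATURES.values())  # 107


def feature_names(role: str | None = None) -> list[str]:
    """The 107 canonical feature names, optionally suffixed with a role."""
    names = [f"{fam}_{name}" for fam, feats in FAMILY_FEATURES.items() for name in feats]
    if role is not None:
        names = [f"{n}_{role}" for n in names]
    return names


# ---------------------------------------------------------------------------
# Discretization and direction bookkeeping
# ---------------------------------------------------------------------------

def discretize(values: np.ndarray, bin_width: float) -> np.ndarray:
    """Map intensities to integer gray levels 1..Ng with a fixed bin width."""
    values = np.asarray(values, dtype=float)
    lo = np.floor(values.min() / bin_width)
    return (np.floor(values / bin_width) - lo).astype(np.int64) + 1


def unique_directions() -> list[tuple[int, int, int]]:
    """The 13 unique distance-1 3-D directions (first nonzero component +1)."""
    dirs = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                d = (dx, dy, dz)
                if d == (0, 0, 0):
                    continue
                for c in d:
                    if c != 0:
                        if c > 0:
                            dirs.append(d)
                        break
    assert len(dirs) == 13
    return dirs


_DIRECTIONS = unique_directions()


def _offset_slices(shape, d):
    """Paired (src, dst) slice tuples so that dst = src + d elementwise."""
    src, dst = [], []
    for n, di in zip(shape, d):
        if di >= 0:
            src.append(slice(0, n - di))
            dst.append(slice(di, n))
        else:
            src.append(slice(-di, n))
            dst.append(slice(0, n + di))
    return tuple(src), tuple(dst)


def _shift(a: np.ndarray, d) -> np.ndarray:
    """Zero-filled shift: out[idx] = a[idx - d]."""
    out = np.zeros_like(a)
    src, dst = _offset_slices(a.shape, d)
    out[dst] = a[src]
    return out


def _crop_to_bbox(volume: np.ndarray, mask: np.ndarray):
    idx = np.nonzero(mask)
    slices = tuple(slice(int(i.min()), int(i.max()) + 1) for i in idx)
    return volume[slices], mask[slices]


def _level_array(volume: ImageVolume, roi: RoiMask, cfg: DiscretizationConfig) -> np.ndarray:
    """Cropped int array: gray level 1..Ng inside the ROI, 0 outside."""
    vox, mask = _crop_to_bbox(volume.voxels, roi.voxels)
    levels = np.zeros(mask.shape, dtype=np.int64)
    levels[mask] = discretize(vox[mask], cfg.bin_width_hu)
    return levels


# ---------------------------------------------------------------------------
# Texture matrix construction
# ---------------------------------------------------------------------------

@dataclass
class TextureMatrices:
    """Raw gray-level texture matrices for one ROI.

    glcm / glrlm map each of the 13 directions to a count matrix
    (level x level, level x run-length); glszm is level x zone-size;
    gldm is level x dependence (dependence index 1..27); ngtdm holds the
    per-level counts ``n`` and summed absolute neighbourhood differences
    ``s`` (index 0 is gray level 1).
    """

    n_levels: int
    glcm: dict = field(default_factory=dict)
    glrlm: dict = field(default_factory=dict)
    glszm: np.ndarray | None = None
    gldm: np.ndarray | None = None
    ngtdm_n: np.ndarray | None = None
    ngtdm_s: np.ndarray | None = None
    n_voxels: int = 0


def glcm_matrix(levels: np.ndarray, d, n_levels: int) -> np.ndarray:
    """Symmetric co-occurrence counts for one direction."""
    src, dst = _offset_slices(levels.shape, d)
    a, b = levels[src], levels[dst]
    m = (a > 0) & (b > 0)
    counts = np.bincount(
        (a[m] - 1) * n_levels + (b[m] - 1), minlength=n_levels * n_levels
    ).reshape(n_levels, n_levels)
    return counts + counts.T


def glrlm_matrix(levels: np.ndarray, d, n_levels: int) -> np.ndarray:
    """Run-length counts for one direction via an in-order slab scan."""
    shape = levels.shape
    axis = next(i for i, c in enumerate(d) if c != 0)  # d[axis] == +1
    rest = [i for i in range(3) if i != axis]
    d_rest = tuple(d[i] for i in rest)
    runlen = np.zeros(shape, dtype=np.int64)
    lm = np.moveaxis(levels, axis, 0)
    rm = np.moveaxis(runlen, axis, 0)
    for i in range(lm.shape[0]):
        cur = lm[i]
        inside = cur > 0
        if i == 0:
            rm[i] = inside.astype(np.int64)
            continue
        prev_l = _shift(lm[i - 1], d_rest)
        prev_r = _shift(rm[i - 1], d_rest)
        bond = inside & (prev_l == cur)
        rm[i] = np.where(bond, prev_r + 1, inside.astype(np.int64))
    # a run is recorded once, at its last voxel (no same-level forward bond)
    src, dst = _offset_slices(shape, d)
    fwd = np.zeros(shape, dtype=bool)
    fwd[src] = (levels[src] > 0) & (levels[src] == levels[dst])
    ends = (levels > 0) & ~fwd
    lev, runs = levels[ends], runlen[ends]
    max_run = int(runs.max())
    return np.bincount(
        (lev - 1) * max_run + (runs - 1), minlength=n_levels * max_run
    ).reshape(n_levels, max_run)


def glszm_matrix(levels: np.ndarray, n_levels: int) -> np.ndarray:
    """Zone-size counts; zones are 26-connected same-level components."""
    conn = np.ones((3, 3, 3), dtype=bool)
    zones: list[tuple[int, int]] = []
    max_size = 1
    for g in range(1, n_levels + 1):
        sub = levels == g
        if not sub.any():
            continue
        sub, _ = _crop_to_bbox(sub, sub)
        lab, n = ndimage.label(sub, structure=conn)
        sizes = np.bincount(lab.ravel())[1:]
        for s in sizes:
            zones.append((g, int(s)))
            max_size = max(max_size, int(s))
    mat = np.zeros((n_levels, max_size), dtype=np.int64)
    for g, s in zones:
        mat[g - 1, s - 1] += 1
    return mat


def gldm_matrix(levels: np.ndarray, n_levels: int) -> np.ndarray:
    """Dependence counts (alpha = 0, 26-neighbourhood, centre included)."""
    inside = levels > 0
    dep = np.zeros(levels.shape, dtype=np.int64)
    for d in _DIRECTIONS:
        src, dst = _offset_slices(levels.shape, d)
        eq = (levels[src] > 0) & (levels[src] == levels[dst])
        dep[src] += eq
        dep[dst] += eq
    j = dep[inside] + 1  # dependence index includes the centre voxel
    lev = levels[inside]
    max_dep = int(j.max())
    return np.bincount(
        (lev - 1) * max_dep + (j - 1), minlength=n_levels * max_dep
    ).reshape(n_levels, max_dep)


def ngtdm_arrays(levels: np.ndarray, n_levels: int):
    """Per-level counts n_i and summed |level - neighbourhood mean| s_i."""
    inside = levels > 0
    nbr_sum = np.zeros(levels.shape, dtype=np.float64)
    nbr_cnt = np.zeros(levels.shape, dtype=np.int64)
    for d in _DIRECTIONS:
        src, dst = _offset_slices(levels.shape, d)
        a_in = levels[src] > 0
        b_in = levels[dst] > 0
        both = a_in & b_in
        nbr_sum[src] += np.where(both, levels[dst], 0)
        nbr_cnt[src] += both
        nbr_sum[dst] += np.where(both, levels[src], 0)
        nbr_cnt[dst] += both
    valid = inside & (nbr_cnt > 0)
    n = np.zeros(n_levels, dtype=np.int64)
    s = np.zeros(n_levels, dtype=np.float64)
    if valid.any():
        diffs = np.abs(levels[valid] - nbr_sum[valid] / nbr_cnt[valid])
        lev = levels[valid] - 1
        n = np.bincount(lev, minlength=n_levels)
        s = np.bincount(lev, weights=diffs, minlength=n_levels)
    return n, s


def texture_matrices(
    volume: ImageVolume, roi: RoiMask, cfg: DiscretizationConfig | None = None
) -> TextureMatrices:
    """Build all five texture matrices for one ROI."""
    cfg = cfg or DiscretizationConfig()
    if roi.count() == 0:
        raise ValueError("ROI is empty")
    levels = _level_array(volume, roi, cfg)
    ng = int(levels.max())
    tm = TextureMatrices(n_levels=ng, n_voxels=int((levels > 0).sum()))
    for d in _DIRECTIONS:
        tm.glcm[d] = glcm_matrix(levels, d, ng)
        tm.glrlm[d] = glrlm_matrix(levels, d, ng)
    tm.glszm = glszm_matrix(levels, ng)
    tm.gldm = gldm_matrix(levels, ng)
    tm.ngtdm_n, tm.ngtdm_s = ngtdm_arrays(levels, ng)
    return tm


# ---------------------------------------------------------------------------
# Shape features
# ---------------------------------------------------------------------------

def _mesh(mask: np.ndarray, spacing):
    padded = np.pad(mask.astype(np.uint8), 1)
    verts, faces, _, _ = marching_cubes(padded, level=0.5, spacing=tuple(spacing))
    return verts, faces

def _mesh_volume(verts: np.ndarray, faces: np.ndarray) -> float:
    tri = verts[faces]
    return float(abs(np.einsum("ij,ij->", tri[:, 0], np.cross(tri[:, 1], tri[:, 2]))) / 6.0)


def _max_pairwise(points: np.ndarray) -> float:
    if len(points) < 2:
        return 0.0
    if len(points) > 10 and points.shape[1] <= 3:
        try:
            hull = ConvexHull(points)
            points = points[hull.vertices]
        except QhullError:
            pass  # degenerate (flat/collinear) point sets fall through
    diffs = points[:, None, :] - points[None, :, :]
    return float(np.sqrt((diffs ** 2).sum(-1).max()))


def mesh_volume_area(roi: RoiMask, spacing) -> tuple[float, float]:
    """Triangulated-surface volume (mm^3) and area (mm^2) of a mask."""
    if roi.count() == 0:
        raise ValueError("ROI is empty")
    mask, _ = _crop_to_bbox(roi.voxels, roi.voxels)
    verts, faces = _mesh(mask, spacing)
    area = float(mesh_surface_area(verts, faces))
    volume = _mesh_volume(verts, faces)
    return volume, area


def sphericity(roi: RoiMask, spacing) -> float:
    """(36 pi V^2)^(1/3) / A from the triangulated ROI surface; in (0, 1]
    for solid shapes (1 = perfect sphere)."""
    volume, area = mesh_volume_area(roi, spacing)
    if area <= 0:
        raise ValueError("degenerate zero-area surface mesh")
    return float((36.0 * np.pi * volume**2) ** (1.0 / 3.0) / area)


def shape_features(roi: RoiMask, spacing) -> dict[str, float]:
    spacing = np.asarray(spacing, dtype=float)
    mask, _ = _crop_to_bbox(roi.voxels, roi.voxels)
    n = int(mask.sum())
    verts, faces = _mesh(mask, spacing)
    area = float(mesh_surface_area(verts, faces))
    volume = _mesh_volume(verts, faces)
    feats: dict[str, float] = {
        "MeshVolume": volume,
        "VoxelVolume": n * float(np.prod(spacing)),
        "SurfaceArea": area,
        "SurfaceVolumeRatio": area / volume,
        "Sphericity": (36.0 * np.pi * volume**2) ** (1.0 / 3.0) / area,
        "Maximum3DDiameter": _max_pairwise(verts),
    }
    coords = np.argwhere(mask) * spacing
    # in-plane maximum diameters per fixed-index plane of each axis
    for name, axis in (
        ("Maximum2DDiameterSlice", 2),   # planes of constant z (axial)
        ("Maximum2DDiameterColumn", 0),  # planes of constant x
        ("Maximum2DDiameterRow", 1),     # planes of constant y
    ):
        keep = [i for i in range(3) if i != axis]
        best = 0.0
        idx = np.argwhere(mask)
        for plane in np.unique(idx[:, axis]):
            pts = coords[idx[:, axis] == plane][:, keep]
            best = max(best, _max_pairwise(pts))
        feats[name] = best
    if n > 1:
        eigvals = np.linalg.eigvalsh(np.cov(coords.T))
        eigvals = np.clip(eigvals, 0.0, None)  # tiny negatives from roundoff
        least, minor, major = eigvals
        feats["MajorAxisLength"] = 4.0 * np.sqrt(major)
        feats["MinorAxisLength"] = 4.0 * np.sqrt(minor)
        feats["LeastAxisLength"] = 4.0 * np.sqrt(least)
        if major > 0:
            feats["Elongation"] = float(np.sqrt(minor / major))
            feats["Flatness"] = float(np.sqrt(least / major))
        else:
            logger.warning("degenerate principal axes; Elongation/Flatness -> 1")
            feats["Elongation"] = 1.0
            feats["Flatness"] = 1.0
    else:
        logger.warning("single-voxel ROI; axis lengths -> 0, Elongation/Flatness -> 1")
        feats.update(
            MajorAxisLength=0.0, MinorAxisLength=0.0, LeastAxisLength=0.0,
            Elongation=1.0, Flatness=1.0,
        )
    return {k: float(feats[k]) for k in SHAPE_FEATURES}


# ---------------------------------------------------------------------------
# First-order features
# ---------------------------------------------------------------------------

def firstorder_features(
    volume: ImageVolume, roi: RoiMask, cfg: DiscretizationConfig
) -> dict[str, float]:
    x = volume.voxels[roi.voxels].astype(float)
    if x.size == 0:
        raise ValueError("ROI is empty")
    voxel_volume = float(np.prod(volume.spacing_mm))
    levels = discretize(x, cfg.bin_width_hu)
    p = np.bincount(levels - 1) / x.size
    p_nz = p[p > 0]
    mean = float(x.mean())
    m2 = float(np.mean((x - mean) ** 2))  # population variance
    p10, p25, p75, p90 = np.percentile(x, [10, 25, 75, 90])
    robust = x[(x >= p10) & (x <= p90)]
    if m2 > 0:
        skew = float(np.mean((x - mean) ** 3) / m2**1.5)
        kurt = float(np.mean((x - mean) ** 4) / m2**2)  # Pearson (not excess)
    else:
        logger.warning("constant-intensity ROI; Skewness/Kurtosis -> 0")
        skew, kurt = 0.0, 0.0
    feats = {
        "Energy": float(np.sum(x**2)),
        "TotalEnergy": voxel_volume * float(np.sum(x**2)),
        "Entropy": float(-np.sum(p_nz * np.log2(p_nz))),
        "Minimum": float(x.min()),
        "10Percentile": float(p10),
        "90Percentile": float(p90),
        "Maximum": float(x.max()),
        "Mean": mean,
        "Median": float(np.median(x)),
        "InterquartileRange": float(p75 - p25),
        "Range": float(x.max() - x.min()),
        "MeanAbsoluteDeviation": float(np.mean(np.abs(x - mean))),
        "RobustMeanAbsoluteDeviation": float(np.mean(np.abs(robust - robust.mean())))
        if robust.size else 0.0,
        "RootMeanSquared": float(np.sqrt(np.mean(x**2))),
        "Skewness": skew,
        "Kurtosis": kurt,
        "Variance": m2,
        "Uniformity": float(np.sum(p_nz**2)),
    }
    return {k: feats[k] for k in FIRSTORDER_FEATURES}


# ---------------------------------------------------------------------------
# GLCM features
# ---------------------------------------------------------------------------

def _glcm_features_one(counts: np.ndarray) -> dict[str, float]:
    """Features of one normalized symmetric co-occurrence matrix."""
    total = counts.sum()
    p = counts.astype(float) / total
    ng = p.shape[0]
    i = np.arange(1, ng + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)  # == py by symmetry
    mu = float(np.sum(i * px))
    sigma2 = float(np.sum((i - mu) ** 2 * px))
    sigma = np.sqrt(sigma2)
    # p_{x+y}, p_{x-y}
    psum = np.zeros(2 * ng + 1)
    np.add.at(psum, (ii + jj).ravel(), p.ravel())
    pdiff = np.zeros(ng)
    np.add.at(pdiff, np.abs(ii - jj).ravel(), p.ravel())
    k_sum = np.arange(2 * ng + 1)
    k_diff = np.arange(ng)
    autoc = float(np.sum(p * ii * jj))
    diff_avg = float(np.sum(k_diff * pdiff))
    nz = p > 0
    hxy = float(-np.sum(p[nz] * np.log2(p[nz])))
    hx = float(-np.sum(px[px > 0] * np.log2(px[px > 0])))
    pxpy = np.outer(px, px)
    nz2 = pxpy > 0
    hxy1 = float(-np.sum(p[nz2] * np.log2(pxpy[nz2])))
    hxy2 = float(-np.sum(pxpy[nz2] * np.log2(pxpy[nz2])))
    feats: dict[str, float] = {
        "Autocorrelation": autoc,
        "JointAverage": mu,
        "ClusterProminence": float(np.sum(p * (ii + jj - 2 * mu) ** 4)),
        "ClusterShade": float(np.sum(p * (ii + jj - 2 * mu) ** 3)),
        "ClusterTendency": float(np.sum(p * (ii + jj - 2 * mu) ** 2)),
        "Contrast": float(np.sum(p * (ii - jj) ** 2)),
        "DifferenceAverage": diff_avg,
        "DifferenceEntropy": float(
            -np.sum(pdiff[pdiff > 0] * np.log2(pdiff[pdiff > 0]))
        ),
        "DifferenceVariance": float(np.sum((k_diff - diff_avg) ** 2 * pdiff)),
        "JointEnergy": float(np.sum(p**2)),
        "JointEntropy": hxy,
        "Idm": float(np.sum(pdiff / (1.0 + k_diff**2))),
        "Idmn": float(np.sum(pdiff / (1.0 + (k_diff / ng) ** 2))),
        "Id": float(np.sum(pdiff / (1.0 + k_diff))),
        "Idn": float(np.sum(pdiff / (1.0 + k_diff / ng))),
        "InverseVariance": float(np.sum(pdiff[1:] / k_diff[1:] ** 2)) if ng > 1 else 0.0,
        "MaximumProbability": float(p.max()),
        "SumAverage": float(np.sum(k_sum * psum)),
        "SumEntropy": float(-np.sum(psum[psum > 0] * np.log2(psum[psum > 0]))),
        "SumSquares": sigma2,
    }
    if sigma2 > 0:
        feats["Correlation"] = (autoc - mu * mu) / sigma2
    else:
        feats["Correlation"] = 1.0  # perfectly dependent degenerate case
    if hx > 0:
        feats["Imc1"] = (hxy - hxy1) / hx
    else:
        feats["Imc1"] = 0.0
    feats["Imc2"] = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))
    valid = px > 0
    if valid.sum() < 2:
        feats["MCC"] = 1.0
    else:
        pv = p[np.ix_(valid, valid)]
        pxv = px[valid]
        a = pv / pxv[:, None]        # a[i, k] = p(i, k) / px(i)
        b = pv / pxv[None, :]        # b[j, k] = p(j, k) / py(k)  (py == px)
        q = a @ b.T                  # q[i, j] = sum_k p(i,k) p(j,k) / (px(i) py(k))
        eigs = np.sort(np.real(np.linalg.eigvals(q)))
        feats["MCC"] = float(np.sqrt(max(0.0, eigs[-2])))
    return feats


def glcm_features(tm: TextureMatrices) -> dict[str, float]:
    """Per-direction features averaged over the 13 unique directions."""
    per_dir = []
    degenerate_logged = False
    for d, counts in tm.glcm.items():
        if counts.sum() == 0:
            # no voxel pairs along this direction (e.g. single-voxel ROI):
            # fall back to the constant single-level matrix
            if not degenerate_logged:
                logger.warning("GLCM has directions with no voxel pairs; using degenerate single-cell matrix")
                degenerate_logged = True
            counts = np.ones((1, 1), dtype=np.int64)
        per_dir.append(_glcm_features_one(counts))
    return {k: float(np.mean([f[k] for f in per_dir])) for k in GLCM_FEATURES}


def glcm_correlation(tm: TextureMatrices) -> float:
    """GLCM Correlation averaged over directions; sigma = 0 directions
    contribute 1 (constant gray level is perfectly dependent)."""
    return glcm_features(tm)["Correlation"]


# ---------------------------------------------------------------------------
# Run-length / zone / dependence / neighbourhood-difference features
# ---------------------------------------------------------------------------

def _weighted_stats(p: np.ndarray):
    """(mu_i, var_i, mu_j, var_j, entropy) of a normalized 2-D matrix."""
    ng, nj = p.shape
    i = np.arange(1, ng + 1)[:, None]
    j = np.arange(1, nj + 1)[None, :]
    mu_i = float(np.sum(p * i))
    mu_j = float(np.sum(p * j))
    var_i = float(np.sum(p * (i - mu_i) ** 2))
    var_j = float(np.sum(p * (j - mu_j) ** 2))
    nz = p[p > 0]
    ent = float(-np.sum(nz * np.log2(nz)))
    return mu_i, var_i, mu_j, var_j, ent


def _size_weighted_features(counts: np.ndarray, n_voxels: int, names, kind: str):
    """Shared feature algebra for GLRLM / GLSZM (level x size matrices)."""
    n_total = counts.sum()
    if n_total == 0:
        raise ValueError(f"empty {kind} matrix")
    ng, ns = counts.shape
    i2 = np.arange(1, ng + 1, dtype=float)[:, None] ** 2
    j2 = np.arange(1, ns + 1, dtype=float)[None, :] ** 2
    P = counts.astype(float)
    row = P.sum(axis=1)
    col = P.sum(axis=0)
    p = P / n_total
    _, var_i, _, var_j, ent = _weighted_stats(p)
    vals = [
        float(np.sum(P / j2) / n_total),            # small emphasis
        float(np.sum(P * j2) / n_total),            # large emphasis
        float(np.sum(row**2) / n_total),            # gray-level non-uniformity
        float(np.sum(row**2) / n_total**2),         # ... normalized
        float(np.sum(col**2) / n_total),            # size non-uniformity
        float(np.sum(col**2) / n_total**2),         # ... normalized
        float(n_total / n_voxels),                  # run/zone percentage
        var_i,                                      # gray-level variance
        var_j,                                      # run/zone variance
        ent,                                        # entropy
        float(np.sum(P / i2) / n_total),            # low gray emphasis
        float(np.sum(P * i2) / n_total),            # high gray emphasis
        float(np.sum(P / (i2 * j2)) / n_total),
        float(np.sum(P * i2 / j2) / n_total),
        float(np.sum(P * j2 / i2) / n_total),
        float(np.sum(P * i2 * j2) / n_total),
    ]
    return dict(zip(names, vals))


def glrlm_features(tm: TextureMatrices) -> dict[str, float]:
    per_dir = [
        _size_weighted_features(counts, tm.n_voxels, GLRLM_FEATURES, "GLRLM")
        for counts in tm.glrlm.values()
    ]
    return {k: float(np.mean([f[k] for f in per_dir])) for k in GLRLM_FEATURES}


def glszm_features(tm: TextureMatrices) -> dict[str, float]:
    return _size_weighted_features(tm.glszm, tm.n_voxels, GLSZM_FEATURES, "GLSZM")


def gldm_features(tm: TextureMatrices) -> dict[str, float]:
    counts = tm.gldm
    n_total = counts.sum()
    if n_total == 0:
        raise ValueError("empty GLDM matrix")
    ng, nd = counts.shape
    i2 = np.arange(1, ng + 1, dtype=float)[:, None] ** 2
    j2 = np.arange(1, nd + 1, dtype=float)[None, :] ** 2
    P = counts.astype(float)
    row, col = P.sum(axis=1), P.sum(axis=0)
    p = P / n_total
    _, var_i, _, var_j, ent = _weighted_stats(p)
    feats = {
        "SmallDependenceEmphasis": float(np.sum(P / j2) / n_total),
        "LargeDependenceEmphasis": float(np.sum(P * j2) / n_total),
        "GrayLevelNonUniformity": float(np.sum(row**2) / n_total),
        "DependenceNonUniformity": float(np.sum(col**2) / n_total),
        "DependenceNonUniformityNormalized": float(np.sum(col**2) / n_total**2),
        "GrayLevelVariance": var_i,
        "DependenceVariance": var_j,
        "DependenceEntropy": ent,
        "LowGrayLevelEmphasis": float(np.sum(P / i2) / n_total),
        "HighGrayLevelEmphasis": float(np.sum(P * i2) / n_total),
        "SmallDependenceLowGrayLevelEmphasis": float(np.sum(P / (i2 * j2)) / n_total),
        "SmallDependenceHighGrayLevelEmphasis": float(np.sum(P * i2 / j2) / n_total),
        "LargeDependenceLowGrayLevelEmphasis": float(np.sum(P * j2 / i2) / n_total),
        "LargeDependenceHighGrayLevelEmphasis": float(np.sum(P * i2 * j2) / n_total),
    }
    return {k: feats[k] for k in GLDM_FEATURES}


def gldm_dependence_entropy(tm: TextureMatrices) -> float:
    """-sum p log2 p over nonzero dependence-matrix cells."""
    return gldm_features(tm)["DependenceEntropy"]


def gldm_dnn(tm: TextureMatrices) -> float:
    """Dependence Non-Uniformity Normalized: sum_j (sum_i P)^2 / Nz^2."""
    return gldm_features(tm)["DependenceNonUniformityNormalized"]


def ngtdm_features(tm: TextureMatrices) -> dict[str, float]:
    n, s = tm.ngtdm_n, tm.ngtdm_s
    nvp = int(n.sum())
    if nvp == 0:
        logger.warning(
            "NGTDM undefined (no voxel has an in-ROI neighbour); using degenerate limits"
        )
        return dict(Coarseness=1e6, Contrast=0.0, Busyness=0.0, Complexity=0.0, Strength=0.0)
    p = n / nvp
    i = np.arange(1, len(n) + 1, dtype=float)
    present = p > 0
    ngp = int(present.sum())
    ip, pp, sp = i[present], p[present], s[present]
    coarse_den = float(np.sum(pp * sp))
    feats: dict[str, float] = {}
    feats["Coarseness"] = 1.0 / coarse_den if coarse_den > 0 else 1e6
    if ngp > 1:
        pij_d2 = np.sum(
            pp[:, None] * pp[None, :] * (ip[:, None] - ip[None, :]) ** 2
        )
        feats["Contrast"] = float(pij_d2 / (ngp * (ngp - 1)) * np.sum(sp) / nvp)
        busy_den = float(np.sum(np.abs(ip[:, None] * pp[:, None] - ip[None, :] * pp[None, :])))
        feats["Busyness"] = coarse_den / busy_den if busy_den > 0 else 0.0
        absdiff = np.abs(ip[:, None] - ip[None, :])
        feats["Complexity"] = float(
            np.sum(
                absdiff
                * (pp[:, None] * sp[:, None] + pp[None, :] * sp[None, :])
                / (pp[:, None] + pp[None, :])
            )
            / nvp
        )
        s_sum = float(np.sum(sp))
        strength_num = float(
            np.sum((pp[:, None] + pp[None, :]) * (ip[:, None] - ip[None, :]) ** 2)
        )
        feats["Strength"] = strength_num / s_sum if s_sum > 0 else 0.0
    else:
        feats.update(Contrast=0.0, Busyness=0.0, Complexity=0.0, Strength=0.0)
    return {k: feats[k] for k in NGTDM_FEATURES}


# ---------------------------------------------------------------------------
# Full extraction
# ---------------------------------------------------------------------------

def extract_features(
    volume: ImageVolume,
    roi: RoiMask,
    cfg: DiscretizationConfig | None = None,
) -> dict[str, float]:
    """Extract all 107 features for one ROI.

    Returns a name -> value map with the ROI role suffixed to every name
    (``shape_Sphericity_intra`` etc.); all values are finite.
    """
    cfg = cfg or DiscretizationConfig()
    if roi.count() == 0:
        raise ValueError("ROI is empty")
    if roi.shape != volume.shape:
        raise ValueError(f"ROI shape {roi.shape} != volume shape {volume.shape}")
    if roi.count() == 1:
        logger.warning("single-voxel ROI: texture features use degenerate-value contracts")
    tm = texture_matrices(volume, roi, cfg)
    blocks = {
        "shape": shape_features(roi, volume.spacing_mm),
        "firstorder": firstorder_features(volume, roi, cfg),
        "glcm": glcm_features(tm),
        "glrlm": glrlm_features(tm),
        "glszm": glszm_features(tm),
        "gldm": gldm_features(tm),
        "ngtdm": ngtdm_features(tm),
    }
    out: dict[str, float] = {}
    for fam, feats in blocks.items():
        for name, value in feats.items():
            if not np.isfinite(value):
                raise AssertionError(f"non-finite feature {fam}_{name}")
            out[f"{fam}_{name}_{roi.role}"] = float(value)
    assert len(out) == N_FEATURES
    return out


def extract_case(
    volume: ImageVolume,
    intra: RoiMask,
    peri: RoiMask | None = None,
    cfg: DiscretizationConfig | None = None,
) -> dict[str, float]:
    """Extract 107 intranodular (and optionally 107 perinodular) features."""
    out = extract_features(volume, intra, cfg)
    if peri is not None:
        out.update(extract_features(volume, peri, cfg))
    return out
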