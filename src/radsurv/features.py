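"""3D radiomic feature extraction from segmented ROIs.

Per ROI and MR sequence, 43 features are computed: 12 first-order
(8 histogram statistics + 4 shape descriptors), 6 grey-level co-occurrence
matrix (GLCM), 11 grey-level run-length matrix (GLRLM), 3 neighbourhood
grey-level difference matrix (NGLDM) and 11 grey-level zone-length matrix
(GLZLM) features — 86 per structure over the two sequences.

Conventions
-----------
* Intensities are discretized to ``n_levels`` grey levels (default 64) by
  relative min–max resampling *within the ROI*, which makes every texture
  feature invariant to strictly increasing affine transforms of the raw
  intensities (scanner scale/offset).
* All texture matrices are accumulated in 3D: co-occurrences and runs over
  the 13 unique lattice directions at distance 1, zones and neighbourhoods
  with 26-connectivity. Counts are POOLED over directions into a single
  matrix before indices are computed.
* Degenerate quantities (correlation of a uniform ROI, skewness of a
  single voxel, busyness with a zero denominator) are returned as NaN —
  explicitly missing, never silently zero.
* Voxels may be anisotropic; lattice directions are not renormalized by
  physical distance. Spacing enters only through the shape features.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage

from .errors import EmptyRoiError
from .io import ImageVolume, RoiMask, check_geometry

__all__ = [
    "DIRECTIONS_13",
    "DiscretizedRoi",
    "discretize_roi",
    "first_order_features",
    "glcm_matrix",
    "glcm_features",
    "glrlm_matrix",
    "glrlm_features",
    "ngldm_table",
    "ngldm_features",
    "glzlm_matrix",
    "glzlm_features",
    "extract_roi_features",
    "extract_structure_features",
    "extract_all",
    "FEATURE_FAMILIES",
    "feature_names",
]

#: The 13 unique 3D lattice directions at Chebyshev distance 1 (half of the
#: 26-neighbourhood; the opposite directions are implied by symmetry).
DIRECTIONS_13: tuple[tuple[int, int, int], ...] = tuple(
    (dz, dy, dx)
    for dz in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dx in (-1, 0, 1)
    if (dz, dy, dx) > (0, 0, 0)
)

#: Small-denominator guard for NGLDM coarseness (finite uniform-ROI limit).
NGLDM_EPSILON = 1e-6

FIRST_ORDER_NAMES = (
    "min", "max", "mean", "std", "skewness", "kurtosis", "entropy",
    "uniformity", "volume_voxels", "volume_ml", "sphericity", "compacity",
)
GLCM_NAMES = ("homogeneity", "energy", "contrast", "correlation", "entropy", "dissimilarity")
GLRLM_NAMES = ("sre", "lre", "lgre", "hgre", "srlge", "srhge", "lrlge", "lrhge",
               "glnu", "rlnu", "rp")
NGLDM_NAMES = ("coarseness", "contrast", "busyness")
GLZLM_NAMES = ("sze", "lze", "lgze", "hgze", "szlge", "szhge", "lzlge", "lzhge",
               "glnu", "zlnu", "zp")

FEATURE_FAMILIES: dict[str, tuple[str, ...]] = {
    "firstorder": FIRST_ORDER_NAMES,
    "glcm": GLCM_NAMES,
    "glrlm": GLRLM_NAMES,
    "ngldm": NGLDM_NAMES,
    "glzlm": GLZLM_NAMES,
}


def feature_names() -> list[str]:
    """The 43 ``<family>_<feature>`` names, in catalogue order."""
    return [f"{fam}_{name}" for fam, names in FEATURE_FAMILIES.items() for name in names]


@dataclass
class DiscretizedRoi:
    """ROI intensities mapped to integer grey levels.

    ``levels`` holds values in ``1..n_levels`` inside the mask and the
    background sentinel 0 outside.
    """

    levels: np.ndarray
    n_levels: int
    source_min: float
    source_max: float

    @property
    def n_voxels(self) -> int:
        return int((self.levels > 0).sum())

    def in_roi_levels(self) -> np.ndarray:
        return self.levels[self.levels > 0]


def discretize_roi(volume: ImageVolume, mask: RoiMask, n_levels: int = 64) -> DiscretizedRoi:
    """Min–max relative discretization of in-ROI intensities to ``n_levels``.

    level(x) = min(N, floor(N * (x - min) / (max - min)) + 1); a uniform
    ROI (max == min) maps entirely to level 1.
    """
    if n_levels < 2:
        raise ValueError(f"n_levels must be >= 2, got {n_levels}")
    check_geometry(volume, mask)
    # crop to the ROI bounding box (1-voxel pad): texture matrices depend
    # only on in-ROI voxels and their adjacency
    bbox = ndimage.find_objects(mask.voxels.astype(np.int8))[0]
    pad = tuple(slice(max(s.start - 1, 0), min(s.stop + 1, n))
                for s, n in zip(bbox, mask.voxels.shape))
    m = mask.voxels[pad]
    intens = volume.intensities[pad]
    vals = intens[m]
    vmin, vmax = float(vals.min()), float(vals.max())
    levels = np.zeros(m.shape, dtype=np.int32)
    if vmax == vmin:
        levels[m] = 1
    else:
        scaled = np.floor(n_levels * (intens[m] - vmin) / (vmax - vmin)) + 1
        levels[m] = np.minimum(scaled, n_levels).astype(np.int32)
    return DiscretizedRoi(levels, n_levels, vmin, vmax)


def _shift(a: np.ndarray, d: Sequence[int], fill=0) -> np.ndarray:
    """Return b with b[v] = a[v + d] (out-of-bounds filled)."""
    out = np.full_like(a, fill)
    if any(abs(di) >= n for di, n in zip(d, a.shape)):
        return out
    src, dst = [], []
    for di, n in zip(d, a.shape):
        src.append(slice(max(di, 0), n + min(di, 0)))
        dst.append(slice(max(-di, 0), n + min(-di, 0)))
    out[tuple(dst)] = a[tuple(src)]
    return out


# ---------------------------------------------------------------------------
# first order
# ---------------------------------------------------------------------------

def _surface_area_mm2(mask: np.ndarray, spacing: Sequence[float]) -> float:
    """Mesh-free surface area from exposed voxel faces."""
    area = 0.0
    face = {
        0: spacing[1] * spacing[2],
        1: spacing[0] * spacing[2],
        2: spacing[0] * spacing[1],
    }
    for axis in range(3):
        for sign in (-1, 1):
            d = [0, 0, 0]
            d[axis] = sign
            exposed = mask & ~_shift(mask, d, fill=False)
            area += exposed.sum() * face[axis]
    return float(area)


def first_order_features(volume: ImageVolume, mask: RoiMask, n_levels: int = 64) -> dict[str, float]:
    """12 first-order features: 8 histogram statistics on raw in-ROI
    intensities (entropy/uniformity on the ``n_levels``-bin discretized
    histogram, entropy base 2) and 4 shape descriptors.

    ``std`` is the population standard deviation. Skewness and kurtosis
    (non-excess) are NaN for single-voxel or zero-variance ROIs.
    Sphericity is pi^(1/3) (6V)^(2/3) / A and compacity A^(3/2) / V with
    V in mm^3 and A in mm^2 from exposed-face counting.
    """
    check_geometry(volume, mask)
    vals = volume.intensities[mask.voxels].astype(np.float64)
    n = vals.size
    mean = float(vals.mean())
    std = float(vals.std())  # population
    if n < 2 or std == 0.0:
        skew = float("nan")
        kurt = float("nan")
    else:
        z = (vals - mean) / std
        skew = float(np.mean(z**3))
        kurt = float(np.mean(z**4))

    droi = discretize_roi(volume, mask, n_levels)
    counts = np.bincount(droi.in_roi_levels(), minlength=n_levels + 1)[1:]
    p = counts[counts > 0] / n
    entropy = float(-(p * np.log2(p)).sum())
    uniformity = float((p**2).sum())

    spacing = volume.voxel_spacing_mm
    voxel_mm3 = spacing[0] * spacing[1] * spacing[2]
    vol_mm3 = n * voxel_mm3
    area = _surface_area_mm2(mask.voxels, spacing)
    sphericity = float(np.pi ** (1 / 3) * (6.0 * vol_mm3) ** (2 / 3) / area)
    compacity = float(area ** 1.5 / vol_mm3)

    return {
        "min": float(vals.min()),
        "max": float(vals.max()),
        "mean": mean,
        "std": std,
        "skewness": skew,
        "kurtosis": kurt,
        "entropy": entropy,
        "uniformity": uniformity,
        "volume_voxels": float(n),
        "volume_ml": vol_mm3 / 1000.0,
        "sphericity": sphericity,
        "compacity": compacity,
    }


# ---------------------------------------------------------------------------
# GLCM
# ---------------------------------------------------------------------------

def glcm_matrix(droi: DiscretizedRoi,
                directions: Sequence[Sequence[int]] = DIRECTIONS_13) -> np.ndarray:
    """Symmetric co-occurrence counts pooled over *directions* (distance 1)."""
    lv = droi.levels
    n = droi.n_levels
    counts = np.zeros((n, n), dtype=np.float64)
    for d in directions:
        nb = _shift(lv, d)
        valid = (lv > 0) & (nb > 0)
        if not valid.any():
            continue
        i = lv[valid] - 1
        j = nb[valid] - 1
        c = np.bincount(i * n + j, minlength=n * n).reshape(n, n)
        counts += c + c.T
    return counts


def glcm_features(droi: DiscretizedRoi,
                  directions: Sequence[Sequence[int]] = DIRECTIONS_13) -> dict[str, float]:
    """6 GLCM features on the pooled, normalized co-occurrence matrix.

    Correlation is NaN when either marginal is degenerate (uniform ROI);
    all six are NaN when the ROI contains no neighbour pair at all.
    """
    counts = glcm_matrix(droi, directions)
    total = counts.sum()
    if total == 0:
        return {name: float("nan") for name in GLCM_NAMES}
    p = counts / total
    n = droi.n_levels
    i = np.arange(1, n + 1, dtype=np.float64)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    pi = p.sum(axis=1)
    mu_i = float((i * pi).sum())
    sigma_i = float(np.sqrt(((i - mu_i) ** 2 * pi).sum()))
    # symmetric matrix: both marginals coincide
    if sigma_i > 0:
        corr = float((((ii - mu_i) * (jj - mu_i) * p).sum()) / (sigma_i * sigma_i))
    else:
        corr = float("nan")
    nz = p[p > 0]
    return {
        "homogeneity": float((p / (1.0 + np.abs(ii - jj))).sum()),
        "energy": float((p**2).sum()),
        "contrast": float(((ii - jj) ** 2 * p).sum()),
        "correlation": corr,
        "entropy": float(-(nz * np.log2(nz)).sum()),
        "dissimilarity": float((np.abs(ii - jj) * p).sum()),
    }


# ---------------------------------------------------------------------------
# GLRLM
# ---------------------------------------------------------------------------

def _run_lengths_one_direction(levels: np.ndarray, d: Sequence[int]) -> tuple[np.ndarray, np.ndarray]:
    """(level, length) of every maximal run along direction *d*.

    Run lengths are computed by logarithmic doubling: f(v) = number of
    consecutive same-level in-ROI voxels starting at v along +d.
    """
    in_roi = levels > 0
    f = in_roi.astype(np.int64)
    k = 1
    bound = max(levels.shape)
    while k < bound:
        kd = [k * di for di in d]
        lev_k = _shift(levels, kd)
        extend = (f == k) & (lev_k == levels) & (lev_k > 0)
        if not extend.any():
            break
        f = f + np.where(extend, _shift(f, kd), 0)
        k *= 2
    prev = _shift(levels, [-di for di in d])
    starts = in_roi & ~((prev == levels) & (prev > 0))
    return levels[starts], f[starts]


def glrlm_matrix(droi: DiscretizedRoi,
                 directions: Sequence[Sequence[int]] = DIRECTIONS_13) -> np.ndarray:
    """Run-length counts ``r[level-1, length-1]`` pooled over *directions*."""
    max_len = int(np.ceil(np.sqrt(3) * max(droi.levels.shape))) + 1
    mat = np.zeros((droi.n_levels, max_len), dtype=np.float64)
    for d in directions:
        lv, ln = _run_lengths_one_direction(droi.levels, d)
        np.add.at(mat, (lv - 1, ln - 1), 1.0)
    used = np.nonzero(mat.any(axis=0))[0]
    if used.size:
        mat = mat[:, : used[-1] + 1]
    else:
        mat = mat[:, :1]
    return mat


def _length_indexed_features(mat: np.ndarray, per_voxel_denominator: int) -> dict[str, float]:
    """The 11 shared run/zone indices of a (level x length) matrix."""
    total = mat.sum()
    i = np.arange(1, mat.shape[0] + 1, dtype=np.float64)[:, None]
    l = np.arange(1, mat.shape[1] + 1, dtype=np.float64)[None, :]
    s = {
        "s": float((mat / l**2).sum() / total),
        "l": float((mat * l**2).sum() / total),
        "lg": float((mat / i**2).sum() / total),
        "hg": float((mat * i**2).sum() / total),
        "slg": float((mat / (i**2 * l**2)).sum() / total),
        "shg": float((mat * i**2 / l**2).sum() / total),
        "llg": float((mat * l**2 / i**2).sum() / total),
        "lhg": float((mat * i**2 * l**2).sum() / total),
        "glnu": float((mat.sum(axis=1) ** 2).sum() / total),
        "lnu": float((mat.sum(axis=0) ** 2).sum() / total),
        "p": float(total / per_voxel_denominator),
    }
    return s


def glrlm_features(droi: DiscretizedRoi,
                   directions: Sequence[Sequence[int]] = DIRECTIONS_13) -> dict[str, float]:
    """11 GLRLM features (Galloway/Chu indices) on the pooled matrix.

    RP = total runs / (n_directions x in-ROI voxel count), so a fully
    fragmented ROI gives RP = 1.
    """
    mat = glrlm_matrix(droi, directions)
    s = _length_indexed_features(mat, len(directions) * droi.n_voxels)
    return {
        "sre": s["s"], "lre": s["l"], "lgre": s["lg"], "hgre": s["hg"],
        "srlge": s["slg"], "srhge": s["shg"], "lrlge": s["llg"], "lrhge": s["lhg"],
        "glnu": s["glnu"], "rlnu": s["lnu"], "rp": s["p"],
    }


# ---------------------------------------------------------------------------
# NGLDM
# ---------------------------------------------------------------------------

def ngldm_table(droi: DiscretizedRoi) -> tuple[np.ndarray, np.ndarray]:
    """Per-level voxel counts N_i and difference sums s_i.

    For each in-ROI voxel the contribution is |level - mean(level of in-ROI
    26-neighbours)|; voxels with no in-ROI neighbour are excluded.
    """
    lv = droi.levels
    n = droi.n_levels
    kernel = np.ones((3, 3, 3))
    kernel[1, 1, 1] = 0.0
    in_roi = (lv > 0).astype(np.float64)
    nb_sum = ndimage.convolve(lv.astype(np.float64) * in_roi, kernel, mode="constant")
    nb_cnt = ndimage.convolve(in_roi, kernel, mode="constant")
    valid = (lv > 0) & (nb_cnt > 0)
    diffs = np.abs(lv[valid] - nb_sum[valid] / nb_cnt[valid])
    levels = lv[valid]
    counts = np.bincount(levels, minlength=n + 1)[1:].astype(np.float64)
    sums = np.bincount(levels, weights=diffs, minlength=n + 1)[1:]
    return counts, sums


def ngldm_features(droi: DiscretizedRoi, epsilon: float = NGLDM_EPSILON) -> dict[str, float]:
    """Amadasun–King coarseness, contrast and busyness.

    Coarseness carries an additive guard ``epsilon`` in the denominator so
    the uniform-ROI limit is the finite value 1/epsilon; contrast and
    busyness are NaN when only one grey level is present.
    """
    counts, sums = ngldm_table(droi)
    n_total = counts.sum()
    if n_total == 0:
        return {name: float("nan") for name in NGLDM_NAMES}
    present = counts > 0
    p = counts / n_total
    i = np.arange(1, droi.n_levels + 1, dtype=np.float64)
    ng = int(present.sum())
    coarseness = float(1.0 / ((p * sums).sum() + epsilon))
    if ng < 2:
        contrast = float("nan")
        busyness = float("nan")
    else:
        ip, jp = np.meshgrid(i[present], i[present], indexing="ij")
        pp = p[present]
        contrast = float(
            (pp[:, None] * pp[None, :] * (ip - jp) ** 2).sum() / (ng * (ng - 1))
            * sums.sum() / n_total
        )
        denom = float(np.abs(ip * pp[:, None] - jp * pp[None, :]).sum())
        busyness = float((p * sums).sum() / denom) if denom > 0 else float("nan")
    return {"coarseness": coarseness, "contrast": contrast, "busyness": busyness}


# ---------------------------------------------------------------------------
# GLZLM
# ---------------------------------------------------------------------------

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


def glzlm_matrix(droi: DiscretizedRoi) -> np.ndarray:
    """Zone counts ``z[level-1, size-1]``; zones are maximal 26-connected
    components of equal grey level."""
    lv = droi.levels
    v = droi.n_voxels
    mat = np.zeros((droi.n_levels, max(v, 1)), dtype=np.float64)
    for level in np.unique(lv[lv > 0]):
        labeled, n_zones = ndimage.label(lv == level, structure=_STRUCT_26)
        if n_zones == 0:
            continue
        sizes = np.bincount(labeled.ravel())[1:]
        np.add.at(mat, (int(level) - 1, sizes - 1), 1.0)
    used = np.nonzero(mat.any(axis=0))[0]
    mat = mat[:, : used[-1] + 1] if used.size else mat[:, :1]
    return mat


def glzlm_features(droi: DiscretizedRoi) -> dict[str, float]:
    """11 GLZLM features; ZP = zones / in-ROI voxel count."""
    mat = glzlm_matrix(droi)
    s = _length_indexed_features(mat, droi.n_voxels)
    return {
        "sze": s["s"], "lze": s["l"], "lgze": s["lg"], "hgze": s["hg"],
        "szlge": s["slg"], "szhge": s["shg"], "lzlge": s["llg"], "lzhge": s["lhg"],
        "glnu": s["glnu"], "zlnu": s["lnu"], "zp": s["p"],
    }


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

def extract_roi_features(volume: ImageVolume, mask: RoiMask, n_levels: int = 64) -> dict[str, float]:
    """All 43 features of one ROI on one sequence, keyed ``<family>_<feature>``."""
    if mask.n_voxels == 0:
        raise EmptyRoiError(f"empty {mask.structure_label} mask passed to feature extraction")
    droi = discretize_roi(volume, mask, n_levels)
    out: dict[str, float] = {}
    for name, val in first_order_features(volume, mask, n_levels).items():
        out[f"firstorder_{name}"] = val
    for name, val in glcm_features(droi).items():
        out[f"glcm_{name}"] = val
    for name, val in glrlm_features(droi).items():
        out[f"glrlm_{name}"] = val
    for name, val in ngldm_features(droi).items():
        out[f"ngldm_{name}"] = val
    for name, val in glzlm_features(droi).items():
        out[f"glzlm_{name}"] = val
    return out


def extract_structure_features(volumes: Mapping[str, ImageVolume], mask: RoiMask,
                               n_levels: int = 64) -> dict[str, float]:
    """86 features of one structure: 43 per sequence, keyed
    ``<sequence>_<family>_<feature>``."""
    out: dict[str, float] = {}
    for seq in sorted(volumes):
        for name, val in extract_roi_features(volumes[seq], mask, n_levels).items():
            out[f"{seq}_{name}"] = val
    return out


def extract_all(volumes: Mapping[str, ImageVolume], masks: Mapping[str, RoiMask],
                n_levels: int = 64) -> dict[str, dict[str, float]]:
    """Per structure, the 86-entry feature vector over both sequences.

    Missing values (degenerate ROIs) propagate as NaN; nothing is imputed
    at this stage.
    """
    return {
        structure: extract_structure_features(volumes, mask, n_levels)
        for structure, mask in masks.items()
    }
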