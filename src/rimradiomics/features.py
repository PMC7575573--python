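"""The 100-feature radiomic panel and the 200-dimensional per-lesion vector.

The panel covers seven families computed on discretized gray levels inside a
region of interest (first-order statistics, GLCM, GLRLM, GLSZM, NGTDM, NGLDM)
plus Gabor filter-bank responses on the raw intensities.  Per lesion the panel
is evaluated twice — on the tumor mask and on the 3 mm-dilated mask — and the
peritumoral-rim features are the differences::

    rim_f = f(dilated region) - f(tumor region)

yielding exactly 100 ``intratumoral_*`` and 100 ``rim_*`` values.

Texture conventions (documented, IBSI-style):

* discretization: within-mask min–max equal-width binning into ``n_bins``
  levels (default 32); constant regions map to level 1;
* GLCM/GLRLM: the 13 unique 3D directions at Chebyshev distance 1, features
  computed per direction and averaged; GLCM is symmetric and normalized;
* GLSZM: zones by 26-connectivity;
* NGTDM/NGLDM: 26-neighborhoods, out-of-mask neighbors excluded;
* logarithms are base 2; degenerate statistics follow the conventions noted
  on each function (e.g. GLCM correlation on a zero-variance region is 0).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal
from skimage.filters import gabor_kernel

from .imaging import CTVolume, LesionRegions, VOIMask, ValidationError

__all__ = [
    "DiscretizedRegion",
    "TextureMatrix",
    "LesionTooSmallError",
    "ExtractionError",
    "FEATURE_MANIFEST",
    "MANIFEST_VERSION",
    "feature_manifest",
    "discretize_region",
    "first_order_features",
    "glcm_features",
    "glrlm_features",
    "glszm_features",
    "ngtdm_features",
    "ngldm_features",
    "gabor_features",
    "compute_panel",
    "extract_lesion_features",
]

MIN_TEXTURE_VOXELS = 27          # texture is ill-defined below a 3x3x3 core
DEFAULT_N_BINS = 32
COARSENESS_DEGENERATE = 1.0e6    # NGTDM coarseness when the denominator is 0
_LOG_EPS = np.finfo(float).tiny

# 13 unique 3D directions (half of the 26-neighborhood, up to sign)
DIRECTIONS_3D: tuple[tuple[int, int, int], ...] = tuple(
    d for d in itertools.product((-1, 0, 1), repeat=3)
    if d > (0, 0, 0)
)
assert len(DIRECTIONS_3D) == 13

# Gabor bank: 4 orientations x 2 wavelengths (mm on the isotropic 1 mm grid)
GABOR_ORIENTATIONS_DEG = (0.0, 45.0, 90.0, 135.0)
GABOR_WAVELENGTHS_MM = (4.0, 8.0)


class LesionTooSmallError(ValidationError):
    """Region below the 27-voxel texture floor."""


class ExtractionError(RuntimeError):
    """A feature evaluated to a non-finite value."""


@dataclass
class DiscretizedRegion:
    """Gray levels 1..n_bins on an in-mask grid (0 outside the mask)."""

    levels: np.ndarray          # int array, cropped to the mask bounding box
    mask: np.ndarray            # bool, same shape
    n_bins: int
    bin_edges: np.ndarray       # HU edges, length n_bins + 1
    region_id: str = ""

    @property
    def levels_in_mask(self) -> np.ndarray:
        return self.levels[self.mask]


@dataclass
class TextureMatrix:
    """A texture summary matrix with its aggregation metadata."""

    family: str
    values: np.ndarray
    meta: dict

    def normalized(self) -> np.ndarray:
        total = self.values.sum()
        return self.values / total if total > 0 else self.values


# ---------------------------------------------------------------------------
# Discretization
# ---------------------------------------------------------------------------

def discretize_region(
    volume: CTVolume | np.ndarray,
    mask: VOIMask | np.ndarray,
    n_bins: int = DEFAULT_N_BINS,
    region_id: str = "",
) -> DiscretizedRegion:
    """Min–max equal-width discretization of the in-mask intensities.

    Levels are 1..n_bins; a constant region maps entirely to level 1.
    Requires at least 27 in-mask voxels (texture matrices are undefined on
    degenerate regions).
    """
    if n_bins < 2:
        raise ValidationError(f"n_bins must be >= 2, got {n_bins}")
    arr = volume.intensities if isinstance(volume, CTVolume) else np.asarray(volume)
    m = (mask.data if isinstance(mask, VOIMask) else np.asarray(mask)) > 0
    n_vox = int(m.sum())
    if n_vox < MIN_TEXTURE_VOXELS:
        raise LesionTooSmallError(
            f"region has {n_vox} voxels; texture requires >= {MIN_TEXTURE_VOXELS}"
        )
    sl = ndimage.find_objects(m.astype(np.int8))[0]
    arr_c, m_c = arr[sl], m[sl]
    vals = arr_c[m_c]
    lo, hi = float(vals.min()), float(vals.max())
    levels = np.zeros(arr_c.shape, dtype=np.int32)
    if hi > lo:
        lv = np.floor((arr_c - lo) / (hi - lo) * n_bins).astype(np.int32) + 1
        np.clip(lv, 1, n_bins, out=lv)
        levels[m_c] = lv[m_c]
        edges = np.linspace(lo, hi, n_bins + 1)
    else:
        levels[m_c] = 1
        edges = lo + np.arange(n_bins + 1, dtype=float)
    return DiscretizedRegion(levels, m_c, int(n_bins), edges, region_id)


def _bin_levels(values: np.ndarray, n_bins: int) -> np.ndarray:
    """Bin a flat value array exactly as :func:`discretize_region` does."""
    lo, hi = float(values.min()), float(values.max())
    if hi <= lo:
        return np.ones(values.shape, dtype=np.int32)
    lv = np.floor((values - lo) / (hi - lo) * n_bins).astype(np.int32) + 1
    return np.clip(lv, 1, n_bins)


# ---------------------------------------------------------------------------
# First-order statistics
# ---------------------------------------------------------------------------

def first_order_features(
    volume: CTVolume | np.ndarray,
    mask: VOIMask | np.ndarray,
    n_bins: int = DEFAULT_N_BINS,
) -> dict[str, float]:
    """The 19 first-order statistics of the in-mask intensity distribution.

    Moments are population moments; skewness and kurtosis are defined as 0 on
    constant regions; entropy and uniformity operate on min–max discretized
    levels; kurtosis is non-excess (a normal distribution scores 3).
    """
    arr = volume.intensities if isinstance(volume, CTVolume) else np.asarray(volume)
    m = (mask.data if isinstance(mask, VOIMask) else np.asarray(mask)) > 0
    x = arr[m].astype(np.float64)
    if x.size == 0:
        raise ValidationError("empty mask")
    mean = float(x.mean())
    d = x - mean
    m2 = float(np.mean(d ** 2))
    m3 = float(np.mean(d ** 3))
    m4 = float(np.mean(d ** 4))
    skew = m3 / m2 ** 1.5 if m2 > 0 else 0.0
    kurt = m4 / m2 ** 2 if m2 > 0 else 0.0
    p10, p25, p50, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])
    inner = x[(x >= p10) & (x <= p90)]
    rmad = float(np.abs(inner - inner.mean()).mean()) if inner.size else 0.0
    levels = _bin_levels(x, n_bins)
    p = np.bincount(levels)[1:].astype(float)
    p = p[p > 0] / x.size
    return {
        "mean": mean,
        "variance": m2,
        "skewness": skew,
        "kurtosis": kurt,
        "energy": float(np.sum(x ** 2)),
        "entropy": float(-np.sum(p * np.log2(p))),
        "minimum": float(x.min()),
        "maximum": float(x.max()),
        "p10": float(p10),
        "p25": float(p25),
        "median": float(p50),
        "p75": float(p75),
        "p90": float(p90),
        "iqr": float(p75 - p25),
        "range": float(x.max() - x.min()),
        "mad": float(np.abs(d).mean()),
        "robust_mad": rmad,
        "rms": float(np.sqrt(np.mean(x ** 2))),
        "uniformity": float(np.sum(p ** 2)),
    }


FIRST_ORDER_NAMES = (
    "mean", "variance", "skewness", "kurtosis", "energy", "entropy",
    "minimum", "maximum", "p10", "p25", "median", "p75", "p90", "iqr",
    "range", "mad", "robust_mad", "rms", "uniformity",
)


# ---------------------------------------------------------------------------
# Shift helpers shared by the matrix families
# ---------------------------------------------------------------------------

def _shift_slices(shape, off):
    """Slice pair (center, neighbor) so arr[a] pairs with arr[b] offset by off."""
    a, b = [], []
    for n, o in zip(shape, off):
        if o >= 0:
            a.append(slice(0, n - o))
            b.append(slice(o, n))
        else:
            a.append(slice(-o, n))
            b.append(slice(0, n + o))
    return tuple(a), tuple(b)


_ALL_26 = tuple(d for d in itertools.product((-1, 0, 1), repeat=3) if d != (0, 0, 0))


# ---------------------------------------------------------------------------
# GLCM
# ---------------------------------------------------------------------------

def glcm_matrices(region: DiscretizedRegion) -> list[TextureMatrix]:
    """Symmetric, normalized co-occurrence matrix per 3D direction."""
    L, nb = region.levels, region.n_bins
    out = []
    for off in DIRECTIONS_3D:
        sa, sb = _shift_slices(L.shape, off)
        a, b = L[sa], L[sb]
        valid = (a > 0) & (b > 0)
        av, bv = a[valid] - 1, b[valid] - 1
        mat = np.zeros((nb, nb), dtype=np.float64)
        np.add.at(mat, (av, bv), 1.0)
        np.add.at(mat, (bv, av), 1.0)
        out.append(TextureMatrix("GLCM", mat, {"direction": off, "distance": 1,
                                               "symmetric": True}))
    return out


def _glcm_stats(P: np.ndarray) -> dict[str, float]:
    nb = P.shape[0]
    i = np.arange(1, nb + 1, dtype=float)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = P.sum(axis=1)
    py = P.sum(axis=0)
    mux = float(np.sum(i * px))
    muy = float(np.sum(i * py))
    sx = float(np.sqrt(np.sum((i - mux) ** 2 * px)))
    sy = float(np.sqrt(np.sum((i - muy) ** 2 * py)))
    # diagonal (difference) and cross-diagonal (sum) distributions
    k_diff = np.arange(nb, dtype=float)
    p_diff = np.array([P[np.abs(ii - jj) == k].sum() for k in range(nb)])
    k_sum = np.arange(2, 2 * nb + 1, dtype=float)
    p_sum = np.array([P[(ii + jj) == k].sum() for k in range(2, 2 * nb + 1)])
    da = float(np.sum(k_diff * p_diff))
    sa = float(np.sum(k_sum * p_sum))
    nz = P > 0
    hxy = float(-np.sum(P[nz] * np.log2(P[nz])))
    pxy = np.outer(px, py)
    both = nz & (pxy > 0)
    hxy1 = float(-np.sum(P[both] * np.log2(pxy[both])))
    pz = pxy > 0
    hxy2 = float(-np.sum(pxy[pz] * np.log2(pxy[pz])))
    hx = float(-np.sum(px[px > 0] * np.log2(px[px > 0])))
    hy = float(-np.sum(py[py > 0] * np.log2(py[py > 0])))
    hmax = max(hx, hy)
    imc1 = (hxy - hxy1) / hmax if hmax > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))
    off = ii != jj
    pd = p_diff[p_diff > 0]
    ps = p_sum[p_sum > 0]
    corr = (float(np.sum(ii * jj * P)) - mux * muy) / (sx * sy) if sx > 0 and sy > 0 else 0.0
    return {
        "autocorrelation": float(np.sum(ii * jj * P)),
        "joint_average": mux,
        "joint_variance": float(np.sum((ii - mux) ** 2 * P)),
        "cluster_prominence": float(np.sum((ii + jj - mux - muy) ** 4 * P)),
        "cluster_shade": float(np.sum((ii + jj - mux - muy) ** 3 * P)),
        "cluster_tendency": float(np.sum((ii + jj - mux - muy) ** 2 * P)),
        "contrast": float(np.sum((ii - jj) ** 2 * P)),
        "correlation": corr,
        "difference_average": da,
        "difference_entropy": float(-np.sum(pd * np.log2(pd))),
        "difference_variance": float(np.sum((k_diff - da) ** 2 * p_diff)),
        "joint_energy": float(np.sum(P ** 2)),
        "joint_entropy": hxy,
        "inverse_difference": float(np.sum(P / (1.0 + np.abs(ii - jj)))),
        "inverse_difference_moment": float(np.sum(P / (1.0 + (ii - jj) ** 2))),
        "idmn": float(np.sum(P / (1.0 + ((ii - jj) / nb) ** 2))),
        "idn": float(np.sum(P / (1.0 + np.abs(ii - jj) / nb))),
        "imc1": imc1,
        "imc2": imc2,
        "inverse_variance": float(np.sum(P[off] / (ii[off] - jj[off]) ** 2)),
        "maximum_probability": float(P.max()),
        "sum_average": sa,
        "sum_entropy": float(-np.sum(ps * np.log2(ps))),
        "sum_variance": float(np.sum((k_sum - sa) ** 2 * p_sum)),
    }


GLCM_NAMES = (
    "autocorrelation", "joint_average", "joint_variance", "cluster_prominence",
    "cluster_shade", "cluster_tendency", "contrast", "correlation",
    "difference_average", "difference_entropy", "difference_variance",
    "joint_energy", "joint_entropy", "inverse_difference",
    "inverse_difference_moment", "idmn", "idn", "imc1", "imc2",
    "inverse_variance", "maximum_probability", "sum_average", "sum_entropy",
    "sum_variance",
)


def glcm_features(region: DiscretizedRegion) -> dict[str, float]:
    """24 co-occurrence features, averaged over the 13 directions.

    Directions with no co-occurring in-mask pair are skipped in the average.
    """
    stats, n_used = None, 0
    for tm in glcm_matrices(region):
        tot = tm.values.sum()
        if tot == 0:
            continue
        s = _glcm_stats(tm.values / tot)
        if stats is None:
            stats = {k: 0.0 for k in s}
        for k, v in s.items():
            stats[k] += v
        n_used += 1
    if stats is None:
        raise LesionTooSmallError("no co-occurring voxel pairs in region")
    return {k: v / n_used for k, v in stats.items()}


# ---------------------------------------------------------------------------
# GLRLM
# ---------------------------------------------------------------------------

def glrlm_matrices(region: DiscretizedRegion) -> list[TextureMatrix]:
    """Run-length matrix (level x run length) per 3D direction."""
    L = region.levels
    nb = region.n_bins
    max_len = max(L.shape)
    out = []
    for off in DIRECTIONS_3D:
        d = np.array(off)
        # run starts: in-mask voxels whose predecessor along -off has a
        # different level (or is out of mask / out of bounds)
        pred = np.zeros_like(L)
        sa, sb = _shift_slices(L.shape, tuple(-d))
        pred[sa] = L[sb]
        starts = (L > 0) & (pred != L)
        coords = np.argwhere(starts)
        lv = L[starts]
        lengths = np.ones(len(coords), dtype=np.int64)
        cur = coords.copy()
        active = np.arange(len(coords))
        while active.size:
            cur_a = cur[active] + d
            inb = np.all((cur_a >= 0) & (cur_a < L.shape), axis=1)
            idx = active[inb]
            pos = cur_a[inb]
            same = L[pos[:, 0], pos[:, 1], pos[:, 2]] == lv[idx]
            idx = idx[same]
            lengths[idx] += 1
            cur[idx] += d
            active = idx
        mat = np.zeros((nb, max_len), dtype=np.float64)
        np.add.at(mat, (lv - 1, lengths - 1), 1.0)
        out.append(TextureMatrix("GLRLM", mat, {"direction": off}))
    return out


def _rlm_stats(R: np.ndarray, n_vox: int) -> dict[str, float]:
    nr = R.sum()
    i = np.arange(1, R.shape[0] + 1, dtype=float)
    j = np.arange(1, R.shape[1] + 1, dtype=float)
    ii, jj = np.meshgrid(i, j, indexing="ij")
    ri = R.sum(axis=1)
    rj = R.sum(axis=0)
    p = R / nr
    mu_g = float(np.sum(ii * p))
    mu_r = float(np.sum(jj * p))
    pnz = p[p > 0]
    return {
        "short_run_emphasis": float(np.sum(rj / j ** 2) / nr),
        "long_run_emphasis": float(np.sum(rj * j ** 2) / nr),
        "gray_level_nonuniformity": float(np.sum(ri ** 2) / nr),
        "gray_level_nonuniformity_normalized": float(np.sum(ri ** 2) / nr ** 2),
        "run_length_nonuniformity": float(np.sum(rj ** 2) / nr),
        "run_length_nonuniformity_normalized": float(np.sum(rj ** 2) / nr ** 2),
        "run_percentage": float(nr / n_vox),
        "gray_level_variance": float(np.sum((ii - mu_g) ** 2 * p)),
        "run_length_variance": float(np.sum((jj - mu_r) ** 2 * p)),
        "run_entropy": float(-np.sum(pnz * np.log2(pnz))),
        "low_gray_level_run_emphasis": float(np.sum(ri / i ** 2) / nr),
        "high_gray_level_run_emphasis": float(np.sum(ri * i ** 2) / nr),
        "short_run_low_gray_level_emphasis": float(np.sum(R / (ii ** 2 * jj ** 2)) / nr),
        "short_run_high_gray_level_emphasis": float(np.sum(R * ii ** 2 / jj ** 2) / nr),
        "long_run_low_gray_level_emphasis": float(np.sum(R * jj ** 2 / ii ** 2) / nr),
        "long_run_high_gray_level_emphasis": float(np.sum(R * ii ** 2 * jj ** 2) / nr),
    }


GLRLM_NAMES = tuple(_rlm_stats(np.ones((2, 2)), 4).keys())


def glrlm_features(region: DiscretizedRegion) -> dict[str, float]:
    """16 run-length features, averaged over the 13 directions."""
    n_vox = int(region.mask.sum())
    acc = None
    mats = glrlm_matrices(region)
    for tm in mats:
        s = _rlm_stats(tm.values, n_vox)
        if acc is None:
            acc = {k: 0.0 for k in s}
        for k, v in s.items():
            acc[k] += v
    return {k: v / len(mats) for k, v in acc.items()}


# ---------------------------------------------------------------------------
# GLSZM
# ---------------------------------------------------------------------------

_STRUCT_26 = np.ones((3, 3, 3), dtype=np.int8)


def glszm_matrix(region: DiscretizedRegion) -> TextureMatrix:
    """Size-zone matrix (level x zone size) with 26-connected zones."""
    L = region.levels
    nb = region.n_bins
    n_vox = int(region.mask.sum())
    mat = np.zeros((nb, n_vox), dtype=np.float64)
    for g in np.unique(L[L > 0]):
        lab, n = ndimage.label(L == g, structure=_STRUCT_26)
        if n == 0:
            continue
        sizes = np.bincount(lab.ravel())[1:]
        for s in sizes:
            mat[g - 1, s - 1] += 1.0
    return TextureMatrix("GLSZM", mat, {"connectivity": 26})


def _szm_stats(Z: np.ndarray, n_vox: int) -> dict[str, float]:
    nz = Z.sum()
    i = np.arange(1, Z.shape[0] + 1, dtype=float)
    j = np.arange(1, Z.shape[1] + 1, dtype=float)
    ii, jj = np.meshgrid(i, j, indexing="ij")
    zi = Z.sum(axis=1)
    zj = Z.sum(axis=0)
    p = Z / nz
    mu_g = float(np.sum(ii * p))
    mu_z = float(np.sum(jj * p))
    pnz = p[p > 0]
    return {
        "small_area_emphasis": float(np.sum(zj / j ** 2) / nz),
        "large_area_emphasis": float(np.sum(zj * j ** 2) / nz),
        "gray_level_nonuniformity": float(np.sum(zi ** 2) / nz),
        "gray_level_nonuniformity_normalized": float(np.sum(zi ** 2) / nz ** 2),
        "size_zone_nonuniformity": float(np.sum(zj ** 2) / nz),
        "size_zone_nonuniformity_normalized": float(np.sum(zj ** 2) / nz ** 2),
        "zone_percentage": float(nz / n_vox),
        "gray_level_variance": float(np.sum((ii - mu_g) ** 2 * p)),
        "zone_variance": float(np.sum((jj - mu_z) ** 2 * p)),
        "zone_entropy": float(-np.sum(pnz * np.log2(pnz))),
        "low_gray_level_zone_emphasis": float(np.sum(zi / i ** 2) / nz),
        "high_gray_level_zone_emphasis": float(np.sum(zi * i ** 2) / nz),
        "small_area_low_gray_level_emphasis": float(np.sum(Z / (ii ** 2 * jj ** 2)) / nz),
        "small_area_high_gray_level_emphasis": float(np.sum(Z * ii ** 2 / jj ** 2) / nz),
        "large_area_low_gray_level_emphasis": float(np.sum(Z * jj ** 2 / ii ** 2) / nz),
        "large_area_high_gray_level_emphasis": float(np.sum(Z * ii ** 2 * jj ** 2) / nz),
    }


GLSZM_NAMES = tuple(_szm_stats(np.ones((2, 2)), 4).keys())


def glszm_features(region: DiscretizedRegion) -> dict[str, float]:
    """16 size-zone features (single matrix; zones are direction-free)."""
    tm = glszm_matrix(region)
    return _szm_stats(tm.values, int(region.mask.sum()))


# ---------------------------------------------------------------------------
# NGTDM
# ---------------------------------------------------------------------------

def _neighbor_sums(L: np.ndarray):
    """Per-voxel sum and count of in-mask 26-neighbor levels."""
    s = np.zeros(L.shape, dtype=np.float64)
    c = np.zeros(L.shape, dtype=np.float64)
    inm = L > 0
    for off in _ALL_26:
        sa, sb = _shift_slices(L.shape, off)
        s[sa] += np.where(inm[sb], L[sb], 0)
        c[sa] += inm[sb]
    return s, c


def ngtdm_features(region: DiscretizedRegion) -> dict[str, float]:
    """5 neighborhood gray-tone difference features (coarseness, contrast,
    busyness, complexity, strength).

    Voxels without any in-mask neighbor are excluded.  Degenerate
    conventions: coarseness with zero denominator is ``1e6``; contrast with a
    single gray level, busyness and strength with zero denominators are 0.
    """
    L = region.levels
    s, c = _neighbor_sums(L)
    use = (L > 0) & (c > 0)
    lv = L[use]
    abar = s[use] / c[use]
    diff = np.abs(lv - abar)
    nb = region.n_bins
    n_i = np.bincount(lv - 1, minlength=nb).astype(float)
    s_i = np.bincount(lv - 1, weights=diff, minlength=nb)
    N = n_i.sum()
    p_i = n_i / N
    present = p_i > 0
    ngp = int(present.sum())
    i = np.arange(1, nb + 1, dtype=float)
    denom_coarse = float(np.sum(p_i * s_i))
    coarseness = 1.0 / denom_coarse if denom_coarse > 0 else COARSENESS_DEGENERATE
    ii, jj = np.meshgrid(i[present], i[present], indexing="ij")
    pi, pj = np.meshgrid(p_i[present], p_i[present], indexing="ij")
    si, sj = np.meshgrid(s_i[present], s_i[present], indexing="ij")
    if ngp > 1:
        contrast = (float(np.sum(pi * pj * (ii - jj) ** 2)) / (ngp * (ngp - 1))
                    * float(s_i.sum()) / N)
    else:
        contrast = 0.0
    denom_busy = float(np.sum(np.abs(ii * pi - jj * pj)))
    busyness = denom_coarse / denom_busy if denom_busy > 0 else 0.0
    complexity = float(np.sum(np.abs(ii - jj) * (pi * si + pj * sj) / (pi + pj))) / N
    strength = (float(np.sum((pi + pj) * (ii - jj) ** 2)) / float(s_i.sum())
                if s_i.sum() > 0 else 0.0)
    return {
        "coarseness": coarseness,
        "contrast": contrast,
        "busyness": busyness,
        "complexity": complexity,
        "strength": strength,
    }


NGTDM_NAMES = ("coarseness", "contrast", "busyness", "complexity", "strength")


# ---------------------------------------------------------------------------
# NGLDM
# ---------------------------------------------------------------------------

def ngldm_matrix(region: DiscretizedRegion) -> TextureMatrix:
    """Dependence matrix (level x dependence size).

    The dependence size of a voxel is 1 plus the number of in-mask
    26-neighbors sharing its exact gray level (coarseness tolerance 0).
    """
    L = region.levels
    inm = L > 0
    dep = np.ones(L.shape, dtype=np.int64)
    for off in _ALL_26:
        sa, sb = _shift_slices(L.shape, off)
        dep[sa] += (inm[sa] & inm[sb] & (L[sa] == L[sb]))
    nb = region.n_bins
    mat = np.zeros((nb, 27), dtype=np.float64)
    np.add.at(mat, (L[inm] - 1, dep[inm] - 1), 1.0)
    return TextureMatrix("NGLDM", mat, {"alpha": 0, "neighborhood": 26})


def _ngldm_stats(M: np.ndarray) -> dict[str, float]:
    ns = M.sum()
    i = np.arange(1, M.shape[0] + 1, dtype=float)
    j = np.arange(1, M.shape[1] + 1, dtype=float)
    ii, jj = np.meshgrid(i, j, indexing="ij")
    mi = M.sum(axis=1)
    mj = M.sum(axis=0)
    p = M / ns
    mu_g = float(np.sum(ii * p))
    mu_d = float(np.sum(jj * p))
    pnz = p[p > 0]
    return {
        "small_dependence_emphasis": float(np.sum(mj / j ** 2) / ns),
        "large_dependence_emphasis": float(np.sum(mj * j ** 2) / ns),
        "gray_level_nonuniformity": float(np.sum(mi ** 2) / ns),
        "dependence_nonuniformity": float(np.sum(mj ** 2) / ns),
        "dependence_nonuniformity_normalized": float(np.sum(mj ** 2) / ns ** 2),
        "gray_level_variance": float(np.sum((ii - mu_g) ** 2 * p)),
        "dependence_variance": float(np.sum((jj - mu_d) ** 2 * p)),
        "dependence_entropy": float(-np.sum(pnz * np.log2(pnz))),
        "low_gray_level_emphasis": float(np.sum(mi / i ** 2) / ns),
        "high_gray_level_emphasis": float(np.sum(mi * i ** 2) / ns),
        "small_dependence_low_gray_level_emphasis": float(np.sum(M / (ii ** 2 * jj ** 2)) / ns),
        "small_dependence_high_gray_level_emphasis": float(np.sum(M * ii ** 2 / jj ** 2) / ns),
    }


NGLDM_NAMES = tuple(_ngldm_stats(np.ones((2, 2))).keys())


def ngldm_features(region: DiscretizedRegion) -> dict[str, float]:
    """12 neighborhood gray-level dependence features."""
    return _ngldm_stats(ngldm_matrix(region).values)


# ---------------------------------------------------------------------------
# Gabor
# ---------------------------------------------------------------------------

def _gabor_bank(orientations_deg=GABOR_ORIENTATIONS_DEG,
                wavelengths_mm=GABOR_WAVELENGTHS_MM):
    """DC-free complex Gabor kernels, one per (orientation, wavelength)."""
    bank = []
    for theta in orientations_deg:
        for lam in wavelengths_mm:
            # orientation label = angle of the grating's wave vector from the
            # first in-plane axis; skimage's theta is measured from the other
            k = gabor_kernel(frequency=1.0 / lam,
                             theta=np.deg2rad(90.0 - theta))
            k = k - k.mean()  # remove residual DC so flat regions respond 0
            bank.append(((theta, lam), k))
    return bank


def gabor_features(
    volume: CTVolume | np.ndarray,
    mask: VOIMask | np.ndarray,
    bank=None,
) -> dict[str, float]:
    """Mean in-mask Gabor magnitude response per bank element.

    Responses are computed in 2D on each axial slice intersecting the mask
    (edge content in CT is primarily in-plane); the per-element feature is
    the mean magnitude over all in-mask voxels.
    """
    arr = volume.intensities if isinstance(volume, CTVolume) else np.asarray(volume)
    m = (mask.data if isinstance(mask, VOIMask) else np.asarray(mask)) > 0
    if not m.any():
        raise ValidationError("empty mask for Gabor features")
    if bank is None:
        bank = _gabor_bank()
    sums = {key: 0.0 for key, _ in bank}
    n_total = 0
    for k in range(arr.shape[2]):
        mk = m[:, :, k]
        if not mk.any():
            continue
        sl = np.asarray(arr[:, :, k], dtype=np.float64)
        n_total += int(mk.sum())
        for key, kern in bank:
            # edge-replicate so image borders do not masquerade as edges
            ph, pw = kern.shape[0] // 2, kern.shape[1] // 2
            padded = np.pad(sl, ((ph, ph), (pw, pw)), mode="edge")
            resp = signal.fftconvolve(padded, kern, mode="valid")
            sums[key] += float(np.abs(resp)[mk].sum())
    return {
        f"mean_o{int(theta)}_w{int(lam)}": sums[(theta, lam)] / n_total
        for (theta, lam) in [key for key, _ in bank]
    }


GABOR_NAMES = tuple(
    f"mean_o{int(t)}_w{int(w)}"
    for t in GABOR_ORIENTATIONS_DEG for w in GABOR_WAVELENGTHS_MM
)


# ---------------------------------------------------------------------------
# Panel assembly
# ---------------------------------------------------------------------------

MANIFEST_VERSION = "1.0"

_FAMILY_NAMES = {
    "firstorder": FIRST_ORDER_NAMES,   # 19
    "glcm": GLCM_NAMES,                # 24
    "glrlm": GLRLM_NAMES,              # 16
    "glszm": GLSZM_NAMES,              # 16
    "ngtdm": NGTDM_NAMES,              # 5
    "ngldm": NGLDM_NAMES,              # 12
    "gabor": GABOR_NAMES,              # 8
}

FEATURE_MANIFEST: tuple[str, ...] = tuple(
    f"{fam}_{name}" for fam, names in _FAMILY_NAMES.items() for name in names
)
assert len(FEATURE_MANIFEST) == 100


def feature_manifest() -> dict:
    """The versioned 100-feature panel manifest (per region)."""
    return {
        "version": MANIFEST_VERSION,
        "n_features_per_region": len(FEATURE_MANIFEST),
        "regions": ["intratumoral", "rim"],
        "families": {fam: list(names) for fam, names in _FAMILY_NAMES.items()},
        "features": list(FEATURE_MANIFEST),
    }


def compute_panel(
    volume: CTVolume | np.ndarray,
    mask: VOIMask | np.ndarray,
    n_bins: int = DEFAULT_N_BINS,
    region_id: str = "",
) -> dict[str, float]:
    """Evaluate the full 100-feature panel on one region."""
    region = discretize_region(volume, mask, n_bins, region_id)
    out: dict[str, float] = {}
    for fam, vals in (
        ("firstorder", first_order_features(volume, mask, n_bins)),
        ("glcm", glcm_features(region)),
        ("glrlm", glrlm_features(region)),
        ("glszm", glszm_features(region)),
        ("ngtdm", ngtdm_features(region)),
        ("ngldm", ngldm_features(region)),
        ("gabor", gabor_features(volume, mask)),
    ):
        for name, v in vals.items():
            out[f"{fam}_{name}"] = v
    return out


def extract_lesion_features(
    volume: CTVolume,
    regions: LesionRegions,
    n_bins: int = DEFAULT_N_BINS,
) -> dict[str, float]:
    """The 200-dimensional lesion vector.

    The panel is computed on the tumor mask and on the dilated mask; rim
    values are the dilated-minus-tumor differences, so the identity
    ``rim_f + f(tumor) = f(dilated)`` holds exactly.
    """
    tumor_panel = compute_panel(volume, regions.tumor, n_bins, "tumor")
    dilated_panel = compute_panel(volume, regions.dilated, n_bins, "dilated")
    out: dict[str, float] = {}
    for name in FEATURE_MANIFEST:
        out[f"intratumoral_{name}"] = tumor_panel[name]
    for name in FEATURE_MANIFEST:
        out[f"rim_{name}"] = dilated_panel[name] - tumor_panel[name]
    for k, v in out.items():
        if not np.isfinite(v):
            raise ExtractionError(f"non-finite value for feature {k!r}")
    return out
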