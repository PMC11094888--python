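"""Texture features from five grey-level matrix families.

All matrices are computed in 3D on the fixed-bin-width discretized ROI:
GLCM (25 features, 13 symmetric directions at distance 1, feature-averaged),
GLRLM (16, direction-averaged), GLSZM (16, 26-connected zones), NGLDM/GLDM
(17, dependence counts over the 26-neighbourhood, alpha = 0) and NGTDM (5).
79 features in total; matrices index only grey levels present in the ROI.
"""

from __future__ import annotations

from typing import Dict, Tuple

import numpy as np
from scipy import ndimage

_EPS = np.spacing(1.0)

# 13 unique direction offsets covering the 26-neighbourhood (antipodes folded)
DIRECTIONS = [
    (0, 0, 1), (0, 1, 0), (1, 0, 0),
    (0, 1, 1), (0, 1, -1), (1, 0, 1), (1, 0, -1), (1, 1, 0), (1, -1, 0),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
]

GLCM_FEATURE_NAMES = [
    "JointMaximum", "JointAverage", "JointVariance", "JointEntropy",
    "DifferenceAverage", "DifferenceVariance", "DifferenceEntropy",
    "SumAverage", "SumVariance", "SumEntropy",
    "JointEnergy", "Contrast", "Dissimilarity",
    "InverseDifference", "InverseDifferenceNormalized",
    "InverseDifferenceMoment", "InverseDifferenceMomentNormalized",
    "InverseVariance", "Correlation", "Autocorrelation",
    "ClusterTendency", "ClusterShade", "ClusterProminence",
    "Imc1", "Imc2",
]

GLRLM_FEATURE_NAMES = [
    "ShortRunEmphasis", "LongRunEmphasis",
    "GrayLevelNonUniformity", "GrayLevelNonUniformityNormalized",
    "RunLengthNonUniformity", "RunLengthNonUniformityNormalized",
    "RunPercentage", "GrayLevelVariance", "RunVariance", "RunEntropy",
    "LowGrayLevelRunEmphasis", "HighGrayLevelRunEmphasis",
    "ShortRunLowGrayLevelEmphasis", "ShortRunHighGrayLevelEmphasis",
    "LongRunLowGrayLevelEmphasis", "LongRunHighGrayLevelEmphasis",
]

GLSZM_FEATURE_NAMES = [
    "SmallAreaEmphasis", "LargeAreaEmphasis",
    "GrayLevelNonUniformity", "GrayLevelNonUniformityNormalized",
    "SizeZoneNonUniformity", "SizeZoneNonUniformityNormalized",
    "ZonePercentage", "GrayLevelVariance", "ZoneVariance", "ZoneEntropy",
    "LowGrayLevelZoneEmphasis", "HighGrayLevelZoneEmphasis",
    "SmallAreaLowGrayLevelEmphasis", "SmallAreaHighGrayLevelEmphasis",
    "LargeAreaLowGrayLevelEmphasis", "LargeAreaHighGrayLevelEmphasis",
]

GLDM_FEATURE_NAMES = [
    "LowDependenceEmphasis", "HighDependenceEmphasis",
    "LowGrayLevelCountEmphasis", "HighGrayLevelCountEmphasis",
    "LowDependenceLowGrayLevelEmphasis", "LowDependenceHighGrayLevelEmphasis",
    "HighDependenceLowGrayLevelEmphasis", "HighDependenceHighGrayLevelEmphasis",
    "GrayLevelNonUniformity", "GrayLevelNonUniformityNormalized",
    "DependenceCountNonUniformity", "DependenceCountNonUniformityNormalized",
    "DependenceCountPercentage", "GrayLevelVariance",
    "DependenceCountVariance", "DependenceCountEntropy", "DependenceCountEnergy",
]

NGTDM_FEATURE_NAMES = ["Coarseness", "Contrast", "Busyness", "Complexity", "Strength"]

TEXTURE_FEATURE_NAMES = (
    [f"glcm_{n}" for n in GLCM_FEATURE_NAMES]
    + [f"glrlm_{n}" for n in GLRLM_FEATURE_NAMES]
    + [f"glszm_{n}" for n in GLSZM_FEATURE_NAMES]
    + [f"gldm_{n}" for n in GLDM_FEATURE_NAMES]
    + [f"ngtdm_{n}" for n in NGTDM_FEATURE_NAMES]
)


def _prepare(image, mask, bin_width):
    """Crop to the mask bounding box; return level image (0 = outside ROI)."""
    from ..preprocess import discretize_fixed_binwidth

    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("empty mask")
    sl = ndimage.find_objects(mask.astype(np.uint8))[0]
    m = mask[sl]
    img = np.asarray(image, dtype=float)[sl]
    roi_min = img[m].min()
    lv = np.zeros(m.shape, dtype=np.int64)
    lv[m] = discretize_fixed_binwidth(img[m], bin_width, roi_min)
    levels = np.unique(lv[m])
    remap = np.zeros(int(levels.max()) + 1, dtype=np.int64)
    remap[levels] = np.arange(1, levels.size + 1)
    lv[m] = remap[lv[m]]
    return lv, m, levels.size


def _shift_pairs(lv, d):
    """Aligned (a, b) level views at offset d; zeros mean outside-ROI."""
    sl_a, sl_b = [], []
    for k, dk in enumerate(d):
        n = lv.shape[k]
        if dk >= 0:
            sl_a.append(slice(0, n - dk))
            sl_b.append(slice(dk, n))
        else:
            sl_a.append(slice(-dk, n))
            sl_b.append(slice(0, n + dk))
    return lv[tuple(sl_a)], lv[tuple(sl_b)]


# ------------------------------------------------------------------ GLCM

_GLCM_GRID_CACHE: dict = {}


def _glcm_grids(ng: int):
    if ng not in _GLCM_GRID_CACHE:
        i = np.arange(1, ng + 1, dtype=float)
        ii = i[:, None] + np.zeros((1, ng))
        jj = ii.T
        k_diff = np.abs(ii - jj)
        diff_idx = k_diff.astype(np.int64).ravel()
        sum_idx = (ii + jj).astype(np.int64).ravel() - 2
        _GLCM_GRID_CACHE[ng] = (i, ii, jj, k_diff, diff_idx, sum_idx)
        if len(_GLCM_GRID_CACHE) > 8:
            _GLCM_GRID_CACHE.pop(next(iter(_GLCM_GRID_CACHE)))
    return _GLCM_GRID_CACHE[ng]


def _glcm_features_batch(P: np.ndarray, ng: int) -> Dict[str, np.ndarray]:
    """All 25 features for a batch of normalized GLCMs, shape (nd, ng, ng)."""
    i, ii, jj, k_diff, diff_idx, sum_idx = _glcm_grids(ng)
    nd = P.shape[0]
    Pf = P.reshape(nd, -1)
    px = P.sum(axis=2)  # (nd, ng)
    mu = (i * px).sum(axis=1)  # symmetric: mu_x == mu_y
    sigma2 = (((i - mu[:, None]) ** 2) * px).sum(axis=1)

    diff_levels = np.arange(0, ng, dtype=float)
    sum_levels = np.arange(2, 2 * ng + 1, dtype=float)
    p_diff = np.vstack([np.bincount(diff_idx, weights=Pf[d], minlength=ng)
                        for d in range(nd)])
    p_sum = np.vstack([np.bincount(sum_idx, weights=Pf[d],
                                   minlength=2 * ng - 1) for d in range(nd)])

    def _ent(p):
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(p > 0, p * np.log2(np.where(p > 0, p, 1.0)), 0.0)
        return -t.sum(axis=1)

    da = (diff_levels * p_diff).sum(axis=1)
    dv = (((diff_levels - da[:, None]) ** 2) * p_diff).sum(axis=1)
    de = _ent(p_diff)
    sa = (sum_levels * p_sum).sum(axis=1)
    sv = (((sum_levels - sa[:, None]) ** 2) * p_sum).sum(axis=1)
    se = _ent(p_sum)

    joint_entropy = _ent(Pf)
    hx = _ent(px)
    pxy = px[:, :, None] * px[:, None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        hxy1 = -(np.where(P > 0, P * np.log2(pxy + _EPS), 0.0)
                 ).sum(axis=(1, 2))
        hxy2 = -(np.where(pxy > 0, pxy * np.log2(np.where(pxy > 0, pxy, 1.0)),
                          0.0)).sum(axis=(1, 2))
    imc1 = np.where(hx > 0, (joint_entropy - hxy1) / np.where(hx > 0, hx, 1.0),
                    0.0)
    imc2 = np.sqrt(np.clip(1 - np.exp(-2 * (hxy2 - joint_entropy)), 0.0, None))

    auto = (ii * jj * P).sum(axis=(1, 2))
    corr = np.where(sigma2 > 0,
                    (auto - mu * mu) / np.where(sigma2 > 0, sigma2, 1.0), 1.0)
    kd = k_diff[None, :, :]
    ipj = (ii + jj)[None, :, :] - 2 * mu[:, None, None]
    iv_mask = k_diff > 0
    inv_var = (P[:, iv_mask] / k_diff[iv_mask] ** 2).sum(axis=1)
    return {
        "JointMaximum": P.max(axis=(1, 2)),
        "JointAverage": mu,
        "JointVariance": sigma2,
        "JointEntropy": joint_entropy,
        "DifferenceAverage": da,
        "DifferenceVariance": dv,
        "DifferenceEntropy": de,
        "SumAverage": sa,
        "SumVariance": sv,
        "SumEntropy": se,
        "JointEnergy": (P ** 2).sum(axis=(1, 2)),
        "Contrast": (kd ** 2 * P).sum(axis=(1, 2)),
        "Dissimilarity": (kd * P).sum(axis=(1, 2)),
        "InverseDifference": (P / (1 + kd)).sum(axis=(1, 2)),
        "InverseDifferenceNormalized": (P / (1 + kd / ng)).sum(axis=(1, 2)),
        "InverseDifferenceMoment": (P / (1 + kd ** 2)).sum(axis=(1, 2)),
        "InverseDifferenceMomentNormalized": (
            P / (1 + kd ** 2 / ng ** 2)).sum(axis=(1, 2)),
        "InverseVariance": inv_var,
        "Correlation": corr,
        "Autocorrelation": auto,
        "ClusterTendency": (ipj ** 2 * P).sum(axis=(1, 2)),
        "ClusterShade": (ipj ** 3 * P).sum(axis=(1, 2)),
        "ClusterProminence": (ipj ** 4 * P).sum(axis=(1, 2)),
        "Imc1": imc1,
        "Imc2": imc2,
    }


def glcm_matrix(lv: np.ndarray, ng: int, direction) -> np.ndarray:
    """Symmetric co-occurrence count matrix for one direction (unnormalized)."""
    a, b = _shift_pairs(lv, direction)
    valid = (a > 0) & (b > 0)
    av, bv = a[valid], b[valid]
    M = np.bincount((av - 1) * ng + (bv - 1), minlength=ng * ng).reshape(ng, ng)
    return (M + M.T).astype(float)


def extract_glcm(lv, ng) -> Dict[str, float]:
    mats = []
    for d in DIRECTIONS:
        M = glcm_matrix(lv, ng, d)
        tot = M.sum()
        if tot > 0:
            mats.append(M / tot)
    if not mats:
        return {k: np.nan for k in GLCM_FEATURE_NAMES}
    feats = _glcm_features_batch(np.stack(mats), ng)
    return {k: float(v.mean()) for k, v in feats.items()}


# ------------------------------------------------------------------ GLRLM

def _runs_for_direction(lv: np.ndarray, d):
    """(level, run-length) pairs along direction d via line-sorted RLE."""
    z, y, x = np.meshgrid(*[np.arange(s) for s in lv.shape], indexing="ij")
    z, y, x = z.ravel(), y.ravel(), x.ravel()
    dz, dy, dx = d
    t = z * dz + y * dy + x * dx
    k1 = z * dy - y * dz
    k2 = z * dx - x * dz
    k3 = y * dx - x * dy
    order = np.lexsort((t, k3, k2, k1))
    seq = lv.ravel()[order]
    key = np.column_stack((k1, k2, k3))[order]
    new_line = np.ones(seq.size, dtype=bool)
    new_line[1:] = (np.diff(key, axis=0) != 0).any(axis=1)
    brk = new_line.copy()
    brk[1:] |= seq[1:] != seq[:-1]
    starts = np.flatnonzero(brk)
    lengths = np.diff(np.append(starts, seq.size))
    values = seq[starts]
    keep = values > 0
    return values[keep], lengths[keep]


def _rl_style_features(M: np.ndarray, n_vox: int, names, small, large) -> Dict[str, float]:
    """Shared run-length/size-zone feature formulas on a counts matrix M(i,l)."""
    ns = M.sum()
    if ns == 0:
        return {k: np.nan for k in names}
    i = np.arange(1, M.shape[0] + 1, dtype=float)
    l = np.arange(1, M.shape[1] + 1, dtype=float)
    ri = M.sum(axis=1)
    rl = M.sum(axis=0)
    p = M / ns
    mu_i = float((i * ri / ns).sum())
    mu_l = float((l * rl / ns).sum())
    nz = p > 0
    ii, ll = np.meshgrid(i, l, indexing="ij")
    return {
        names[0]: float((rl / l ** 2).sum() / ns),
        names[1]: float((rl * l ** 2).sum() / ns),
        names[2]: float((ri ** 2).sum() / ns),
        names[3]: float((ri ** 2).sum() / ns ** 2),
        names[4]: float((rl ** 2).sum() / ns),
        names[5]: float((rl ** 2).sum() / ns ** 2),
        names[6]: float(ns / n_vox),
        names[7]: float((((i - mu_i) ** 2) * ri / ns).sum()),
        names[8]: float((((l - mu_l) ** 2) * rl / ns).sum()),
        names[9]: float(-(p[nz] * np.log2(p[nz])).sum()),
        names[10]: float((ri / i ** 2).sum() / ns),
        names[11]: float((ri * i ** 2).sum() / ns),
        names[12]: float((M / (ii ** 2 * ll ** 2)).sum() / ns),
        names[13]: float((M * ii ** 2 / ll ** 2).sum() / ns),
        names[14]: float((M * ll ** 2 / ii ** 2).sum() / ns),
        names[15]: float((M * ii ** 2 * ll ** 2).sum() / ns),
    }


_GLRLM_ORDER = [
    "ShortRunEmphasis", "LongRunEmphasis",
    "GrayLevelNonUniformity", "GrayLevelNonUniformityNormalized",
    "RunLengthNonUniformity", "RunLengthNonUniformityNormalized",
    "RunPercentage", "GrayLevelVariance", "RunVariance", "RunEntropy",
    "LowGrayLevelRunEmphasis", "HighGrayLevelRunEmphasis",
    "ShortRunLowGrayLevelEmphasis", "ShortRunHighGrayLevelEmphasis",
    "LongRunLowGrayLevelEmphasis", "LongRunHighGrayLevelEmphasis",
]

_GLSZM_ORDER = [
    "SmallAreaEmphasis", "LargeAreaEmphasis",
    "GrayLevelNonUniformity", "GrayLevelNonUniformityNormalized",
    "SizeZoneNonUniformity", "SizeZoneNonUniformityNormalized",
    "ZonePercentage", "GrayLevelVariance", "ZoneVariance", "ZoneEntropy",
    "LowGrayLevelZoneEmphasis", "HighGrayLevelZoneEmphasis",
    "SmallAreaLowGrayLevelEmphasis", "SmallAreaHighGrayLevelEmphasis",
    "LargeAreaLowGrayLevelEmphasis", "LargeAreaHighGrayLevelEmphasis",
]


def glrlm_matrix(lv: np.ndarray, ng: int, direction) -> np.ndarray:
    values, lengths = _runs_for_direction(lv, direction)
    if values.size == 0:
        return np.zeros((ng, 1))
    max_l = int(lengths.max())
    M = np.zeros((ng, max_l))
    np.add.at(M, (values - 1, lengths - 1), 1.0)
    return M


def extract_glrlm(lv, ng, n_vox) -> Dict[str, float]:
    acc = None
    count = 0
    for d in DIRECTIONS:
        M = glrlm_matrix(lv, ng, d)
        f = _rl_style_features(M, n_vox, _GLRLM_ORDER, "run", "run")
        if np.isnan(f[_GLRLM_ORDER[0]]):
            continue
        acc = f if acc is None else {k: acc[k] + f[k] for k in f}
        count += 1
    if acc is None:
        return {k: np.nan for k in _GLRLM_ORDER}
    return {k: v / count for k, v in acc.items()}


# ------------------------------------------------------------------ GLSZM

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


def glszm_matrix(lv: np.ndarray, ng: int) -> np.ndarray:
    sizes_by_level = []
    max_size = 1
    for g in range(1, ng + 1):
        lab, nz = ndimage.label(lv == g, structure=_STRUCT26)
        if nz == 0:
            sizes_by_level.append(np.array([], dtype=int))
            continue
        sizes = np.bincount(lab.ravel())[1:]
        sizes_by_level.append(sizes)
        max_size = max(max_size, int(sizes.max()))
    M = np.zeros((ng, max_size))
    for g, sizes in enumerate(sizes_by_level):
        if sizes.size:
            np.add.at(M, (g, sizes - 1), 1.0)
    return M


def extract_glszm(lv, ng, n_vox) -> Dict[str, float]:
    M = glszm_matrix(lv, ng)
    return _rl_style_features(M, n_vox, _GLSZM_ORDER, "zone", "zone")


# ------------------------------------------------------------------ GLDM

def gldm_matrix(lv: np.ndarray, ng: int) -> np.ndarray:
    """Dependence-count matrix, alpha = 0, 26-neighbourhood.

    Dependence of a voxel = 1 + number of neighbours with the same level
    (centre included so the count index starts at 1).
    """
    dep = np.zeros(lv.shape, dtype=np.int64)
    for d in DIRECTIONS:
        a, b = _shift_pairs(lv, d)
        same = (a > 0) & (b > 0) & (a == b)
        # accumulate on both ends of the symmetric offset
        sl_a, sl_b = [], []
        for k, dk in enumerate(d):
            n = lv.shape[k]
            if dk >= 0:
                sl_a.append(slice(0, n - dk))
                sl_b.append(slice(dk, n))
            else:
                sl_a.append(slice(-dk, n))
                sl_b.append(slice(0, n + dk))
        dep[tuple(sl_a)] += same
        dep[tuple(sl_b)] += same
    inroi = lv > 0
    counts = dep[inroi] + 1
    levels = lv[inroi]
    M = np.zeros((ng, int(counts.max())))
    np.add.at(M, (levels - 1, counts - 1), 1.0)
    return M


def extract_gldm(lv, ng, n_vox) -> Dict[str, float]:
    M = gldm_matrix(lv, ng)
    ns = M.sum()
    i = np.arange(1, M.shape[0] + 1, dtype=float)
    j = np.arange(1, M.shape[1] + 1, dtype=float)
    ii, jj = np.meshgrid(i, j, indexing="ij")
    ri = M.sum(axis=1)
    rj = M.sum(axis=0)
    p = M / ns
    mu_i = float((i * ri / ns).sum())
    mu_j = float((j * rj / ns).sum())
    nz = p > 0
    return {
        "LowDependenceEmphasis": float((rj / j ** 2).sum() / ns),
        "HighDependenceEmphasis": float((rj * j ** 2).sum() / ns),
        "LowGrayLevelCountEmphasis": float((ri / i ** 2).sum() / ns),
        "HighGrayLevelCountEmphasis": float((ri * i ** 2).sum() / ns),
        "LowDependenceLowGrayLevelEmphasis": float((M / (ii ** 2 * jj ** 2)).sum() / ns),
        "LowDependenceHighGrayLevelEmphasis": float((M * ii ** 2 / jj ** 2).sum() / ns),
        "HighDependenceLowGrayLevelEmphasis": float((M * jj ** 2 / ii ** 2).sum() / ns),
        "HighDependenceHighGrayLevelEmphasis": float((M * ii ** 2 * jj ** 2).sum() / ns),
        "GrayLevelNonUniformity": float((ri ** 2).sum() / ns),
        "GrayLevelNonUniformityNormalized": float((ri ** 2).sum() / ns ** 2),
        "DependenceCountNonUniformity": float((rj ** 2).sum() / ns),
        "DependenceCountNonUniformityNormalized": float((rj ** 2).sum() / ns ** 2),
        "DependenceCountPercentage": float(ns / n_vox),
        "GrayLevelVariance": float((((i - mu_i) ** 2) * ri / ns).sum()),
        "DependenceCountVariance": float((((j - mu_j) ** 2) * rj / ns).sum()),
        "DependenceCountEntropy": float(-(p[nz] * np.log2(p[nz])).sum()),
        "DependenceCountEnergy": float((p ** 2).sum()),
    }


# ------------------------------------------------------------------ NGTDM

def extract_ngtdm(lv, ng, n_vox) -> Dict[str, float]:
    inroi = lv > 0
    nb_sum = np.zeros(lv.shape, dtype=float)
    nb_cnt = np.zeros(lv.shape, dtype=np.int64)
    for d in DIRECTIONS:
        sl_a, sl_b = [], []
        for k, dk in enumerate(d):
            n = lv.shape[k]
            if dk >= 0:
                sl_a.append(slice(0, n - dk))
                sl_b.append(slice(dk, n))
            else:
                sl_a.append(slice(-dk, n))
                sl_b.append(slice(0, n + dk))
        a, b = lv[tuple(sl_a)], lv[tuple(sl_b)]
        valid = (a > 0) & (b > 0)
        nb_sum[tuple(sl_a)] += np.where(valid, b, 0)
        nb_cnt[tuple(sl_a)] += valid
        nb_sum[tuple(sl_b)] += np.where(valid, a, 0)
        nb_cnt[tuple(sl_b)] += valid
    use = inroi & (nb_cnt > 0)
    nv = int(use.sum())
    if nv == 0:
        return {k: np.nan for k in NGTDM_FEATURE_NAMES}
    diff = np.abs(lv[use] - nb_sum[use] / nb_cnt[use])
    levels = lv[use]
    n_i = np.bincount(levels - 1, minlength=ng).astype(float)
    s_i = np.bincount(levels - 1, weights=diff, minlength=ng)
    p_i = n_i / nv
    present = p_i > 0
    i = np.arange(1, ng + 1, dtype=float)
    ngp = int(present.sum())

    coarseness = 1.0 / max((p_i * s_i).sum(), _EPS)
    pi_p, i_p, si_p = p_i[present], i[present], s_i[present]
    dd = (i_p[:, None] - i_p[None, :])
    pp = pi_p[:, None] * pi_p[None, :]
    contrast = (
        (pp * dd ** 2).sum() / (ngp * (ngp - 1)) * s_i.sum() / nv
        if ngp > 1 else 0.0
    )
    busy_den = np.abs(i_p[:, None] * pi_p[:, None] - i_p[None, :] * pi_p[None, :]).sum()
    busyness = (p_i * s_i).sum() / busy_den if busy_den > 0 else 0.0
    complexity = (
        np.abs(i_p[:, None] - i_p[None, :])
        * (pi_p[:, None] * si_p[:, None] + pi_p[None, :] * si_p[None, :])
        / (pi_p[:, None] + pi_p[None, :])
    ).sum() / nv
    strength_num = ((pi_p[:, None] + pi_p[None, :]) * dd ** 2).sum()
    strength = strength_num / max(s_i.sum(), _EPS)
    return {
        "Coarseness": float(coarseness),
        "Contrast": float(contrast),
        "Busyness": float(busyness),
        "Complexity": float(complexity),
        "Strength": float(strength),
    }


# ------------------------------------------------------------------ facade

def extract_texture(image: np.ndarray, mask: np.ndarray,
                    bin_width: float = 5.0) -> Dict[str, float]:
    """All 79 texture features for one image/mask pair."""
    lv, m, ng = _prepare(image, mask, bin_width)
    n_vox = int(m.sum())
    out = {}
    out.update({f"glcm_{k}": v for k, v in extract_glcm(lv, ng).items()})
    out.update({f"glrlm_{k}": v for k, v in extract_glrlm(lv, ng, n_vox).items()})
    out.update({f"glszm_{k}": v for k, v in extract_glszm(lv, ng, n_vox).items()})
    out.update({f"gldm_{k}": v for k, v in extract_gldm(lv, ng, n_vox).items()})
    out.update({f"ngtdm_{k}": v for k, v in extract_ngtdm(lv, ng, n_vox).items()})
    return {k: out[k] for k in TEXTURE_FEATURE_NAMES}
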