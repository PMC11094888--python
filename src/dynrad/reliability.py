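"""Perturbation-based repeatability screening and phase-variation testing.

Features are kept only if they are repeatable (ICC >= 0.9 against random
mask perturbations) in every phase AND vary significantly across phases.
"""

from __future__ import annotations

import warnings
from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .config import PerturbationParams
from .synthetic import PhaseStack

__all__ = [
    "perturb_mask",
    "compute_icc",
    "filter_repeatable",
    "phase_variation_test",
    "reliability_report",
]


def _rigid_transform_mask(mask: np.ndarray, spacing, shift_mm, angles_deg):
    """Rotate about the mask centroid then translate; nearest-neighbour."""
    out = mask.astype(float)
    # successive rotations about the three axes (array centre), then shift;
    # linear interpolation + 0.5 threshold keeps partial-volume smoothness
    for axis_pair, ang in zip(((1, 2), (0, 2), (0, 1)), angles_deg):
        if ang != 0.0:
            out = ndimage.rotate(out, ang, axes=axis_pair, reshape=False,
                                 order=1, mode="constant", cval=0.0)
    shift_vox = np.asarray(shift_mm) / np.asarray(spacing)
    if np.any(shift_vox != 0):
        out = ndimage.shift(out, shift_vox, order=1, mode="constant", cval=0.0)
    return out > 0.5


def _contour_noise(mask: np.ndarray, strength: float, rng: np.random.Generator):
    """Randomly erode/dilate boundary voxels to emulate contour uncertainty."""
    if strength <= 0:
        return mask
    struct = ndimage.generate_binary_structure(3, 1)
    eroded = ndimage.binary_erosion(mask, struct)
    dilated = ndimage.binary_dilation(mask, struct)
    inner_boundary = mask & ~eroded
    outer_boundary = dilated & ~mask
    p = min(0.5 * strength, 1.0)
    out = mask.copy()
    out[inner_boundary] &= rng.random(int(inner_boundary.sum())) >= p
    out[outer_boundary] |= rng.random(int(outer_boundary.sum())) < p
    return out


def perturb_mask(stack: PhaseStack, params: PerturbationParams, k: int) -> PhaseStack:
    """The k-th random rigid + contour perturbation of a patient's mask.

    Deterministic given (params.seed, k). Retries transforms that would empty
    the mask (up to 10 times) before raising.
    """
    params.validate()
    for attempt in range(10):
        rng = np.random.default_rng((params.seed, k, attempt))
        shift = rng.uniform(-params.max_translation, params.max_translation, 3)
        angles = rng.uniform(-params.max_rotation, params.max_rotation, 3)
        if params.max_translation == 0:
            shift = np.zeros(3)
        if params.max_rotation == 0:
            angles = np.zeros(3)
        new_mask = _rigid_transform_mask(stack.mask, stack.spacing, shift, angles)
        new_mask = _contour_noise(new_mask, params.contour_randomization_strength, rng)
        if new_mask.any():
            return PhaseStack(image=stack.image, mask=new_mask,
                              spacing=stack.spacing, phase_order=stack.phase_order)
    raise RuntimeError("perturbation emptied the mask in 10 consecutive attempts")


def compute_icc(measurements: np.ndarray) -> float:
    """One-way random-effects ICC(1,1) from ANOVA mean squares.

    ``measurements`` is subjects x raters. Returns 1.0 by convention when the
    total variance is zero.
    """
    m = np.asarray(measurements, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError("need >= 2 subjects and >= 2 raters")
    if not np.all(np.isfinite(m)):
        raise ValueError("non-finite measurements")
    n, k = m.shape
    grand = m.mean()
    if np.allclose(m, grand):
        return 1.0
    row_means = m.mean(axis=1)
    ss_between = k * ((row_means - grand) ** 2).sum()
    ss_within = ((m - row_means[:, None]) ** 2).sum()
    bms = ss_between / (n - 1)
    wms = ss_within / (n * (k - 1))
    return float((bms - wms) / (bms + (k - 1) * wms))


def filter_repeatable(icc_by_phase: pd.DataFrame, threshold: float = 0.9) -> List[str]:
    """Feature names whose ICC reaches the threshold in EVERY phase.

    ``icc_by_phase``: rows = feature base names, columns = phases.
    """
    if icc_by_phase.empty:
        return []
    ok = (icc_by_phase >= threshold).all(axis=1)
    return list(icc_by_phase.index[ok])


def phase_variation_test(series_values: np.ndarray) -> Tuple[float, bool]:
    """Single-sample t test on pooled |successive-phase differences|.

    ``series_values``: patients x phases array for one feature. Returns
    (p-value, varying flag at p < 0.05).
    """
    v = np.asarray(series_values, dtype=float)
    if v.ndim == 1:
        v = v[None, :]
    if v.shape[1] < 2:
        raise ValueError("need at least two phases")
    diffs = np.abs(np.diff(v, axis=1)).ravel()
    diffs = diffs[np.isfinite(diffs)]
    if diffs.size < 2:
        warnings.warn("too few finite phase differences for a t test")
        return 1.0, False
    if np.all(diffs == 0):
        return 1.0, False
    if np.ptp(diffs) == 0:  # constant nonzero differences: degenerate t
        return 0.0, True
    t, p = stats.ttest_1samp(diffs, 0.0)
    return float(p), bool(p < 0.05)


def reliability_report(feature_rows_by_perturbation: Dict[int, pd.DataFrame],
                       n_phases: int, icc_threshold: float = 0.9) -> pd.DataFrame:
    """Assemble per-feature, per-phase ICCs from repeated extractions.

    ``feature_rows_by_perturbation`` maps perturbation index -> FeatureTable
    (patients x features) extracted with that perturbed mask; index 0 should
    be the unperturbed reference (it participates as one 'rater').
    """
    pert_ids = sorted(feature_rows_by_perturbation)
    tables = [feature_rows_by_perturbation[i] for i in pert_ids]
    cols = tables[0].columns
    records = []
    for col in cols:
        m = np.column_stack([t[col].to_numpy() for t in tables])
        finite = np.all(np.isfinite(m), axis=1)
        if finite.sum() < 2:
            icc = np.nan
        else:
            icc = compute_icc(m[finite])
        records.append({"column": col, "icc": icc,
                        "repeatable": bool(icc >= icc_threshold)
                        if np.isfinite(icc) else False})
    return pd.DataFrame(records).set_index("column")
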