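"""Normalization, resampling, discretization and FTV-style enhancement masking."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy import ndimage

from .config import PreprocessParams
from .synthetic import PhaseStack

__all__ = [
    "joint_normalize",
    "resample_isotropic",
    "discretize_fixed_binwidth",
    "compute_ftv_mask",
    "EnhancementMap",
]


@dataclass
class EnhancementMap:
    percent_enhancement: np.ndarray
    signal_enhancement_ratio: np.ndarray


def joint_normalize(stack: PhaseStack, scale: float = 1.0) -> PhaseStack:
    """Z-score all phases with ONE pooled mean/SD so inter-phase contrast
    (the enhancement dynamics) is preserved.

    With the default ``scale=1`` the pooled output has mean 0 and SD 1; a
    larger scale simply multiplies the z-scores (useful before fixed-bin-width
    discretization).
    """
    img = stack.image
    if not np.all(np.isfinite(img)):
        raise ValueError("non-finite intensities")
    mu = img.mean()
    sd = img.std()
    if sd == 0:
        raise ValueError("constant image")
    return PhaseStack(
        image=(img - mu) / sd * scale,
        mask=stack.mask,
        spacing=stack.spacing,
        phase_order=stack.phase_order,
    )


def resample_isotropic(stack: PhaseStack, params: PreprocessParams) -> PhaseStack:
    """Resample image (linear) and mask (nearest-neighbour) to target spacing."""
    target = np.asarray(params.target_spacing, dtype=float)
    current = np.asarray(stack.spacing, dtype=float)
    if np.allclose(target, current):
        return stack
    zoom = current / target
    out_shape = tuple(int(round(d * z)) for d, z in zip(stack.mask.shape, zoom))
    phases = [
        ndimage.zoom(stack.image[k], zoom, order=1, mode="nearest",
                     grid_mode=True)[: out_shape[0], : out_shape[1], : out_shape[2]]
        for k in range(stack.n_phases)
    ]
    mask = ndimage.zoom(stack.mask.astype(np.uint8), zoom, order=0,
                        mode="nearest", grid_mode=True)[
        : out_shape[0], : out_shape[1], : out_shape[2]
    ].astype(bool)
    if not mask.any():
        raise ValueError("mask empty after resampling")
    return PhaseStack(
        image=np.stack(phases),
        mask=mask,
        spacing=tuple(target),
        phase_order=stack.phase_order,
    )


def discretize_fixed_binwidth(values: np.ndarray, bin_width: float,
                              roi_min: Optional[float] = None) -> np.ndarray:
    """IBSI fixed-bin-size discretization: floor((x - roi_min)/w) + 1."""
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    values = np.asarray(values, dtype=float)
    if roi_min is None:
        roi_min = values.min()
    return (np.floor((values - roi_min) / bin_width) + 1).astype(np.int64)


def compute_ftv_mask(stack: PhaseStack, params: PreprocessParams,
                     bounding_box: Optional[Tuple[slice, slice, slice]] = None):
    """Enhancement-threshold (functional-tumour-volume style) mask.

    Keeps voxels inside the bounding box whose pre-contrast signal is above a
    background floor and whose percent enhancement at the first post-contrast
    phase reaches ``pe_threshold``. Returns (mask, EnhancementMap).
    """
    if stack.n_phases < 2:
        raise ValueError("need at least two phases")
    pre = stack.image[0]
    early = stack.image[params.ser_early_phase]
    late = stack.image[params.ser_late_phase]
    floor = params.background_floor_frac * pre.max()
    with np.errstate(divide="ignore", invalid="ignore"):
        pe = np.where(pre > floor, (early - pre) / pre, 0.0)
        ser = np.where(np.abs(late - pre) > 1e-12, (early - pre) / (late - pre), 0.0)
    box = np.zeros(pre.shape, dtype=bool)
    if bounding_box is None:
        box[:] = True
    else:
        box[bounding_box] = True
    mask = box & (pre > floor) & (pe >= params.pe_threshold)
    if not mask.any():
        warnings.warn("FTV mask empty: no voxel reaches the enhancement threshold")
    return mask, EnhancementMap(percent_enhancement=pe, signal_enhancement_ratio=ser)
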