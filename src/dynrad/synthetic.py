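"""Synthetic multi-phase cohort generator.

Creates phantom DCE series, clinical covariates, outcome labels and a paired
expression matrix with a planted differential-expression signal, all driven by
one seeded generator so a cohort is exactly reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd

from .config import SimulationConfig, KineticParams

__all__ = [
    "PhaseStack",
    "ExpressionMatrix",
    "generate_phase_stack",
    "generate_cohort",
    "split_train_test",
    "kinetic_curve",
]


@dataclass
class PhaseStack:
    """One patient's co-registered multi-phase volume plus lesion mask."""

    image: np.ndarray  # (phase, z, y, x)
    mask: np.ndarray  # (z, y, x) boolean
    spacing: Tuple[float, float, float]
    phase_order: Tuple[int, ...]

    def __post_init__(self):
        self.image = np.asarray(self.image)
        if not np.issubdtype(self.image.dtype, np.floating):
            self.image = self.image.astype(float)
        self.mask = np.asarray(self.mask).astype(bool)
        if self.image.ndim != 4:
            raise ValueError("image must be 4-D (phase, z, y, x)")
        if self.mask.shape != self.image.shape[1:]:
            raise ValueError("mask shape must equal per-phase image shape")
        if list(self.phase_order) != sorted(self.phase_order):
            raise ValueError("phase_order must be acquisition-ordered")

    @property
    def n_phases(self) -> int:
        return self.image.shape[0]


@dataclass
class ExpressionMatrix:
    values: pd.DataFrame  # genes x patients, log2 scale
    planted_deg_ids: List[str]

    @property
    def gene_ids(self) -> List[str]:
        return list(self.values.index)


def kinetic_curve(t: np.ndarray, amplitude: float, time_to_peak: float,
                  alpha: float) -> np.ndarray:
    """Gamma-variate uptake: zero pre-contrast, rise to peak, washout."""
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    pos = t > 0
    tr = t[pos] / time_to_peak
    out[pos] = amplitude * tr ** alpha * np.exp(alpha * (1.0 - tr))
    return out


def _sphere_mask(shape, spacing, center_mm, radius_mm) -> np.ndarray:
    grids = np.meshgrid(
        *[np.arange(s) * sp for s, sp in zip(shape, spacing)], indexing="ij"
    )
    d2 = sum((g - c) ** 2 for g, c in zip(grids, center_mm))
    return d2 <= radius_mm ** 2


def generate_phase_stack(patient_class: int, config: SimulationConfig,
                         rng: np.random.Generator) -> PhaseStack:
    """Build one phantom: noisy background plus an enhancing spherical lesion."""
    config.validate()
    shape = tuple(config.grid_shape)
    spacing = tuple(config.voxel_spacing)
    kp: KineticParams = config.kinetic_params_by_class[
        "responder" if patient_class else "nonresponder"
    ]

    r = rng.uniform(*config.lesion_radius_range)
    extent = [s * sp for s, sp in zip(shape, spacing)]
    center = [rng.uniform(r + sp, e - r - sp) for e, sp in zip(extent, spacing)]
    mask = _sphere_mask(shape, spacing, center, r)
    if not mask.any():  # pragma: no cover - geometry is validated upstream
        raise ValueError("empty lesion mask")

    amplitude = max(rng.normal(kp.amplitude_mean, kp.amplitude_sd), 0.0)
    ttp = max(rng.normal(kp.time_to_peak_mean, kp.time_to_peak_sd), 0.5)
    t = np.arange(config.n_phases, dtype=float)
    curve = kinetic_curve(t, amplitude * config.enhancement_scale, ttp,
                          kp.washout_alpha)

    # static anatomy: smooth-ish random texture shared by all phases
    texture = rng.normal(0.0, config.texture_noise_sd, size=shape)
    base = config.baseline_intensity + texture
    lesion_texture = rng.normal(0.0, config.texture_noise_sd, size=shape)

    image = np.empty((config.n_phases,) + shape, dtype=float)
    for k in range(config.n_phases):
        phase = base + rng.normal(0.0, config.texture_noise_sd / 4, size=shape)
        enh = curve[k] * (1.0 + lesion_texture)
        phase = phase + np.where(mask, enh, 0.0)
        image[k] = phase
    return PhaseStack(image=image, mask=mask, spacing=spacing,
                      phase_order=tuple(range(config.n_phases)))


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


def generate_cohort(config: SimulationConfig):
    """Generate (phase stacks, clinical table, expression matrix).

    The latent kinetic class links imaging, outcome and expression: it selects
    the enhancement kinetics, enters the pCR logit, and shifts the planted
    differentially expressed genes.
    """
    config.validate()
    rng = np.random.default_rng(config.rng_seed)
    n = config.n_patients

    if n == 0:
        clinical = pd.DataFrame(
            columns=["patient_id", "hr_status", "her2_status", "treatment_arm",
                     "kinetic_class", "pcr"]
        )
        expr = ExpressionMatrix(values=pd.DataFrame(), planted_deg_ids=[])
        return [], clinical, expr

    hr = (rng.random(n) < config.covariate_prevalences["hr_pos"]).astype(int)
    her2 = (rng.random(n) < config.covariate_prevalences["her2_pos"]).astype(int)
    arms = list(config.arm_counts)
    arm_p = np.array([config.arm_counts[a] for a in arms], dtype=float)
    arm_p /= arm_p.sum()
    arm = rng.choice(arms, size=n, p=arm_p)
    kin = (rng.random(n) < config.p_kinetic_class).astype(int)

    b = config.effect_logits
    base_logit = np.log(config.pcr_base_rate / (1 - config.pcr_base_rate))
    # centre covariate contributions so the marginal rate stays near base rate
    centering = (
        b.get("hr", 0.0) * config.covariate_prevalences["hr_pos"]
        + b.get("her2", 0.0) * config.covariate_prevalences["her2_pos"]
        + b.get("kinetic", 0.0) * config.p_kinetic_class
    )
    logit = (
        base_logit - centering
        + b.get("hr", 0.0) * hr
        + b.get("her2", 0.0) * her2
        + b.get("kinetic", 0.0) * kin
    )
    pcr = (rng.random(n) < _sigmoid(logit)).astype(int)

    stacks = [generate_phase_stack(kin[i], config, rng) for i in range(n)]

    clinical = pd.DataFrame(
        {
            "patient_id": [f"P{i:04d}" for i in range(n)],
            "hr_status": hr,
            "her2_status": her2,
            "treatment_arm": arm,
            "kinetic_class": kin,
            "pcr": pcr,
        }
    )

    gene_ids = [f"G{g:05d}" for g in range(config.n_genes)]
    base_expr = rng.normal(8.0, config.expression_sd,
                           size=(config.n_genes, n))
    planted = list(rng.choice(config.n_genes, config.n_planted_degs,
                              replace=False))
    shift = np.zeros((config.n_genes, 1))
    shift[planted, 0] = config.planted_log2fc
    values = base_expr + shift * kin[np.newaxis, :]
    expr = pd.DataFrame(values, index=gene_ids,
                        columns=clinical["patient_id"])
    expression = ExpressionMatrix(values=expr,
                                  planted_deg_ids=[gene_ids[g] for g in planted])
    return stacks, clinical, expression


def split_train_test(clinical: pd.DataFrame, ratio: float = 3.0,
                     seed: int = 0) -> pd.DataFrame:
    """Assign a stratified train/test split with train fraction ratio/(ratio+1).

    Stratified by pCR; the train count in each stratum is floored, which for
    the emulated 785-patient cohort (254 positives) reproduces a 588/197 split
    with 190 positives in train.
    """
    if "pcr" not in clinical.columns:
        raise ValueError("clinical table lacks pcr labels")
    out = clinical.copy()
    if ratio <= 0:
        raise ValueError("ratio must be positive")
    if np.isinf(ratio):
        warnings.warn("degenerate ratio: all patients assigned to train")
        out["split"] = "train"
        return out
    frac = ratio / (ratio + 1.0)
    rng = np.random.default_rng(seed)
    out["split"] = "test"
    for label, grp in out.groupby("pcr"):
        if len(grp) < 2:
            raise ValueError(f"pCR stratum {label} has fewer than 2 members")
        n_train = int(np.floor(len(grp) * frac))
        chosen = rng.permutation(grp.index.to_numpy())[:n_train]
        out.loc[chosen, "split"] = "train"
    return out
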