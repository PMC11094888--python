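"""Configuration objects for simulation, preprocessing and perturbation."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Dict, Tuple

import yaml

# Treatment-arm frequencies of the emulated trial population (n=785).
DEFAULT_ARM_COUNTS: Dict[str, int] = {
    "Paclitaxel": 142,
    "Paclitaxel + ABT 888 + Carboplatin": 57,
    "Paclitaxel + AMG 386": 96,
    "Paclitaxel + AMG 386 + Trastuzumab": 16,
    "Paclitaxel + Ganetespib": 78,
    "Paclitaxel + Ganitumab": 89,
    "Paclitaxel + MK-2206": 46,
    "Paclitaxel + MK-2206 + Trastuzumab": 30,
    "Paclitaxel + Neratinib": 85,
    "Paclitaxel + Pembrolizumab": 54,
    "Paclitaxel + Pertuzumab + Trastuzumab": 33,
    "Paclitaxel + Trastuzumab": 20,
    "T-DM1 + Pertuzumab": 39,
}


@dataclass
class KineticParams:
    """Per-class gamma-variate enhancement kinetics (phase-index time units)."""

    amplitude_mean: float = 1.0
    amplitude_sd: float = 0.15
    time_to_peak_mean: float = 2.5
    time_to_peak_sd: float = 0.3
    washout_alpha: float = 2.0  # shape of rise; larger = sharper peak


@dataclass
class SimulationConfig:
    n_patients: int = 785
    n_phases: int = 6
    grid_shape: Tuple[int, int, int] = (22, 30, 30)
    voxel_spacing: Tuple[float, float, float] = (1.5, 1.5, 1.5)
    lesion_radius_range: Tuple[float, float] = (4.5, 7.5)  # mm
    kinetic_params_by_class: Dict[str, KineticParams] = field(
        default_factory=lambda: {
            # responder-like lesions enhance earlier and wash out faster
            "responder": KineticParams(amplitude_mean=1.15, time_to_peak_mean=2.0),
            "nonresponder": KineticParams(amplitude_mean=0.95, time_to_peak_mean=3.2),
        }
    )
    p_kinetic_class: float = 0.45  # P(responder-like kinetics)
    texture_noise_sd: float = 0.08
    baseline_intensity: float = 1.0
    enhancement_scale: float = 1.0
    covariate_prevalences: Dict[str, float] = field(
        default_factory=lambda: {"hr_pos": 431 / 785, "her2_pos": 184 / 785}
    )
    arm_counts: Dict[str, int] = field(default_factory=lambda: dict(DEFAULT_ARM_COUNTS))
    pcr_base_rate: float = 254 / 785
    effect_logits: Dict[str, float] = field(
        default_factory=lambda: {"hr": -0.8, "her2": 0.7, "kinetic": 1.2}
    )
    n_genes: int = 2000
    n_planted_degs: int = 60
    planted_log2fc: float = 1.0
    expression_sd: float = 1.0
    rng_seed: int = 0

    def validate(self) -> None:
        if self.n_phases < 2:
            raise ValueError("n_phases must be >= 2")
        for key, p in self.covariate_prevalences.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"prevalence {key}={p} outside [0,1]")
        if not 0.0 <= self.pcr_base_rate <= 1.0:
            raise ValueError("pcr_base_rate outside [0,1]")
        max_r = self.lesion_radius_range[1]
        for dim, sp in zip(self.grid_shape, self.voxel_spacing):
            if 2 * max_r >= dim * sp:
                raise ValueError(
                    "lesion (diameter %.1f mm) does not fit inside grid axis of %.1f mm"
                    % (2 * max_r, dim * sp)
                )
        if self.n_planted_degs > self.n_genes:
            raise ValueError("more planted DEGs than genes")


@dataclass
class PreprocessParams:
    target_spacing: Tuple[float, float, float] = (1.0, 1.0, 1.0)
    bin_width: float = 5.0
    normalization_scale: float = 30.0  # rescale applied after pooled z-score
    pe_threshold: float = 0.7  # fractional percent-enhancement cutoff for FTV
    background_floor_frac: float = 0.1  # floor = frac * max(pre-contrast)
    ser_early_phase: int = 1
    ser_late_phase: int = -1


@dataclass
class PerturbationParams:
    n_perturbations: int = 20
    max_translation: float = 1.0  # mm
    max_rotation: float = 10.0  # degrees
    contour_randomization_strength: float = 0.2  # boundary flip intensity
    seed: int = 0

    def validate(self) -> None:
        if self.n_perturbations < 2:
            raise ValueError("n_perturbations must be >= 2")


def _as_dict(cfg) -> dict:
    return asdict(cfg)


def dump_yaml(cfg, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_as_dict(cfg), fh, sort_keys=False)


def load_simulation_config(path) -> SimulationConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "kinetic_params_by_class" in raw:
        raw["kinetic_params_by_class"] = {
            k: KineticParams(**v) for k, v in raw["kinetic_params_by_class"].items()
        }
    for key in ("grid_shape", "voxel_spacing", "lesion_radius_range"):
        if key in raw:
            raw[key] = tuple(raw[key])
    cfg = SimulationConfig(**raw)
    cfg.validate()
    return cfg
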