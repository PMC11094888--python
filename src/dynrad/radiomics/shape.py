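"""Morphological (shape) features: 14 mesh/voxel-based descriptors."""

from __future__ import annotations

from typing import Dict

import numpy as np
from scipy.spatial import ConvexHull
from skimage.measure import marching_cubes

SHAPE_FEATURE_NAMES = [
    "MeshVolume",
    "VoxelVolume",
    "SurfaceArea",
    "SurfaceVolumeRatio",
    "Sphericity",
    "Maximum3DDiameter",
    "Maximum2DDiameterSlice",
    "Maximum2DDiameterColumn",
    "Maximum2DDiameterRow",
    "MajorAxisLength",
    "MinorAxisLength",
    "LeastAxisLength",
    "Elongation",
    "Flatness",
]


def _mesh(mask: np.ndarray, spacing) -> tuple[float, float]:
    """Surface area and enclosed volume of the 0.5-level mesh."""
    padded = np.pad(mask.astype(np.uint8), 1)
    verts, faces, _, _ = marching_cubes(padded, level=0.5, spacing=tuple(spacing))
    tri = verts[faces]
    a = tri[:, 1] - tri[:, 0]
    b = tri[:, 2] - tri[:, 0]
    cross = np.cross(a, b)
    area = 0.5 * np.linalg.norm(cross, axis=1).sum()
    # signed volume of tetrahedra against the origin
    vol = np.abs(np.einsum("ij,ij->i", tri[:, 0], cross).sum() / 6.0)
    return float(area), float(vol)


def _max_pairwise(points: np.ndarray) -> float:
    if len(points) == 1:
        return 0.0
    if len(points) > 4:
        try:
            points = points[ConvexHull(points).vertices]
        except Exception:
            pass  # degenerate (coplanar/collinear) hulls fall back to all points
    d = points[:, None, :] - points[None, :, :]
    return float(np.sqrt((d ** 2).sum(-1)).max())


def extract_shape(mask: np.ndarray, spacing) -> Dict[str, float]:
    """Compute the 14 morphological features on a binary mask (mm units)."""
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("empty mask")
    spacing = np.asarray(spacing, dtype=float)
    voxel_vol = float(spacing.prod())

    coords = np.column_stack(np.nonzero(mask)).astype(float)
    phys = coords * spacing

    surface_area, mesh_volume = _mesh(mask, spacing)
    n_vox = int(mask.sum())
    voxel_volume = n_vox * voxel_vol

    sphericity = (np.pi ** (1 / 3)) * (6.0 * mesh_volume) ** (2 / 3) / surface_area

    max3d = _max_pairwise(phys)
    # per-plane maximum diameters (slice: z fixed; column: y fixed; row: x fixed)
    diam2d = []
    for axis in range(3):
        best = 0.0
        keep = [a for a in range(3) if a != axis]
        for v in np.unique(coords[:, axis]):
            pts = phys[coords[:, axis] == v][:, keep]
            best = max(best, _max_pairwise(pts))
        diam2d.append(best)

    centered = phys - phys.mean(axis=0)
    cov = np.cov(centered.T) if n_vox > 1 else np.zeros((3, 3))
    eig = np.sort(np.linalg.eigvalsh(cov))[::-1]
    eig = np.clip(eig, 0.0, None)
    major, minor, least = (4.0 * np.sqrt(eig)).tolist()
    elongation = float(np.sqrt(eig[1] / eig[0])) if eig[0] > 0 else 0.0
    flatness = float(np.sqrt(eig[2] / eig[0])) if eig[0] > 0 else 0.0

    return {
        "MeshVolume": mesh_volume,
        "VoxelVolume": voxel_volume,
        "SurfaceArea": surface_area,
        "SurfaceVolumeRatio": surface_area / mesh_volume if mesh_volume > 0 else np.nan,
        "Sphericity": float(sphericity),
        "Maximum3DDiameter": max3d,
        "Maximum2DDiameterSlice": diam2d[0],
        "Maximum2DDiameterColumn": diam2d[1],
        "Maximum2DDiameterRow": diam2d[2],
        "MajorAxisLength": major,
        "MinorAxisLength": minor,
        "LeastAxisLength": least,
        "Elongation": elongation,
        "Flatness": flatness,
    }
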