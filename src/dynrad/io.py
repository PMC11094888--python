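"""Disk I/O: NIfTI phase stacks, clinical/expression CSVs, truth JSON."""

from __future__ import annotations

import json
import os
from pathlib import Path
from typing import Dict, List

import nibabel as nib
import numpy as np
import pandas as pd

from .synthetic import PhaseStack, ExpressionMatrix


def write_phase_stack(stack: PhaseStack, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    affine = np.diag(list(stack.spacing) + [1.0])
    for k in range(stack.n_phases):
        nib.save(nib.Nifti1Image(stack.image[k].astype(np.float32), affine),
                 out / f"image_phase{k}.nii.gz")
    nib.save(nib.Nifti1Image(stack.mask.astype(np.uint8), affine),
             out / "mask.nii.gz")


def read_phase_stack(patient_dir) -> PhaseStack:
    d = Path(patient_dir)
    phases = sorted(d.glob("image_phase*.nii.gz"),
                    key=lambda p: int(p.stem.split("phase")[1].split(".")[0]))
    if not phases:
        raise FileNotFoundError(f"no phase images under {d}")
    imgs = [nib.load(str(p)) for p in phases]
    spacing = tuple(float(z) for z in imgs[0].header.get_zooms()[:3])
    image = np.stack([np.asanyarray(i.dataobj, dtype=float) for i in imgs])
    mask = np.asanyarray(nib.load(str(d / "mask.nii.gz")).dataobj) > 0
    return PhaseStack(image=image, mask=mask, spacing=spacing,
                      phase_order=tuple(range(len(phases))))


def write_cohort(stacks: List[PhaseStack], clinical: pd.DataFrame,
                 expression: ExpressionMatrix, out_dir, truth: Dict) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for stack, pid in zip(stacks, clinical["patient_id"]):
        write_phase_stack(stack, out / "images" / pid)
    clinical.to_csv(out / "clinical.csv", index=False)
    expression.values.to_csv(out / "expression.csv")
    truth = dict(truth)
    truth["planted_deg_ids"] = expression.planted_deg_ids
    with open(out / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1)


def read_cohort(in_dir):
    d = Path(in_dir)
    clinical = pd.read_csv(d / "clinical.csv")
    expr = pd.read_csv(d / "expression.csv", index_col=0)
    with open(d / "truth.json") as fh:
        truth = json.load(fh)
    expression = ExpressionMatrix(values=expr,
                                  planted_deg_ids=truth.get("planted_deg_ids", []))
    stacks = [read_phase_stack(d / "images" / pid)
              for pid in clinical["patient_id"]]
    return stacks, clinical, expression, truth
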