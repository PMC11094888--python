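"""Per-patient feature extraction across all phases."""

from __future__ import annotations

import logging
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from ..config import PreprocessParams
from ..synthetic import PhaseStack
from .shape import extract_shape, SHAPE_FEATURE_NAMES
from .firstorder import extract_firstorder, FIRSTORDER_FEATURE_NAMES
from .texture import extract_texture, TEXTURE_FEATURE_NAMES

log = logging.getLogger(__name__)

N_SHAPE = len(SHAPE_FEATURE_NAMES)          # 14
N_FIRSTORDER = len(FIRSTORDER_FEATURE_NAMES)  # 17
N_TEXTURE = len(TEXTURE_FEATURE_NAMES)      # 79
N_PER_PHASE = N_SHAPE + N_FIRSTORDER + N_TEXTURE  # 110


def phase_feature_columns(n_phases: int) -> List[str]:
    cols = [f"shape_{n}" for n in SHAPE_FEATURE_NAMES]
    for k in range(n_phases):
        cols += [f"firstorder_{n}_phase{k}" for n in FIRSTORDER_FEATURE_NAMES]
        cols += [f"texture_{n}_phase{k}" for n in TEXTURE_FEATURE_NAMES]
    return cols


def column_metadata(n_phases: int) -> pd.DataFrame:
    """Family/phase provenance for every feature column."""
    rows = []
    for n in SHAPE_FEATURE_NAMES:
        rows.append({"column": f"shape_{n}", "family": "shape", "phase": -1})
    for k in range(n_phases):
        for n in FIRSTORDER_FEATURE_NAMES:
            rows.append({"column": f"firstorder_{n}_phase{k}",
                         "family": "firstorder", "phase": k})
        for n in TEXTURE_FEATURE_NAMES:
            rows.append({"column": f"texture_{n}_phase{k}",
                         "family": "texture", "phase": k})
    return pd.DataFrame(rows)


def extract_all_phases(stack: PhaseStack, params: Optional[PreprocessParams] = None,
                       patient_id: str = "P0000") -> pd.Series:
    """One row of the FeatureTable: shape once, intensity/texture per phase.

    Per-feature failures become NaN (missing) rather than aborting the patient.
    """
    params = params or PreprocessParams()
    values: Dict[str, float] = {}
    try:
        shp = extract_shape(stack.mask, stack.spacing)
        values.update({f"shape_{k}": v for k, v in shp.items()})
    except Exception as exc:  # pragma: no cover
        log.warning("shape extraction failed for %s: %s", patient_id, exc)
        values.update({f"shape_{k}": np.nan for k in SHAPE_FEATURE_NAMES})
    for k in range(stack.n_phases):
        phase = stack.image[k]
        if not np.all(np.isfinite(phase[stack.mask])):
            log.warning("phase %d of %s has non-finite ROI values", k, patient_id)
            values.update({f"firstorder_{n}_phase{k}": np.nan
                           for n in FIRSTORDER_FEATURE_NAMES})
            values.update({f"texture_{n}_phase{k}": np.nan
                           for n in TEXTURE_FEATURE_NAMES})
            continue
        try:
            fo = extract_firstorder(phase, stack.mask, params.bin_width)
            values.update({f"firstorder_{n}_phase{k}": fo[n]
                           for n in FIRSTORDER_FEATURE_NAMES})
        except Exception as exc:
            log.warning("first-order failed (%s, phase %d): %s", patient_id, k, exc)
            values.update({f"firstorder_{n}_phase{k}": np.nan
                           for n in FIRSTORDER_FEATURE_NAMES})
        try:
            tx = extract_texture(phase, stack.mask, params.bin_width)
            values.update({f"texture_{n}_phase{k}": tx[n]
                           for n in TEXTURE_FEATURE_NAMES})
        except Exception as exc:
            log.warning("texture failed (%s, phase %d): %s", patient_id, k, exc)
            values.update({f"texture_{n}_phase{k}": np.nan
                           for n in TEXTURE_FEATURE_NAMES})
    return pd.Series(values, name=patient_id)[phase_feature_columns(stack.n_phases)]


def extract_feature_table(stacks, patient_ids, params: Optional[PreprocessParams] = None
                          ) -> pd.DataFrame:
    rows = [extract_all_phases(s, params, pid) for s, pid in zip(stacks, patient_ids)]
    return pd.DataFrame(rows)
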