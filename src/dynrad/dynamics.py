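"""Phase-ordered radiomic feature series and their 22-characteristic summary."""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Dict, List, Sequence

import numpy as np
import pandas as pd

from .catch22 import CATCH22_NAMES, catch22_all

log = logging.getLogger(__name__)

__all__ = ["FeatureSeries", "build_feature_series", "compute_catch22",
           "extract_dynamic_features", "CATCH22_NAMES"]

_PHASE_RE = re.compile(r"^(firstorder|texture)_(.+)_phase(\d+)$")


@dataclass
class FeatureSeries:
    patient_id: str
    feature_name: str
    values: np.ndarray  # phase-ordered

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)


def _phase_columns(feature_table: pd.DataFrame) -> Dict[str, Dict[int, str]]:
    out: Dict[str, Dict[int, str]] = {}
    for col in feature_table.columns:
        m = _PHASE_RE.match(col)
        if m:
            base = f"{m.group(1)}_{m.group(2)}"
            out.setdefault(base, {})[int(m.group(3))] = col
    return out


def build_feature_series(feature_table: pd.DataFrame,
                         eligible_features: Sequence[str]) -> List[FeatureSeries]:
    """One series per (patient, eligible feature), phase order preserved.

    ``eligible_features`` are base names like ``firstorder_Mean``; shape
    features are rejected (they carry no dynamics). Patients with a missing
    phase value for a feature are skipped for that feature, with a log entry.
    """
    for name in eligible_features:
        if name.startswith("shape"):
            raise ValueError(f"shape feature {name!r} cannot form a series")
    col_map = _phase_columns(feature_table)
    series: List[FeatureSeries] = []
    for name in eligible_features:
        if name not in col_map:
            raise KeyError(f"feature {name!r} not present in table")
        phases = sorted(col_map[name])
        cols = [col_map[name][p] for p in phases]
        block = feature_table[cols]
        for pid, row in block.iterrows():
            vals = row.to_numpy(dtype=float)
            if not np.all(np.isfinite(vals)):
                log.warning("series %s dropped for %s: missing phase value",
                            name, pid)
                continue
            series.append(FeatureSeries(str(pid), name, vals))
    return series


def compute_catch22(values: Sequence[float]) -> Dict[str, float]:
    """The 22 canonical time-series characteristics of one series."""
    return catch22_all(np.asarray(values, dtype=float))


def extract_dynamic_features(series: Sequence[FeatureSeries]) -> pd.DataFrame:
    """Patients x (series x 22) dynamic feature table.

    Column naming: ``{feature_name}__{characteristic}``. NaN entries mark
    characteristics undefined at the series length; they are handled by the
    downstream variance/missing filter.
    """
    if not series:
        return pd.DataFrame()
    lengths = {s.values.size for s in series}
    if len(lengths) != 1:
        raise ValueError(f"series lengths not uniform: {sorted(lengths)}")
    rows: Dict[str, Dict[str, float]] = {}
    for s in series:
        c22 = catch22_all(s.values)
        dest = rows.setdefault(s.patient_id, {})
        for k, v in c22.items():
            dest[f"{s.feature_name}__{k}"] = v
    table = pd.DataFrame.from_dict(rows, orient="index")
    feature_names = sorted({s.feature_name for s in series})
    ordered = [f"{f}__{c}" for f in feature_names for c in CATCH22_NAMES]
    table = table.reindex(columns=ordered)
    n_nan = int(table.isna().sum().sum())
    if n_nan:
        log.info("dynamic feature table contains %d NaN entries", n_nan)
    return table
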