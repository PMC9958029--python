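"""Carcinoma-in-situ detection in premalignant tissue.

Premalignant (LP) epithelial cells are labeled CIS when their smoothed
copy-number track is both correlated with the mean malignant track and
carries a minimum aberrant-gene burden. Immune cells with excessive burden
are reassigned to an undetermined pool and dropped from immune analyses.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .cna_inference import CNAProfile, cna_burden
from .core_io import DegenerateInputError


@dataclass
class CisCall:
    cell_id: str
    burden: int
    correlation_to_malignant: float
    label: str  # "CIS" or "normal_epithelial"


def mean_malignant_track(profiles: Sequence[CNAProfile],
                         min_cells: int = 50) -> np.ndarray:
    """Per-gene mean smoothed log ratio over the malignant population."""
    if len(profiles) < min_cells:
        raise DegenerateInputError(
            f"need >= {min_cells} malignant cells for a reference track, "
            f"got {len(profiles)}"
        )
    return np.mean([p.log_ratio for p in profiles], axis=0)


def _safe_corr(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson r; 0 when either side has zero variance."""
    if np.std(x) == 0 or np.std(y) == 0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


def classify_cis(lp_profiles: Sequence[CNAProfile], malignant_track: np.ndarray,
                 r_min: float = 0.3, burden_min: int = 50) -> list[CisCall]:
    """Label LP epithelial cells: CIS iff correlation >= ``r_min`` AND
    burden >= ``burden_min``. Deterministic."""
    calls = []
    for p in lp_profiles:
        r = _safe_corr(p.log_ratio, malignant_track)
        burden = cna_burden(p)
        label = "CIS" if (r >= r_min and burden >= burden_min) else "normal_epithelial"
        calls.append(CisCall(p.cell_id, burden, r, label))
    return calls


def flag_undetermined_immune(immune_profiles: Sequence[CNAProfile],
                             burden_undetermined: int = 200) -> set:
    """Immune cells whose burden strictly exceeds the threshold; these are
    excluded from downstream immune analyses."""
    return {
        p.cell_id for p in immune_profiles if cna_burden(p) > burden_undetermined
    }


def cis_calls_frame(calls: Sequence[CisCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "cell_id": c.cell_id,
                "burden": c.burden,
                "correlation_to_malignant": c.correlation_to_malignant,
                "label": c.label,
            }
            for c in calls
        ],
        columns=["cell_id", "burden", "correlation_to_malignant", "label"],
    )
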