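"""Interdependent ligand-receptor detection between cell populations.

A pair is interdependent when the ligand's detection fraction in the source
population rises stepwise along the tissue progression and ends high, the
receptor is detected in the target population, and the ligand is essentially
absent from the target — the obligate paracrine pattern. Per-patient
ligand/receptor coupling is quantified by Pearson correlation of population
means, with an autocrine negative control.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .config import PipelineConfig
from .core_io import CellMatrix, DegenerateInputError

logger = logging.getLogger("hnscc_stepwise")


@dataclass
class LRPairResult:
    ligand: str
    receptor: str
    frac_ligand_source: dict          # tissue -> detection fraction, progression order
    frac_ligand_target: float
    frac_receptor_target: float
    stepwise_ligand: bool
    interdependent: bool
    patient_correlation: float = float("nan")
    patient_correlation_p: float = float("nan")


@dataclass
class CouplingResult:
    r: float
    p: float
    n_patients: int
    per_patient: pd.DataFrame
    autocrine_r: float
    autocrine_p: float
    reason: str = ""


def expressed_fraction(matrix: CellMatrix, gene: str, cells) -> float:
    """Fraction of the given cells detecting the gene (value > 0)."""
    cells = np.asarray(cells)
    if cells.size == 0:
        raise DegenerateInputError("expressed_fraction needs a non-empty cell set")
    row = matrix.gene_ids.index(gene)
    return float((matrix.values[row, cells] > 0).mean())


def _stepwise_fractions(fracs: Sequence[float], min_increase: float) -> bool:
    """Monotone non-decreasing with an overall increase of at least
    ``min_increase``."""
    arr = np.asarray(fracs, dtype=float)
    return bool(np.all(np.diff(arr) >= 0) and (arr[-1] - arr[0]) >= min_increase)


def find_interdependent_pairs(matrix: CellMatrix, lr_list: pd.DataFrame,
                              source_cells_by_tissue: Mapping[str, Sequence[int]],
                              target_cells,
                              config: PipelineConfig | None = None,
                              ) -> list[LRPairResult]:
    """Evaluate every ligand/receptor pair of ``lr_list``.

    ``source_cells_by_tissue`` maps tissue types (in progression order,
    at least two) to source-population cell indices. A pair is
    interdependent iff (1) ligand source fractions rise stepwise and the
    final fraction reaches ``lr_expr_min``, (2) the receptor target fraction
    reaches ``lr_expr_min``, and (3) the ligand target fraction stays at or
    below ``lr_absent_max``. Pairs whose genes are absent from the matrix
    are skipped with a logged warning. Results come back sorted by final
    source-ligand fraction, descending.
    """
    config = config or PipelineConfig()
    tissues = list(source_cells_by_tissue)
    if len(tissues) < 2:
        raise DegenerateInputError("need source cells for >= 2 tissue types")
    target_cells = np.asarray(target_cells)
    known = set(matrix.gene_ids)
    results = []
    n_skipped = 0
    for _, row in lr_list.iterrows():
        ligand, receptor = str(row["ligand_gene"]), str(row["receptor_gene"])
        if ligand not in known or receptor not in known:
            n_skipped += 1
            logger.warning("skipping pair %s/%s: gene absent from matrix",
                           ligand, receptor)
            continue
        fracs = {
            t: expressed_fraction(matrix, ligand, source_cells_by_tissue[t])
            for t in tissues
        }
        ordered = [fracs[t] for t in tissues]
        stepwise = (
            _stepwise_fractions(ordered, config.lr_step_min_increase)
            and ordered[-1] >= config.lr_expr_min
        )
        f_lig_target = expressed_fraction(matrix, ligand, target_cells)
        f_rec_target = expressed_fraction(matrix, receptor, target_cells)
        interdependent = (
            stepwise
            and f_rec_target >= config.lr_expr_min
            and f_lig_target <= config.lr_absent_max
        )
        results.append(
            LRPairResult(
                ligand=ligand,
                receptor=receptor,
                frac_ligand_source=fracs,
                frac_ligand_target=f_lig_target,
                frac_receptor_target=f_rec_target,
                stepwise_ligand=stepwise,
                interdependent=interdependent,
            )
        )
    if n_skipped:
        logger.info("skipped %d pairs with genes absent from the matrix", n_skipped)
    results.sort(key=lambda r: -list(r.frac_ligand_source.values())[-1])
    return results


def patient_coupling(matrix: CellMatrix, ligand: str, receptor: str,
                     source_cells, target_cells,
                     min_patients: int = 5) -> CouplingResult:
    """Per-patient source-ligand vs target-receptor coupling.

    For each patient contributing cells to both populations, the mean ligand
    expression in the source and mean receptor expression in the target are
    correlated across patients (Pearson, two-sided t-based p). The autocrine
    control correlates ligand and receptor within the source population.
    Zero variance on either axis yields NaN with a stated reason.
    """
    source_cells = np.asarray(source_cells)
    target_cells = np.asarray(target_cells)
    lig_row = matrix.gene_ids.index(ligand)
    rec_row = matrix.gene_ids.index(receptor)
    patients = matrix.cell_meta["patient_id"].to_numpy()

    rows = []
    for patient in pd.unique(patients):
        src = source_cells[patients[source_cells] == patient]
        tgt = target_cells[patients[target_cells] == patient]
        if src.size == 0 or tgt.size == 0:
            continue
        rows.append(
            {
                "patient_id": patient,
                "ligand_source_mean": float(matrix.values[lig_row, src].mean()),
                "receptor_target_mean": float(matrix.values[rec_row, tgt].mean()),
                "receptor_source_mean": float(matrix.values[rec_row, src].mean()),
            }
        )
    table = pd.DataFrame(rows)
    if len(table) < min_patients:
        raise DegenerateInputError(
            f"patient coupling needs >= {min_patients} patients with both "
            f"populations, got {len(table)}"
        )
    x = table["ligand_source_mean"].to_numpy()
    y = table["receptor_target_mean"].to_numpy()
    y_auto = table["receptor_source_mean"].to_numpy()
    if np.std(x) == 0 or np.std(y) == 0:
        return CouplingResult(
            float("nan"), float("nan"), len(table), table,
            float("nan"), float("nan"),
            reason="zero variance in per-patient means",
        )
    r, p = pearsonr(x, y)
    if np.std(y_auto) == 0:
        r_auto, p_auto = float("nan"), float("nan")
    else:
        r_auto, p_auto = pearsonr(x, y_auto)
    return CouplingResult(float(r), float(p), len(table), table,
                          float(r_auto), float(p_auto))


def pairs_frame(results: Sequence[LRPairResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        row = {"ligand": r.ligand, "receptor": r.receptor}
        for tissue, frac in r.frac_ligand_source.items():
            row[f"frac_ligand_source_{tissue}"] = frac
        row.update(
            {
                "frac_ligand_target": r.frac_ligand_target,
                "frac_receptor_target": r.frac_receptor_target,
                "stepwise_ligand": r.stepwise_ligand,
                "interdependent": r.interdependent,
                "patient_correlation": r.patient_correlation,
                "patient_correlation_p": r.patient_correlation_p,
            }
        )
        rows.append(row)
    return pd.DataFrame(rows)


def default_lr_list() -> pd.DataFrame:
    """Small curated matrix-ligand / adhesion-receptor fixture; users may
    supply any two-column list."""
    ligands = ["COL1A1", "COL1A2", "COL6A3", "THBS1", "THBS2", "TNC", "LAMA4"]
    receptors = ["CD44", "ITGB1", "SDC4", "CD47", "ITGB1", "SDC4", "ITGA6"]
    return pd.DataFrame({"ligand_gene": ligands, "receptor_gene": receptors})
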