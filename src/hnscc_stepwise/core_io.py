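"""Shared data model and plain-text I/O for every pipeline stage.

The universal carrier for single-cell stages is :class:`CellMatrix`, a dense
genes x cells expression matrix with per-cell and per-gene annotation.
Matrices are read either from MatrixMarket triplet files or from dense TSV;
all tabular results are written as TSV with a header so that every artifact
round-trips through :func:`write_table` / :func:`read_table`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.io import mmread, mmwrite
from scipy.sparse import coo_matrix

logger = logging.getLogger("hnscc_stepwise")

TISSUE_TYPES = ("NL", "LP", "CA", "LN")
HPV_STATUSES = ("pos", "neg", "NA")

CELL_META_REQUIRED = ("patient_id", "tissue_type", "hpv_status", "cell_type")
GENE_META_REQUIRED = ("chrom", "start_bp", "end_bp", "biotype")


class SchemaError(ValueError):
    """A required column is missing or a categorical value is out of range."""


class ShapeError(ValueError):
    """Matrix dimensions disagree with the metadata tables."""


class DegenerateInputError(ValueError):
    """An operation received input on which its result is undefined."""


_AUTOSOMES = tuple(str(i) for i in range(1, 23))
_PLACED = _AUTOSOMES + ("X", "Y")


def normalize_chrom(chrom: str) -> str:
    """Strip a leading ``chr`` prefix; chromosome names are bare (``1``..``22``, ``X``, ``Y``)."""
    chrom = str(chrom)
    return chrom[3:] if chrom.lower().startswith("chr") else chrom


def chrom_sort_key(chrom: str) -> tuple[int, int]:
    """Deterministic chromosome ordering: autosomes numerically, then X, then Y."""
    c = normalize_chrom(chrom)
    if c in _AUTOSOMES:
        return (0, int(c))
    if c == "X":
        return (1, 0)
    if c == "Y":
        return (1, 1)
    return (2, hash(c) % (2**31))


def _parse_go_terms(value) -> frozenset:
    if isinstance(value, frozenset):
        return value
    if isinstance(value, (set, list, tuple)):
        return frozenset(value)
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return frozenset()
    s = str(value).strip()
    if not s or s.lower() == "nan":
        return frozenset()
    return frozenset(t for t in s.split(";") if t)


@dataclass
class CellMatrix:
    """Genes x cells expression with annotation.

    Parameters
    ----------
    values
        Dense non-negative float array, shape ``(n_genes, n_cells)``.
    gene_ids, cell_ids
        Row / column identifiers, unique.
    gene_meta
        Indexed by gene id; columns ``chrom``, ``start_bp``, ``end_bp``
        (1-based inclusive), ``biotype``, ``go_terms`` (frozenset).
    cell_meta
        Indexed by cell id; columns ``patient_id``, ``tissue_type``,
        ``hpv_status``, ``cell_type`` and optionally ``cluster_label``.
    scale
        ``"counts"`` for raw counts, ``"lognorm"`` for per-cell normalized
        log2 expression (see :meth:`log_normalize`).
    """

    values: np.ndarray
    gene_ids: list
    cell_ids: list
    gene_meta: pd.DataFrame
    cell_meta: pd.DataFrame
    scale: str = "counts"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = list(self.gene_ids)
        self.cell_ids = list(self.cell_ids)
        if self.values.ndim != 2:
            raise ShapeError("expression matrix must be two-dimensional")
        n_genes, n_cells = self.values.shape
        if len(self.gene_ids) != n_genes or len(self.cell_ids) != n_cells:
            raise ShapeError(
                f"matrix is {n_genes}x{n_cells} but ids are "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        if np.any(self.values < 0):
            raise SchemaError("expression values must be non-negative")
        for col in GENE_META_REQUIRED:
            if col not in self.gene_meta.columns:
                raise SchemaError(f"gene_meta is missing required column {col!r}")
        for col in CELL_META_REQUIRED:
            if col not in self.cell_meta.columns:
                raise SchemaError(f"cell_meta is missing required column {col!r}")
        if list(self.gene_meta.index) != self.gene_ids:
            self.gene_meta = self.gene_meta.reindex(self.gene_ids)
            if self.gene_meta[["chrom"]].isna().any().any():
                raise ShapeError("gene_meta does not cover all matrix genes")
        if list(self.cell_meta.index) != self.cell_ids:
            self.cell_meta = self.cell_meta.reindex(self.cell_ids)
            if self.cell_meta[["tissue_type"]].isna().any().any():
                raise ShapeError("cell_meta does not cover all matrix cells")
        bad = set(self.cell_meta["tissue_type"]) - set(TISSUE_TYPES)
        if bad:
            raise SchemaError(f"unknown tissue_type values: {sorted(bad)}")
        bad_hpv = set(self.cell_meta["hpv_status"]) - set(HPV_STATUSES)
        if bad_hpv:
            raise SchemaError(f"unknown hpv_status values: {sorted(bad_hpv)}")
        self.gene_meta = self.gene_meta.copy()
        self.gene_meta["chrom"] = [normalize_chrom(c) for c in self.gene_meta["chrom"]]
        self.gene_meta["start_bp"] = self.gene_meta["start_bp"].astype(np.int64)
        self.gene_meta["end_bp"] = self.gene_meta["end_bp"].astype(np.int64)
        if (self.gene_meta["start_bp"] > self.gene_meta["end_bp"]).any():
            raise SchemaError("gene coordinates must satisfy start_bp <= end_bp")
        if "go_terms" not in self.gene_meta.columns:
            self.gene_meta["go_terms"] = [frozenset()] * n_genes
        else:
            self.gene_meta["go_terms"] = [
                _parse_go_terms(v) for v in self.gene_meta["go_terms"]
            ]
        if self.scale not in ("counts", "lognorm"):
            raise SchemaError(f"unknown scale tag {self.scale!r}")

    # ------------------------------------------------------------------ #

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    @property
    def midpoints(self) -> np.ndarray:
        """Gene midpoints in bp, used as the single ordering coordinate."""
        return (
            self.gene_meta["start_bp"].to_numpy() + self.gene_meta["end_bp"].to_numpy()
        ) // 2

    def gene_order(self) -> np.ndarray:
        """Indices that sort genes by (chromosome, midpoint, gene id)."""
        keys = [
            (chrom_sort_key(c), m, g)
            for c, m, g in zip(self.gene_meta["chrom"], self.midpoints, self.gene_ids)
        ]
        return np.array(sorted(range(self.n_genes), key=lambda i: keys[i]), dtype=int)

    def sort_genes(self) -> "CellMatrix":
        return self.subset_genes(self.gene_order())

    def subset_genes(self, idx) -> "CellMatrix":
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return CellMatrix(
            values=self.values[idx, :],
            gene_ids=[self.gene_ids[i] for i in idx],
            cell_ids=self.cell_ids,
            gene_meta=self.gene_meta.iloc[idx],
            cell_meta=self.cell_meta,
            scale=self.scale,
        )

    def subset_cells(self, idx) -> "CellMatrix":
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return CellMatrix(
            values=self.values[:, idx],
            gene_ids=self.gene_ids,
            cell_ids=[self.cell_ids[i] for i in idx],
            gene_meta=self.gene_meta,
            cell_meta=self.cell_meta.iloc[idx],
            scale=self.scale,
        )

    def cells_where(self, **conditions) -> np.ndarray:
        """Cell indices whose metadata matches every ``column=value`` condition.

        A value may be a scalar or an iterable of admissible values.
        """
        mask = np.ones(self.n_cells, dtype=bool)
        for col, val in conditions.items():
            series = self.cell_meta[col]
            if isinstance(val, (list, tuple, set, frozenset)):
                mask &= series.isin(list(val)).to_numpy()
            else:
                mask &= (series == val).to_numpy()
        return np.flatnonzero(mask)

    def log_normalize(self, target_sum: float = 1e4) -> "CellMatrix":
        """Per-cell scaling to ``target_sum`` total counts, then ``log2(x + 1)``."""
        if self.scale == "lognorm":
            return self
        totals = self.values.sum(axis=0)
        totals = np.where(totals > 0, totals, 1.0)
        scaled = self.values / totals * target_sum
        out = replace(self)
        out.values = np.log2(scaled + 1.0)
        out.scale = "lognorm"
        return out


@dataclass
class SurvivalRecord:
    """One follow-up record; ``event`` is 1 for observed, 0 for censored."""

    sample_id: str
    time: float
    event: int
    endpoint: str = "OS"
    time_unit: str = "months"

    def __post_init__(self):
        if self.time < 0:
            raise SchemaError(f"negative follow-up time for {self.sample_id}")
        if self.event not in (0, 1):
            raise SchemaError(f"event must be 0 or 1, got {self.event!r}")


# ---------------------------------------------------------------------- #
# Readers / writers
# ---------------------------------------------------------------------- #


def _read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_cell_matrix(path_matrix, path_cell_meta, path_gene_meta,
                     drop_unplaced: bool = True) -> CellMatrix:
    """Load an annotated expression matrix.

    ``path_matrix`` is either MatrixMarket (``.mtx``, genes x cells, row
    order matching ``path_gene_meta``) or a dense TSV whose first column
    holds gene ids and whose header holds cell ids. Mitochondrial and
    unplaced-contig genes are dropped (logged); genes come back sorted by
    (chromosome, midpoint).
    """
    path_matrix = Path(path_matrix)
    gene_meta = _read_tsv(path_gene_meta)
    cell_meta = _read_tsv(path_cell_meta)
    if "gene_id" not in gene_meta.columns:
        raise SchemaError("gene_meta must contain a 'gene_id' column")
    if "cell_id" not in cell_meta.columns:
        raise SchemaError("cell_meta must contain a 'cell_id' column")
    for col in GENE_META_REQUIRED:
        if col not in gene_meta.columns:
            raise SchemaError(f"gene_meta is missing required column {col!r}")
    for col in CELL_META_REQUIRED:
        if col not in cell_meta.columns:
            raise SchemaError(f"cell_meta is missing required column {col!r}")
    gene_meta = gene_meta.set_index("gene_id")
    cell_meta = cell_meta.set_index("cell_id")

    if path_matrix.suffix == ".mtx":
        values = np.asarray(mmread(path_matrix).todense(), dtype=float)
        gene_ids = list(gene_meta.index)
        cell_ids = list(cell_meta.index)
        if values.shape != (len(gene_ids), len(cell_ids)):
            raise ShapeError(
                f"MTX matrix is {values.shape} but metadata describes "
                f"{len(gene_ids)} genes x {len(cell_ids)} cells"
            )
    else:
        table = pd.read_csv(path_matrix, sep="\t", index_col=0)
        values = table.to_numpy(dtype=float)
        gene_ids = list(table.index)
        cell_ids = list(table.columns)
        if set(gene_ids) != set(gene_meta.index):
            raise ShapeError("dense TSV gene ids do not match gene_meta")
        if set(cell_ids) != set(cell_meta.index):
            raise ShapeError("dense TSV cell ids do not match cell_meta")

    matrix = CellMatrix(values, gene_ids, cell_ids, gene_meta, cell_meta)
    if drop_unplaced:
        placed = np.array(
            [normalize_chrom(c) in _PLACED for c in matrix.gene_meta["chrom"]]
        )
        n_dropped = int((~placed).sum())
        if n_dropped:
            logger.info("dropping %d mitochondrial/unplaced genes at load", n_dropped)
            matrix = matrix.subset_genes(placed)
        if matrix.n_genes == 0:
            raise DegenerateInputError("no genes left after dropping unplaced contigs")
    return matrix.sort_genes()


def write_cell_matrix(matrix: CellMatrix, out_dir) -> dict:
    """Emit ``matrix.mtx`` plus ``cells.tsv`` / ``genes.tsv`` under ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": out_dir / "matrix.mtx",
        "cells": out_dir / "cells.tsv",
        "genes": out_dir / "genes.tsv",
    }
    sparse = coo_matrix(matrix.values)
    mmwrite(str(paths["matrix"]), sparse)
    cell_meta = matrix.cell_meta.reset_index(names="cell_id")
    gene_meta = matrix.gene_meta.copy()
    gene_meta["go_terms"] = [";".join(sorted(t)) for t in gene_meta["go_terms"]]
    gene_meta = gene_meta.reset_index(names="gene_id")
    write_table(cell_meta, paths["cells"])
    write_table(gene_meta, paths["genes"])
    return paths


def write_table(table: pd.DataFrame, path) -> None:
    """Write any tabular result as TSV with a header (full float precision)."""
    pd.DataFrame(table).to_csv(path, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return _read_tsv(path)


def read_lr_list(path) -> pd.DataFrame:
    """Two-column ligand/receptor list with columns ``ligand_gene``, ``receptor_gene``."""
    table = _read_tsv(path)
    for col in ("ligand_gene", "receptor_gene"):
        if col not in table.columns:
            raise SchemaError(f"ligand-receptor list is missing column {col!r}")
    return table


def read_survival(path) -> list[SurvivalRecord]:
    table = _read_tsv(path)
    for col in ("sample_id", "time", "event"):
        if col not in table.columns:
            raise SchemaError(f"survival table is missing column {col!r}")
    endpoint = table["endpoint"] if "endpoint" in table.columns else ["OS"] * len(table)
    return [
        SurvivalRecord(str(s), float(t), int(e), str(ep))
        for s, t, e, ep in zip(table["sample_id"], table["time"], table["event"], endpoint)
    ]


def survival_frame(records: Iterable[SurvivalRecord]) -> pd.DataFrame:
    rows = [
        {"sample_id": r.sample_id, "time": r.time, "event": r.event, "endpoint": r.endpoint}
        for r in records
    ]
    return pd.DataFrame(rows).set_index("sample_id")
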