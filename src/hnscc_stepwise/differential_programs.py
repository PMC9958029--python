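"""Permutation-based differential expression and derived gene programs.

The workhorse is a Welch-t permutation test: the t statistic is computed on
observed labels and referred to the distribution of the same statistic over
random relabelings, with exact enumeration replacing sampling whenever the
number of distinct relabelings fits in the permutation budget. On top of it
sit cluster marker discovery (rank-sum), copy-number-dependent gene calls
(concordant track and expression shifts), and stepwise gene detection along
the tissue progression.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .config import PipelineConfig
from .core_io import CellMatrix, DegenerateInputError

__all__ = [
    "DiffResult", "CnaDependentGene", "permuted_t_test", "permuted_t_matrix",
    "wilcoxon_markers", "cna_dependent_genes", "stepwise_genes",
]


@dataclass
class DiffResult:
    gene_id: str
    group_a: str
    group_b: str
    mean_a: float
    mean_b: float
    fold_diff: float       # mean_a - mean_b on the log2 scale
    t_stat: float
    perm_p: float
    n_permutations: int


@dataclass
class CnaDependentGene:
    gene_id: str
    cna_fold_diff: float
    cna_perm_p: float
    expr_fold_diff: float
    expr_perm_p: float
    concordant: bool


def _welch_t(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = len(a), len(b)
    ma, mb = a.mean(), b.mean()
    va = a.var(ddof=1)
    vb = b.var(ddof=1)
    denom = math.sqrt(va / na + vb / nb)
    if denom == 0:
        return 0.0 if ma == mb else math.copysign(math.inf, ma - mb)
    return (ma - mb) / denom


def _perm_group_stats(pooled: np.ndarray, na: int, n_perm: int,
                      rng: np.random.Generator) -> np.ndarray:
    """|Welch t| for ``n_perm`` random relabelings of a 1-D pooled sample."""
    X = pooled[None, :]  # 1 x n
    masks = np.argsort(rng.random((n_perm, len(pooled))), axis=1) < na
    return np.abs(_welch_t_from_masks(X, masks, na))[:, 0]


def _welch_t_from_masks(X: np.ndarray, masks: np.ndarray, na: int) -> np.ndarray:
    """Welch t for every (permutation, gene) pair.

    ``X`` is genes x n pooled values, ``masks`` is perms x n boolean with
    ``na`` Trues per row. Returns perms x genes.
    """
    n = X.shape[1]
    nb = n - na
    M = masks.astype(float)
    sa = M @ X.T                      # perms x genes
    ssa = M @ (X ** 2).T
    tot = X.sum(axis=1)[None, :]
    tot2 = (X ** 2).sum(axis=1)[None, :]
    sb = tot - sa
    ssb = tot2 - ssa
    ma = sa / na
    mb = sb / nb
    va = (ssa - na * ma ** 2) / max(na - 1, 1)
    vb = (ssb - nb * mb ** 2) / max(nb - 1, 1)
    va = np.maximum(va, 0.0)
    vb = np.maximum(vb, 0.0)
    denom = np.sqrt(va / na + vb / nb)
    diff = ma - mb
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / denom
    t[(denom == 0) & (diff == 0)] = 0.0
    t[(denom == 0) & (diff > 0)] = np.inf
    t[(denom == 0) & (diff < 0)] = -np.inf
    return t


def permuted_t_test(values_a, values_b, n_permutations: int = 10_000,
                    seed: int | None = None,
                    force_sampling: bool = False) -> tuple[float, float]:
    """Two-sided Welch-t permutation test.

    Exact enumeration over all ``C(n, n_a)`` relabelings when that count is
    within the permutation budget (then ``p = #{|t*| >= |t|} / total``,
    which includes the observed labeling); otherwise ``n_permutations``
    sampled relabelings with the add-one estimate
    ``p = (1 + #{|t*| >= |t|}) / (1 + n_permutations)``.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise DegenerateInputError("both groups must have size >= 2")
    t_obs = _welch_t(a, b)
    if t_obs == 0.0 and a.var(ddof=1) + b.var(ddof=1) == 0:
        return 0.0, 1.0
    pooled = np.concatenate([a, b])
    n, na = len(pooled), len(a)
    total = math.comb(n, na)
    if total <= n_permutations and not force_sampling:
        count = 0
        idx_all = set(range(n))
        for subset in combinations(range(n), na):
            sel = np.fromiter(subset, dtype=int)
            rest = np.fromiter(idx_all - set(subset), dtype=int)
            if abs(_welch_t(pooled[sel], pooled[rest])) >= abs(t_obs) - 1e-12:
                count += 1
        return t_obs, count / total
    rng = np.random.default_rng(seed)
    t_perm = _perm_group_stats(pooled, na, n_permutations, rng)
    count = int(np.sum(t_perm >= abs(t_obs) - 1e-12))
    return t_obs, (1 + count) / (1 + n_permutations)


def permuted_t_matrix(A: np.ndarray, B: np.ndarray, n_permutations: int = 1000,
                      seed: int | None = None,
                      chunk: int = 200) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise permutation Welch t over many genes sharing the same cells.

    ``A`` is genes x n_a, ``B`` genes x n_b. One set of label permutations
    is shared by all genes. Returns ``(t_stats, perm_ps)`` per gene with the
    add-one estimate.
    """
    A = np.atleast_2d(np.asarray(A, dtype=float))
    B = np.atleast_2d(np.asarray(B, dtype=float))
    na, nb = A.shape[1], B.shape[1]
    if na < 2 or nb < 2:
        raise DegenerateInputError("both groups must have size >= 2")
    X = np.concatenate([A, B], axis=1)
    n = na + nb
    obs_mask = np.zeros((1, n), dtype=bool)
    obs_mask[0, :na] = True
    t_obs = _welch_t_from_masks(X, obs_mask, na)[0]
    rng = np.random.default_rng(seed)
    count = np.zeros(X.shape[0], dtype=np.int64)
    done = 0
    while done < n_permutations:
        m = min(chunk, n_permutations - done)
        masks = np.argsort(rng.random((m, n)), axis=1) < na
        t_perm = np.abs(_welch_t_from_masks(X, masks, na))
        count += (t_perm >= np.abs(t_obs)[None, :] - 1e-12).sum(axis=0)
        done += m
    p = (1 + count) / (1 + n_permutations)
    return t_obs, p


# ---------------------------------------------------------------------- #
# Cluster markers (rank-sum)
# ---------------------------------------------------------------------- #


def wilcoxon_markers(matrix: CellMatrix, cluster_labels: Sequence,
                     marker_p: float = 0.001,
                     marker_fold: float = 1.0) -> pd.DataFrame:
    """One-vs-rest rank-sum markers per cluster.

    A gene is a marker for a cluster when the two-sided rank-sum p is below
    ``marker_p`` and the difference of mean log2 expression favors the
    cluster by more than ``marker_fold``. Clusters of fewer than 3 cells
    are skipped with a warning. Returns all tested genes with a boolean
    ``is_marker`` column, sorted by (cluster, p, -fold).
    """
    if matrix.scale != "lognorm":
        raise ValueError("wilcoxon_markers requires log-normalized expression")
    labels = np.asarray(cluster_labels)
    clusters = sorted(pd.unique(labels))
    if len(clusters) < 2:
        raise DegenerateInputError("need >= 2 clusters for marker discovery")
    rows = []
    for cl in clusters:
        in_cl = labels == cl
        if in_cl.sum() < 3:
            warnings.warn(f"cluster {cl!r} has fewer than 3 cells; skipped")
            continue
        Xa = matrix.values[:, in_cl]
        Xb = matrix.values[:, ~in_cl]
        mean_in = Xa.mean(axis=1)
        mean_out = Xb.mean(axis=1)
        fold = mean_in - mean_out
        with np.errstate(invalid="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore")
            stat, p = mannwhitneyu(Xa, Xb, axis=1, alternative="two-sided",
                                   method="auto")
        for g in range(matrix.n_genes):
            is_marker = bool(p[g] < marker_p and fold[g] > marker_fold)
            rows.append(
                {
                    "cluster": cl,
                    "gene_id": matrix.gene_ids[g],
                    "p_value": float(p[g]),
                    "fold_diff": float(fold[g]),
                    "mean_in": float(mean_in[g]),
                    "mean_out": float(mean_out[g]),
                    "is_marker": is_marker,
                }
            )
    frame = pd.DataFrame(rows)
    return frame.sort_values(
        ["cluster", "p_value", "fold_diff"], ascending=[True, True, False]
    ).reset_index(drop=True)


# ---------------------------------------------------------------------- #
# CNA-dependent genes
# ---------------------------------------------------------------------- #


def cna_dependent_genes(tracks: pd.DataFrame, matrix: CellMatrix,
                        cells_a, cells_b,
                        config: PipelineConfig | None = None,
                        group_names: tuple[str, str] = ("A", "B"),
                        ) -> list[CnaDependentGene]:
    """Genes whose copy-number track AND expression shift together.

    ``tracks`` is a genes x cells DataFrame of smoothed log ratios whose
    columns are cell ids of ``matrix``. For each gene shared between tracks
    and matrix, a permutation Welch t runs on (a) track values and (b) log2
    expression between the two cell groups; a gene is reported when both
    p-values clear ``perm_p``, the expression fold clears ``marker_fold``,
    the track fold clears ``cna_fold_cutoff``, and the signs agree.
    """
    config = config or PipelineConfig()
    if matrix.scale != "lognorm":
        raise ValueError("cna_dependent_genes requires log-normalized expression")
    cells_a = np.asarray(cells_a)
    cells_b = np.asarray(cells_b)
    if np.intersect1d(cells_a, cells_b).size:
        raise ValueError("cell groups must not overlap")
    genes = [g for g in matrix.gene_ids if g in tracks.index]
    gpos = {g: i for i, g in enumerate(matrix.gene_ids)}
    ids_a = [matrix.cell_ids[c] for c in cells_a]
    ids_b = [matrix.cell_ids[c] for c in cells_b]
    track_a = tracks.loc[genes, ids_a].to_numpy()
    track_b = tracks.loc[genes, ids_b].to_numpy()
    expr_rows = np.array([gpos[g] for g in genes])
    expr_a = matrix.values[np.ix_(expr_rows, cells_a)]
    expr_b = matrix.values[np.ix_(expr_rows, cells_b)]

    seed = config.rng_seed
    _, cna_p = permuted_t_matrix(track_a, track_b, config.n_permutations, seed)
    _, expr_p = permuted_t_matrix(expr_a, expr_b, config.n_permutations, seed + 1)
    cna_fold = track_a.mean(axis=1) - track_b.mean(axis=1)
    expr_fold = expr_a.mean(axis=1) - expr_b.mean(axis=1)

    out = []
    for i, g in enumerate(genes):
        passing = (
            cna_p[i] < config.perm_p
            and expr_p[i] < config.perm_p
            and abs(expr_fold[i]) > config.marker_fold
            and abs(cna_fold[i]) > config.cna_fold_cutoff
            and np.sign(cna_fold[i]) == np.sign(expr_fold[i])
        )
        if passing:
            out.append(
                CnaDependentGene(
                    gene_id=str(g),
                    cna_fold_diff=float(cna_fold[i]),
                    cna_perm_p=float(cna_p[i]),
                    expr_fold_diff=float(expr_fold[i]),
                    expr_perm_p=float(expr_p[i]),
                    concordant=True,
                )
            )
    return out


# ---------------------------------------------------------------------- #
# Stepwise genes along the tissue progression
# ---------------------------------------------------------------------- #


def stepwise_genes(matrix: CellMatrix, cell_type: str,
                   tissue_order: Sequence[str] = ("NL", "LP", "CA"),
                   config: PipelineConfig | None = None) -> pd.DataFrame:
    """Genes whose mean expression moves monotonically along ``tissue_order``.

    Stepwise-up: strictly increasing tissue means with every adjacent
    contrast significant (permutation Welch t, ``p < perm_p``) and a log2
    step above ``step_fold``; stepwise-down is symmetric. Returns a frame
    of all genes with per-tissue means, per-step p-values, and a
    ``direction`` column in {up, down, none}.
    """
    config = config or PipelineConfig()
    if matrix.scale != "lognorm":
        raise ValueError("stepwise_genes requires log-normalized expression")
    groups = []
    for tissue in tissue_order:
        idx = matrix.cells_where(cell_type=cell_type, tissue_type=tissue)
        if idx.size == 0:
            raise DegenerateInputError(
                f"cell type {cell_type!r} has no cells in tissue {tissue!r}"
            )
        groups.append(idx)
    X = [matrix.values[:, idx] for idx in groups]
    means = np.stack([x.mean(axis=1) for x in X], axis=1)  # genes x tissues

    step_p = np.ones((matrix.n_genes, len(tissue_order) - 1))
    for s in range(len(tissue_order) - 1):
        if X[s].shape[1] < 2 or X[s + 1].shape[1] < 2:
            continue  # underpowered contrast keeps p = 1 and blocks the call
        _, p = permuted_t_matrix(
            X[s], X[s + 1], config.n_permutations, config.rng_seed + s
        )
        step_p[:, s] = p

    steps = np.diff(means, axis=1)  # genes x (tissues-1), log2 units
    sig = step_p < config.perm_p
    up = (steps > config.step_fold).all(axis=1) & sig.all(axis=1)
    down = (steps < -config.step_fold).all(axis=1) & sig.all(axis=1)

    frame = pd.DataFrame({"gene_id": matrix.gene_ids})
    for t, tissue in enumerate(tissue_order):
        frame[f"mean_{tissue}"] = means[:, t]
    for s in range(len(tissue_order) - 1):
        frame[f"p_{tissue_order[s]}_{tissue_order[s + 1]}"] = step_p[:, s]
    frame["direction"] = np.where(up, "up", np.where(down, "down", "none"))
    return frame
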