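"""Signature-based bulk deconvolution, template subtyping, and survival.

Cluster signatures are the union of per-cluster rank-sum markers with mean
linear expression as weights; bulk proportions come from per-sample
non-negative least squares normalized to sum one; external profiles are
re-assigned by nearest-template prediction with a gene-permutation null;
cohorts are stratified at a percentile of a focal cluster's proportion and
compared with Kaplan-Meier / log-rank machinery (O/E-based hazard ratio).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from scipy.stats import chi2, pearsonr, false_discovery_control

from .config import PipelineConfig
from .core_io import CellMatrix, DegenerateInputError, survival_frame
from .differential_programs import wilcoxon_markers

logger = logging.getLogger("hnscc_stepwise")


@dataclass
class SignatureMatrix:
    """Marker genes x clusters mean linear expression, plus the per-cluster
    marker sets used as nearest-template weights."""

    data: pd.DataFrame                       # genes x clusters, linear scale
    markers: Mapping[str, Sequence[str]]     # cluster -> its own marker genes
    params: dict = field(default_factory=dict)

    @property
    def clusters(self) -> list:
        return list(self.data.columns)


@dataclass
class ProportionTable:
    proportions: pd.DataFrame   # samples x clusters, rows sum to 1
    residual: pd.Series         # per-sample residual norm


@dataclass
class StratifiedCohort:
    groups: pd.Series           # sample -> "high" / "low"
    cutoff: float
    focal_cluster: str
    percentile: float
    survival: pd.DataFrame      # indexed by sample: time, event


@dataclass
class LogrankResult:
    chi_sq: float
    p: float
    hr_estimate: float
    observed: dict              # group -> observed events
    expected: dict              # group -> expected events
    km_curves: dict             # group -> DataFrame(time, survival)


# ---------------------------------------------------------------------- #
# Signature construction
# ---------------------------------------------------------------------- #


def build_signature(matrix: CellMatrix, cluster_labels: Sequence,
                    top_k: int = 50, min_cells: int = 20,
                    candidate_p: float = 0.05) -> SignatureMatrix:
    """Union-of-markers signature.

    Markers per cluster: the ``top_k`` genes ranked by rank-sum p (ties by
    fold, descending) among genes overexpressed in the cluster (positive
    fold, ``p < candidate_p``). Clusters below ``min_cells`` are excluded
    with a warning; a cluster with no overexpressed genes at all is a
    degenerate input. Entries are per-cluster mean linear expression.
    """
    labels = np.asarray(cluster_labels)
    counts = pd.Series(labels).value_counts()
    kept = [c for c in sorted(counts.index) if counts[c] >= min_cells]
    dropped = sorted(set(counts.index) - set(kept))
    if dropped:
        warnings.warn(f"clusters below {min_cells} cells excluded: {dropped}")
    if len(kept) < 2:
        raise DegenerateInputError("need >= 2 clusters of sufficient size")
    keep_mask = np.isin(labels, kept)
    sub = matrix.subset_cells(np.flatnonzero(keep_mask))
    lognorm = sub.log_normalize()
    table = wilcoxon_markers(lognorm, labels[keep_mask], marker_p=1.0, marker_fold=0.0)

    marker_sets: dict = {}
    for cl in kept:
        cand = table[
            (table["cluster"] == cl)
            & (table["fold_diff"] > 0)
            & (table["p_value"] < candidate_p)
        ]
        if cand.empty:
            raise DegenerateInputError(
                f"cluster {cl!r} has no overexpressed genes; clusters may be identical"
            )
        marker_sets[cl] = list(cand.head(top_k)["gene_id"])

    union = sorted({g for genes in marker_sets.values() for g in genes})
    rows = {g: i for i, g in enumerate(matrix.gene_ids)}
    gidx = np.array([rows[g] for g in union])
    if matrix.scale == "lognorm":
        linear = np.exp2(matrix.values) - 1.0
    else:
        linear = matrix.values
    cols = {}
    for cl in kept:
        cells = np.flatnonzero(labels == cl)
        cols[cl] = linear[np.ix_(gidx, cells)].mean(axis=1)
    data = pd.DataFrame(cols, index=union)
    if (data.sum(axis=0) == 0).any():
        raise DegenerateInputError("signature has an all-zero cluster column")
    return SignatureMatrix(
        data=data,
        markers=marker_sets,
        params={"top_k": top_k, "min_cells": min_cells, "candidate_p": candidate_p},
    )


# ---------------------------------------------------------------------- #
# Bulk deconvolution
# ---------------------------------------------------------------------- #


def estimate_proportions(bulk_matrix: pd.DataFrame, signature: SignatureMatrix,
                         min_genes: int = 50) -> ProportionTable:
    """Per-sample NNLS of the bulk profile on signature columns, normalized
    to proportions; the residual norm of the (unnormalized) fit is kept."""
    sig = signature.data
    shared = [g for g in sig.index if g in bulk_matrix.index]
    if len(shared) < min_genes:
        raise DegenerateInputError(
            f"only {len(shared)} genes overlap the signature; need >= {min_genes}"
        )
    A = sig.loc[shared].to_numpy()
    props = {}
    residuals = {}
    for sample in bulk_matrix.columns:
        y = bulk_matrix.loc[shared, sample].to_numpy(dtype=float)
        coef, resid = nnls(A, y)
        total = coef.sum()
        props[sample] = coef / total if total > 0 else np.full(len(coef), 1 / len(coef))
        residuals[sample] = resid
    table = pd.DataFrame(props, index=sig.columns).T
    return ProportionTable(table, pd.Series(residuals, name="residual_norm"))


# ---------------------------------------------------------------------- #
# Nearest-template prediction
# ---------------------------------------------------------------------- #


def _cosine_distance(u: np.ndarray, v: np.ndarray) -> float:
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        return 1.0
    return float(1.0 - np.dot(u, v) / (nu * nv))


def ntp_assign(profiles: pd.DataFrame, templates: SignatureMatrix,
               n_perm: int = 1000, fdr_max: float = 0.05,
               seed: int | None = None) -> pd.DataFrame:
    """Nearest-template assignment with a gene-permutation null.

    ``profiles`` is genes x cells (any common scale). For each cell the
    cosine distance to each template is computed on that template's marker
    genes; templates with more than half their markers missing from the
    profile are skipped. Significance of the nearest distance comes from
    ``n_perm`` random draws of equally many genes from the cell's own
    profile; p-values are Benjamini-Hochberg adjusted across cells and
    assignments with FDR above ``fdr_max`` are voided (``assigned = None``).
    """
    rng = np.random.default_rng(seed)
    available = set(profiles.index)
    rows = []
    for cell in profiles.columns:
        vec_full = profiles[cell]
        best = None
        for cl in templates.clusters:
            markers = [g for g in templates.markers[cl] if g in available]
            if len(markers) * 2 < len(templates.markers[cl]):
                continue
            d = _cosine_distance(
                vec_full.loc[markers].to_numpy(dtype=float),
                templates.data.loc[markers, cl].to_numpy(dtype=float),
            )
            if best is None or d < best[1]:
                best = (cl, d, markers)
        if best is None:
            rows.append({"cell": cell, "assigned": None, "distance": np.nan, "p": np.nan})
            continue
        cl, d_obs, markers = best
        weights = templates.data.loc[markers, cl].to_numpy(dtype=float)
        values = vec_full.to_numpy(dtype=float)
        count = 0
        for _ in range(n_perm):
            draw = values[rng.choice(len(values), size=len(markers), replace=False)]
            if _cosine_distance(draw, weights) <= d_obs:
                count += 1
        p = (1 + count) / (1 + n_perm)
        rows.append({"cell": cell, "assigned": cl, "distance": d_obs, "p": p})
    frame = pd.DataFrame(rows)
    mask = frame["p"].notna()
    fdr = pd.Series(np.nan, index=frame.index)
    if mask.any():
        fdr[mask] = false_discovery_control(frame.loc[mask, "p"], method="bh")
    frame["fdr"] = fdr
    frame.loc[frame["fdr"] > fdr_max, "assigned"] = None
    return frame


# ---------------------------------------------------------------------- #
# Stratification and survival
# ---------------------------------------------------------------------- #


def stratify(proportions: pd.DataFrame, focal_cluster: str, percentile: float,
             survival: pd.DataFrame) -> StratifiedCohort | None:
    """Split samples at the given percentile of the focal proportion.

    High = strictly above the linear-interpolation percentile value (ties at
    the boundary go low). A zero percentile value voids stratification with
    a warning (returns None).
    """
    values = proportions[focal_cluster]
    cutoff = float(np.percentile(values.to_numpy(), percentile))
    if cutoff == 0:
        warnings.warn(
            f"{focal_cluster}: percentile {percentile} of the proportion is zero; "
            "stratification skipped"
        )
        return None
    groups = pd.Series(
        np.where(values > cutoff, "high", "low"), index=values.index, name="group"
    )
    if (groups == "high").sum() == 0:
        warnings.warn(f"{focal_cluster}: high group is empty at cutoff {cutoff:.4g}")
    surv = survival.loc[survival.index.intersection(values.index)]
    return StratifiedCohort(groups, cutoff, focal_cluster, percentile, surv)


def logrank_survival(cohort: StratifiedCohort,
                     horizon: float | None = None) -> LogrankResult:
    """Two-group log-rank test with O/E hazard-ratio estimate and KM curves.

    Follow-up is truncated (administratively censored) at ``horizon`` when
    given. The hazard ratio is ``(O_high/E_high) / (O_low/E_low)``.
    """
    surv = cohort.survival.copy()
    groups = cohort.groups.loc[surv.index]
    time = surv["time"].to_numpy(dtype=float)
    event = surv["event"].to_numpy(dtype=int)
    if horizon is not None:
        over = time > horizon
        time = np.where(over, horizon, time)
        event = np.where(over, 0, event)
    is_high = (groups == "high").to_numpy()
    if is_high.all() or (~is_high).all():
        raise DegenerateInputError("both groups must be non-empty")
    if event.sum() == 0:
        raise DegenerateInputError("no events observed")

    event_times = np.unique(time[event == 1])
    o_high = e_high = var_sum = 0.0
    for t in event_times:
        at_risk = time >= t
        n = at_risk.sum()
        n_h = (at_risk & is_high).sum()
        d = ((time == t) & (event == 1)).sum()
        d_h = ((time == t) & (event == 1) & is_high).sum()
        o_high += d_h
        e_high += d * n_h / n
        if n > 1:
            var_sum += d * (n_h / n) * (1 - n_h / n) * (n - d) / (n - 1)
    o_total = float(event.sum())
    o_low = o_total - o_high
    e_low = o_total - e_high
    chi_sq = (o_high - e_high) ** 2 / var_sum if var_sum > 0 else 0.0
    p = float(chi2.sf(chi_sq, df=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        hr = (o_high / e_high) / (o_low / e_low) if e_high > 0 and e_low > 0 and o_low > 0 else np.inf

    km = {
        name: _km_curve(time[sel], event[sel])
        for name, sel in (("high", is_high), ("low", ~is_high))
    }
    return LogrankResult(
        chi_sq=float(chi_sq), p=p, hr_estimate=float(hr),
        observed={"high": float(o_high), "low": float(o_low)},
        expected={"high": float(e_high), "low": float(e_low)},
        km_curves=km,
    )


def _km_curve(time: np.ndarray, event: np.ndarray) -> pd.DataFrame:
    """Kaplan-Meier step curve: survival after each distinct event time."""
    order = np.argsort(time)
    time, event = time[order], event[order]
    surv = 1.0
    rows = [{"time": 0.0, "survival": 1.0}]
    for t in np.unique(time[event == 1]):
        n = (time >= t).sum()
        d = ((time == t) & (event == 1)).sum()
        surv *= 1 - d / n
        rows.append({"time": float(t), "survival": float(surv)})
    return pd.DataFrame(rows)


def proportion_gene_correlation(proportions: pd.DataFrame,
                                bulk_matrix: pd.DataFrame, cluster: str,
                                gene: str, min_samples: int = 10):
    """Pearson correlation between a cluster's proportion and a gene's bulk
    expression across samples; NaN for zero variance."""
    samples = [s for s in proportions.index if s in bulk_matrix.columns]
    if len(samples) < min_samples:
        raise DegenerateInputError(
            f"need >= {min_samples} samples with both proportions and bulk data"
        )
    x = proportions.loc[samples, cluster].to_numpy(dtype=float)
    y = bulk_matrix.loc[gene, samples].to_numpy(dtype=float)
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan"), float("nan")
    r, p = pearsonr(x, y)
    return float(r), float(p)
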