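"""Synthetic cohort generation with planted ground truth.

Generates multi-patient, four-tissue-type single-cell cohorts whose
statistical structure matches what the downstream stages assume: negative
binomial counts around cell-type base means, clonal copy-number segments
that scale expression multiplicatively, a malignant clone restricted to
CA/LN plus an optional in-situ subclone in LP, stepwise ligand programs in
fibroblasts, receptor programs in malignant cells, and proportion-linked
survival for bulk cohorts. Every planted quantity is returned in a
:class:`GroundTruth` so recovery can be tested quantitatively.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import CellMatrix, SurvivalRecord, TISSUE_TYPES

CELL_TYPES = ("epithelial", "fibroblast", "nk_t", "b_plasma", "macrophage", "endothelial")

IMMUNE_CELL_TYPES = ("nk_t", "b_plasma", "macrophage")


class SpecError(ValueError):
    """The cohort specification is internally inconsistent."""


@dataclass
class CNASegmentSpec:
    """A planted clonal copy-number segment over a run of ordered genes."""

    chrom: str
    gene_start: int          # global gene index (sorted order), inclusive
    gene_end: int            # global gene index, exclusive
    direction: str           # "gain" or "loss"
    copy_ratio: float        # multiplicative effect on the expression mean
    carrier_fraction: float  # fraction of clone cells carrying the segment
    tissue_types: tuple = ("CA", "LN")

    def __post_init__(self):
        if self.direction not in ("gain", "loss"):
            raise SpecError(f"direction must be gain/loss, got {self.direction!r}")
        if self.copy_ratio <= 0:
            raise SpecError("copy_ratio must be > 0")
        if not 0 < self.carrier_fraction <= 1:
            raise SpecError("carrier_fraction must lie in (0, 1]")
        if self.gene_end <= self.gene_start:
            raise SpecError("empty segment")


@dataclass
class StepwiseGeneSpec:
    """A gene whose mean shifts across the tissue progression in one cell type."""

    gene_index: int
    cell_type: str
    tissue_multipliers: Mapping[str, float]  # e.g. {"NL": 1, "LP": 2.5, "CA": 6}


@dataclass
class LRPairSpec:
    """A planted ligand/receptor pair with a known interdependence verdict.

    ``ligand_target_silent`` controls whether the ligand is silenced outside
    the source population (the paracrine pattern); autocrine decoys set it
    to False so the target also expresses the ligand.
    """

    ligand_index: int
    receptor_index: int
    source_type: str = "fibroblast"
    target_type: str = "epithelial"
    interdependent: bool = True
    ligand_target_silent: bool = True
    receptor_expressed: bool = True


@dataclass
class CohortSpec:
    """Generative parameters for one synthetic cohort (defaults mirror a
    9/4/20/4 NL/LP/CA/LN design)."""

    n_patients: Mapping[str, int] = field(
        default_factory=lambda: {"NL": 9, "LP": 4, "CA": 20, "LN": 4}
    )
    cells_per_sample: int = 80
    n_genes: int = 600
    genes_per_chrom: int = 150
    gene_spacing_bp: int = 100_000
    cell_type_mixture: Mapping[str, Sequence[float]] = field(
        default_factory=lambda: {
            "NL": (0.35, 0.20, 0.20, 0.10, 0.10, 0.05),
            "LP": (0.35, 0.20, 0.20, 0.10, 0.10, 0.05),
            "CA": (0.50, 0.20, 0.15, 0.05, 0.05, 0.05),
            "LN": (0.45, 0.15, 0.20, 0.10, 0.05, 0.05),
        }
    )
    cna_segments: Sequence[CNASegmentSpec] = field(
        default_factory=lambda: (
            CNASegmentSpec("2", 205, 245, "gain", 1.5, 0.8),
            CNASegmentSpec("4", 505, 545, "loss", 0.5, 0.8),
        )
    )
    cis_fraction: float = 0.0        # fraction of LP epithelial cells in the CIS subclone
    driver_genes: Sequence[int] = ()  # segment genes with dosage-coupled expression boost
    driver_boost: float = 1.6
    stepwise_genes: Sequence[StepwiseGeneSpec] = ()
    lr_truth: Sequence[LRPairSpec] = ()
    n_marker_genes: int = 24   # laid out as blocks of 8 consecutive genes
    marker_strength: float = 6.0
    # Base counts are calibrated so per-gene log2 noise stays well below the
    # copy-ratio signal after segment averaging (high depth, low dispersion).
    base_mean_log_mu: float = 4.0
    base_mean_log_sigma: float = 0.4
    nb_size: float = 100.0           # NB shape; var = mu + mu^2 / nb_size
    rng_seed: int = 0

    def __post_init__(self):
        for tissue, mix in self.cell_type_mixture.items():
            if len(mix) != len(CELL_TYPES):
                raise SpecError(f"mixture for {tissue} must have {len(CELL_TYPES)} entries")
            if any(p < 0 for p in mix):
                raise SpecError(f"negative mixture proportion for {tissue}")
            if abs(sum(mix) - 1.0) > 1e-8:
                raise SpecError(f"mixture for {tissue} must sum to 1")
        for tissue in self.n_patients:
            if tissue not in TISSUE_TYPES:
                raise SpecError(f"unknown tissue type {tissue!r}")
        if self.n_genes % self.genes_per_chrom:
            raise SpecError("n_genes must be a multiple of genes_per_chrom")
        for seg in self.cna_segments:
            if seg.gene_end > self.n_genes:
                raise SpecError("CNA segment exceeds gene count")
        if not 0 <= self.cis_fraction <= 1:
            raise SpecError("cis_fraction must lie in [0, 1]")
        if self.nb_size <= 0:
            raise SpecError("nb_size must be > 0")


@dataclass
class GroundTruth:
    """Everything the generator planted, keyed to the emitted matrix."""

    cells: pd.DataFrame            # cell_id-indexed: sample, tissue, type, is_malignant, is_cis
    copy_state: np.ndarray         # int8 genes x cells: +1 gain, -1 loss, 0 neutral
    segments: Sequence[CNASegmentSpec]
    stepwise_genes: Sequence[StepwiseGeneSpec]
    lr_truth: Sequence[LRPairSpec]
    marker_genes: Mapping[str, Sequence[int]]
    go_background: Mapping[str, set]  # term -> gene ids; marker clusters are annotated
    base_means: np.ndarray
    type_multipliers: np.ndarray   # genes x cell types

    def aberrant_gene_mask(self, tissue_types=("CA", "LN")) -> dict:
        """Per direction, the global gene index set inside planted segments
        active in the given tissue types."""
        out = {"gain": set(), "loss": set()}
        for seg in self.segments:
            if set(seg.tissue_types) & set(tissue_types):
                out[seg.direction].update(range(seg.gene_start, seg.gene_end))
        return out


def _gene_meta(spec: CohortSpec) -> pd.DataFrame:
    n_chrom = spec.n_genes // spec.genes_per_chrom
    rows = []
    for g in range(spec.n_genes):
        chrom = str(g // spec.genes_per_chrom + 1)
        pos_on_chrom = g % spec.genes_per_chrom
        start = 1 + pos_on_chrom * spec.gene_spacing_bp
        rows.append(
            {
                "gene_id": f"G{g:04d}",
                "chrom": chrom,
                "start_bp": start,
                "end_bp": start + 999,
                "biotype": "protein_coding",
                "go_terms": frozenset(),
            }
        )
    assert n_chrom >= 1
    return pd.DataFrame(rows).set_index("gene_id")


def generate_cohort(spec: CohortSpec) -> tuple[CellMatrix, GroundTruth]:
    """Draw a full cohort. Deterministic under ``spec.rng_seed``."""
    rng = np.random.default_rng(spec.rng_seed)
    gene_meta = _gene_meta(spec)
    gene_ids = list(gene_meta.index)
    n_genes = spec.n_genes

    base_means = rng.lognormal(spec.base_mean_log_mu, spec.base_mean_log_sigma, n_genes)

    # Cell-type multipliers: each type gets exclusive marker genes laid out
    # as contiguous genomic blocks, each block sharing one GO term. Blocks
    # are what the co-functional 1 Mb cluster filter is designed to remove,
    # so type identity cannot masquerade as dosage on the CNA track.
    type_mult = np.ones((n_genes, len(CELL_TYPES)))
    reserved = set()
    for seg in spec.cna_segments:
        reserved.update(range(seg.gene_start, seg.gene_end))
    for sw in spec.stepwise_genes:
        reserved.add(sw.gene_index)
    for pair in spec.lr_truth:
        reserved.add(pair.ligand_index)
        reserved.add(pair.receptor_index)

    block_width = 8
    n_blocks = max(1, spec.n_marker_genes // block_width)
    n_chrom = n_genes // spec.genes_per_chrom
    preferred = [c for c in (0, 2, 5) if c < n_chrom]
    marker_chroms = (preferred * n_blocks)[:n_blocks] if preferred else [0] * n_blocks
    offset_step = max(block_width, spec.genes_per_chrom // len(CELL_TYPES))
    marker_genes: dict[str, list[int]] = {}
    go_background: dict[str, set] = {}
    go_terms_by_gene: dict[int, set] = {}
    for t_idx, ct in enumerate(CELL_TYPES):
        genes: list[int] = []
        for k in range(n_blocks):
            row = k // max(len(preferred), 1)
            start = (
                marker_chroms[k] * spec.genes_per_chrom
                + t_idx * offset_step
                + row * block_width
            )
            block = list(range(start, start + block_width))
            if block[-1] >= n_genes:
                raise SpecError("marker block exceeds gene count; enlarge genes_per_chrom")
            if reserved & set(block):
                raise SpecError(
                    f"marker block {block[0]}..{block[-1]} collides with planted genes"
                )
            term = f"GO:MK{t_idx}{k}"
            go_background[term] = {gene_ids[g] for g in block}
            for g in block:
                go_terms_by_gene.setdefault(g, set()).add(term)
            genes.extend(block)
        marker_genes[ct] = genes
        type_mult[genes, t_idx] = spec.marker_strength
    gene_meta = gene_meta.copy()
    gene_meta["go_terms"] = [
        frozenset(go_terms_by_gene.get(g, ())) for g in range(n_genes)
    ]

    # Receptor genes are target-population programs; planted ligands are
    # source programs whose tissue trajectory is applied below per cell.
    # LR genes get a fixed base mean so detection fractions are controlled.
    epi_idx = CELL_TYPES.index("epithelial")
    for pair in spec.lr_truth:
        base_means[pair.ligand_index] = 4.0
        base_means[pair.receptor_index] = 4.0
        if pair.receptor_expressed:
            type_mult[pair.receptor_index, CELL_TYPES.index(pair.target_type)] = 8.0
        else:
            type_mult[pair.receptor_index, :] = 0.01
        if pair.ligand_target_silent:
            type_mult[pair.ligand_index, :] = 0.002
            type_mult[pair.ligand_index, CELL_TYPES.index(pair.source_type)] = 1.0

    stepwise_by_type: dict[str, list[StepwiseGeneSpec]] = {}
    for sw in spec.stepwise_genes:
        stepwise_by_type.setdefault(sw.cell_type, []).append(sw)

    cell_rows = []
    columns = []
    copy_cols = []
    type_order = {ct: i for i, ct in enumerate(CELL_TYPES)}

    tissue_sequence = [t for t in TISSUE_TYPES if spec.n_patients.get(t, 0) > 0]
    for tissue in tissue_sequence:
        mix = np.asarray(spec.cell_type_mixture[tissue], dtype=float)
        for p in range(spec.n_patients[tissue]):
            sample = f"{tissue}{p + 1:02d}"
            n_cells = spec.cells_per_sample
            types = rng.choice(len(CELL_TYPES), size=n_cells, p=mix)
            # CIS subclone: a deterministic-fraction subset of LP epithelial cells
            epi_cells = np.flatnonzero(types == epi_idx)
            cis_cells = set()
            if tissue == "LP" and spec.cis_fraction > 0 and len(epi_cells):
                n_cis = int(round(spec.cis_fraction * len(epi_cells)))
                cis_cells = set(rng.choice(epi_cells, size=n_cis, replace=False))
            for i in range(n_cells):
                ct = CELL_TYPES[types[i]]
                cell_id = f"{sample}_c{i:03d}"
                is_cis = i in cis_cells
                is_malignant = ct == "epithelial" and tissue in ("CA", "LN")
                mu = base_means * type_mult[:, types[i]]
                copy = np.zeros(n_genes, dtype=np.int8)
                if is_malignant or is_cis:
                    for seg in spec.cna_segments:
                        active = tissue in seg.tissue_types or is_cis
                        if not active:
                            continue
                        carries = is_cis or (rng.random() < seg.carrier_fraction)
                        if carries:
                            sl = slice(seg.gene_start, seg.gene_end)
                            mu[sl] = mu[sl] * seg.copy_ratio
                            copy[sl] = 1 if seg.direction == "gain" else -1
                            for d in spec.driver_genes:
                                if seg.gene_start <= d < seg.gene_end:
                                    mu[d] *= spec.driver_boost
                for sw in stepwise_by_type.get(ct, ()):
                    mult = sw.tissue_multipliers.get(tissue)
                    if mult is not None:
                        mu[sw.gene_index] *= mult
                p_nb = spec.nb_size / (spec.nb_size + mu)
                counts = rng.negative_binomial(spec.nb_size, p_nb)
                columns.append(counts)
                copy_cols.append(copy)
                cell_rows.append(
                    {
                        "cell_id": cell_id,
                        "patient_id": sample,
                        "tissue_type": tissue,
                        "hpv_status": "neg",
                        "cell_type": ct,
                        "cluster_label": ct,
                        "is_malignant": is_malignant,
                        "is_cis": is_cis,
                    }
                )

    values = np.stack(columns, axis=1).astype(float)
    copy_state = np.stack(copy_cols, axis=1)
    cells = pd.DataFrame(cell_rows).set_index("cell_id")
    cell_meta = cells[["patient_id", "tissue_type", "hpv_status", "cell_type", "cluster_label"]]
    matrix = CellMatrix(
        values=values,
        gene_ids=gene_ids,
        cell_ids=list(cells.index),
        gene_meta=gene_meta,
        cell_meta=cell_meta.copy(),
        scale="counts",
    )
    truth = GroundTruth(
        cells=cells,
        copy_state=copy_state,
        segments=tuple(spec.cna_segments),
        stepwise_genes=tuple(spec.stepwise_genes),
        lr_truth=tuple(spec.lr_truth),
        marker_genes=marker_genes,
        go_background=go_background,
        base_means=base_means,
        type_multipliers=type_mult,
    )
    return matrix, truth


# ---------------------------------------------------------------------- #
# Cohort-spec presets used by tests and the acceptance report
# ---------------------------------------------------------------------- #


def default_cna_spec(seed: int = 0, cis_fraction: float = 0.0,
                     cells_per_sample: int = 80) -> CohortSpec:
    """Preset with two planted clonal segments (1.5x gain, 0.5x loss)."""
    return CohortSpec(
        rng_seed=seed,
        cis_fraction=cis_fraction,
        cells_per_sample=cells_per_sample,
    )


def stepwise_lr_spec(n_interdependent: int = 5, n_decoy: int = 45,
                     seed: int = 0) -> CohortSpec:
    """Preset planting interdependent ligand/receptor pairs among decoys.

    Decoys alternate between autocrine pairs (ligand also expressed by the
    target), flat pairs (no stepwise trend), and absent-receptor pairs.
    """
    step_mult = {"NL": 0.05, "LP": 0.5, "CA": 2.0, "LN": 2.0}
    flat_mult = {"NL": 3.0, "LP": 3.0, "CA": 3.0, "LN": 3.0}
    low_mult = {"NL": 0.02, "LP": 0.02, "CA": 0.02, "LN": 0.02}
    target_on = {"NL": 2.0, "LP": 2.0, "CA": 2.0, "LN": 2.0}
    lr_truth: list[LRPairSpec] = []
    stepwise: list[StepwiseGeneSpec] = []
    gene = 200  # chromosome free of marker blocks; no CNA segments in this preset
    for k in range(n_interdependent + n_decoy):
        ligand, receptor = gene, gene + 1
        gene += 2
        if k < n_interdependent:
            lr_truth.append(LRPairSpec(ligand, receptor, interdependent=True))
            stepwise.append(StepwiseGeneSpec(ligand, "fibroblast", step_mult))
        else:
            kind = k % 3
            if kind == 0:
                # autocrine: stepwise ligand in source but target expresses it too
                lr_truth.append(
                    LRPairSpec(ligand, receptor, interdependent=False,
                               ligand_target_silent=False)
                )
                stepwise.append(StepwiseGeneSpec(ligand, "fibroblast", step_mult))
                stepwise.append(StepwiseGeneSpec(ligand, "epithelial", target_on))
            elif kind == 1:
                # flat ligand in source: well expressed but no stepwise trend
                lr_truth.append(LRPairSpec(ligand, receptor, interdependent=False))
                stepwise.append(StepwiseGeneSpec(ligand, "fibroblast", flat_mult))
            else:
                # ligand near-silent even in the source: fails expr_min
                lr_truth.append(LRPairSpec(ligand, receptor, interdependent=False))
                stepwise.append(StepwiseGeneSpec(ligand, "fibroblast", low_mult))
    return CohortSpec(
        rng_seed=seed,
        n_patients={"NL": 4, "LP": 4, "CA": 6, "LN": 2},
        cells_per_sample=60,
        cna_segments=(),
        stepwise_genes=tuple(stepwise),
        lr_truth=tuple(lr_truth),
    )


def generate_bulk(true_proportions: pd.DataFrame, cluster_means: pd.DataFrame,
                  noise_sd: float = 0.0, rng_seed: int = 0):
    """Mix cluster mean profiles into bulk samples.

    ``bulk[:, s] = sum_k proportions[s, k] * cluster_means[:, k]``, then
    multiplicative log2-normal noise of scale ``noise_sd`` (none when 0),
    floored at 0. Returns ``(bulk genes x samples, proportions)``.
    """
    props = pd.DataFrame(true_proportions)
    means = pd.DataFrame(cluster_means)
    if (props.to_numpy() < 0).any():
        raise SpecError("proportions must be non-negative")
    sums = props.sum(axis=1)
    if not np.allclose(sums, 1.0, atol=1e-8):
        raise SpecError("proportions must sum to 1 per sample")
    if list(props.columns) != list(means.columns):
        means = means[list(props.columns)]
    mix = means.to_numpy() @ props.to_numpy().T
    if noise_sd > 0:
        rng = np.random.default_rng(rng_seed)
        mix = mix * np.exp2(rng.normal(0.0, noise_sd, size=mix.shape))
    mix = np.maximum(mix, 0.0)
    bulk = pd.DataFrame(mix, index=means.index, columns=props.index)
    return bulk, props


def percentile_hazard_link(rho: float, percentile: float = 70.0) -> Callable:
    """Relative hazard ``rho`` for samples strictly above the percentile cutoff."""

    def link(proportions: np.ndarray) -> np.ndarray:
        cut = np.percentile(proportions, percentile)
        return np.where(proportions > cut, rho, 1.0)

    return link


def generate_survival(proportions: pd.Series, hazard_link: Callable,
                      baseline_rate: float, censor_rate: float,
                      rng_seed: int = 0, endpoint: str = "OS") -> list[SurvivalRecord]:
    """Exponential event times with proportion-linked hazards.

    Event time ~ Exp(baseline_rate * hazard_link(p)); independent exponential
    censoring at ``censor_rate`` (0 disables censoring).
    """
    if baseline_rate <= 0:
        raise SpecError("baseline_rate must be > 0")
    if censor_rate < 0:
        raise SpecError("censor_rate must be >= 0")
    props = pd.Series(proportions)
    if (props < 0).any():
        raise SpecError("proportions must be non-negative")
    rng = np.random.default_rng(rng_seed)
    rel = np.asarray(hazard_link(props.to_numpy()), dtype=float)
    rates = baseline_rate * rel
    event_times = rng.exponential(1.0 / rates)
    if censor_rate > 0:
        censor_times = rng.exponential(1.0 / censor_rate, size=len(props))
    else:
        censor_times = np.full(len(props), np.inf)
    records = []
    for sid, t_event, t_cens in zip(props.index, event_times, censor_times):
        observed = t_event <= t_cens
        records.append(
            SurvivalRecord(str(sid), float(min(t_event, t_cens)), int(observed), endpoint)
        )
    return records
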