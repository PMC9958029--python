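"""Pipeline configuration: one dataclass holding every tunable threshold.

All stages take an explicit :class:`PipelineConfig`; the YAML config files
consumed by the CLI mirror the field names one-to-one.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, fields
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    # CNA inference
    cna_fold_cutoff: float = 0.1          # |segment mean log2 ratio| must exceed this
    recurrence_freq: float = 0.05         # within-sample carrier frequency cutoff
    recurrence_min_samples: int = 2       # samples that must pass the frequency cutoff
    cluster_window_bp: int = 1_000_000    # window for co-functional gene-cluster exclusion
    go_p_cutoff: float = 0.05             # hypergeometric enrichment cutoff
    go_min_term_genes: int = 3            # minimum window genes sharing a term
    smoothing_window: int = 101           # centered moving-average width (genes)
    clip_log_ratio: float = 3.0           # clip raw per-gene log ratios to +/- this
    center_cells: str = "median"          # per-cell track re-centering: "median" or "none"
    min_reference_cells: int = 20
    cbs_alpha: float = 0.01               # split acceptance level for segmentation
    cbs_n_perm: int = 1000                # permutations per candidate split
    cbs_min_width: int = 5                # minimum segment width in genes
    cna_call_on: str = "segment_mean"     # "segment_mean" or "per_gene"
    # differential programs
    marker_p: float = 0.001
    marker_fold: float = 1.0              # log2 units
    perm_p: float = 0.001
    step_fold: float = 0.25               # per-step log2 margin for stepwise genes
    fold_scale: str = "log2"              # "log2" or "linear"
    n_permutations: int = 10_000
    # CIS / immune reassignment
    burden_undetermined: int = 200        # strict > on aberrant-gene count
    cis_r_min: float = 0.3
    cis_burden_min: int = 50
    # ligand-receptor interdependence
    lr_expr_min: float = 0.25
    lr_absent_max: float = 0.05
    lr_step_min_increase: float = 0.1
    lr_min_patients: int = 5
    # deconvolution / survival
    top_k_markers: int = 50
    signature_min_cells: int = 20
    ntp_n_perm: int = 1000
    ntp_fdr_max: float = 0.05
    high_group_percentile: float = 70.0
    survival_horizon: float = 60.0        # follow-up truncation (time units of the data)
    # reproducibility
    rng_seed: int = 0

    def __post_init__(self):
        positive = (
            "cna_fold_cutoff", "recurrence_freq", "cluster_window_bp",
            "go_p_cutoff", "marker_p", "marker_fold", "perm_p", "step_fold",
            "burden_undetermined", "cis_r_min", "cis_burden_min",
            "lr_expr_min", "lr_absent_max", "cbs_alpha", "survival_horizon",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0 < self.high_group_percentile < 100:
            raise ValueError("high_group_percentile must lie in (0, 100)")
        if self.n_permutations < 100:
            raise ValueError("n_permutations must be >= 100")
        if self.smoothing_window < 1 or self.smoothing_window % 2 == 0:
            raise ValueError("smoothing_window must be a positive odd integer")
        if self.center_cells not in ("median", "none"):
            raise ValueError("center_cells must be 'median' or 'none'")
        if self.cna_call_on not in ("segment_mean", "per_gene"):
            raise ValueError("cna_call_on must be 'segment_mean' or 'per_gene'")
        if self.fold_scale not in ("log2", "linear"):
            raise ValueError("fold_scale must be 'log2' or 'linear'")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
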