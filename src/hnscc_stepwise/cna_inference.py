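"""Copy-number inference from expression.

Per-cell relative log2 tracks against an immune reference, chromosome-wise
smoothing, change-point detection by circular binary segmentation with a
permutation split test, gain/loss calls against a fold cutoff, aberrant-gene
burden, and recurrent-region calling across samples within a tissue type.

Gene-set hygiene precedes everything: sex-chromosome genes, immunoglobulin /
T-cell-receptor biotypes, and 1 Mb windows of co-functional genes (GO term
enriched by one-sided hypergeometric test) are excluded, because clustered
co-regulated genes mimic dosage effects.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .config import PipelineConfig
from .core_io import CellMatrix, DegenerateInputError, normalize_chrom

logger = logging.getLogger("hnscc_stepwise")

IMMUNE_BIOTYPE_PREFIXES = ("IG_", "TR_")


class InsufficientReferenceError(ValueError):
    """Fewer reference cells than the configured minimum."""


# ---------------------------------------------------------------------- #
# Gene-set filtering
# ---------------------------------------------------------------------- #


def filter_gene_set(gene_meta: pd.DataFrame, go_background: Mapping[str, set],
                    config: PipelineConfig | None = None) -> np.ndarray:
    """Indices (into ``gene_meta`` row order) of genes retained for CNA work.

    Removes, in order: (a) genes on X/Y, (b) IG_*/TR_* biotypes, (c) every
    gene annotated to a GO term that is enriched (one-sided hypergeometric,
    ``P < go_p_cutoff``) in some 1 Mb window anchored at a gene midpoint,
    provided at least ``go_min_term_genes`` window genes carry the term.
    The hypergeometric background is the annotated-gene universe of
    ``go_background``.
    """
    config = config or PipelineConfig()
    chroms = np.array([normalize_chrom(c) for c in gene_meta["chrom"]])
    mids = (
        gene_meta["start_bp"].to_numpy(np.int64) + gene_meta["end_bp"].to_numpy(np.int64)
    ) // 2
    keep = ~np.isin(chroms, ("X", "Y"))
    biotypes = gene_meta["biotype"].astype(str).to_numpy()
    keep &= ~np.array([b.startswith(IMMUNE_BIOTYPE_PREFIXES) for b in biotypes])

    go_terms = [
        t if isinstance(t, (set, frozenset)) else frozenset()
        for t in gene_meta.get("go_terms", pd.Series([frozenset()] * len(gene_meta)))
    ]
    universe = set()
    for genes in go_background.values():
        universe.update(genes)
    M = len(universe)
    term_sizes = {term: len(genes) for term, genes in go_background.items()}

    excluded_go = np.zeros(len(gene_meta), dtype=bool)
    if M > 0:
        order = np.lexsort((mids, chroms))
        for chrom in np.unique(chroms):
            idx = order[chroms[order] == chrom]
            cmids = mids[idx]
            for a, anchor in enumerate(idx):
                lo = cmids[a]
                hi = lo + config.cluster_window_bp
                in_win = idx[(cmids >= lo) & (cmids < hi)]
                if len(in_win) < config.go_min_term_genes:
                    continue
                n_draw = sum(
                    1 for g in in_win if str(gene_meta.index[g]) in universe
                )
                if n_draw < config.go_min_term_genes:
                    continue
                counts: dict[str, list[int]] = {}
                for g in in_win:
                    for term in go_terms[g]:
                        if term in term_sizes:
                            counts.setdefault(term, []).append(g)
                for term, members in counts.items():
                    k = len(members)
                    if k < config.go_min_term_genes:
                        continue
                    p = hypergeom.sf(k - 1, M, term_sizes[term], n_draw)
                    if p < config.go_p_cutoff:
                        excluded_go[members] = True
    keep &= ~excluded_go
    retained = np.flatnonzero(keep)
    if retained.size == 0:
        raise DegenerateInputError("no genes retained after CNA gene-set filtering")
    n_dropped = len(gene_meta) - retained.size
    if n_dropped:
        logger.info("gene-set filter removed %d of %d genes", n_dropped, len(gene_meta))
    return retained


# ---------------------------------------------------------------------- #
# Relative tracks
# ---------------------------------------------------------------------- #


def moving_average(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average truncated at the ends (window = odd width)."""
    n = len(x)
    half = window // 2
    cs = np.concatenate(([0.0], np.cumsum(x)))
    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + half + 1, n)
    return (cs[hi] - cs[lo]) / (hi - lo)


def relative_track(matrix: CellMatrix, reference_cells,
                   config: PipelineConfig | None = None,
                   cells=None) -> np.ndarray:
    """Smoothed per-cell log2 ratio tracks against the reference mean.

    ``matrix`` must be log-normalized and gene-sorted. Per gene the reference
    mean (over ``reference_cells``, at least ``min_reference_cells``) is
    subtracted, ratios are clipped to +/- ``clip_log_ratio``, then smoothed
    within each chromosome by a centered moving average of
    ``smoothing_window`` genes (truncated at chromosome ends).

    Returns a genes x cells array for ``cells`` (default: all cells).
    """
    config = config or PipelineConfig()
    if matrix.scale != "lognorm":
        raise ValueError("relative_track requires a log-normalized matrix")
    reference_cells = np.asarray(reference_cells)
    if reference_cells.size < config.min_reference_cells:
        raise InsufficientReferenceError(
            f"need >= {config.min_reference_cells} reference cells, "
            f"got {reference_cells.size}"
        )
    ref_mean = matrix.values[:, reference_cells].mean(axis=1)
    cols = np.arange(matrix.n_cells) if cells is None else np.asarray(cells)
    raw = matrix.values[:, cols] - ref_mean[:, None]
    np.clip(raw, -config.clip_log_ratio, config.clip_log_ratio, out=raw)
    if config.center_cells == "median":
        # library-composition shifts move a cell's whole track; re-center on
        # the per-cell median so neutral genes sit at zero
        raw -= np.median(raw, axis=0, keepdims=True)
    smoothed = np.empty_like(raw)
    for _, sl in chromosome_blocks(matrix.gene_meta):
        for j in range(raw.shape[1]):
            smoothed[sl, j] = moving_average(raw[sl, j], config.smoothing_window)
    return smoothed


def chromosome_blocks(gene_meta: pd.DataFrame) -> list:
    """Contiguous (chrom, slice) runs of the gene-sorted metadata."""
    chroms = [normalize_chrom(c) for c in gene_meta["chrom"]]
    blocks = []
    start = 0
    for i in range(1, len(chroms) + 1):
        if i == len(chroms) or chroms[i] != chroms[start]:
            blocks.append((chroms[start], slice(start, i)))
            start = i
    return blocks


# ---------------------------------------------------------------------- #
# Circular binary segmentation
# ---------------------------------------------------------------------- #


def _arc_indices(n: int):
    """All arc boundaries (i, j), 0 <= i < j <= n, excluding the full span."""
    i, j = np.triu_indices(n + 1, k=1)
    mask = ~((i == 0) & (j == n))
    return i[mask], j[mask]


def _max_arc_stat(x: np.ndarray, i: np.ndarray, j: np.ndarray, sd: float):
    """Max |standardized mean difference| between arc x[i:j] and its complement.

    Ties are broken toward the lexicographically smallest (i, j); the index
    arrays are in that order already, so the first argmax wins.
    """
    n = len(x)
    cs = np.concatenate(([0.0], np.cumsum(x)))
    total = cs[n]
    k = j - i
    seg = (cs[j] - cs[i]) / k
    rest = (total - cs[j] + cs[i]) / (n - k)
    t = np.abs(seg - rest) / (sd * np.sqrt(1.0 / k + 1.0 / (n - k)))
    best = int(np.argmax(t))
    return float(t[best]), int(i[best]), int(j[best])


def _arc_factors(n: int, i_idx: np.ndarray, j_idx: np.ndarray, sd: float):
    """Precompute per-arc constants: seg-rest = a*(S_j - S_i) - b*T, and the
    standardization factor 1/(sd*sqrt(1/k + 1/(n-k)))."""
    k = (j_idx - i_idx).astype(float)
    inv_rest = 1.0 / (n - k)
    a = 1.0 / k + inv_rest
    inv_denom = 1.0 / (sd * np.sqrt(a))
    return a * inv_denom, inv_rest * inv_denom


def _max_arc_stat_rows(P: np.ndarray, i_idx: np.ndarray, j_idx: np.ndarray,
                       fa: np.ndarray, fb: np.ndarray) -> np.ndarray:
    """Row-wise maximum arc statistic for a batch of (permuted) tracks.

    ``fa``/``fb`` come from :func:`_arc_factors`; the statistic per arc is
    ``|fa*(S_j - S_i) - fb*T|`` which equals the standardized mean difference.
    """
    m, n = P.shape
    cs = np.concatenate([np.zeros((m, 1)), np.cumsum(P, axis=1)], axis=1)
    t = cs[:, j_idx]
    t -= cs[:, i_idx]
    t *= fa[None, :]
    t -= cs[:, n][:, None] * fb[None, :]
    np.abs(t, out=t)
    return t.max(axis=1)


def _split_significant(x: np.ndarray, t_obs: float, i_idx, j_idx, sd: float,
                       alpha: float, n_perm: int, rng: np.random.Generator) -> bool:
    """Permutation test of the best-arc statistic; early exit once the
    exceedance count guarantees p >= alpha."""
    reject_at = alpha * (1 + n_perm)  # split refused once (1 + count) >= this
    fa, fb = _arc_factors(len(x), i_idx, j_idx, sd)
    count = 0
    done = 0
    chunk = 25  # small first chunks reject null splits cheaply, then widen
    while done < n_perm:
        m = min(chunk, n_perm - done)
        P = rng.permuted(np.tile(x, (m, 1)), axis=1)
        t_perm = _max_arc_stat_rows(P, i_idx, j_idx, fa, fb)
        count += int(np.sum(t_perm >= t_obs))
        done += m
        if 1 + count >= reject_at:
            return False
        chunk = min(chunk * 4, 400)
    return (1 + count) / (1 + n_perm) < alpha


@dataclass
class Segment:
    chrom: str
    start: int              # gene index into the track order, inclusive
    end: int                # exclusive
    mean_log_ratio: float
    call: str = "neutral"   # gain / loss / neutral

    @property
    def n_genes(self) -> int:
        return self.end - self.start


def segment_track(values: np.ndarray, alpha: float = 0.01, n_perm: int = 1000,
                  min_width: int = 5, rng: np.random.Generator | None = None,
                  chrom: str = "NA") -> list[Segment]:
    """Segment one chromosome's ordered smoothed values.

    Recursive circular binary segmentation: find the arc maximizing the
    standardized mean-difference statistic, accept the split when its
    permutation p-value is below ``alpha``, recurse into the pieces, then
    merge segments shorter than ``min_width`` into the neighbor with the
    closer mean.
    """
    rng = rng or np.random.default_rng()
    x = np.asarray(values, dtype=float)
    n = len(x)
    if n == 0:
        return []
    if n < 2 * min_width:
        warnings.warn(
            f"track of {n} genes is shorter than 2*min_width; returning one segment"
        )
        return [Segment(chrom, 0, n, float(x.mean()))]

    boundaries = {0, n}

    def recurse(lo: int, hi: int):
        m = hi - lo
        if m < 2 * min_width:
            return
        seg = x[lo:hi]
        sd = seg.std(ddof=1)
        if sd == 0 or not np.isfinite(sd):
            return
        i_idx, j_idx = _arc_indices(m)
        t_obs, bi, bj = _max_arc_stat(seg, i_idx, j_idx, sd)
        if not _split_significant(seg, t_obs, i_idx, j_idx, sd, alpha, n_perm, rng):
            return
        cuts = sorted({lo + bi, lo + bj} - {lo, hi})
        if not cuts:
            return
        boundaries.update(cuts)
        pieces = [lo] + cuts + [hi]
        for a, b in zip(pieces[:-1], pieces[1:]):
            recurse(a, b)

    recurse(0, n)
    bounds = sorted(boundaries)
    segments = [
        Segment(chrom, a, b, float(x[a:b].mean()))
        for a, b in zip(bounds[:-1], bounds[1:])
    ]
    return _merge_short(segments, x, min_width, chrom)


def _merge_short(segments: list[Segment], x: np.ndarray, min_width: int,
                 chrom: str) -> list[Segment]:
    """Merge segments shorter than ``min_width`` into the neighbor whose mean
    is closest; single segments are exempt."""
    segs = list(segments)
    while len(segs) > 1:
        short = [s for s in segs if s.n_genes < min_width]
        if not short:
            break
        s = min(short, key=lambda s: (s.n_genes, s.start))
        k = segs.index(s)
        neighbors = []
        if k > 0:
            neighbors.append(k - 1)
        if k < len(segs) - 1:
            neighbors.append(k + 1)
        j = min(neighbors, key=lambda j: abs(segs[j].mean_log_ratio - s.mean_log_ratio))
        a, b = (segs[j], s) if j < k else (s, segs[j])
        merged = Segment(chrom, a.start, b.end, float(x[a.start:b.end].mean()))
        segs[min(j, k)] = merged
        del segs[max(j, k)]
    return segs


# ---------------------------------------------------------------------- #
# Calls, profiles, burden
# ---------------------------------------------------------------------- #


@dataclass
class CNAProfile:
    """Per-cell smoothed track plus gain/loss/neutral segment calls."""

    cell_id: str
    log_ratio: np.ndarray
    segments: list[Segment] = field(default_factory=list)

    def gene_calls(self) -> np.ndarray:
        """Per-gene call vector: +1 gain, -1 loss, 0 neutral."""
        calls = np.zeros(len(self.log_ratio), dtype=np.int8)
        for seg in self.segments:
            if seg.call == "gain":
                calls[seg.start:seg.end] = 1
            elif seg.call == "loss":
                calls[seg.start:seg.end] = -1
        return calls


def call_cna(segments: Sequence[Segment], cna_fold_cutoff: float = 0.1,
             log_ratio: np.ndarray | None = None,
             mode: str = "segment_mean") -> list[Segment]:
    """Assign gain/loss/neutral to segments: strict ``|mean| > cutoff``.

    ``mode="per_gene"`` instead requires the median of per-gene smoothed
    values inside the segment to clear the cutoff (documented toggle).
    """
    out = []
    for seg in segments:
        if mode == "per_gene":
            if log_ratio is None:
                raise ValueError("per_gene mode requires the smoothed track")
            stat = float(np.median(log_ratio[seg.start:seg.end]))
        else:
            stat = seg.mean_log_ratio
        call = "gain" if stat > cna_fold_cutoff else "loss" if stat < -cna_fold_cutoff else "neutral"
        out.append(Segment(seg.chrom, seg.start, seg.end, seg.mean_log_ratio, call))
    return out


def cna_burden(profile: CNAProfile) -> int:
    """Number of genes lying in non-neutral segments."""
    return int(sum(seg.n_genes for seg in profile.segments if seg.call != "neutral"))


def infer_cna_profiles(matrix: CellMatrix, reference_cells, cells=None,
                       config: PipelineConfig | None = None,
                       rng: np.random.Generator | None = None):
    """End-to-end per-cell profiles: tracks, segmentation, calls.

    Returns ``(tracks genes x cells array, list of CNAProfile)`` for
    ``cells`` (default all), in matrix gene order.
    """
    config = config or PipelineConfig()
    rng = rng or np.random.default_rng(config.rng_seed)
    cols = np.arange(matrix.n_cells) if cells is None else np.asarray(cells)
    tracks = relative_track(matrix, reference_cells, config, cells=cols)
    blocks = chromosome_blocks(matrix.gene_meta)
    profiles = []
    for j, c in enumerate(cols):
        track = tracks[:, j]
        segments: list[Segment] = []
        for chrom, sl in blocks:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                segs = segment_track(
                    track[sl],
                    alpha=config.cbs_alpha,
                    n_perm=config.cbs_n_perm,
                    min_width=config.cbs_min_width,
                    rng=rng,
                    chrom=chrom,
                )
            for s in segs:
                segments.append(Segment(chrom, s.start + sl.start, s.end + sl.start,
                                        s.mean_log_ratio))
        segments = call_cna(segments, config.cna_fold_cutoff, track, config.cna_call_on)
        profiles.append(CNAProfile(str(matrix.cell_ids[c]), track, segments))
    return tracks, profiles


# ---------------------------------------------------------------------- #
# Recurrence across samples
# ---------------------------------------------------------------------- #


@dataclass
class RecurrentRegion:
    """A maximal run of genes recurrently gained/lost within one tissue type."""

    tissue_type: str
    chrom: str
    start: int                       # gene index, inclusive
    end: int                         # exclusive
    start_bp: int
    end_bp: int
    direction: str
    sample_frequencies: dict         # sample -> mean carrier frequency over the run
    n_samples_passing: int


def carrier_frequencies(profiles_by_sample: Mapping[str, Sequence[CNAProfile]],
                        n_genes: int):
    """Per-sample fraction of cells calling each gene gained / lost.

    Returns two DataFrames (gain, loss) of shape genes x samples.
    """
    gain = {}
    loss = {}
    for sample, profiles in profiles_by_sample.items():
        if not profiles:
            continue
        calls = np.stack([p.gene_calls() for p in profiles], axis=1)
        gain[sample] = (calls == 1).mean(axis=1)
        loss[sample] = (calls == -1).mean(axis=1)
    return (
        pd.DataFrame(gain, index=range(n_genes)),
        pd.DataFrame(loss, index=range(n_genes)),
    )


def recurrent_cna(profiles_by_sample: Mapping[str, Sequence[CNAProfile]],
                  tissue_type: str, gene_meta: pd.DataFrame,
                  config: PipelineConfig | None = None) -> list[RecurrentRegion]:
    """Recurrent regions for one tissue type.

    A gene/direction is recurrent when its within-sample carrier frequency
    reaches ``recurrence_freq`` in at least ``recurrence_min_samples``
    samples; maximal same-chromosome, same-direction runs of recurrent genes
    are merged into regions.
    """
    config = config or PipelineConfig()
    samples = [s for s, p in profiles_by_sample.items() if p]
    if len(samples) < config.recurrence_min_samples:
        raise DegenerateInputError(
            f"recurrent_cna for {tissue_type} requires >= "
            f"{config.recurrence_min_samples} samples with cells, got {len(samples)}"
        )
    n_genes = len(gene_meta)
    gain, loss = carrier_frequencies(profiles_by_sample, n_genes)
    chroms = np.array([normalize_chrom(c) for c in gene_meta["chrom"]])
    starts = gene_meta["start_bp"].to_numpy(np.int64)
    ends = gene_meta["end_bp"].to_numpy(np.int64)

    regions: list[RecurrentRegion] = []
    for direction, freqs in (("gain", gain), ("loss", loss)):
        passing = (freqs.to_numpy() >= config.recurrence_freq)
        n_pass = passing.sum(axis=1)
        recurrent = n_pass >= config.recurrence_min_samples
        g = 0
        while g < n_genes:
            if not recurrent[g]:
                g += 1
                continue
            h = g
            while h < n_genes and recurrent[h] and chroms[h] == chroms[g]:
                h += 1
            run = slice(g, h)
            freq_mean = freqs.iloc[run].mean(axis=0)
            regions.append(
                RecurrentRegion(
                    tissue_type=tissue_type,
                    chrom=str(chroms[g]),
                    start=g,
                    end=h,
                    start_bp=int(starts[g]),
                    end_bp=int(ends[h - 1]),
                    direction=direction,
                    sample_frequencies=freq_mean.to_dict(),
                    n_samples_passing=int(n_pass[run].min()),
                )
            )
            g = h
    return regions


def regions_frame(regions: Sequence[RecurrentRegion]) -> pd.DataFrame:
    rows = []
    for r in regions:
        rows.append(
            {
                "tissue_type": r.tissue_type,
                "chrom": r.chrom,
                "gene_index_start": r.start,
                "gene_index_end": r.end,
                "start_bp": r.start_bp,
                "end_bp": r.end_bp,
                "direction": r.direction,
                "n_samples_passing": r.n_samples_passing,
                "max_sample_frequency": max(r.sample_frequencies.values()),
            }
        )
    cols = ["tissue_type", "chrom", "gene_index_start", "gene_index_end",
            "start_bp", "end_bp", "direction", "n_samples_passing",
            "max_sample_frequency"]
    return pd.DataFrame(rows, columns=cols)


# ---------------------------------------------------------------------- #
# Burden contrast
# ---------------------------------------------------------------------- #


@dataclass
class BurdenContrast:
    mean_a: float
    mean_b: float
    diff: float
    perm_p: float


def burden_contrast(profiles_a: Sequence[CNAProfile],
                    profiles_b: Sequence[CNAProfile],
                    n_permutations: int = 10_000,
                    seed: int | None = None) -> BurdenContrast:
    """Group mean burdens with a permutation p-value for the mean difference.

    Degenerate groups (size 1) still run; the permutation null is then wide
    and the p-value close to uninformative, which is the intended contract.
    """
    a = np.array([cna_burden(p) for p in profiles_a], dtype=float)
    b = np.array([cna_burden(p) for p in profiles_b], dtype=float)
    if a.size == 0 or b.size == 0:
        raise DegenerateInputError("both groups need at least one profile")
    obs = abs(a.mean() - b.mean())
    pooled = np.concatenate([a, b])
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(pooled)
        d = abs(perm[: a.size].mean() - perm[a.size:].mean())
        if d >= obs:
            count += 1
    p = (1 + count) / (1 + n_permutations)
    return BurdenContrast(float(a.mean()), float(b.mean()), float(a.mean() - b.mean()), p)
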