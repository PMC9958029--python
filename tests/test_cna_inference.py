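import math
import warnings

import numpy as np
import pandas as pd
import pytest

from hnscc_stepwise.config import PipelineConfig
from hnscc_stepwise.core_io import DegenerateInputError
from hnscc_stepwise import cna_inference as cna
from hnscc_stepwise.cna_inference import (
    CNAProfile, InsufficientReferenceError, Segment, burden_contrast, call_cna,
    cna_burden, filter_gene_set, moving_average, recurrent_cna, relative_track,
    segment_track,
)

from conftest import tiny_matrix


# ---------------------------------------------------------------------- #
# Gene-set filtering
# ---------------------------------------------------------------------- #


def _meta(chroms, positions, biotypes=None, go_terms=None):
    n = len(chroms)
    return pd.DataFrame(
        {
            "chrom": chroms,
            "start_bp": positions,
            "end_bp": [p + 100 for p in positions],
            "biotype": biotypes or ["protein_coding"] * n,
            "go_terms": go_terms or [frozenset()] * n,
        },
        index=[f"G{i:03d}" for i in range(n)],
    )


class TestFilterGeneSet:
    def test_sex_chromosomes_removed(self):
        meta = _meta(["1", "X", "2", "Y"], [100, 100, 100, 100])
        kept = filter_gene_set(meta, {})
        assert list(kept) == [0, 2]

    def test_all_sex_genes_is_degenerate(self):
        meta = _meta(["Y"] * 5, [100 * i for i in range(5)])
        with pytest.raises(DegenerateInputError):
            filter_gene_set(meta, {})

    def test_immune_biotypes_removed(self):
        meta = _meta(
            ["1"] * 4, [100, 200, 300, 400],
            biotypes=["protein_coding", "IG_V_gene", "TR_C_gene", "lncRNA"],
        )
        kept = filter_gene_set(meta, {})
        assert list(kept) == [0, 3]

    def test_enriched_window_excluded_exact_hypergeometric(self):
        """Four clustered genes sharing a term carried by 10 of 1000
        background genes: P(X=4) = C(10,4)*C(990,0)/C(1000,4), far below 0.05,
        so all four are excluded."""
        p_exact = (math.comb(10, 4) * math.comb(990, 0)) / math.comb(1000, 4)
        assert p_exact < 0.05
        positions = [100_000, 300_000, 500_000, 700_000, 5_000_000]
        meta = _meta(
            ["1"] * 5, positions,
            go_terms=[frozenset({"T"})] * 4 + [frozenset()],
        )
        background = {"T": {f"B{i}" for i in range(6)} | {"G000", "G001", "G002", "G003"}}
        # background universe of 1000 annotated genes
        background["ALL"] = {f"B{i}" for i in range(990)} | {"G000", "G001", "G002", "G003",
                                                            "B0", "B1", "B2", "B3", "B4", "B5"}
        background["ALL"] |= {f"U{i}" for i in range(1000 - len(background["ALL"]))}
        kept = filter_gene_set(meta, background)
        assert list(kept) == [4]

    def test_no_shared_terms_keeps_all(self):
        meta = _meta(["1"] * 4, [100_000 * i for i in range(4)],
                     go_terms=[frozenset({f"T{i}"}) for i in range(4)])
        background = {f"T{i}": {f"G{i:03d}"} | {f"B{j}" for j in range(50)}
                      for i in range(4)}
        kept = filter_gene_set(meta, background)
        assert list(kept) == [0, 1, 2, 3]

    def test_window_needs_minimum_term_genes(self):
        # only 2 window genes share the term: below the 3-gene floor
        meta = _meta(["1"] * 2, [100_000, 200_000],
                     go_terms=[frozenset({"T"})] * 2)
        background = {"T": {"G000", "G001"} | {f"B{i}" for i in range(8)}}
        kept = filter_gene_set(meta, background)
        assert list(kept) == [0, 1]


# ---------------------------------------------------------------------- #
# Relative tracks
# ---------------------------------------------------------------------- #


class TestRelativeTrack:
    def _matrix(self, n_genes=30, n_cells=30, seed=0):
        rng = np.random.default_rng(seed)
        values = rng.poisson(20.0, size=(n_genes, n_cells)).astype(float)
        return tiny_matrix(values).log_normalize()

    def _config(self, **kw):
        base = dict(smoothing_window=3, center_cells="none")
        base.update(kw)
        return PipelineConfig(**base)

    def test_reference_mean_cell_gives_zero_track(self):
        m = self._matrix()
        # append a cell equal to the reference mean
        ref = np.arange(25)
        ref_mean = m.values[:, ref].mean(axis=1)
        values = np.concatenate([m.values, ref_mean[:, None]], axis=1)
        m2 = tiny_matrix(np.zeros_like(values), scale="lognorm")
        m2.values = values
        tracks = relative_track(m2, ref, self._config(), cells=[m2.n_cells - 1])
        np.testing.assert_allclose(tracks[:, 0], 0.0, atol=1e-12)

    def test_constant_offset_preserved_by_smoothing(self):
        m = self._matrix()
        ref = np.arange(25)
        ref_mean = m.values[:, ref].mean(axis=1)
        values = np.concatenate([m.values, (ref_mean + 0.2)[:, None]], axis=1)
        m2 = tiny_matrix(np.zeros_like(values), scale="lognorm")
        m2.values = values
        tracks = relative_track(m2, ref, self._config(smoothing_window=5),
                                cells=[m2.n_cells - 1])
        np.testing.assert_allclose(tracks[:, 0], 0.2, atol=1e-12)

    def test_hand_computed_moving_average(self):
        assert list(moving_average(np.array([0, 0, 3, 0, 0.0]), 3)) == [0, 1, 1, 1, 0]

    def test_insufficient_reference(self):
        m = self._matrix()
        with pytest.raises(InsufficientReferenceError):
            relative_track(m, np.arange(5), self._config())

    def test_requires_lognorm(self):
        m = tiny_matrix(np.ones((10, 25)))
        with pytest.raises(ValueError, match="log-normalized"):
            relative_track(m, np.arange(20), self._config())

    def test_clipping(self):
        m = self._matrix()
        m.values[0, 0] = 50.0  # extreme outlier before smoothing
        cfg = self._config(smoothing_window=1, clip_log_ratio=3.0)
        tracks = relative_track(m, np.arange(25), cfg, cells=[0])
        assert tracks[0, 0] <= 3.0

    def test_smoothing_respects_chromosome_boundaries(self):
        values = np.zeros((6, 25))
        values[2, 0] = 30.0  # spike at last gene of chrom 1
        m = tiny_matrix(values, chroms=["1", "1", "1", "2", "2", "2"],
                        scale="lognorm")
        m.values = values
        cfg = self._config(smoothing_window=3)
        tracks = relative_track(m, np.arange(25), cfg, cells=[0])
        # spike bleeds within chrom 1 but not into chrom 2
        assert tracks[3, 0] == pytest.approx(tracks[4, 0])

    def test_median_centering_removes_global_offset(self):
        m = self._matrix()
        ref = np.arange(25)
        ref_mean = m.values[:, ref].mean(axis=1)
        values = np.concatenate([m.values, (ref_mean + 0.4)[:, None]], axis=1)
        m2 = tiny_matrix(np.zeros_like(values), scale="lognorm")
        m2.values = values
        cfg = self._config(center_cells="median", smoothing_window=1)
        tracks = relative_track(m2, ref, cfg, cells=[m2.n_cells - 1])
        np.testing.assert_allclose(tracks[:, 0], 0.0, atol=1e-12)


# ---------------------------------------------------------------------- #
# Segmentation
# ---------------------------------------------------------------------- #


def brute_force_two_segment(x, min_width=1):
    """Independent oracle: best single split by the same standardized
    mean-difference statistic, via direct loops."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    sd = x.std(ddof=1)
    best = (None, -np.inf)
    for b in range(min_width, n - min_width + 1):
        left, right = x[:b], x[b:]
        t = abs(left.mean() - right.mean()) / (sd * math.sqrt(1 / b + 1 / (n - b)))
        if t > best[1]:
            best = (b, t)
    return best[0]


class TestSegmentTrack:
    def test_constant_track_single_segment(self):
        rng = np.random.default_rng(0)
        segs = segment_track(np.full(40, 0.7), rng=rng)
        assert len(segs) == 1
        assert segs[0].start == 0 and segs[0].end == 40
        assert segs[0].mean_log_ratio == pytest.approx(0.7)

    def test_noiseless_step_exact_breakpoint(self):
        rng = np.random.default_rng(0)
        x = np.concatenate([np.zeros(50), np.ones(50)])
        segs = segment_track(x, rng=rng)
        assert [s.start for s in segs] == [0, 50]
        assert [s.mean_log_ratio for s in segs] == [0.0, 1.0]

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_exhaustive_two_segment_search(self, seed):
        """Tracks <= 20 genes with one strongly planted breakpoint: CBS
        boundaries equal the brute-force single-split maximizer."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(14, 21))
        b_true = int(rng.integers(5, n - 4))
        x = rng.normal(0, 0.05, n)
        x[b_true:] += 2.0
        segs = segment_track(x, alpha=0.01, n_perm=2000, min_width=5,
                             rng=np.random.default_rng(seed + 100))
        b_oracle = brute_force_two_segment(x, min_width=1)
        assert len(segs) == 2
        assert segs[1].start == b_oracle == b_true
        np.testing.assert_allclose(
            [segs[0].mean_log_ratio, segs[1].mean_log_ratio],
            [x[:b_oracle].mean(), x[b_oracle:].mean()],
        )

    def test_short_track_single_segment_with_warning(self):
        rng = np.random.default_rng(0)
        with pytest.warns(UserWarning, match="min_width"):
            segs = segment_track(np.array([0, 1, 0, 1, 0, 1.0]), min_width=5, rng=rng)
        assert len(segs) == 1

    def test_pure_noise_rarely_splits(self):
        rng = np.random.default_rng(42)
        n_split = 0
        for rep in range(20):
            x = rng.normal(0, 1, 60)
            segs = segment_track(x, alpha=0.01, n_perm=500,
                                 rng=np.random.default_rng(rep))
            n_split += len(segs) > 1
        assert n_split <= 2

    def test_min_width_merging(self):
        rng = np.random.default_rng(0)
        x = np.concatenate([np.zeros(30), np.full(3, 5.0), np.zeros(30)])
        segs = segment_track(x, min_width=5, n_perm=500, rng=rng)
        assert all(s.n_genes >= 5 for s in segs)

    def test_segment_means_conserve_track_mean(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 1, 80)
        x[30:60] += 2
        segs = segment_track(x, n_perm=500, rng=rng)
        weighted = sum(s.mean_log_ratio * s.n_genes for s in segs) / len(x)
        assert weighted == pytest.approx(x.mean(), abs=1e-9)
        # segments partition the track
        bounds = [(s.start, s.end) for s in segs]
        assert bounds[0][0] == 0 and bounds[-1][1] == len(x)
        assert all(a[1] == b[0] for a, b in zip(bounds[:-1], bounds[1:]))


# ---------------------------------------------------------------------- #
# Calls and burden
# ---------------------------------------------------------------------- #


class TestCallCNA:
    def test_gain_above_cutoff(self):
        segs = call_cna([Segment("1", 0, 10, 0.15)], 0.1)
        assert segs[0].call == "gain"

    def test_exact_cutoff_is_neutral(self):
        segs = call_cna([Segment("1", 0, 10, 0.1), Segment("1", 10, 20, -0.1)], 0.1)
        assert [s.call for s in segs] == ["neutral", "neutral"]

    def test_loss_below_cutoff(self):
        segs = call_cna([Segment("1", 0, 10, -0.2)], 0.1)
        assert segs[0].call == "loss"

    def test_zero_track_all_neutral(self):
        segs = call_cna([Segment("1", 0, 30, 0.0)], 0.1)
        assert segs[0].call == "neutral"


class TestBurden:
    def _profile(self, segment_specs):
        n = max(e for _, e, _ in segment_specs)
        segs = [Segment("1", s, e, m) for s, e, m in segment_specs]
        segs = call_cna(segs, 0.1)
        return CNAProfile("c0", np.zeros(n), segs)

    def test_all_neutral_zero(self):
        p = self._profile([(0, 100, 0.0)])
        assert cna_burden(p) == 0

    def test_single_gain_segment(self):
        p = self._profile([(0, 250, 0.3)])
        assert cna_burden(p) == 250
        assert cna_burden(p) > 200  # crosses the undetermined-immune threshold

    def test_additivity(self):
        p = self._profile([(0, 30, 0.5), (30, 80, 0.0), (80, 100, -0.5)])
        assert cna_burden(p) == 50

    def test_monotone_in_cutoff(self):
        rng = np.random.default_rng(0)
        segs = [Segment("1", i * 10, (i + 1) * 10, rng.normal(0, 0.2))
                for i in range(10)]
        burdens = []
        for cutoff in (0.05, 0.1, 0.2, 0.4):
            called = call_cna(segs, cutoff)
            burdens.append(cna_burden(CNAProfile("c", np.zeros(100), called)))
        assert burdens == sorted(burdens, reverse=True)


# ---------------------------------------------------------------------- #
# Recurrence
# ---------------------------------------------------------------------- #


def _profile_with_calls(cell_id, n_genes, gain_ranges=(), loss_ranges=()):
    segs = []
    cursor = 0
    marks = sorted(
        [(s, e, "gain") for s, e in gain_ranges] + [(s, e, "loss") for s, e in loss_ranges]
    )
    for s, e, call in marks:
        if s > cursor:
            segs.append(Segment("1", cursor, s, 0.0, "neutral"))
        segs.append(Segment("1", s, e, 0.5 if call == "gain" else -0.5, call))
        cursor = e
    if cursor < n_genes:
        segs.append(Segment("1", cursor, n_genes, 0.0, "neutral"))
    return CNAProfile(cell_id, np.zeros(n_genes), segs)


def _gene_meta_1chrom(n):
    return pd.DataFrame(
        {
            "chrom": ["1"] * n,
            "start_bp": [1 + 1000 * i for i in range(n)],
            "end_bp": [500 + 1000 * i for i in range(n)],
            "biotype": ["protein_coding"] * n,
        },
        index=[f"G{i:03d}" for i in range(n)],
    )


class TestRecurrentCNA:
    def _cohort(self, freqs_by_sample, n_genes=50, gain=(10, 20), cells=100):
        """Samples whose cells carry a gain over `gain` at given frequency."""
        out = {}
        for sample, freq in freqs_by_sample.items():
            n_carrier = round(freq * cells)
            profiles = [
                _profile_with_calls(f"{sample}_{i}", n_genes,
                                    gain_ranges=[gain] if i < n_carrier else [])
                for i in range(cells)
            ]
            out[sample] = profiles
        return out

    def test_two_samples_passing_is_recurrent(self, default_config):
        cohort = self._cohort({"S1": 0.06, "S2": 0.07, "S3": 0.01})
        regions = recurrent_cna(cohort, "CA", _gene_meta_1chrom(50), default_config)
        assert len(regions) == 1
        r = regions[0]
        assert (r.start, r.end, r.direction) == (10, 20, "gain")
        assert r.n_samples_passing == 2

    def test_one_sample_not_recurrent(self, default_config):
        cohort = self._cohort({"S1": 0.20, "S2": 0.01})
        regions = recurrent_cna(cohort, "CA", _gene_meta_1chrom(50), default_config)
        assert regions == []

    def test_single_sample_raises(self, default_config):
        cohort = self._cohort({"S1": 0.5})
        with pytest.raises(DegenerateInputError, match="samples"):
            recurrent_cna(cohort, "CA", _gene_meta_1chrom(50), default_config)

    def test_monotone_in_recurrence_freq(self, default_config):
        rng = np.random.default_rng(0)
        cohort = self._cohort(
            {f"S{i}": float(f) for i, f in enumerate(rng.uniform(0, 0.3, 6))}
        )
        n_regions = []
        for freq in (0.01, 0.05, 0.1, 0.2):
            cfg = PipelineConfig(recurrence_freq=freq)
            regions = recurrent_cna(cohort, "CA", _gene_meta_1chrom(50), cfg)
            n_regions.append(len(regions))
        assert n_regions == sorted(n_regions, reverse=True)

    def test_runs_split_by_direction(self, default_config):
        profiles = {
            s: [
                _profile_with_calls(f"{s}_{i}", 60, gain_ranges=[(5, 15)],
                                    loss_ranges=[(15, 25)])
                for i in range(20)
            ]
            for s in ("S1", "S2")
        }
        regions = recurrent_cna(profiles, "LP", _gene_meta_1chrom(60), default_config)
        assert {(r.direction, r.start, r.end) for r in regions} == {
            ("gain", 5, 15), ("loss", 15, 25)
        }

    def test_region_bp_bounds(self, default_config):
        cohort = self._cohort({"S1": 0.5, "S2": 0.5})
        meta = _gene_meta_1chrom(50)
        regions = recurrent_cna(cohort, "CA", meta, default_config)
        r = regions[0]
        assert r.start_bp == meta["start_bp"].iloc[10]
        assert r.end_bp == meta["end_bp"].iloc[19]


class TestEndToEndRecovery:
    def test_planted_gain_recovered_as_single_region(self, synthetic_config):
        """Small cohort, one 30-gene gain carried by 40% of malignant cells in
        3 CA samples: exactly one gain region covering >= 80% of the planted
        run, and no loss regions."""
        from hnscc_stepwise import synthetic_data as syn

        spec = syn.CohortSpec(
            n_patients={"NL": 2, "CA": 3},
            cells_per_sample=80,
            cell_type_mixture={
                "NL": (0.20, 0.15, 0.30, 0.15, 0.15, 0.05),
                "CA": (0.50, 0.20, 0.15, 0.05, 0.05, 0.05),
            },
            cna_segments=(syn.CNASegmentSpec("2", 205, 235, "gain", 1.5, 0.4),),
            rng_seed=21,
        )
        matrix, truth = syn.generate_cohort(spec)
        cfg = synthetic_config
        retained = filter_gene_set(matrix.gene_meta, truth.go_background, cfg)
        sub = matrix.subset_genes(retained).log_normalize()
        ref = sub.cells_where(tissue_type="NL",
                              cell_type={"nk_t", "b_plasma", "macrophage"})
        cells = sub.cells_where(tissue_type="CA", cell_type="epithelial")
        _, profiles = cna.infer_cna_profiles(sub, ref, cells, cfg)
        by_sample = {}
        samples = sub.cell_meta["patient_id"]
        for c, p in zip(cells, profiles):
            by_sample.setdefault(samples.iloc[c], []).append(p)
        regions = recurrent_cna(by_sample, "CA", sub.gene_meta, cfg)

        gains = [r for r in regions if r.direction == "gain"]
        losses = [r for r in regions if r.direction == "loss"]
        assert losses == []
        assert len(gains) == 1
        global_idx = {g: i for i, g in enumerate(matrix.gene_ids)}
        covered = {global_idx[sub.gene_ids[i]]
                   for i in range(gains[0].start, gains[0].end)}
        planted = set(range(205, 235))
        assert len(covered & planted) / len(planted) >= 0.8


class TestBurdenContrast:
    def _profiles(self, burdens):
        out = []
        for i, b in enumerate(burdens):
            segs = [Segment("1", 0, b, 0.5, "gain")] if b else []
            out.append(CNAProfile(f"c{i}", np.zeros(300), segs))
        return out

    def test_identical_groups(self):
        a = self._profiles([100] * 10)
        b = self._profiles([100] * 10)
        result = burden_contrast(a, b, n_permutations=200, seed=0)
        assert result.diff == 0
        assert result.perm_p == pytest.approx(1.0)

    def test_separated_groups(self):
        a = self._profiles([250] * 12)
        b = self._profiles([100] * 12)
        result = burden_contrast(a, b, n_permutations=500, seed=0)
        assert result.mean_a == 250 and result.mean_b == 100
        assert result.perm_p < 0.01

    def test_degenerate_single_cell_group_runs(self):
        a = self._profiles([200])
        b = self._profiles([100] * 10)
        result = burden_contrast(a, b, n_permutations=200, seed=0)
        assert 0 < result.perm_p <= 1

    def test_recovers_planted_burden_ratio(self, synthetic_config):
        """Two clones with 2x planted aberrant-gene difference recover the
        ratio within 15%."""
        rng = np.random.default_rng(1)
        a = self._profiles(rng.poisson(240, 60))
        b = self._profiles(rng.poisson(120, 60))
        result = burden_contrast(a, b, n_permutations=500, seed=0)
        assert result.mean_a / result.mean_b == pytest.approx(2.0, rel=0.15)
        assert result.perm_p < 0.01
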