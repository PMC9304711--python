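"""Repli-seq timing: smoothing, normalization, S50, z-scores, segmentation."""

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage

from msidyn.genic import GeneModel
from msidyn.repliseq import (
    FeatureParams,
    RepliseqMatrix,
    bin_timing,
    classify_features,
    gene_timing,
    normalize_columns,
    process_matrices,
    quantile_timing,
    sdiff_z,
    smooth,
    timing_correlations,
)


def mk_matrix(values, missing=None, chrom="chr1"):
    values = np.asarray(values, dtype=float)
    if missing is None:
        missing = np.zeros(values.shape[1], dtype=bool)
    return RepliseqMatrix(chrom, values, missing)


def column(weights):
    """A single-bin matrix from 16 fraction weights."""
    return mk_matrix(np.asarray(weights, dtype=float).reshape(16, 1))


class TestSmooth:
    def test_constant_matrix_unchanged(self):
        m = mk_matrix(np.full((16, 30), 7.0))
        out = smooth(m, sd=1.0)
        assert np.allclose(out.values, 7.0, atol=1e-9)

    def test_impulse_symmetric_peak(self):
        vals = np.zeros((16, 21))
        vals[8, 10] = 1.0
        out = smooth(mk_matrix(vals), sd=1.0)
        assert out.values.argmax() == np.ravel_multi_index((8, 10), (16, 21))
        assert np.allclose(out.values[8, 9], out.values[8, 11])
        assert np.allclose(out.values[7, 10], out.values[9, 10])

    def test_matches_dense_convolution_oracle(self):
        """Direct kernel summation (reflect boundary) reproduces the filter."""
        rng = np.random.default_rng(0)
        vals = rng.random((16, 40))
        sd = 1.0
        radius = int(4 * sd + 0.5)
        x = np.arange(-radius, radius + 1)
        k = np.exp(-0.5 * (x / sd) ** 2)
        k /= k.sum()

        def reflect(i, n):
            while i < 0 or i >= n:
                i = -i - 1 if i < 0 else 2 * n - i - 1
            return i

        expect = np.zeros_like(vals)
        for r in range(16):
            for c in range(40):
                acc = 0.0
                for dr in range(-radius, radius + 1):
                    for dc in range(-radius, radius + 1):
                        acc += (k[dr + radius] * k[dc + radius]
                                * vals[reflect(r + dr, 16), reflect(c + dc, 40)])
                expect[r, c] = acc
        out = smooth(mk_matrix(vals), sd=sd)
        assert np.allclose(out.values, expect, atol=1e-8)

    def test_missing_columns_restored_as_missing(self):
        vals = np.ones((16, 10))
        missing = np.zeros(10, bool)
        missing[4] = True
        vals[:, 4] = 0
        out = smooth(mk_matrix(vals, missing), sd=1.0)
        assert out.missing_mask[4]
        # neighbors are unaffected by the excluded column
        assert np.allclose(out.values[:, 3], 1.0, atol=1e-9)

    def test_negative_sd_errors(self):
        with pytest.raises(ValueError):
            smooth(mk_matrix(np.ones((16, 3))), sd=-1)


class TestNormalize:
    def test_uniform_column(self):
        out = normalize_columns(column(np.ones(16)))
        assert np.allclose(out.values, 6.25)

    def test_zero_column_marked_missing(self):
        vals = np.ones((16, 3))
        vals[:, 1] = 0
        out = normalize_columns(mk_matrix(vals))
        assert out.missing_mask.tolist() == [False, True, False]

    def test_random_columns_sum_100(self):
        rng = np.random.default_rng(1)
        out = normalize_columns(mk_matrix(rng.random((16, 500)) + 0.01))
        assert np.allclose(out.values.sum(axis=0), 100.0, atol=1e-9)


class TestQuantileTiming:
    def test_all_mass_first_fraction(self):
        w = np.zeros(16)
        w[0] = 100
        assert quantile_timing(column(w), 0.5)[0] == pytest.approx(0.03125)

    def test_uniform_mass(self):
        assert quantile_timing(normalize_columns(column(np.ones(16))), 0.5)[
            0] == pytest.approx(0.5)

    def test_split_mass_first_and_last(self):
        w = np.zeros(16)
        w[0] = w[15] = 50
        # cumulative curve reaches exactly 50 at node 1/16
        assert quantile_timing(column(w), 0.5)[0] == pytest.approx(0.0625)

    def test_quantile_bounds(self):
        with pytest.raises(ValueError):
            quantile_timing(column(np.ones(16)), 1.5)

    def test_quantile_order_on_random_columns(self):
        rng = np.random.default_rng(2)
        m = normalize_columns(mk_matrix(rng.random((16, 2000)) + 1e-6))
        s25, s50, s75 = (quantile_timing(m, q) for q in (0.25, 0.5, 0.75))
        assert (0 <= s25).all() and (s25 <= s50).all()
        assert (s50 <= s75).all() and (s75 <= 1).all()

    def test_later_mass_never_decreases_s50(self):
        """Moving mass from an earlier to a later fraction is monotone."""
        rng = np.random.default_rng(3)
        for _ in range(50):
            w = rng.random(16) + 0.05
            base = quantile_timing(normalize_columns(column(w)), 0.5)[0]
            i = int(rng.integers(0, 15))
            j = int(rng.integers(i + 1, 16))
            w2 = w.copy()
            moved = w2[i] * rng.random()
            w2[i] -= moved
            w2[j] += moved
            shifted = quantile_timing(normalize_columns(column(w2)), 0.5)[0]
            assert shifted >= base - 1e-12


class TestSdiffZ:
    def mk_bins(self, sdiff, chrom="chr1"):
        n = len(sdiff)
        return pd.DataFrame(
            {"chrom": chrom, "bin": range(n), "start": 0, "end": 1,
             "s25": 0.2, "s50": 0.5, "s75": 0.2 + np.asarray(sdiff),
             "sdiff": np.asarray(sdiff, dtype=float), "missing": False}
        )

    def test_constant_sdiff_no_noise(self):
        out = sdiff_z(self.mk_bins([0.3] * 100))
        assert (out["sdiff_z"] == 0).all() and not out["noisy"].any()

    def test_single_outlier_flagged(self):
        vals = [0.2] * 1000 + [0.9]
        out = sdiff_z(self.mk_bins(vals))
        assert out["noisy"].sum() == 1 and bool(out["noisy"].iloc[-1])

    def test_infinite_cutoff_flags_nothing(self):
        rng = np.random.default_rng(0)
        out = sdiff_z(self.mk_bins(rng.random(200)), cutoff=np.inf)
        assert not out["noisy"].any()


class TestClassify:
    def labelled(self, s50, **kw):
        n = len(s50)
        bins = pd.DataFrame(
            {"chrom": "chr1", "bin": range(n), "start": np.arange(n) * 50_000,
             "end": (np.arange(n) + 1) * 50_000, "s25": 0.0, "s50": s50,
             "s75": 0.0, "sdiff": 0.0, "missing": False, "sdiff_z": 0.0,
             "noisy": False}
        )
        return classify_features(bins, FeatureParams(**kw))

    def test_valley_is_iz(self):
        s = [0.5, 0.4, 0.3, 0.1, 0.3, 0.4, 0.5]
        out, _ = self.labelled(s)
        assert out.loc[3, "label"] == "IZ"

    def test_flat_plateau_is_ctr(self):
        s = [0.6, 0.5, 0.4] + [0.2] * 10 + [0.4, 0.5, 0.6]
        out, _ = self.labelled(s, tau=0.4)
        mid = out.iloc[4:12]
        assert (mid["label"] == "CTR_EARLY").all()

    def test_short_peak_is_termination(self):
        s = [0.2, 0.3, 0.4, 0.55, 0.55, 0.4, 0.3, 0.2]
        out, _ = self.labelled(s)
        assert (out.loc[3:4, "label"] == "TERMINATION").all()

    def test_segments_tile_non_missing(self, sim_bundle):
        cfg, sim_dir, _ = sim_bundle
        from msidyn.repliseq import read_matrix_tsv

        mats = read_matrix_tsv(sim_dir / "repliseq.tsv")
        bins, segments = process_matrices(mats)
        covered = np.zeros(len(bins), dtype=int)
        for seg in segments:
            covered[seg.start_bin:seg.end_bin] += 1
        missing = bins["missing"].to_numpy()
        assert (covered[~missing] == 1).all()
        assert (covered[missing] == 0).all()
        for seg in segments:
            if seg.label == "TERMINATION":
                assert seg.end_bin - seg.start_bin <= 3

    def test_planted_landscape_recovery(self):
        """>= 90% bin-label agreement on the noise-free planted landscape."""
        from msidyn.simulate import (RepliseqParams, SimulationConfig,
                                     simulate_repliseq)

        cfg = SimulationConfig(
            seed=21, repliseq=RepliseqParams(n_bins=2000, missing_fraction=0.0)
        )
        mats, truth = simulate_repliseq(cfg)
        bins, _ = process_matrices(mats, sd=1.0)
        merged = truth.merge(bins[["bin", "label"]], on="bin",
                             suffixes=("_true", "_called"))
        agreement = (merged["label_true"] == merged["label_called"]).mean()
        assert agreement >= 0.90


class TestGeneTiming:
    def mk_bins(self, s50s, chrom="chr1"):
        n = len(s50s)
        return pd.DataFrame(
            {"chrom": chrom, "bin": range(n), "start": np.arange(n) * 50_000,
             "end": (np.arange(n) + 1) * 50_000, "s50": s50s,
             "sdiff": 0.1, "missing": [not np.isfinite(v) for v in s50s]}
        )

    def gene(self, gid, start, end, chrom="chr1"):
        return GeneModel(gid, gid, chrom, "+", start, end, [(start, end)], [])

    def test_single_bin(self):
        out = gene_timing([self.gene("g1", 10_000, 20_000)],
                          self.mk_bins([0.3, 0.6]))
        assert out["s50"].iloc[0] == pytest.approx(0.3)

    def test_equal_span_mean(self):
        out = gene_timing([self.gene("g1", 25_000, 75_000)],
                          self.mk_bins([0.2, 0.4]))
        assert out["s50"].iloc[0] == pytest.approx(0.3)

    def test_chrx_excluded(self):
        g = self.gene("gx", 0, 50_000, chrom="chrX")
        out = gene_timing([g], self.mk_bins([0.3], chrom="chrX"),
                          autosomes_only=True)
        assert np.isnan(out["s50"].iloc[0])
        out2 = gene_timing([g], self.mk_bins([0.3], chrom="chrX"),
                           autosomes_only=False)
        assert out2["s50"].iloc[0] == pytest.approx(0.3)

    def test_missing_bins_excluded_from_mean(self):
        out = gene_timing([self.gene("g1", 0, 100_000)],
                          self.mk_bins([0.2, np.nan]))
        assert out["s50"].iloc[0] == pytest.approx(0.2)


class TestCorrelations:
    def test_perfect_linear(self):
        df = pd.DataFrame({"x": [1.0, 2, 3, 4], "y": [2.0, 4, 6, 8]})
        cmp = timing_correlations(df, "x", "y")
        assert cmp.estimate == pytest.approx(1.0)

    def test_independent_draws_near_zero(self):
        rng = np.random.default_rng(4)
        hits = 0
        for _ in range(20):
            df = pd.DataFrame({"x": rng.normal(size=1000),
                               "y": rng.normal(size=1000)})
            if abs(timing_correlations(df, "x", "y").estimate) < 0.1:
                hits += 1
        assert hits >= 19

    def test_planted_length_timing_dependence_detected(self):
        """Generator coupling: later-replicating genes drawn longer."""
        from msidyn.simulate import (GeneParams, SimulationConfig,
                                     simulate_gene_models, simulate_genome,
                                     simulate_repliseq, _streams)

        cfg = SimulationConfig(
            seed=31, chrom_length=8_000_000,
            genes=GeneParams(n_genes=200, timing_length_coupling=0.6,
                             pol2_length_factor=1.0,
                             intergenic_gap=(1500, 8000)),
        )
        streams = _streams(cfg.seed)
        genome, _ = simulate_genome(cfg, streams["genome"])
        _, truth = simulate_repliseq(cfg, streams["repliseq"])
        genes, _, _ = simulate_gene_models(cfg, genome, streams["genes"],
                                           bin_s50=truth["s50"].to_numpy())
        bw = cfg.repliseq.bin_width
        df = pd.DataFrame(
            {"length": [g.length for g in genes],
             "s50": [truth["s50"].iloc[min(g.start // bw,
                                           len(truth) - 1)] for g in genes]}
        )
        cmp = timing_correlations(df, "s50", "length")
        assert cmp.estimate > 0 and cmp.p_value < 0.05

    def test_zero_variance_errors(self):
        df = pd.DataFrame({"x": [1.0, 1, 1, 1], "y": [1.0, 2, 3, 4]})
        with pytest.raises(ValueError):
            timing_correlations(df, "x", "y")


class TestQuantileProperties:
    """Hypothesis: quantile ordering holds for arbitrary positive columns."""

    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(st.lists(st.floats(min_value=1e-3, max_value=1e3), min_size=16,
                    max_size=16))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_quantiles_ordered(self, weights):
        m = normalize_columns(column(weights))
        s25, s50, s75 = (quantile_timing(m, q)[0] for q in (0.25, 0.5, 0.75))
        assert 0 <= s25 <= s50 <= s75 <= 1
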