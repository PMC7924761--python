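"""Window aggregation, gene-scale counting, anchored profiles, and QC."""
import numpy as np
import pandas as pd
import pytest

from dimorphatac.coverage import (
    accessibility_expression_r2,
    anchored_signal,
    chrom_read_fractions,
    gene_scale_counts,
    sample_correlation,
    windowed_counts,
)
from dimorphatac.intervals import GeneModel, GenomeSpec, GenomicInterval


def frame(starts, chrom="chr2", length=100):
    starts = np.asarray(starts)
    return pd.DataFrame({"chrom": chrom, "start": starts,
                         "end": starts + length})


def frags_at_midpoints(mids, chrom="chr2"):
    mids = np.asarray(mids)
    return pd.DataFrame({"chrom": chrom, "start": mids - 10, "end": mids + 10})


class TestWindowedCounts:
    def test_hand_assignment(self, small_genome):
        locus = GenomicInterval("chr2", 0, 10_000)
        frags = {"s": frags_at_midpoints([100, 4900, 5100])}
        wa = windowed_counts(frags, locus, small_genome, 5000)
        assert list(wa.counts["s"]) == [2, 1]

    def test_empty_fragments_all_zero(self, small_genome):
        locus = GenomicInterval("chr2", 0, 10_000)
        wa = windowed_counts({"s": frame([], length=0)}, locus, small_genome, 5000)
        assert (wa.counts["s"] == 0).all()

    def test_window_counts_conserve_locus_fragments(self, small_genome):
        rng = np.random.default_rng(0)
        mids = rng.integers(0, 50_000, size=2_000)
        locus = GenomicInterval("chr2", 0, 50_000)
        wa = windowed_counts({"s": frags_at_midpoints(mids)}, locus,
                             small_genome, 3000)
        assert wa.counts["s"].sum() == 2_000

    def test_partial_last_window_true_width(self, small_genome):
        locus = GenomicInterval("chr2", 0, 12_000)
        wa = windowed_counts({"s": frame([])}, locus, small_genome, 5000)
        assert list(wa.counts["window_end"])[-1] == 12_000

    def test_locus_outside_genome_rejected(self, small_genome):
        with pytest.raises(ValueError, match="outside"):
            windowed_counts({}, GenomicInterval("chr2", 0, 10 ** 7),
                            small_genome, 5000)


class TestGeneScale:
    def test_single_gene_per_bp(self):
        g = GeneModel("g", "chr2", "+", [GenomicInterval("chr2", 0, 1000)])
        out = gene_scale_counts({"s": frags_at_midpoints([10, 990])}, [g])
        assert out.loc[0, "s"] == 2
        assert out.loc[0, "s_per_bp"] == pytest.approx(0.002)

    def test_midpoint_in_overlapping_spans_counted_twice(self):
        g1 = GeneModel("a", "chr2", "+", [GenomicInterval("chr2", 0, 1000)])
        g2 = GeneModel("b", "chr2", "+", [GenomicInterval("chr2", 500, 1500)])
        out = gene_scale_counts({"s": frags_at_midpoints([700])}, [g1, g2])
        assert out["s"].tolist() == [1, 1]

    def test_tiling_genes_conserve_total(self):
        genes = [GeneModel(f"g{i}", "chr2", "+",
                           [GenomicInterval("chr2", i * 1000, (i + 1) * 1000)])
                 for i in range(50)]
        rng = np.random.default_rng(1)
        mids = rng.integers(0, 50_000, size=3_000)
        out = gene_scale_counts({"s": frags_at_midpoints(mids)}, genes)
        assert out["s"].sum() == 3_000


class TestAnchoredSignal:
    def test_constant_track_gives_flat_profile(self):
        track = {"chr2": np.full(10_000, 3.0)}
        regions = [GenomicInterval("chr2", 4000, 4400),
                   GenomicInterval("chr2", 6000, 6400)]
        am = anchored_signal(track, regions, "center", flank=500, bins=10)
        np.testing.assert_allclose(am.matrix, 3.0)
        np.testing.assert_allclose(am.mean_profile, 3.0)

    def test_delta_spike_maximal_at_center_bin(self):
        track = {"chr2": np.zeros(10_000)}
        track["chr2"][5000] = 100.0
        am = anchored_signal(track, [GenomicInterval("chr2", 4800, 5200)],
                             "center", flank=500, bins=10)
        assert np.nanargmax(am.mean_profile) in (4, 5)

    def test_minus_strand_mirror_pair(self):
        rng = np.random.default_rng(2)
        sig = rng.uniform(size=3_000)
        track = {"chr2": np.concatenate([sig, sig[::-1]])}
        fwd = GenomicInterval("chr2", 1000, 2000, strand="+")
        rev = GenomicInterval("chr2", 6000 - 2000, 6000 - 1000, strand="-")
        am = anchored_signal(track, [fwd, rev], "scaled_body",
                             flank=500, bins=5, body_bins=10)
        np.testing.assert_allclose(am.matrix[0], am.matrix[1], atol=1e-9)

    def test_out_of_bounds_bins_masked(self):
        track = {"chr2": np.ones(1_000)}
        am = anchored_signal(track, [GenomicInterval("chr2", 0, 100)],
                             "center", flank=500, bins=10)
        assert np.isnan(am.matrix[0]).any()
        assert np.isfinite(am.mean_profile[-1])


class TestQC:
    def test_self_correlation_and_rank_invariance(self, small_genome):
        rng = np.random.default_rng(3)
        mids = rng.integers(0, 200_000, size=5_000)
        a = frags_at_midpoints(mids)
        doubled = pd.concat([a, a], ignore_index=True)
        corr = sample_correlation({"a": a, "b": doubled}, small_genome)
        assert corr.loc["a", "a"] == 1.0
        assert corr.loc["a", "b"] == pytest.approx(1.0, abs=1e-9)

    def test_independent_samples_near_zero(self):
        # single-chromosome genome: no shared zero-coverage bins that
        # would induce spurious rank correlation
        genome = GenomeSpec([("chr2", 3_000_000, "autosome")])
        rng = np.random.default_rng(4)
        frags = {k: frags_at_midpoints(rng.integers(0, 3_000_000, size=100_000))
                 for k in ("a", "b")}
        corr = sample_correlation(frags, genome, bin_size=1_000)
        assert abs(corr.loc["a", "b"]) < 0.05

    def test_chrom_fractions_sum_to_one(self, small_genome):
        frags = {"s": pd.DataFrame({
            "chrom": ["chrX"] * 3 + ["chr2"] * 7,
            "start": range(10), "end": range(10, 20)})}
        out = chrom_read_fractions(frags, small_genome)
        assert out.loc[0, "X"] == pytest.approx(0.3)
        assert out.loc[0, "X"] + out.loc[0, "autosome"] == pytest.approx(1.0)

    def test_all_x_gives_fraction_one(self, small_genome):
        frags = {"s": frags_at_midpoints([10, 20, 30], chrom="chrX")}
        out = chrom_read_fractions(frags, small_genome)
        assert out.loc[0, "X"] == 1.0

    def test_female_x_fraction_exceeds_male(self, default_sim, default_fragments):
        config, _, _ = default_sim
        out = chrom_read_fractions(default_fragments, config.genome)
        out = out.set_index("sample_id")
        female = out.loc[out.index.str.startswith("female"), "X"].mean()
        male = out.loc[out.index.str.startswith("male"), "X"].mean()
        assert female > male


class TestAccessibilityExpression:
    def test_proportional_gives_r2_one(self):
        acc = pd.Series([1.0, 2, 4, 8, 16], index=list("abcde"))
        expr = (10 ** (np.log10(acc + 1) * 2)) - 1  # exact linear log-log
        assert accessibility_expression_r2(acc, expr) == pytest.approx(1.0)

    def test_permutation_null_near_zero(self):
        rng = np.random.default_rng(5)
        idx = [f"g{i}" for i in range(1000)]
        acc = pd.Series(rng.lognormal(0, 1, 1000), index=idx)
        expr = pd.Series(rng.permutation(acc.to_numpy()), index=idx)
        assert accessibility_expression_r2(acc, expr) < 0.01

    def test_too_few_shared_genes_rejected(self):
        with pytest.raises(ValueError):
            accessibility_expression_r2(pd.Series([1.0], index=["a"]),
                                        pd.Series([1.0], index=["a"]))
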