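"""Consensus building, counting conventions, normalization, dispersion,
the NB Wald test, and the stratified driver."""
import numpy as np
import pandas as pd
import pytest

from dimorphatac import simulate as sim
from dimorphatac.diffacc import (
    DifferentialAccessibilityModel,
    bh_adjust,
    build_consensus,
    count_in_regions,
    estimate_dispersion,
    nb_wald_test,
    size_factors,
    stratified_differential,
)
from dimorphatac.intervals import GenomicInterval


def iv(chrom, start, end):
    return GenomicInterval(chrom, start, end)


class TestConsensus:
    def test_min_samples_two_is_intersection(self):
        out = build_consensus([[iv("chr2", 100, 200)], [iv("chr2", 150, 250)]], 2)
        assert [(r.start, r.end) for r in out] == [(150, 200)]

    def test_min_samples_one_is_union(self):
        out = build_consensus([[iv("chr2", 100, 200)], [iv("chr2", 150, 250)]], 1)
        assert [(r.start, r.end) for r in out] == [(100, 250)]

    def test_disjoint_sets_give_empty_consensus(self):
        out = build_consensus([[iv("chr2", 100, 200)], [iv("chr2", 300, 400)]], 2)
        assert out == []

    def test_min_samples_exceeding_sets_errors(self):
        with pytest.raises(ValueError):
            build_consensus([[iv("chr2", 1, 2)]], 2)


class TestCounting:
    def _samples(self):
        return pd.DataFrame({"sample_id": ["s1"], "condition": ["c"],
                             "replicate": [1]})

    def test_boundary_conventions(self):
        regions = [iv("chr2", 100, 200)]
        frags = pd.DataFrame({
            "chrom": ["chr2", "chr2"],
            # midpoints exactly 100 (in, half-open) and 200 (out)
            "start": [95, 195], "end": [105, 205],
        })
        cm = count_in_regions({"s1": frags}, regions, self._samples())
        assert cm.counts[0, 0] == 1

    def test_overlapping_regions_rejected(self):
        with pytest.raises(ValueError, match="non-overlapping"):
            count_in_regions({"s1": pd.DataFrame(columns=["chrom", "start", "end"])},
                             [iv("chr2", 0, 100), iv("chr2", 50, 150)],
                             self._samples())

    def test_tiling_regions_conserve_fragments(self):
        rng = np.random.default_rng(2)
        regions = [iv("chr2", i * 1000, (i + 1) * 1000) for i in range(100)]
        starts = rng.integers(0, 99_000, size=5_000)
        frags = pd.DataFrame({"chrom": "chr2", "start": starts,
                              "end": starts + 100})
        cm = count_in_regions({"s1": frags}, regions, self._samples())
        assert cm.counts.sum() == 5_000


class TestSizeFactors:
    def test_worked_three_by_two_matrix(self):
        s = size_factors(np.array([[10, 20], [20, 40], [30, 60]]))
        np.testing.assert_allclose(s, [0.70710678, 1.41421356], rtol=1e-6)

    def test_identical_columns_give_unit_factors(self):
        s = size_factors(np.tile([[7], [13], [29]], (1, 3)))
        np.testing.assert_allclose(s, 1.0)

    def test_doubling_a_column_doubles_its_factor(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(50, size=(500, 4)) + 1
        s = size_factors(counts)
        counts2 = counts.copy()
        counts2[:, 2] *= 2
        s2 = size_factors(counts2)
        ratio = (s2[2] / s[2]) / (s2[0] / s[0])  # relative to an untouched column
        assert ratio == pytest.approx(2.0, rel=1e-6)

    def test_geometric_mean_is_one(self):
        rng = np.random.default_rng(1)
        s = size_factors(rng.poisson(30, size=(200, 6)) + 1)
        assert np.exp(np.mean(np.log(s))) == pytest.approx(1.0, abs=1e-9)

    def test_all_zero_region_matrix_errors(self):
        with pytest.raises(ValueError, match="depth"):
            size_factors(np.array([[0, 1], [2, 0]]))


class TestDispersion:
    def test_worked_pair_example(self):
        counts = np.array([[10, 20]])
        est = estimate_dispersion(counts, np.ones(2), [np.array([0, 1])])
        assert est.raw[0] == pytest.approx(35 / 225, rel=1e-9)

    def test_poisson_counts_give_small_raw_alpha(self):
        rng = np.random.default_rng(4)
        counts = rng.poisson(100, size=(2000, 50))
        est = estimate_dispersion(counts, np.ones(50), [np.arange(50)])
        assert np.median(est.raw) < 0.02

    def test_trend_recovers_one_over_mean_coefficient(self):
        rng = np.random.default_rng(8)
        m = rng.uniform(5, 500, size=2000)
        a0_true, a1_true = 0.05, 2.0
        alpha = a0_true + a1_true / m
        n = 1.0 / alpha
        counts = rng.negative_binomial(n[:, None], (n / (n + m))[:, None],
                                       size=(2000, 20))
        est = estimate_dispersion(counts, np.ones(20), [np.arange(20)])
        a0, a1 = est.trend_coef
        assert a1 == pytest.approx(a1_true, rel=0.2)

    def test_floor_applied(self):
        counts = np.tile([[50, 50, 50, 50]], (20, 1))
        est = estimate_dispersion(counts, np.ones(4), [np.arange(4)])
        assert (est.final >= 1e-4).all()


class TestWaldTest:
    def test_identical_groups_give_null_result(self):
        counts = np.tile([[30, 30, 30, 30]], (5, 1))
        res = nb_wald_test(counts, np.ones(4), np.full(5, 0.05),
                           np.array([0, 1]), np.array([2, 3]))
        np.testing.assert_allclose(res["log2fc"], 0.0)
        np.testing.assert_allclose(res["pvalue"], 1.0)

    def test_swapping_groups_negates_lfc(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson([20, 20, 60, 60], size=(50, 4))
        a, b = np.array([0, 1]), np.array([2, 3])
        fwd = nb_wald_test(counts, np.ones(4), np.full(50, 0.05), a, b)
        rev = nb_wald_test(counts, np.ones(4), np.full(50, 0.05), b, a)
        np.testing.assert_allclose(fwd["log2fc"], -rev["log2fc"], atol=1e-12)
        np.testing.assert_allclose(fwd["pvalue"], rev["pvalue"], atol=1e-12)

    def test_null_type_one_error_calibrated(self):
        rng = np.random.default_rng(123)
        mu = 50
        alpha = 0.05
        n = 1 / alpha
        counts = rng.negative_binomial(n, n / (n + mu), size=(2000, 4))
        sf = size_factors(counts)
        est = estimate_dispersion(counts, sf, [np.array([0, 1]), np.array([2, 3])])
        res = nb_wald_test(counts, sf, est.final, np.array([0, 1]),
                           np.array([2, 3]))
        frac = (res["pvalue"] < 0.05).mean()
        assert 0.02 <= frac <= 0.08


class TestBH:
    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(bh_adjust(np.array([0.01, 0.02, 0.03, 0.04])),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_monotone_in_input(self):
        p = np.array([0.001, 0.01, 0.2, 0.9])
        q = bh_adjust(p)
        assert (np.diff(q[np.argsort(p)]) >= -1e-12).all()


class TestStratified:
    def _matrix_with_identical_strata(self):
        rng = np.random.default_rng(5)
        counts = rng.poisson(40, size=(50, 4))
        counts = np.vstack([counts, counts])  # identical X and autosome blocks
        regions = ([iv("chrX", i * 1000, i * 1000 + 500) for i in range(50)]
                   + [iv("chr2", i * 1000, i * 1000 + 500) for i in range(50)])
        for k, r in enumerate(regions):
            object.__setattr__(r, "name", f"r{k}")
        samples = pd.DataFrame({
            "sample_id": ["a1", "a2", "b1", "b2"],
            "condition": ["A", "A", "B", "B"], "replicate": [1, 2, 1, 2]})
        strata = np.array(["X"] * 50 + ["autosome"] * 50)
        return sim.CountMatrix(regions=regions, strata=strata,
                               samples=samples, counts=counts)

    def test_identical_strata_give_identical_results(self):
        cm = self._matrix_with_identical_strata()
        res = stratified_differential(cm, "B", "A", mode="stratified")
        x = res[res["stratum"] == "X"].reset_index(drop=True)
        a = res[res["stratum"] == "autosome"].reset_index(drop=True)
        np.testing.assert_allclose(x["log2fc"], a["log2fc"])
        np.testing.assert_allclose(x["fdr"], a["fdr"])

    def test_unknown_mode_rejected(self):
        cm = self._matrix_with_identical_strata()
        with pytest.raises(ValueError, match="mode"):
            stratified_differential(cm, "B", "A", mode="bogus")

    def test_scaling_one_sample_leaves_lfc_invariant(self):
        config = sim.SimulationConfig(seed=3, n_peaks_per_chrom=60,
                                      baseline_mu=200, n_open_planted=5,
                                      n_closed_planted=5)
        cm, _ = sim.simulate_counts(config)
        res = stratified_differential(cm, "male_fru_plus", "female_fru_plus")
        cm2 = sim.CountMatrix(regions=cm.regions, strata=cm.strata,
                              samples=cm.samples, counts=cm.counts.copy())
        cm2.counts[:, 0] *= 3
        res2 = stratified_differential(cm2, "male_fru_plus", "female_fru_plus")
        big = res["base_mean"] > 50
        assert np.abs(res2["log2fc"][big] - res["log2fc"][big]).max() < 0.01

    def test_every_region_once_with_finite_lfc(self, default_sim):
        _, cm, _ = default_sim
        res = stratified_differential(cm, "male_fru_plus", "female_fru_plus")
        assert len(res) == len(cm.regions)
        assert res["region"].is_unique
        assert np.isfinite(res["log2fc"]).all()

    def test_model_results_surface(self, default_sim):
        _, cm, _ = default_sim
        model = DifferentialAccessibilityModel.from_count_matrix(cm)
        res = model.fit("male_fru_plus", "female_fru_plus")
        assert "log2fc = log2(male_fru_plus / female_fru_plus)" in res.orientation
        text = res.summary()
        assert "stratified" in text and "significant" in text
        assert len(res.significant(0.05)) == (res.table["fdr"] < 0.05).sum()
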