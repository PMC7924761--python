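"""Generative-model contracts: mean structure, NB limits, fragment
conservation, sequence planting, and determinism."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dimorphatac import simulate as sim
from dimorphatac.pipeline import default_motif


def _mini_config(**kw):
    defaults = dict(seed=1, n_peaks_per_chrom=30, n_open_planted=4,
                    n_closed_planted=3)
    defaults.update(kw)
    return sim.SimulationConfig(**defaults)


class TestCountModel:
    def test_mean_formula_under_null(self):
        """With no effects, Monte-Carlo peak means match s_j*f_i*mu*x_ij."""
        config = _mini_config(planted_abs_log2fc=0.0, dcc_boost=1.0,
                              dispersion=0.05, n_open_planted=0,
                              n_closed_planted=0)
        rng = np.random.default_rng(0)
        samples = sim._sample_sheet(config, rng)
        peaks = sim._layout_peaks(config, rng)
        f = rng.uniform(*config.cell_fraction_range, size=len(peaks))
        mu = sim.expected_counts(config, peaks, samples, f)
        draws = np.stack([sim._nb_draw(rng, mu, config.dispersion)
                          for _ in range(1000)])
        emp_mean = draws.mean(axis=0)
        emp_se = draws.std(axis=0) / np.sqrt(1000)
        assert (np.abs(emp_mean - mu) < 3.5 * emp_se + 1e-9).mean() > 0.99

    def test_zero_dispersion_is_poisson(self):
        rng = np.random.default_rng(1)
        draws = sim._nb_draw(rng, np.full(10_000, 40.0), 0.0)
        assert draws.var() / draws.mean() == pytest.approx(1.0, abs=0.1)

    def test_female_male_x_ratio_is_two_in_mean(self):
        config = _mini_config(dcc_boost=1.0)
        rng = np.random.default_rng(0)
        samples = sim._sample_sheet(config, rng).assign(size_factor=1.0)
        peaks = sim._layout_peaks(config, rng)
        mu = sim.expected_counts(config, peaks, samples, np.ones(len(peaks)))
        is_x = (peaks["stratum"] == "X").to_numpy()
        non_dcc_x = is_x & (peaks["peak_class"] != "DCC")
        j_f = samples.index[samples["condition"] == "female_fru_minus"][0]
        j_m = samples.index[samples["condition"] == "male_fru_minus"][0]
        np.testing.assert_allclose(mu[non_dcc_x, j_f] / mu[non_dcc_x, j_m], 2.0)

    def test_planted_count_error(self):
        with pytest.raises(ValueError, match="planted"):
            sim.simulate_counts(_mini_config(n_open_planted=100,
                                             n_closed_planted=100))

    def test_class_placement(self):
        _, truth = sim.simulate_counts(_mini_config())
        p = truth.peaks
        assert (p.loc[p["peak_class"] == "DCC", "stratum"] == "X").all()
        frum = p["peak_class"].isin(["FruM_open", "FruM_closed"])
        assert (p.loc[frum, "stratum"] == "autosome").all()


class TestFragments:
    def test_midpoint_counting_reproduces_matrix(self):
        config = _mini_config(background_rate=0.0)
        cm, _ = sim.simulate_counts(config)
        frags = sim.simulate_fragments(config, cm)
        for j, sid in enumerate(cm.samples["sample_id"]):
            df = frags[sid]
            df = df[df["name"] != "background"]
            mids = (df["start"].to_numpy() + df["end"].to_numpy()) // 2
            for i, region in enumerate(cm.regions):
                in_peak = df["name"] == f"peak:{region.name}"
                n_inside = ((mids >= region.start) & (mids < region.end)
                            & in_peak.to_numpy()).sum()
                assert n_inside == cm.counts[i, j]

    def test_no_background_means_all_fragments_flagged(self):
        config = _mini_config(background_rate=0.0)
        cm, _ = sim.simulate_counts(config)
        frags = sim.simulate_fragments(config, cm)
        for df in frags.values():
            assert (df["name"] != "background").all()

    def test_total_fragments_conserved(self):
        config = _mini_config()
        cm, _ = sim.simulate_counts(config)
        frags = sim.simulate_fragments(config, cm)
        for j, sid in enumerate(cm.samples["sample_id"]):
            df = frags[sid]
            n_bg = (df["name"] == "background").sum()
            assert len(df) == cm.counts[:, j].sum() + n_bg

    def test_length_mixture_is_bimodal(self):
        rng = np.random.default_rng(9)
        mix = ((0.65, 80.0, 25.0), (0.35, 200.0, 40.0))
        lengths = sim._draw_lengths(rng, 100_000, mix)

        def mixture_cdf(x):
            out = 0.0
            for w, m, s in mix:
                # truncation at 20 matches the generator
                z = stats.norm(m, s)
                out += w * (z.cdf(np.maximum(x, 20)) - z.cdf(20)) / z.sf(20)
            return out / sum(w for w, _, _ in mix)

        # rounding to integers makes a strict KS test miscalibrated; the
        # distance itself should still be tiny
        d = stats.kstest(lengths, mixture_cdf).statistic
        assert d < 0.02
        hist, edges = np.histogram(lengths, bins=np.arange(20, 400, 10))
        # two local modes near the configured means; the search for the
        # second skips the first component's shoulder (< 150 bp)
        peak1 = edges[np.argmax(hist[:11])]
        peak2 = edges[13 + np.argmax(hist[13:])]
        assert abs(peak1 - 80) < 30 and abs(peak2 - 200) < 40


class TestSequences:
    def test_no_planting_when_prob_zero(self):
        config = _mini_config(motif_plant_prob={})
        _, truth = sim.simulate_counts(config)
        sim.simulate_sequences(config, truth, default_motif())
        assert not truth.peaks["motif_planted"].any()

    def test_prob_one_plants_consensus_everywhere(self):
        from dimorphatac.motif import reverse_complement
        config = _mini_config(motif_plant_prob={"FruM_closed": 1.0})
        _, truth = sim.simulate_counts(config)
        records = sim.simulate_sequences(config, truth, default_motif())
        cons = default_motif().consensus
        closed = truth.peaks["peak_class"] == "FruM_closed"
        for (header, seq), is_closed in zip(records, closed):
            if is_closed:
                assert cons in seq or reverse_complement(cons) in seq

    def test_planting_frequency_within_binomial_ci(self):
        prob = 0.3
        config = sim.SimulationConfig(
            seed=4, n_peaks_per_chrom=700, n_open_planted=0,
            n_closed_planted=0, motif_plant_prob={"unchanged": prob})
        _, truth = sim.simulate_counts(config)
        sim.simulate_sequences(config, truth, default_motif())
        n = (truth.peaks["peak_class"] == "unchanged").sum()
        k = truth.peaks["motif_planted"].sum()
        lo, hi = stats.binom.interval(0.99, n, prob)
        assert lo <= k <= hi


class TestDeterminism:
    def test_same_seed_identical_outputs(self):
        config = _mini_config(seed=77)
        a_cm, a_truth = sim.simulate_counts(config)
        b_cm, b_truth = sim.simulate_counts(_mini_config(seed=77))
        np.testing.assert_array_equal(a_cm.counts, b_cm.counts)
        pd.testing.assert_frame_equal(a_truth.peaks, b_truth.peaks)
        fa = sim.simulate_fragments(config, a_cm)
        fb = sim.simulate_fragments(config, b_cm)
        for sid in fa:
            pd.testing.assert_frame_equal(fa[sid], fb[sid])

    def test_different_seed_differs(self):
        a, _ = sim.simulate_counts(_mini_config(seed=1))
        b, _ = sim.simulate_counts(_mini_config(seed=2))
        assert (a.counts != b.counts).any()


class TestExpression:
    def test_female_bias_applied(self):
        counts, sheet = sim.simulate_expression(
            n_genes=400, seed=0, baseline_mu=300,
            female_biased_genes=list(range(200)), delta_expr=1.0)
        f_ids = sheet.loc[sheet["condition"].str.startswith("female"), "sample_id"]
        m_ids = sheet.loc[sheet["condition"].str.startswith("male"), "sample_id"]
        f = counts[list(f_ids)].mean(axis=1)
        m = counts[list(m_ids)].mean(axis=1)
        lfc = np.log2((f + 1) / (m + 1))
        assert lfc[:200].mean() > lfc[200:].mean() + 0.5
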