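"""Conditional per-SNP effects, bin machinery, empirical p, Stouffer meta."""

import numpy as np
import pytest
from scipy import stats

import duopgs
from duopgs import BinSpec, conditional_betas, empirical_p, meta_p, observed_bin_means
from duopgs.deviation import DeviationResult, simulate_null
from duopgs.phenotype import ZScoreTable


def ztable(z):
    return ZScoreTable(
        individual_id=np.array([f"i{k}" for k in range(len(z))], dtype=object),
        bw_z=np.asarray(z, dtype=float),
        method="within_cohort_residual",
    )


class TestBinSpec:
    def test_ten_percent_lower_bins(self):
        b = BinSpec(10, "lower")
        assert b.n_bins == 10
        np.testing.assert_allclose(b.edges, np.linspace(0, 1, 11))
        assert b.labels[0] == "0-10%"

    def test_three_percent_upper_anchoring(self):
        b = BinSpec(3, "upper")
        assert b.labels[-1] == "97-100%"
        assert "88-91%" in b.labels
        assert b.labels[0] == "0-1%"  # short remainder at the bottom

    def test_three_percent_lower_anchoring(self):
        b = BinSpec(3, "lower")
        assert b.labels[0] == "0-3%"
        assert b.labels[1] == "3-6%"
        assert b.labels[-1] == "99-100%"

    def test_counts_partition_n(self):
        b = BinSpec(3, "lower")
        counts = b.counts(5000)
        assert counts.sum() == 5000
        assert counts[0] == 150

    def test_empty_bin_rejected(self):
        with pytest.raises(ValueError, match="bin"):
            BinSpec(3, "lower").assign(np.arange(10.0))

    def test_assignment_is_rank_based(self):
        b = BinSpec(10, "lower")
        vals = np.arange(100.0)[::-1]  # descending input
        idx = b.assign(vals)
        assert idx[-1] == 0  # smallest value in lowest bin
        assert idx[0] == 9


class TestConditionalBetas:
    def test_recovers_generative_fetal_effects(self, term_cohort, zscores, panel):
        cb = conditional_betas(term_cohort, zscores, member="fetal")
        se_approx = 1.0 / np.sqrt(
            term_cohort.n * 2 * panel.freq * (1 - panel.freq) * 0.75
        )
        within = np.abs(cb.beta_cond - panel.true_beta_fetal) <= 3 * se_approx
        assert within.mean() >= 0.9

    def test_null_phenotype_gives_null_betas(self, term_cohort):
        rng = np.random.default_rng(0)
        z = ztable(rng.normal(size=term_cohort.n))
        cb = conditional_betas(term_cohort, z, member="fetal")
        se_approx = 1.0 / np.sqrt(term_cohort.n * 2 * cb.freq_obs * (1 - cb.freq_obs))
        assert (np.abs(cb.beta_cond) <= 3 * se_approx).mean() >= 0.9

    def test_var_explained_plugin_formula(self):
        cb = duopgs.ConditionalBetas(
            variant_id=["a"], beta_cond=[0.1], freq_obs=[0.5], member="fetal"
        )
        assert cb.var_explained[0] == pytest.approx(2 * 0.25 * 0.01)
        assert cb.total_var == pytest.approx(0.005)

    def test_child_only_cohort_rejected(self, term_cohort, zscores):
        solo = duopgs.DuoCohort(
            cohort_id="solo", g_fetal=term_cohort.g_fetal, g_maternal=None,
            phenotypes=term_cohort.phenotypes,
        )
        with pytest.raises(ValueError, match="both"):
            conditional_betas(solo, zscores)

    def test_monomorphic_snp_warns_and_zeroes(self, term_cohort, zscores):
        g_f = term_cohort.g_fetal.copy()
        g_f[:, 0] = 2.0
        mono = duopgs.DuoCohort(
            cohort_id="m", g_fetal=g_f, g_maternal=term_cohort.g_maternal,
            phenotypes=term_cohort.phenotypes,
        )
        with pytest.warns(UserWarning, match="monomorphic"):
            cb = conditional_betas(mono, zscores, member="fetal")
        assert cb.beta_cond[0] == 0.0
        assert cb.var_explained[0] == 0.0


class TestObservedBinMeans:
    def test_independent_score_has_flat_bins(self):
        rng = np.random.default_rng(1)
        n = 20_000
        means = observed_bin_means(rng.normal(size=n), ztable(rng.normal(size=n)),
                                   BinSpec(10))
        assert np.all(np.abs(means) < 4 / np.sqrt(n / 10))

    def test_score_equal_to_phenotype_gives_truncated_normal_means(self):
        # lowest decile of a standard normal has mean -phi(1.2816)/0.1 = -1.755
        rng = np.random.default_rng(2)
        z = rng.standard_normal(50_000)
        means = observed_bin_means(z.copy(), ztable(z), BinSpec(10))
        q = stats.norm.ppf(0.1)
        expected = -stats.norm.pdf(q) / 0.1
        assert means[0] == pytest.approx(expected, abs=0.03)
        assert means[-1] == pytest.approx(-expected, abs=0.03)

    def test_count_weighted_mean_is_zero(self):
        rng = np.random.default_rng(3)
        n = 5000
        s = rng.normal(size=n)
        z = rng.normal(size=n)
        bins = BinSpec(3, "lower")
        means = observed_bin_means(s, ztable(z), bins)
        counts = bins.counts(n)
        assert np.sum(means * counts) / n == pytest.approx(0.0, abs=1e-10)

    def test_scale_invariance(self):
        rng = np.random.default_rng(4)
        s = rng.normal(size=1000)
        z = ztable(rng.normal(size=1000))
        a = observed_bin_means(s, z, BinSpec(10))
        b = observed_bin_means(5 * s + 3, z, BinSpec(10))
        np.testing.assert_allclose(a, b, atol=1e-9)


class TestSimulateNull:
    def test_zero_betas_give_flat_null(self):
        cb = duopgs.ConditionalBetas(
            variant_id=[f"v{i}" for i in range(5)],
            beta_cond=np.zeros(5), freq_obs=np.full(5, 0.3), member="fetal",
        )
        null = simulate_null(cb, 500, n_sims=200, bins=BinSpec(10), seed=1)
        assert abs(null.mean()) < 0.02
        assert null.shape == (200, 10)

    def test_single_large_snp_gives_monotone_bin_means(self):
        cb = duopgs.ConditionalBetas(
            variant_id=["v"], beta_cond=[0.9], freq_obs=[0.5], member="fetal"
        )
        null = simulate_null(cb, 4000, n_sims=100, bins=BinSpec(10), seed=2)
        avg = null.mean(axis=0)
        assert np.all(np.diff(avg) > 0)

    def test_excess_variance_rejected(self):
        cb = duopgs.ConditionalBetas(
            variant_id=["v"], beta_cond=[1.5], freq_obs=[0.5], member="fetal"
        )
        with pytest.raises(ValueError, match="variance"):
            simulate_null(cb, 100, n_sims=10, seed=3)

    def test_fixed_seed_bit_identical_and_chunk_invariant(self, term_cohort, zscores):
        cb = conditional_betas(term_cohort, zscores)
        a = simulate_null(cb, 300, n_sims=100, bins=BinSpec(10), seed=9)
        b = simulate_null(cb, 300, n_sims=100, bins=BinSpec(10), seed=9)
        np.testing.assert_array_equal(a, b)


class TestEmpiricalP:
    @staticmethod
    def results(observed, null, **kw):
        return empirical_p(np.atleast_1d(observed), null, BinSpec(50, "lower"), **kw)

    def test_observed_at_null_median_has_p_one(self):
        null = np.linspace(-1, 1, 201)[:, None].repeat(2, axis=1)
        res = self.results([0.0, 0.0], null)
        assert res[0].p_emp == pytest.approx(1.0)

    def test_observed_beyond_all_nulls(self):
        rng = np.random.default_rng(5)
        null = rng.normal(size=(500, 2))
        res = self.results([99.0, -99.0], null)
        assert res[0].p_emp == pytest.approx(2 / 501)
        assert res[1].p_emp == pytest.approx(2 / 501)

    def test_one_sided_upper_tail(self):
        null = np.linspace(0, 1, 99)[:, None].repeat(2, axis=1)
        res = self.results([2.0, -1.0], null, two_sided=False)
        assert res[0].p_emp == pytest.approx(1 / 100)
        assert res[1].p_emp == pytest.approx(1.0)

    def test_invariant_to_monotone_rescaling(self):
        rng = np.random.default_rng(6)
        null = rng.normal(size=(400, 2))
        obs = np.array([0.7, -0.4])
        a = self.results(obs, null)
        b = self.results(np.exp(obs), np.exp(null))
        assert [r.p_emp for r in a] == [r.p_emp for r in b]

    def test_envelope_brackets_null_mean(self):
        rng = np.random.default_rng(7)
        null = rng.normal(size=(1000, 2))
        for r in self.results([0.1, 0.2], null):
            assert r.null_lo95 <= r.null_mean <= r.null_hi95


def dev_result(p, obs, null_mean, n_sims=999, label="0-10%"):
    lo, hi = null_mean - 1, null_mean + 1
    return DeviationResult(
        bin_label=label, observed_mean=obs, null_mean=null_mean,
        null_lo95=lo, null_hi95=hi, p_emp=p, n_sims=n_sims, n=1000,
    )


class TestMetaP:
    def test_concordant_cohorts_strengthen_evidence(self):
        res = [[dev_result(0.05, 1.0, 0.0)], [dev_result(0.05, 1.0, 0.0)]]
        out = meta_p(res, [1000, 1000])
        assert out["p_combined"][0] < 0.05

    def test_opposite_directions_cancel(self):
        res = [[dev_result(0.05, 1.0, 0.0)], [dev_result(0.05, -1.0, 0.0)]]
        out = meta_p(res, [1000, 1000])
        assert out["p_combined"][0] == pytest.approx(1.0)

    def test_single_cohort_is_identity(self):
        res = [[dev_result(0.04, 1.0, 0.0)]]
        out = meta_p(res, [500])
        assert out["p_combined"][0] == pytest.approx(0.04, rel=1e-9)

    def test_mismatched_bins_rejected(self):
        res = [[dev_result(0.5, 0.1, 0.0, label="0-10%")],
               [dev_result(0.5, 0.1, 0.0, label="0-3%")]]
        with pytest.raises(ValueError, match="bin"):
            meta_p(res, [100, 100])


class TestEndToEnd:
    def test_contaminated_lowest_bin_mean_sits_above_null(self, panel):
        # an environmental deficit drags genetically ordinary babies into
        # the smallest bin, so its mean score exceeds the additive-model null
        import copy

        p = copy.deepcopy(panel)
        p.true_beta_maternal = np.zeros(p.n_snps)
        spec = duopgs.ContaminationSpec(
            mode="environmental", fraction=0.10, shift_sd=2.5
        )
        cohort = duopgs.generate_cohort(p, n=8000, seed=77, contamination=spec)
        z = duopgs.zscore_within_cohort(cohort.phenotypes)
        res = duopgs.run_deviation_test(
            cohort, z, member="fetal", bins=BinSpec(3), n_sims=400, seed=78
        )
        assert res[0].observed_mean > res[0].null_mean

    def test_envelope_plot_renders(self, term_cohort, zscores):
        import matplotlib

        matplotlib.use("Agg")
        res = duopgs.run_deviation_test(
            term_cohort, zscores, member="fetal", bins=BinSpec(10),
            n_sims=120, seed=4,
        )
        ax = duopgs.plot_deviation(res, title="fetal")
        assert len(ax.lines) == 4
        assert ax.get_title() == "fetal"

    def test_rerun_with_same_seed_reproduces_p(self, term_cohort, zscores):
        kw = dict(member="fetal", bins=BinSpec(10), n_sims=150, seed=5)
        a = duopgs.run_deviation_test(term_cohort, zscores, **kw)
        b = duopgs.run_deviation_test(term_cohort, zscores, **kw)
        assert [r.p_emp for r in a] == [r.p_emp for r in b]
        assert [r.observed_mean for r in a] == [r.observed_mean for r in b]
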