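"""Logistic association fits, joint duo models, fixed-effect meta-analysis.

The toy-data fit is cross-checked against an independent maximum-likelihood
oracle (direct minimisation of the negative log-likelihood with scipy),
keeping the statsmodels route and the oracle separate.
"""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

import duopgs
from duopgs import fit_joint, fit_logistic, fit_secondary, meta_fixed
from duopgs.association import AssocResult, SeparationError
from duopgs.phenotype import OutcomeLabels
from duopgs.scores import ScoreSet


def labels_from_y(y, control_scheme="complement", outcome="SGA"):
    lab = np.where(np.asarray(y) == 1, outcome, "AGA").astype(object)
    return OutcomeLabels(
        individual_id=[f"i{k}" for k in range(len(lab))],
        label=lab,
        control_scheme=control_scheme,
    )


def scoreset(values, role="fetal", deciles=None):
    values = np.asarray(values, dtype=float)
    return ScoreSet(
        individual_id=[f"i{k}" for k in range(len(values))],
        score=values,
        score_role=role,
        decile=deciles,
    )


def nll_logistic(coef, y, X):
    eta = X @ coef
    return float(np.sum(np.logaddexp(0.0, eta)) - y @ eta)


# 20-row toy dataset: decile exposure and outcome fixed once
TOY_DECILES = np.array([1, 2, 3, 4, 5, 6, 7, 8, 9, 10] * 2)
TOY_Y = np.array([1, 1, 0, 1, 0, 0, 1, 0, 0, 0, 1, 0, 1, 0, 0, 1, 0, 0, 0, 0])


class TestFitLogistic:
    def test_toy_fit_matches_brute_force_mle(self):
        ss = scoreset(TOY_DECILES.astype(float), deciles=TOY_DECILES)
        res = fit_logistic(labels_from_y(TOY_Y), ss, "SGA")
        X = np.column_stack([np.ones(20), TOY_DECILES.astype(float)])
        opt = optimize.minimize(
            nll_logistic, x0=[0.0, 0.0], args=(TOY_Y, X), method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 10_000},
        )
        assert res.beta == pytest.approx(opt.x[1], abs=1e-6)

    def test_null_exposure_gives_or_near_one(self):
        rng = np.random.default_rng(0)
        n = 5000
        y = rng.random(n) < 0.1
        dec = rng.integers(1, 11, size=n)
        res = fit_logistic(
            labels_from_y(y.astype(int)), scoreset(dec, deciles=dec), "SGA"
        )
        assert abs(res.beta) <= 3 * res.se

    def test_doubling_exposure_scale_halves_beta(self):
        rng = np.random.default_rng(1)
        n = 2000
        x = rng.integers(1, 11, size=n).astype(float)
        y = (rng.random(n) < 1 / (1 + np.exp(-(-2 + 0.2 * x)))).astype(int)
        res1 = fit_logistic(labels_from_y(y), scoreset(x), "SGA", use_deciles=False)
        res2 = fit_logistic(
            labels_from_y(y), scoreset(2 * x), "SGA", use_deciles=False
        )
        assert res2.beta == pytest.approx(res1.beta / 2, rel=1e-6)
        assert res2.se == pytest.approx(res1.se / 2, rel=1e-6)

    def test_complete_separation_raises(self):
        x = np.arange(1.0, 21.0)
        y = (x > 10).astype(int)
        with pytest.raises(SeparationError):
            fit_logistic(labels_from_y(y), scoreset(x), "SGA", use_deciles=False)

    def test_constant_exposure_rejected(self):
        y = np.array([0, 1] * 10)
        with pytest.raises(ValueError, match="constant"):
            fit_logistic(labels_from_y(y), scoreset(np.full(20, 5.0)), "SGA",
                         use_deciles=False)

    def test_constant_covariate_dropped_with_warning(self):
        rng = np.random.default_rng(2)
        n = 400
        y = (rng.random(n) < 0.2).astype(int)
        x = rng.integers(1, 11, size=n).astype(float)
        phen = pd.DataFrame(
            {"sex": ["male"] * n, "gestational_age_wk": rng.integers(37, 43, n)}
        )
        with pytest.warns(UserWarning, match="sex"):
            res = fit_logistic(
                labels_from_y(y), scoreset(x), "SGA", phenotypes=phen,
                covariates=["sex", "gestational_age"], use_deciles=False,
            )
        assert res.adjusted_for == ["gestational_age"]

    def test_result_derived_fields_consistent(self):
        res = AssocResult("fetal", "SGA", "C", beta=0.2, se=0.1,
                          n_cases=10, n_controls=90)
        assert res.or_ == pytest.approx(np.exp(0.2))
        assert res.ci_low == pytest.approx(np.exp(0.2 - 1.96 * 0.1))
        assert res.ci_high == pytest.approx(np.exp(0.2 + 1.96 * 0.1))
        assert res.p == pytest.approx(2 * stats.norm.sf(2.0))


class TestFitJoint:
    def test_independent_exposures_match_marginal_fits(self):
        rng = np.random.default_rng(3)
        n = 8000
        xf = rng.integers(1, 11, size=n).astype(float)
        xm = rng.integers(1, 11, size=n).astype(float)
        eta = -2.5 + 0.15 * xf
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
        lab = labels_from_y(y)
        rf, rm = fit_joint(
            lab, scoreset(xf, "fetal"), scoreset(xm, "maternal"), "SGA",
            use_deciles=False,
        )
        marg = fit_logistic(lab, scoreset(xf, "fetal"), "SGA", use_deciles=False)
        assert rf.beta == pytest.approx(marg.beta, abs=3 * marg.se)
        assert abs(rm.beta) <= 3 * rm.se
        assert rf.adjusted_for == ["maternal_gs"]

    def test_duplicated_exposure_is_collinear(self):
        y = np.array([0, 1] * 20)
        x = np.arange(40.0)
        with pytest.raises(ValueError, match="rank deficient"):
            fit_joint(
                labels_from_y(y), scoreset(x, "fetal"), scoreset(x, "maternal"),
                "SGA", use_deciles=False,
            )

    def test_simulated_fetal_only_effect_leaves_maternal_null(self, panel):
        # generative ground truth: phenotype built from fetal effects only
        import copy

        p = copy.deepcopy(panel)
        p.true_beta_maternal = np.zeros(p.n_snps)
        p.w_maternal = p.w_fetal.copy()
        cohort = duopgs.generate_cohort(p, n=6000, seed=19)
        z = duopgs.zscore_within_cohort(cohort.phenotypes)
        lab = duopgs.classify(z)
        sf = duopgs.to_deciles(duopgs.compute_gs(cohort.g_fetal, p, "fetal"))
        sm = duopgs.to_deciles(duopgs.compute_gs(cohort.g_maternal, p, "maternal"))
        rf, rm = fit_joint(lab, sf, sm, "SGA")
        assert rf.beta < 0  # higher fetal score protects against SGA
        assert abs(rm.beta) <= 3 * rm.se


class TestFitSecondary:
    def test_maternal_environment_effect_raises_sga_odds(self):
        # maternal exposure score lowers bw_z: SGA odds rise per decile,
        # the direction reported for blood-pressure scores
        rng = np.random.default_rng(4)
        n = 12_000
        sbp = rng.normal(size=n)
        fetal = rng.normal(size=n)
        bw_z = -0.15 * sbp + 0.2 * fetal + rng.normal(0, 0.97, n)
        y = (bw_z <= -1.28).astype(int)
        phen = pd.DataFrame(
            {
                "sex": np.where(rng.random(n) < 0.5, "male", "female"),
                "gestational_age_wk": rng.integers(37, 43, n),
            }
        )
        res = fit_secondary(
            labels_from_y(y),
            duopgs.to_deciles(scoreset(sbp, "sbp")),
            duopgs.to_deciles(scoreset(fetal, "fetal")),
            "SGA",
            phenotypes=phen,
        )
        assert res.beta > 0
        assert res.beta / res.se > 3
        assert set(res.adjusted_for) == {"fetal_gs", "sex", "gestational_age"}

    def test_null_secondary_score_is_flat(self):
        rng = np.random.default_rng(5)
        n = 6000
        fg = rng.normal(size=n)
        fetal = rng.normal(size=n)
        y = (rng.random(n) < 0.1).astype(int)
        phen = pd.DataFrame(
            {
                "sex": np.where(rng.random(n) < 0.5, "male", "female"),
                "gestational_age_wk": rng.integers(37, 43, n),
            }
        )
        res = fit_secondary(
            labels_from_y(y),
            duopgs.to_deciles(scoreset(fg, "fg")),
            duopgs.to_deciles(scoreset(fetal, "fetal")),
            "SGA",
            phenotypes=phen,
        )
        assert abs(res.beta) <= 3 * res.se


def assoc(beta, se, role="fetal", outcome="SGA", cohort="C"):
    return AssocResult(role, outcome, cohort, beta=beta, se=se,
                       n_cases=50, n_controls=450)


class TestMetaFixed:
    def test_identical_studies_pool_exactly(self):
        m = meta_fixed([assoc(0.2, 0.1), assoc(0.2, 0.1)])
        assert m.pooled_beta == pytest.approx(0.2)
        assert m.pooled_se == pytest.approx(0.1 / np.sqrt(2))
        assert m.q_stat == pytest.approx(0.0, abs=1e-12)

    def test_worked_two_study_example(self):
        # (0.1, 0.1) and (0.3, 0.1): pooled 0.2, Q = 2, df 1, q_p = 0.157
        m = meta_fixed([assoc(0.1, 0.1), assoc(0.3, 0.1)])
        assert m.pooled_beta == pytest.approx(0.2)
        assert m.q_stat == pytest.approx(2.0)
        assert m.q_df == 1
        assert m.q_p == pytest.approx(stats.chi2.sf(2.0, 1), rel=1e-9)
        assert m.q_p == pytest.approx(0.157, abs=0.001)

    def test_infinite_se_study_has_zero_weight(self):
        m = meta_fixed([assoc(0.4, 0.2), assoc(9.9, np.inf)])
        assert m.pooled_beta == pytest.approx(0.4)
        assert m.pooled_se == pytest.approx(0.2)

    def test_pooled_se_never_exceeds_study_ses(self):
        rng = np.random.default_rng(6)
        studies = [assoc(rng.normal(), rng.uniform(0.05, 0.5)) for _ in range(5)]
        m = meta_fixed(studies)
        assert m.pooled_se <= min(s.se for s in studies)
        assert m.q_df == 4

    def test_mismatched_outcomes_rejected(self):
        with pytest.raises(ValueError, match="outcome"):
            meta_fixed([assoc(0.1, 0.1, outcome="SGA"), assoc(0.1, 0.1, outcome="LGA")])

    def test_single_study_rejected(self):
        with pytest.raises(ValueError, match="2"):
            meta_fixed([assoc(0.1, 0.1)])

    def test_split_cohort_meta_approximates_single_fit(self):
        rng = np.random.default_rng(7)
        n = 12_000
        x = rng.integers(1, 11, size=n).astype(float)
        y = (rng.random(n) < 1 / (1 + np.exp(-(-2.3 + 0.12 * x)))).astype(int)
        whole = fit_logistic(labels_from_y(y), scoreset(x), "SGA", use_deciles=False)
        parts = []
        for k in range(3):
            sl = slice(k * 4000, (k + 1) * 4000)
            parts.append(
                fit_logistic(
                    labels_from_y(y[sl]), scoreset(x[sl]), "SGA", use_deciles=False,
                    cohort_id=f"part{k}",
                )
            )
        m = meta_fixed(parts)
        assert m.pooled_beta == pytest.approx(whole.beta, abs=2 * whole.se)
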