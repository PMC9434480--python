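"""Phenotype derivation, regression models, suite grid, polychorics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from liabsem import assoc
from liabsem.assoc import (
    AssocError,
    derive_phenotypes,
    fit_logistic,
    fit_ordinal,
    polychoric_correlation,
    run_association_suite,
)


class TestDerivePhenotypes:
    def test_threshold_rules_on_boundaries(self):
        raw = pd.DataFrame(
            {
                "badds_p": [9, 10, 40, 40],
                "badds_i": [np.nan, 19, 20, np.nan],
                "badds_m": [10, 10, 10, 10],
                "badds_d": [10, 10, 10, 10],
            }
        )
        out = derive_phenotypes(raw)
        assert list(out["psychosis"]) == [0, 1, 1, 1]
        assert np.isnan(out["mips"].iloc[0])       # not psychotic, not rated
        assert out["mips"].iloc[1] == 0            # badds_i 19 < 20
        assert out["mips"].iloc[2] == 1            # badds_i 20 >= 20
        assert np.isnan(out["mips"].iloc[3])       # psychotic but unrated

    def test_inconsistent_rating_flagged_and_excluded(self):
        raw = pd.DataFrame(
            {"badds_p": [5], "badds_i": [25], "badds_m": [10], "badds_d": [10]}
        )
        out = derive_phenotypes(raw)
        assert out["mips_inconsistent"].iloc[0]
        assert np.isnan(out["mips"].iloc[0])

    def test_ordinal_scales_passed_through(self):
        raw = pd.DataFrame(
            {"badds_p": [15], "badds_i": [20], "badds_m": [30], "badds_d": [40]}
        )
        out = derive_phenotypes(raw)
        assert out["badds_m"].iloc[0] == 30
        assert out["badds_d"].iloc[0] == 40


def _covariates(rng, n):
    return pd.DataFrame({"age": rng.normal(46, 12, n), "pc1": rng.normal(size=n)})


class TestFitLogistic:
    def test_forward_simulation_recovery(self, rng):
        n, beta = 4000, 0.3
        prs = pd.Series(rng.normal(size=n))
        y = rng.random(n) < 1 / (1 + np.exp(-(0.2 + beta * prs)))
        res = fit_logistic(pd.Series(y.astype(float)), prs, _covariates(rng, n))
        assert res.beta == pytest.approx(beta, abs=0.1)
        assert res.ci_low < res.beta < res.ci_high

    def test_permutation_null_p_uniform(self, rng):
        n = 400
        y = pd.Series((rng.random(n) < 0.4).astype(float))
        cov = _covariates(rng, n)
        pvals = []
        for _ in range(200):
            prs = pd.Series(rng.normal(size=n))
            pvals.append(fit_logistic(y, prs, cov).p)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_constant_predictor_fatal(self, rng):
        n = 200
        y = pd.Series((rng.random(n) < 0.5).astype(float))
        with pytest.raises(AssocError, match="collinear"):
            fit_logistic(y, pd.Series(np.ones(n)), _covariates(rng, n))

    def test_one_class_outcome_fatal(self, rng):
        n = 100
        with pytest.raises(AssocError):
            fit_logistic(pd.Series(np.ones(n)), pd.Series(rng.normal(size=n)),
                         _covariates(rng, n))


class TestFitOrdinal:
    def test_two_categories_reduce_to_logistic(self, rng):
        n = 1500
        prs = pd.Series(rng.normal(size=n))
        cov = _covariates(rng, n)
        y = pd.Series((rng.random(n) < 1 / (1 + np.exp(-0.4 * prs))).astype(int))
        lo = fit_logistic(y.astype(float), prs, cov)
        od = fit_ordinal(y, prs, cov)
        assert od.beta == pytest.approx(lo.beta, abs=1e-8)
        assert od.p == pytest.approx(lo.p, rel=1e-4)

    def test_latent_variable_recovery(self, rng):
        n, slope = 4000, 0.25
        prs = pd.Series(rng.normal(size=n))
        latent = slope * prs + rng.logistic(size=n)
        y = pd.Series(np.digitize(latent, [-1.5, -0.3, 0.8, 2.0]))
        res = fit_ordinal(y, prs, _covariates(rng, n))
        assert res.beta == pytest.approx(slope, abs=0.1)

    def test_null_p_uniform_across_replicates(self, rng):
        n = 400
        cov = _covariates(rng, n)
        pvals = []
        for _ in range(100):
            prs = pd.Series(rng.normal(size=n))
            y = pd.Series(rng.integers(0, 4, size=n))
            pvals.append(fit_ordinal(y, prs, cov).p)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_single_category_fatal(self, rng):
        n = 100
        with pytest.raises(AssocError):
            fit_ordinal(pd.Series(np.ones(n, int)), pd.Series(rng.normal(size=n)),
                        _covariates(rng, n))


def _null_cohort(rng, n=900):
    """Cohort whose symptoms are independent of all PRS columns."""
    badds_p = rng.choice([0, 5, 15, 30, 50], size=n)
    cohort = pd.DataFrame(
        {
            "individual_id": [f"I{i}" for i in range(n)],
            "badds_p": badds_p,
            "badds_i": np.where(badds_p >= 10, rng.choice([0, 10, 20, 30], n), np.nan),
            "badds_m": rng.choice([10, 20, 30, 40, 50], size=n),
            "badds_d": rng.choice([10, 20, 30, 40, 50], size=n),
            "diagnosis_subtype": rng.choice(
                ["BD-I", "BD-II", "SAB", "other"], size=n, p=[0.6, 0.25, 0.1, 0.05]
            ),
            "age_at_interview": rng.normal(46, 12, n),
            "platform": rng.choice(["chipA", "chipB"], size=n),
        }
    )
    for i in range(1, 11):
        cohort[f"pc{i}"] = rng.normal(size=n)
    for comp in assoc.PRS_COMPONENTS:
        cohort[comp] = rng.normal(size=n)
    return derive_phenotypes(cohort)


class TestSuite:
    def test_grid_is_complete(self, rng):
        suite = run_association_suite(_null_cohort(rng))
        # 8 model kinds x 4 components x 2 subsets
        assert len(suite) == 64
        assert (suite["status"] == "ok").all()
        cells = suite.groupby(["phenotype", "condition", "subset"]).size()
        assert (cells == 4).all()
        assert len(cells) == 16

    def test_mips_models_restricted_to_psychotic(self, rng):
        cohort = _null_cohort(rng)
        suite = run_association_suite(cohort)
        n_psych_rated = int(
            ((cohort["psychosis"] == 1) & cohort["mips"].notna()).sum()
        )
        mips_rows = suite.query("phenotype == 'mips' and subset == 'all'")
        assert (mips_rows["n_used"] == n_psych_rated).all()

    def test_global_null_rejection_rate(self, rng):
        # no genetic symptom effects: ~5% of main+sensitivity models reject
        pvals = []
        for seed in range(3):
            suite = run_association_suite(_null_cohort(np.random.default_rng(seed)))
            ok = suite.query("subset == 'all' and status == 'ok'")
            pvals.extend(ok["p"].tolist())
        frac = np.mean(np.array(pvals) < 0.05)
        n = len(pvals)
        assert frac <= 0.05 + 1.96 * np.sqrt(0.05 * 0.95 / n) + 0.02

    def test_independent_conditioner_leaves_beta_unchanged(self, rng):
        # conditioning on a covariate independent of PRS and outcome
        n = 2000
        prs = pd.Series(rng.normal(size=n))
        cov = _covariates(rng, n)
        y = pd.Series((rng.random(n) < 1 / (1 + np.exp(-0.3 * prs))).astype(float))
        plain = fit_logistic(y, prs, cov)
        extra = cov.copy()
        extra["noise_cond"] = rng.normal(size=n)
        conditioned = fit_logistic(y, prs, extra)
        assert conditioned.beta == pytest.approx(plain.beta, abs=0.05)


class TestPolychoric:
    @staticmethod
    def _cut(x, cuts):
        return np.digitize(x, cuts)

    def test_independence_gives_zero(self, rng):
        n = 6000
        x = self._cut(rng.normal(size=n), [-0.5, 0.5])
        y = self._cut(rng.normal(size=n), [-1.0, 0.0, 1.0])
        rho, _ = polychoric_correlation(x, y, n_boot=0)
        assert rho == pytest.approx(0.0, abs=0.04)

    def test_latent_normal_recovery(self, rng):
        n, true_rho = 4000, 0.61
        cov = np.array([[1, true_rho], [true_rho, 1]])
        lat = rng.multivariate_normal([0, 0], cov, size=n)
        x = self._cut(lat[:, 0], [-0.8, 0.0, 0.9])
        y = self._cut(lat[:, 1], [-0.5, 0.6])
        rho, p = polychoric_correlation(x, y, n_boot=500, seed=1)
        assert rho == pytest.approx(true_rho, abs=0.05)
        assert p < 0.05

    def test_two_by_two_matches_grid_search_oracle(self, rng):
        n, true_rho = 1500, 0.45
        cov = np.array([[1, true_rho], [true_rho, 1]])
        lat = rng.multivariate_normal([0, 0], cov, size=n)
        x = (lat[:, 0] > 0.3).astype(int)
        y = (lat[:, 1] > -0.2).astype(int)
        rho, _ = polychoric_correlation(x, y, n_boot=0)
        # fine-grid likelihood search with scipy's bivariate normal CDF
        from scipy.stats import multivariate_normal, norm

        tab = pd.crosstab(x, y).to_numpy().astype(float)
        a = norm.ppf(tab.sum(1).cumsum()[:-1] / tab.sum())
        b = norm.ppf(tab.sum(0).cumsum()[:-1] / tab.sum())
        grid = np.arange(-0.998, 0.999, 1e-4)
        best, best_ll = 0.0, -np.inf
        for r in grid:
            mvn = multivariate_normal(cov=[[1, r], [r, 1]])
            c = mvn.cdf([a[0], b[0]])
            probs = np.array(
                [
                    [c, norm.cdf(a[0]) - c],
                    [norm.cdf(b[0]) - c,
                     1 - norm.cdf(a[0]) - norm.cdf(b[0]) + c],
                ]
            )
            ll = (tab * np.log(np.clip(probs, 1e-300, None))).sum()
            if ll > best_ll:
                best, best_ll = r, ll
        assert rho == pytest.approx(best, abs=1e-3)

    def test_monotone_relabel_invariance(self, rng):
        n = 2000
        lat = rng.multivariate_normal([0, 0], [[1, 0.4], [0.4, 1]], size=n)
        x = self._cut(lat[:, 0], [-0.5, 0.5])
        y = self._cut(lat[:, 1], [0.0])
        rho1, _ = polychoric_correlation(x, y, n_boot=0)
        relabel = {0: 10, 1: 55, 2: 700}
        rho2, _ = polychoric_correlation([relabel[v] for v in x], y * 9 + 1,
                                         n_boot=0)
        assert rho2 == pytest.approx(rho1, abs=1e-12)

    def test_single_category_fatal(self, rng):
        with pytest.raises(AssocError):
            polychoric_correlation(np.ones(100), rng.integers(0, 3, 100))

    def test_bvn_cdf_matches_scipy(self, rng):
        from scipy.stats import multivariate_normal

        for rho in (-0.8, -0.3, 0.0, 0.45, 0.9):
            h = np.array([-1.5, -0.2, 0.0, 0.7, 2.0])
            k = np.array([-2.0, 0.0, 0.3, 1.1, 0.5])
            ours = assoc._bvn_cdf(h, k, rho)
            mvn = multivariate_normal(cov=[[1, rho], [rho, 1]])
            ref = np.array([mvn.cdf([hi, ki]) for hi, ki in zip(h, k)])
            assert ours == pytest.approx(ref, abs=1e-7)

    def test_cohort_mania_psychosis_correlation(self, full_study, full_result):
        # the psychosis and mania scales correlate positively in the
        # simulated BD cohort; the latent correlation implied by the
        # symptom-weight matrix is the dot product of the two weight rows
        cohort = full_result.cohort
        W = np.asarray(full_study.config.W)
        implied = float(W[0] @ W[2])  # badds_p row . badds_m row
        rho, p = polychoric_correlation(cohort["badds_p"], cohort["badds_m"],
                                        n_boot=200, seed=3)
        assert rho == pytest.approx(implied, abs=0.07)
        assert rho > 0 and p < 0.05


from hypothesis import given, settings
from hypothesis import strategies as st


@settings(derandomize=True, max_examples=60, deadline=None)
@given(
    h=st.floats(min_value=-3, max_value=3, allow_nan=False),
    k=st.floats(min_value=-3, max_value=3, allow_nan=False),
    rho=st.floats(min_value=-0.95, max_value=0.95, allow_nan=False),
)
def test_bvn_cdf_respects_frechet_bounds(h, k, rho):
    """The bivariate normal CDF stays inside the Frechet-Hoeffding bounds."""
    from scipy.stats import norm

    c = float(assoc._bvn_cdf(np.array([h]), np.array([k]), rho)[0])
    lower = max(norm.cdf(h) + norm.cdf(k) - 1.0, 0.0)
    upper = min(norm.cdf(h), norm.cdf(k))
    assert lower - 1e-9 <= c <= upper + 1e-9
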