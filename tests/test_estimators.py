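"""ITT/AT/PP/IV fits and the cluster-robust sandwich."""

import dataclasses

import numpy as np
import pytest
import statsmodels.api as sm
from statsmodels.sandbox.regression.gmm import IV2SLS

from crtsim import (
    cluster_robust_covariance,
    fit_approach,
    fit_at,
    fit_itt,
    fit_iv,
    fit_pp,
)


def _brute_force_sandwich(X, e, clusters, correction):
    """Independent double-loop evaluation of the clustered sandwich."""
    n, k = X.shape
    bread = np.linalg.inv(X.T @ X)
    labels = sorted(set(clusters.tolist()))
    meat = np.zeros((k, k))
    for g in labels:
        s = np.zeros(k)
        for i in range(n):
            if clusters[i] == g:
                s += X[i] * e[i]
        meat += np.outer(s, s)
    c = 1.0
    if correction == "CR1":
        G = len(labels)
        c = G / (G - 1) * (n - 1) / (n - k)
    return c * bread @ meat @ bread


class TestClusterRobustCovariance:
    # small printed fixture: 3 clusters x 2 subjects
    FIXTURE_X = np.array(
        [[1.0, 0.5], [1.0, -1.2], [1.0, 0.3], [1.0, 2.0], [1.0, -0.7], [1.0, 0.1]]
    )
    FIXTURE_E = np.array([0.3, -0.4, 1.1, -0.2, 0.05, -0.8])
    FIXTURE_G = np.array([0, 0, 1, 1, 2, 2])

    @pytest.mark.parametrize("correction", ["CR1", "none"])
    def test_equals_brute_force_on_fixture(self, correction):
        got = cluster_robust_covariance(
            self.FIXTURE_X, self.FIXTURE_E, self.FIXTURE_G, correction
        )
        want = _brute_force_sandwich(
            self.FIXTURE_X, self.FIXTURE_E, self.FIXTURE_G, correction
        )
        assert got == pytest.approx(want, abs=1e-10)

    def test_single_subject_clusters_reduce_to_hc1(self):
        rng = np.random.default_rng(4)
        n = 60
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        y = X @ [1.0, 0.5] + rng.standard_normal(n) * (1 + np.abs(X[:, 1]))
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        e = y - X @ beta
        got = cluster_robust_covariance(X, e, np.arange(n), "CR1")
        hc1 = sm.OLS(y, X).fit(cov_type="HC1").cov_params()
        assert got == pytest.approx(np.asarray(hc1), rel=1e-10)

    def test_matches_statsmodels_clustered_ols(self):
        rng = np.random.default_rng(5)
        clusters = np.repeat(np.arange(25), 4)
        X = np.column_stack([np.ones(100), rng.standard_normal(100)])
        y = X @ [0.3, 1.2] + rng.standard_normal(25)[clusters] + rng.standard_normal(100)
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        e = y - X @ beta
        got = cluster_robust_covariance(X, e, clusters, "CR1")
        ref = sm.OLS(y, X).fit(
            cov_type="cluster", cov_kwds={"groups": clusters}
        ).cov_params()
        assert got == pytest.approx(np.asarray(ref), rel=1e-8)

    def test_agrees_with_classical_ols_under_homoskedasticity(self):
        rng = np.random.default_rng(6)
        n = 20000
        clusters = np.repeat(np.arange(n // 4), 4)
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        y = X @ [0.0, 1.0] + rng.standard_normal(n)
        fit = sm.OLS(y, X).fit()
        got = cluster_robust_covariance(X, fit.resid, clusters, "CR1")
        classical = np.asarray(fit.cov_params())
        assert np.abs(np.diag(got) / np.diag(classical) - 1).max() < 0.1

    def test_rank_deficient_design_raises(self):
        X = np.ones((6, 2))
        with pytest.raises(np.linalg.LinAlgError):
            cluster_robust_covariance(X, np.ones(6), self.FIXTURE_G)

    def test_unknown_correction_rejected(self):
        with pytest.raises(ValueError):
            cluster_robust_covariance(
                self.FIXTURE_X, self.FIXTURE_E, self.FIXTURE_G, "CR7"
            )


class TestFullComplianceIdentities:
    def test_itt_at_pp_coincide_and_iv_matches(self, make_trial):
        data = make_trial(pbar=0.0, n2=80)  # even number of clusters
        itt = fit_itt(data, with_covariate=False)
        at = fit_at(data, with_covariate=False)
        pp = fit_pp(data, with_covariate=False)
        iv = fit_iv(data, with_covariate=False)
        assert itt.estimate == at.estimate == pp.estimate
        assert itt.se == at.se == pp.se
        assert iv.estimate == pytest.approx(itt.estimate, abs=1e-8)

    def test_iv_equals_ols_of_outcome_on_assignment(self, make_trial):
        data = make_trial(pbar=0.0)
        iv = fit_iv(data, with_covariate=False)
        design = np.column_stack([np.ones(data.n_subjects), data.Z])
        ols = np.linalg.lstsq(design, data.Y, rcond=None)[0]
        assert iv.estimate == pytest.approx(ols[1], abs=1e-10)


class TestMixedModelApproaches:
    def test_itt_never_reads_compliance_status(self, make_trial):
        data = make_trial(level="subject", pbar=0.4)
        rng = np.random.default_rng(8)
        shuffled = dataclasses.replace(
            data, C=rng.permutation(data.C), D=rng.permutation(data.D)
        )
        for with_cov in (True, False):
            a = fit_itt(data, with_cov)
            b = fit_itt(shuffled, with_cov)
            assert a.estimate == b.estimate
            assert a.se == b.se

    def test_covariate_flag_changes_design_not_sample(self, make_trial):
        data = make_trial(level="subject", pbar=0.3)
        for fitter in (fit_itt, fit_at, fit_pp):
            with_x = fitter(data, True)
            without_x = fitter(data, False)
            assert with_x.n_subjects_used == without_x.n_subjects_used
            assert with_x.n_clusters_used == without_x.n_clusters_used

    def test_pp_cluster_level_drops_whole_clusters(self, make_trial):
        data = make_trial(level="cluster", pbar=0.4)
        n1 = data.condition.design.n1
        pp = fit_pp(data, True)
        excluded = data.n_subjects - pp.n_subjects_used
        assert excluded > 0
        assert excluded % n1 == 0
        assert pp.n_clusters_used == data.n_clusters - excluded // n1

    def test_pp_subject_level_exclusion_rate_matches_never_taker_rate(self, make_trial):
        data = make_trial(level="subject", pbar=0.3, n2=400)
        pp = fit_pp(data, True)
        n_treated = int((data.Z == 1).sum())
        excluded = data.n_subjects - pp.n_subjects_used
        assert excluded / n_treated == pytest.approx(0.3, abs=0.03)

    def test_pp_flags_nonconvergence_when_an_arm_empties(self, make_trial):
        data = make_trial(level="cluster", pbar=0.5)
        # force every intervention cluster to deviate
        forced = dataclasses.replace(
            data, C=np.zeros_like(data.C), D=np.zeros_like(data.D)
        )
        res = fit_pp(forced, True)
        assert not res.converged
        assert np.isnan(res.estimate)

    def test_confidence_interval_convention(self, make_trial):
        data = make_trial(level="subject", pbar=0.2)
        for approach in ("ITT", "AT", "PP", "IV"):
            fit = fit_approach(approach, data, True)
            assert fit.ci_low == pytest.approx(fit.estimate - 1.96 * fit.se, abs=1e-12)
            assert fit.ci_high == pytest.approx(fit.estimate + 1.96 * fit.se, abs=1e-12)
            assert 0.0 <= fit.p_value <= 1.0
            assert fit.se > 0

    def test_unknown_approach_rejected(self, make_trial):
        with pytest.raises(ValueError):
            fit_approach("TT", make_trial(), True)


class TestInstrumentalVariables:
    def test_point_estimate_is_the_wald_ratio(self, make_trial):
        data = make_trial(level="cluster", pbar=0.3)
        iv = fit_iv(data, with_covariate=False)
        t, c = data.Z == 1, data.Z == 0
        wald = (data.Y[t].mean() - data.Y[c].mean()) / (
            data.D[t].mean() - data.D[c].mean()
        )
        assert iv.estimate == pytest.approx(wald, abs=1e-10)

    def test_matches_statsmodels_two_stage_least_squares(self, make_trial):
        data = make_trial(level="subject", pbar=0.3)
        iv = fit_iv(data, with_covariate=True)
        exog = np.column_stack([np.ones(data.n_subjects), data.D, data.X])
        instr = np.column_stack([np.ones(data.n_subjects), data.Z, data.X])
        ref = IV2SLS(data.Y, exog, instrument=instr).fit()
        assert iv.estimate == pytest.approx(ref.params[1], abs=1e-8)

    def test_first_stage_recovers_compliance_rate(self, make_trial):
        data = make_trial(level="subject", pbar=0.4)
        iv = fit_iv(data, with_covariate=False)
        fs = iv.first_stage
        # slope of D on Z is the intervention-arm compliance rate
        assert fs.alpha1 == pytest.approx(data.D[data.Z == 1].mean(), abs=1e-10)
        assert fs.alpha0 == pytest.approx(0.0, abs=1e-10)
        assert fs.partial_F > 10

    def test_classical_first_stage_f_equals_squared_t(self, make_trial):
        data = make_trial(level="cluster", pbar=0.3)
        iv = fit_iv(data, with_covariate=False, classical_first_stage_F=True)
        design = np.column_stack([np.ones(data.n_subjects), data.Z])
        ref = sm.OLS(data.D.astype(float), design).fit()
        assert iv.first_stage.partial_F == pytest.approx(
            float(ref.tvalues[1] ** 2), rel=1e-8
        )

    def test_zero_first_stage_flags_nonconvergence(self, make_trial):
        data = make_trial(level="cluster", pbar=0.3)
        broken = dataclasses.replace(
            data, C=np.zeros_like(data.C), D=np.zeros_like(data.D)
        )
        res = fit_iv(broken, with_covariate=False)
        assert not res.converged
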