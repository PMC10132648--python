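"""Model-core tests: covariance operator, likelihood oracles, ML fitting."""

import dataclasses
import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy.stats import multivariate_normal

from bpjoint import bivml, cohort, synth
from bpjoint.bivml import ModelParams, VarianceComponents


def random_instance(rng, p=None, n_households=None, max_size=4):
    """A small random dataset + random PD components for oracle comparisons."""
    p = p or int(rng.integers(1, 4))
    n_households = n_households or int(rng.integers(2, 8))
    hh = np.repeat(np.arange(n_households),
                   rng.integers(1, max_size + 1, size=n_households))
    n = len(hh)
    x = rng.normal(size=(n, p))
    x[:, 0] = 1.0
    y = rng.normal(size=(n, 2)) * 10 + [110, 70]
    data = pd.DataFrame({"household_id": hh, "sbp": y[:, 0], "dbp": y[:, 1]})
    a = rng.normal(size=(2, 2))
    b = rng.normal(size=(2, 2))
    vc = VarianceComponents(sigma_h=a @ a.T + 0.1 * np.eye(2),
                            sigma_e=b @ b.T + 0.5 * np.eye(2))
    params = ModelParams(beta1=rng.normal(size=p), beta2=rng.normal(size=p), varcomp=vc)
    return data, x, params


def dense_loglik(params, data, design):
    """Independent oracle: per-household dense multivariate-normal density."""
    vc = params.varcomp
    total = 0.0
    for _, grp in data.groupby("household_id", sort=False):
        idx = grp.index.to_numpy()
        n = len(idx)
        v = (np.kron(np.eye(n), vc.sigma_e)
             + np.kron(np.ones((n, n)), vc.sigma_h))
        resid = np.empty(2 * n)
        resid[0::2] = grp["sbp"].to_numpy() - design[idx] @ params.beta1
        resid[1::2] = grp["dbp"].to_numpy() - design[idx] @ params.beta2
        total += multivariate_normal.logpdf(resid, mean=np.zeros(2 * n), cov=v)
    return total


class TestHouseholdCovariance:
    def test_single_woman_is_sum_of_components(self, simple_varcomp):
        op = bivml.household_marginal_covariance(simple_varcomp, 1)
        np.testing.assert_allclose(
            op.dense(), simple_varcomp.sigma_h + simple_varcomp.sigma_e)

    def test_identity_residual_no_household_effect(self):
        vc = VarianceComponents(sigma_h=np.zeros((2, 2)), sigma_e=np.eye(2))
        op = bivml.household_marginal_covariance(vc, 3)
        assert op.logdet == pytest.approx(0.0)
        x = np.arange(6.0)
        np.testing.assert_allclose(op.solve(x), x)

    @pytest.mark.parametrize("n", [2, 3, 5])
    def test_matches_dense_kronecker_construction(self, n):
        rng = np.random.default_rng(n)
        for _ in range(10):
            a, b = rng.normal(size=(2, 2, 2))
            vc = VarianceComponents(sigma_h=a @ a.T + 0.05 * np.eye(2),
                                    sigma_e=b @ b.T + 0.5 * np.eye(2))
            op = bivml.household_marginal_covariance(vc, n)
            dense = op.dense()
            sign, logdet = np.linalg.slogdet(dense)
            assert sign > 0
            assert op.logdet == pytest.approx(logdet, abs=1e-8)
            x = rng.normal(size=2 * n)
            np.testing.assert_allclose(op.solve(x), np.linalg.solve(dense, x),
                                       atol=1e-8)
            assert op.quad_form(x) == pytest.approx(
                x @ np.linalg.solve(dense, x), abs=1e-8)

    def test_invalid_size(self, simple_varcomp):
        with pytest.raises(ValueError):
            bivml.household_marginal_covariance(simple_varcomp, 0)


class TestLogLikelihood:
    def test_matches_dense_oracle_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(30):
            data, x, params = random_instance(rng)
            ll = bivml.log_likelihood(params, data, x)
            assert ll == pytest.approx(dense_loglik(params, data, x), abs=1e-8)

    def test_independence_limit_no_household_effect(self):
        rng = np.random.default_rng(1)
        data, x, params = random_instance(rng)
        vc0 = VarianceComponents(sigma_h=np.zeros((2, 2)),
                                 sigma_e=params.varcomp.sigma_e)
        params0 = dataclasses.replace(params, varcomp=vc0)
        ll = bivml.log_likelihood(params0, data, x)
        resid = np.column_stack([
            data["sbp"] - x @ params.beta1, data["dbp"] - x @ params.beta2])
        per_woman = multivariate_normal.logpdf(
            resid, mean=np.zeros(2), cov=vc0.sigma_e).sum()
        assert ll == pytest.approx(per_woman, abs=1e-8)

    def test_duplicating_households_doubles_loglik(self):
        rng = np.random.default_rng(2)
        data, x, params = random_instance(rng)
        vc0 = VarianceComponents(sigma_h=np.zeros((2, 2)),
                                 sigma_e=params.varcomp.sigma_e)
        params0 = dataclasses.replace(params, varcomp=vc0)
        doubled = pd.concat([data, data.assign(
            household_id=data["household_id"] + 1000)], ignore_index=True)
        x2 = np.vstack([x, x])
        assert bivml.log_likelihood(params0, doubled, x2) == pytest.approx(
            2 * bivml.log_likelihood(params0, data, x), rel=1e-12)

    def test_dimension_mismatch(self):
        rng = np.random.default_rng(3)
        data, x, params = random_instance(rng, p=3)
        with pytest.raises(ValueError):
            bivml.log_likelihood(params, data, x[:, :2])


class TestFitting:
    def test_null_household_variance_recovered_at_boundary(self):
        vc = VarianceComponents(sigma_h=np.zeros((2, 2)),
                                sigma_e=np.diag([100.0, 50.0]))
        cfg = synth.GeneratorConfig(
            n_households=2000,
            household_women_count_distribution={1: 0.5, 2: 0.5},
            covariate_marginals={"age": {"15–24": 0.5, "25–34": 0.5}},
            intercepts=(110.0, 70.0),
            beta1={"age 25–34": 3.0}, beta2={"age 25–34": 2.0},
            varcomp=vc, region_names=("A",))
        df = synth.generate_population(cfg, seed=4)
        x, labels = cohort.build_design(df, cfg.scheme())
        fit = bivml.fit_bivariate_multilevel(df, x, labels)
        assert np.abs(np.diag(fit.params.varcomp.sigma_h)).max() < 3.0

    def test_parameter_recovery_small(self, small_cfg, small_data):
        records, design, labels = small_data
        fit = bivml.fit_bivariate_multilevel(records, design, labels)
        assert fit.converged
        b1, b2 = small_cfg.beta_vectors()
        z = np.abs(fit.stacked_beta() - np.concatenate([b1, b2]))
        z = z / fit.standard_errors()
        # 32 coefficients at 4 SE: overwhelming-probability sanity band at n=300
        assert z.max() < 4.0
        assert fit.n_params == 2 * 16 + 6
        assert fit.n_multiwoman_households > 0

    def test_single_level_equals_constrained_bivariate(self, small_data):
        records, design, labels = small_data
        sl = bivml.fit_single_level_multivariate(records, design, labels)
        params0 = ModelParams(
            beta1=sl.params.beta1, beta2=sl.params.beta2,
            varcomp=VarianceComponents(sigma_h=np.zeros((2, 2)),
                                       sigma_e=sl.params.varcomp.sigma_e))
        assert bivml.log_likelihood(params0, records, design) == pytest.approx(
            sl.loglik, abs=1e-6)
        assert sl.n_params == 2 * 16 + 3

    def test_full_fit_never_below_nested(self, small_data):
        records, design, labels = small_data
        sl = bivml.fit_single_level_multivariate(records, design, labels)
        biv = bivml.fit_bivariate_multilevel(records, design, labels)
        assert biv.loglik >= sl.loglik - 1e-6

    def test_singleton_households_single_level_is_ols(self):
        rng = np.random.default_rng(6)
        n = 400
        x = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = x @ [110, 3] + rng.normal(size=n) * 10
        z = x @ [70, 2] + rng.normal(size=n) * 7
        df = pd.DataFrame({"household_id": np.arange(n), "sbp": y, "dbp": z})
        fit = bivml.fit_single_level_multivariate(df, x)
        beta_ols, *_ = np.linalg.lstsq(x, np.column_stack([y, z]), rcond=None)
        np.testing.assert_allclose(fit.params.beta1, beta_ols[:, 0], atol=1e-8)
        np.testing.assert_allclose(fit.params.beta2, beta_ols[:, 1], atol=1e-8)

    def test_permutation_invariance(self, small_data):
        records, design, labels = small_data
        fit = bivml.fit_bivariate_multilevel(records, design, labels)
        rng = np.random.default_rng(7)
        perm = rng.permutation(len(records))
        shuffled = records.iloc[perm].reset_index(drop=True)
        fit_p = bivml.fit_bivariate_multilevel(shuffled, design[perm], labels)
        assert fit_p.loglik == pytest.approx(fit.loglik, abs=1e-5)
        np.testing.assert_allclose(fit_p.params.beta1, fit.params.beta1, atol=1e-5)
        np.testing.assert_allclose(fit_p.params.varcomp.sigma_h,
                                   fit.params.varcomp.sigma_h, atol=1e-3)

    def test_outcome_swap_symmetry(self, small_data):
        records, design, labels = small_data
        fit = bivml.fit_bivariate_multilevel(records, design, labels)
        swapped = records.rename(columns={"sbp": "dbp", "dbp": "sbp"})
        fit_s = bivml.fit_bivariate_multilevel(swapped, design, labels)
        assert fit_s.loglik == pytest.approx(fit.loglik, abs=1e-5)
        np.testing.assert_allclose(fit_s.params.beta1, fit.params.beta2, atol=1e-4)
        np.testing.assert_allclose(fit_s.params.beta2, fit.params.beta1, atol=1e-4)
        flip = np.array([[0.0, 1.0], [1.0, 0.0]])
        np.testing.assert_allclose(
            fit_s.params.varcomp.sigma_e,
            flip @ fit.params.varcomp.sigma_e @ flip, atol=1e-2)

    def test_univariate_margin_close_to_bivariate(self, small_data):
        records, design, labels = small_data
        biv = bivml.fit_bivariate_multilevel(records, design, labels)
        uni = bivml.fit_univariate_multilevel(records, design, "sbp", labels)
        assert uni.converged and uni.n_params == 16 + 2
        se = uni.standard_errors()
        # the joint model's SBP margin lands inside the separate model's CI
        assert np.all(np.abs(uni.params.beta1 - biv.params.beta1) < 1.96 * se)

    def test_rank_deficient_design_names_columns(self, small_data):
        records, design, labels = small_data
        bad = np.column_stack([design, design[:, 1]])
        with pytest.raises(ValueError, match="collinear"):
            bivml.fit_bivariate_multilevel(records, bad, labels + ["dup"])

    def test_serialization(self, small_data):
        import json

        records, design, labels = small_data
        fit = bivml.fit_bivariate_multilevel(records, design, labels)
        round_trip = json.loads(fit.to_json())
        assert round_trip["model_tag"] == "bivariate_multilevel"
        assert len(round_trip["beta1"]) == 16


class TestAnalyticGradient:
    def test_profiled_gradient_matches_finite_differences(self):
        from bpjoint.bivml import (_SuffStats, _chol_to_theta,
                                   _grad_sigma_to_theta, _theta_to_chol)
        rng = np.random.default_rng(11)
        data, x, params = random_instance(rng, p=2, n_households=12)
        stats = _SuffStats(data[["sbp", "dbp"]].to_numpy(), x,
                           data["household_id"].to_numpy())
        theta = np.concatenate([
            _chol_to_theta(np.linalg.cholesky(params.varcomp.sigma_h)),
            _chol_to_theta(np.linalg.cholesky(params.varcomp.sigma_e))])

        def value(t):
            lh, le = _theta_to_chol(t[:3], 2), _theta_to_chol(t[3:], 2)
            sh, se = lh @ lh.T, le @ le.T
            beta, _, _ = stats.gls(sh, se)
            return stats.loglik(beta, sh, se)

        def grad(t):
            lh, le = _theta_to_chol(t[:3], 2), _theta_to_chol(t[3:], 2)
            sh, se = lh @ lh.T, le @ le.T
            beta, _, _ = stats.gls(sh, se)
            gh, ge = stats.score_varcomp(beta, sh, se)
            return np.concatenate([_grad_sigma_to_theta(gh, lh),
                                   _grad_sigma_to_theta(ge, le)])

        eps = 1e-6
        numeric = np.array([
            (value(theta + eps * e) - value(theta - eps * e)) / (2 * eps)
            for e in np.eye(6)])
        np.testing.assert_allclose(grad(theta), numeric, atol=1e-4, rtol=1e-5)


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript unavailable")
def test_univariate_fit_matches_lme4(tmp_path, small_data):
    """Independent cross-check: the same ML fit from a reference mixed-model package."""
    records, design, labels = small_data
    fit = bivml.fit_univariate_multilevel(records, design, "sbp", labels)
    np.savetxt(tmp_path / "x.csv", design, delimiter=",")
    records[["household_id", "sbp"]].to_csv(tmp_path / "y.csv", index=False)
    script = textwrap.dedent("""
        suppressMessages(library(lme4))
        x <- as.matrix(read.csv("X_PATH", header=FALSE))
        y <- read.csv("Y_PATH")
        dat <- data.frame(y, x[, -1])
        rhs <- paste(colnames(dat)[3:ncol(dat)], collapse="+")
        m <- lmer(as.formula(paste("sbp ~", rhs, "+ (1|household_id)")),
                  data=dat, REML=FALSE)
        vc <- as.data.frame(VarCorr(m))
        cat(vc$vcov[1], vc$vcov[2], as.numeric(logLik(m)),
            fixef(m)[1], fixef(m)[2], sep="\\n")
    """).replace("X_PATH", str(tmp_path / "x.csv")).replace(
        "Y_PATH", str(tmp_path / "y.csv"))
    out = subprocess.run(["Rscript", "-e", script], capture_output=True,
                         text=True, check=True, timeout=300)
    sig_h, sig_e, loglik, b0, b1 = map(float, out.stdout.strip().split("\n"))
    assert fit.params.varcomp.sigma_h[0, 0] == pytest.approx(sig_h, rel=1e-3, abs=1e-2)
    assert fit.params.varcomp.sigma_e[0, 0] == pytest.approx(sig_e, rel=1e-4)
    assert fit.loglik == pytest.approx(loglik, abs=1e-3)
    assert fit.params.beta1[0] == pytest.approx(b0, abs=1e-3)
    assert fit.params.beta1[1] == pytest.approx(b1, abs=1e-3)
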