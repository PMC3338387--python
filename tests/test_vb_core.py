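import math

import numpy as np
import pytest

from vbnetrec.vb_core import (
    FixedHyperparameters,
    RegressionProblem,
    SpikeSlabPrior,
    fit_restarts,
    fit_vb,
    init_state,
    lower_bound,
    truncation_bound,
    update_feature,
    update_hyperparameters,
    update_unpenalized,
)


class TestTruncationBound:
    def test_paper_scale(self):
        # sqrt(300) / 999
        assert truncation_bound(300, 0, 1000) == pytest.approx(0.017337845, abs=1e-6)

    def test_capped_at_one(self):
        assert truncation_bound(4, 0, 3) == 1.0

    def test_large_feature_count(self):
        assert truncation_bound(100, 10**6, 1) == pytest.approx(1e-5)

    def test_rejects_bad_dims(self):
        with pytest.raises(ValueError):
            truncation_bound(0, 0, 10)
        with pytest.raises(ValueError):
            truncation_bound(10, 0, 0)


class TestRegressionProblem:
    def test_mean_centering(self, rng):
        y = rng.standard_normal(30) + 5.0
        Z = rng.standard_normal((30, 3)) + 2.0
        X = rng.integers(0, 3, size=(30, 2)).astype(float)
        prob = RegressionProblem(y=y, Z=Z, X=X, T=np.empty((30, 0)))
        assert abs(prob.y.mean()) < 1e-12
        assert np.abs(prob.W.mean(axis=0)).max() < 1e-12
        assert prob.n_penalized == 5

    def test_rejects_missing(self, rng):
        y = rng.standard_normal(10)
        Z = rng.standard_normal((10, 2))
        Z[3, 1] = np.nan
        with pytest.raises(ValueError, match="missing"):
            RegressionProblem(y=y, Z=Z, X=np.empty((10, 0)), T=np.empty((10, 0)))

    def test_prior_bound_from_dims(self, small_problem):
        prior = SpikeSlabPrior.for_problem(small_problem)
        assert prior.bound == min(1.0, math.sqrt(120) / 12)


class TestInitState:
    def test_deterministic(self, small_problem):
        a = init_state(small_problem, seed=5)
        b = init_state(small_problem, seed=5)
        assert np.array_equal(a.p, b.p)

    def test_seeds_differ(self, small_problem):
        assert not np.array_equal(
            init_state(small_problem, seed=1).p, init_state(small_problem, seed=2).p
        )

    def test_invariants(self, small_problem):
        st = init_state(small_problem, seed=0)
        st.validate()
        assert np.all((st.p >= 0.05) & (st.p <= 0.95))
        assert np.all(st.mu == 0.0)

    def test_zero_variance_column_masked(self, rng):
        W = rng.standard_normal((40, 4))
        W[:, 2] = 3.14  # constant: centered to zero
        prob = RegressionProblem.from_design(rng.standard_normal(40), W)
        with pytest.warns(UserWarning, match="zero-variance"):
            st = init_state(prob, seed=0)
        assert st.p[2] == 0.0 and not st.active[2]


class TestUpdateFeature:
    def test_orthogonal_column_zero_mean(self, rng):
        # y orthogonal to column j -> mu_j = 0, p_j at prior-odds level
        n = 50
        W = np.zeros((n, 2))
        W[:, 0] = rng.standard_normal(n)
        W[:, 1] = rng.standard_normal(n)
        y = W[:, 0].copy()
        y -= y.mean()  # pre-centered: column centering preserves dot products
        W[:, 1] -= (W[:, 1] @ y) / (y @ y) * y
        prob = RegressionProblem.from_design(y, W)
        assert abs(prob.W[:, 1] @ prob.y) < 1e-10
        st = init_state(prob, seed=0)
        st.p[:] = 0.0
        st.mu[:] = 0.0
        update_feature(st, prob, 1)
        assert st.mu[1] == pytest.approx(0.0, abs=1e-12)
        expected_logit = (
            st.elog_theta - st.elog_1mtheta
            + 0.5 * (st.e_log_kappa + math.log(st.s2[1]))
        )
        assert math.log(st.p[1] / (1 - st.p[1])) == pytest.approx(expected_logit, abs=1e-9)

    def test_strong_single_predictor_included(self, rng):
        n = 300
        x = rng.standard_normal(n)
        y = 5.0 * x + 0.2 * rng.standard_normal(n)
        prob = RegressionProblem.from_design(y, x.reshape(-1, 1))
        st = fit_vb(prob, seed=0)
        assert st.p[0] > 0.999

    def test_duplicate_columns_share_mass(self, rng):
        n = 300
        x = rng.standard_normal(n)
        W = np.column_stack([x, x])
        y = 2.0 * x + 0.5 * rng.standard_normal(n)
        prob = RegressionProblem.from_design(y, W)
        fr = fit_restarts(prob, n_restarts=10, master_seed=0)
        total_effect = fr.effect.sum()
        # combined expected effect matches the single-column estimate
        single = RegressionProblem.from_design(y, x.reshape(-1, 1))
        st = fit_vb(single, seed=0)
        assert total_effect == pytest.approx(st.p[0] * st.mu[0], rel=0.1)


class TestUpdateHyperparameters:
    def test_empty_model_returns_to_prior(self, small_problem):
        prior = SpikeSlabPrior.for_problem(small_problem)
        st = init_state(small_problem, prior, seed=0)
        st.p[:] = 0.0
        st.mu[:] = 0.0
        update_hyperparameters(st, small_problem, prior)
        P = small_problem.n_penalized
        assert st.beta_a == pytest.approx(1.0)
        assert st.beta_b == pytest.approx(1.0 + P)
        assert st.kappa_shape == pytest.approx(prior.gamma_shape)
        assert st.kappa_rate == pytest.approx(prior.gamma_rate)

    def test_theta_mean_below_bound(self, small_problem, rng):
        prior = SpikeSlabPrior.for_problem(small_problem)
        st = init_state(small_problem, prior, seed=0)
        for _ in range(10):
            st.p[st.active] = rng.uniform(0, 1, size=int(st.active.sum()))
            update_hyperparameters(st, small_problem, prior)
            assert st.theta_mean <= prior.bound + 1e-9


class TestUpdateUnpenalized:
    def test_empty_covariates_zero_intercept(self, rng):
        W = rng.standard_normal((50, 3))
        prob = RegressionProblem.from_design(rng.standard_normal(50), W)
        st = init_state(prob, seed=0)
        update_unpenalized(st, prob)
        assert st.intercept == pytest.approx(0.0, abs=1e-10)

    def test_exact_covariate_recovered(self, rng):
        n = 60
        t = rng.standard_normal((n, 1))
        y = 3.0 * t[:, 0]
        W = rng.standard_normal((n, 2))
        prob = RegressionProblem.from_design(y, W, T=t)
        st = init_state(prob, seed=0)
        st.p[:] = 0.0
        update_unpenalized(st, prob)
        assert st.alpha[0] == pytest.approx(3.0, abs=1e-8)

    def test_elbo_gradient_zero_at_update(self, small_problem):
        prior = SpikeSlabPrior.for_problem(small_problem)
        st = fit_vb(small_problem, prior, seed=1, max_sweeps=20)
        update_unpenalized(st, small_problem)
        base = lower_bound(st, small_problem, prior)
        eps = 1e-6
        for k in range(small_problem.n_covariates):
            st.alpha[k] += eps
            up = lower_bound(st, small_problem, prior)
            st.alpha[k] -= 2 * eps
            dn = lower_bound(st, small_problem, prior)
            st.alpha[k] += eps
            grad = (up - dn) / (2 * eps)
            assert abs(grad) < 1e-4
            assert up <= base + 1e-10 and dn <= base + 1e-10


class TestLowerBound:
    def test_monotone_on_random_problems(self, rng):
        for trial in range(10):
            n = int(rng.integers(30, 120))
            P = int(rng.integers(5, 60))
            W = rng.standard_normal((n, P))
            beta = np.zeros(P)
            k = int(rng.integers(0, 3))
            if k:
                beta[rng.choice(P, size=k, replace=False)] = rng.normal(0, 2, size=k)
            y = W @ beta + rng.standard_normal(n)
            prob = RegressionProblem.from_design(y, W)
            st = fit_vb(prob, seed=trial, max_sweeps=60, track_elbo=True)
            trace = np.asarray(st.elbo_trace)
            assert np.all(np.diff(trace) >= -1e-8), f"trial {trial}"

    def test_permutation_invariance(self, rng):
        n, P = 60, 8
        W = rng.standard_normal((n, P))
        y = W[:, 0] * 2 + rng.standard_normal(n)
        prob = RegressionProblem.from_design(y, W)
        prior = SpikeSlabPrior.for_problem(prob)
        st = fit_vb(prob, prior, seed=0, max_sweeps=30)
        L1 = lower_bound(st, prob, prior)

        perm = rng.permutation(P)
        prob2 = RegressionProblem.from_design(y, W[:, perm])
        st2 = init_state(prob2, prior, seed=0)
        st2.p = st.p[perm].copy()
        st2.mu = st.mu[perm].copy()
        st2.s2 = st.s2[perm].copy()
        for attr in ("beta_a", "beta_b", "theta_mean", "elog_theta", "elog_1mtheta",
                     "log_norm_theta", "tau_shape", "tau_rate", "kappa_shape",
                     "kappa_rate", "intercept"):
            setattr(st2, attr, getattr(st, attr))
        assert lower_bound(st2, prob2, prior) == pytest.approx(L1, abs=1e-8)

    def test_null_fixed_hypers_closed_form(self, rng):
        # all p_j -> 0 with fixed hypers: ELBO = Gaussian loglik + P*log(1-theta)
        n, P = 80, 6
        W = rng.standard_normal((n, P))
        y = rng.standard_normal(n)
        prob = RegressionProblem.from_design(y, W)
        fx = FixedHyperparameters(sigma_e2=1.0, sigma_beta2=1.0, p_nonzero=1e-8)
        prior = SpikeSlabPrior.for_problem(prob)
        st = fit_vb(prob, prior, seed=0, fixed=fx)
        assert st.p.max() < 1e-4
        expected = (
            -0.5 * n * math.log(2 * math.pi) - 0.5 * float(prob.y @ prob.y)
            + P * math.log1p(-1e-8)
        )
        assert st.lower_bound == pytest.approx(expected, abs=0.01)


class TestFitVB:
    def test_planted_recovery_small(self, rng):
        n, P = 200, 80
        W = rng.standard_normal((n, P))
        beta = np.zeros(P)
        beta[[5, 40]] = [3.0, -3.0]
        y = W @ beta + rng.standard_normal(n)
        prob = RegressionProblem.from_design(y, W)
        st = fit_vb(prob, seed=0)
        hits = set(np.flatnonzero(st.p > 0.99))
        assert hits == {5, 40}

    def test_convergence_flag(self, small_problem):
        st = fit_vb(small_problem, seed=0)
        assert st.converged and st.n_sweeps < 500

    def test_exchangeability_of_outputs(self, rng):
        # permuting columns permutes p_j (same fit seed, same init per feature
        # requires identical update order; here we check fitted support only)
        n, P = 150, 20
        W = rng.standard_normal((n, P))
        y = 3.0 * W[:, 3] + rng.standard_normal(n)
        perm = rng.permutation(P)
        st1 = fit_vb(RegressionProblem.from_design(y, W), seed=0)
        st2 = fit_vb(RegressionProblem.from_design(y, W[:, perm]), seed=0)
        assert set(np.flatnonzero(st1.p > 0.99)) == {3}
        assert set(perm[np.flatnonzero(st2.p > 0.99)]) == {3}


class TestFitRestarts:
    def test_single_restart_identity(self, small_problem):
        fr = fit_restarts(small_problem, n_restarts=1, master_seed=7)
        assert np.array_equal(fr.p_hat, fr.restarts[0].p)
        assert fr.weights[0] == 1.0

    def test_equal_evidence_averages(self, small_problem):
        fr = fit_restarts(small_problem, n_restarts=2, master_seed=3)
        L = [r.lower_bound for r in fr.restarts]
        w = np.exp(np.subtract(L, max(L)))
        w = w / w.sum()
        manual = w[0] * fr.restarts[0].p + w[1] * fr.restarts[1].p
        assert fr.p_hat == pytest.approx(manual, abs=1e-12)

    def test_dominant_mode_weight(self):
        # 50-nat evidence gap -> weight > 1 - 1e-20
        L = np.array([0.0, 50.0])
        w = np.exp(L - L.max())
        w /= w.sum()
        assert 1.0 - w[1] < 1e-20

    def test_convex_combination(self, small_problem):
        fr = fit_restarts(small_problem, n_restarts=4, master_seed=1)
        assert np.all(fr.weights >= 0) and fr.weights.sum() == pytest.approx(1.0)
        assert np.all(fr.p_hat >= 0) and np.all(fr.p_hat <= 1)


class TestFitResultSerialization:
    def test_frames(self, small_problem, tmp_path):
        import pandas as pd
        from vbnetrec.vb_core import fit_restarts

        fr = fit_restarts(small_problem, n_restarts=3, master_seed=0)
        names = [f"feat{j}" for j in range(small_problem.n_penalized)]
        df = fr.to_frame(names)
        assert list(df.columns) == ["feature", "p_hat", "effect"]
        df.to_csv(tmp_path / "fit.tsv", sep="\t", index=False)
        back = pd.read_csv(tmp_path / "fit.tsv", sep="\t")
        assert back["p_hat"].tolist() == pytest.approx(fr.p_hat.tolist())
        rs = fr.restarts_frame()
        assert len(rs) == 3 and rs["weight"].sum() == pytest.approx(1.0)
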