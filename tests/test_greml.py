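"""REML core: likelihood correctness, optimizer behaviour, derived quantities."""

import numpy as np
import pytest
from scipy.optimize import minimize

from covgreml.greml import (
    BivariateGREML,
    SingularVError,
    UnivariateGREML,
    genetic_correlation,
    restricted_loglik,
    snp_heritability,
)
from covgreml.greml import _score_and_ai, _evaluate, _theta_to_matrices
from covgreml.grm import build_grm
from covgreml.simulate import simulate_model_mode

THETA = np.array([0.3, 0.15, 0.3, 0.7, 0.15, 0.7])


def _dense_reml_reference(theta, ys, Xs, A):
    """Independent dense evaluation of the REML criterion (explicit V,
    generic determinant / solve routines)."""
    n = A.shape[0]
    T = len(ys)
    y = np.concatenate(ys)
    X = np.zeros((n * T, sum(x.shape[1] for x in Xs)))
    off = 0
    for t, x in enumerate(Xs):
        X[t * n : (t + 1) * n, off : off + x.shape[1]] = x
        off += x.shape[1]
    if T == 1:
        sg = np.array([[theta[0]]])
        se = np.array([[theta[1]]])
    else:
        sg = np.array([[theta[0], theta[1]], [theta[1], theta[2]]])
        se = np.array([[theta[3], theta[4]], [theta[4], theta[5]]])
    V = np.kron(sg, A) + np.kron(se, np.eye(n))
    sign, logdet_v = np.linalg.slogdet(V)
    Vi = np.linalg.inv(V)
    C = X.T @ Vi @ X
    _, logdet_c = np.linalg.slogdet(C)
    P = Vi - Vi @ X @ np.linalg.inv(C) @ X.T @ Vi
    p = X.shape[1]
    return -0.5 * (logdet_v + logdet_c + y @ P @ y) - 0.5 * (n * T - p) * np.log(2 * np.pi)


@pytest.fixture(scope="module")
def small_fit_problem():
    panel, dyads, _ = simulate_model_mode(40, 300, THETA, seed=21)
    grm = build_grm(panel)
    y1 = dyads["y1"].to_numpy()
    y2 = dyads["y2"].to_numpy()
    ones = np.ones((40, 1))
    return grm, y1, y2, ones


class TestRestrictedLoglik:
    def test_dense_matches_reference_oracle(self, small_fit_problem):
        grm, y1, y2, ones = small_fit_problem
        theta = THETA * 1.1
        X = np.kron(np.eye(2), ones)
        got = restricted_loglik(theta, np.concatenate([y1, y2]), X, grm)
        want = _dense_reml_reference(theta, [y1, y2], [ones, ones], grm.values)
        assert got == pytest.approx(want, abs=1e-8)

    def test_eigen_path_matches_dense(self, small_fit_problem):
        grm, y1, y2, ones = small_fit_problem
        model = BivariateGREML(y1, y2, grm)
        X = np.kron(np.eye(2), ones)
        for scale in (0.7, 1.0, 1.6):
            theta = THETA * scale
            dense = restricted_loglik(theta, np.concatenate([y1, y2]), X, grm)
            assert model.loglike(theta) == pytest.approx(dense, abs=1e-6)

    def test_identity_grm_collapses_to_total_covariance(self, small_fit_problem):
        _, y1, y2, ones = small_fit_problem
        A = np.eye(40)
        model = BivariateGREML(y1, y2, A)
        theta_a = np.array([0.2, 0.05, 0.2, 0.5, 0.1, 0.5])
        shift = np.array([0.1, 0.02, 0.1, -0.1, -0.02, -0.1])
        assert model.loglike(theta_a) == pytest.approx(
            model.loglike(theta_a + shift), abs=1e-8
        )

    def test_rank_deficient_design_rejected(self, small_fit_problem):
        grm, y1, y2, ones = small_fit_problem
        X_bad = np.hstack([ones, ones])
        with pytest.raises(ValueError, match="rank"):
            BivariateGREML(y1, y2, grm, X1=X_bad, X2=ones)
        with pytest.raises(ValueError, match="rank"):
            restricted_loglik(
                THETA, np.concatenate([y1, y2]), np.kron(np.eye(2), X_bad)[:, :4], grm
            )

    def test_singular_v_raises_with_theta(self, small_fit_problem):
        grm, y1, y2, _ = small_fit_problem
        model = BivariateGREML(y1, y2, grm)
        bad = np.array([0.0, 0.0, 0.0, 0.0, 0.0, 0.0])
        with pytest.raises(SingularVError):
            model.loglike(bad)


def _nelder_mead_oracle(model, n_starts=5, seed=0):
    """Derivative-free maximization of the restricted likelihood from
    random starts; independent of the AI-REML update path."""
    rng = np.random.default_rng(seed)

    def neg_ll(theta):
        try:
            return -model.loglike(theta)
        except SingularVError:
            return 1e10

    best = -np.inf
    for _ in range(n_starts):
        x0 = np.array([0.5, 0.1, 0.5, 0.5, 0.1, 0.5]) * rng.uniform(0.3, 2.0, size=6)
        res = minimize(
            neg_ll, x0, method="Nelder-Mead",
            options={"maxfev": 4000, "xatol": 1e-7, "fatol": 1e-9},
        )
        best = max(best, -res.fun)
    return best


class TestBivariateFit:
    def test_ai_reml_matches_derivative_free_oracle(self, small_fit_problem):
        grm, y1, y2, _ = small_fit_problem
        model = BivariateGREML(y1, y2, grm)
        fit = model.fit()
        oracle = _nelder_mead_oracle(model, seed=1)
        assert fit.loglik >= oracle - 1e-3

    def test_duplicated_trait_degenerates(self, small_fit_problem):
        grm, y1, _, _ = small_fit_problem
        fit = BivariateGREML(y1, y1.copy(), grm).fit()
        assert fit.sigma_g12 == pytest.approx(fit.sigma_g1, abs=1e-3)
        assert fit.sigma_e12 == pytest.approx(fit.sigma_e1, abs=1e-3)
        rg, ok = genetic_correlation(fit)
        if ok:
            assert rg == pytest.approx(1.0, abs=1e-3)

    def test_null_genetic_covariance_within_two_se(self):
        panel, dyads, _ = simulate_model_mode(
            400, 800, [0.0, 0.0, 0.0, 1.0, 0.2, 1.0], seed=22
        )
        grm = build_grm(panel)
        fit = BivariateGREML(dyads["y1"].to_numpy(), dyads["y2"].to_numpy(), grm).fit()
        se = fit.bse[1]
        assert abs(fit.sigma_g12) < 2 * se

    def test_score_vanishes_at_optimum(self, small_fit_problem):
        grm, y1, y2, _ = small_fit_problem
        model = BivariateGREML(y1, y2, grm)
        fit = model.fit()
        if fit.converged:
            sg, se = _theta_to_matrices(fit.params, 2)
            ev = _evaluate(model._ws, sg, se)
            score, _ = _score_and_ai(model._ws, ev)
            assert np.abs(score).max() < 1e-3

    def test_likelihood_invariant_to_dyad_reordering(self, small_fit_problem):
        grm, y1, y2, _ = small_fit_problem
        perm = np.random.default_rng(23).permutation(len(y1))
        a = BivariateGREML(y1, y2, grm.values).loglike(THETA)
        b = BivariateGREML(
            y1[perm], y2[perm], grm.values[np.ix_(perm, perm)]
        ).loglike(THETA)
        assert a == pytest.approx(b, abs=1e-6)

    def test_warm_start_matches_cold_start(self, small_fit_problem):
        grm, y1, y2, _ = small_fit_problem
        model = BivariateGREML(y1, y2, grm)
        cold = model.fit()
        warm = model.fit(start=cold.params * 1.2)
        np.testing.assert_allclose(warm.params, cold.params, atol=1e-4)


class TestUnivariateFit:
    def test_recovers_h2_within_two_se(self):
        panel, dyads, _ = simulate_model_mode(
            1000, 2000, [0.5, 0.0, 0.5, 0.5, 0.0, 0.5], seed=24
        )
        grm = build_grm(panel)
        fit = UnivariateGREML(dyads["y1"].to_numpy(), grm).fit()
        h2, ok = snp_heritability(fit)
        assert ok
        se_h2 = 2 * fit.bse[0]  # coarse bound: SE(h2) <= 2 SE(sigma_g) here
        assert h2 == pytest.approx(0.5, abs=max(2 * se_h2, 0.15))

    def test_permuted_phenotype_destroys_signal(self):
        panel, dyads, _ = simulate_model_mode(
            400, 800, [0.5, 0.0, 0.5, 0.5, 0.0, 0.5], seed=25
        )
        grm = build_grm(panel)
        y = dyads["y1"].to_numpy().copy()
        np.random.default_rng(0).shuffle(y)
        fit = UnivariateGREML(y, grm).fit()
        assert abs(fit.sigma_g) < 2 * fit.bse[0] + 0.05

    def test_identity_grm_unidentifiable_total_recovered(self):
        rng = np.random.default_rng(26)
        y = rng.normal(scale=2.0, size=200)
        fit = UnivariateGREML(y, np.eye(200)).fit()
        assert fit.sigma_g + fit.sigma_e == pytest.approx(np.var(y, ddof=1), rel=0.1)


class TestDerivedQuantities:
    def test_genetic_correlation_arithmetic(self, small_fit_problem):
        grm, y1, y2, _ = small_fit_problem
        fit = BivariateGREML(y1, y2, grm).fit()
        fit.sigma_g1, fit.sigma_g12, fit.sigma_g2 = 0.2, 0.1, 0.2
        rg, ok = genetic_correlation(fit)
        assert ok and rg == pytest.approx(0.5)

    def test_heritability_arithmetic(self, small_fit_problem):
        grm, y1, y2, _ = small_fit_problem
        fit = BivariateGREML(y1, y2, grm).fit()
        fit.sigma_g1, fit.sigma_e1 = 0.3, 0.7
        h2, ok = snp_heritability(fit, 1)
        assert ok and h2 == pytest.approx(0.3)

    def test_negative_variance_flags_undefined_rg(self, small_fit_problem):
        grm, y1, y2, _ = small_fit_problem
        fit = BivariateGREML(y1, y2, grm).fit()
        fit.sigma_g1 = -0.05
        rg, ok = genetic_correlation(fit)
        assert not ok and np.isnan(rg)

    def test_summary_mentions_components(self, small_fit_problem):
        grm, y1, y2, _ = small_fit_problem
        text = BivariateGREML(y1, y2, grm).fit().summary()
        assert "sigma_g12" in text and "logL" in text
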