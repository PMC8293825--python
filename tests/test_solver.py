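import numpy as np
import pytest

from huberlasso.losses import HUBER, QUANTILE, SQUARED, LossSpec, rho
from huberlasso.solver import (
    RegressionProblem,
    cross_validate,
    default_lambda_grid,
    fit_path,
    kkt_violation,
    lambda_max,
    predict,
    selected_variables,
)
from conftest import make_problem

ALL_SPECS = [SQUARED, HUBER, LossSpec("quantile", tau=0.5)]


def _standardized(problem):
    center = problem.X.mean(axis=0)
    scale = problem.X.std(axis=0)
    return (problem.X - center) / np.where(scale == 0, 1, scale)


def path_objective(problem, spec, fit, idx):
    """Penalized objective of a fitted grid point, on the standardized scale."""
    Xs = _standardized(problem)
    beta = fit._std_coefficients[:, idx]
    b0 = fit._std_intercepts[idx]
    e = problem.y - b0 - Xs @ beta
    return float(np.mean(rho(e, spec)) + fit.lambdas[idx] * np.abs(beta).sum())


def _smoothed_rho(e, tau, gamma):
    """Huberized check loss: quadratic within the gamma-zone of the kink,
    the usual tilted-absolute branches outside (test-side re-derivation)."""
    up, lo = tau * gamma, -(1.0 - tau) * gamma
    out = np.where(
        e > up,
        tau * e - tau**2 * gamma / 2,
        np.where(e < lo, (tau - 1.0) * e - (1.0 - tau) ** 2 * gamma / 2, e**2 / (2 * gamma)),
    )
    return out


def _smoothed_psi(e, tau, gamma):
    return np.clip(e / gamma, tau - 1.0, tau)


def fista_oracle(problem, spec, lam, gamma=1e-2, n_iters=40000):
    """Independent slow solver: accelerated proximal gradient (FISTA) with a
    fixed 1/L step on the smooth part (the quantile check loss huberized at
    width ``gamma``), soft-threshold prox for the penalty, unpenalized
    intercept.  Shares no code with the coordinate-descent path; returns the
    best objective visited."""
    from huberlasso.losses import psi

    Xs = _standardized(problem)
    n, p = Xs.shape
    y = problem.y
    A = np.column_stack([np.ones(n), Xs])
    curv = 1.0 / gamma if spec.family == "quantile" else 1.0
    L = curv * np.linalg.eigvalsh(A.T @ A / n).max() + 1e-9

    def loss(e):
        if spec.family == "quantile":
            return float(np.mean(_smoothed_rho(e, spec.tau, gamma)))
        return float(np.mean(rho(e, spec)))

    def influence(e):
        if spec.family == "quantile":
            return _smoothed_psi(e, spec.tau, gamma)
        return psi(e, spec)

    theta = np.zeros(p + 1)  # [b0, beta]
    theta[0] = float(np.median(y))
    z = theta.copy()
    t_acc = 1.0
    best = np.inf
    for _ in range(n_iters):
        e = y - A @ z
        grad = -A.T @ influence(e) / n
        new = z - grad / L
        new[1:] = np.sign(new[1:]) * np.maximum(np.abs(new[1:]) - lam / L, 0.0)
        t_next = (1.0 + np.sqrt(1.0 + 4.0 * t_acc**2)) / 2.0
        z = new + (t_acc - 1.0) / t_next * (new - theta)
        theta, t_acc = new, t_next
        obj = loss(y - A @ theta) + lam * np.abs(theta[1:]).sum()
        best = min(best, obj)
    return best


class TestLambdaMax:
    def test_all_zero_at_lambda_max(self, small_problem):
        for spec in ALL_SPECS:
            lam = lambda_max(small_problem, spec)
            fit = fit_path(small_problem, spec, lambdas=[lam])
            assert np.all(fit.coefficients == 0.0)

    def test_single_predictor_closed_form(self):
        # soft-threshold oracle: for one standardized predictor under the
        # squared loss, lambda_max = |(1/n) x'y| exactly
        rng = np.random.default_rng(0)
        n = 50
        x = rng.normal(size=n)
        x = (x - x.mean()) / x.std()
        y = rng.normal(size=n)
        y = y - y.mean()
        target = 0.4
        y = y * target / abs(x @ y / n)  # scale so (1/n) x'y = ±0.4
        prob = RegressionProblem(y, x[:, None])
        assert lambda_max(prob, SQUARED) == pytest.approx(0.4, rel=1e-9)

    def test_homogeneity_in_y(self, small_problem):
        lam1 = lambda_max(small_problem, SQUARED)
        doubled = RegressionProblem(2 * small_problem.y, small_problem.X)
        assert lambda_max(doubled, SQUARED) == pytest.approx(2 * lam1, rel=1e-9)

    def test_constant_y_warns_zero(self, rng):
        prob = RegressionProblem(np.ones(20), rng.normal(size=(20, 3)))
        with pytest.warns(UserWarning, match="constant"):
            assert lambda_max(prob, SQUARED) == 0.0


class TestFitPath:
    def test_unpenalized_squared_matches_ols(self, small_problem):
        fit = fit_path(small_problem, SQUARED, lambdas=[lambda_max(small_problem, SQUARED), 0.0])
        A = np.column_stack([np.ones(small_problem.n), small_problem.X])
        ols = np.linalg.lstsq(A, small_problem.y, rcond=None)[0]
        np.testing.assert_allclose(fit.coefficients[:, 1], ols[1:], atol=1e-6)
        assert fit.intercepts[1] == pytest.approx(ols[0], abs=1e-6)

    def test_huge_c_huber_equals_squared(self, small_problem):
        lam_grid = default_lambda_grid(lambda_max(small_problem, SQUARED), 30)
        big_c = LossSpec("huber", c=10 * np.abs(small_problem.y).max())
        f_sq = fit_path(small_problem, SQUARED, lambdas=lam_grid)
        f_hu = fit_path(small_problem, big_c, lambdas=lam_grid)
        np.testing.assert_allclose(f_hu.coefficients, f_sq.coefficients, atol=1e-5)
        np.testing.assert_allclose(f_hu.intercepts, f_sq.intercepts, atol=1e-5)

    @pytest.mark.parametrize("spec", ALL_SPECS, ids=lambda s: s.family)
    @pytest.mark.parametrize("seed", range(5))
    def test_kkt_all_grid_points(self, spec, seed):
        prob = make_problem(seed)
        fit = fit_path(prob, spec, n_lambdas=30)
        assert kkt_violation(prob, spec, fit).max() < 1e-4

    @pytest.mark.parametrize("spec", ALL_SPECS, ids=lambda s: s.family)
    def test_objective_beats_slow_oracle(self, spec):
        # for the quantile family both routes minimize the same huberized
        # check loss (the solver's documented smoothing), so the comparison
        # is exact there as well
        prob = make_problem(99, n=30, p=8)
        fit = fit_path(prob, spec, n_lambdas=5, lambda_min_ratio=0.1)
        for idx in range(5):
            if spec.family == "quantile":
                Xs = _standardized(prob)
                beta = fit._std_coefficients[:, idx]
                e = prob.y - fit._std_intercepts[idx] - Xs @ beta
                ours = float(
                    np.mean(_smoothed_rho(e, spec.tau, fit.quantile_smoothing))
                    + fit.lambdas[idx] * np.abs(beta).sum()
                )
            else:
                ours = path_objective(prob, spec, fit, idx)
            oracle = fista_oracle(prob, spec, fit.lambdas[idx], gamma=fit.quantile_smoothing)
            assert ours <= oracle + 1e-6

    def test_warm_start_continuity(self, small_problem):
        fit = fit_path(small_problem, HUBER, n_lambdas=50)
        jumps = np.abs(np.diff(fit.coefficients, axis=1)).max(axis=0)
        # adjacent-lambda solutions change boundedly along the path
        assert jumps.max() < 0.5 * max(1, np.abs(fit.coefficients).max())

    @pytest.mark.parametrize("spec", ALL_SPECS, ids=lambda s: s.family)
    def test_objective_monotone_within_lambda(self, spec):
        prob = make_problem(3, n=40, p=10)
        fit = fit_path(prob, spec, n_lambdas=10, track_objective=True)
        for hist in fit.objective_history:
            if len(hist) > 1:
                assert np.all(np.diff(hist) <= 1e-10)

    def test_ascending_grid_rejected(self, small_problem):
        with pytest.raises(ValueError, match="descending"):
            fit_path(small_problem, SQUARED, lambdas=[0.1, 0.2])

    def test_zero_variance_column_stays_zero(self, rng):
        X = rng.normal(size=(40, 4))
        X[:, 2] = 1.5
        y = X[:, 0] + rng.normal(size=40)
        prob = RegressionProblem(y, X)
        assert list(prob.constant_columns) == [2]
        fit = fit_path(prob, SQUARED, n_lambdas=20)
        assert np.all(fit.coefficients[2] == 0.0)

    def test_robustness_single_corrupted_phenotype(self):
        # one corrupted phenotype (set to +5) moves the causal coefficient
        # strictly less under huber(1.345) than under the squared loss
        rng = np.random.default_rng(17)
        n = 100
        X = rng.binomial(2, 0.3, size=(n, 5)).astype(float)
        y = 0.4 * X[:, 0] + rng.normal(size=n) * 0.9
        y = y - y.mean()
        lam = 0.05
        shifts = {}
        for spec in (SQUARED, HUBER):
            b_clean = fit_path(RegressionProblem(y, X), spec, lambdas=[lam]).coefficients[0, 0]
            y_bad = y.copy()
            y_bad[0] = 5.0
            b_bad = fit_path(RegressionProblem(y_bad, X), spec, lambdas=[lam]).coefficients[0, 0]
            shifts[spec.family] = abs(b_bad - b_clean)
        assert shifts["huber"] < shifts["squared"]


class TestCrossValidate:
    def test_deterministic_given_seed(self, small_problem):
        a = cross_validate(small_problem, HUBER, k=5, seed=11, n_lambdas=20)
        b = cross_validate(small_problem, HUBER, k=5, seed=11, n_lambdas=20)
        assert a.lambda_opt == b.lambda_opt
        np.testing.assert_array_equal(a.fold_assignment, b.fold_assignment)
        np.testing.assert_allclose(a.cv_curve, b.cv_curve)

    def test_lambda_opt_attains_minimum_largest_on_ties(self, small_problem):
        cv = cross_validate(small_problem, SQUARED, k=5, seed=0, n_lambdas=20)
        mins = cv.lambdas[cv.cv_curve == cv.cv_curve.min()]
        assert cv.lambda_opt == mins.max()

    def test_pure_noise_selects_few(self):
        # simulation oracle: with no signal the CV-chosen model stays sparse
        sizes = []
        for seed in range(20):
            r = np.random.default_rng(seed)
            prob = RegressionProblem(r.normal(size=60), r.normal(size=(60, 30)))
            cv = cross_validate(prob, SQUARED, k=5, seed=seed, n_lambdas=30)
            sizes.append(len(selected_variables(cv.path, cv.lambda_opt)))
        assert np.median(sizes) < 0.1 * 30

    def test_strong_predictor_always_selected(self):
        # simulation oracle: a predictor explaining half the variance is
        # picked at lambda_opt in >= 95 of 100 seeded runs
        hits = 0
        for seed in range(100):
            r = np.random.default_rng(1000 + seed)
            n = 500
            X = r.normal(size=(n, 10))
            y = X[:, 0] + r.normal(size=n)  # EV = 0.5
            prob = RegressionProblem(y, X, snp_ids=[f"s{j}" for j in range(10)])
            cv = cross_validate(prob, SQUARED, k=10, seed=seed, n_lambdas=20)
            hits += "s0" in selected_variables(cv.path, cv.lambda_opt)
        assert hits >= 95

    def test_validation_errors(self, small_problem):
        with pytest.raises(ValueError, match="folds"):
            cross_validate(small_problem, SQUARED, k=1)
        tiny = make_problem(0, n=12, p=3)
        with pytest.raises(ValueError, match="n >= 2k"):
            cross_validate(tiny, SQUARED, k=10)


class TestPredictAndSelection:
    def test_all_zero_gives_intercept(self, small_problem):
        lam = lambda_max(small_problem, SQUARED)
        fit = fit_path(small_problem, SQUARED, lambdas=[lam])
        pred = predict(fit, small_problem.X, lam)
        np.testing.assert_allclose(pred, fit.intercepts[0])

    def test_training_predictions_equal_ols_at_zero(self, small_problem):
        fit = fit_path(small_problem, SQUARED, lambdas=[lambda_max(small_problem, SQUARED), 0.0])
        pred = predict(fit, small_problem.X, 0.0)
        A = np.column_stack([np.ones(small_problem.n), small_problem.X])
        ols_fitted = A @ np.linalg.lstsq(A, small_problem.y, rcond=None)[0]
        np.testing.assert_allclose(pred, ols_fitted, atol=1e-5)

    def test_dosage_effect_per_allele(self):
        rng = np.random.default_rng(2)
        X = rng.binomial(2, 0.4, size=(50, 1)).astype(float)
        y = 0.5 * X[:, 0] + 0.01 * rng.normal(size=50)
        fit = fit_path(RegressionProblem(y, X), SQUARED, lambdas=[0.0])
        pred = {g: predict(fit, [[float(g)]], 0.0)[0] for g in (0, 1, 2)}
        assert pred[1] - pred[0] == pytest.approx(pred[2] - pred[1], abs=1e-6)

    def test_unknown_lambda_rejected_interpolation_opt_in(self, small_problem):
        fit = fit_path(small_problem, SQUARED, n_lambdas=10)
        bad = (fit.lambdas[3] + fit.lambdas[4]) / 2
        with pytest.raises(ValueError, match="not on the fitted grid"):
            predict(fit, small_problem.X, bad)
        interp = predict(fit, small_problem.X, bad, interpolate=True)
        lo = predict(fit, small_problem.X, fit.lambdas[3])
        hi = predict(fit, small_problem.X, fit.lambdas[4])
        assert np.all((interp >= np.minimum(lo, hi) - 1e-9) & (interp <= np.maximum(lo, hi) + 1e-9))

    def test_snp_id_mismatch_named(self, small_problem):
        fit = fit_path(small_problem, SQUARED, n_lambdas=5)
        wrong = list(fit.snp_ids)
        wrong[0] = "rs_unknown"
        with pytest.raises(ValueError, match="rs_unknown"):
            predict(fit, small_problem.X, fit.lambdas[0], snp_ids=wrong)

    def test_selected_empty_at_lambda_max(self, small_problem):
        lam = lambda_max(small_problem, HUBER)
        fit = fit_path(small_problem, HUBER, lambdas=[lam])
        assert selected_variables(fit, lam) == set()

    def test_selection_grows_along_descending_path(self, small_problem):
        fit = fit_path(small_problem, SQUARED, n_lambdas=30)
        first = len(selected_variables(fit, fit.lambdas[0]))
        last = len(selected_variables(fit, fit.lambdas[-1]))
        assert first <= last

    def test_known_support_recovered(self):
        # oracle: strong single signal, moderate lambda -> exactly {snp0}
        rng = np.random.default_rng(4)
        X = rng.normal(size=(80, 4))
        y = 2.0 * X[:, 0] + 0.05 * rng.normal(size=80)
        prob = RegressionProblem(y, X, snp_ids=["snp0", "snp1", "snp2", "snp3"])
        lam = 0.5 * lambda_max(prob, SQUARED)
        fit = fit_path(prob, SQUARED, lambdas=[lambda_max(prob, SQUARED), lam])
        assert selected_variables(fit, lam) == {"snp0"}


class TestProblemValidation:
    def test_missing_values_rejected(self, rng):
        X = rng.normal(size=(20, 3))
        y = rng.normal(size=20)
        y[3] = np.nan
        with pytest.raises(ValueError, match="missing"):
            RegressionProblem(y, X)

    def test_minimum_n(self, rng):
        with pytest.raises(ValueError, match="at least 10"):
            RegressionProblem(rng.normal(size=5), rng.normal(size=(5, 2)))

    def test_shape_mismatch(self, rng):
        with pytest.raises(ValueError, match="rows"):
            RegressionProblem(rng.normal(size=20), rng.normal(size=(19, 2)))
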