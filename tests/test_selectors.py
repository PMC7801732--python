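"""Selector fitters against closed-form, enumeration and grid-search oracles."""

import numpy as np
import pytest

from triboot import _solvers, selectors
from triboot.selectors import (
    SELECTORS,
    CvSpec,
    fit_elastic_net,
    fit_mbic,
    fit_ncv,
    fit_selector,
    fit_sparsestep,
    fit_stepwise_aic,
    mbic_score,
    penalty_mcp,
    penalty_scad_derivative,
)


def _ols(X, y):
    Xd = np.column_stack([np.ones(len(y)), X])
    beta, *_ = np.linalg.lstsq(Xd, y, rcond=None)
    return beta  # [intercept, coefs...]


# ---------------------------------------------------------------------------
# Penalty functions
# ---------------------------------------------------------------------------

class TestPenalties:
    @pytest.mark.parametrize(
        "beta,lam,gamma,expected",
        [
            (0.5, 1.0, 3.7, 1.0),              # flat region: slope = lambda
            (-0.5, 1.0, 3.7, 1.0),             # symmetric in beta
            (2.0, 1.0, 3.7, (3.7 - 2.0) / 2.7),  # clipped-linear region
            (3.7, 1.0, 3.7, 0.0),              # |beta| >= gamma*lambda
            (10.0, 1.0, 3.7, 0.0),
        ],
    )
    def test_scad_derivative_branches(self, beta, lam, gamma, expected):
        assert penalty_scad_derivative(beta, lam, gamma) == pytest.approx(expected)

    def test_scad_derivative_continuous_at_knots(self):
        lam, gamma = 0.8, 3.7
        for knot in (lam, gamma * lam):
            below = penalty_scad_derivative(knot - 1e-9, lam, gamma)
            above = penalty_scad_derivative(knot + 1e-9, lam, gamma)
            assert below == pytest.approx(above, abs=1e-7)

    @pytest.mark.parametrize(
        "beta,lam,gamma,expected",
        [
            (0.0, 1.3, 3.0, 0.0),
            (0.5, 1.0, 3.0, 0.5 - 0.25 / 6.0),
            (10.0, 1.0, 3.0, 1.5),  # saturated: 0.5 * gamma * lambda^2
        ],
    )
    def test_mcp_value(self, beta, lam, gamma, expected):
        assert penalty_mcp(beta, lam, gamma) == pytest.approx(expected)

    def test_mcp_continuous_at_knot(self):
        lam, gamma = 0.7, 3.0
        knot = gamma * lam
        inner = lam * knot - knot**2 / (2 * gamma)
        assert inner == pytest.approx(0.5 * gamma * lam**2)
        assert penalty_mcp(knot, lam, gamma) == pytest.approx(penalty_mcp(knot + 1e-12, lam, gamma))

    def test_scad_penalty_value_integrates_derivative(self):
        # numeric integral of the derivative == penalty value
        lam, gamma = 0.9, 3.7
        for b in (0.4, 1.5, 4.0):
            grid = np.linspace(0, b, 20001)
            integral = np.trapezoid(
                [penalty_scad_derivative(t, lam, gamma) for t in grid], grid
            )
            assert _solvers.scad_penalty(b, lam, gamma) == pytest.approx(integral, rel=1e-4)

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            penalty_scad_derivative(1.0, -0.1)
        with pytest.raises(ValueError):
            penalty_scad_derivative(1.0, 1.0, gamma=2.0)
        with pytest.raises(ValueError):
            penalty_mcp(1.0, -1.0)
        with pytest.raises(ValueError):
            penalty_mcp(1.0, 1.0, gamma=1.0)


class TestMbicScore:
    def test_pr_half_drops_extra_penalty(self):
        assert mbic_score(-50.0, 3, 100, 0.5) == pytest.approx(
            -50.0 - 1.5 * np.log(100)
        )

    def test_zero_predictors_is_loglik(self):
        assert mbic_score(-7.25, 0, 1000, 0.01) == -7.25

    def test_direct_arithmetic(self):
        # independent arithmetic: -100 - 1.5*log(200) - 3*log(906/4)
        expected = -100.0 - 1.5 * np.log(200.0) - 3.0 * np.log(906.0 / 4.0)
        assert mbic_score(-100.0, 3, 200, 4 / 910) == pytest.approx(expected, abs=1e-12)

    def test_invalid_pr(self):
        with pytest.raises(ValueError):
            mbic_score(0.0, 1, 10, 0.0)
        with pytest.raises(ValueError):
            mbic_score(0.0, 1, 10, 1.0)


# ---------------------------------------------------------------------------
# Stepwise (AIC and mBIC) against a naive re-implementation
# ---------------------------------------------------------------------------

def _naive_greedy(X, y, penalty_per_param):
    """Oracle: greedy forward selection refitting OLS from scratch each step."""
    n, p = X.shape

    def crit(subset):
        if subset:
            Xd = np.column_stack([np.ones(n), X[:, sorted(subset)]])
        else:
            Xd = np.ones((n, 1))
        beta, *_ = np.linalg.lstsq(Xd, y, rcond=None)
        rss = float(((y - Xd @ beta) ** 2).sum())
        return n * np.log(max(rss, 1e-300) / n) + penalty_per_param * len(subset)

    subset = set()
    while len(subset) < n - 3 and len(subset) < p:
        current = crit(subset)
        options = [(crit(subset | {j}), j) for j in range(p) if j not in subset]
        best_val, best_j = min(options)
        if best_val >= current:
            break
        subset.add(best_j)
    return sorted(subset)


class TestStepwiseAic:
    def test_noiseless_single_predictor(self, rng):
        x1 = rng.standard_normal(100)
        X = np.column_stack([x1, rng.standard_normal(100)])
        res = fit_stepwise_aic(X, 3.0 * x1, prefilter_p=1.01)
        assert list(res.support) == [0]
        assert res.coefficients[0] == pytest.approx(3.0)

    def test_matches_naive_greedy_oracle(self, rng):
        n, p = 50, 6
        X = rng.standard_normal((n, p))
        y = X[:, 0] * 1.5 - X[:, 3] * 0.8 + rng.standard_normal(n)
        res = fit_stepwise_aic(X, y, prefilter_p=1.01)
        oracle = _naive_greedy(X, y, penalty_per_param=2.0)
        assert sorted(res.support) == oracle
        # and the selected model's coefficients are the OLS fit
        beta = _ols(X[:, oracle], y)
        np.testing.assert_allclose(res.coefficients[oracle], beta[1:], atol=1e-8)

    def test_returned_aic_is_local_minimum_over_equal_size_subsets(self, rng):
        # exhaustive check: no same-size subset reachable by swapping one
        # variable has lower RSS than the greedy result *at the greedy path*
        n, p = 60, 6
        X = rng.standard_normal((n, p))
        y = 2.0 * X[:, 1] + rng.standard_normal(n)
        res = fit_stepwise_aic(X, y, prefilter_p=1.01)
        sel = set(res.support.tolist())

        def aic_of(subset):
            subset = sorted(subset)
            Xd = np.column_stack([np.ones(n), X[:, subset]]) if subset else np.ones((n, 1))
            beta, *_ = np.linalg.lstsq(Xd, y, rcond=None)
            rss = float(((y - Xd @ beta) ** 2).sum())
            return 2.0 * (len(subset) + 2) - 2.0 * _solvers.gaussian_loglik(rss, n)

        base = aic_of(sel)
        # single additions and deletions cannot improve AIC
        for j in range(p):
            if j not in sel:
                assert aic_of(sel | {j}) >= base - 1e-8
        for j in list(sel):
            assert aic_of(sel - {j}) >= base - 1e-8

    def test_prefilter_removes_uncorrelated(self, rng):
        n = 200
        x1 = rng.standard_normal(n)
        X = np.column_stack([x1] + [rng.standard_normal(n) for _ in range(10)])
        res = fit_stepwise_aic(X, 4.0 * x1 + 0.1 * rng.standard_normal(n), prefilter_p=0.8)
        assert res.hyperparams["n_candidates"] <= 11
        assert 0 in res.support


class TestMbicStepwise:
    def test_matches_naive_greedy_oracle(self, rng):
        n, p = 60, 8
        X = rng.standard_normal((n, p))
        y = 1.2 * X[:, 2] - 2.0 * X[:, 5] + rng.standard_normal(n)
        pr = 0.1
        a = np.log(n) + 2 * np.log((1 - pr) / pr)
        res = fit_mbic(X, y, pr=pr)
        assert sorted(res.support) == _naive_greedy(X, y, a)

    def test_mbic_beats_all_exhaustive_subsets(self, rng):
        # strong, well-separated signal: greedy must find the global optimum
        # over all 2^8 subsets
        n, p = 80, 8
        X = rng.standard_normal((n, p))
        y = 3.0 * X[:, 1] + 2.5 * X[:, 6] + 0.5 * rng.standard_normal(n)
        pr = 0.2
        res = fit_mbic(X, y, pr=pr)

        def score(subset):
            subset = sorted(subset)
            Xd = np.column_stack([np.ones(n), X[:, subset]]) if subset else np.ones((n, 1))
            beta, *_ = np.linalg.lstsq(Xd, y, rcond=None)
            rss = float(((y - Xd @ beta) ** 2).sum())
            return mbic_score(_solvers.gaussian_loglik(rss, n), len(subset), n, pr)

        import itertools

        best = max(
            score(s)
            for r in range(p + 1)
            for s in itertools.combinations(range(p), r)
        )
        assert res.criterion == pytest.approx(best, abs=1e-8)

    def test_pure_noise_gives_near_empty_support(self, rng):
        X = rng.standard_normal((150, 60))
        y = rng.standard_normal(150)
        res = fit_mbic(X, y)
        assert res.n_selected <= 1


# ---------------------------------------------------------------------------
# Penalized fitters: limits and oracles
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def small_problem():
    rng = np.random.default_rng(77)
    n, p = 80, 6
    X = rng.standard_normal((n, p))
    beta = np.array([2.0, -1.0, 0.0, 0.0, 1.0, 0.0])
    y = X @ beta + 0.3 * rng.standard_normal(n)
    return X, y


class TestZeroPenaltyLimits:
    def test_enet_lambda_zero_is_ols(self, small_problem):
        X, y = small_problem
        res = fit_elastic_net(
            X, y, CvSpec(repeats=1, folds=3, grids={"lambdas": [0.0], "alpha": [1.0]})
        )
        beta = _ols(X, y)
        np.testing.assert_allclose(res.coefficients, beta[1:], atol=1e-6)
        assert res.intercept == pytest.approx(beta[0], abs=1e-6)

    @pytest.mark.parametrize("penalty", ["scad", "mcp"])
    def test_ncv_lambda_zero_is_ols(self, small_problem, penalty):
        X, y = small_problem
        res = fit_ncv(
            X, y, penalty=penalty, cv=CvSpec(repeats=1, folds=3, grids={"lambdas": [0.0]})
        )
        beta = _ols(X, y)
        np.testing.assert_allclose(res.coefficients, beta[1:], atol=1e-6)


class TestElasticNet:
    def test_single_covariate_soft_threshold_closed_form(self, rng):
        # Oracle: for one standardized covariate and alpha=1 the lasso
        # solution is S(z, lam) with z = x'y/n in centered coordinates.
        n = 500
        x = rng.standard_normal(n)
        x = (x - x.mean()) / x.std()
        y = 1.7 * x + 0.4 * rng.standard_normal(n)
        z = x @ (y - y.mean()) / n
        for lam in (0.3, 1.0, abs(z) + 0.5):
            res = fit_elastic_net(
                x[:, None],
                y,
                CvSpec(repeats=1, folds=3, grids={"lambdas": [lam], "alpha": [1.0]}),
            )
            expected = np.sign(z) * max(abs(z) - lam, 0.0)
            assert res.coefficients[0] == pytest.approx(expected, abs=1e-6)

    def test_lasso_support_monotone_in_lambda(self, rng):
        # exact monotonicity holds for orthogonal designs, where the lasso
        # solution is coordinate-wise soft thresholding
        n, p = 120, 30
        X, _ = np.linalg.qr(rng.standard_normal((n, p)))
        X *= np.sqrt(n)
        y = X[:, :4] @ np.array([3.0, -2.0, 1.5, 1.0]) + rng.standard_normal(n)
        lambdas = np.geomspace(2.0, 1e-3, 40)
        coefs, _ = selectors._enet_path_fit(X, y, alpha=1.0, lambdas=lambdas)
        sizes = (np.abs(coefs) > selectors.ZERO_TOL).sum(axis=1)
        assert np.all(np.diff(sizes) >= 0)  # support grows as lambda decreases

    def test_zero_variance_column_warns_and_unselected(self, rng):
        X = np.column_stack([rng.standard_normal(60), np.full(60, 3.0)])
        y = 2.0 * X[:, 0] + 0.1 * rng.standard_normal(60)
        with pytest.warns(UserWarning, match="zero-variance"):
            res = fit_elastic_net(
                X, y, CvSpec(repeats=1, folds=3, grids={"lambdas": [0.1], "alpha": [1.0]})
            )
        assert 1 not in res.support


class TestNcv:
    @pytest.mark.parametrize("penalty,gamma", [("scad", 3.7), ("mcp", 3.0)])
    def test_orthonormal_design_matches_grid_search_oracle(self, penalty, gamma):
        # Oracle: with a single standardized covariate the solution minimizes
        # 0.5*(b - z)^2 + P(b); found by brute-force grid search.
        rng = np.random.default_rng(5)
        n = 4000
        x = rng.standard_normal(n)
        x = (x - x.mean()) / x.std()
        lam = 0.5
        for target in (0.3, 1.0, 5.0):
            y = target * x
            _, coefs, _, _ = _solvers.ncv_path(
                x[:, None], y, penalty, lambdas=np.array([lam]), gamma=gamma
            )
            z = x @ (y - y.mean()) / n
            grid = np.linspace(-8, 8, 400001)
            pen = (
                _solvers.scad_penalty(grid, lam, gamma)
                if penalty == "scad"
                else _solvers.mcp_penalty(grid, lam, gamma)
            )
            oracle = grid[np.argmin(0.5 * (grid - z) ** 2 + pen)]
            assert coefs[0, 0] == pytest.approx(oracle, abs=1e-4)

    def test_recovers_sparse_signal(self, small_problem):
        X, y = small_problem
        res = fit_ncv(X, y, "mcp", CvSpec(repeats=1, folds=5, seed=1))
        assert set(res.support) == {0, 1, 4}

    def test_bad_penalty_rejected(self, small_problem):
        X, y = small_problem
        with pytest.raises(ValueError):
            fit_ncv(X, y, penalty="lasso")


class TestSparseStep:
    def test_penalty_limits(self):
        # beta=0 contributes nothing; |beta| >> gamma saturates at lam
        lam, gamma = 2.0, 1e-3
        assert lam * 0.0**2 / (0.0**2 + gamma**2) == 0.0
        b = 10.0
        assert lam * b**2 / (b**2 + gamma**2) == pytest.approx(lam, rel=1e-6)

    def test_single_covariate_matches_1d_grid_oracle(self, rng):
        n = 300
        x = rng.standard_normal(n)
        x = (x - x.mean()) / x.std()
        gmin = 1e-6
        for target, lam in [(2.0, 0.5), (0.05, 1.0)]:
            y = target * x + 0.05 * rng.standard_normal(n)
            coef, icept, _ = _solvers.sparsestep_fit(
                x[:, None], y, lam=lam, gamma_min=gmin, screen_k=None
            )
            yc = y - y.mean()
            grid = np.linspace(-4, 4, 200001)
            obj = 0.5 * ((yc[:, None] - np.outer(x, grid)) ** 2).mean(axis=0) + (
                lam * grid**2 / (grid**2 + gmin**2)
            )
            oracle = grid[np.argmin(obj)]
            assert coef[0] == pytest.approx(oracle, abs=5e-2)

    def test_recovers_sparse_signal(self, small_problem):
        X, y = small_problem
        res = fit_sparsestep(X, y, CvSpec(repeats=1, folds=5, seed=2))
        assert set(res.support) == {0, 1, 4}


# ---------------------------------------------------------------------------
# Registry-level invariants
# ---------------------------------------------------------------------------

class TestRegistry:
    def test_unknown_method_raises(self, small_problem):
        with pytest.raises(ValueError):
            fit_selector("ridge", *small_problem)

    def test_all_methods_return_aligned_vectors(self, tiny_dataset):
        cv = CvSpec.fast(seed=3, folds=3)
        for method in SELECTORS:
            res = fit_selector(method, tiny_dataset.X, tiny_dataset.y, cv)
            assert res.coefficients.shape == (tiny_dataset.p,)
            assert res.method == method
            assert np.all(res.support < tiny_dataset.p)

    def test_sparsity_ordering_on_signal_dataset(self, tiny_dataset):
        # qualitative ordering: mBIC sparsest, stepwise AIC densest
        cv = CvSpec.fast(seed=3, folds=3)
        sizes = {
            m: fit_selector(m, tiny_dataset.X, tiny_dataset.y, cv).n_selected
            for m in SELECTORS
        }
        assert sizes["mbic"] <= sizes["enet"]
        assert sizes["enet"] <= sizes["aic"]
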