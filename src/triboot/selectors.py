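"""Six variable-selection methods under one contract.

Every fitter takes a design matrix ``X`` (n x p) and outcome ``y`` and
returns a :class:`SelectionResult` whose full-length coefficient vector
defines the selected support (zero = not selected).  Methods:

``aic``
    Forward stepwise OLS minimizing AIC after a univariate correlation
    pre-filter (covariates with correlation-test p-value > 0.80 dropped).
``enet``
    Elastic net, (lambda, alpha) tuned by repeated k-fold CV minimizing
    mean absolute error (sklearn coordinate descent).
``scad`` / ``mcp``
    Nonconvex penalized least squares (smoothly clipped absolute deviation /
    minimax concave penalty), coordinate descent with warm starts along a
    decreasing lambda path, lambda tuned by CV-MAE.
``sparsestep``
    SparseStep penalty lam * b^2/(b^2+g^2) solved by iterative majorization
    with a tightening gamma schedule, lambda tuned by CV-MAE.
``mbic``
    Forward stepwise maximizing a modified BIC whose extra k*log((1-pr)/pr)
    term increases sparsity when candidate predictors vastly outnumber the
    expected true ones.

The intercept is always unpenalized and never part of the support.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import ElasticNet

from . import _solvers
from ._solvers import gaussian_loglik

__all__ = [
    "ZERO_TOL",
    "SelectionResult",
    "CvSpec",
    "SELECTORS",
    "fit_selector",
    "fit_stepwise_aic",
    "fit_elastic_net",
    "fit_ncv",
    "fit_scad",
    "fit_mcp",
    "fit_sparsestep",
    "fit_mbic",
    "penalty_scad_derivative",
    "penalty_mcp",
    "mbic_score",
]

#: Coefficients below this magnitude (standardized data) count as "not selected".
ZERO_TOL = 1e-8


@dataclass
class SelectionResult:
    """Outcome of one selection fit: coefficients, support and diagnostics."""

    coefficients: np.ndarray
    intercept: float
    method: str
    hyperparams: dict = field(default_factory=dict)
    criterion: float = np.nan
    converged: bool = True

    @property
    def support(self) -> np.ndarray:
        return np.flatnonzero(np.abs(self.coefficients) > ZERO_TOL)

    @property
    def n_selected(self) -> int:
        return int(self.support.size)

    def predict(self, X) -> np.ndarray:
        return self.intercept + np.asarray(X, dtype=float) @ self.coefficients


@dataclass(frozen=True)
class CvSpec:
    """Cross-validation settings for hyperparameter tuning.

    ``grids`` overrides per-method defaults; recognized keys are
    ``alpha``/``n_lambdas``/``lambda_min_ratio``/``lambdas``/
    ``enet_screen_k`` (elastic net), ``gamma``/``n_lambdas``/
    ``lambda_min_ratio_ncv``/``lambdas`` (SCAD/MCP),
    ``lam``/``gamma_min``/``gamma_factor``/``screen_k`` (SparseStep) and
    ``dfmax`` (largest support evaluated during CV, shared by the penalized
    methods).  The only supported loss is mean absolute error.
    """

    repeats: int = 10
    folds: int = 10
    loss: str = "mae"
    grids: dict | None = None
    seed: int = 0

    def __post_init__(self):
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.loss != "mae":
            raise ValueError(f"unsupported CV loss {self.loss!r}; only 'mae'")

    @classmethod
    def fast(cls, seed: int = 0, folds: int = 5, grids: dict | None = None) -> "CvSpec":
        """Single-repeat, few-fold CV with reduced grids (bootstrap speed mode)."""
        merged = dict(FAST_GRIDS)
        if grids:
            merged.update(grids)
        return cls(repeats=1, folds=folds, grids=merged, seed=seed)


#: Full-scale default grids (10 x 10-fold CV callers).
DEFAULT_GRIDS = {
    "alpha": tuple(np.round(np.arange(0.1, 1.01, 0.1), 2)),
    "n_lambdas": 100,
    "lambda_min_ratio": 1e-3,
    "lambda_min_ratio_ncv": 1e-3,
    "gamma_scad": (3.7,),
    "gamma_mcp": (3.0,),
    "lam_sparsestep": tuple(float(2.0**k) for k in range(-6, 4)),
    "gamma_min": (1e-6,),
    "gamma_factor": 0.5,
    "screen_k": 400,
    "enet_screen_k": None,
    "dfmax": None,
}

#: Reduced grids for CV inside bootstrap replicates.
FAST_GRIDS = {
    "alpha": (0.1, 0.55, 1.0),
    "n_lambdas": 15,
    "lambda_min_ratio": 0.02,
    "lambda_min_ratio_ncv": 0.05,
    "gamma_scad": (3.7,),
    "gamma_mcp": (3.0,),
    "lam_sparsestep": (0.125, 0.5, 2.0, 8.0),
    "gamma_min": (1e-6,),
    "gamma_factor": 0.25,
    "screen_k": 300,
    "enet_screen_k": None,
    "dfmax": 150,
}


def _grid(cv: CvSpec | None, key: str, default_key: str | None = None):
    grids = (cv.grids if cv and cv.grids else {})
    return grids.get(key, DEFAULT_GRIDS[default_key or key])


def _cv_folds(n: int, cv: CvSpec):
    """Yield (train_idx, val_idx) for repeats x folds, seeded."""
    rng = np.random.default_rng(cv.seed)
    for _ in range(cv.repeats):
        perm = rng.permutation(n)
        for fold in np.array_split(perm, cv.folds):
            mask = np.ones(n, dtype=bool)
            mask[fold] = False
            yield np.flatnonzero(mask), fold


def _check_xy(X, y):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-dimensional")
    if y.shape[0] != X.shape[0]:
        raise ValueError("X and y have different numbers of rows")
    return X, y


def _warn_zero_variance(X) -> np.ndarray:
    sd = X.std(axis=0)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        warnings.warn(
            f"{zero.size} zero-variance column(s) excluded from selection",
            stacklevel=3,
        )
    return zero


# ---------------------------------------------------------------------------
# Penalty building blocks (exposed for direct verification)
# ---------------------------------------------------------------------------

def penalty_scad_derivative(beta: float, lam: float, gamma: float = 3.7) -> float:
    """Derivative of the SCAD penalty: lam, then linearly clipped, then 0."""
    if lam < 0:
        raise ValueError("lam must be >= 0")
    if gamma <= 2:
        raise ValueError("SCAD requires gamma > 2")
    b = abs(beta)
    if b <= lam:
        return float(lam)
    if b < gamma * lam:
        return float((gamma * lam - b) / (gamma - 1.0))
    return 0.0


def penalty_mcp(beta: float, lam: float, gamma: float = 3.0) -> float:
    """MCP penalty value: lam|b| - b^2/(2 gamma) for |b| <= gamma*lam, else 0.5*gamma*lam^2."""
    if lam < 0:
        raise ValueError("lam must be >= 0")
    if gamma <= 1:
        raise ValueError("MCP requires gamma > 1")
    return float(_solvers.mcp_penalty(beta, lam, gamma))


def mbic_score(logL: float, k: int, n: int, pr: float) -> float:
    """Modified BIC: logL - 0.5*k*log(n) - k*log((1-pr)/pr); larger is better."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not (0.0 < pr < 1.0):
        raise ValueError(f"pr must be in (0, 1), got {pr}")
    return float(logL - 0.5 * k * np.log(n) - k * np.log((1.0 - pr) / pr))


# ---------------------------------------------------------------------------
# Stepwise AIC
# ---------------------------------------------------------------------------

def _univariate_corr_pvalues(X, y) -> np.ndarray:
    """Two-sided p-values of the Pearson correlation test, vectorized."""
    from scipy import stats

    n = X.shape[0]
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    sx = np.sqrt((Xc**2).sum(axis=0))
    sy = np.sqrt(yc @ yc)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc.T @ yc) / (sx * sy)
    r = np.clip(np.nan_to_num(r), -1.0, 1.0)
    df = n - 2
    with np.errstate(divide="ignore", over="ignore"):
        t = r * np.sqrt(df / np.maximum(1.0 - r**2, np.finfo(float).tiny))
    return 2.0 * stats.t.sf(np.abs(t), df)


def fit_stepwise_aic(
    X, y, cv: CvSpec | None = None, *, prefilter_p: float = 0.80, max_steps: int | None = None
) -> SelectionResult:
    """Forward stepwise OLS minimizing AIC = 2k - 2 ln L (Gaussian).

    Covariates whose univariate correlation-test p-value exceeds
    ``prefilter_p`` are removed first; steps that would leave the model
    non-estimable are rejected.  ``cv`` is accepted for registry uniformity
    and ignored.
    """
    X, y = _check_xy(X, y)
    n, p = X.shape
    if n <= 2:
        raise ValueError("need n > 2 observations")
    pvals = _univariate_corr_pvalues(X, y)
    candidates = np.flatnonzero(pvals <= prefilter_p)
    selected, coef, intercept, rss = _solvers.forward_stepwise(
        X, y, penalty_per_param=2.0, candidates=candidates, max_steps=max_steps
    )
    k = selected.size
    aic = 2.0 * (k + 2) - 2.0 * gaussian_loglik(rss, n)
    return SelectionResult(
        coefficients=coef,
        intercept=intercept,
        method="aic",
        hyperparams={"prefilter_p": prefilter_p, "n_candidates": int(candidates.size)},
        criterion=aic,
    )


# ---------------------------------------------------------------------------
# Elastic net
# ---------------------------------------------------------------------------

def _enet_lambda_path(X, y, alpha, n_lambdas, lambda_min_ratio):
    n = X.shape[0]
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    lam_max = np.abs(Xc.T @ yc).max() / (n * max(alpha, 1e-3))
    if lam_max <= 0:
        lam_max = 1.0
    return np.geomspace(lam_max, lam_max * lambda_min_ratio, n_lambdas)


#: Precompute the p x p Gram matrix for the path solver below this width.
_GRAM_MAX_P = 2000


def _enet_path_fit(Xtr, ytr, alpha, lambdas, gram=None, tol=1e-4, max_iter=3000):
    """Warm-started coordinate-descent path (decreasing lambda).

    Data are centered here (unpenalized intercept); ``gram`` may carry the
    centered Gram matrix Xc'Xc to share across alpha values.  Returns
    (coefs, icepts) with rows aligned to ``lambdas``.
    """
    from sklearn.linear_model import enet_path

    x_mean = Xtr.mean(axis=0)
    y_mean = ytr.mean()
    Xc = Xtr - x_mean
    yc = ytr - y_mean
    coefs = np.empty((lambdas.size, Xtr.shape[1]))
    pos = lambdas > 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        if pos.any():
            precompute = gram if gram is not None else (Xtr.shape[1] <= _GRAM_MAX_P)
            _, path_coefs, _ = enet_path(
                Xc,
                yc,
                l1_ratio=alpha,
                alphas=lambdas[pos],
                precompute=precompute,
                Xy=Xc.T @ yc if precompute is not False else None,
                tol=tol,
                max_iter=max_iter,
            )
            coefs[pos] = path_coefs.T
    if (~pos).any():  # lambda = 0: unpenalized least squares
        beta, *_ = np.linalg.lstsq(Xc, yc, rcond=None)
        coefs[~pos] = beta
    icepts = y_mean - coefs @ x_mean
    return coefs, icepts


def _centered_gram(X):
    Xc = X - X.mean(axis=0)
    return Xc.T @ Xc if X.shape[1] <= _GRAM_MAX_P else None


def _enet_cv_errors(
    Xtr, ytr, Xva, yva, alpha, lambdas, gram=None, dfmax=None, tol=1e-3, max_iter=3000,
):
    """Validation MAE along a decreasing lambda path.

    Models whose support outgrows ``dfmax`` are excluded (infinite error)
    and the rest of the path abandoned: the dense deep end of the path is
    useless for sparse selection and dominates runtime on weak-signal data.
    """
    x_mean = Xtr.mean(axis=0)
    y_mean = ytr.mean()
    Xc = Xtr - x_mean
    yc = ytr - y_mean
    Xvc = Xva - x_mean
    err = np.full(lambdas.size, np.inf)
    est = ElasticNet(
        l1_ratio=alpha, warm_start=True, fit_intercept=False,
        precompute=gram if gram is not None else False,
        tol=tol, max_iter=max_iter,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for i, lam in enumerate(lambdas):
            if lam == 0.0:
                coef, *_ = np.linalg.lstsq(Xc, yc, rcond=None)
                nnz = Xc.shape[1]
            else:
                est.set_params(alpha=lam)
                est.fit(Xc, yc)
                coef = est.coef_
                nnz = np.count_nonzero(coef)
            if dfmax is not None and nnz > dfmax:
                break
            err[i] = np.abs(Xvc @ coef + y_mean - yva).mean()
    return err


def fit_elastic_net(X, y, cv: CvSpec | None = None) -> SelectionResult:
    """Elastic net (Eq.-3 mixed L1/L2 penalty), tuned by repeated k-fold CV-MAE.

    The loss is (1/2n)||y - Xb||^2 + lam*[(1-alpha)/2 ||b||^2 + alpha ||b||_1],
    i.e. sklearn's ElasticNet with alpha=lam and l1_ratio=alpha.  Ties in CV
    MAE go to the larger lambda (sparser model), then the larger alpha.
    """
    X, y = _check_xy(X, y)
    cv = cv or CvSpec()
    _warn_zero_variance(X)
    alphas = np.atleast_1d(np.asarray(_grid(cv, "alpha"), dtype=float))
    explicit = cv.grids.get("lambdas") if cv.grids else None
    n_lam = int(_grid(cv, "n_lambdas"))
    min_ratio = float(_grid(cv, "lambda_min_ratio"))
    screen_k = _grid(cv, "enet_screen_k")

    p_full = X.shape[1]
    keep = np.arange(p_full)
    if screen_k is not None and p_full > int(screen_k):
        # Marginal-correlation screening for very wide designs: the dense CD
        # path then runs over the top-k candidates only.
        Xc = X - X.mean(axis=0)
        score = np.abs(Xc.T @ (y - y.mean()))
        keep = np.sort(np.argsort(score)[::-1][: int(screen_k)])
        X = X[:, keep]

    folds = list(_cv_folds(X.shape[0], cv))
    paths = {
        alpha: (
            np.asarray(explicit, dtype=float)
            if explicit is not None
            else _enet_lambda_path(X, y, alpha, n_lam, min_ratio)
        )
        for alpha in alphas
    }
    dfmax = _grid(cv, "dfmax")
    err = {alpha: np.zeros(paths[alpha].size) for alpha in alphas}
    for tr, va in folds:
        gram = _centered_gram(X[tr])  # shared across the alpha grid
        for alpha in alphas:
            err[alpha] += _enet_cv_errors(
                X[tr], y[tr], X[va], y[va], alpha, paths[alpha], gram=gram, dfmax=dfmax
            )
    best = None  # ((mae, -lam, -alpha), lam, alpha)
    for alpha in alphas:
        for i, lam in enumerate(paths[alpha]):
            cand = (err[alpha][i] / len(folds), -lam, -alpha)
            if best is None or cand < best[0]:
                best = (cand, lam, alpha)
    _, lam_star, alpha_star = best
    # Final fit at the tuned pair, warm-started from lambda_max for stability.
    lambdas = paths[alpha_star]
    upto = lambdas >= lam_star
    path = np.append(lambdas[upto], lam_star) if not np.any(lambdas == lam_star) else lambdas[upto]
    coefs, icepts = _enet_path_fit(X, y, alpha_star, path)
    coef_full = np.zeros(p_full)
    coef_full[keep] = coefs[-1]
    return SelectionResult(
        coefficients=coef_full,
        intercept=float(icepts[-1]),
        method="enet",
        hyperparams={"lambda": float(lam_star), "alpha": float(alpha_star)},
        criterion=float(best[0][0]),
    )


# ---------------------------------------------------------------------------
# SCAD / MCP
# ---------------------------------------------------------------------------

def fit_ncv(X, y, penalty: str = "scad", cv: CvSpec | None = None) -> SelectionResult:
    """SCAD or MCP penalized least squares; (lambda, gamma) tuned by CV-MAE."""
    penalty = penalty.lower()
    if penalty not in ("scad", "mcp"):
        raise ValueError(f"penalty must be 'scad' or 'mcp', got {penalty!r}")
    X, y = _check_xy(X, y)
    cv = cv or CvSpec()
    _warn_zero_variance(X)
    gammas = np.atleast_1d(np.asarray(_grid(cv, "gamma", f"gamma_{penalty}"), dtype=float))
    explicit = cv.grids.get("lambdas") if cv.grids else None
    n_lam = int(_grid(cv, "n_lambdas"))
    min_ratio = float(_grid(cv, "lambda_min_ratio_ncv"))

    Xs, ys, *_ = _solvers.standardize(X, y)
    lambdas = (
        np.asarray(explicit, dtype=float)
        if explicit is not None
        else _solvers.default_lambda_path(Xs, ys, n_lam, min_ratio)
    )

    folds = list(_cv_folds(X.shape[0], cv))
    dfmax = _grid(cv, "dfmax")
    best = None
    for gamma in gammas:
        err = np.zeros(lambdas.size)
        for tr, va in folds:
            # CV paths run at a relaxed tolerance; only the error ranking
            # matters here, the tuned model is refit at full tolerance below.
            _, coefs, icepts, _ = _solvers.ncv_path(
                X[tr], y[tr], penalty=penalty, lambdas=lambdas, gamma=gamma,
                dfmax=dfmax, tol=1e-3,
            )
            pred = X[va] @ coefs.T + icepts
            with np.errstate(invalid="ignore"):
                fold_err = np.abs(pred - y[va][:, None]).mean(axis=0)
            err += np.where(np.isnan(fold_err), np.inf, fold_err)  # truncated tail
        err /= len(folds)
        for i, lam in enumerate(lambdas):
            cand = (err[i], -lam, gamma)
            if best is None or cand < best[0]:
                best = (cand, lam, gamma)
    _, lam_star, gamma_star = best
    path = lambdas[lambdas >= lam_star]
    if not np.any(path == lam_star):
        path = np.append(path, lam_star)
    _, coefs, icepts, converged = _solvers.ncv_path(
        X, y, penalty=penalty, lambdas=path, gamma=gamma_star
    )
    return SelectionResult(
        coefficients=coefs[-1],
        intercept=float(icepts[-1]),
        method=penalty,
        hyperparams={"lambda": float(lam_star), "gamma": float(gamma_star)},
        criterion=float(best[0][0]),
        converged=converged,
    )


def fit_scad(X, y, cv: CvSpec | None = None) -> SelectionResult:
    return fit_ncv(X, y, penalty="scad", cv=cv)


def fit_mcp(X, y, cv: CvSpec | None = None) -> SelectionResult:
    return fit_ncv(X, y, penalty="mcp", cv=cv)


# ---------------------------------------------------------------------------
# SparseStep
# ---------------------------------------------------------------------------

def fit_sparsestep(X, y, cv: CvSpec | None = None) -> SelectionResult:
    """SparseStep regression; lambda (and gamma-schedule endpoint) tuned by CV-MAE."""
    X, y = _check_xy(X, y)
    cv = cv or CvSpec()
    _warn_zero_variance(X)
    lams = np.atleast_1d(np.asarray(_grid(cv, "lam", "lam_sparsestep"), dtype=float))
    gmins = np.atleast_1d(np.asarray(_grid(cv, "gamma_min"), dtype=float))
    gfactor = float(_grid(cv, "gamma_factor"))
    screen_k = int(_grid(cv, "screen_k"))

    folds = list(_cv_folds(X.shape[0], cv))
    best = None
    for gmin in gmins:
        err = np.zeros(lams.size)
        for tr, va in folds:
            coefs, icepts, _ = _solvers.sparsestep_path(
                X[tr], y[tr], lams, gamma_min=gmin, gamma_factor=gfactor, screen_k=screen_k
            )
            pred = X[va] @ coefs.T + icepts
            err += np.abs(pred - y[va][:, None]).mean(axis=0)
        err /= len(folds)
        for i, lam in enumerate(lams):
            cand = (err[i], -lam, gmin)
            if best is None or cand < best[0]:
                best = (cand, lam, gmin)
    _, lam_star, gmin_star = best
    coef, icept, converged = _solvers.sparsestep_fit(
        X, y, lam=lam_star, gamma_min=gmin_star, gamma_factor=gfactor, screen_k=screen_k
    )
    return SelectionResult(
        coefficients=coef,
        intercept=icept,
        method="sparsestep",
        hyperparams={"lambda": float(lam_star), "gamma_min": float(gmin_star)},
        criterion=float(best[0][0]),
        converged=converged,
    )


# ---------------------------------------------------------------------------
# mBIC stepwise
# ---------------------------------------------------------------------------

def fit_mbic(X, y, cv: CvSpec | None = None, *, pr: float | str = "auto") -> SelectionResult:
    """Forward stepwise selection maximizing the modified BIC.

    ``pr`` is the prior probability that a random candidate influences y;
    the auto rule uses 4/p (expected four true predictors), clamped below
    0.5 so the extra penalty never becomes a bonus.  ``cv`` is ignored.
    """
    X, y = _check_xy(X, y)
    n, p = X.shape
    if pr == "auto":
        pr = min(4.0 / p, 0.45)
    if not (0.0 < pr < 1.0):
        raise ValueError(f"pr must be in (0, 1), got {pr}")
    a = np.log(n) + 2.0 * np.log((1.0 - pr) / pr)
    selected, coef, intercept, rss = _solvers.forward_stepwise(X, y, penalty_per_param=a)
    score = mbic_score(gaussian_loglik(rss, n), selected.size, n, pr)
    return SelectionResult(
        coefficients=coef,
        intercept=intercept,
        method="mbic",
        hyperparams={"pr": float(pr)},
        criterion=score,
    )


#: Registry of selectors under the uniform signature f(X, y, cv) -> SelectionResult.
SELECTORS = {
    "aic": fit_stepwise_aic,
    "enet": fit_elastic_net,
    "scad": fit_scad,
    "mcp": fit_mcp,
    "sparsestep": fit_sparsestep,
    "mbic": fit_mbic,
}


def fit_selector(method: str, X, y, cv: CvSpec | None = None) -> SelectionResult:
    """Dispatch a fit through the method registry."""
    try:
        fn = SELECTORS[method]
    except KeyError:
        raise ValueError(f"unknown method {method!r}; known: {sorted(SELECTORS)}") from None
    return fn(X, y, cv)
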