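"""Numerical workhorses behind the selector fitters.

Three independent engines live here:

* an active-set coordinate-descent path solver for nonconvex penalties
  (SCAD / MCP) on the 1/(2n)-scaled least-squares objective, with warm
  starts along a decreasing lambda path and KKT screening sweeps;
* an iterative-majorization solver for the SparseStep penalty
  lambda * beta^2 / (beta^2 + gamma^2) with a halving gamma schedule;
* a greedy forward-stepwise engine for penalized log-likelihood criteria
  of the form n*log(RSS/n) + a*k (AIC, mBIC), using incremental
  Gram-Schmidt orthogonalization so each step costs O(n p).

All solvers center y and standardize the columns of X internally
(population SD) and report coefficients on the original scale.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# Penalty codes for the jitted kernel.
_SCAD = 0
_MCP = 1


def standardize(X: np.ndarray, y: np.ndarray):
    """Center y, center and unit-scale columns of X (population SD).

    Zero-variance columns get scale 1 and become all-zero after centering,
    so their coefficients stay exactly 0. Returns (Xs, ys, x_mean, x_sd,
    y_mean, zero_var_mask).
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    x_mean = X.mean(axis=0)
    x_sd = X.std(axis=0)
    zero_var = x_sd == 0.0
    x_sd = np.where(zero_var, 1.0, x_sd)
    Xs = (X - x_mean) / x_sd
    y_mean = y.mean()
    return np.asfortranarray(Xs), y - y_mean, x_mean, x_sd, y_mean, zero_var


@njit(cache=True)
def _cd_sweeps(Xs, r, b, active, lam, gamma, penalty, tol, max_sweeps):
    """Coordinate-descent sweeps over the active set (unit-variance columns).

    Updates b and the residual r in place; returns the number of sweeps.
    Threshold operators assume (1/n)||x_j||^2 == 1.
    """
    n = Xs.shape[0]
    for sweep in range(max_sweeps):
        max_delta = 0.0
        for idx in range(active.shape[0]):
            j = active[idx]
            xj = Xs[:, j]
            z = b[j]
            for i in range(n):
                z += xj[i] * r[i] / n
            az = abs(z)
            if penalty == _SCAD:
                if az <= 2.0 * lam:
                    new = np.sign(z) * max(az - lam, 0.0)
                elif az <= gamma * lam:
                    t = gamma * lam / (gamma - 1.0)
                    new = np.sign(z) * max(az - t, 0.0) / (1.0 - 1.0 / (gamma - 1.0))
                else:
                    new = z
            else:  # MCP
                if az <= gamma * lam:
                    new = np.sign(z) * max(az - lam, 0.0) / (1.0 - 1.0 / gamma)
                else:
                    new = z
            delta = new - b[j]
            if delta != 0.0:
                for i in range(n):
                    r[i] -= delta * xj[i]
                b[j] = new
                if abs(delta) > max_delta:
                    max_delta = abs(delta)
        if max_delta < tol:
            return sweep + 1
    return max_sweeps


def scad_penalty(beta, lam: float, gamma: float = 3.7):
    """SCAD penalty value (the integral of the clipped-linear derivative)."""
    beta = np.abs(np.asarray(beta, dtype=float))
    out = np.where(
        beta <= lam,
        lam * beta,
        np.where(
            beta < gamma * lam,
            (2.0 * gamma * lam * beta - beta**2 - lam**2) / (2.0 * (gamma - 1.0)),
            lam**2 * (gamma + 1.0) / 2.0,
        ),
    )
    return out if out.ndim else float(out)


def mcp_penalty(beta, lam: float, gamma: float = 3.0):
    """MCP penalty value: lam|b| - b^2/(2 gamma) inside, 0.5 gamma lam^2 beyond."""
    beta = np.abs(np.asarray(beta, dtype=float))
    out = np.where(
        beta <= gamma * lam,
        lam * beta - beta**2 / (2.0 * gamma),
        0.5 * gamma * lam**2,
    )
    return out if out.ndim else float(out)


def default_lambda_path(Xs, ys, n_lambdas=100, lambda_min_ratio=1e-3):
    """Geometric lambda path from lambda_max (all-zero solution) downward."""
    n = Xs.shape[0]
    lam_max = np.abs(Xs.T @ ys).max() / n
    if lam_max <= 0:
        lam_max = 1.0
    return np.geomspace(lam_max, lam_max * lambda_min_ratio, n_lambdas)


def ncv_path(
    X,
    y,
    penalty: str = "scad",
    lambdas=None,
    gamma: float | None = None,
    n_lambdas: int = 100,
    lambda_min_ratio: float = 1e-3,
    tol: float = 1e-4,
    max_sweeps: int = 200,
    max_kkt_rounds: int = 20,
    dfmax: int | None = None,
    callback=None,
):
    """Solve min (1/2n)||y - b0 - X b||^2 + sum_j P(b_j; lam, gamma) along a lambda path.

    P is the SCAD or MCP penalty applied to internally standardized
    coefficients.  Returns (lambdas, coefs, intercepts, converged) with
    coefs of shape (n_lambda, p) on the original scale.

    ``dfmax`` truncates the path once the active set outgrows it (the dense
    deep end of the path is useless for selection and dominates runtime on
    weak-signal data); truncated entries are returned as NaN rows.
    ``callback(li, coef, intercept) -> bool`` is invoked after each solved
    lambda (original-scale values); returning False abandons the rest of
    the path the same way.
    """
    pen_code = {"scad": _SCAD, "mcp": _MCP}[penalty.lower()]
    if gamma is None:
        gamma = 3.7 if pen_code == _SCAD else 3.0
    if pen_code == _SCAD and gamma <= 2.0:
        raise ValueError(f"SCAD requires gamma > 2, got {gamma}")
    if pen_code == _MCP and gamma <= 1.0:
        raise ValueError(f"MCP requires gamma > 1, got {gamma}")

    Xs, ys, _, x_sd, y_mean, _ = standardize(X, y)
    n, p = Xs.shape
    if lambdas is None:
        lambdas = default_lambda_path(Xs, ys, n_lambdas, lambda_min_ratio)
    lambdas = np.asarray(lambdas, dtype=float)
    if np.any(lambdas < 0):
        raise ValueError("lambda must be >= 0")

    b = np.zeros(p)
    r = ys.copy()
    coefs = np.full((lambdas.size, p), np.nan)
    x_mean = np.asarray(X, dtype=float).mean(axis=0)
    converged = True

    for li, lam in enumerate(lambdas):
        if lam == 0.0:
            # Unpenalized limit: plain least squares (well-posed only for p < n).
            beta, *_ = np.linalg.lstsq(Xs, ys, rcond=None)
            b = beta
            r = ys - Xs @ b
        else:
            for _ in range(max_kkt_rounds):
                active = np.flatnonzero(b)
                if active.size:
                    sweeps = _cd_sweeps(
                        Xs, r, b, active, lam, gamma, pen_code, tol, max_sweeps
                    )
                    if sweeps >= max_sweeps:
                        converged = False
                # KKT check over all coordinates: a zero coefficient may enter
                # when its gradient magnitude exceeds the penalty slope at 0+.
                z = Xs.T @ r / n
                viol = np.flatnonzero((np.abs(z) > lam * (1 + 1e-9)) & (b == 0.0))
                if viol.size == 0:
                    break
                _cd_sweeps(Xs, r, b, viol, lam, gamma, pen_code, tol, 1)
            else:
                converged = False
        if dfmax is not None and np.count_nonzero(b) > dfmax:
            break
        coefs[li] = b / x_sd
        if callback is not None:
            icept = y_mean - coefs[li] @ x_mean
            if not callback(li, coefs[li], icept):
                break
    with np.errstate(invalid="ignore"):
        intercepts = y_mean - coefs @ x_mean  # NaN rows stay NaN
    return lambdas, coefs, intercepts, converged


def sparsestep_path(
    X,
    y,
    lams,
    gamma_init: float = 1.0,
    gamma_min: float = 1e-6,
    gamma_factor: float = 0.5,
    max_im_iter: int = 2,
    tol: float = 1e-6,
    zero_tol: float = 1e-3,
    screen_k: int | None = 400,
):
    """SparseStep: min (1/2n)||y - b0 - X b||^2 + lam * sum_j b_j^2/(b_j^2 + g^2).

    The nonconvex penalty is attacked by iterative majorization: at the
    current iterate the penalty term is overbounded by the quadratic
    g^2/(b0^2+g^2)^2 * b^2, so each step is a weighted ridge solve; gamma is
    tightened geometrically from ``gamma_init`` to ``gamma_min`` so the
    penalty approaches lam * ||b||_0.  Coefficients below ``zero_tol`` (on
    the standardized scale) are hard-zeroed at the end.

    When p > ``screen_k`` the problem is first screened to the top
    ``screen_k`` covariates by absolute marginal correlation; every dense
    solve then costs O(screen_k^3).  The screening set and Gram matrix are
    shared across all values in ``lams``.

    Returns (coefs, intercepts, converged) with coefs of shape
    (len(lams), p) on the original scale.
    """
    lams = np.atleast_1d(np.asarray(lams, dtype=float))
    if np.any(lams < 0):
        raise ValueError("lam must be >= 0")
    Xs, ys, _, x_sd, y_mean, _ = standardize(X, y)
    n, p = Xs.shape

    keep = np.arange(p)
    if screen_k is not None and p > screen_k:
        score = np.abs(Xs.T @ ys)
        keep = np.sort(np.argsort(score)[::-1][:screen_k])
        Xs = Xs[:, keep]
    k = Xs.shape[1]

    G = (Xs.T @ Xs) / n
    c = Xs.T @ ys / n
    # Ridge warm start keeps the first majorization step well-conditioned.
    b_init = np.linalg.solve(G + 1e-3 * np.eye(k), c)

    coefs = np.zeros((lams.size, p))
    converged = True
    eye_idx = np.diag_indices(k)
    for li, lam in enumerate(lams):
        b = b_init.copy()
        gamma = gamma_init
        while gamma >= gamma_min * (1 - 1e-12):
            for _ in range(max_im_iter):
                w = gamma**2 / (b**2 + gamma**2) ** 2
                A = G + 2.0 * lam * np.diag(w)
                A[eye_idx] += 1e-10
                try:
                    b_new = np.linalg.solve(A, c)
                except np.linalg.LinAlgError:
                    converged = False
                    b_new = b
                delta = np.max(np.abs(b_new - b))
                b = b_new
                if delta < tol:
                    break
            gamma *= gamma_factor
        b[np.abs(b) < zero_tol] = 0.0
        coefs[li, keep] = b
    coefs /= x_sd
    x_mean = np.asarray(X, dtype=float).mean(axis=0)
    intercepts = y_mean - coefs @ x_mean
    return coefs, intercepts, converged


def sparsestep_fit(X, y, lam: float, **kwargs):
    """Single-lambda convenience wrapper around :func:`sparsestep_path`."""
    coefs, intercepts, converged = sparsestep_path(X, y, [lam], **kwargs)
    return coefs[0], float(intercepts[0]), converged


def forward_stepwise(
    X,
    y,
    penalty_per_param: float,
    candidates=None,
    max_steps: int | None = None,
    collinear_tol: float = 1e-10,
):
    """Greedy forward selection minimizing n*log(RSS/n) + a*k.

    ``penalty_per_param`` is a (2 for AIC, log n + 2 log((1-pr)/pr) for mBIC,
    both on the deviance scale).  An intercept is always included (handled by
    centering).  At each step the candidate with the largest RSS reduction is
    added if it improves the criterion; candidates whose residualized norm
    falls below ``collinear_tol`` (relative) are frozen out to keep the model
    estimable.  Returns (selected_indices, coef, intercept, rss) where coef
    holds the OLS coefficients of the final model embedded in a length-p
    vector.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if candidates is None:
        candidates = np.arange(p)
    candidates = np.asarray(candidates, dtype=int)

    xc = X[:, candidates] - X[:, candidates].mean(axis=0)
    r = y - y.mean()
    norms2 = (xc**2).sum(axis=0)
    norms2_init = np.maximum(norms2, 1.0)
    alive = norms2 > collinear_tol * norms2_init
    rss = float(r @ r)
    if max_steps is None:
        max_steps = max(n - 3, 0)
    max_steps = min(max_steps, candidates.size)

    selected: list[int] = []
    for _ in range(max_steps):
        if not alive.any() or rss <= 0:
            break
        proj = xc.T @ r
        gains = np.zeros_like(proj)
        ok = alive & (norms2 > 0)
        gains[ok] = proj[ok] ** 2 / norms2[ok]
        jbest = int(np.argmax(gains))
        gain = gains[jbest]
        rss_new = max(rss - gain, 0.0)
        # criterion change: n*log(rss_new/rss) + a
        if rss_new <= 0:
            improve = True  # perfect fit always wins over any finite penalty
        else:
            improve = n * np.log(rss_new / rss) + penalty_per_param < 0
        if not improve:
            break
        q = xc[:, jbest] / np.sqrt(norms2[jbest])
        r = r - q * (q @ r)
        qc = q @ xc
        xc = xc - np.outer(q, qc)
        norms2 = norms2 - qc**2
        np.maximum(norms2, 0.0, out=norms2)
        alive &= norms2 > collinear_tol * norms2_init
        alive[jbest] = False
        selected.append(int(candidates[jbest]))
        rss = rss_new
        if rss_new == 0:
            break

    coef = np.zeros(p)
    if selected:
        Xsel = np.column_stack([np.ones(n), X[:, selected]])
        beta, *_ = np.linalg.lstsq(Xsel, y, rcond=None)
        intercept = float(beta[0])
        coef[selected] = beta[1:]
        rss = float(((y - Xsel @ beta) ** 2).sum())
    else:
        intercept = float(y.mean())
        rss = float(((y - intercept) ** 2).sum())
    return np.array(sorted(selected), dtype=int), coef, intercept, rss


def gaussian_loglik(rss: float, n: int) -> float:
    """Profile Gaussian log-likelihood at the MLE sigma^2 = RSS/n."""
    rss = max(rss, np.finfo(float).tiny)
    return -0.5 * n * (np.log(2.0 * np.pi * rss / n) + 1.0)
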