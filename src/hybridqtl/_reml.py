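"""Restricted maximum likelihood machinery for linear mixed models.

Two fitters live here:

``reml_sparse``
    Variance-component models with independent random-effect blocks
    (environment, genotype-by-environment, replicate-in-environment,
    block-in-replicate ...), written as y = X b + sum_i Z_i u_i + e with
    u_i ~ N(0, sigma_i^2 I).  The profiled REML criterion is evaluated
    through the penalized least-squares factorization (the lme4 device):
    for variance ratios gamma_i = sigma_i^2 / sigma_e^2 the deviance is a
    function of gamma alone, minimized by Nelder-Mead over log(gamma).

``reml_kernels``
    Kernel (covariance) models y = X b + g + e with
    cov(g) = sum_c sigma_c^2 K_c for dense symmetric kernels K_c, used by
    the association scan's polygenic background.  Dense Cholesky of
    V = sum_c sigma_c^2 K_c + sigma_e^2 I per objective evaluation; fine
    for a few hundred individuals.

Negative components are handled by optimizing on the log scale and
clamping ratios below ``_GAMMA_FLOOR`` to exactly zero on exit (boundary
REML).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.optimize
import scipy.sparse as sp
import scipy.sparse.linalg as spla

_GAMMA_FLOOR = 1e-6
_LOG_GAMMA_BOUNDS = (-18.0, 18.0)


@dataclass
class MixedFit:
    """Result of a REML fit.

    ``variances`` maps random-term names to sigma^2 estimates, with the
    residual under ``"residual"``.  ``fixed_effects`` are the GLS/BLUE
    estimates of the columns of X at the REML variance estimates.
    """

    variances: dict[str, float]
    fixed_effects: np.ndarray
    random_effects: dict[str, np.ndarray] = field(default_factory=dict)
    reml_deviance: float = np.nan
    converged: bool = True
    n_obs: int = 0


def indicator_matrix(labels) -> tuple[sp.csc_matrix, np.ndarray]:
    """Sparse n x q 0/1 design for a categorical label vector."""
    labels = np.asarray(labels)
    levels, idx = np.unique(labels, return_inverse=True)
    n = labels.shape[0]
    Z = sp.csc_matrix(
        (np.ones(n), (np.arange(n), idx)), shape=(n, levels.shape[0])
    )
    return Z, levels


def _pls_deviance(log_gamma, y, X, Zs, return_fit=False):
    """Profiled REML deviance at variance ratios exp(log_gamma).

    Solves the penalized least-squares system
        min_{u,b} ||y - X b - Z Lambda u||^2 + ||u||^2
    with Lambda = blockdiag(sqrt(gamma_i) I); the REML criterion is
    2 log|L| + 2 log|R_X| + (n-p) (1 + log(2 pi r^2 / (n-p))).
    """
    n, p = X.shape
    gammas = np.exp(np.clip(log_gamma, *_LOG_GAMMA_BOUNDS))
    scaled = [Z * np.sqrt(g) for Z, g in zip(Zs, gammas)]
    Zg = sp.hstack(scaled, format="csc")
    q = Zg.shape[1]
    Xs = sp.csc_matrix(X)

    # full penalized normal-equations matrix [[Z'Z + I, Z'X], [X'Z, X'X]];
    # SPD when X has full column rank, and log|Z'Z+I| + log|R_X|^2 equals
    # its log-determinant, so one sparse factorization yields both the
    # determinant term and the joint (u, b) solution.
    M = sp.bmat(
        [[Zg.T @ Zg + sp.identity(q, format="csc"), Zg.T @ Xs],
         [Xs.T @ Zg, Xs.T @ Xs]],
        format="csc",
    )
    try:
        lu = spla.splu(M, permc_spec="MMD_AT_PLUS_A")
    except RuntimeError:
        return (np.inf, None) if return_fit else np.inf
    diag_u = lu.U.diagonal()
    if np.any(diag_u == 0):
        return (np.inf, None) if return_fit else np.inf
    logdet = float(np.sum(np.log(np.abs(diag_u))))

    rhs = np.concatenate([Zg.T @ y, X.T @ y])
    sol = lu.solve(rhs)
    u, b = sol[:q], sol[q:]

    resid = y - X @ b - Zg @ u
    r2 = float(resid @ resid + u @ u)
    df = n - p
    dev = logdet + df * (1.0 + np.log(2.0 * np.pi * r2 / df))
    if not return_fit:
        return dev
    sigma_e2 = r2 / df
    # back out per-block u on the original (unscaled) basis: u_orig = Lambda u
    u_blocks = []
    off = 0
    for Z, g in zip(Zs, gammas):
        qi = Z.shape[1]
        u_blocks.append(np.sqrt(g) * u[off : off + qi])
        off += qi
    return dev, (gammas, sigma_e2, b, u_blocks)


def reml_sparse(y, X, z_terms, maxiter: int = 400) -> MixedFit:
    """REML fit of a variance-component mixed model.

    Parameters
    ----------
    y : (n,) response vector.
    X : (n, p) dense fixed-effect design, full column rank.
    z_terms : list of (name, Z) with Z a sparse n x q_i indicator/design
        matrix for an independent random block.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    names = [t[0] for t in z_terms]
    Zs = [sp.csc_matrix(t[1]) for t in z_terms]
    n, p = X.shape
    if n <= p:
        raise ValueError("more fixed-effect columns than observations")

    x0 = np.zeros(len(Zs))
    bounds = [(_LOG_GAMMA_BOUNDS[0] + 2, _LOG_GAMMA_BOUNDS[1] - 2)] * len(Zs)
    res = scipy.optimize.minimize(
        _pls_deviance,
        x0,
        args=(y, X, Zs),
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": maxiter, "ftol": 1e-10, "gtol": 1e-6, "eps": 1e-5},
    )
    if not res.success or not np.isfinite(res.fun):
        res = scipy.optimize.minimize(
            _pls_deviance,
            res.x if np.isfinite(res.fun) else x0,
            args=(y, X, Zs),
            method="Nelder-Mead",
            options={"maxiter": maxiter * max(1, len(Zs)), "xatol": 2e-3,
                     "fatol": 1e-7, "adaptive": len(Zs) > 2},
        )
    dev, fit = _pls_deviance(res.x, y, X, Zs, return_fit=True)
    gammas, sigma_e2, b, u_blocks = fit
    gammas = np.where(gammas < _GAMMA_FLOOR, 0.0, gammas)
    variances = {nm: float(g * sigma_e2) for nm, g in zip(names, gammas)}
    variances["residual"] = float(sigma_e2)
    return MixedFit(
        variances=variances,
        fixed_effects=b,
        random_effects={nm: u for nm, u in zip(names, u_blocks)},
        reml_deviance=float(dev),
        converged=bool(res.success),
        n_obs=n,
    )


def _kernel_profiled_crit(log_gamma, y, X, kernels, want_fit=False):
    """Profiled REML criterion over variance ratios gamma_c = sigma_c^2/sigma_e^2.

    With V = sigma_e^2 (I + sum_c gamma_c K_c) the residual scale drops
    out analytically:
        crit = (n-p) log(r' V0^-1 r) + log|V0| + log|X' V0^-1 X|
    for V0 = I + sum_c gamma_c K_c and the GLS residual r.
    """
    n, p = X.shape
    gammas = np.exp(np.clip(log_gamma, -30.0, 30.0))
    V0 = np.eye(n)
    for g, K in zip(gammas, kernels):
        V0 += g * K
    try:
        cf = scipy.linalg.cho_factor(V0, lower=True)
    except scipy.linalg.LinAlgError:
        return (np.inf, None) if want_fit else np.inf
    logdet_V0 = 2.0 * np.sum(np.log(np.diag(cf[0])))
    Vi_X = scipy.linalg.cho_solve(cf, X)
    Vi_y = scipy.linalg.cho_solve(cf, y)
    XtViX = X.T @ Vi_X
    sign, logdet_XtViX = np.linalg.slogdet(XtViX)
    if sign <= 0:
        return (np.inf, None) if want_fit else np.inf
    b = np.linalg.solve(XtViX, X.T @ Vi_y)
    r = y - X @ b
    quad = float(r @ scipy.linalg.cho_solve(cf, r))
    if quad <= 0:
        return (np.inf, None) if want_fit else np.inf
    crit = (n - p) * np.log(quad) + logdet_V0 + logdet_XtViX
    if not want_fit:
        return crit
    sigma_e2 = quad / (n - p)
    return crit, (gammas, sigma_e2, b, V0)


def reml_kernels(y, X, kernel_terms, maxiter: int = 400) -> MixedFit:
    """REML for a kernel-covariance mixed model (dense, small n).

    ``kernel_terms`` is a list of (name, K) with K symmetric PSD n x n.
    Returns variance components per kernel plus ``"residual"`` and the
    GLS fixed effects at the optimum; the full fitted covariance matrix
    is attached as the ``covariance`` attribute.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    names = [t[0] for t in kernel_terms]
    kernels = [np.asarray(t[1], dtype=float) for t in kernel_terms]
    # normalize kernel scale so the ratio search starts well-conditioned
    scales = [max(float(np.mean(np.diag(K))), 1e-12) for K in kernels]
    kernels_n = [K / s for K, s in zip(kernels, scales)]
    x0 = np.zeros(len(kernels))
    bounds = [(-16.0, 16.0)] * len(kernels)
    res = scipy.optimize.minimize(
        _kernel_profiled_crit,
        x0,
        args=(y, X, kernels_n),
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": maxiter, "ftol": 1e-12, "gtol": 1e-8, "eps": 1e-5},
    )
    if not np.isfinite(res.fun):
        res = scipy.optimize.minimize(
            _kernel_profiled_crit,
            x0,
            args=(y, X, kernels_n),
            method="Nelder-Mead",
            options={"maxiter": maxiter * (len(kernels) + 1), "xatol": 1e-5,
                     "fatol": 1e-9, "adaptive": len(kernels) > 1},
        )
    _, fitted = _kernel_profiled_crit(res.x, y, X, kernels_n, want_fit=True)
    if fitted is None:
        raise RuntimeError("kernel REML failed: criterion not finite at optimum")
    gammas, sigma_e2, b, V0 = fitted
    gammas = np.where(gammas < _GAMMA_FLOOR, 0.0, gammas)
    variances = {
        nm: float(g * sigma_e2 / s) for nm, g, s in zip(names, gammas, scales)
    }
    variances["residual"] = float(sigma_e2)
    fit = MixedFit(
        variances=variances,
        fixed_effects=b,
        reml_deviance=float(res.fun),
        converged=bool(np.isfinite(res.fun)),
        n_obs=y.shape[0],
    )
    fit.covariance = sigma_e2 * V0  # used by the GLS scan
    return fit
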