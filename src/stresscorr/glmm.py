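"""Mixed-effects logistic regression with per-group random intercept and slope.

The model for strain i in genus g is

    y_i ~ Bernoulli(logit^-1(beta0 + beta1 * x_i + b0_g + b1_g * x_i)),
    (b0_g, b1_g) ~ N(0, Sigma),   Sigma an unstructured 2x2 covariance,

fitted by maximising the Laplace approximation to the marginal likelihood.
The random-effect covariance is parameterised through its Cholesky factor
``Sigma = L L'`` with nonnegative diagonal, so the boundary Sigma -> 0
(a singular fit, where the model collapses to plain logistic regression)
is reachable by the optimizer and flagged.  Conditional modes of the
per-genus effects come from a penalised Newton inner loop; the outer
optimisation over (beta, L) uses L-BFGS-B with numerical gradients.

Goodness of fit is summarised by the latent-scale variance decomposition
for binary GLMMs: with f = var of the fixed linear predictor, r = mean
per-observation random-effect variance z' Sigma z, and the logit
distribution-specific variance pi^2/3,

    marginal R^2    = f / (f + r + pi^2/3)      (fixed effects only)
    conditional R^2 = (f + r) / (f + r + pi^2/3) (entire model).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .logistic import bernoulli_loglik, fit_logistic

__all__ = ["GlmmFit", "R2Decomposition", "fit_glmm", "nakagawa_r2"]

LOGIT_RESIDUAL_VARIANCE = np.pi**2 / 3.0

#: Sigma is declared singular when its smallest eigenvalue is below this
#: fraction of the largest (or both are essentially zero).
SINGULAR_TOL = 1e-4


@dataclass
class GlmmFit:
    fixed: np.ndarray  # (intercept, slope)
    fixed_names: list[str]
    re_cov: np.ndarray  # 2x2 covariance of (intercept dev, slope dev)
    genus_effects: pd.DataFrame  # genus, intercept_dev, slope_dev, total_slope
    logL_laplace: float
    n: int
    n_groups: int
    converged: bool
    singular_flag: bool
    predictor: str
    group: str
    X: np.ndarray = field(repr=False)
    y: np.ndarray = field(repr=False)
    groups: np.ndarray = field(repr=False)


@dataclass
class R2Decomposition:
    marginal_r2: float
    conditional_r2: float
    fixed_variance: float
    random_variance: float
    residual_variance: float = LOGIT_RESIDUAL_VARIANCE


def _sigmoid(eta):
    out = np.empty_like(eta, dtype=float)
    pos = eta >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-eta[pos]))
    e = np.exp(eta[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def _group_mode(y, Z, eta_fixed, L, max_iter=100, tol=1e-10):
    """Penalised Newton for one group's spherical effects u (b = L u).

    Maximises sum_i loglik(eta_fixed_i + (Z L u)_i) - u'u/2 and returns the
    mode, its objective value, and log det of the negative Hessian.
    """
    A = Z @ L  # n_g x 2
    u = np.zeros(2)
    f = bernoulli_loglik(y, eta_fixed)  # at u = 0
    for _ in range(max_iter):
        eta = eta_fixed + A @ u
        mu = _sigmoid(eta)
        grad = A.T @ (y - mu) - u
        W = mu * (1.0 - mu)
        H = A.T @ (A * W[:, None]) + np.eye(2)
        step = np.linalg.solve(H, grad)
        # step-halving line search on the penalised objective
        t = 1.0
        f0 = bernoulli_loglik(y, eta) - 0.5 * u @ u
        for _ in range(30):
            u_new = u + t * step
            f_new = bernoulli_loglik(y, eta_fixed + A @ u_new) - 0.5 * u_new @ u_new
            if f_new >= f0 - 1e-14:
                break
            t *= 0.5
        u = u_new
        if np.linalg.norm(grad) < tol:
            break
    eta = eta_fixed + A @ u
    mu = _sigmoid(eta)
    W = mu * (1.0 - mu)
    H = A.T @ (A * W[:, None]) + np.eye(2)
    sign, logdet = np.linalg.slogdet(H)
    f_mode = bernoulli_loglik(y, eta) - 0.5 * u @ u
    return u, f_mode, logdet


def _laplace_negloglik(params, y, X, group_index, group_slices):
    beta = params[:2]
    L = np.array([[params[2], 0.0], [params[3], params[4]]])
    eta_fixed = X @ beta
    total = 0.0
    for sl in group_slices:
        _, f_mode, logdet = _group_mode(y[sl], X[sl], eta_fixed[sl], L)
        total += f_mode - 0.5 * logdet
    return -total


def fit_glmm(
    table: pd.DataFrame,
    outcome: str,
    fixed_predictor: str,
    group: str = "genus",
) -> GlmmFit:
    """Fit outcome ~ fixed_predictor + (1 + fixed_predictor | group).

    Requires at least two groups and a binary outcome. The returned fit
    carries the per-group conditional modes (intercept and slope
    deviations) and each group's total slope = fixed slope + deviation.
    """
    y = table[outcome].to_numpy(dtype=float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("outcome must be binary (0/1)")
    x = table[fixed_predictor].to_numpy(dtype=float)
    g = table[group].to_numpy()
    labels, codes = np.unique(g, return_inverse=True)
    if len(labels) < 2:
        raise ValueError("mixed model requires at least 2 groups")
    order = np.argsort(codes, kind="stable")
    y_s, x_s, codes_s = y[order], x[order], codes[order]
    X = np.column_stack([np.ones(len(y_s)), x_s])
    bounds = np.searchsorted(codes_s, np.arange(len(labels) + 1))
    slices = [slice(bounds[i], bounds[i + 1]) for i in range(len(labels))]

    glm = fit_logistic(y_s, X, predictor_names=["(Intercept)", fixed_predictor])
    sx = x.std() if x.std() > 0 else 1.0
    # start at the fixed-effect solution; two random-effect scales tried
    starts = [
        np.concatenate([glm.beta, [1.0, 0.0, 1.0 / sx]]),
        np.concatenate([glm.beta, [0.1, 0.0, 0.1 / sx]]),
    ]
    best = None
    for s0 in starts:
        res = optimize.minimize(
            _laplace_negloglik,
            s0,
            args=(y_s, X, codes_s, slices),
            method="L-BFGS-B",
            bounds=[(None, None)] * 2 + [(0.0, None), (None, None), (0.0, None)],
            options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-8},
        )
        if best is None or res.fun < best.fun - 1e-9:
            best = res
    p = best.x
    beta = p[:2]
    L = np.array([[p[2], 0.0], [p[3], p[4]]])
    re_cov = L @ L.T

    eta_fixed = X @ beta
    effects = []
    for lab, sl in zip(labels, slices):
        u, _, _ = _group_mode(y_s[sl], X[sl], eta_fixed[sl], L)
        b = L @ u
        effects.append(
            {
                "genus": lab,
                "intercept_dev": b[0],
                "slope_dev": b[1],
                "total_slope": beta[1] + b[1],
            }
        )
    eig = np.linalg.eigvalsh(re_cov)
    singular = eig[1] < 1e-10 or eig[0] < SINGULAR_TOL * max(eig[1], 1e-10)
    return GlmmFit(
        fixed=beta,
        fixed_names=["(Intercept)", fixed_predictor],
        re_cov=re_cov,
        genus_effects=pd.DataFrame(effects),
        logL_laplace=-best.fun,
        n=len(y_s),
        n_groups=len(labels),
        converged=bool(best.success),
        singular_flag=bool(singular),
        predictor=fixed_predictor,
        group=group,
        X=X,
        y=y_s,
        groups=codes_s,
    )


def nakagawa_r2(fit: GlmmFit) -> R2Decomposition:
    """Latent-scale marginal and conditional R^2 of a fitted binary GLMM.

    The fixed-effect variance is the sample variance of the fixed linear
    predictor over the data; the random-effect variance averages
    z_i' Sigma z_i over observations (z_i = (1, x_i)); the residual
    variance is the logit-link constant pi^2/3.
    """
    if not fit.converged:
        raise ValueError("R^2 decomposition requires a converged fit")
    eta_fixed = fit.X @ fit.fixed
    var_f = float(np.var(eta_fixed, ddof=1))
    var_r = float(np.mean(np.einsum("ij,jk,ik->i", fit.X, fit.re_cov, fit.X)))
    denom = var_f + var_r + LOGIT_RESIDUAL_VARIANCE
    return R2Decomposition(
        marginal_r2=var_f / denom,
        conditional_r2=(var_f + var_r) / denom,
        fixed_variance=var_f,
        random_variance=var_r,
    )
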