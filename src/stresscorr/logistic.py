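"""Maximum-likelihood logistic regression with small-sample information
criteria, Wald inference, collinearity diagnostics, and ROC evaluation.

The fitter is a from-scratch iteratively reweighted least squares (IRLS)
implementation so that the exhaustive model-enumeration machinery downstream
has full control over convergence and separation diagnostics.  AICc — the
Akaike information criterion with the small-sample correction
``AIC + 2k(k+1)/(n-k-1)`` — is attached to every fit because it is the model
weight currency of the multi-model inference stage.

ROC areas come with DeLong 95% confidence intervals: the variance of the
empirical AUC (a two-sample U-statistic) is estimated from the per-score
structural components, and the normal-approximation interval is truncated
to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "LogisticFit",
    "RocResult",
    "fit_logistic",
    "wald",
    "gvif",
    "roc",
]

#: |linear predictor| beyond which a converged fit is flagged as separated.
SEPARATION_BOUND = 30.0

Z975 = 1.959964  # standard-normal 97.5% quantile; Wald intervals


@dataclass
class LogisticFit:
    """A fitted logistic regression (intercept always first)."""

    predictor_names: list[str]
    beta: np.ndarray
    cov: np.ndarray
    logL: float
    n: int
    k: int
    aic: float
    aicc: float
    converged: bool
    separation_flag: bool
    X: np.ndarray = field(repr=False)
    y: np.ndarray = field(repr=False)

    @property
    def fitted_probabilities(self) -> np.ndarray:
        return _sigmoid(self.X @ self.beta)

    def summary_frame(self) -> pd.DataFrame:
        """Per-term Wald summary as a DataFrame (term, estimate, SE, z, p, CI)."""
        return wald(self)


def _sigmoid(eta: np.ndarray) -> np.ndarray:
    out = np.empty_like(eta, dtype=float)
    pos = eta >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-eta[pos]))
    e = np.exp(eta[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def bernoulli_loglik(y: np.ndarray, eta: np.ndarray) -> float:
    """Log-likelihood of a Bernoulli GLM at linear predictor eta (logit link)."""
    # log(1+exp(eta)) computed stably
    return float(y @ eta - np.logaddexp(0.0, eta).sum())


def fit_logistic(
    y: np.ndarray,
    X: np.ndarray,
    predictor_names: list[str] | None = None,
    max_iter: int = 100,
    tol_beta: float = 1e-8,
    tol_dev: float = 1e-10,
) -> LogisticFit:
    """Fit a logistic regression by IRLS started from beta = 0.

    ``X`` must contain the intercept column; it is checked for full column
    rank.  Convergence is declared when the largest coefficient update falls
    below ``tol_beta`` or the relative deviance change falls below
    ``tol_dev``.  The covariance is the inverse observed (= expected, for
    the canonical link) information at the optimum.  A converged fit whose
    linear predictor exceeds :data:`SEPARATION_BOUND` in absolute value is
    flagged as (quasi-)separated; its coefficients and Wald SEs are
    unreliable and downstream consumers receive the flag.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X must be 2-D with one row per element of y")
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("y must be binary (0/1)")
    n, k = X.shape
    if np.linalg.matrix_rank(X) < k:
        raise ValueError("design matrix is rank deficient")
    if predictor_names is None:
        predictor_names = ["(Intercept)"] + [f"x{j}" for j in range(1, k)]
    if len(predictor_names) != k:
        raise ValueError("predictor_names length must match X columns")

    beta = np.zeros(k)
    eta = X @ beta
    dev = -2.0 * bernoulli_loglik(y, eta)
    converged = False
    for _ in range(max_iter):
        mu = _sigmoid(eta)
        w = mu * (1.0 - mu)
        w = np.maximum(w, 1e-12)
        z = eta + (y - mu) / w
        WX = X * w[:, None]
        XtWX = X.T @ WX
        beta_new = np.linalg.solve(XtWX, WX.T @ z)
        step = np.abs(beta_new - beta).max()
        beta = beta_new
        eta = X @ beta
        dev_new = -2.0 * bernoulli_loglik(y, eta)
        rel = abs(dev_new - dev) / (abs(dev) + 0.1)
        dev = dev_new
        if step < tol_beta or rel < tol_dev:
            converged = True
            break

    mu = _sigmoid(eta)
    w = np.maximum(mu * (1.0 - mu), 1e-12)
    info = X.T @ (X * w[:, None])
    cov = np.linalg.pinv(info)
    logL = bernoulli_loglik(y, eta)
    aic = -2.0 * logL + 2.0 * k
    aicc = aic + 2.0 * k * (k + 1) / (n - k - 1) if n - k - 1 > 0 else np.nan
    return LogisticFit(
        predictor_names=list(predictor_names),
        beta=beta,
        cov=cov,
        logL=logL,
        n=n,
        k=k,
        aic=aic,
        aicc=aicc,
        converged=converged,
        separation_flag=bool(np.abs(eta).max() > SEPARATION_BOUND),
        X=X,
        y=y,
    )


def fit_from_table(
    table: pd.DataFrame, outcome: str, predictors: list[str], **kwargs
) -> LogisticFit:
    """Convenience wrapper: fit outcome ~ predictors (with intercept) from a table."""
    X = np.column_stack(
        [np.ones(len(table))] + [table[p].to_numpy(dtype=float) for p in predictors]
    )
    names = ["(Intercept)"] + list(predictors)
    return fit_logistic(table[outcome].to_numpy(), X, predictor_names=names, **kwargs)


def wald(fit: LogisticFit) -> pd.DataFrame:
    """Per-coefficient Wald summary: SE, z, two-sided p, 95% CI.

    Intervals use the normal multiplier 1.959964.  If the fit carries a
    separation flag the returned frame has ``reliable = False`` throughout.
    """
    se = np.sqrt(np.diag(fit.cov))
    z = np.divide(fit.beta, se, out=np.full_like(fit.beta, np.nan), where=se > 0)
    p = 2.0 * stats.norm.sf(np.abs(z))
    out = pd.DataFrame(
        {
            "term": fit.predictor_names,
            "estimate": fit.beta,
            "se": se,
            "z": z,
            "p": p,
            "ci_lo": fit.beta - Z975 * se,
            "ci_hi": fit.beta + Z975 * se,
        }
    )
    out["reliable"] = fit.converged and not fit.separation_flag
    return out


def gvif(fit: LogisticFit, target: str, method: str = "covariance") -> float:
    """Variance inflation factor of one predictor in a multi-predictor fit.

    ``method='covariance'`` computes the generalized VIF from the
    correlation structure of the non-intercept coefficient covariance,
    ``det(R[target]) * det(R[others]) / det(R)`` — this is the GLM-native
    diagnostic and for a single column reduces to 1/(1 - R^2) of the
    precision-weighted regression of the target on the other terms.
    ``method='design'`` instead computes the classical OLS VIF
    1/(1 - R^2) from an ordinary least-squares regression of the target
    design column on the remaining (non-intercept) columns.
    """
    names = fit.predictor_names[1:]
    if target not in names:
        raise ValueError(f"{target!r} is not a predictor of this fit")
    if len(names) < 2:
        raise ValueError("VIF requires at least two non-intercept predictors")
    j = names.index(target)
    if method == "covariance":
        cov = fit.cov[1:, 1:]
        d = np.sqrt(np.diag(cov))
        R = cov / np.outer(d, d)
        others = [i for i in range(len(names)) if i != j]
        det_all = np.linalg.det(R)
        if abs(det_all) < 1e-300:
            raise ValueError(f"singular coefficient correlation among {names}")
        return float(
            R[j, j] * np.linalg.det(R[np.ix_(others, others)]) / det_all
        )
    if method == "design":
        Xp = fit.X[:, 1:]
        yv = Xp[:, j]
        Z = np.column_stack([np.ones(len(yv)), np.delete(Xp, j, axis=1)])
        coef, *_ = np.linalg.lstsq(Z, yv, rcond=None)
        resid = yv - Z @ coef
        ss_res = float(resid @ resid)
        ss_tot = float(((yv - yv.mean()) ** 2).sum())
        r2 = 1.0 - ss_res / ss_tot
        if r2 >= 1.0 - 1e-12:
            raise ValueError(f"{target!r} is collinear with the other predictors")
        return float(1.0 / (1.0 - r2))
    raise ValueError(f"unknown method {method!r}")


@dataclass
class RocResult:
    """Empirical ROC curve with AUC and a DeLong 95% confidence interval."""

    thresholds: np.ndarray
    sensitivities: np.ndarray
    specificities: np.ndarray
    auc: float
    ci95: tuple[float, float]
    auc_se: float


def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def roc(scores: np.ndarray, labels: np.ndarray, ci: str = "delong") -> RocResult:
    """Empirical ROC over all distinct score thresholds.

    The AUC equals the tie-corrected concordance probability
    P(score_pos > score_neg) + 0.5 P(tie) and is computed via midranks.  The
    95% CI uses the DeLong variance of the AUC U-statistic (structural
    components of the positive and negative score sets), normal
    approximation, truncated to [0, 1].  ``ci='bootstrap'`` substitutes a
    2000-draw stratified percentile bootstrap.
    """
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels).ravel()
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be binary (0/1)")
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise ValueError("both outcome classes must be present")

    # empirical curve over distinct thresholds, descending
    thr = np.unique(scores)[::-1]
    sens = np.array([(pos >= t).mean() for t in thr])
    spec = np.array([(neg < t).mean() for t in thr])
    thresholds = np.concatenate(([np.inf], thr))
    sens = np.concatenate(([0.0], sens))
    spec = np.concatenate(([1.0], spec))

    # midrank AUC (DeLong's computational form)
    allr = _midrank(np.concatenate([pos, neg]))
    rpos = _midrank(pos)
    rneg = _midrank(neg)
    auc = (allr[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v_pos = (allr[:m] - rpos) / n  # structural components for positives
    v_neg = 1.0 - (allr[m:] - rneg) / m
    s_pos = np.var(v_pos, ddof=1) if m > 1 else 0.0
    s_neg = np.var(v_neg, ddof=1) if n > 1 else 0.0
    se = float(np.sqrt(s_pos / m + s_neg / n))

    if ci == "delong":
        lo = max(0.0, auc - Z975 * se)
        hi = min(1.0, auc + Z975 * se)
    elif ci == "bootstrap":
        rng = np.random.default_rng(0)
        reps = np.empty(2000)
        for b in range(2000):
            ps = pos[rng.integers(0, m, m)]
            ns = neg[rng.integers(0, n, n)]
            r = _midrank(np.concatenate([ps, ns]))
            reps[b] = (r[:m].sum() - m * (m + 1) / 2.0) / (m * n)
        lo, hi = np.percentile(reps, [2.5, 97.5])
    else:
        raise ValueError(f"unknown ci method {ci!r}")
    return RocResult(
        thresholds=thresholds,
        sensitivities=sens,
        specificities=spec,
        auc=float(auc),
        ci95=(float(lo), float(hi)),
        auc_se=se,
    )
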