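"""IRLS logistic regression, Wald inference, GVIF, ROC/AUC with DeLong CI."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

import stresscorr as sc
from stresscorr.logistic import LogisticFit, bernoulli_loglik


def _toy_fit(seed=0, n=8, k=2):
    rng = np.random.default_rng(seed)
    X = np.column_stack([np.ones(n), rng.standard_normal((n, k - 1))])
    y = (rng.random(n) < 0.5).astype(float)
    if y.min() == y.max():
        y[0] = 1 - y[0]
    return y, X


def test_intercept_only_balanced_outcome():
    y = np.array([0, 0, 1, 1, 0, 1, 1, 0], dtype=float)
    fit = sc.fit_logistic(y, np.ones((8, 1)))
    assert fit.beta[0] == pytest.approx(0.0, abs=1e-8)


@pytest.mark.parametrize("seed", [1, 2, 3])
def test_irls_matches_derivative_free_maximization(seed):
    y, X = _toy_fit(seed=seed, n=8, k=2)
    fit = sc.fit_logistic(y, X)
    res = optimize.minimize(
        lambda b: -bernoulli_loglik(y, X @ b),
        np.zeros(2),
        method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000},
    )
    assert not fit.separation_flag
    assert fit.beta == pytest.approx(res.x, abs=1e-4)


def test_irls_matches_statsmodels_on_real_data(asco):
    sm = pytest.importorskip("statsmodels.api")
    fit = sc.fit_from_table(asco, "CIRgrowth", ["logCrCl3", "Tmax"])
    X = sm.add_constant(asco[["logCrCl3", "Tmax"]])
    ref = sm.GLM(asco["CIRgrowth"], X, family=sm.families.Binomial()).fit()
    assert fit.beta == pytest.approx(ref.params.to_numpy(), abs=1e-6)
    assert np.sqrt(np.diag(fit.cov)) == pytest.approx(ref.bse.to_numpy(), rel=1e-5)
    assert fit.logL == pytest.approx(ref.llf, abs=1e-8)
    assert fit.aic == pytest.approx(ref.aic, abs=1e-6)


def test_aicc_exceeds_aic_and_small_sample_formula():
    y, X = _toy_fit(seed=5, n=20, k=3)
    fit = sc.fit_logistic(y, X)
    assert fit.aicc == pytest.approx(fit.aic + 2 * 3 * 4 / (20 - 3 - 1))
    assert fit.aicc > fit.aic


def test_loglik_is_local_maximum():
    y, X = _toy_fit(seed=7, n=30, k=3)
    fit = sc.fit_logistic(y, X)
    rng = np.random.default_rng(0)
    for _ in range(25):
        pert = fit.beta + rng.standard_normal(3) * 0.05
        assert bernoulli_loglik(y, X @ pert) <= fit.logL + 1e-12


def test_separation_is_flagged():
    x = np.array([-2.0, -1.0, -0.5, 0.5, 1.0, 2.0])
    y = (x > 0).astype(float)
    fit = sc.fit_logistic(y, np.column_stack([np.ones(6), x]))
    assert fit.separation_flag
    assert not sc.wald(fit)["reliable"].any()


def test_rank_deficient_design_rejected():
    y, X = _toy_fit(seed=9, n=10, k=2)
    X2 = np.column_stack([X, X[:, 1]])
    with pytest.raises(ValueError, match="rank"):
        sc.fit_logistic(y, X2)


def test_wald_identity_covariance_gives_unit_se():
    fit = LogisticFit(
        predictor_names=["(Intercept)", "x"],
        beta=np.array([0.5, -0.5]),
        cov=np.eye(2),
        logL=-1.0, n=10, k=2, aic=6.0, aicc=7.0,
        converged=True, separation_flag=False,
        X=np.ones((10, 2)), y=np.zeros(10),
    )
    w = sc.wald(fit)
    assert np.allclose(w["se"], 1.0)
    assert w["ci_lo"].iloc[0] == pytest.approx(0.5 - 1.959964)


def test_wald_coverage_on_simulated_data():
    # 95% Wald CI for the slope should cover truth for ~95% of replicates
    rng = np.random.default_rng(12345)
    slope_true, cover = 0.8, 0
    reps = 200
    for _ in range(reps):
        x = rng.standard_normal(500)
        p = 1 / (1 + np.exp(-(0.2 + slope_true * x)))
        y = (rng.random(500) < p).astype(float)
        fit = sc.fit_logistic(y, np.column_stack([np.ones(500), x]))
        w = sc.wald(fit)
        cover += w["ci_lo"].iloc[1] <= slope_true <= w["ci_hi"].iloc[1]
    assert cover / reps == pytest.approx(0.95, abs=0.03)


def test_gvif_orthogonal_predictors_is_one():
    rng = np.random.default_rng(2)
    a = rng.standard_normal(50)
    b = rng.standard_normal(50)
    b -= a * (a @ b) / (a @ a)  # exactly orthogonal
    a = (a - a.mean()) / a.std()
    b = (b - b.mean()) / b.std()
    df = pd.DataFrame({"a": a, "b": b, "y": (rng.random(50) < 0.5).astype(int)})
    fit = sc.fit_from_table(df, "y", ["a", "b"])
    assert sc.gvif(fit, "a", method="design") == pytest.approx(1.0, abs=1e-6)


def test_gvif_matches_ols_oracle_and_exceeds_one():
    rng = np.random.default_rng(8)
    n = 60
    z = rng.standard_normal((n, 2))
    x3 = 0.6 * z[:, 0] + 0.3 * z[:, 1] + 0.5 * rng.standard_normal(n)
    df = pd.DataFrame({"x1": z[:, 0], "x2": z[:, 1], "x3": x3})
    df["y"] = (rng.random(n) < 0.5).astype(int)
    fit = sc.fit_from_table(df, "y", ["x1", "x2", "x3"])
    # independent OLS oracle: R^2 of x3 on (x1, x2)
    Z = np.column_stack([np.ones(n), z])
    bhat = np.linalg.lstsq(Z, x3, rcond=None)[0]
    resid = x3 - Z @ bhat
    r2 = 1 - resid @ resid / ((x3 - x3.mean()) ** 2).sum()
    assert sc.gvif(fit, "x3", method="design") == pytest.approx(1 / (1 - r2), rel=1e-8)
    for target in ["x1", "x2", "x3"]:
        for method in ["design", "covariance"]:
            assert sc.gvif(fit, target, method=method) >= 1.0


def test_auc_matches_pairwise_concordance_bruteforce():
    rng = np.random.default_rng(11)
    scores = rng.integers(0, 5, 10).astype(float)  # forces ties
    labels = np.array([0, 1, 0, 1, 1, 0, 0, 1, 1, 0])
    r = sc.roc(scores, labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    conc = np.mean([
        1.0 if sp > sn else 0.5 if sp == sn else 0.0
        for sp in pos for sn in neg
    ])
    assert r.auc == pytest.approx(conc, abs=1e-12)
    assert r.ci95[0] <= r.auc <= r.ci95[1]


def test_auc_invariances():
    rng = np.random.default_rng(13)
    scores = rng.standard_normal(40)
    labels = (rng.random(40) < 0.4).astype(int)
    a1 = sc.roc(scores, labels).auc
    a2 = sc.roc(np.exp(scores), labels).auc  # strictly increasing transform
    a3 = sc.roc(-scores, labels).auc
    assert a1 == pytest.approx(a2, abs=1e-12)
    assert a1 + a3 == pytest.approx(1.0, abs=1e-12)


def test_perfect_separation_auc_one():
    r = sc.roc(np.array([0.1, 0.2, 0.8, 0.9]), np.array([0, 0, 1, 1]))
    assert r.auc == 1.0
    assert r.ci95[1] <= 1.0


def test_roc_curve_monotone_and_class_check(basidio):
    fit = sc.fit_from_table(basidio, "CIRgrowth", ["Tmax"])
    r = sc.roc(fit.fitted_probabilities, basidio["CIRgrowth"].to_numpy())
    assert (np.diff(r.sensitivities) >= -1e-12).all()
    assert (np.diff(r.specificities) <= 1e-12).all()
    with pytest.raises(ValueError, match="class"):
        sc.roc(np.array([0.1, 0.9]), np.array([1, 1]))


def test_delong_and_bootstrap_ci_agree_roughly(asco):
    fit = sc.fit_from_table(asco, "CIRgrowth", ["logCrCl3"])
    labels = asco["CIRgrowth"].to_numpy()
    d = sc.roc(fit.fitted_probabilities, labels)
    b = sc.roc(fit.fitted_probabilities, labels, ci="bootstrap")
    assert d.ci95[0] == pytest.approx(b.ci95[0], abs=0.05)
    assert d.ci95[1] == pytest.approx(b.ci95[1], abs=0.05)


# --- hypothesis property checks -------------------------------------------

from hypothesis import given, settings
from hypothesis import strategies as st


@settings(max_examples=40, deadline=None, derandomize=True)
@given(
    scores=st.lists(st.integers(min_value=-5, max_value=5), min_size=4, max_size=25),
    seed=st.integers(min_value=0, max_value=10_000),
)
def test_auc_concordance_property(scores, seed):
    """AUC always equals the brute-force tie-corrected concordance count."""
    rng = np.random.default_rng(seed)
    s = np.array(scores, dtype=float)
    labels = rng.integers(0, 2, len(s))
    if labels.min() == labels.max():
        labels[0] = 1 - labels[0]
    r = sc.roc(s, labels)
    pos, neg = s[labels == 1], s[labels == 0]
    brute = np.mean([
        1.0 if p > q else 0.5 if p == q else 0.0 for p in pos for q in neg
    ])
    assert r.auc == pytest.approx(brute, abs=1e-12)
    assert 0.0 <= r.ci95[0] <= r.auc <= r.ci95[1] <= 1.0
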