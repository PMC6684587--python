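"""Exhaustive model enumeration, Akaike weighting, importance, averaging."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

import stresscorr as sc
from stresscorr.logistic import bernoulli_loglik
from stresscorr.mmi import ModelStructure, enumerate_models


def test_enumeration_counts():
    assert len(enumerate_models([f"p{i}" for i in range(7)])) == 128
    assert len(enumerate_models([])) == 1
    structures = enumerate_models(["a", "b"], interactions=[("a", "b")])
    assert {str(s) for s in structures} == {"1", "a", "b", "a + b", "a + b + a:b"}


def test_enumeration_input_validation():
    with pytest.raises(ValueError, match="duplicate"):
        enumerate_models(["a", "a"])
    with pytest.raises(ValueError, match="itself"):
        enumerate_models(["a", "b"], interactions=[("a", "a")])
    with pytest.raises(ValueError, match="unknown"):
        enumerate_models(["a"], interactions=[("a", "z")])


def test_marginality_enforced():
    with pytest.raises(ValueError, match="marginality"):
        ModelStructure(frozenset({"a"}), frozenset({("a", "b")}))


def _toy_table(seed=0, n=40, slopes=(1.0, 0.0, 0.0)):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, 3))
    eta = X @ np.array(slopes)
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
    df = pd.DataFrame(X, columns=["a", "b", "c"])
    df["y"] = y
    return df


def test_akaike_weight_arithmetic_and_normalization():
    df = _toy_table(seed=1)
    res = sc.run_mmi(df, "y", ["a", "b", "c"])
    w = res.models["weight"].to_numpy()
    d = res.models["delta"].to_numpy()
    assert w.sum() == pytest.approx(1.0, abs=1e-12)
    assert d.min() == 0.0
    # two models at delta 0 and 2 have weight ratio exp(1)
    assert np.exp(-0 / 2) / np.exp(-2 / 2) == pytest.approx(np.exp(1))


def test_importance_complement_identity():
    df = _toy_table(seed=2)
    res = sc.run_mmi(df, "y", ["a", "b", "c"])
    for term in ["a", "b", "c"]:
        contains = res.models["structure"].str.contains(term)
        lacking = res.models.loc[~contains, "weight"].sum()
        imp = res.summary.set_index("term").loc[term, "importance"]
        assert imp + lacking == pytest.approx(1.0, abs=1e-12)


def test_mmi_matches_bruteforce_oracle():
    """All 8 models of a 3-predictor set, fitted by a generic optimizer."""
    df = _toy_table(seed=3, n=40)
    y = df["y"].to_numpy().astype(float)
    n = len(df)

    import itertools
    crits, betas = {}, {}
    for r in range(4):
        for combo in itertools.combinations(["a", "b", "c"], r):
            X = np.column_stack([np.ones(n)] + [df[c] for c in combo])
            k = X.shape[1]
            res = optimize.minimize(
                lambda b: -bernoulli_loglik(y, X @ b),
                np.zeros(k), method="BFGS",
                options={"gtol": 1e-10, "maxiter": 2000},
            )
            aicc = 2 * res.fun + 2 * k + 2 * k * (k + 1) / (n - k - 1)
            crits[combo] = aicc
            betas[combo] = dict(zip(("(Intercept)",) + combo, res.x))
    c = np.array(list(crits.values()))
    w = np.exp(-(c - c.min()) / 2)
    w /= w.sum()
    oracle_w = dict(zip(crits.keys(), w))
    oracle_imp = {
        t: sum(wi for combo, wi in oracle_w.items() if t in combo)
        for t in ["a", "b", "c"]
    }

    res = sc.run_mmi(df, "y", ["a", "b", "c"])
    got_imp = res.summary.set_index("term")["importance"]
    for t in ["a", "b", "c"]:
        assert got_imp[t] == pytest.approx(oracle_imp[t], abs=1e-5)
    # full-averaging estimates against the oracle's zero-substitution average
    for t in ["a", "b", "c"]:
        est_oracle = sum(
            wi * betas[combo].get(t, 0.0) for combo, wi in oracle_w.items()
        )
        got = res.summary.set_index("term").loc[t, "estimate"]
        assert got == pytest.approx(est_oracle, abs=1e-5)


def test_weights_invariant_to_criterion_shift():
    df = _toy_table(seed=4)
    res = sc.run_mmi(df, "y", ["a", "b", "c"])
    c = res.models["aicc"].to_numpy()
    w2 = np.exp(-(c + 37.0 - (c + 37.0).min()) / 2)
    w2 /= w2.sum()
    assert res.models["weight"].to_numpy() == pytest.approx(w2, abs=1e-12)


def test_best_model_invariant_to_enumeration_order():
    df = _toy_table(seed=5)
    r1 = sc.run_mmi(df, "y", ["a", "b", "c"])
    r2 = sc.run_mmi(df, "y", ["c", "a", "b"])
    assert str(r1.best_structure) == str(r2.best_structure)


def test_true_signal_gets_top_importance():
    # only predictor 'a' is active; its median importance should dominate
    imps = {"a": [], "b": [], "c": []}
    for seed in range(50):
        df = _toy_table(seed=100 + seed, n=400, slopes=(1.5, 0.0, 0.0))
        res = sc.run_mmi(df, "y", ["a", "b", "c"])
        s = res.summary.set_index("term")["importance"]
        for t in imps:
            imps[t].append(s[t])
    med = {t: np.median(v) for t, v in imps.items()}
    assert med["a"] > med["b"]
    assert med["a"] > med["c"]


def test_interaction_check_recovers_strong_interaction():
    rng = np.random.default_rng(21)
    n = 400
    a, b = rng.standard_normal(n), rng.standard_normal(n)
    eta = 0.5 * a + 0.5 * b + 2.0 * a * b
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
    df = pd.DataFrame({"a": a, "b": b, "y": y})
    lo, hi = sc.interaction_check(df, "y", ("a", "b"), ["a", "b"])
    assert lo > 0  # CI excludes zero

    with pytest.raises(ValueError, match="itself"):
        sc.interaction_check(df, "y", ("a", "a"), ["a", "b"])
    with pytest.raises(ValueError, match="base_predictors"):
        sc.interaction_check(df, "y", ("a", "z"), ["a", "b"])


def test_strict_mode_drops_separated_fits(basidio):
    from stresscorr.data import WITHIN_PHYLUM_PREDICTORS
    res = sc.run_mmi(basidio, "CIRgrowth", list(WITHIN_PHYLUM_PREDICTORS),
                     strict=True)
    assert res.diagnostics["n_separation_flagged"] > 0
    assert not res.models["separation_flag"].any()
    assert res.models["weight"].sum() == pytest.approx(1.0, abs=1e-12)


# --- hypothesis property checks -------------------------------------------

from hypothesis import given, settings
from hypothesis import strategies as st


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.lists(st.floats(min_value=0.0, max_value=60.0), min_size=2, max_size=12))
def test_akaike_weight_softmax_properties(deltas):
    """Weights from any AICc vector sum to 1 and are shift-invariant."""
    c = np.array(deltas)
    for shift in (0.0, 123.0):
        d = (c + shift) - (c + shift).min()
        w = np.exp(-d / 2)
        w /= w.sum()
        assert w.sum() == pytest.approx(1.0, abs=1e-12)
        assert (w >= 0).all()
        assert w[np.argmin(c)] == w.max()
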