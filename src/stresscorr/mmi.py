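"""Exhaustive multi-model inference (MMI) for logistic regression.

Every subset of the candidate predictors — including the intercept-only
model, and optionally interaction terms under the marginality constraint —
is fitted by maximum likelihood and scored by AICc.  Akaike weights
``w_i = exp(-delta_i/2) / sum_j exp(-delta_j/2)`` (delta = AICc above the
best model) then drive three summaries per predictor:

* relative importance: the sum of weights of all models containing it;
* a model-averaged coefficient, by default "full" averaging where a model
  that excludes the predictor contributes a coefficient of zero
  (conditional averaging over containing models only is available);
* an unconditional standard error combining within-model variance with
  the between-model spread of estimates,
  ``SE_u = sum_i w_i * sqrt(SE_i^2 + (beta_i - beta_avg)^2)``,
  and the Wald-style interval ``beta_avg +/- 1.96 * SE_u``.

Non-convergent fits can either stay in the weighted set (flag-propagating
default) or be dropped before weight normalisation in strict mode; either
way the diagnostics record how many fits converged or tripped the
separation flag.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .logistic import Z975, LogisticFit, fit_logistic

__all__ = [
    "ModelStructure",
    "MMIResult",
    "enumerate_models",
    "run_mmi",
    "interaction_check",
]


@dataclass(frozen=True)
class ModelStructure:
    """A candidate model: a set of main effects plus interaction pairs.

    Marginality is enforced: an interaction (a, b) may appear only when
    both a and b are present as main effects.
    """

    predictors: frozenset[str]
    interactions: frozenset[tuple[str, str]] = frozenset()

    def __post_init__(self):
        for a, b in self.interactions:
            if a not in self.predictors or b not in self.predictors:
                raise ValueError(
                    f"interaction ({a}, {b}) violates marginality: "
                    "both main effects must be present"
                )

    @property
    def terms(self) -> list[str]:
        out = sorted(self.predictors)
        out += [f"{a}:{b}" for a, b in sorted(self.interactions)]
        return out

    def __str__(self) -> str:
        return " + ".join(self.terms) if self.terms else "1"


def enumerate_models(
    predictors: list[str],
    interactions: list[tuple[str, str]] | None = None,
) -> list[ModelStructure]:
    """All 2^m main-effect subsets, optionally augmented by interactions.

    Each requested interaction is added, alone and in combination with the
    other admissible ones, to every subset that contains both of its main
    effects. The intercept-only model (empty set) is always included.
    """
    if len(set(predictors)) != len(predictors):
        raise ValueError("duplicate predictor names")
    if len(predictors) > 16:
        raise ValueError("exhaustive enumeration capped at 16 predictors")
    interactions = interactions or []
    norm: list[tuple[str, str]] = []
    for a, b in interactions:
        if a == b:
            raise ValueError(f"interaction of {a!r} with itself is invalid")
        if a not in predictors or b not in predictors:
            raise ValueError(f"interaction ({a}, {b}) references unknown predictors")
        norm.append(tuple(sorted((a, b))))
    if len(set(norm)) != len(norm):
        raise ValueError("duplicate interaction pairs")

    out: list[ModelStructure] = []
    for r in range(len(predictors) + 1):
        for combo in itertools.combinations(predictors, r):
            base = frozenset(combo)
            admissible = [p for p in norm if p[0] in base and p[1] in base]
            for rr in range(len(admissible) + 1):
                for ic in itertools.combinations(admissible, rr):
                    out.append(ModelStructure(base, frozenset(ic)))
    return out


def _design(table: pd.DataFrame, structure: ModelStructure) -> tuple[np.ndarray, list[str]]:
    cols = [np.ones(len(table))]
    names = ["(Intercept)"]
    for p in sorted(structure.predictors):
        cols.append(table[p].to_numpy(dtype=float))
        names.append(p)
    for a, b in sorted(structure.interactions):
        cols.append(table[a].to_numpy(dtype=float) * table[b].to_numpy(dtype=float))
        names.append(f"{a}:{b}")
    return np.column_stack(cols), names


@dataclass
class MMIResult:
    models: pd.DataFrame  # structure, logL, k, AICc, delta, weight + flags
    fits: list[tuple[ModelStructure, LogisticFit]] = field(repr=False)
    summary: pd.DataFrame = None  # per-term importance / averaged estimate / CI
    diagnostics: dict = field(default_factory=dict)

    @property
    def best_structure(self) -> ModelStructure:
        return self.fits[int(self.models["delta"].idxmin())][0]

    def term_ci(self, term: str) -> tuple[float, float]:
        row = self.summary.set_index("term").loc[term]
        return float(row["ci_lo"]), float(row["ci_hi"])


def run_mmi(
    table: pd.DataFrame,
    outcome: str,
    predictors: list[str],
    interactions: list[tuple[str, str]] | None = None,
    averaging: str = "full",
    criterion: str = "aicc",
    strict: bool = False,
) -> MMIResult:
    """Fit all candidate structures and aggregate AICc-weighted summaries.

    ``averaging='full'`` substitutes beta = 0 (SE = 0) for models that omit
    a term; ``'conditional'`` renormalises over containing models only.
    ``strict=True`` drops non-convergent and separation-flagged fits from
    the weighted set before normalisation (on small subsets, models that
    perfectly separate the outcome otherwise soak up the Akaike weight
    with meaningless infinite-coefficient fits).
    """
    if averaging not in ("full", "conditional"):
        raise ValueError(f"unknown averaging convention {averaging!r}")
    if criterion not in ("aicc", "aic"):
        raise ValueError(f"criterion must be 'aicc' or 'aic'")
    y = table[outcome].to_numpy()
    structures = enumerate_models(predictors, interactions)
    fits: list[tuple[ModelStructure, LogisticFit]] = []
    for s in structures:
        X, names = _design(table, s)
        fits.append((s, fit_logistic(y, X, predictor_names=names)))

    n_nonconv = sum(1 for _, f in fits if not f.converged)
    n_sep = sum(1 for _, f in fits if f.separation_flag)
    kept = (
        [(s, f) for s, f in fits if f.converged and not f.separation_flag]
        if strict
        else fits
    )
    if not kept:
        raise RuntimeError("no candidate model converged")

    crit = np.array([f.aicc if criterion == "aicc" else f.aic for _, f in kept])
    if np.isnan(crit).any():
        raise ValueError(
            "AICc undefined (n - k - 1 <= 0) for some candidate models; "
            "use criterion='aic' or reduce the predictor set"
        )
    delta = crit - crit.min()
    w = np.exp(-delta / 2.0)
    w /= w.sum()

    models = pd.DataFrame(
        {
            "structure": [str(s) for s, _ in kept],
            "logL": [f.logL for _, f in kept],
            "k": [f.k for _, f in kept],
            criterion: crit,
            "delta": delta,
            "weight": w,
            "converged": [f.converged for _, f in kept],
            "separation_flag": [f.separation_flag for _, f in kept],
        }
    )

    all_terms = sorted({t for s, _ in kept for t in s.terms})
    rows = []
    for term in all_terms:
        betas = np.zeros(len(kept))
        ses = np.zeros(len(kept))
        contains = np.zeros(len(kept), dtype=bool)
        for i, (s, f) in enumerate(kept):
            if term in s.terms:
                j = f.predictor_names.index(term)
                betas[i] = f.beta[j]
                ses[i] = np.sqrt(f.cov[j, j])
                contains[i] = True
        importance = float(w[contains].sum())
        if averaging == "full":
            ww, bb, ss = w, betas, ses
        else:
            ww = w[contains] / w[contains].sum()
            bb, ss = betas[contains], ses[contains]
        est = float(ww @ bb)
        se_u = float(ww @ np.sqrt(ss**2 + (bb - est) ** 2))
        rows.append(
            {
                "term": term,
                "importance": importance,
                "estimate": est,
                "unconditional_se": se_u,
                "ci_lo": est - Z975 * se_u,
                "ci_hi": est + Z975 * se_u,
            }
        )
    summary = pd.DataFrame(rows)
    return MMIResult(
        models=models,
        fits=kept,
        summary=summary,
        diagnostics={
            "n_models": len(structures),
            "n_nonconverged": n_nonconv,
            "n_separation_flagged": n_sep,
            "strict": strict,
            "averaging": averaging,
            "criterion": criterion,
        },
    )


def interaction_check(
    table: pd.DataFrame,
    outcome: str,
    pair: tuple[str, str],
    base_predictors: list[str],
    **kwargs,
) -> tuple[float, float]:
    """Model-averaged 95% CI of one interaction term.

    Re-runs the exhaustive search with the interaction admitted (under
    marginality) and returns the averaged CI of the product term — the
    check used to ask whether two strong predictors act synergistically.
    """
    a, b = pair
    if a == b:
        raise ValueError("interaction of a predictor with itself is invalid")
    if a not in base_predictors or b not in base_predictors:
        raise ValueError("both members of the pair must be in base_predictors")
    res = run_mmi(table, outcome, base_predictors, interactions=[pair], **kwargs)
    term = f"{min(a, b)}:{max(a, b)}"
    return res.term_ci(term)
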