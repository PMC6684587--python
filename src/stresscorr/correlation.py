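"""Pairwise Pearson correlation screening with significance stars.

All analysis variables — continuous, log-transformed, and binary coded 0/1 —
enter a single product-moment correlation matrix (so binary-vs-continuous
cells are point-biserial and binary-vs-binary cells are phi coefficients).
Two-sided p-values come from t = r * sqrt((n-2)/(1-r^2)) on n-2 degrees of
freedom, and cells are starred at p < 0.05 (*), < 0.01 (**), < 0.001 (***).
No multiplicity correction is applied; with this many simultaneous pairs
only the three-star level is a reliable signal of a strong association,
which the result records as an interpretive note.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["CorrelationMatrix", "pearson_matrix", "star"]

MULTIPLICITY_NOTE = (
    "No multiple-testing correction applied; with many simultaneous pairs "
    "only the three-star (p < 0.001) level is likely to indicate a strong "
    "association."
)


def star(p: float) -> str:
    """Significance stars: *** p<0.001, ** p<0.01, * p<0.05, '' otherwise."""
    if np.isnan(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass
class CorrelationMatrix:
    variables: list[str]
    r: pd.DataFrame
    p: pd.DataFrame
    stars: pd.DataFrame
    n: int
    note: str = MULTIPLICITY_NOTE
    constant_variables: list[str] = field(default_factory=list)

    def long_format(self) -> pd.DataFrame:
        """Unique off-diagonal pairs as rows (var1, var2, r, p, stars)."""
        rows = []
        for i, a in enumerate(self.variables):
            for b in self.variables[i + 1 :]:
                rows.append(
                    {
                        "var1": a,
                        "var2": b,
                        "r": self.r.loc[a, b],
                        "p": self.p.loc[a, b],
                        "stars": self.stars.loc[a, b],
                    }
                )
        return pd.DataFrame(rows)

    def strongest_with(self, target: str) -> tuple[str, float]:
        """Variable with the largest |r| against ``target`` (and that r)."""
        r = self.r[target].drop(index=target).dropna()
        name = r.abs().idxmax()
        return name, float(r[name])


def pearson_matrix(table: pd.DataFrame, variables: list[str]) -> CorrelationMatrix:
    """Pearson correlation matrix over ``variables`` of a transformed table.

    Requires at least 3 rows. A constant column yields NaN r and p against
    every other variable (flagged in ``constant_variables``) rather than an
    exception. Diagonal r is 1 with an empty star cell (self-correlation is
    not a test).
    """
    n = len(table)
    if n < 3:
        raise ValueError("correlation requires at least 3 rows")
    missing = [v for v in variables if v not in table.columns]
    if missing:
        raise ValueError(f"variables not in table: {missing}")
    X = table[variables].to_numpy(dtype=float)
    sd = X.std(axis=0, ddof=1)
    constant = [v for v, s in zip(variables, sd) if s == 0.0]
    with np.errstate(invalid="ignore", divide="ignore"):
        R = np.corrcoef(X, rowvar=False)
    R = np.asarray(R, dtype=float)
    iu = np.triu_indices_from(R, k=1)
    R[iu[1], iu[0]] = R[iu]  # exact (bitwise) symmetry
    np.fill_diagonal(R, 1.0)
    for v in constant:
        j = variables.index(v)
        R[j, :] = np.nan
        R[:, j] = np.nan
        R[j, j] = 1.0

    with np.errstate(invalid="ignore", divide="ignore"):
        t = R * np.sqrt((n - 2) / (1.0 - R**2))
    P = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    P[np.isclose(np.abs(R), 1.0)] = 0.0  # |r|=1: t is infinite
    P[np.isnan(R)] = np.nan
    np.fill_diagonal(P, np.nan)

    S = np.empty(R.shape, dtype=object)
    for i in range(len(variables)):
        for j in range(len(variables)):
            S[i, j] = "" if i == j else star(P[i, j])

    idx = list(variables)
    return CorrelationMatrix(
        variables=idx,
        r=pd.DataFrame(R, index=idx, columns=idx),
        p=pd.DataFrame(P, index=idx, columns=idx),
        stars=pd.DataFrame(S, index=idx, columns=idx),
        n=n,
        constant_variables=constant,
    )
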