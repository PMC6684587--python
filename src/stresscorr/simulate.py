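"""Synthetic strain-phenotype tables with known ground truth.

Real stress-phenotype panels are small, the predictors are correlated, the
strains cluster into genera, and the outcome is binary.  The generator here
reproduces exactly those features with full control of the truth:

* continuous predictors are drawn from a correlated multivariate normal
  hitting a target correlation matrix;
* binary predictors come from thresholding latent normals at the quantile
  matching the requested Bernoulli rate (so mixed continuous/binary
  correlation targets stay meaningful on the latent scale — the realised
  point-biserial correlations are attenuated relative to the target);
* genus labels are assigned round-robin, and optional genus-level random
  intercepts/slopes with a 2x2 covariance perturb the linear predictor;
* the outcome is Bernoulli(logistic(linear predictor)).

Seeds are split hierarchically (config seed -> replicate -> genus) so the
stream for one replicate never depends on how many replicates are drawn.
The ground-truth record returned alongside each table is sufficient to
recompute every row's exact linear predictor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["PredictorSpec", "SimulationConfig", "GroundTruth", "generate", "fixture_like"]


@dataclass
class PredictorSpec:
    """Marginals of one predictor: continuous N(mean, sd) or Bernoulli(rate)."""

    name: str
    kind: str = "continuous"  # or "binary"
    mean: float = 0.0
    sd: float = 1.0
    rate: float = 0.5


@dataclass
class SimulationConfig:
    n_strains: int
    n_genera: int
    predictors: list[PredictorSpec]
    correlation: np.ndarray | None = None  # target latent correlation
    intercept: float = 0.0
    slopes: dict[str, float] = field(default_factory=dict)
    interaction: tuple[str, str, float] | None = None  # (a, b, coefficient)
    re_cov: np.ndarray | None = None  # 2x2 genus (intercept, slope) covariance
    re_slope_predictor: str | None = None
    seed: int = 0

    def validate(self) -> None:
        m = len(self.predictors)
        names = [p.name for p in self.predictors]
        if len(set(names)) != m:
            raise ValueError("duplicate predictor names")
        if self.correlation is not None:
            C = np.asarray(self.correlation, dtype=float)
            if C.shape != (m, m) or not np.allclose(C, C.T):
                raise ValueError("correlation must be a symmetric m x m matrix")
            if not np.allclose(np.diag(C), 1.0):
                raise ValueError("correlation diagonal must be 1")
            w = np.linalg.eigvalsh(C)
            if w[0] < -1e-10:
                raise ValueError(
                    f"correlation matrix is not positive semi-definite "
                    f"(smallest eigenvalue {w[0]:.3g})"
                )
        for p in self.predictors:
            if p.kind == "binary" and not 0.0 < p.rate < 1.0:
                raise ValueError(f"Bernoulli rate for {p.name} must be in (0,1)")
        unknown = set(self.slopes) - set(names)
        if unknown:
            raise ValueError(f"slopes reference unknown predictors {sorted(unknown)}")
        if self.re_cov is not None:
            R = np.asarray(self.re_cov, dtype=float)
            if R.shape != (2, 2) or np.linalg.eigvalsh(R)[0] < -1e-10:
                raise ValueError("re_cov must be 2x2 positive semi-definite")
            if self.re_slope_predictor is not None and self.re_slope_predictor not in names:
                raise ValueError("re_slope_predictor not among predictors")


@dataclass
class GroundTruth:
    intercept: float
    slopes: dict[str, float]
    interaction: tuple[str, str, float] | None
    genus_effects: pd.DataFrame  # genus, intercept_dev, slope_dev
    re_slope_predictor: str | None
    linear_predictor: np.ndarray


def _latent_to_columns(Z: np.ndarray, specs: list[PredictorSpec]) -> pd.DataFrame:
    out = {}
    for j, p in enumerate(specs):
        if p.kind == "continuous":
            out[p.name] = p.mean + p.sd * Z[:, j]
        else:
            out[p.name] = (Z[:, j] < stats.norm.ppf(p.rate)).astype(int)
    return pd.DataFrame(out)


def generate(
    config: SimulationConfig, replicate: int = 0
) -> tuple[pd.DataFrame, GroundTruth]:
    """Draw one synthetic table plus its ground truth, reproducibly.

    The table has the same shape as a transformed phenotype table: one row
    per strain with predictors, a ``genus`` label, and binary ``CIRgrowth``.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, replicate]))
    m = len(config.predictors)
    C = (
        np.asarray(config.correlation, dtype=float)
        if config.correlation is not None
        else np.eye(m)
    )
    # eigendecomposition square root tolerates PSD-singular targets
    w, V = np.linalg.eigh(C)
    A = V @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
    Z = rng.standard_normal((config.n_strains, m)) @ A.T
    df = _latent_to_columns(Z, config.predictors)

    genera = [f"genus_{i:03d}" for i in range(config.n_genera)]
    df["genus"] = [genera[i % config.n_genera] for i in range(config.n_strains)]

    eta = np.full(config.n_strains, config.intercept, dtype=float)
    for name, slope in config.slopes.items():
        eta += slope * df[name].to_numpy(dtype=float)
    if config.interaction is not None:
        a, b, c = config.interaction
        eta += c * df[a].to_numpy(dtype=float) * df[b].to_numpy(dtype=float)

    ge_rows = []
    if config.re_cov is not None and np.any(config.re_cov):
        Lc = np.linalg.cholesky(
            np.asarray(config.re_cov, dtype=float) + 1e-12 * np.eye(2)
        )
        xsl = (
            df[config.re_slope_predictor].to_numpy(dtype=float)
            if config.re_slope_predictor is not None
            else np.zeros(config.n_strains)
        )
        for gi, gname in enumerate(genera):
            grng = np.random.default_rng(
                np.random.SeedSequence([config.seed, replicate, 1000 + gi])
            )
            b = Lc @ grng.standard_normal(2)
            mask = df["genus"].to_numpy() == gname
            eta[mask] += b[0] + b[1] * xsl[mask]
            ge_rows.append({"genus": gname, "intercept_dev": b[0], "slope_dev": b[1]})
    else:
        ge_rows = [
            {"genus": g, "intercept_dev": 0.0, "slope_dev": 0.0} for g in genera
        ]

    p = 1.0 / (1.0 + np.exp(-eta))
    df["CIRgrowth"] = rng.binomial(1, p)
    truth = GroundTruth(
        intercept=config.intercept,
        slopes=dict(config.slopes),
        interaction=config.interaction,
        genus_effects=pd.DataFrame(ge_rows),
        re_slope_predictor=config.re_slope_predictor,
        linear_predictor=eta,
    )
    return df, truth


def fixture_like(seed: int = 0) -> pd.DataFrame:
    """A 95-row synthetic table shaped like the packaged strain panel.

    Two phyla split 67/28, one dominant species group of 34 strains, raw
    positive metal-tolerance and temperature columns, and a binary outcome
    driven positively by CrCl3 tolerance and Tmax.  Intended for
    integration tests that must not touch the real data; it mimics
    marginals and correlation signs, not the actual measurements.
    """
    names = ["logD10", "Tmax", "logHgCl2", "logMER", "logCrCl3", "logK2Cr2O7"]
    specs = [
        PredictorSpec("logD10", mean=0.2, sd=0.25),
        PredictorSpec("Tmax", mean=37.0, sd=5.0),
        PredictorSpec("logHgCl2", mean=2.5, sd=0.6),
        PredictorSpec("logMER", mean=2.6, sd=0.5),
        PredictorSpec("logCrCl3", mean=2.6, sd=0.4),
        PredictorSpec("logK2Cr2O7", mean=2.3, sd=0.6),
        PredictorSpec("lowpHgrowth", kind="binary", rate=0.7),
    ]
    C = np.eye(7)
    pos_pairs = [(1, 4, 0.4), (2, 3, 0.5), (4, 5, 0.4), (0, 2, 0.3)]
    for i, j, r in pos_pairs:
        C[i, j] = C[j, i] = r
    cfg = SimulationConfig(
        n_strains=95,
        n_genera=18,
        predictors=specs,
        correlation=C,
        intercept=-9.0,
        slopes={"logCrCl3": 2.5, "Tmax": 0.06},
        seed=seed,
    )
    df, _ = generate(cfg)

    rng = np.random.default_rng(np.random.SeedSequence([seed, 424242]))
    phylum = np.array(["A"] * 67 + ["B"] * 28)
    species = np.array([f"Genus{i % 18:02d} species{i % 7}" for i in range(95)], dtype=object)
    species[:34] = "Saccharomyces cerevisiae"
    df = df.drop(columns=["genus"])
    out = pd.DataFrame(
        {
            "strain_id": [f"SYN-{i:04d}" for i in range(95)],
            "species_name": species,
            "phylum": phylum,
            "D10_kGy": np.round(10.0 ** df["logD10"], 2),
            "CIRgrowth": df["CIRgrowth"],
            "lowpHgrowth": df["lowpHgrowth"],
            "Tmax_C": np.clip(np.round(df["Tmax"]), 25, 50),
            "HgCl2_uM": np.round(10.0 ** df["logHgCl2"], 1),
            "MER_uM": np.round(10.0 ** df["logMER"], 1),
            "CrCl3_uM": np.round(10.0 ** df["logCrCl3"], 1),
            "K2Cr2O7_uM": np.round(10.0 ** df["logK2Cr2O7"], 1),
        }
    )
    return out
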