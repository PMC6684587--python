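"""Orchestration: run the full analysis flow from a config into report CSVs.

The flow mirrors the study design: load (or simulate) a strain-phenotype
table, transform it, and for each requested subset run correlation
screening, exhaustive AICc multi-model inference, preferred single-predictor
models with ROC evaluation, noise-benchmarked boosted-tree importance, and
per-genus mixed-effects logistic models.  Every stage writes plain CSV; a
JSON manifest records the seed, subset sizes, a data checksum, and any
stage failures (independent stages continue past a failure).
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from . import data as data_mod
from .correlation import pearson_matrix
from .gb_noise import NoiseBenchmarkConfig, benchmark_importance
from .glmm import fit_glmm, nakagawa_r2
from .logistic import fit_from_table, roc, wald
from .mmi import interaction_check, run_mmi

__all__ = ["AnalysisConfig", "preferred_model_report", "run", "reproduce_paper"]

_STAGES = ("correlation", "mmi", "preferred", "gb", "glmm")


@dataclass
class AnalysisConfig:
    """What to run, on what data, into which directory.

    ``data`` is a CSV path or ``builtin:<name>``. ``subsets`` maps a label
    to keyword arguments of :func:`stresscorr.data.subset` (empty dict =
    the full table). ``preferred`` maps a subset label to the single
    predictor of its preferred model.
    """

    data: str = "builtin:strains95"
    outcome: str = "CIRgrowth"
    predictors: list[str] | None = None  # None = within-phylum default set
    subsets: dict[str, dict] = field(
        default_factory=lambda: {
            "ascomycota": {"phylum": "A"},
            "basidiomycota": {"phylum": "B"},
        }
    )
    stages: tuple[str, ...] = _STAGES
    preferred: dict[str, str] = field(
        default_factory=lambda: {
            "ascomycota": "logCrCl3",
            "basidiomycota": "Tmax",
        }
    )
    glmm_predictors: list[str] = field(
        default_factory=lambda: ["logCrCl3", "Tmax"]
    )
    gb: NoiseBenchmarkConfig = field(default_factory=NoiseBenchmarkConfig)
    mmi_strict: bool = False
    mmi_averaging: str = "full"
    interaction_pair: tuple[str, str] | None = None
    out_dir: str = "stresscorr_out"
    seed: int = 0

    @classmethod
    def from_mapping(cls, m: dict) -> "AnalysisConfig":
        m = dict(m)
        if "gb" in m and isinstance(m["gb"], dict):
            m["gb"] = NoiseBenchmarkConfig(**m["gb"])
        if "stages" in m:
            m["stages"] = tuple(m["stages"])
        if "interaction_pair" in m and m["interaction_pair"] is not None:
            m["interaction_pair"] = tuple(m["interaction_pair"])
        return cls(**m)


def _load(source: str) -> pd.DataFrame:
    if source.startswith("builtin:"):
        return data_mod.load_builtin(source.split(":", 1)[1])
    return data_mod.load_table(source)


def _checksum(df: pd.DataFrame) -> str:
    return hashlib.sha256(
        df.to_csv(index=False).encode("utf-8")
    ).hexdigest()[:16]


def preferred_model_report(
    table: pd.DataFrame, outcome: str, predictor: str
) -> dict:
    """Single-predictor logistic fit with Wald summary and ROC/AUC.

    Returns a dict with the fit, the Wald frame, and the ROC result — the
    summary used to report a subset's preferred model.
    """
    fit = fit_from_table(table, outcome, [predictor])
    w = wald(fit)
    r = roc(fit.fitted_probabilities, table[outcome].to_numpy())
    return {
        "predictor": predictor,
        "fit": fit,
        "wald": w,
        "roc": r,
        "n": fit.n,
        "slope": float(fit.beta[1]),
        "intercept": float(fit.beta[0]),
        "auc": r.auc,
        "auc_ci95": r.ci95,
    }


def run(config: AnalysisConfig) -> dict:
    """Execute the configured stages per subset; write CSVs and a manifest.

    Returns the in-memory report bundle keyed by subset label; file outputs
    land under ``config.out_dir``.
    """
    unknown = [s for s in config.stages if s not in _STAGES]
    if unknown:
        raise ValueError(f"unknown stages {unknown}; valid: {_STAGES}")
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    raw = _load(config.data)
    table = data_mod.transform(raw)
    if config.predictors is not None:
        missing = [p for p in config.predictors if p not in table.columns]
        if missing:
            raise ValueError(f"configured predictors not in table: {missing}")

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "data": config.data,
        "data_checksum": _checksum(raw),
        "n_strains": len(raw),
        "subsets": {},
        "failures": {},
        "stage_seconds": {},
    }
    bundle: dict[str, dict] = {}

    for label, sub_kw in config.subsets.items():
        sub = data_mod.subset(table, **sub_kw)
        manifest["subsets"][label] = len(sub)
        preds = config.predictors
        if preds is None:
            # within a single phylum the indicator is constant
            single_phylum = sub["Ascomycota"].nunique() == 1
            preds = (
                data_mod.WITHIN_PHYLUM_PREDICTORS
                if single_phylum
                else data_mod.PREDICTORS
            )
        reports: dict = {"n": len(sub), "predictors": preds}
        prefix = out_dir / label

        def _stage(name, fn):
            if name not in config.stages:
                return
            t0 = time.perf_counter()
            try:
                fn()
            except Exception as e:  # independent stages continue
                manifest["failures"][f"{label}/{name}"] = repr(e)
            manifest["stage_seconds"][f"{label}/{name}"] = round(
                time.perf_counter() - t0, 3
            )

        def _correlation():
            cm = pearson_matrix(sub, list(preds) + [config.outcome])
            cm.r.to_csv(f"{prefix}_correlation_matrix.csv")
            cm.long_format().to_csv(f"{prefix}_correlation_long.csv", index=False)
            reports["correlation"] = cm

        def _mmi():
            res = run_mmi(
                sub,
                config.outcome,
                list(preds),
                strict=config.mmi_strict,
                averaging=config.mmi_averaging,
            )
            res.summary.to_csv(f"{prefix}_mmi_summary.csv", index=False)
            res.models.to_csv(f"{prefix}_mmi_models.csv", index=False)
            reports["mmi"] = res

        def _preferred():
            pred = config.preferred.get(label)
            if pred is None:
                return
            rep = preferred_model_report(sub, config.outcome, pred)
            rep["wald"].to_csv(f"{prefix}_preferred_wald.csv", index=False)
            with open(f"{prefix}_preferred.json", "w") as fh:
                json.dump(
                    {
                        "predictor": pred,
                        "n": rep["n"],
                        "slope": rep["slope"],
                        "intercept": rep["intercept"],
                        "auc": rep["auc"],
                        "auc_ci95": list(rep["auc_ci95"]),
                        "logL": rep["fit"].logL,
                        "aicc": rep["fit"].aicc,
                    },
                    fh,
                    indent=2,
                )
            reports["preferred"] = rep

        def _gb():
            gb_cfg = NoiseBenchmarkConfig(**{**config.gb.__dict__, "seed": config.seed})
            rep = benchmark_importance(sub, config.outcome, list(preds), gb_cfg)
            rep.summary.to_csv(f"{prefix}_gb_importance.csv", index=False)
            with open(f"{prefix}_gb_config.json", "w") as fh:
                json.dump(gb_cfg.__dict__, fh, indent=2)
            reports["gb"] = rep

        def _glmm():
            rows = []
            for pred in config.glmm_predictors:
                fit = fit_glmm(sub, config.outcome, pred)
                r2 = nakagawa_r2(fit) if fit.converged else None
                fit.genus_effects.to_csv(
                    f"{prefix}_glmm_{pred}_genus_effects.csv", index=False
                )
                rows.append(
                    {
                        "predictor": pred,
                        "intercept": fit.fixed[0],
                        "slope": fit.fixed[1],
                        "re_var_intercept": fit.re_cov[0, 0],
                        "re_var_slope": fit.re_cov[1, 1],
                        "re_cov_is": fit.re_cov[0, 1],
                        "marginal_r2": r2.marginal_r2 if r2 else float("nan"),
                        "conditional_r2": r2.conditional_r2 if r2 else float("nan"),
                        "converged": fit.converged,
                        "singular": fit.singular_flag,
                    }
                )
                reports.setdefault("glmm", {})[pred] = (fit, r2)
            pd.DataFrame(rows).to_csv(f"{prefix}_glmm_summary.csv", index=False)

        _stage("correlation", _correlation)
        _stage("mmi", _mmi)
        _stage("preferred", _preferred)
        _stage("gb", _gb)
        _stage("glmm", _glmm)
        bundle[label] = reports

    if config.interaction_pair is not None:
        base = config.predictors or list(data_mod.WITHIN_PHYLUM_PREDICTORS)
        ci = interaction_check(
            table,
            config.outcome,
            config.interaction_pair,
            base,
            strict=config.mmi_strict,
            averaging=config.mmi_averaging,
        )
        bundle["interaction"] = {"pair": config.interaction_pair, "ci95": ci}
        manifest["interaction_ci95"] = list(ci)

    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    bundle["manifest"] = manifest
    return bundle


def reproduce_paper(out_dir: str = "stresscorr_paper", seed: int = 0) -> dict:
    """Run the packaged 95-strain panel through the full published flow.

    Subsets: each phylum separately, both combined, the dominant
    S. cerevisiae group alone, and the panel without it.  The combined
    interaction check (logCrCl3 x Tmax) is included.  Multi-model inference
    runs in strict mode with natural (conditional) averaging: on these
    small subsets many candidate models perfectly separate the outcome, and
    dropping those degenerate fits is required to obtain meaningful
    model-averaged intervals.
    """
    sc = "Saccharomyces cerevisiae"
    cfg = AnalysisConfig(
        mmi_strict=True,
        mmi_averaging="conditional",
        subsets={
            "ascomycota": {"phylum": "A"},
            "basidiomycota": {"phylum": "B"},
            "combined": {},
            "scerevisiae_only": {"species_include": [sc]},
            "scerevisiae_excluded": {"species_exclude": [sc]},
        },
        preferred={"ascomycota": "logCrCl3", "basidiomycota": "Tmax"},
        interaction_pair=("logCrCl3", "Tmax"),
        out_dir=out_dir,
        seed=seed,
    )
    return run(cfg)
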