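"""Preferred single-predictor models of chronic-irradiation growth.

Loads the packaged 95-strain yeast panel, splits it by phylum, and fits the
preferred logistic model of each subset: CIRgrowth ~ log10(CrCl3 tolerance)
for Ascomycota and CIRgrowth ~ Tmax for Basidiomycota.  Prints the
coefficients (log-odds per unit of the predictor), their Wald standard
errors, and the ROC area with a DeLong 95% confidence interval — the AUC is
the probability that a randomly chosen CIR-grower scores higher than a
randomly chosen non-grower.
"""

import stresscorr as sc

table = sc.transform(sc.load_builtin("strains95"))

for phylum, predictor in [("A", "logCrCl3"), ("B", "Tmax")]:
    sub = sc.subset(table, phylum=phylum)
    rep = sc.preferred_model_report(sub, "CIRgrowth", predictor)
    name = "Ascomycota" if phylum == "A" else "Basidiomycota"
    print(f"\n{name} (n={rep['n']}): CIRgrowth ~ {predictor}")
    w = rep["wald"].set_index("term")
    print(f"  slope     {rep['slope']:7.3f}  (SE {w.loc[predictor, 'se']:.3f}, "
          f"p = {w.loc[predictor, 'p']:.2e})")
    print(f"  intercept {rep['intercept']:7.3f}  (SE {w.loc['(Intercept)', 'se']:.3f})")
    lo, hi = rep["auc_ci95"]
    print(f"  ROC AUC   {rep['auc']:.3f}  (95% CI {lo:.3f}, {hi:.3f})")
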