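"""Genus-level mixed-effects logistic models and their R^2 decomposition.

Species from the same genus are not independent observations.  This script
fits, for each headline predictor, a logistic model with per-genus random
intercepts and slopes (Laplace approximation) on the combined 95-strain
panel, then decomposes the latent-scale variance into fixed-effect,
random-effect, and logit-residual (pi^2/3) parts.  Marginal R^2 is the
share explained by the fixed effect alone; conditional R^2 adds the genus
effects.  A large gap between the two means the predictor's effect varies
by genus.
"""

import stresscorr as sc

table = sc.transform(sc.load_builtin("strains95"))

for predictor in ["logCrCl3", "Tmax"]:
    fit = sc.fit_glmm(table, "CIRgrowth", predictor, group="genus")
    r2 = sc.nakagawa_r2(fit)
    print(f"\nCIRgrowth ~ {predictor} + (1 + {predictor} | genus), "
          f"n={fit.n}, {fit.n_groups} genera"
          f"{'  [singular random effects]' if fit.singular_flag else ''}")
    print(f"  fixed: intercept {fit.fixed[0]:+.3f}, slope {fit.fixed[1]:+.3f}")
    print(f"  marginal R^2    {r2.marginal_r2:.3f}")
    print(f"  conditional R^2 {r2.conditional_r2:.3f}")
    slopes = fit.genus_effects.sort_values("total_slope")
    lo, hi = slopes.iloc[0], slopes.iloc[-1]
    print(f"  per-genus slope range: {lo.total_slope:.3f} ({lo.genus}) "
          f"to {hi.total_slope:.3f} ({hi.genus})")
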