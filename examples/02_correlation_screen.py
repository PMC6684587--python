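"""Pearson correlation screening of all stress-resistance phenotypes.

Builds the pairwise correlation matrix of the eight analysis variables
against chronic-irradiation growth within each phylum and prints each
variable's correlation with the outcome, starred at p < 0.05 / 0.01 / 0.001.
The strongest correlate differs by phylum: chromium(III) tolerance in
Ascomycota, maximum growth temperature in Basidiomycota.
"""

import stresscorr as sc
from stresscorr.data import WITHIN_PHYLUM_PREDICTORS

table = sc.transform(sc.load_builtin("strains95"))
variables = list(WITHIN_PHYLUM_PREDICTORS) + ["CIRgrowth"]

for phylum in ["A", "B"]:
    sub = sc.subset(table, phylum=phylum)
    cm = sc.pearson_matrix(sub, variables)
    name = "Ascomycota" if phylum == "A" else "Basidiomycota"
    print(f"\n{name} (n={cm.n}) — correlation with CIRgrowth:")
    for v in WITHIN_PHYLUM_PREDICTORS:
        r = cm.r.loc[v, "CIRgrowth"]
        stars = cm.stars.loc[v, "CIRgrowth"]
        print(f"  {v:12s} r = {r:+.3f} {stars}")
    best, r = cm.strongest_with("CIRgrowth")
    print(f"  strongest: {best} (r = {r:+.3f})")
print(f"\nnote: {cm.note}")
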