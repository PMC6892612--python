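"""Combining abilities and heritability on a worked 4-parent diallel.

The six hybrid phenotypes 10..20 are exactly additive: every cross equals
mu + g_i + g_j, so all SCA terms vanish and h2 = H2 = 1.  A +4 perturbation
of the C x D cross creates a specific combining ability of +4/3.
"""

import pandas as pd

from diallel import PhenotypeTable, analyze_condition, enumerate_half_diallel

values = {"AxB": 10.0, "AxC": 12.0, "AxD": 14.0, "BxC": 16.0, "BxD": 18.0, "CxD": 20.0}
panel = enumerate_half_diallel(list("ABCD"))


def table(vals):
    return PhenotypeTable(summary=pd.DataFrame(
        {"individual_id": list(vals), "condition": "c",
         "median": list(vals.values()), "sd": 0.0, "n": 6}))


res = analyze_condition(table(values), panel, "c")
print(f"additive data:    mu = {res.mu:.1f}")
print("  GCA:", {p: round(g, 2) for p, g in res.gca.items()})
print(f"  max |SCA| = {res.sca.abs().max():.2e}  ->  h2 = {res.h2}, H2 = {res.H2}")

res2 = analyze_condition(table(dict(values, CxD=24.0)), panel, "c")
print(f"perturbed z_CD=24: mu = {res2.mu:.3f}")
print("  GCA:", {p: round(g, 2) for p, g in res2.gca.items()})
print(f"  SCA(C,D) = {res2.sca[('C', 'D')]:.4f}  (the +4 shock minus what GCAs absorb)")
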