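"""Derive the seven fertility traits from foaling histories.

A mare's career is just her ages at foaling (months) plus a culling age;
everything else - age at first/last foaling, foaling count, intervals,
productive life and reproductive efficiency - is derived. The summary table
mirrors the descriptive statistics a breeding association would publish.
"""

import equifert as eq
from equifert.traits import ReproHistory

# a hand-readable mare: foals at 48, 60, 84 and 108 months, still active
mare = ReproHistory(mare_id="example", foaling_ages=[48, 60, 84, 108])
row = eq.derive_traits(mare)
print("single mare:", {k: round(v, 1) for k, v in row.items()})
# RE = 66.7%: four foalings against an optimum of six in a 60-month window

cfg = eq.SimConfig(n_founders=150, n_generations=5, n_snps=10, seed=3)
ped = eq.simulate_pedigree(cfg)
histories = eq.simulate_foaling_histories(ped, config=cfg)
table = eq.derive_trait_table(histories)
print("\ndescriptive statistics over", len(table), "mares:")
print(eq.describe(table).round(2).to_string())
# AIF/IF12 are missing for mares with a single foaling; they are excluded
# per trait, so each trait reports its own record count n.
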