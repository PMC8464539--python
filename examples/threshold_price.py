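"""Threshold (headroom) pricing: the maximum per-analysis price at which the
AI strategy is still dominant.

Prices the tool in the base case and in a conservative scenario (1% missed
LVOs, 25% of misses recovered).
"""
import dataclasses

from strokecea import ModelParams, read_life_table, threshold_price

params = ModelParams.defaults()
table = read_life_table("data/life_table_uk_synthetic.csv")

base = threshold_price(params, table)
conservative = dataclasses.replace(
    params, clinical=dataclasses.replace(params.clinical, p_missed=0.01, reduction=0.25)
)
cons = threshold_price(conservative, table)

print(f"base case (6% missed, 50% recovered):        ${base:.0f} per analysis")
print(f"conservative (1% missed, 25% recovered):     ${cons:.0f} per analysis")
print()
print("Below these prices the AI strategy saves money AND gains QALYs; above")
print("them it still gains QALYs but at a net cost, so it is no longer dominant.")
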