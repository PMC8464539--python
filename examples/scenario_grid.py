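"""Scenario grid: how the headroom for an AI tool scales with miss rate and
detection performance.

Evaluates the per-patient incremental cost and QALYs over a grid of
missed-LVO rates (usual care) x fraction of misses recovered by AI, with the
AI fee set to zero — so each cell's cost saving is the maximum per-analysis
price at which the tool would still be dominant in that scenario.
"""
from strokecea import ModelParams, read_life_table, scenario_grid, scenario_grid_frame

params = ModelParams.defaults()
table = read_life_table("data/life_table_uk_synthetic.csv")

cells = scenario_grid(
    params, table,
    missed_values=[0.01, 0.03, 0.06, 0.10, 0.20],
    reduction_values=[0.01, 0.25, 0.50, 0.75, 1.00],
    ai_cost=0.0,
)
df = scenario_grid_frame(cells)
print(df.pivot(index="p_missed", columns="reduction", values="ic_pp").to_string())
print()
print("Each cell: incremental cost per patient (USD) at zero AI fee. Savings")
print("scale with the product (missed rate) x (fraction recovered): doubling")
print("either doubles the recovered-miss mass and hence the saving.")
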