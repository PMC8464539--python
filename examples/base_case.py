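"""Base-case incremental analysis: AI-aided LVO detection vs usual care.

Runs the acute-phase decision tree and the lifetime Markov model for both
strategies at the built-in base case (6% missed LVOs, 50% of misses
recovered by AI, $40 per analysis) using the bundled synthetic UK-like life
table, and prints the incremental results per patient and per yearly cohort.
"""
from strokecea import ModelParams, base_case_frame, compare_strategies, read_life_table

params = ModelParams.defaults()
table = read_life_table("data/life_table_uk_synthetic.csv")
res = compare_strategies(params, table)

print(base_case_frame(res).to_string(index=False))
print()
print(f"incremental cost per patient : {res.ic_pp:+.0f} USD")
print(f"incremental QALYs per patient: {res.ie_pp:+.4f}")
print(f"net monetary benefit (at ${params.settings.wtp_per_qaly:,.0f}/QALY): "
      f"{res.nmb_pp:+.0f} USD per patient")
print(f"dominant: {res.dominant}")
print()
print("A negative incremental cost with positive incremental QALYs means the")
print("AI strategy both saves money and gains health (it is dominant): the")
print("extra thrombectomies it enables cost more up front (acute phase) but")
print("avoid far larger long-term disability costs over the remaining lifetime.")
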