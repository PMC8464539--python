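# strokecea

Early health-technology assessment of AI-aided large-vessel-occlusion (LVO)
detection in acute ischemic stroke: a cost-effectiveness model comparing
standard-of-care CTA reading against AI-aided reading, for health economists
and imaging-AI researchers who want to bound the value of a detection tool
before clinical evidence exists.

## Model

A cohort of suspected-stroke patients receiving CTA enters an acute-phase
decision tree: a fraction `p_LVO` has an LVO, of whom `p_elig` are eligible
for intra-arterial thrombectomy (IAT). Usual care detects a fraction
`1 − p_miss` of LVOs; the AI-aided reader detects `1 − p_miss(1 − r)`, where
`r` is the fraction of misses the software recovers. Only detected, eligible
patients receive IAT, so the treated cohort fraction is

```
f_IAT = p_LVO · p_elig · (1 − p_miss(1 − r))
```

Treated and untreated LVO patients take pooled 90-day modified-Rankin-Scale
(mRS 0–5, 6 = death) outcome distributions from large randomized
thrombectomy trials. The 90-day distribution seeds a Markov cohort model run
in yearly cycles over 70 years: each cycle applies general-population
mortality `q_x` from a life table, then recurrent stroke with annual
probability 2.84%, whose outcome follows the untreated distribution under a
no-improvement constraint. Per-cycle accruals are per-mRS annual costs
(discounted at 4%/yr) and per-mRS utility weights (discounted at 1.5%/yr).
Results are incremental costs `IC` and incremental QALYs `IE` of the AI
strategy versus usual care, per patient and per yearly UK cohort
(n = 71,840), with net monetary benefit `NMB = λ·IE − IC` at
λ = $25,662/QALY, threshold (headroom) pricing, scenario grids and one-way
sensitivity analysis.

## Worked example

```
python examples/base_case.py
```

prints (with the bundled synthetic UK-like life table):

```
                  phase  ic_population  ic_patient  ic_pct_usual_care  ie_population  ie_patient  ie_pct_usual_care
       acute (<90 days)        4449399          62               0.10          12.08      0.0002               0.00
rest of life (>90 days)      -14146632        -197              -0.32         644.08      0.0090               0.07
                  total       -9697233        -135              -0.22         656.16      0.0091               0.07

incremental cost per patient : -135 USD
incremental QALYs per patient: +0.0091
net monetary benefit (at $25,662/QALY): +369 USD per patient
dominant: True
```

Reading: at the base case (6% of LVOs missed in usual care, 50% of misses
recovered by AI, $40 per analysis) the AI arm costs $62 more per patient in
the first 90 days — more patients get the expensive thrombectomy plus the
software fee — but saves $197 per patient in discounted lifetime disability
costs, for a net saving of $135 and a gain of 0.0091 QALYs per suspected
stroke patient. Because it saves money *and* gains health it is dominant,
and the cohort totals (×71,840) are a ~$9.7M yearly saving and ~656 QALYs.

Other entry points: `examples/scenario_grid.py` (savings across miss-rate ×
performance scenarios), `examples/threshold_price.py` (maximum dominant
price per analysis), `examples/tornado.py` (one-way sensitivity),
`examples/microsim_check.py` (cohort engine vs patient-level simulation).
A thin CLI wraps the same functions, e.g.

```
strokecea base --life-table data/life_table_uk_synthetic.csv --out out/
strokecea grid --life-table data/life_table_uk_synthetic.csv --missed 1,3,6,10,20 --reduction 1,25,50,75,100
strokecea make-lifetable --out my_table.csv
```

The bundled life table is a synthetic Gompertz–Makeham table calibrated to
UK-like adult mortality (see `docs/methods.md`); substitute a real national
life table CSV (`age,qx`) for production analyses.

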