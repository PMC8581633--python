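# oncocea

Health-economic modeling engine for oncology treatment comparisons:
partitioned-survival and Markov cohort models over three health states
(progression-free, progressed, dead), parametric survival extrapolation
from digitized Kaplan-Meier data, discounted cost/QALY accrual, ICERs,
one-way and probabilistic sensitivity analyses, cost-effectiveness
acceptability curves, value-based threshold pricing and subgroup analysis.

It ships with a fully specified case study: sacituzumab govitecan (SG)
versus single-agent chemotherapy for metastatic triple-negative breast
cancer, evaluated from the Chinese healthcare-system and US payer
perspectives over a 5-year horizon in 28-day cycles (5%/3% annual
discounting respectively).

## Who this is for

Health-economics and HTA analysts who need a scriptable, testable
alternative to spreadsheet/commercial cohort models: every stage — curve
reconstruction, fitting, trace generation, accrual, uncertainty analysis —
is a plain Python function operating on YAML-serializable configs.

## The model in brief

For each arm, OS and PFS are parametric survival laws in AFT form
(log-logistic `S(t) = 1/(1+(t/scale)^shape)`, Weibull
`S(t) = exp(-(t/scale)^shape)`, time in months). The partitioned-survival
rule reads state occupancy off the curves at each cycle boundary t:

    PFD(t) = min(S_pfs(t), S_os(t));   dead(t) = 1 - S_os(t);   PD(t) = rest

A time-dependent three-state Markov chain, with transitions derived from
the same curves plus life-table background mortality, serves as a
structural cross-check. Discounted accrual turns a trace into life-years,
QALYs (utilities 0.85 progression-free / 0.52 progressed, one-time
adverse-event disutility) and itemized costs (drug, administration,
follow-up imaging, AE management, best supportive care, end-of-life care);
the incremental cost-effectiveness ratio is ΔCost/ΔQALY. See
`docs/methods.md` for the accrual conventions and their rationale.

## Worked example

```
$ oncocea run --perspective china --engine ps
engine: ps
  sg: LY=1.294 QALY=0.889 drug=2,322,710 total=2,420,771
  chemo: LY=0.887 QALY=0.539 drug=39,639 total=137,542
  incremental: dCost=2,283,228 dQALY=0.3498 ICER=6,526,916/QALY
```

Read: over five years a Chinese cohort on SG accrues 1.294 discounted
life-years and 0.889 QALYs at a total discounted cost of ¥2.42M (¥2.32M of
it drug acquisition at ¥192.5/mg); chemotherapy accrues 0.539 QALYs at
¥0.14M. SG buys 0.35 extra QALYs for ¥2.28M — ¥6.5M per QALY, about thirty
times the upper Chinese willingness-to-pay threshold of ¥217,341/QALY.
The US perspective (`--perspective us`) gives $527,300 per QALY against a
$150,000 threshold; `--engine markov` reproduces the partitioned-survival
result. Sensitivity analyses:

```
oncocea owsa --perspective china --out tornado.csv --plot tornado.png
oncocea psa  --perspective us --iterations 10000 --seed 1 --out draws.csv
oncocea ceac --perspective us --iterations 10000 --seed 1 --out ceac.csv
oncocea threshold --perspective us --wtp 150000 --seed 1
oncocea subgroup --perspective china --hr-os 0.48 --hr-pfs 0.41
oncocea synth --out fixtures/        # configs, life tables, digitized KM
```

The same operations are available as library calls
(`oncocea.run_pipeline`, `oncocea.owsa`, `oncocea.run_psa`,
`oncocea.threshold_price`, ...), and the full China/US input sets as
`oncocea.builtin_configs()`.

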