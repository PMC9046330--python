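# fallscea

A Markov cohort cost-utility model of supervised exercise for preventing
falls and fractures in men receiving androgen deprivation therapy (ADT)
for non-metastatic prostate cancer.

ADT causes muscle loss and bone-density decline, making these men a
high-risk falls population. The model compares a 12-month programme of
twice-weekly group exercise supervised by an accredited exercise
physiologist against usual care (advice only), from an Australian
health-system perspective: costs in 2019 AUD, QALYs as the outcome,
3-year horizon, 3-month cycles, 5% annual discounting, willingness to
pay AU$50,000 per QALY.

The package is aimed at health-economic modellers: it is a library first
(see `examples/`), with a thin `fallscea` CLI for report generation.

## Model

A cohort starts at age 68 in an *at risk of first fall* state and moves
between seven operational states: first-fall risk, recurrent-fall risk
(carrying a fear-of-falling utility decrement), major/minor fracture,
major/minor non-fracture injury (all four single-cycle tunnel states
with one-off treatment costs), and death. Conditional on a fall, a
faller fractures with probability 0.12 (major with 0.62), otherwise
sustains a non-fracture injury with probability 0.88 (major with 0.06);
only major events can be fatal, with an age-band case fatality
(0.023/0.043/0.065 for 60–64/65–69/70–74). Exercise lowers the annual
first-fall risk (RR 0.76), fracture risk (RR 0.44) and injury risk
(RR 0.70), and softens the fear-of-falling decrement (utility 0.74 vs
0.72). Non-fallers face background (life-table) mortality.

Per arm the engine accumulates the discounted, half-cycle-corrected
cost C and QALYs E, and the decision statistic is the incremental net
monetary benefit

    iNMB = WTP · ΔE − ΔC,        NMB_arm = WTP · E_arm − C_arm.

Around that base case the package provides one-way deterministic
sensitivity analysis (tornado data over the 95% CI of every input),
named cost scenarios, a probabilistic sensitivity analysis over fitted
Beta/Gamma/logNormal distributions with a cost-effectiveness
acceptability curve, and an individual-level microsimulation twin used
to validate the cohort engine (see `docs/methods.md`).

## Worked example

```python
import fallscea as fc

params = fc.load_parameters()          # packaged published inputs
result = fc.run_base_case(params)
```

Running `python examples/base_case.py` prints:

```
Base case (3-year horizon, 5% discount, WTP AU$50,000/QALY)
  control      cost AU$    4474  QALYs 2.0707  NMB AU$   99063
  intervention cost AU$    3204  QALYs 2.1074  NMB AU$  102165
  incremental cost : AU$-1270  (negative = cost saving)
  incremental QALYs: +0.0366
  iNMB             : AU$+3102  (intervention_dominant)
```

The exercise arm costs less (fewer fractures and injuries to treat,
more than offsetting the AU$767 programme cost) and yields more QALYs,
so it *dominates* usual care; the iNMB of roughly AU$3,100 per patient
is the money-metric value of switching. The other scripts in
`examples/` demonstrate distribution fitting, the tornado/scenario
analysis, the PSA with its acceptability curve, and the microsimulation
validation, each printing a short interpretation of its output.

The same analyses are available from the shell:

```bash
fallscea base-case --out out/
fallscea dsa --out out/ --scenario SA4a
fallscea psa --out out/ --iterations 10000 --seed 1
fallscea microsim-check --out out/ --iterations 200000 --seed 1
```

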