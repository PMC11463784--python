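# aedes-ude

Coupled mechanistic–neural modelling of *Aedes* mosquito population
dynamics under climate forcing — a universal-differential-equation (UDE)
workflow for vector surveillance data, built for ecologists and
epidemiological modellers who want mechanistic structure *and* a learned
component where the biology is unknown.

## The model

Mosquito abundance is described by a two-stage ODE (immatures `P`, adults
`A`) driven by daily temperature `T(t)` and precipitation `R(t)`:

    dP/dt = ANN(T, R)·A − dp(T)·P − mp(T)·P
    dA/dt = ef(R_norm)·dp(T)·P − ma(T)·A

Mortalities `mp`, `ma` are Gaussian survival curves; development `dp`
follows the Sharpe–DeMichele enzyme-kinetics equation; emergence success
`ef` is density- and rainfall-limited; a diapause switch (half-month mean
temperature below 21 °C) freezes immature mortality and scales development
by a ratio δ. The oviposition rate `ANN(T, R)` — biologically uncertain —
is a 2-10-10-1 sigmoid neural network embedded in the ODE and trained
through the solver against half-monthly ovitrap-style abundance indices
(MOI), using per-city rotation factors λ_j, an L1 loss, and a three-stage
ADAM schedule. A genetic-programming symbolic-regression stage then
distills the trained network into a closed-form expression over
{add, sub, mul, div, sig}.

Everything runs on synthetic data with known ground truth: the packaged
generator emulates a subtropical monsoon climate and plants the closed-form
reference oviposition expression `16/(1+e^(−φ)) + 4` as the truth, so every
pipeline stage can be validated end to end. See `docs/methods.md` for the
full model account and design decisions.

## Worked example

Generate the packaged 3-city benchmark, fit the coupled model at the
desk-scale schedule (100/400/200 iterations), and distill the result:

```bash
python analysis/01_make_benchmark.py
python analysis/02_fit_model.py
python analysis/03_symbolic_regression.py
python analysis/04_report.py
```

`02_fit_model.py` prints (seed 1):

```
final loss 3.0863 (initial 4.3157)
  city00: fitted-vs-observed r = 0.9812; rotation factor 1.95e-05 (truth 1.9e-05)
  city01: fitted-vs-observed r = 0.9830; rotation factor 6.08e-05 (truth 6.1e-05)
  city02: fitted-vs-observed r = 0.9909; rotation factor 1.4e-05 (truth 1.36e-05)
```

The loss is the mean absolute error between the scaled fitted half-month
adult series and the synthetic index; `r` is the per-city Pearson
correlation between the two, and the recovered rotation factors sit within
a few percent of the hidden truth. `03_symbolic_regression.py` demonstrates
the GP engine on a planted surface:

```
planted recovery (truth: sig(T - 25)):
  best expression: sig((T - 24.9982))
  raw MSE 2.46e-08 after 5 generations
```

i.e. the engine recovers the planted sigmoid threshold to three decimal
places from a population of 500 in a handful of generations.
`04_report.py` writes per-city correlations, a residual P-P table and the
network-vs-reference oviposition surface comparison under `results/report/`.

The same pipeline is available as a CLI
(`aedes-ude synth|simulate|fit|symreg|report`); the analysis scripts are
thin drivers over the identical library calls.

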