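# obtmon

Oscillation-based monitoring of adherent cell cultures: equivalent-circuit
models of cell-covered microelectrodes, a describing-function solver for the
relay/band-pass oscillation loop, fill-factor estimation from oscillation
amplitude, and an end-to-end time-series pipeline that segments
growth / growth-arrest / differentiation phases and derives interface
resistances — together with a fully synthetic study generator used as
ground truth for every analysis stage.

## What it does

- **`circuit_models`** — complex impedance of a fill-factor-parameterised
  two-branch cell–electrode network (uncovered branch `R_1‖C_1`, covered
  branch `R_gap + R_2‖C_2`) and of a differentiated-tissue circuit
  (`R_bulk + R_tissue + R_ct‖C_dl`), with exact limit reductions at
  `ff = 0` and `ff = 1` and an algebraic consistency check between the two
  models at full coverage.
- **`obt_engine`** — harmonic balance of the oscillation condition
  `1 + H_BP·H_z·H_CMP·N(a) = 0` with an ideal-relay describing function
  `N(a) = 4·Vsat/(π·a)`, returning `(f_osc, a_osc)`; validated by an
  independent time-domain relay-feedback simulator (state-space integration
  with event-located comparator switching) plus a waveform measurement
  routine.
- **`estimation`** — fill factor from cell counts
  (`ff = A_cell·N_cell/A_p`), forward calibration `ff → (a_osc, f_osc)`,
  monotone inversion of measured amplitudes to fill factor, least-squares
  interface-parameter fits, and the resistance-derivation rules
  (`R_bulk` = mean of undifferentiated-well `R_gap`; one-dimensional
  `R_tissue` fit at full coverage).
- **`timeseries_pipeline`** — trace CSV I/O, 70%-confluence threshold
  detection, slope-threshold plateau segmentation, exact rank-sum group
  comparison of amplitude gains, and assembly of the per-experiment
  resistance table.
- **`synthetic_data`** — generates multi-well studies (media-only wells,
  undifferentiated and differentiating wells, unmonitored controls) with
  logistic confluence growth, a stochastic growth-arrest plateau
  (Normal(0.8 d, 0.1 d), truncated at 0), a linear differentiation rise and
  multiplicative measurement noise, all mapped through the oscillator
  forward model, with full ground truth saved alongside.
- **`io_cli`** — strict YAML/JSON run configuration and the `obt` CLI.

## CLI

```bash
obt simulate    --out fixtures/ --seed 7          # synthetic study + truth
obt predict     --ff 0.5                          # (f_osc, a_osc) for one ff
obt estimate-ff --trace fixtures/traces.csv       # amplitude -> fill factor
obt fit         --trace fixtures/traces.csv       # per-well R_gap fit
obt pipeline    --traces fixtures/traces.csv --out report/
```

All commands accept `--config cfg.yaml`; a snapshot of the effective
configuration is written next to every output so runs are reproducible
bit-for-bit. Exit codes: 0 success, 1 runtime failure, 2 usage error.

## Default configuration

Ten 250 µm gold microelectrodes in a 0.8 cm² well; `R_s = 200 Ω`,
`R_ct = 1 MΩ`, `C_dl = 120 nF`, `R_gap = 1 kΩ`; band-pass `f0 = 10 kHz`,
`Q = 5`, comparator swing 3.3 V; the voltage-to-current gain is derived
from the 10 µA injected-current limit. All of these are test fixtures,
not claims about any physical instrument, and every analysis routine is
parameterised.
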