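# retikin

Population-based whole-body vitamin A kinetics and retinol isotope
dilution (RID) in Python.

## The problem

Vitamin A status is hard to measure: plasma retinol concentration is
homeostatically controlled and says little about the size of the body's
retinol stores. Two tracer-based approaches do better:

- **Compartmental modeling** of the plasma appearance/disappearance of an
  oral stable-isotope dose ([²H₆]retinol) yields the transfer
  coefficients of a whole-body model, and with them total body stores
  (TBS), the disposal rate, and turnover descriptors.
- **Retinol isotope dilution (RID)** estimates TBS from a *single*
  post-dose blood sample via TBS = Fa·S·(1/SAp), where SAp is the plasma
  tracer specific activity and Fa and S are model-derived coefficients.

In community settings each participant can only contribute a few blood
samples. This package implements the *super-subject* design: every
subject is assigned a small number of sampling times spread over ~3
months, per-time geometric means are pooled into one composite
fraction-of-dose curve, and a single compartmental model is fitted to
that curve. The fitted group model then supplies the RID coefficients
used to predict each individual's TBS from her one qualifying sample.

## The model

An 8-component linear compartmental system: the oral dose enters
compartment 1; compartments 1–3 cover digestion, absorption and
chylomicron processing (component 3 is a pure time delay); hepatocytes
(4) secrete retinol into plasma (5), which exchanges with two
extravascular storage pools (6, larger; 7, smaller — together TBS) and
feeds an irreversible tissue-uptake delay (8). Losses leave from
compartments 1, 6 and 8. A loss-partition constraint R(8,5) = R(0,6)
splits irreversible disposal equally between the plasma-side and storage
pathways, and absorption efficiency is fixed at 75% via the compartment-1
rate constants.

Because everything upstream of plasma is feed-forward, the delayed
forcing fluxes are analytic, and the tracer response of the exchange
block has an exact closed-form solution (used by default; a numerical
ODE path is kept as a cross-check).

## Worked example

```python
from retikin import (
    reference_parameters, solve_steady_state,
    compute_kinetic_summaries, simulate_rid_coefficients,
)

params, m5 = reference_parameters()   # bundled group estimates + M(5)
ss = solve_steady_state(params, m5)
print(f"TBS  {ss.tbs:.1f} umol")      # TBS  973.1 umol
print(f"DR   {ss.dr:.3f} umol/d")     # DR   1.303 umol/d
print(f"U(1) {ss.u1:.3f} umol/d")     # U(1) 1.737 umol/d

ks = compute_kinetic_summaries(params, ss)
print(f"plasma transit   {ks.transit_time_plasma_h:.2f} h")   # 2.36 h
print(f"plasma residence {ks.residence_time_plasma_d:.2f} d") # 2.58 d
print(f"store half-life  {ks.store_half_life_d:.0f} d")       # 375 d

coeffs = simulate_rid_coefficients(params, ss, (14.0, 28.0, 91.0))
print([f"{v:.3f}" for v in coeffs.fas])   # ['0.974', '0.684', '0.604']
```

Command line (synthetic end-to-end demo, then a report of the bundled
group model):

```bash
retikin all --synthetic --seed 0 --outdir demo_out
retikin report --outdir report_out
```

`retikin all` writes the cohort/samples/truth CSVs, the composite
dataset, the fit report, state variables, the RID coefficient table,
per-subject TBS and liver-concentration predictions, and a
machine-readable `results.json`. Runs are deterministic for a fixed
seed.

## Package layout

| module | contents |
| --- | --- |
| `retikin.model` | parameters, tracer simulation, steady state, kinetic summaries |
| `retikin.supersubject` | plasma volume, FDp, composite (super-subject) dataset |
| `retikin.fitting` | FSD-weighted nonlinear least squares, parameter FSDs |
| `retikin.rid` | RID coefficients, TBS/liver predictions, group summaries |
| `retikin.cohort` | synthetic cohort generator with known truth |
| `retikin.pipeline` / `retikin.cli` | end-to-end orchestration and the `retikin` CLI |

See `docs/methods.md` for the model equations, numerical choices, and
known limitations.
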