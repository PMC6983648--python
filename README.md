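# dcenirs

Quantification of tissue blood flow by **dynamic contrast-enhanced
time-resolved near-infrared spectroscopy** (DCE TR-NIRS), packaged as a tested,
reusable analysis pipeline — from raw photon time-of-flight histograms and
arterial dye curves to absolute perfusion in mL/min/100 g — together with the
surrounding study machinery: tissue-phantom validation, longitudinal
repeated-measures statistics, cohort clustering, and power analysis.  A
first-class synthetic-data module generates every input with known ground
truth, so the whole chain is exercised end to end and its calibration is
testable.

**Who it is for.** Researchers doing optical perfusion measurements in small
joints or similar thin-tissue geometries (e.g. monitoring inflammatory
arthritis models), and anyone who needs a transparent reference
implementation of the indicator-dilution deconvolution and its statistics.

## The method in brief

A pulsed laser and a single-photon counting detector record distributions of
times of flight (DTOFs) through the tissue.  Three relations carry the
physics:

1. **Pathlength** from the mean time of flight against the instrument
   response: `p = (c/n)(⟨t⟩_DTOF − ⟨t⟩_IRF)`, with `n = 1.4`.
2. **Modified Beer–Lambert law** for absorption changes after an indocyanine
   green (ICG) bolus: `Δμ_a(t) = ln(I₀ / I(t)) / p`, and tissue tracer
   concentration `Q(t) = Δμ_a(t) / (ln10 · ε_ICG)`.
3. **Indicator dilution**: `Q(t) = (C_a ⊛ f·R)(t)`, deconvolved for the
   flow-scaled impulse residue function `h = f·R` by Tikhonov-regularized
   nonnegative least squares (GCV-selected weight plus a roughness penalty);
   blood flow is `BF = 6000·max(h)/ρ` in mL/min/100 g.

Phantom validation regresses measured vs expected absorption changes of an
India-ink titration through the origin; study statistics run a three-way
mixed ANOVA (time × side within, group between) with Mauchly, Shapiro–Wilk
and Tukey HSD checks; power for the time × group interaction uses the
noncentral F distribution under both common effect-size conventions.  See
`docs/methods.md` for the full model account.

## Worked example

Run the whole pipeline — simulate a bolus measurement, a phantom titration
and a 12-animal longitudinal study; process, quantify and analyze — with one
command:

```bash
dcenirs run --seed 1 --out demo
```

`demo/report.json` from this exact command contains (abridged):

```
blood_flow:  bf_ml_min_100g = 15.44   (ground truth 15.0)
             pathlength_sensitivity_pct = 0.50
phantom:     slope = 1.0005,  R² = 1.000,  F(1,9) = 2.8e7
anova:       time        F(5,50) = 20.91,  p < 0.001,  partial η² = 0.68
             time*group  F(5,50) =  3.69,  p = 0.006,  partial η² = 0.27
             side        F(1,10) =  0.85,  p = 0.38
power:       gpower_default = 0.49,  spss_etasq = 0.29   (for this run's η²)
```

Reading it: the deconvolution recovered the planted flow of 15 mL/min/100 g
within 3% under realistic shot noise; perturbing the optical pathlength by
±0.5% moves BF by only 0.5%; the synthetic titration is linear through the
origin; and the study's planted time and disease effects surface in the
ANOVA with the expected (5,50)/(1,10) degrees of freedom.  Post-hoc power is
always reported under both noncentrality conventions, because calculators
disagree on the effect-size metric (see `docs/methods.md`).

The same stages are available as individual subcommands
(`simulate {airf,tissue,dtof,phantom,study}`, `process-dtof`, `quantify-bf`,
`phantom-validate`, `study-stats`, `power {posthoc,apriori}`) and, more
flexibly, as library functions:

```python
from dcenirs import generate_bolus_measurement, quantify_stack

m = generate_bolus_measurement(seed=1)          # 400 DTOFs over 120 s
est = quantify_stack(m.stack, m.irf, m.arterial)
print(est.bf_ml_min_100g)                       # 15.06
```

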