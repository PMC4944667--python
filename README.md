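# dmtpk

Pharmacokinetic modelling and target-controlled infusion (TCI) design for
intravenous *N,N*-dimethyltryptamine (DMT).

A fully psychedelic intravenous DMT bolus lasts under 20 minutes, which
makes careful study of the state's phenomenology — and functional imaging
of it — nearly impossible with single doses.  Because DMT shows no acute
tolerance, a computer-controlled infusion can in principle hold a stable
brain (effect-site) concentration indefinitely, the way TCI pumps hold
anesthetic levels during surgery.  `dmtpk` provides the quantitative
machinery for that idea, for pharmacometricians and psychedelic
researchers:

- a **two-compartment disposition model with saturable (Michaelis–Menten)
  clearance** `Vm·Cc/(Km+Cc)` — DMT is cleared by monoamine oxidase A —
  plus a mass-less first-order **effect-site link**
  `dCe/dt = k1e·Cc − ke0·Ce` with `k1e = ke0` calibrated so peak effect
  falls at 3 min;
- an event-aware stiff ODE **simulator** with dense output, mass-balance
  auditing, peak and threshold-crossing analysis (the ~60 ng/ml effect-site
  "breakthrough" window);
- a **B.E.T. (bolus-elimination-transfer) designer**: loading bolus
  `B0 = CT·Vc` plus maintenance rate
  `R_T(t) = Vm·CT/(Km+CT) + CT·Vc·k12·e^(−k21·t)` discretized into a
  per-minute pump schedule, with a simulated-overshoot bolus correction;
- a **naive-pooled fitting workflow**: per-timepoint averaging with CV
  summaries, proportional-error weighted least squares over
  1/2/3-compartment × linear/saturable candidates, AICc model selection;
- a **synthetic cohort generator** reproducing the design of the original
  bolus study (two dose groups of nine subjects, 30 s infusion, sampling
  2–60 min post-administration) so every workflow is testable end to end
  without clinical data.

The fitted parameter table for the 0.2 and 0.4 mg/kg dose groups ships
with the package.  Its printed units are internally inconsistent with the
published simulation narrative; both readings are exposed as explicit
*unit dialects* (see `docs/methods.md`), and the default (`rescaled`)
reproduces the published 25 mg-bolus / 200 ng/ml-spike design narrative.

## Worked example

Simulate the reference administration (0.4 mg/kg over 30 s, 75 kg
subject) with the calibrated effect-site link:

```sh
dmtpk simulate --regimen examples/bolus_0p4_75kg.csv --horizon 20 --out runs/bolus
```

```
total dose: 30.000 mg over 0.5 min
mass balance residual: 2.072e-15
plasma peak: 272.1 ng/ml at 0.50 min
effect-site peak: 72.1 ng/ml at 3.00 min (ke0 = 0.2561 /min)
breakthrough window (> 60 ng/ml): 1.56-5.74 min (duration 4.18 min)
```

Plasma peaks at the end of the 30 s infusion and redistributes within
minutes; the effect site lags, peaking at 3.0 min (the calibration
landmark, where `Ce = Cc` by the link identity) and staying above the
~60 ng/ml breakthrough threshold for about 4 minutes — the width of the
fully immersive window after a single bolus.

Design an infusion protocol holding ~100 ng/ml:

```sh
dmtpk design --target 100 --out runs/tci
```

```
B.E.T. infusion protocol — target 100 ng/ml
  bolus: 22.06 mg over 0.5 min
  infusion start: 2 min, updates every 1 min
  interval (min)    rate (mg/min)
     2.00-   3.00        5.360
     3.00-   4.00        4.796
     4.00-   5.00        4.318
     ...
    35.00-  60.00        1.646  (steady state)
verification: effect-site peak 71.9 ng/ml, overshoot 0.00%,
plasma time in ±20% band 99.7% of maintenance, final 99.8 ng/ml
```

The corrected bolus (22.1 mg versus the ideal `CT·Vc = 9.3 mg`)
compensates mass lost to elimination and tissue transfer before the
maintenance law takes over; plasma briefly spikes to ~198 ng/ml, then the
per-minute schedule decays from 5.4 mg/min to the steady-state rate
`Rss = Vm·CT/(Km+CT) = 1.65 mg/min`, holding plasma within ±20% of
target for 99.7% of the session and bringing the effect site to the
target with under 0.1% overshoot.

The same machinery is available as a library:

```python
import dmtpk

params = dmtpk.load_table2(0.4)            # fitted 0.4 mg/kg parameter set
effect = dmtpk.tune_effect_site(params)    # ke0 -> 3-min peak effect
spec = dmtpk.design_protocol(100.0, params, effect)
metrics = dmtpk.evaluate_protocol(spec, params, effect)
```

Other subcommands: `evaluate` scores an arbitrary regimen for overshoot
(e.g. `examples/gouzoulis_75kg.csv`, the constant-rate literature
protocol), `generate` writes synthetic cohorts, `fit` runs the
naive-averaged fitting and model-selection workflow, and `report`
pretty-prints a saved protocol.

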