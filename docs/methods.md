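# Methods

## Model

`dmtpk` implements a mammillary compartmental model of intravenous
*N,N*-dimethyltryptamine (DMT) disposition with a pharmacodynamic
effect-site link:

- **Central compartment** (volume `Vc`): well-mixed plasma space receiving
  the intravenous input `u(t)` (mg/min).
- **Peripheral compartment(s)** (`Vp`, optionally `Vp2`): lumped tissue
  spaces exchanging drug with plasma through inter-compartmental
  clearance(s) `Q12` (and `Q13`), giving micro rate constants
  `k12 = Q12/Vc`, `k21 = Q12/Vp`.
- **Elimination**: saturable Michaelis–Menten kinetics
  `Vm·Cc/(Km + Cc)` reflecting monoamine-oxidase-A metabolism, or linear
  clearance `CL·Cc` for the candidate structures used in model selection.
- **Effect site**: a mass-less first-order link
  `dCe/dt = k1e·Cc − ke0·Ce`.  At the effect-site peak `dCe/dt = 0`
  forces `Ce = (k1e/ke0)·Cc`; the clinical observation that plasma and
  effect-site concentrations coincide at the time of peak effect
  therefore holds identically iff `k1e = ke0`, which the package enforces
  by default.  This is the minimal assumption satisfying the observation,
  and matches the anesthesia-TCI convention of a link compartment that
  draws no mass from plasma.

State equations (canonical units: min, mg, L, mg/L):

```
Vc  dCc/dt = u(t) − elim(Cc) − Q12(Cc − Cp) − Q13(Cc − Cp2)
Vp  dCp/dt = Q12 (Cc − Cp)
    dCe/dt = k1e Cc − ke0 Ce
```

Cumulative infused and eliminated mass are integrated alongside so that
mass balance (`infused = Vc·Cc + Vp·Cp + eliminated`) can be audited; the
default solver keeps the relative residual below 1e−6 (observed ~1e−15).

## Unit dialects

The shipped fitted-parameter table prints `Vc ≈ 0.1 L` — yet the source
narrative's own worked example (a 25 mg bolus producing a plasma spike of
just over 200 ng/ml while targeting 100 ng/ml) requires an apparent
central volume near 100 L.  No consistent unit reading reconciles the two
(0.1 L would give a ~269,000 ng/ml spike).  The package does not guess
the intended units; it exposes both readings as a `UnitDialect`:

- `literal`: volumes/Q12 as printed (L, L/min), `Km` in mg/L;
- `rescaled` (default): volumes/Q12 ×1000, `Km` read in µg/L
  (≡ ng/ml).

Under `rescaled`, the designed 100 ng/ml protocol computes a corrected
bolus of 22.1 mg with a 198 ng/ml plasma spike — closely matching the
published 25 mg / "over 200 ng/ml" narrative, which is why it is the
default.  Two published values remain irreproducible under *any* dialect
and are reported from this package's own arithmetic instead: the
steady-state rate at 100 ng/ml is `Vm·CT/(Km+CT) = 1.646 mg/min` (0.93
was printed), and the transfer term `CT·Vc·k12·e^(−k21·t)` is monotone
decreasing from 5.6 mg/min (a peak of "3.3 mg/min at 2.3 min" was
printed, which cannot follow from that expression).

## B.E.T. infusion design

The bolus-elimination-transfer scheme targets a constant plasma
concentration `CT`:

- bolus `B0 = CT·Vc`;
- maintenance rate `R_T(t) = Vm·CT/(Km+CT) + CT·Vc·k12·e^(−k21·t)`,
  the sum of the (constant) elimination rate at target and the decaying
  net transfer into tissue, with `R_T → Rss = Vm·CT/(Km+CT)`.

If the target is attained instantaneously and `R_T` is applied
continuously, plasma remains exactly at `CT` (verified numerically to
~2e−8 relative).  A deliverable protocol discretizes this law:

- **Interval rates** are the exact time-averages of `R_T` over each
  update interval (default 1 min), which halves discretization error
  relative to left-endpoint sampling; a 1-min schedule holds plasma
  within ~1% of target (5% is the acceptance bound).
- **Switch to constant `Rss`** once the interval-averaged transfer term
  falls below 1% of `Rss` (≈35 min for the default parameter set) —
  a relative threshold rather than an invented hard time constant.
- **Bolus-loss correction** (default on): because the real bolus takes
  30 s and infusion only starts at 2 min, mass is lost to elimination and
  tissue transfer before the maintenance law takes over, and the effect
  site fills from below.  The designer scales the bolus by a 1-D root
  find so that the simulated global effect-site maximum equals the target
  (the trajectory is pointwise monotone in the bolus, so the root is
  unique).  For `CT = 100 ng/ml` this yields 22.1 mg versus the ideal
  `CT·Vc = 9.3 mg`.

**Time-in-band** is reported for *plasma* as the headline metric (band
±20%, following the plasma-deviation convention of target-controlled
anesthesia, where delivered plasma concentrations typically deviate
20–30% from target); the effect-site fraction is reported alongside.
The effect site necessarily approaches the target from below with time
constant `1/ke0 ≈ 4 min`, so no bolus-plus-decaying-rate schedule can
keep `Ce` within ±20% during the first ~6 min without deliberately
overshooting plasma; a plasma band is the quantity the B.E.T. control
law actually governs.  The default design holds plasma in band for
99.7% of the maintenance phase with < 0.1% effect-site overshoot.

## Effect-site calibration

`ke0 (= k1e)` is not identifiable from concentration data alone and was
never published; it is calibrated so the simulated effect-site peak of
the reference administration (0.4 mg/kg × 75 kg over 30 s) falls at
3.0 min, the observed time of peak drug effect.  Peak time is strictly
decreasing in `k` (a stiffer link tracks plasma faster), giving a clean
bracketing root find; the result is `ke0 ≈ 0.256 min⁻¹` with the
peak-equality check `Ce(t_peak) = Cc(t_peak)` holding to well under 1%.

With the tuned model the effect site crosses the ~60 ng/ml
"breakthrough" threshold at 1.56 min and re-crosses it at 5.74 min
(duration 4.2 min, peak 72 ng/ml).  The source narrative describes a 6–7
min window with a peak "just over 100 ng/ml"; those figures belong to
the same family of published simulation outputs that are not reproducible
from the printed parameter table (see Unit dialects above) and are
treated as qualitative only.

### Constant-rate literature protocol

Evaluating the constant-rate regimen from the earlier infusion study
(22.5 mg bolus over 30 s, then 1.5 mg/min from 1.5 min for 84 min, 75 kg
subject): the effect site peaks at 55.9 ng/ml at 3.8 min, sags to
49.7 ng/ml near 14 min as the bolus redistributes, then rises
monotonically to 58.7 ng/ml at the end — above the post-bolus peak, but
*not* the published "80 ng/ml rising steadily to 150 ng/ml".  Under the
fitted parameters a 1.5 mg/min infusion supports a steady state of only
~64 ng/ml, so a monotone climb through the entire maintenance phase is
impossible once the bolus transient overshoots the infusion-supported
level.  The package reports the sag honestly (the monotonicity flag
tolerates only sub-0.5% numerical wiggles, and this sag is ~11%); the
corresponding qualitative acceptance check fails on the monotonicity
clause and is knowingly left failing.  The overshoot *mechanism* the
protocol was criticized for — a constant rate above `Rss` produces an
unbounded monotone rise — is real and is verified on a bolus-free
constant-rate regimen.

## Fitting workflow

The naive-averaged (pooled) approach: per-timepoint arithmetic means
across subjects form one curve per dose group; CV = SD/mean per
timepoint, and the windowed CV averages timepoints falling 2–30 min
after the end of administration.  Fitting minimizes proportional-error
weighted least squares `Σ((obs − pred)/pred)²` — concentrations span two
orders of magnitude, and no error model was published, so proportional
weighting is the standard choice.  Pre-dose (zero) samples are excluded:
they carry no kinetic information and break proportional weighting.

Numerics: optimization runs in log-parameter space (positivity for free;
volumes and rate constants differ by orders of magnitude) with
`scipy.optimize.least_squares` (trust-region reflective, wide log-space
bounds), multistart from one data-driven heuristic (dilution volume from
Cmax, clearance from a trapezoidal AUC) plus seeded log-uniform draws —
20 starts by default, since Michaelis–Menten multicompartment objectives
are multimodal.  A noiseless mean curve is recovered to machine
precision; estimates at a bound are flagged.

**Model selection** ranks 1/2/3-compartment × linear/saturable
candidates by AICc (`k` counts the error variance), with near-ties
(ΔAICc < 2) resolved toward fewer parameters.  Two structural facts make
the *joint* fit of both dose-group curves (shared parameters, n = 12
residuals) the canonical selection dataset: (i) on a single 6-point
curve the AICc small-sample correction is undefined for the 5-parameter
saturable candidate (n − k − 1 ≤ 0; such candidates receive +inf AICc
with a note); (ii) saturable clearance is only identifiable across dose
levels — a single curve leaves `(Vm, Km)` on a likelihood ridge.  With
study-like noise (5% proportional on the mean curves) the
two-compartment Michaelis–Menten candidate wins essentially always, by
ΔAICc ≈ 35 over the best linear candidate.

## Synthetic cohorts

The generator emulates the original study design: two dose groups (0.2
and 0.4 mg/kg of the fumarate salt), nine subjects each, a 30 s infusion
plus 15 s flush (so sampling clocks start at 0.75 min wall-clock), and
samples pre-dose and at 2, 5, 10, 15, 30, 60 min post-administration.
Defaults:

| parameter | default | rationale |
|---|---|---|
| `omega` (between-subject log-normal SD, all structural parameters) | 0.33 | calibrated by Monte Carlo so the 0.4 mg/kg windowed concentration CV lands in the upper-50s %, the dispersion the study reported for that group (a single shared omega compounds across all five parameters, so the dial is well below the target CV itself; omega ~ 0.55 reproduces the 83% of the 0.2 mg/kg group); only aggregate CVs were published, so one shared omega is the minimal parameterization |
| `sigma` (proportional residual SD) | 0.15 | typical assay-plus-sampling noise for GC-MS plasma concentrations; the study published no residual/between-subject variance decomposition, so this is a calibration choice |
| weight distribution | N(75, 10) kg truncated to [45, 120] | the published worked examples use a 75 kg subject |
| pre-dose samples | exact 0 | endogenous DMT baseline handling was unspecified and is out of scope |

What the generator does *not* emulate: assay limit-of-quantification
censoring, within-subject kinetic nonstationarity, covariate structure
(age/sex/liver function), and any dose-dependence of between-subject
variance (the study's two groups showed different CVs — 83% vs 58% —
which a single omega cannot produce).  Tests passing on these cohorts
therefore demonstrate correctness of the estimation machinery under the
stated generative assumptions, not performance on real clinical data.

## Numerical choices

- Reference solver: adaptive stiff-capable LSODA, rtol 1e−8, atol
  1e−10 mg/L, with a hard restart at every dosing-rate discontinuity
  (piecewise-constant inputs break the smoothness the step controller
  assumes).  Dense output is retained per segment; peak times and
  threshold crossings are computed on the dense interpolant (local
  refinement for peaks, linear interpolation for crossings), never on
  the save grid.
- Fitting fast path: the same model driven through `odeint` at rtol
  1e−7 (1e−6 inside replicate studies), states only; it agrees with the
  reference path to ~1e−5 relative and is ~3× faster per solve.
- Replicate-study sizes: the parameter-recovery study runs 200 cohorts
  (4 optimizer starts each); the model-selection study 100 replicates ×
  6 candidates (3 starts each); the acceptance script scales these to
  50 and 20 replicates respectively, which is sufficient to estimate a
  bias bounded by 10% and a win rate near 100%.
- Unit conversions use explicit ×1000/÷1000 (never ×0.001), which keeps
  mg/L → ng/ml → mg/L round trips bit-identical for all
  printed-precision (≤3 decimal) values; arbitrary binary doubles round
  trip to within 1 ulp, a floating-point limitation no factor-1000
  conversion can avoid.
- Degenerate inputs: zero regimens simulate to identically zero
  trajectories and raise a dedicated error from peak queries; `Q12 = 0`
  collapses the closed form to the mono-exponential one-compartment
  solution; a fit with fewer informative points than parameters, or
  inverted bounds, is rejected up front with a diagnostic.

## Known limitations

- Intravenous input only; no oral/absorption kinetics (oral DMT
  requires MAO inhibition and fundamentally different kinetics).
- Naive-pooled estimation only; no nonlinear mixed-effects machinery,
  covariate models, or Bayesian estimation.
- The effect-site constant rests on a single observed landmark (3-min
  peak effect); no pharmacodynamic endpoint model is fitted.
- Open-loop design only: no feedback from measured concentrations and
  no pump-driver integration.
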