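# Methods

## Scope and model

`drinksim` models a drinking-event episode imposed on a batch fermentation
system: a stainless-steel water bath (default 12.5 L working volume in a
20 L tray) held at a 39 °C baseline by a heating immersion circulator, with
a sealed 250 mL fermentation jar immersed in it. An episode is

1. a baseline hold,
2. a cold-water addition that pulls the bath down (sized by the law of
   mixtures),
3. a programmed recovery ramp executed by the circulator, activated at the
   first sample within ±0.01 °C of the profile's anchor temperature,

with the jar temperature at all times given by the forced Newton model
dj/dt = −k (j − b(t)).

Assumptions baked into this structure:

- **Well-mixed bath and jar.** Each medium has a single temperature; no
  spatial gradients, no jar-to-jar coupling, no ambient losses. All
  jar-side physics is collapsed into the one rate constant k.
- **Setpoints are achieved.** Once the ramp activates, the bath equals the
  circulator setpoint exactly (no controller overshoot or lag). Between
  profile rows the setpoint is interpolated linearly; the recovery in real
  recordings looks smooth, which is consistent with a linear ramp.
- **Water bookkeeping in litres = kilograms** (density 1.0 kg/L), and a
  shared specific heat for all water (default 4.18 J/(g·°C)); for
  water–water mixtures the value cancels and does not affect any result.
- **Removal is thermally neutral.** Water shifted out of the bath to make
  room leaves at the current mixed temperature, so it changes mass but not
  temperature. It does change the final equilibrium: removing warm mixed
  water before a second cold addition deepens the final drop, which is why
  staged totals are sized by solving the staged mixture chain rather than
  the single-mix inversion.

## Parameters that matter

| parameter | unit | default | rationale |
|---|---|---|---|
| rate constant k | min⁻¹ | 0.33 (reference fit) | ~3-min jar time constant; reproduces the observed 6–7 min lag of the jar minimum. A per-second or per-hour reading of the same number would put the lag at milliseconds or hours, contradicting observation. |
| baseline temperature | °C | 39.0 | normal reticulorumen temperature |
| target jar drop | °C | 9.0 | upper range of drinking-induced RT drops reported in vivo |
| recovery ramp | — | 27 → 36 → 38 → 39 °C over 0/30/30/60 min | standard 2-h recovery profile; other lengths scale the segment durations proportionally |
| cold-water temperature | °C | 4.0 | refrigerated water |
| mixing_tau | min | 0.5 | first-order time constant of bath mixing after an addition; recordings show a near-vertical drop, so the transient is fast but finite |
| stage_dwell | min | 3.0 | pause between staged additions (equilibration + water shifting) |
| pre-event hold | min | 10 | gives fits an equilibrium context before the drop |
| logger sampling | s | 3 | matches the deployed data loggers |
| sensor noise SD | °C | 0.05 | no measured value exists for the deployed loggers; chosen below their best resolution. A free generator parameter. |
| quantization | °C | 0.0625 | finest iButton resolution (hardware supports 0.0625–0.5) |
| fit bounds for k | min⁻¹ | (10⁻³, 10) | brackets equilibration time constants from ~6 s to ~17 h; estimates pinned at a bound are flagged unconverged |

## Numerical choices

- **Production solver.** On each piecewise-linear bath segment the ODE has
  the exact solution j(t) = b(t) − β/k + (jᵢ − bᵢ + β/k)e^(−k(t−tᵢ)); the
  state is propagated segment-by-segment, so only decaying exponentials are
  evaluated and the computation is stable for arbitrary k·t (the naive
  integrating-factor form overflows near k·t ≈ 700). On uniform grids the
  propagation is a first-order recurrence evaluated as an IIR filter.
- **Oracle.** A fixed-step RK4 integrator over the linear interpolant is
  kept purely as an independent test cross-check; its grid is aligned to
  the bath knots and output times so its own error stays far below the
  1×10⁻⁴ °C agreement bound asserted in tests.
- **Fitting.** One-parameter bounded Brent minimisation (xatol 10⁻⁶),
  deterministic for fixed inputs. j₀ defaults to the first jar observation.
  Residuals are evaluated at the jar observation times only; the bath may
  be sampled on a different grid.
- **Inverse design.** The bath drop needed for a target jar drop is located
  by bisection to 0.01 °C. The standalone routine uses an idealised episode
  (instantaneous drop, ramp re-anchored at baseline − d). `plan_event`
  instead simulates the same transient bath trajectory that
  `simulate_event` produces (mixing transient, staging, activation
  detection), so a planned event round-trips through simulation to within
  the bisection tolerance.
- **Staging rule.** A single addition is used whenever bath volume + cold
  volume fits the tray; otherwise stage 1 fills the tray to capacity and
  the balance is added after shifting that same balance out. The reference
  protocol (`protocol_plan`) staged its 7 L addition even though it fit the
  tray — practical headroom — and is therefore provided as an explicit
  plan rather than derived from the rule.
- **Rounding.** Tabulated mixture results are reported at full precision;
  a round-half-up helper reproduces 2-dp printed tables. Quantization in
  the sensor model rounds to the nearest multiple on the absolute Celsius
  scale, ties to even.
- **Degenerate inputs.** All-zero-mass mixtures, empty profiles, targets
  outside the mixing-reachable band, non-monotone logger files, and traces
  with no sub-baseline minimum are rejected with specific errors; recovery
  criteria never met raise a signal carrying the closing deficit.

## The synthetic-data generator

Real paired bath/jar recordings of this protocol are not publicly
available, so the generator stands in for them: ideal episode trajectory →
forward jar model → Gaussian sensor noise → quantization, all deterministic
given a seed. It emulates 3-s sampling, the staged-addition "interruption"
of the decline, ramp activation at the anchor, and iButton-style
resolution. It does **not** emulate: gradual pouring (additions mix with a
single first-order time constant), removal of the jar to a holding tray
during water shifting (the simulated jar stays in the bath, which deepens
its drop slightly relative to the physical protocol), circulator control
error, sensor drift, or non-Gaussian noise. Passing tests therefore
demonstrate internal consistency of design, simulation and estimation under
this sensor model — not validation against physical recordings, whose
noise structure and handling transients may differ.

Parameter-recovery results use twenty ~140-min episodes (3-s sampling,
σ = 0.1 °C, 0.0625 °C quantization); each fit sees ~2 800 observations.
These sizes keep the full suite and the reproduction script in the seconds
range while leaving the Monte-Carlo spread of the estimate an order of
magnitude below the ±0.02 acceptance band.

## Known limitations

- The model predicts that a simulated reference event reaches 99 %
  recovery about 110–112 min after the jar minimum, short of the nominal
  120-min figure usually quoted for this profile: the jar minimum occurs
  ~6–7 min *after* ramp activation, and the jar crosses the 99 % threshold
  a few minutes *before* the ramp ends (its terminal lag of β/k ≈ 0.05 °C
  is smaller than the allowed deficit). The nominal figure describes the
  ramp length, not the min-to-threshold interval this package computes.
- For drops above 10 °C the ±0.10 °C absolute recovery criterion is
  *stricter* than 99 % recovery (0.01·drop > 0.10 °C); below 1 °C drops the
  90 % criterion becomes stricter than the absolute one. Reported recovery
  periods must therefore always name their criterion.
- k is treated as constant per jar and bath configuration. Physically it
  aggregates convection and jar-wall conduction and could vary with stirring
  and fill level; refitting per configuration is recommended.
- The estimator returns a point estimate only (no confidence interval), and
  perfect-tracking observations (jar ≡ bath) push k to the search bound,
  which is flagged rather than resolved.
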