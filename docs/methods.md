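# Methods

This note documents the models and conventions behind `circascreen`: what
is computed, which choices were open and how they were settled, and what
the synthetic-data tests do and do not establish about real recordings.

## Time base and canonical grid

All analysis runs in zeitgeber time (ZT, hours since lights-on; lights-off
at ZT12 under 12:12 LD). Recordings in the supported phenotyping pipelines
start five hours before lights-off and end a few hours after the next
lights-on, so the canonical grid is the 25 hourly bins **ZT6…ZT30**; clock
hours before ZT6 are interpreted as the following morning and shifted by
+24 h. Samples are assigned to the bin `[k, k+1)` and averaged within it.
A profile needs ≥12 observed canonical bins to proceed (recordings are
specified as ≥21 h, so this only drops seriously truncated traces).

## QC rules

Three removal rules run in a fixed order; the profile maximum `y_max` used
by a rule is computed after earlier removals (the rules are worded
sequentially and the out-of-range rule exists precisely to stop artefact
spikes from inflating `y_max`):

1. **Out of range** — food intake > 0.65 g/hr at any hour; activity
   > 4000 counts/hr during the light phase (ZT mod 24 in [0, 12); "daytime"
   is taken as the lights-on half of the cycle). Comparisons are strict.
2. **ZT12 transient** — the lights-off bin is removed iff it is a strict
   local maximum, exceeds (4/5)·`y_max`, and no other local maximum lies
   strictly inside (ZT12, ZT17). Local maxima are evaluated on the
   sequence of observed values (missing bins skipped), interior points
   only, strict inequality (ties never qualify).
3. **Pulse break-up** — a point is removed iff
   `min(|y_τ − y_{τ−1}|, |y_τ − y_{τ+1}|) ≥ 0.57·y_max`, endpoints using
   their single neighbour ("reaches" → inclusive ≥). All candidates are
   evaluated on the series as it enters the rule; removals do not cascade
   within the pass.

**Caveat — QC is not exactly idempotent.** The ZT12 and pulse thresholds
are fractions of `y_max`; if a pass removes the profile maximum, a second
pass would see a lower threshold and could remove further points. In
simulation this affects <1% of realistic curves. The pipeline runs the
pass once, as specified; re-running QC on cleaned output is neither needed
nor recommended.

Removed and missing bins are linearly interpolated between the nearest
observed neighbours (edge bins take the nearest observed value) so the
regressor always receives a complete 25-vector, then each curve is min-max
scaled to [0, 1]. How removed points should be refilled is not prescribed
anywhere; linear interpolation is this package's choice and is recorded in
each run's QC report so the raw values remain recoverable. A constant
curve has no usable range and is rejected rather than silently scaled.

## Generative rhythm model

One **template** per centre × modality holds the standard parameters:

* transition (t ∈ [t1, t3]): `dx/dt = ε(F − x)` with
  `F(t) = ramp(u·h1 → u·h2)` on [t1, t2] and `F = u·h3` on (t2, t3];
  `u = 1.1`, `x(t1) = h1`. Integration is classical fixed-step RK4 with
  dt = 0.05 h (global error ~(ε·dt)⁴, verified against the closed-form
  exponential);
* remainder (t > t3): baseline `a4` plus three Gaussian bumps — evening
  peak (centre t3), late-night/morning peak (centre ≈ ZT22), and a small
  early bump near the recording start. The three printed offsets would
  triple-count the baseline if the components were summed naively, so the
  curve is assembled as `a4 + Σ amplitude·exp(−(t−c)²/2w²)` with
  `a8 = a12 = a4`.

Continuity at t3 between the two segments is not enforced; the sampling
construction ties them through `a1 = max(y1) − y1(t1)` and `a4 = y1(t1)`,
which keeps the mismatch small in practice.

### Template fitting

`fit_template` reads the heights off the mean wild-type curve (`h1`, `h2`,
`h3` at t1, onset−1, peak), fits ε by bounded scalar least squares on the
transition samples, then fits the Gaussian remainder by bounded
least-squares with the evening-peak amplitude and phase pinned to the data
(amplitude = range of the transition segment, phase = the peak hint).
Peak-phase initial values come from local maxima that exceed their four
surrounding points; widths are initialized at 2 h and bounded in (0, 4];
the food-intake baseline is bounded in [0, 0.15] g/hr (activity: [0, max]).
When the mean curve has no early-morning local maximum, the third-peak
measured value `m3` is zero and its amplitude is pinned at 0.

### Built-in template

No raw centre data ship with the package, so `canonical_template` provides
a wild-type-like standard: t1 = 6, t2 = 11, t3 = 13; activity ε = 0.8/h,
peak ≈ 2600 counts/hr over a ≈1000 counts/hr light-phase level; food
intake ε = 0.7/h, peak ≈ 0.32 g/hr; morning peak at ZT22. Heights are
made self-consistent with the ODE by a damped fixed point (the curve value
at t2/t3 equals the height driving the switch) so that refitting the
template to its own noiseless curve is exact; this requires
`1 − u(1 − e^{−εΔt}) > 0`, which bounds ε below ≈1.2/h for the 2 h
onset-to-peak interval — one reason the defaults use gentler relaxation
than the fitting bound allows.

### Randomized draws

Each training curve draws (all uniform, as specified): `t2 ~ U(9, 13)`;
`Δt = t3 − t2 ~ U(0, 3)` **resampled until ≥ 1 h** — the raw support
admits Δt < 1, which would put the onset label after the peak label;
`h3 = U(0.5, 1.5)·h3*`; `h2 = U(0.2, 0.9)·h3`; `h1 = h2/U(1, 1.2)`;
`ε = U(0.8, 1.2)·ε*`. Gaussian parameters: evening width =
max{U(0, 3)·(t3 − t_mid), U(2, 3)} where t_mid is the half-rise time of
the transition; second-peak amplitude `U(0.8, 1.2)·a1`, width
`U(0.8, 1.2)·a6*`, phase `a7* + U(−1, 2)`; third-bump amplitude
`max(0, U(0.5, 1.5)·(a4 + a1) − a4)` (the printed expression can go
negative; amplitudes are clamped at zero), width `U(0.8, 1.2)·a10*`,
centre `t1 + U(0, 1)` (an early bump near the recording start, taken at
face value — on the ZT6…ZT30 grid it contributes mostly tails). White
noise s.d. defaults to 0.05 × the curve maximum; the original noise scale
is not recoverable, and 5% of peak is typical of hourly IC binning.
Labels: onset = t2 + 1 (first point inside the transition on an hourly
grid), peak = t3.

The generator emulates: bimodal shape with a dominant evening peak,
chronotype variation through phase/height/width randomization, and white
measurement error. It does **not** emulate: missing bins or artefact
spikes (QC is tested separately), day-to-day variability within a mouse,
ultradian bouts, sex or husbandry effects, or inter-centre equipment
differences beyond the template parameters. Tests passing on synthetic
curves therefore establish that the estimator recovers the generative
model's own labels, not that those labels are unbiased for any real
mouse.

## Phase regressor

A numpy CNN: three valid 1-D convolutions (16/32/64 filters, kernels
6/4/4, stride 1, ReLU; lengths 25→20→17→14) followed by two 1×2 max-pools
(14→7→3), two 1024-unit ReLU layers (dropout keep 0.5 on the first) and a
2-unit linear head predicting hours directly, clipped to [6, 30]. The
layer order (all convolutions before both pools) is the only arrangement
consistent with the tabulated per-layer neuron counts. Loss is the mean
absolute deviation (the printed loss omits an absolute value and would be
a signed mean); optimizer Adam at 1e-4. Training defaults: batch 128,
90/10 split, early stopping on validation MAE with patience 10, output
bias initialized at the training-label mean (with sign-based MAE gradients
and a 1e-4 step, starting the head a dozen hours off would waste most of
the budget). Backprop is verified against central differences in the test
suite; with fixed seeds on one thread, training is bitwise reproducible.

One model is trained per template (centre × modality). Prediction
invariance to per-curve affine scaling is supplied by the upstream min-max
normalization, not by the network, and is asserted at pipeline level.

Problem sizes used by the tests: 20 000 training + 2 000 held-out curves,
15 epochs (~1–2 min on one CPU core). Held-out accuracy: onset MAE
≈ 0.25 h, peak MAE ≈ 0.27 h, both well inside the 1 h grid resolution;
onset error s.d. is marginally smaller than peak error s.d.

## Screening statistics

* Deviation of a line = phase estimate of its **averaged** curve minus the
  wild-type per-mouse mean of the same centre × modality.
* Primary outlier: |deviation − mean(deviations)| > 2 × sample s.d. of the
  deviations across the centre's lines, per parameter (onset/peak ×
  modality). Under a normal null this flags the ≈4.6% two-sided tail
  ("approximately 5%").
* Cohen's d uses the pooled s.d. with n_m + n_wt − 2 degrees of freedom;
  the t-test is the matching pooled-variance Student test (not Welch),
  two-sided. No multiple-testing correction is applied — the design uses
  fixed thresholds (d > 1.2, p < 0.001).
* Concordance: fraction of a line's mice deviating from the baseline mean
  in the line's direction by ≥1 baseline s.d. The margin is this package's
  convention; "similar phenotype" has no printed definition.
* Secondary hit ⇔ primary outlier ∧ concordance ≥ 0.5 ∧ d > 1.2 ∧
  p < 0.001.
* Bland–Altman: bias = mean paired difference; limits = bias ± 1.96 s.d.
  (sample s.d., ddof = 1); coverage is the inclusive fraction inside the
  limits.

Degenerate inputs: zero pooled s.d. with equal means gives d = 0 and
p = 1; with unequal means d = ∞ and p = 0. A zero-spread deviation set
flags nothing (tolerance 1e-12 relative, to absorb float fuzz).

## Fixture cohorts

`make_fixture` emulates a positive-control screen: mice of one genotype
share the line's transition phase (t2 = 11 + shift + N(0, 0.3 h)) and
onset-to-peak interval (2 ± 0.2 h) while amplitude/shape parameters vary
freely per mouse. A −3 h onset line among 11 null lines is recovered as
the sole secondary hit; note that a 3 h advance lies outside the training
label support (onsets 10–14), so the regressor saturates near the support
edge and the measured deviation (−2.2 h) understates the injected shift —
detection is unaffected, magnitude estimation near the support boundary
is not trustworthy.

## Known limitations

* Estimates are only defined on the ZT6…ZT30 window; phases outside the
  training-label support are clipped/saturated rather than extrapolated.
* The ZT12 rule can delete a genuine evening peak that happens to sit
  exactly at lights-off with no competitor in (12, 17); this is inherent
  to the rule as defined.
* Free-running period analysis, re-entrainment kinetics and rhythmicity
  tests (e.g. JTK_CYCLE) are out of scope; only the two phase parameters
  are screened.
* Food-intake tables are assumed to hold per-bin (not cumulative) values.
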