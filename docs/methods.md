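# Methods

## The census model

The package treats an emerging bat stream as a set of roughly
equal-strength, independently timed sound sources at a common range. Under
those assumptions acoustic power at the microphone is proportional to the
number of bats in view, so the received level obeys

    L(N) = 10·log10(N) + c        [dB re full scale]

and the calibration regression `log10(N) = a + b·L` has theoretical slope
`b = 1/10` per dB. The method never relies on knowing `c` (microphones are
uncalibrated): an absolute-reference shift moves only the intercept, which
is refit per deployment.

Three clip statistics are exposed. RMS pressure (`20·log10(sd)`) is the
primary feature: it integrates over the whole clip and tracks summed power
most directly. Peak-to-peak level saturates once any single nearby call
dominates the extremes, and total energy is the un-logged power sum; both
are computed for completeness and are strongly correlated with RMS, which
is why the calibration is simple (one predictor), not multiple regression.

Counts below or at 10 bats per frame are excluded before fitting. At low
density bats circle rather than stream, breaking both the equal-range and
the passage-rate assumptions; the filter restricts the model to the regime
it describes.

### Statistical machinery

* Simple regressions are OLS (statsmodels). Counts are log10-transformed
  for the two pressure features; the base is a convention (R², p-values and
  back-transformed predictions are base-invariant, which the tests assert).
  Total-energy fits use raw counts: energy is already on a linear power
  scale.
* Slope homogeneity across caves (or days) is the classical ANCOVA
  interaction test: full model with per-group slopes and intercepts versus
  reduced model with a common slope, compared by an F-test. For this
  single comparison the sums-of-squares typology is irrelevant — the
  full-vs-reduced F-test is unambiguous.
* Cross-validation applies one group's fitted line to the other group's
  feature values. The headline score is the squared Pearson correlation
  between predicted and observed transformed counts, which is bounded in
  [0, 1] and coincides with R² when a model is scored on its own training
  data. The test-set `1 − SSE/SST`, which can go negative when an intercept
  transfers badly, is exposed as a secondary field.
* Census means are compared by two-sided paired t-tests with Bonferroni
  adjustment, `min(1, p·m)`. For the packaged reference table `m = 4`: two
  model-vs-video comparisons per cave, two caves. That divisor reproduces
  the table's printed adjusted p-values (0.737, 0.289, 1.00, 1.00) exactly,
  which is how it was confirmed. Missing cells (day 1 at the South cave)
  are dropped pairwise for tests and casewise for means; standard errors
  use the n−1 standard deviation, which reproduces every printed s.e. to
  the printed digit (one cell, 7823, is a truncation of the computed
  7823.6).

### From counts to a population

TSBC is the plain sum of per-frame counts over sampled frames — no
correction factors, matching how the reference table is built. The
extrapolated population is

    total = Σ counts × (clip_duration / crossing_time) × sampling_interval

with defaults crossing_time = 0.7 s (so the factor is 1/0.7 ≈ 1.43; full
precision is used in arithmetic, 1.43 is display rounding) and
sampling_interval = 10 s. Predictions from log fits are back-transformed as
`10^(a + b·L)` with **no** smearing correction: the reference tables apply
none, and adding one would break their reproduction. The estimate covers
whatever part of the emergence passes the low-count filter; extrapolating
into the unobserved sparse phases is out of scope.

## The spot counter

Bats appear as bright spots; counting them is local-maximum detection with
prominence merging, the behaviour of ImageJ's "Find Maxima":

1. candidates are pixels ≥ all 8-neighbours; an equal-valued plateau
   contributes its lexicographically smallest coordinate (adjacent
   candidates are necessarily equal-valued, so plateaus are connected
   components of the candidate mask);
2. in decreasing intensity order, each candidate region-grows over
   8-connected pixels strictly above `value − noise_tolerance`; touching a
   region claimed by an already-accepted (brighter) maximum merges the
   candidate away, otherwise it is accepted and claims its region.

Flat frames have no maxima (count 0). Edge pixels may be maxima; there is
deliberately no edge-exclusion or secondary intensity threshold — one
parameter, one behaviour.

The implementation adds one optimisation: pixels visited by a *merged*
candidate are marked as claimed by the maximum it merged into. This never
changes the result — a merged candidate's visited set lies entirely above
its own threshold, hence above the threshold of every later (dimmer)
candidate, and is connected to a genuinely claimed pixel, so any later
region touching it would have reached that claim anyway. It makes the scan
effectively single-pass (each pixel is expanded at most once), which is
what lets the test suite count hundreds of frames per second in pure
Python.

Correctness is pinned by an independent oracle (`tests/oracles.py`) that
decides each candidate from first principles: a candidate of value `v` is
merged exactly when the connected component of `{pixels > v − tol}`
containing it holds a strictly brighter pixel, or an equal-valued candidate
earlier in the deterministic plateau order. The acceptance suite checks
exact agreement on 10 000 random small integer frames.

The noise tolerance is a required analysis setting (the field workflow
does not document a universal value); the synthetic defaults use 30
intensity units against spots of peak 180 over background 10.

## The emergence simulator

The generator produces the joint structure the analysis assumes, with known
ground truth:

* **Arrivals** — inhomogeneous Poisson: rate ramps linearly from onset to
  `peak_rate` at `peak_offset`, then decays exponentially with constant
  `decay_time`. Field emergences peak a few minutes after onset and tail
  off over ~90 min; any smooth unimodal profile would serve, and
  linear-ramp-plus-exponential is the simplest with separate rise and fall
  scales. Sampling is by thinning, and the expected total is the closed-form
  profile integral (tested against realized counts within Poisson error).
* **Acoustics** — each bat in view emits a linear downward FM chirp
  (raised-cosine envelope) every `call.interval`, with a uniformly random
  train phase; incoherence comes from the random timing, as it does in real
  overlapping call trains, rather than from explicit random phase. Each
  call is attenuated by spherical spreading `1/r` for the slant range of
  the bat's position along its transit, referenced to the flight height.
  Atmospheric absorption is omitted: at fixed flight height it is a
  near-constant offset absorbed by the calibration intercept. Summed calls
  plus white ambient noise form the waveform; configurations that would
  clip (|sample| > 1) raise an error rather than silently distorting.
* **Frames** — one radially symmetric Gaussian spot per in-view bat at a
  position consistent with its transit, over a constant background with
  Gaussian pixel noise, quantised to 8-bit integers. Ground truth records
  the exact in-view count per frame and per-bat entry/exit times.

One seeded generator drives everything; a fixed seed reproduces the
recording exactly.

### Scales and defaults

`EmergenceConfig` defaults are field-shaped: 90 min, 250 kHz, density peak
330 s after onset, 0.7 ± 0.1 s crossings, 50→25 kHz calls. The test suite
and validation experiments use `desk_config()`: 120 s at 50 kHz (calls
18→9 kHz to stay under Nyquist), peak 30 s after onset, decay constant
60 s, peak rate 60 bats/s, frames of 96×96 px every 0.5 s. This yields
~3 700 bats and ~200+ retained observations per run — enough to estimate
the calibration slope to a few thousandths — while a full simulation,
spot-counting and calibration cycle takes a few seconds. The acoustic
parameters themselves are sample-rate independent (asserted in the tests),
so the reduced rate changes nothing but runtime. Sampling every rendered
frame (0.5 s) rather than every 10 s is what gives a desk-scale run a
usable calibration sample; the 10-s protocol remains the default for
field-shaped pipelines.

What the simulator does **not** emulate: call harmonics and directionality,
inter-bat variation in source level, Doppler, range spread beyond the
transit geometry, overlapping-spot occlusion beyond simple additive
rendering, and video artefacts (motion blur, rolling shutter). Passing the
validation suite therefore shows the *pipeline* is correct under the
model's assumptions, not that the assumptions hold at a given field site.

## Validation experiments and observed behaviour

* **Slope recovery** — regressing log10(true count) on clip RMS over one
  desk-scale emergence recovers slopes of ~0.082–0.090 per dB across seeds,
  inside the 0.10 ± 0.02 acceptance band. The shortfall from the ideal 0.1
  is regression dilution: the 1-s clip measures mean power over a window
  while the count is instantaneous, and finite call trains add power noise,
  both of which attenuate an errors-in-x slope. Truth counts are used here
  so the check isolates the acoustic law from spot-counting error.
* **Cross-cave transfer** — calibrating on one simulation (peak rate 45)
  and predicting another's video-count TSBC (peak rate 70) gives median
  relative errors of ~6% over 20 seed pairs, well inside the 25% band.
* **ANCOVA size** — under the null of a shared slope the interaction test
  rejects at 4–6% at α = 0.05 over 1000 simulations (nominal 5%).

## Numerical conventions and degenerate inputs

* Standard deviation uses the population (divide-by-n) convention: at
  250 000 samples per clip the n/(n−1) distinction is ~2 × 10⁻⁶ dB, and
  fixing it keeps outputs bit-reproducible.
* Constant clips raise `DegenerateClipError` instead of returning −inf, so
  non-finite features can never reach the regression.
* Integer PCM is rescaled by the format's full-scale magnitude (32768 for
  16-bit), mapping +full-scale just below 1.0; float WAV passes through.
* Clip extraction drops a final partial window; each clip starts exactly at
  its paired frame's timestamp.
* Plateau ties in the maxima detector break lexicographically (smallest
  row, then column) — deterministic across runs and platforms.
* Frames with timestamps outside the recording raise (listing the times);
  frames merely off the sampling grid are skipped as subsampling.
* Sub-seeds in the acceptance script come from `SeedSequence.generate_state`
  reduced below 2³¹.

## Known limitations

* The calibration assumes equal per-bat source power at a common range;
  colonies with mixed species, spread flight heights or vegetation-cluttered
  exits will bend the log-linear law.
* Spot counting saturates when spots overlap at high density, biasing video
  counts low at the emergence peak; the simulator reproduces this and the
  transfer experiment absorbs it, but it is a real bias of frame counting.
* The population extrapolation covers only the filtered (dense) part of the
  emergence and inherits the crossing-time estimate linearly: a ±0.1 s
  error on 0.7 s moves the total by ~14%.
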