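# Methods

This note documents the models, numerical choices and limitations behind
`fingertap`. It is the package's own account; every number quoted here is
recomputed by the test suite or `scripts/acceptance.py`.

## Signal model and preprocessing

The unit of analysis is a palm-normalized thumb–index distance signal
sampled at the camera frame rate. Normalization by the wrist-to-middle-MCP
distance makes the signal dimensionless ("palm units"); all downstream
features are therefore invariant to uniform rescaling of the input
coordinates (hand size, camera distance, metric vs normalized pose
coordinates), which the acceptance checks verify to ~1e-6 relative.

**Dropouts.** Frames where the pose estimator failed (non-finite
coordinates) are flagged, never dropped; gaps up to 0.5 s are filled by
linear interpolation, longer gaps reject the recording — the automated
analogue of the manual quality exclusion applied to clinical video. Palm
sizes below 1e-6 of the recording's median (folded or lost hands) are
treated the same way per-frame.

**EMD.** Empirical Mode Decomposition uses classic sifting with
cubic-spline envelopes. Two implementation details matter:

* *Boundaries.* Envelope knots are the interior extrema, mirrored across
  both signal ends (two knots per side); an end sample lying outside the
  nearest extremum becomes a knot itself so a running trend is not
  undershot.
* *Stopping.* Sifting stops by the Rilling envelope-ratio criterion
  (|envelope mean| / envelope amplitude < 0.05 on 95% of samples and < 0.5
  everywhere) combined with the IMF property that extrema and zero-crossing
  counts differ by at most one. The more common Cauchy SD criterion is
  unsuitable here: the distance signal is non-negative, and its large DC
  offset inflates the SD denominator so sifting halts after a single pass
  with heavily mixed modes.

The residual is defined as `input − sum(IMFs)`, so the reconstruction
identity holds to rounding error on every input by construction; the
acceptance check measures ≤ 1e-15 relative on 50 signal families.

**Mode selection.** The tapping oscillation is carried by the first three
(highest-frequency) IMFs; they are retained by default. The slow residual
is *excluded* except for its median, which recentres the oscillation on a
flat baseline — slow drift (camera motion, posture) is thereby discarded,
at the cost of flattening part of a genuine amplitude decrement. The
alternative, `keep_residual=True`, adds the residual back wholesale and
preserves envelope decrement exactly; the generator-closure tests use it.
Both behaviours are config flags because either reading of "keep the first
three IMFs" is defensible; classification results on the synthetic grid are
insensitive to the choice.

**Smoothing.** A second-order Savitzky–Golay filter with a 0.25 s window
(forced odd, ≥ 5 samples). Local polynomial regression preserves peak
amplitudes far better than a moving average of the same bandwidth, which
matters because every kinematic feature is a function of the peak
amplitudes. Residual attenuation is still measurable: at a 3 Hz tap rate
and 60 fps the detected peak amplitudes sit ≈ 4% below truth. This is a
bias, not noise — it is common to all recordings processed with the same
settings and does not reorder severity classes.

**Peak detection** uses prominence ≥ 10% of the cleaned signal's range and
minimum separation 0.1 s (tapping above 10 Hz is physiologically
implausible). Zero detected peaks marks the recording unusable rather than
returning an empty result.

## Features

The 15-feature vector follows a fixed canonical order (age, sex, amplitude
variance/mean/breakpoint/slope1/slope2, velocity
variance/mean/breakpoint/slope1/slope2, frequency, halt count, peak count).
Notable definitions:

* **Variances are population (1/N)** quantities, matching the defining
  formulas of the feature set.
* **Broken-stick trend.** The two-segment continuous model is fitted by its
  definition: exhaustive search of the breakpoint over interior peak
  ordinals with an OLS fit of `[1, x, (x − bp)+]` per candidate; smallest
  RSS wins, earliest breakpoint on ties (determinism). The abscissa is the
  peak ordinal, not wall time, because the clinical criteria grade
  decrement by *where in the tap sequence* it starts ("midway in the 10-tap
  sequence"). With fewer than 4 points the fit degrades to a single line
  and is flagged.
* **Halt/hesitation count.** An interior peak is counted when its amplitude
  falls *below* the fitted amplitude trend by at least
  θ = α·(A_{n−1}+A_{n+1})/2 with α = 0.2. Only downward deviations count —
  an upward outlier is not a clinical halt. The trend is the all-peaks fit
  by default; a leave-one-out variant exists for sensitivity analysis. The
  count subsumes the binary halt indicator. The threshold scales with the
  neighbour amplitudes, so the count is invariant to uniform amplitude
  rescaling.
* **Frequency** is (N−1)/(t_N−t_1), insensitive to idle recording before
  and after the task. A single-peak recording has no frequency; 0 is
  reported with a flag.
* **Velocity** V_n = (A_n + A_{n−1})/Δt_n is a per-cycle average speed
  (close + re-open distance over the cycle interval), in palm units/s.

## Classifiers

**Decision tree.** A self-contained CART: Gini impurity, thresholds at
midpoints between consecutive distinct values, features scanned in
canonical order with strict-improvement updates, so ties resolve to the
lowest feature index and threshold and training is reproducible to the
byte. Zero-gain splits are allowed (XOR-like structure pays off deeper
down). Defaults: depth ≤ 5, ≥ 2 samples per leaf — shallow enough that the
printed tree remains clinically auditable. The model serializes to nested
JSON with feature names and thresholds; a serialized-and-reloaded model
predicts identically. All 15 features are retained even though frequency
and mean velocity are strongly correlated; the tree simply never splits on
a redundant copy.

**Rule-based baseline (`baseline_sp`).** A literal cascade of the rating
bands, worst triggered criterion wins: interruptions 1–2 → ≥1, 3–5 → ≥2,
>5 → ≥3; amplitude decrement (incremental slope < −0.005 palm units/tap)
with onset in the last third → ≥1, middle third → ≥2, after the first tap
(bp ≤ 2) → ≥3; slowing by mean velocity below 6.5 / 3.9 / 1.6 palm
units/s → ≥1/≥2/≥3; fewer than 4 taps or mean amplitude below 0.15 → 4.
The rating scale names no numbers for "slight/mild/moderate slowing", so
the velocity cutoffs are calibrated once as the midpoints between adjacent
class means of the default synthetic severity grid and kept in an editable
config. A literal reading of the scale is deliberately strict near class
boundaries; the rules are not softened.

## Synthetic data

The generator emulates the *kinematics* the rating criteria describe, not
the videos: raised-cosine open/close cycles (smooth, so EMD sees no
corner-induced spurious modes) at a constant within-recording rate, cycle
maxima following the same broken-stick envelope family the features
estimate, optional per-tap halt suppression, a 4–6 Hz tremor sinusoid, and
Gaussian measurement noise, clipped at zero because distances are
non-negative. The pose embedding keeps the palm static and moves the index
tip along a line, so palm normalization recovers the constructed signal
exactly.

The default severity profile (editable YAML) maps the clinical bands onto
parameters: class means of base amplitude 1.4/1.15/0.85/0.55/0.22 palm
units and tap rate 3.0/2.5/2.0/1.4/0.8 Hz for classes 0–4, halt counts
rising 0 → 6–9, decrement onset moving from "near the end" (breakpoint at
70–85% of taps) through "midway" (40–60%) to "right after the first tap"
(5–15%), and noise 0.5–4% of amplitude. Recordings are 10 s at 60 fps —
long enough for ≥ 8 taps even at severe slowing. Amplitude and rate were
chosen to be distinct but adjacent-overlapping (SDs ≈ 0.04–0.1), i.e. a
plausible idealization of the clinical separation rather than a trivially
separable toy. Demographics are sampled independently of the label, since
the rating reflects motor performance only.

What the simulator does **not** emulate — and therefore what passing tests
cannot show about real data: pose-estimation artifacts beyond i.i.d. noise
and dropouts (correlated jitter, identity swaps), within-recording rate
drift and arrhythmia, multi-second freezes (a halt here is a single
suppressed cycle), camera perspective effects, and genuinely ambiguous
boundary patients. Held-out accuracies on the grid (t1 ≈ 0.95, t2 = 1.0 at
100 recordings/class) are an internal-consistency result for the pipeline,
not a clinical performance claim.

## Verification design

Correctness is established oracle-first: closed-form examples are asserted
exactly; statistics are compared to loop-based brute-force recomputation
(≤ 1e-12); the broken-stick fitter is checked by inverting its own model
(noiseless recovery exact; at 5% noise the breakpoint lands within ±1
ordinal in ≥ 90% of seeded runs); the metric identities (trace and ±1-band
of the confusion matrix) are asserted on random predictions; and the full
pipeline is closed against the generator's ground truth. End-to-end closure
tolerances are: counts and breakpoints exact, frequency within 2%,
continuous amplitude/velocity features within 5% — the slack is the
Savitzky–Golay attenuation and frame-grid quantization described above, not
estimation noise.

One documented shortfall: at measurement noise of only 1% of the signal,
the EMD + smoothing chain does not reduce full-signal RMSE — the method's
own bias floor (smoothing attenuation, occasional EMD leakage of tap energy
into discarded slow modes) exceeds so small a noise floor. Denoising is
demonstrably beneficial at realistic 5% noise, and is tested there (in the
median over seeded trials). The pipeline's purpose is robust *peak*
recovery, which holds at both noise levels.

## Reproducibility

Preprocessing, feature extraction and tree training are fully
deterministic. All randomness (synthetic sampling, splits) flows through
explicitly passed seeds; `generate_dataset` and the CLI commands are
byte-reproducible given (config, seed). Problem sizes in the acceptance
script (50 EMD signals, 100 fits/constructions, 1000 metric pairs, 100
recordings per class) were chosen to make the stochastic rates stable to a
few percent while keeping a full run around a minute.
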