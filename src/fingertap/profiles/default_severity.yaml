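# Default severity profile for the synthetic tapping generator.
#
# Each class block maps the clinical rating bands onto generator parameters:
# amplitude (palm units) and tap rate (Hz) fall with severity; halts
# (interruptions) and decrement onset (bp_frac = breakpoint as a fraction of
# the tap count; slope2 = incremental per-tap amplitude change beyond it)
# worsen with severity.  Ranges [low, high] are sampled uniformly; amplitude
# and rate are Gaussian.  Values are editable; ordering constraints
# (amplitude/rate non-increasing, halts non-decreasing with class) are
# validated at load time.

duration: 10.0        # seconds per recording
fps: 60.0             # camera frame rate
tremor_freq: 5.0      # Hz, typical parkinsonian rest tremor band (4-6 Hz)
age_range: [45, 85]

classes:
  "0":                       # normal: wide, fast, regular tapping
    amplitude: {mean: 1.40, sd: 0.10}
    rate: {mean: 3.0, sd: 0.25}
    slope1: [-0.004, 0.0]
    slope2: [-0.001, 0.0]    # effectively no decrement
    bp_frac: [0.6, 0.9]
    n_halts: [0, 0]
    halt_depth: [0.0, 0.0]
    tremor_amp: [0.0, 0.01]
    noise_sd: [0.005, 0.015]
  "1":                       # slight: 1-2 interruptions / slight slowing /
    amplitude: {mean: 1.15, sd: 0.10}   # decrement near the end
    rate: {mean: 2.5, sd: 0.20}
    slope1: [-0.008, 0.0]
    slope2: [-0.035, -0.02]
    bp_frac: [0.70, 0.85]
    n_halts: [0, 2]
    halt_depth: [0.30, 0.50]
    tremor_amp: [0.0, 0.02]
    noise_sd: [0.010, 0.020]
  "2":                       # mild: 3-5 interruptions / mild slowing /
    amplitude: {mean: 0.85, sd: 0.08}   # decrement midway
    rate: {mean: 2.0, sd: 0.20}
    slope1: [-0.008, 0.0]
    slope2: [-0.050, -0.030]
    bp_frac: [0.40, 0.60]
    n_halts: [3, 5]
    halt_depth: [0.35, 0.60]
    tremor_amp: [0.005, 0.03]
    noise_sd: [0.010, 0.025]
  "3":                       # moderate: >5 interruptions / moderate slowing /
    amplitude: {mean: 0.55, sd: 0.07}   # decrement right after the first tap
    rate: {mean: 1.4, sd: 0.15}
    slope1: [-0.006, 0.0]
    slope2: [-0.040, -0.020]
    bp_frac: [0.05, 0.15]
    n_halts: [6, 9]
    halt_depth: [0.40, 0.65]
    tremor_amp: [0.01, 0.04]
    noise_sd: [0.015, 0.030]
  "4":                       # severe: can barely perform the task
    amplitude: {mean: 0.22, sd: 0.04}
    rate: {mean: 0.8, sd: 0.10}
    slope1: [-0.006, 0.0]
    slope2: [-0.020, -0.005]
    bp_frac: [0.2, 0.6]
    n_halts: [2, 4]
    halt_depth: [0.40, 0.70]
    tremor_amp: [0.01, 0.05]
    noise_sd: [0.020, 0.040]
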