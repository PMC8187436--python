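# Example pipeline configuration (all values shown are the defaults).
# Any key may be omitted; unknown keys are rejected.
cohort:
  n_subjects: 27
  n_trials: 90           # per condition
  n_vertices: 64
  n_visits: 2
  sfreq: 500.0           # Hz
  t_start: -1.0          # epoch window (s, relative to stimulus onset)
  t_end: 1.2
  velocities: [0.0, 1.2, 3.6, 6.0]   # deg/s; first entry must be 0 (static)
  rho_sens: -0.4         # population Spearman(beta, sens_score)
  seed: 0
  # subject-parameter distributions: truncated normals
  alpha: {mean: 1.1, sd: 0.2, lower: 0.05, upper: 3.0}    # enhancement, per deg/s
  beta: {mean: 0.5, sd: 0.09, lower: 0.05, upper: 1.5}    # attenuation, per deg/s
  f0: {mean: 55.0, sd: 5.0, lower: 40.0, upper: 80.0}     # gamma frequency at v=0, Hz
  gamma_slope: {mean: 2.5, sd: 0.3, lower: 0.5, upper: 5.0}  # Hz per deg/s
  snr: {mean: 0.6, sd: 0.15, lower: 0.0, upper: 5.0}      # gamma/background RMS, slow condition
  pink_exponent: {mean: 1.0, sd: 0.0, lower: 0.5, upper: 2.0}
  age: {mean: 27.6, sd: 6.0, lower: 18.0, upper: 40.0}    # years
  sens_mean: 37.7
  sens_sd: 6.5
analysis:
  baseline: [-0.9, 0.0]      # s
  stimulation: [0.3, 1.2]    # s
  bandwidth: 10.0            # Hz (full multitaper bandwidth)
  vertex_band: [40.0, 80.0]  # Hz, vertex-selection band
  n_select: 26               # vertices kept
  gamma_range: [30.0, 115.0] # Hz, averaging/smoothing range
  peak_band: [35.0, 90.0]    # Hz, weighted-GR peak search band
  smooth_window: 3           # bins, centered moving average
  reliability_alpha: 1.0e-4
pairs:
  - [gss, sens_score]
  - [gei, sens_score]
  - [gss, age]
  - [gei, age]
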