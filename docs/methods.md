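# Methods

## Scientific background

Large, high-contrast drifting gratings induce narrow-band gamma oscillations
(~30–90 Hz) in human visual cortex that MEG records reliably. The induced
gamma response (GR) depends non-linearly on stimulation intensity: its power
rises from a static grating to slow drift (~1.2 °/s) and then attenuates as
drift velocity grows, while its peak frequency increases roughly linearly with
velocity. The degree of velocity-related attenuation is interpreted as a
readout of inhibitory gain control in the visual circuit, and it covaries with
self-reported sensory sensitivity. This package implements the analysis chain
that extracts two per-subject indices from source-space epochs —

* **GSS (Gamma Suppression Slope)** — each moving condition's weighted GR
  power is divided by the 'slow' condition's power and shifted so the slow
  condition maps to zero, `y_v = GR_v / GR_slow − 1`; GSS is the
  least-squares slope of `y` on velocity with the intercept forced through
  the origin, `GSS = Σ v·y_v / Σ v²` over v ∈ {1.2, 3.6, 6.0} °/s. More
  negative GSS ⇔ stronger attenuation.
* **GEI (Gamma Enhancement Index)** — `(GR_slow − GR_static) / GR_slow`,
  the ascending-branch change from static to slow drift.

— and correlates them across subjects with sensitivity scores by Spearman
rank correlation.

## Analysis pipeline

Per subject, visit and condition (static / 1.2 / 3.6 / 6.0 °/s):

1. **Window power** (`spectral`). Epochs span −1.0…1.2 s at 500 Hz. One DPSS
   multitaper power spectrum is computed per trial and vertex for the baseline
   (−0.9, 0) s and stimulation (0.3, 1.2) s windows (half-open intervals,
   sample index `round(t·sfreq)`). Full bandwidth 10 Hz over a 0.9 s window
   gives time-half-bandwidth 4.5 and 2·4.5 − 1 = 8 unit-energy tapers,
   averaged uniformly; the rfft grid yields ~1.11 Hz bins. Only
   window-averaged power feeds every downstream statistic, so one PSD per
   window replaces a sliding spectrogram with an identical contract. The
   one-sided PSD scaling is chosen so integrated power equals windowed
   variance (checked to 10 % on stationary noise).
2. **Normalization**. Per vertex and bin, `(stim − base)/base` on
   trial-averaged power. Amplitude gain cancels exactly; swapping the windows
   maps `x` to `1/(1+x) − 1`.
3. **Vertex selection and averaging** (`response`). The 26 vertices (or all,
   if fewer exist) with the largest mean normalized power over 40–80 Hz are
   selected (ties by ascending index), their spectra averaged over
   30–115 Hz, and smoothed with a centered 3-bin moving average whose edge
   bins shrink to the available window (constants are preserved).
4. **Weighted GR metrics**. Within 35–90 Hz, the peak bin is located; the
   weighted GR power is the mean of the bins strictly exceeding 2/3 of the
   peak and the weighted GR frequency is their power-weighted center of
   gravity. A non-positive peak means no detectable response; the condition
   is marked unusable (NaN metrics, not reliable).
5. **Reliability gate**. A two-sided Wilcoxon signed-rank test compares
   single-trial baseline vs stimulation power at the peak bin (averaged over
   the selected vertices). The paired (signed-rank) form is used because both
   windows come from the same trial; zero differences are dropped; the null
   is exact up to n = 50 pairs without ties and a normal approximation with
   continuity correction above. A subject is included iff the condition with
   maximal weighted power is reliable (p < 10⁻⁴) in **both** visits; the
   maximal condition is determined per visit and may differ between them.
6. **Indices and cohort stage** (`indices`, `cohort`). GSS/GEI per visit,
   averaged over visits; Spearman correlations (mid-ranks on ties; exact
   permutation p for n ≤ 9 by full enumeration, t-approximation with n − 2 df
   above) against sensitivity scores and covariates, reported uncorrected
   with n so users may apply their own multiplicity control.

### Anticonservatism of the peak-selected reliability test

The gate tests the bin at the *empirical* maximum of the normalized spectrum.
Under the null (no response) this selection inflates the nominal level
substantially (~29 % rejections at α = 0.05 on no-signal simulations) — which
is precisely why the gate threshold is the stringent 10⁻⁴. The Wilcoxon test
itself is well calibrated: evaluated at a fixed a-priori bin (55 Hz, the
population mean gamma frequency) on no-signal epochs its type-I rate at
α = 0.05 is ~0.05, and that is the calibration property the test suite
verifies.

## Synthetic cohort generator (`synth`)

Per trial and vertex the simulated source signal is

    x(t) = pink(t) + g_vertex · A(v) · env(t) · cos(2π f(v) t + φ_trial)

* **Background**: unit-variance 1/f^`pink_exponent` noise (default exponent
  1), independent across vertices and trials, generated by spectral shaping
  of white noise.
* **Gamma component**: frequency `f(v) = f0 + gamma_slope·v`; amplitude
  `A(v) = √2 · snr · r(v)/r(v_slow)` with the bell-shaped velocity curve
  `r(v) = (1 + α v)·e^(−β v)`, so `snr` is the gamma-to-background RMS ratio
  in the slow condition at a unit-gain vertex. The phase φ is uniform per
  trial, making the response induced (it survives in power, cancels in the
  average waveform). The envelope is zero before onset and reaches 1 by
  0.3 s through a raised-cosine ramp, so the stimulation analysis window sees
  a stationary response; baseline statistics are independent of velocity.
* **Curve family**: `r(v) = (1 + αv)e^(−βv)` factorizes enhancement (α, the
  ascending branch GEI probes) and attenuation (β, the descending branch GSS
  probes); `r(0) = 1` always and for α > β > 0 the interior maximum sits at
  `v* = 1/β − 1/α`. Normalized GR power is proportional to `r(v)²`.
* **Spatial profile**: fixed per subject across visits; log-normal gains
  with a clearly elevated subset (min(26, n_vertices/2) vertices) so the
  top-26 selection stage is exercised non-trivially.
* **Sensitivity score**: β is a monotone quantile transform of a standard
  normal latent; the score shares that latent through a Gaussian copula with
  Pearson loading `2·sin(π·ρ_s/6)`, making the population Spearman
  correlation between β and the score equal `rho_sens` *exactly* (default
  −0.4: stronger attenuation ⇔ lower reported sensitivity, i.e. a positive
  GSS–sensitivity correlation). Where the designed quantity is instead the
  Spearman correlation between the *derived* GSS and the score, no closed
  form exists and `calibrate_rho_sens` solves for the required loading by
  Monte-Carlo bisection on the theoretical curves.
* **Seeding**: every stochastic stage draws from a `SeedSequence` keyed by
  (seed, stream, subject, visit) counters, so runs are bit-reproducible and
  changing the cohort size never reshuffles existing subjects.

### Default parameters

| parameter | default | why |
|---|---|---|
| n_subjects / n_trials / n_visits | 27 / 90 / 2 | cohort geometry of the emulated experiment |
| n_vertices | 64 | enough to make top-26 selection meaningful |
| sfreq, epoch | 500 Hz, −1.0…1.2 s | acquisition geometry |
| velocities | 0, 1.2, 3.6, 6.0 °/s | the four grating conditions |
| α ~ N(1.1, 0.2), β ~ N(0.5, 0.09) | truncated ≥ 0.05 | calibrated once by Monte-Carlo grid search so the *theoretical* curves reproduce the qualitative cohort facts: ~97 % of subjects slow > static, ~92 % maximal at 'slow', ~3 % maximal at static, ~2 % at medium |
| f0 ~ N(55, 5) Hz, slope ~ N(2.5, 0.3) Hz/(°/s) | truncated 40–80 | keeps f(v) inside the 35–90 Hz analysis band at all velocities |
| snr ~ N(0.6, 0.15) | ≥ 0 | yields normalized weighted GR powers of order 1–5, matching the magnitudes the analysis is designed for |
| pink_exponent | 1.0 (fixed) | canonical 1/f neural background |
| rho_sens | −0.4 | designed trait–score coupling |

## What the simulator does and does not emulate

It reproduces the features the analysis depends on: 1/f background, an
induced narrow-band gamma component with bell-shaped velocity tuning and
linear frequency scaling, a sparse spatial gain profile, two visits, and a
latent trait coupled to a noisy questionnaire-like score. It does **not**
model sensor-level physics (forward/inverse modelling, beamformer leakage,
vertex-to-vertex correlation), physiological artifacts (eye movements,
heartbeat, myogenic bursts), trial-to-trial amplitude dynamics, or visit
effects beyond independent noise. Passing tests therefore demonstrate that
the *analysis chain* is correct and recovers known ground truth under this
signal model — not that the pipeline is robust to real-data artifacts, which
the emulated experiment removes upstream.

## Numerical and design choices

* "Exceeds 2/3 of the peak" is a strict inequality; a ≥ rule differs only on
  exact ties (measure zero on real data). Fixed for reproducibility.
* Moving-average edges use the shrinking window; the alternative (dropping
  edge bins) would shorten the analyzed band by one bin at each end.
* The GSS regression variable is the slow-normalized ratio **minus one**:
  regressing the raw ratio through the origin would force a positive slope
  even under attenuation, contradicting the index's sign semantics (more
  negative ⇔ stronger attenuation). Any affine variant changes values, not
  subject rankings, and all downstream statistics are rank-based.
* The static condition enters GEI only; GSS is defined on the moving
  conditions.
* Spearman p-values at n = 27 use the t-approximation; exactness below
  n = 10 by full permutation enumeration.
* Degenerate inputs raise typed errors (`ConfigError`,
  `DegenerateDataError`, `NoResponseError`) rather than propagating NaN,
  except that an absent spectral peak is recorded as an unusable condition so
  cohort processing can continue.

## Problem sizes used in the automated checks

Simulation-backed checks are scaled to run on one CPU in minutes, chosen as
the package's own test geometry: null calibration uses 2 vertices (2000
condition-visits × 90 trials); velocity-tuning proportions use 27 subjects ×
90 trials at 8 vertices and one visit (20 seeds); trait recovery uses 100
subjects at the same geometry; end-to-end correlation recovery uses 20 trials
× 4 vertices (n = 5000, plus 200 cohorts of 27). At these sizes the estimated
GSS still rank-correlates with the true attenuation coefficient at
|ρ| ≈ 0.96, so the reductions do not mask the effects being tested.

## Known limitations

* Vertex signals are independent; real beamformer outputs are spatially
  correlated, so the effective number of independent vertices is lower in
  real data.
* The reliability gate's composite procedure (argmax bin + paired test) has
  no closed-form null; its stringent threshold is inherited, not re-derived.
* `snr` and the velocity-curve parameter distributions are calibrated to
  qualitative cohort facts, not fitted to any recording.
* Bring-your-own-data mode expects the documented HDF5 layout; vendor MEG
  formats are out of scope.
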