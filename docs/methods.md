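# Methods

This note documents the models, parameter choices and numerical decisions
behind `ipidyn`, and what the synthetic experiments do and do not show.

## Signal model and measurement chain

The object of study is a uniformly sampled single-channel EEG-like trace
(100 Hz default; amplitudes in µV). Predictability is measured not on the
waveform but on its **inter-peak intervals (IPI)**: the trace is smoothed
with a unit-sum discrete Gaussian kernel (σ = 1 sample, truncated at 4σ,
half-sample-symmetric reflect padding), every sample strictly greater than
both immediate neighbours is a peak, and consecutive peak indices are
differenced. Intervals are kept in integer sample units (10 ms per sample
at 100 Hz) and converted to milliseconds only for reporting.

Decisions where the procedure was underdetermined:

- **σ is in samples.** At 100 Hz this is a 10 ms kernel scale, enough to
  remove one-sample noise spikes without erasing the ~120 ms peak rhythm.
- **Reflect padding** avoids the edge attenuation of zero padding, which
  would manufacture spurious boundary peaks. The kernel is discretized on
  integer offsets in [−⌈4σ⌉, +⌈4σ⌉] and normalized to unit sum; the
  implementation delegates to `scipy.ndimage.gaussian_filter1d` with an
  explicit radius, which computes exactly this kernel.
- **Strict-inequality plateau rule.** A flat-topped peak yields no index
  rather than an arbitrary one. Exact plateaus have measure zero in noisy
  data; the rule matters only for pathological inputs.
- **No amplitude threshold** is applied to peaks.

## Predictor

A feed-forward network with k = 10 inputs (the 10 previous intervals),
10 tanh hidden units, one linear output. Windowed pairs are tagged
**chronologically** — first 60 % train, next 15 % validation, remaining
~25 % test (train/validation counts rounded down) — because adjacent
windows share 9 of 10 values; a shuffled split would leak test
information. Inputs and targets are z-scored with the mean/SD of the
training portion only (raw interval magnitudes of 10–15 with tanh hidden
units make the Gauss–Newton normal equations needlessly ill-conditioned);
predictions are mapped back to sample units before errors are taken.

Training is full-batch **Levenberg–Marquardt** on the training sum of
squared errors: per epoch, residuals r = y − ŷ and the Jacobian J = ∂ŷ/∂θ
are computed by backpropagation and the step solves (JᵀJ + λI)Δ = Jᵀr.
A step that lowers the training SSE is accepted and λ ← 0.1·λ; otherwise
λ ← 10·λ and the step is re-solved within the same epoch, giving a
monotone accepted-SSE sequence by construction. λ starts at 0.001. Small λ
approaches Gauss–Newton; large λ approaches small-step gradient descent.

Numerical/stopping details:

- Weights initialize uniform in [−0.5, 0.5] scaled by 1/√fan-in, seeded;
  all training is bit-reproducible given the seed.
- A singular normal-equations solve is treated as a rejected step (λ
  escalates). λ > 1e10 without an accepted step aborts the epoch loop.
- Early stopping: 6 consecutive epochs without validation improvement
  (patience), or 1000 epochs. The returned weights are those with the
  best validation error seen, the canonical use of a validation split.
- A non-finite loss raises immediately with the offending epoch and λ.

One network is trained per (subject, state) input; networks are never
shared across conditions.

## Statistics

Signed errors are e = true − predicted on test pairs only. Absolute
errors are transformed as log(|e| + ε), ε = 1e−8; the guard makes the
transform total without affecting continuous-valued predictions. Groups
are compared with **Welch's** two-sample t-test (the error variances
differ visibly between states, so the pooled-variance test's assumption
is not defensible), while **Cohen's d keeps its standard pooled-SD
definition**, signed first-group-minus-second. Skewness is the moment
estimator g1 = m3/m2^1.5 with no small-sample correction (n is in the
thousands per condition). No multiple-testing correction is applied across
the three pairwise state comparisons; the report flags this. Spectra are
Welch periodograms (Hann window, 50 % overlap, segment length
min(4096, N)) of the **raw** trace — smoothing belongs to the peak
measurement, not the spectrum. The alpha band is 7.5–12.5 Hz.

## Synthetic generator

The generator produces exactly the statistical structure the analysis
consumes, with a known ground truth:

- **Intervals**: x_t = 0.5·x_{t−1} + 0.2·x_{t−2} + η_t, interval =
  round(12 + x_t) clipped to [2, 36] samples. Innovations η are a shifted
  lognormal (shape 0.6) standardized to zero mean/unit SD and scaled by
  the state's innovation SD — REM 0.6, AWAKE 1.0, SWS 2.5 samples. The
  AR(2) conditional mean is the optimal one-step predictor, so the
  innovation SD is an analytic floor for achievable test error, and the
  lognormal shape makes interval distributions positively skewed
  (measured sample skewness ≈ 0.85–1.4 at the defaults). The upper clip
  (hit with probability ~1e−4) prevents extreme outlier intervals from
  flattening the rendered waveform so far that a peak stops being a
  resolvable local maximum. A 200-step burn-in removes initial-state
  transients.
- **Waveform**: peaks are placed at cumulative interval positions (plus a
  ⌈mean interval⌉ pad at both ends so the first/last peaks are interior);
  each inter-peak segment is a raised-cosine arc from the left peak down
  to baseline and up to the right peak, so every cycle contributes exactly
  one strict local maximum. Peak heights are N(40, 4²) µV (SWS: mean 75)
  truncated below at 1 µV; white measurement noise is N(0, 2²) µV.
- **SWS slow drift**: the SWS profile adds a 150 µV, 0.05 Hz sinusoidal
  baseline with random phase. Deep-sleep EEG is dominated by
  high-amplitude low-frequency activity, and without such a component the
  arc rhythm (~8.3 Hz at 120 ms intervals) would dominate the spectrum.
  The drift's maximum slope (≈0.47 µV/sample) is kept below the arc
  curvature at every admissible peak (≥0.57 µV/sample² at the 36-sample
  interval cap), so peak *positions* are provably unmoved; with it, >90 %
  of SWS spectral power lies below 3 Hz and the alpha-band fraction is
  ≈0.035.

What the generator does **not** emulate: 1/f background, spindles,
K-complexes, artifacts, non-stationarity across the night, or inter-peak
amplitude correlations. Passing the end-to-end tests therefore shows the
*measurement chain* recovers a known predictability ordering under
realistic noise — not that real recordings would show any particular
effect size.

Recovery behaviour, quantified at the defaults (500–1000 intervals,
several seeds): peak detection on the *unsmoothed* noiseless trace
recovers every interval exactly; the full smoothed chain on noisy traces
agrees with ground truth on ≈98.7 % (REM), ≈97.8 % (AWAKE) and ≈96.3 %
(SWS) of interval positions. Smoothing itself shifts ~2–3 % of SWS peaks
by one sample where the two flanking intervals are very unequal (a
symmetric kernel pulls a peak toward its flatter flank); this is inherent
to σ = 1 smoothing of asymmetric cycles, affects intervals only in ±1
pairs, and is far below the level that would disturb the state
comparison.

## Experiment sizes

The standard comparison uses 3,000 intervals per state (≈1,800 training
pairs, ≈750 test errors per run, matching the thousands-of-peaks regime
the analysis targets), three seeds, one network per (state, seed) — nine
trainings, a few seconds total on one CPU. Under these conditions the
mean log|test error| ordering REM < AWAKE < SWS holds in every seed, the
conscious-vs-SWS Welch p-values are far below 1e−6, and pooled-SD |d| is
≈1.1 (REM vs SWS) and ≈0.77 (AWAKE vs SWS).

## Raw-waveform mode

`mode: RAW` in the pipeline predicts the smoothed waveform directly
instead of its intervals. It exists for exploration only and the report
stamps it exploratory; no claims are attached to it here.

## Known limitations

- The EDF writer is minimal (one data record, 16-bit quantization over
  the per-channel range); it exists for round-tripping and fixtures, not
  for producing archival polysomnography files.
- Segment selection from long recordings (which 30,000-sample excerpts to
  analyze per state) is left to the user; the pipeline consumes whatever
  trace it is given.
- The LM trainer is full-batch and dense (121 parameters); it is not
  intended for networks orders of magnitude larger.
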