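# Methods

## Signal model

The nanomotion sensor's raw output is a uniformly sampled cantilever
deflection x(t) whose broadband, colored-noise fluctuations scale with the
metabolic activity of the attached cells. The package models a record as

    x_k = drift_intercept + drift_slope · t_k + sqrt(m(t_k − t_stim)) · c_k + e_k

where

* **c** is a stationary first-order autoregressive (AR(1)) process with
  marginal variance σ₀² and lag-1 autocorrelation φ — the simplest process
  with a colored (1/f-like rolloff) spectrum. The innovation variance is
  scaled by (1 − φ²) so the marginal variance is exactly σ₀² at every
  sampling rate.
* **m(t)** is the dimensionless *variance envelope*: 1 for t ≤ 0 (before
  the oxidant stimulus) and, after it, `max(0.01, 1 − Σᵢ depthᵢ·gᵢ(t))`
  with asymmetric-Gaussian dip shapes gᵢ (standard deviation `width_rise`
  before the dip centre, `width_decay` after). The 0.01 floor prevents
  degenerate zero-variance windows. Modulating the *amplitude* by √m makes
  the windowed variance recover m(t) exactly in expectation, which is what
  lets every downstream quantity be checked by parameter recovery.
* **e** is optional additive white measurement noise (σ_meas).

Defaults: σ₀ = 1 a.u., φ = 0.95 at the 2 kHz reference rate, σ_meas = 0,
drift 10⁻⁴ a.u./s (nonzero so the detrending step is actually exercised).
At other sampling rates φ is rescaled as φ^(Δt/Δt_ref), which fixes the
correlation *time* in seconds and makes the per-window variance statistics
sampling-rate invariant (verified by a two-sample KS test at 2 vs 8 kHz).

### Scenario presets

Each experimental condition is one envelope. Depths ("units" of drop below
baseline) and centre times are the values reported for the corresponding
condition; widths are free modelling parameters chosen so that described
qualitative features (sharp vs. diffuse minima, recovery or not within the
recording) are reproduced while any two dips of a preset contribute < 0.01
at each other's centre (so the depths remain individually recoverable):

| id | condition | dips (depth @ centre, rise/decay σ) |
|----|-----------|--------------------------------------|
| P0 | flat control | none |
| P1 | endogenous frataxin + iron | 0.4 @ 600 s (60/120) |
| P2 | mild overexpression + iron | 0.6 @ 300 s (60/180), 0.35 @ 1620 s (60/120) |
| P3 | strong overexpression + iron | 0.7 @ 180 s (60/120), 0.2 @ 840 s (60/180), 0.50 @ 2160 s (60/300) |
| P4 | mild overexpression, no iron | 0.3 @ 420 s (60/180), 0.25 @ 1800 s (60/180) |
| P5 | strong overexpression, no iron | 0.2 @ 480 s (60/180), 0.5 @ 2100 s (60/120) |

P4's depths are design values (only "shallower" minima are described for
that condition). P3's third dip decays over 300 s so that the trough is
still in progress when a 45-minute post-stimulus recording ends — that
condition's signature is precisely that the cells had not recovered by the
end of the measurement.

Default simulated study conditions: 20 min pre-stimulus baseline, 45 min
post-stimulus, 2 kHz sampling (a desk-scale stand-in for the instrument's
20 kHz acquisition, which is also supported), three replicates per
condition.

## Variance pipeline

* **Windows**: contiguous 30-s sets laid out from t = 0; the grid restarts
  at the stimulus so no set mixes pre- and post-stimulus signal, and partial
  sets (trailing, or truncated at the stimulus) are discarded. NaN samples
  are rejected outright, never imputed.
* **Detrend + variance**: OLS line per set; residual variance RSS/(n − 2).
  The n − 2 denominator matches the two fitted parameters and is unbiased
  under the model; at 60 000 samples per window the choice is numerically
  irrelevant. Computation is vectorized over windows with the centred-time
  normal equations; a brute-force per-window OLS is kept in the test suite
  as an independent oracle (agreement to 1e−9 relative).
* **Normalization**: each window variance is divided by the mean variance of
  *all* complete pre-stimulus windows and multiplied by 100, so the
  pre-stimulus mean is 100 exactly by construction. At least 5 baseline
  windows are required (configurable). A record with no stimulus time
  (a pure control acquisition) is normalized to its own overall mean.
* **Binning**: post-stimulus points averaged in consecutive bins aligned at
  t = 0; width 240 s by default, configurable 180–300 s in multiples of the
  window length. Pre-stimulus points are averaged into same-width bins for
  plotting. The trailing partial bin is kept and flagged. Bin time is the
  nominal bin centre.
* **Aggregation**: replicate traces on an identical grid are combined
  pointwise (mean, SD with ddof = 1, n). Mismatched grids are rejected, not
  resampled.

Invariances guaranteed (and tested): adding any affine ramp a + b·t to a
record leaves the variance trace unchanged; scaling a record by c scales
every window variance by c² and leaves the normalized trace unchanged.

## Response features

Troughs are located on a 5-window (150 s) centred moving average of the
unbinned trace, using local-minima detection with three gates: the smoothed
value must fall below 100·(1 − min_depth) with min_depth = 0.1 units
(smaller than every reported minimum, larger than flat-control fluctuation
under the default noise), prominence ≥ min_depth·100/2, and pairwise
separation ≥ 240 s.

Depth, time and duration are then measured on the **unsmoothed** 30-s trace:
the trough is re-located as the argmin within the smoothing half-width
(±2 windows) of the smoothed candidate, depth_units = 1 − value/100 there,
and duration is the contiguous span below the half-depth level
100·(1 − depth/2). The split matters: a 150-s moving average attenuates a
sharp dip (60 s rise / 120 s decay) by roughly 13 %, so reading depth off
the smoothed trace would turn a 0.7-unit drop into ~0.61. Smoothing is the
right tool for *where* and *how many*; the unsmoothed trace is the right
place to read *how deep*. Ties between equal smoothed minima resolve to the
earlier trough.

**Recovery**: the signal has recovered when the mean of the final two
post-stimulus bins is ≥ 100·(1 − 0.1) *and* no detected minimum's
half-depth interval overlaps that tail span. The two-part rule
distinguishes "returned to basal levels" from "still inside a trough that
happens to end near 100".

Super-baseline excursions (variance rising above 100 late in a recording)
are not reported as features.

## Numerical and I/O choices

* All randomness flows through an explicit integer seed
  (`numpy.random.default_rng`); identical inputs give bit-identical records,
  and no output file contains a timestamp, so full reruns are byte-identical.
* Records travel as a `.npy` float array plus a JSON sidecar
  (schema-versioned: sampling_rate, stimulus_time, condition, replicate_id,
  seed); small fixtures can use a two-column text format with `# key =
  value` headers. Missing sampling_rate, schema mismatch and NaN samples are
  explicit format errors.
* Traces are TSV (t_center_rel_s, value_pct, sd_pct, n, is_partial_bin)
  with a one-line JSON metadata header; profiles and analysis reports are
  JSON with the configuration embedded.

## What the synthetic data does and does not emulate

The generator reproduces the features the pipeline measures: colored-noise
statistics, slow instrumental drift, baseline-relative variance drops with
condition-specific depth/timing structure, and replicate-to-replicate
estimator noise. It does **not** emulate cell attachment/detachment events,
non-Gaussian bursts, oscillatory or above-baseline metabolic excursions,
H₂O₂ diffusion kinetics, or any cantilever mechanics (spring constant,
thermal spectra). Passing parameter-recovery tests therefore shows the
*pipeline* is correct and well-calibrated for envelope-modulated colored
noise — it does not validate the biological interpretation of real sensor
recordings, and real data with artefacts may need screening the pipeline
deliberately does not attempt.

## Test problem sizes

Monte-Carlo checks run the full study conditions (2 kHz, 65-min records):
parameter recovery uses 3 replicates per condition, count/flat-control
stability uses 20 seeds per condition, with each simulated record shared
across tests through a session cache. Distributional properties that do not
depend on record length (stationarity of window variances, sampling-rate
invariance) use shorter records — 300 s × 100 seeds and 900 s × 8 seeds per
rate respectively — as 10 windows per record already give the trend test and
KS test the points they need.
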