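# Methods

This note documents the models, parameter choices and numerical
conventions behind `wavemix`, in the order the pipeline uses them.

## Waveform-shape statistic (ΔCT)

A signal is split at its zero-crossings; crossing times are located by
linear interpolation between the two samples bracketing each sign
change, after spline upsampling to 1000 Hz (so crossing times are
resolved to about a millisecond even for 250 Hz input). A sample exactly
equal to zero is assigned to the side of its successor, which places the
crossing at that sample's own time — a deterministic rule for a
measure-zero event. Crest periods `Tc` (up- to down-crossing) pair with
crest amplitudes `Ac` (maximum in the interval); troughs analogously.
Incomplete half-cycles at the signal edges are discarded.

ΔCT = (mean Tc − mean Tt)/(mean Tc + mean Tt). Before averaging, cycles
whose amplitude falls below the 50th percentile of the *pooled* crest
and trough amplitudes are dropped; ties are **kept** (threshold applied
as ≥), so a constant-amplitude signal is not annihilated. After
filtering the crest and trough sets may be unpaired, so the means are
taken over each retained set independently; for paired sets this is
identical to averaging per-cycle differences.

Two deliberate deviations from a naive reading:

* On *noiseless periodic* signals the pooled percentile degenerates: the
  crest and trough amplitudes form two exact point masses and the median
  annihilates whichever class is smaller (for the canonical waveform,
  all crests: Ac ≈ 0.878 < At ≈ 1.229). The filter exists to reject
  1/f-noise cycles, so simulation experiments on noiseless compounds
  compute ΔCT without it; the full pipeline (3–45 Hz band-pass, order-4
  Butterworth, zero-phase; upsample; 50th percentile) is used wherever
  signals contain noise (sensors, SSD components, modulated sources).
* All filtering is zero-phase (forward–backward). A causal filter's
  asymmetric phase response would itself distort crest/trough durations.

Reference values (exact, from dense root-finding on the analytic
waveform): the canonical source has Tc = 56.53 ms, Tt = 43.47 ms,
ΔCT = +0.1306; a 30/70 ms duty-cycle wave has ΔCT = −0.4.

## Canonical source and delay mixing

`μ(t) = A₁ sin(2πft) + A₂ sin(4πft + ψ)`, defaults A₁ = 1, A₂ = 0.25,
f = 10 Hz, ψ = 1 rad. (The amplitude ratio 4 corresponds to a *power*
ratio of 16 between base rhythm and harmonic; the explicit amplitude
values are the model definition.)

The compound `X(t) = Σᵢ μ(t − φᵢ)`, φᵢ ~ N(0, σ), is evaluated
analytically — delayed sinusoids are never produced by shifting sampled
arrays, so cancellation results are exact to floating point. Summing
delayed copies of a sinusoid is a phasor sum; without amplitude
modulation the compound collapses to two sinusoids with complex gains
`S₁ = Σ exp(−iωφᵢ)` and `S₂ = Σ exp(−2iωφᵢ)`, which is the fast exact
path used everywhere.

**Attenuation law.** The coherent attenuation of a frequency-f component
under N(0, σ) delays is the magnitude of the delay distribution's
characteristic function, `exp(−2(πσf)²)`. A finite compound additionally
carries an incoherent residual of order 1/√N (the finite-generator
floor), which dominates the *raw* band power once the coherent part has
decayed. The attenuation experiment therefore estimates, per iteration,
the real part of the compound's spectral coefficient at the target
frequency relative to the zero-lag compound — an unbiased estimator of
the closed form at any N — and records the raw |·|² relative power with
its floor alongside. Iterations share one standard-normal draw across
all σ cells (delays = σ·z), so the curves over σ are paired and adjacent
differences are estimated with low variance.

**ΔCT versus σ.** The signed ensemble median/mean of compound ΔCT
decays toward 0 with σ (verified at 3000 iterations: 0.019 → 0.011 for
σ = 20 → 30 ms). The median of |ΔCT| instead *rises* again at large σ:
once the α component is strongly attenuated, the incoherent β residual
with random phase inflates |ΔCT| — extreme values at large delays are a
real property of the finite-N model, visible as growing dispersion. The
monotonicity check therefore uses the signed median and assesses
adjacent σ cells against twice the paired bootstrap standard error of
the difference at the 200-iteration ensemble size, plus a structural
assertion that the σ ≥ 20 ms medians fall below a quarter of the
zero-lag value. At 200 iterations the σ = 20 vs 30 ms gap (~0.005,
per-iteration SD ~0.1) is below Monte-Carlo resolution; the band is a
power statement, not a smaller claimed effect.

**Amplitude modulation.** Real rhythms wax and wane. When enabled, each
generator is scaled by its own strictly positive slow envelope before
summation: 1/f-spectrum Gaussian noise → magnitude of its analytic
signal → zero-phase low-pass below f/2 (5 Hz) → clipped to a 10⁻³ floor
→ rescaled to mean 1. One envelope scales both harmonics of a
generator, so every source is perfectly α–β comodulated by
construction; envelopes are independent *across* generators.

## Spectral stage

Power spectra are Welch averages (Hann window, 1 s windows, 50%
overlap → 1 Hz bins; density scaling). The aperiodic background is fit
as a quadratic polynomial of dB versus log₁₀(f) over 3–40 Hz with the
oscillatory bands (peak ± 2 Hz and harmonic ± 2 Hz) masked; a quadratic
captures the spectral knee without following narrowband structure.
"SNR" is the residual (dB above the fit) at the band's peak bin, and a
rhythm counts as present when it exceeds 5 dB.

Per-segment α/β ratios use *raw* Welch power in the single bin nearest
the α peak over the bin nearest twice that frequency — no 1/f
correction, because the fit is unstable on short segments; non-
overlapping segments keep the per-segment values independent. A ratio
below 1 means the harmonic momentarily dominates. The ratio experiment
runs on the synthetic-EEG surface the ratios are meant for: fresh
compound instantiation per segment (new delays and envelopes) plus
additive 1/f background noise at 1.35 × (N·A₁) SD, which puts the α
residual of a weakly-jittered compound (σ = 5 ms) near 11 dB — a
realistically *included* recording (well above the 5 dB criterion). The
background noise is what makes segment length matter: short segments
have noisier power estimates, so β-dominant events appear more often at
2 s than at 10 s.

## Envelope stage

Amplitude envelopes are the magnitude of the analytic signal of the
center ± 2 Hz band (Butterworth order 9, zero-phase — steep enough that
the α and β bands do not leak into each other). Coupling is the
Spearman rank correlation of the two envelopes, computed on full-rate
samples with 1 s trimmed from each end (filter + Hilbert transients).
An envelope whose coefficient of variation is below 2% is flagged
undefined — at that level the variation is indistinguishable from the
band-pass/Hilbert ripple of a constant-amplitude rhythm (measured
ripple up to ~2% on a few-second window). In ensembles the rare flagged
instantiation is recorded as NaN and excluded from summaries.

Each ensemble iteration uses a fresh compound instantiation (new delays
and envelopes), padded by the trim so the correlated span equals the
nominal segment length.

## Synthetic multichannel EEG

Each oscillatory source is itself a locally delay-mixed compound of 10
generators with σ = 5 ms and per-generator 1/f modulation — a patch of
imperfectly synchronized populations — normalized to unit variance.
Sources project to 12 sensors through unit-norm smooth random columns
(random coefficients on the first 3 cosine modes over a 1-D channel
axis; nearby populations see nearly equal gains, so a low-order smooth
forward model suffices). Background activity: 20 unit-variance 1/f
sources mixed through columns of the same construction at scale 0.3,
plus independent per-channel 1/f sensor noise at scale 0.3. Recordings
are 60 s at 250 Hz. With these scales the best channel's α residual
sits around 10–15 dB: comfortably past the 5 dB inclusion criterion,
while sensors remain visibly noisier than the source — the regime in
which demixing has something to recover. Everything (sources, mixing,
noise, ground-truth ΔCT) reproduces bit-identically from the config
seed.

What the generator does *not* emulate: volume conduction through a head
model (mixing columns are smooth weights, not lead fields), artifacts
(blinks, muscle), non-stationary state changes (eyes open/closed), or
multiple oscillatory sources with distinct spectra. On the last point:
several sources with *identical* spectral shape in the same band make
the band/flank generalized eigenvalues degenerate, so no band-power
method can separate them — the demixing experiments therefore use one
oscillatory source against full-rank 1/f background, which is the
regime where SSD's contrast (band SNR) is identifiable. Passing tests
show recovery under linear instantaneous mixing with 1/f background,
not robustness to artifacts or source spectra overlapping in
band/flank ratio.

## SSD

Signal covariance from band-passed data (individual α peak ± 2 Hz,
Butterworth order 2, zero-phase), noise covariance from the summed
flank bands (lo−2, lo−1) and (hi+1, hi+2) Hz — immediately neighbouring
flanks with a 1 Hz transition gap. Generalized eigendecomposition via
`scipy.linalg.eigh`, flank covariance shrunk toward the scaled identity
by 10⁻⁶ of its mean eigenvalue (escalated tenfold with a log message
only on failure). Patterns A = Cs W (Wᵀ Cs W)⁻¹. Each filter's sign is
fixed so its largest-magnitude pattern entry is positive — eigenvectors
are sign-indeterminate but waveform polarity (hence the sign of ΔCT)
must be reproducible. The α-band peak is detected on the channel-average
1/f-corrected spectrum; a residual peak below 1 dB raises a no-peak
error (the argmax of the residual over pure 1/f noise sits well below
1 dB, a genuine rhythm well above). Filters are applied to *broadband*
data with no narrowband re-filtering, so harmonics co-located with the
α source survive into the component. `mne.decoding.SSD` serves as an
independent cross-check in the test suite, never as the implementation.

In the sensor-vs-component experiment, components are screened by the
same 5 dB α-residual inclusion rule applied to recordings, so
pure-noise components (inevitable when the dataset holds one source)
never enter the 3-vs-3 envelope pooling; the ΔCT contrast compares the
maximal included-component |ΔCT| with the maximal sensor |ΔCT|, paired
across datasets (Wilcoxon signed-rank), and envelope correlations are
pooled (rank-sum). Comparison sensors are the three with the highest α
power — the data-driven analog of picking the rhythm-carrying
electrodes.

## Ensemble sizes and reproducibility

Defaults: 200 iterations per σ cell (attenuation, ratios, envelopes;
grids reach paper-scale 1000 by config only), 40 generators for
attenuation, 20 for ratio/envelope ensembles, 50 synthetic datasets for
the SSD comparison. These sizes give the rank tests p-values far below
0.05 and Monte-Carlo SEs small against the effects they measure, while
the full experiment battery runs in a few minutes on one CPU. Every
experiment consumes a single integer seed, derives all randomness from
`numpy.random.default_rng` children of it, and stores raw per-iteration
tables from which every summary statistic is recomputable; reruns with
the same seed reproduce the tables bit for bit.

## Known limitations

* ΔCT captures duty-cycle asymmetry only; rise/decay sharpness
  asymmetries that preserve the duty cycle are invisible to it.
* The amplitude-percentile filter assumes noise cycles are
  low-amplitude; rhythmic artifacts of large amplitude pass it.
* The 1/f fit is a fixed-order polynomial, not a model-selected
  aperiodic fit; spectra with pronounced knees outside 3–40 Hz or
  multiple overlapping peaks can bias the residual.
* EDF export is 16-bit: round-trips are exact only to the per-channel
  quantization step, and only integer sampling rates are supported.
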