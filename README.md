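# wavemix

Waveform-shape analysis of neuronal oscillations under spatial mixing.

EEG and MEG sensors record the sum of many neuronal populations. Invasive
recordings show that cortical rhythms such as the sensorimotor mu rhythm
are *non-sinusoidal* — arc-shaped, with a beta harmonic phase-locked at
twice the alpha frequency — yet the same rhythms usually look sinusoidal
at the scalp. `wavemix` implements the analysis chain that explains why:
summing copies of a non-sinusoidal source with small temporal jitter
between populations dephases the harmonic faster than the base rhythm,
washing the waveform's asymmetry out of the mixture. The degree of
non-sinusoidality left in a recording is therefore informative about the
spatial synchronization of its generators.

The package is aimed at EEG/MEG methods researchers who want to quantify
waveform shape, simulate mixing scenarios, or test shape-recovery
pipelines against ground truth.

## The statistic and the model

**ΔCT (crest–trough difference).** Split a zero-mean oscillation at its
zero-crossings: the crest period `Tc` runs from an up-crossing to the
next down-crossing, the trough period `Tt` the other way. Then

    ΔCT = (mean Tc − mean Tt) / (mean Tc + mean Tt)

is 0 for a sinusoid, bounded in (−1, 1), and moves away from 0 as the
duty cycle departs from 50%. Cycles below the 50th percentile of pooled
crest/trough amplitudes are discarded to suppress 1/f-noise cycles.

**Canonical source.** `μ(t) = A₁·sin(2πft) + A₂·sin(4πft + ψ)` with
defaults `A₁ = 1, A₂ = 0.25, f = 10 Hz, ψ = 1`.

**Compound (sensor) signal.** `X(t) = Σᵢ μ(t − φᵢ)` with delays
`φᵢ ~ N(0, σ)`. A component at frequency `f` attenuates coherently by
`exp(−2(πσf)²)`, so the 2f harmonic decays with four times the exponent
— the compound becomes more sinusoidal as σ grows. The same mechanism
spreads per-segment α/β power ratios (the harmonic can transiently
*dominate*) and can flip the sign of α–β amplitude-envelope
correlations even though every source is positively comodulated.

**SSD (spatio-spectral decomposition).** Spatial filters from the
generalized eigendecomposition of band-passed vs. flank-passed channel
covariances, trained at the individual alpha peak ± 2 Hz and applied to
broadband data, so harmonics sharing the source's spatial pattern
survive and the component recovers the waveform that mixing hides.

## Worked example

```python
import numpy as np
from wavemix import (CanonicalWaveParams, DelayMixingConfig, TimeSeries,
                     canonical_waveform, compound_signal, compute_delta_ct,
                     delta_ct, extract_cycles)

params = CanonicalWaveParams()                      # A1=1, A2=0.25, f=10, psi=1
t = np.arange(10_000) / 1000.0
mu = TimeSeries(canonical_waveform(params, t), rate=1000.0)
cat = extract_cycles(mu)
print(np.mean(cat.crest_periods), np.mean(cat.trough_periods))
# 0.056531  0.043469        -> crests last 56.5 ms, troughs 43.5 ms
print(delta_ct(cat).delta_ct)
# 0.13062746003113132      -> clearly non-sinusoidal

# forty delayed copies, 20 ms delay spread: the asymmetry washes out
cfg = DelayMixingConfig(n_sources=40, sigma=0.020, seed=1, duration=5.0)
comp = compound_signal(params, cfg)
print(delta_ct(extract_cycles(comp.signal)).delta_ct)
# 0.030654988852803928     -> the compound is far closer to sinusoidal
```

The numbered drivers under `analysis/` run the full studies and write
raw/summary tables to `results/`:

```
01_waveform_shape.py            ΔCT on closed-form reference waveforms
02_delay_mixing_attenuation.py  harmonic attenuation vs exp(−2(πσf)²), ΔCT collapse
03_alpha_beta_ratios.py         per-segment α/β ratios vs delay spread and length
04_envelope_correlations.py     α–β envelope correlation distributions
05_ssd_demixing.py              sensor space vs SSD components on synthetic EEG
```

For instance `python analysis/05_ssd_demixing.py --seed 0` prints:

```
Across 50 synthetic datasets:
  median |pattern corr| with true mixing column: 1.000
  median |component ΔCT - source ΔCT|:           0.018
  component |ΔCT| beats best sensor in 94% of datasets (Wilcoxon signed-rank p = 5.9e-14)
  envelope rho: components median 0.10 vs sensors 0.06 (rank-sum p = 7.1e-06)
```

i.e. on ground-truthed synthetic recordings, demixing recovers the
source pattern essentially perfectly, and the extracted components are
reliably more non-sinusoidal and more harmonically comodulated than the
best sensors — the signature that sensor-level mixing, not the sources,
makes scalp rhythms look sinusoidal.

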