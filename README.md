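# pronypv

Prony analysis of left-ventricular pressure and volume signals.

Cardiac catheterization yields cyclic pressure (mmHg) and volume (µL)
time series — typically ~1 s records at 1000 Hz.  `pronypv` decomposes
such signals into sums of exponentially damped sinusoids,

  y(t) = Σᵢ Aᵢ e^{σᵢ t} cos(2π fᵢ t + φᵢ),

via the Prony method: a linear-prediction (Hankel) solve, companion-matrix
polynomial rooting to obtain the complex poles μᵢ = e^{σᵢ + 2πj fᵢ}, and a
Vandermonde least-squares solve for the complex amplitudes Cᵢ = Aᵢ e^{jφᵢ}.
A time-scale factor d, chosen by maximising R², keeps the Vandermonde
basis well-conditioned at high sampling rates.  On top of the fit the
package provides:

- **Spectra**: per-component amplitude, damping-coefficient and phase
  spectra (the damping spectrum has no Fourier counterpart), plus FFT
  power spectra and truncated Fourier-series fits for comparison.
- **Pole analysis**: stability classification (|μ| ≤ 1), stable-only
  refits, and pole-diagram metrics — importance weights αᵢ = |Cᵢ|/max|Cᵢ|,
  importance-weighted mean pole angle, dispersion 1/std(|Cᵢ|), and
  unit-circle deviation measures (top-5 mean distance, count of poles
  ≥ 0.2 radial units off the circle).
- **Transfer function**: the analytic Laplace-domain ratio
  Z(s) = L{pressure}/L{volume} built from the closed-form transforms of
  the fitted components, its pseudo pole-zero structure (pressure poles →
  poles of Z, volume poles → zeros), and Bode magnitude/phase curves over
  1–100 Hz with composite averaging.
- **Synthetic signals**: exact damped-sinusoid sums with ground truth and
  pulsatile pressure/volume waveform generators (default 420 bpm, 1 s at
  1000 Hz) for testing and demonstration, with scenario presets that mimic
  baseline/shock/resuscitation group structure.

Intended users: researchers processing hemodynamic (or other cyclic
physiological) signals who want pole-domain features and analytic
transfer functions rather than purely Fourier-based descriptions.

## Worked example

```python
import pronypv as pv

# synthetic 1 s, 1000 Hz pressure/volume record at 420 bpm,
# noise SD = 2% of the pressure range
cfg = pv.PVSimConfig(noise_sd=0.02 * 112, seed=1)
pressure, volume, truth = pv.make_pv_waveforms(cfg)

model_p = pv.prony_fit(pressure)          # auto order, auto scale
model_v = pv.prony_fit(volume)
print(model_p.n_components, model_p.r_squared)   # 450 0.999533

metrics = pv.pole_metrics(model_p)
print(metrics.mean_angle_deg)             # 0.10
print(metrics.n_stable, metrics.n_unstable)      # 294 156

psd = pv.fourier_power_spectrum(pressure)
print(pv.dominant_frequency(psd))         # 7.0  (= 420 bpm)

tf = pv.build_transfer_function(model_p, model_v)
curve = pv.bode(tf)                       # 1..100 Hz, 1 Hz steps
print(round(float(curve.magnitude_db[9]), 2))    # -14.54  (at 10 Hz)
```

The auto-order fit reconstructs the noisy waveform with R² ≈ 0.9995; the
FFT power spectrum peaks at exactly 7 Hz, the heart-rate fundamental; the
importance-weighted mean pole angle of ~0° reflects the dominant
low-frequency poles near the positive real axis; and the Bode curve
samples the analytic pressure→volume transfer function across the
physiologically relevant band.

A command-line interface mirrors the library:

```sh
pronypv simulate --out rec.tsv
pronypv run rec.tsv --out results/
```

writing model JSON, component/pole tables (TSV), pole metrics, and the
transfer-function Bode curve for each input file.

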