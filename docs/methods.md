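# Methods

## The model

`pronypv` fits a uniformly sampled real signal `y(t_k)`, `t_k = k/SR`,
`k = 0..M-1`, to a sum of exponentially damped sinusoids

    y(t_k) = sum_{i=0}^{N-1} A_i exp(sigma_i t_k) cos(2 pi f_i t_k + phi_i),

equivalently, with poles `mu_i = exp(sigma_i + 2j pi f_i)` and complex
amplitudes `C_i = A_i exp(j phi_i)`, to `y_k = Re sum_i C_i mu_i^k`.  The
fit is the classical three-stage Prony procedure:

1. **Linear prediction.**  Every sample is modelled as a fixed linear
   combination of the N preceding samples.  Stacking rows
   `y_l = sum_j a_j y_{l-1-j}` for `l = N..M-1` gives an (M-N) x N Hankel
   system solved by least squares (LAPACK `gelsd`).  Using all available
   rows rather than only the first N keeps the estimate defined and more
   robust when the samples are noisy; for the maximal order
   `N = floor(M/2)` the two formulations coincide.  A rank-deficient
   system is solved in the minimum-norm sense with a warning, never an
   error — low-rank Hankel matrices are the *expected* outcome for
   signals composed of fewer than N modes.
2. **Rooting.**  The prediction coefficients are the coefficients of the
   monic characteristic polynomial `x^N - a_0 x^{N-1} - ... - a_{N-1}`;
   its roots (computed via the companion-matrix eigenvalues) are the
   poles.  The admissible order is capped at `floor(M/2)`, the Prony
   analogue of the Nyquist criterion.
3. **Amplitudes.**  With poles fixed, the complex amplitudes solve the
   linear system `y = V C` with Vandermonde-type basis
   `V[k, i] = mu_i^{tau_k}`, by an SVD-truncated pseudoinverse (relative
   singular-value cutoff 1e-13, configurable).

### Time-scale factor d

At high sampling rates the per-sample poles crowd around `1 + 0j` and the
Vandermonde basis becomes numerically rank deficient.  The basis exponent
is therefore rescaled, `tau_k = k / d`, and `d >= 1` is chosen to maximise
the coefficient of determination R^2 between reconstruction and raw
signal.  `optimize_scale` scans a 25-point logarithmic grid of `d` over
`[1, SR]` and refines the bracket around the grid maximum by
golden-section search (derivative-free, deterministic; R^2(d) is cheap
but not guaranteed smooth, so no gradient steps are taken).  At `d = 1`
the model reduces exactly to the unscaled Prony series on index time.

Fitted damping and frequency are *per scaled time unit*; physical units
(1/s, Hz) are obtained by multiplying by `SR/d`.  Both forms are exposed;
all spectra and transfer-function components use physical units.

### Order selection

With `n_poles="auto"`, candidate orders are the multiples of
`floor(M/20)` up to `floor(M/2)` (configurable via `n_grid`) and the
R^2-maximising order wins.  Running the full d-optimisation for every
candidate is quadratically expensive at M = 1000, so each candidate is
scored on a coarse 5-point logarithmic d-grid and only the winning order
receives the full 25-point grid plus golden-section refinement.  Final
coefficients are always recomputed with the SVD-truncated solve; the
faster rank-revealing-QR driver is used only inside the search loop.

## Spectra

A fitted model yields one spectral point per component: amplitude,
damping-coefficient, and phase spectra.  Real signals produce conjugate
pole pairs, which are folded to a single representative with `f >= 0` and
amplitude `2|C|`, so a fitted unit cosine reports amplitude 1.  The
Fourier comparators are a one-sided PSD normalised as `|DFT|^2 / M^2`
with one-sided doubling (except DC and Nyquist), making Parseval checks
bit-reproducible, and a truncated Fourier-series fit on the fundamental
`1/T` computed by least squares so that it stays defined for records
spanning a non-integer number of cycles.  `dominant_frequency` excludes
the DC bin by default: pulsatile pressure records have a large positive
mean whose zero-frequency power exceeds the heart-rate fundamental, and
the spectral "peak" of interest is the nonzero-frequency maximum.

## Pole analysis

A pole is stable iff `|mu| <= 1` (`sigma <= 0`); the boundary counts as
stable and carries an outward tolerance of 1e-9 because fitted undamped
cosines land within companion-eigenvalue float error (~1e-11) of the
circle.  `stable_refit` keeps the stable pole subset and re-solves the
amplitudes against the original signal at the same `d`.

Diagram metrics over a pole set (all poles or the stable subset):

- importance `alpha_i = |C_i| / max_j |C_j|`;
- mean angle: weighted mean `sum(alpha_i theta_i) / sum(alpha_i)` of the
  principal pole angles in degrees.  An alternative denominator
  `sum(theta_i)` is available via `as_printed=True` but fails the
  single-pole sanity check (the mean angle of one pole should be that
  pole's angle) and is sign-unstable, so the weighted mean is the
  default.  Angles are treated linearly in (-180, 180], without circular
  averaging;
- dispersion: `1 / s` with `s` the (n-1)-denominator standard deviation
  of the raw `|C_i|`.  All-equal weights give `s = 0` and dispersion
  `+inf`, flagged.  Note dispersion scales inversely under a common
  scaling of C; comparisons across signals should use matched units;
- unit-circle deviation: `dist_i = ||mu_i| - 1|` (inward and outward both
  count); the mean of the five largest distances (all of them if N < 5,
  flagged) and the count of poles with `dist_i >= 0.2` (threshold
  configurable).

The pressure/volume ratio of the two deviation metrics is reported as a
pair; a zero volume-side denominator is an error, not an infinity.

## Transfer function and Bode curves

Each physical-unit damped cosine has the closed-form Laplace transform

    A [cos(phi)(s - sigma) - 2 pi f sin(phi)] / [(s - sigma)^2 + 4 pi^2 f^2],

validated in the tests against truncated numerical quadrature of
`integral f(t) e^{-st} dt`.  The transfer function is the ratio of the
pressure model's component-transform sum to the volume model's.  In
pseudo pole-zero form the pressure model's poles are poles of Z and the
volume model's poles are its zeros, so each signal's pole diagram doubles
as a pseudo-pole diagram of Z and reuses the pole metrics verbatim.

Bode curves sample `Z(2j pi f)` on a uniform grid, 1–100 Hz at 1 Hz by
default.  Magnitude is reported in dB (`20 log10 |Z|`) with the linear
magnitude exported alongside, phase unwrapped along the grid in degrees.
A grid point that hits a singularity (an undamped component places an
s-plane pole exactly on the imaginary axis) is masked and flagged rather
than failing the curve.  Composite curves average magnitude-dB and
phase-degrees pointwise (excluding masked points pairwise); complex-domain
averaging is deliberately not used.

## Synthetic signals

`make_damped_sinusoids` samples the model's own generative form with
known parameters.  `make_pv_waveforms` emulates a rat left-ventricular
catheterization record: 420 bpm (7 Hz fundamental), 1 s at 1000 Hz,
pressure spanning 8–120 mmHg, volume 200–400 uL.  The morphology is a
harmonic synthesis — `n_harmonics` cosines at multiples of the
fundamental with `1/k` amplitude decay for pressure (a sharper pulse) and
`1/k^2` for volume (smoother filling), volume peaking half a cycle after
pressure — affinely normalised so the noiseless extrema hit the
configured ranges exactly.  Noise is additive white Gaussian from a
single seeded generator.

This generator is deliberately *not* a mechanistic elastance model: the
analysis methods need realistic spectra and cyclicity with closed-form
ground truth (the noiseless waveform is exactly a 2·n_harmonics + 1 pole
Prony model), not hemodynamic physiology.  Consequently, passing tests
demonstrate correctness of the decomposition, metrics and transfer
machinery on signals with catheterization-scale structure; they do not
demonstrate robustness to baseline drift, beat-to-beat variability,
catheter artefacts, or non-stationary heart rate, none of which the
generator produces.  `perturb_to_shock` scales developed pressure and
stroke volume to provide distinguishable "baseline/shock/resuscitation"
groups for pipeline smoke tests only; no physiological effect sizes are
claimed.

## Numerical conditioning and problem sizes

Prony fitting is notoriously ill-conditioned, and two regimes matter:

- **Gross oversampling.**  At 1000 Hz, per-sample poles of sub-50 Hz
  components cluster near `1 + 0j`; the Hankel system's condition number
  reaches ~1e15 at the waveform's minimal order (13) and small-order fits
  fail outright — this is precisely the regime the `d` rescaling and the
  large auto-selected orders address.  Exact-recovery tests therefore run
  at 250 Hz (components up to 31 Hz), where the minimal-order fit is
  well-conditioned and parameters come back at ~1e-11 relative error;
  the 1000 Hz pipeline is exercised through the R^2 fidelity checks with
  the auto order search.
- **Long high-rate records** (beyond ~10 s at 1000 Hz) are outside the
  intended regime and are not targeted.

Default problem sizes used by the tests and the acceptance script:
M = 1000 (1 s at 1000 Hz) for fidelity and spectra, M = 250 (1 s at
250 Hz) for structural and recovery tests.

## Known limitations

- The mean pole angle is a linear average of principal angles; pole sets
  straddling the ±180° branch cut will average across the cut.
- Dispersion has the units of 1/|C|, so it is comparable only between
  signals in the same units.
- `fit_coefficients` at `d != 1` uses principal-branch fractional pole
  powers; poles on the negative real axis then contribute non-conjugate
  terms whose imaginary residue is discarded (its maximum magnitude is
  recorded on the model).
- The auto order search maximises raw R^2 and will happily absorb noise
  into high orders; it mirrors how the method is used, but the selected
  order should not be over-interpreted.
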