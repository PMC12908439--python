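"""Prony and Fourier spectra of fitted signals.

A Prony fit yields one (frequency, value) point per component, giving not
only amplitude and phase spectra but a damping-coefficient spectrum that a
Fourier analysis cannot provide.  The Fourier side supplies the standard
comparators: a one-sided FFT power spectral density and a truncated
Fourier-series least-squares fit on the record's fundamental 1/T.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .prony import (
    PronyComponent,
    PronyModel,
    Signal,
    evaluate_model,
    physical_components,
    r_squared,
)

__all__ = [
    "Spectrum",
    "TopComponent",
    "FourierFit",
    "prony_spectra",
    "top_components",
    "fourier_power_spectrum",
    "fourier_series_fit",
    "dominant_frequency",
]


@dataclass(frozen=True)
class Spectrum:
    """Paired (frequency, value) arrays of one spectral kind."""

    frequencies: np.ndarray
    values: np.ndarray
    kind: str  # amplitude | damping | phase | power

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if f.size != v.size:
            raise ValueError("frequencies and values must have equal length")
        if self.kind not in {"amplitude", "damping", "phase", "power"}:
            raise ValueError(f"unknown spectrum kind {self.kind!r}")
        object.__setattr__(self, "frequencies", f)
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class TopComponent:
    """A high-importance component with its evaluated time course."""

    component: PronyComponent  # physical units (1/s, Hz)
    pole: complex
    coefficient: complex
    trace: np.ndarray  # Re(C mu^(k/d)) over the signal window


def prony_spectra(model: PronyModel) -> tuple[Spectrum, Spectrum, Spectrum]:
    """Amplitude, damping, and phase spectra of a Prony model.

    One point per folded component at its physical frequency (Hz, f >= 0);
    conjugate pairs are merged with amplitude 2|C| so a fitted unit cosine
    shows amplitude 1.  Points are emitted sorted by frequency.
    """
    comps = physical_components(model, fold=True)
    comps = sorted(comps, key=lambda c: (c.frequency, -c.amplitude))
    freqs = np.array([c.frequency for c in comps])
    amp = Spectrum(freqs, np.array([c.amplitude for c in comps]), "amplitude")
    damp = Spectrum(freqs, np.array([c.damping for c in comps]), "damping")
    phase = Spectrum(freqs, np.array([c.phase for c in comps]), "phase")
    return amp, damp, phase


def top_components(model: PronyModel, k: int) -> list[TopComponent]:
    """The k components of largest |C|, each with its time trace.

    Traces are the real part of each term's contribution over the fitted
    window, so the traces of all N components sum to the full
    reconstruction.
    """
    n = model.n_components
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    order = np.lexsort((np.angle(model.poles), -np.abs(model.coefficients)))
    factor = model.sampling_rate / model.scale_d
    idx = np.arange(model.source_length)
    out: list[TopComponent] = []
    for i in order[:k]:
        mu, c = model.poles[i], model.coefficients[i]
        sub = PronyModel(
            poles=np.array([mu]),
            coefficients=np.array([c]),
            n_components=1,
            scale_d=model.scale_d,
            sampling_rate=model.sampling_rate,
            source_length=model.source_length,
        )
        trace = evaluate_model(sub, idx)
        mag = abs(mu)
        comp = PronyComponent(
            amplitude=abs(c),
            damping=(math.log(mag) if mag > 0 else -math.inf) * factor,
            frequency=np.angle(mu) / (2 * math.pi) * factor,
            phase=float(np.angle(c)),
        )
        out.append(TopComponent(component=comp, pole=complex(mu), coefficient=complex(c), trace=trace))
    return out


def fourier_power_spectrum(signal: Signal) -> Spectrum:
    """One-sided FFT power spectrum on the discrete frequency grid k/T.

    Normalisation is power = |DFT|^2 / M^2 with one-sided doubling of all
    bins except DC and (for even M) Nyquist, so the total equals the mean
    squared signal (Parseval).
    """
    y = signal.samples
    m = y.size
    spec = np.fft.rfft(y)
    power = np.abs(spec) ** 2 / m**2
    scale = np.full(power.size, 2.0)
    scale[0] = 1.0
    if m % 2 == 0:
        scale[-1] = 1.0
    freqs = np.fft.rfftfreq(m, d=1.0 / signal.sampling_rate)
    return Spectrum(freqs, power * scale, "power")


def dominant_frequency(spectrum: Spectrum, *, exclude_dc: bool = True) -> float:
    """Frequency of the maximum-valued bin (DC excluded by default).

    Pulsatile pressure/volume records have a large positive mean, so the
    zero-frequency bin can outweigh the heart-rate fundamental; the
    spectral "peak" of interest is the nonzero-frequency maximum.
    """
    f, v = spectrum.frequencies, spectrum.values
    if exclude_dc:
        keep = f > 0
        f, v = f[keep], v[keep]
    if f.size == 0:
        raise ValueError("spectrum has no usable bins")
    return float(f[int(np.argmax(v))])


@dataclass(frozen=True)
class FourierFit:
    """Truncated Fourier-series least-squares fit on fundamental 1/T."""

    fitted: np.ndarray
    spectrum: Spectrum  # amplitude per harmonic (DC included at 0 Hz)
    r_squared: float
    cosine_coefficients: np.ndarray  # a_k, k = 0..H (a_0 is the mean term)
    sine_coefficients: np.ndarray  # b_k, k = 1..H


def fourier_series_fit(signal: Signal, n_harmonics: int) -> FourierFit:
    """Least-squares truncated Fourier series with fundamental 1/T.

    Fitting by least squares (rather than coefficient integration) keeps
    the series defined for records spanning a non-integer number of
    cycles, the regime where Fourier edge effects appear.
    """
    if n_harmonics < 1:
        raise ValueError("n_harmonics must be >= 1")
    y = signal.samples
    m = y.size
    t = np.arange(m) / signal.sampling_rate
    f0 = 1.0 / signal.duration
    cols = [np.ones(m)]
    for k in range(1, n_harmonics + 1):
        w = 2 * math.pi * k * f0 * t
        cols.append(np.cos(w))
        cols.append(np.sin(w))
    design = np.column_stack(cols)
    beta, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    fitted = design @ beta
    a = np.concatenate(([beta[0]], beta[1::2]))
    b = beta[2::2]
    amps = np.concatenate(([abs(a[0])], np.hypot(a[1:], b)))
    freqs = f0 * np.arange(n_harmonics + 1)
    return FourierFit(
        fitted=fitted,
        spectrum=Spectrum(freqs, amps, "amplitude"),
        r_squared=r_squared(y, fitted),
        cosine_coefficients=a,
        sine_coefficients=b,
    )
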