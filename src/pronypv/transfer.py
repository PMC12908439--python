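"""Analytic pressure->volume transfer function and Bode curves.

Each fitted damped cosine ``A e^{sigma t} cos(2 pi f t + phi)`` has the
closed-form Laplace transform

    A * [cos(phi) (s - sigma) - 2 pi f sin(phi)] / [(s - sigma)^2 + 4 pi^2 f^2]

so the ratio of the pressure model's transform to the volume model's gives
an analytic transfer function Z(s).  In pseudo pole-zero form the poles of
the pressure model are poles of Z and the poles of the volume model are its
zeros, which is why each signal's pole diagram doubles as a pseudo-pole
diagram of Z.  Bode curves sample Z at s = 2j*pi*f over 1..100 Hz.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .prony import PronyComponent, PronyModel, physical_components

__all__ = [
    "TransferFunction",
    "BodeCurve",
    "SingularityError",
    "laplace_of_components",
    "build_transfer_function",
    "evaluate",
    "bode",
    "composite_bode",
]

#: Evaluations with |denominator sum| below this are treated as singular.
DENOMINATOR_TOL = 1e-12

#: Relative distance to a component's s-plane pole below which the closed
#: form itself is considered singular.
POLE_TOL = 1e-9


class SingularityError(ZeroDivisionError):
    """Evaluation at (or too near) a pole of the transfer function."""


@dataclass(frozen=True)
class TransferFunction:
    """Ratio of component Laplace transforms, pressure over volume.

    Components are stored in physical units (damping 1/s, frequency Hz).
    ``pressure_poles`` / ``volume_poles`` are the discrete Prony poles of
    the two models — the pseudo-poles and pseudo-zeros used for diagram
    metrics.
    """

    numerator_components: tuple[PronyComponent, ...]
    denominator_components: tuple[PronyComponent, ...]
    pressure_poles: np.ndarray
    volume_poles: np.ndarray
    sampling_rate: float

    def __post_init__(self) -> None:
        if not self.numerator_components or not self.denominator_components:
            raise ValueError("both component lists must be nonempty")


@dataclass(frozen=True)
class BodeCurve:
    """Sampled magnitude/phase of a transfer function.

    ``valid`` marks grid points where evaluation succeeded; singular points
    carry NaN and ``valid=False``.
    """

    frequencies_hz: np.ndarray
    magnitude_db: np.ndarray
    phase_deg: np.ndarray
    magnitude: np.ndarray = field(default=None)  # linear |Z|
    valid: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies_hz, dtype=float)
        if f.size < 1 or np.any(np.diff(f) <= 0):
            raise ValueError("frequencies must be strictly increasing")
        n = f.size
        for name in ("magnitude_db", "phase_deg"):
            if np.asarray(getattr(self, name)).size != n:
                raise ValueError("curve arrays must share the grid length")
        if self.magnitude is None:
            object.__setattr__(self, "magnitude", 10 ** (np.asarray(self.magnitude_db) / 20))
        if self.valid is None:
            object.__setattr__(self, "valid", np.isfinite(np.asarray(self.magnitude_db)))


def _component_s_poles(components) -> np.ndarray:
    return np.array(
        [c.damping + 2j * math.pi * c.frequency for c in components]
        + [c.damping - 2j * math.pi * c.frequency for c in components]
    )


def laplace_of_components(components, s: complex) -> complex:
    """Closed-form Laplace transform of a damped-cosine sum at one point.

    Raises
    ------
    SingularityError
        If s coincides (within tolerance) with a component pole
        sigma_i +/- 2j*pi*f_i.
    """
    s = complex(s)
    total = 0.0 + 0.0j
    for i, c in enumerate(components):
        w = 2 * math.pi * c.frequency
        denom = (s - c.damping) ** 2 + w**2
        scale = max(1.0, abs(s) ** 2, c.damping**2 + w**2)
        if abs(denom) <= POLE_TOL * scale:
            raise SingularityError(
                f"s={s} is at a pole of component {i} "
                f"(sigma={c.damping}, f={c.frequency} Hz)"
            )
        total += (
            c.amplitude
            * (math.cos(c.phase) * (s - c.damping) - w * math.sin(c.phase))
            / denom
        )
    return total


def build_transfer_function(
    model_pressure: PronyModel, model_volume: PronyModel
) -> TransferFunction:
    """Transfer function Z(s) = L{pressure}(s) / L{volume}(s).

    Both models must share a sampling rate.  Components are converted to
    physical units (conjugate pairs folded to real cosines) before the
    closed-form transforms are taken.
    """
    if model_pressure.sampling_rate != model_volume.sampling_rate:
        raise ValueError("pressure and volume models must share a sampling rate")
    return TransferFunction(
        numerator_components=tuple(physical_components(model_pressure)),
        denominator_components=tuple(physical_components(model_volume)),
        pressure_poles=np.array(model_pressure.poles, copy=True),
        volume_poles=np.array(model_volume.poles, copy=True),
        sampling_rate=model_pressure.sampling_rate,
    )


def evaluate(tf: TransferFunction, s: complex) -> complex:
    """Z(s) as the ratio of the two component-transform sums.

    Raises
    ------
    SingularityError
        If the denominator sum magnitude falls below the tolerance.
    """
    num = laplace_of_components(tf.numerator_components, s)
    den = laplace_of_components(tf.denominator_components, s)
    if abs(den) <= DENOMINATOR_TOL:
        raise SingularityError(
            f"denominator is singular at s={s} (|denominator|={abs(den):.3e})"
        )
    return num / den


def bode(
    tf: TransferFunction,
    f_min_hz: float = 1.0,
    f_max_hz: float = 100.0,
    step_hz: float = 1.0,
) -> BodeCurve:
    """Bode curve of Z over a uniform frequency grid (default 1..100 Hz).

    Magnitude is reported in dB (20 log10 |Z|) with the linear magnitude
    kept alongside; phase is unwrapped along the grid and reported in
    degrees.  Singular grid points are masked (NaN) and flagged via
    ``valid`` without failing the whole curve.
    """
    if step_hz <= 0 or f_max_hz < f_min_hz:
        raise ValueError("invalid Bode grid")
    freqs = np.arange(f_min_hz, f_max_hz + step_hz / 2, step_hz)
    z = np.full(freqs.size, np.nan + 0j)
    valid = np.zeros(freqs.size, dtype=bool)
    for i, f in enumerate(freqs):
        try:
            z[i] = evaluate(tf, 2j * math.pi * f)
            valid[i] = True
        except SingularityError:
            pass
    mag = np.abs(z)
    mag_db = 20 * np.log10(mag)
    phase = np.full(freqs.size, np.nan)
    if valid.any():
        phase[valid] = np.degrees(np.unwrap(np.angle(z[valid])))
    return BodeCurve(
        frequencies_hz=freqs,
        magnitude_db=mag_db,
        phase_deg=phase,
        magnitude=mag,
        valid=valid,
    )


def composite_bode(curves) -> BodeCurve:
    """Pointwise arithmetic mean of Bode curves on a common grid.

    Magnitude (dB) and phase (degrees) are averaged separately; at each
    grid point, masked values are excluded pairwise from the mean.
    """
    curves = list(curves)
    if not curves:
        raise ValueError("composite_bode requires at least one curve")
    grid = curves[0].frequencies_hz
    for c in curves[1:]:
        if c.frequencies_hz.size != grid.size or not np.allclose(
            c.frequencies_hz, grid
        ):
            raise ValueError("all curves must share the same frequency grid")
    mags = np.vstack([c.magnitude_db for c in curves])
    phases = np.vstack([c.phase_deg for c in curves])
    valid = np.vstack([c.valid for c in curves])
    counts = valid.sum(axis=0)
    with np.errstate(invalid="ignore"):
        mean_mag = np.where(
            counts > 0, np.nansum(np.where(valid, mags, 0.0), axis=0) / np.maximum(counts, 1), np.nan
        )
        mean_phase = np.where(
            counts > 0, np.nansum(np.where(valid, phases, 0.0), axis=0) / np.maximum(counts, 1), np.nan
        )
    return BodeCurve(
        frequencies_hz=grid.copy(),
        magnitude_db=mean_mag,
        phase_deg=mean_phase,
        magnitude=10 ** (mean_mag / 20),
        valid=counts > 0,
    )
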