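"""Synthetic test signals with known ground truth.

Two generators: exact damped-sinusoid sums (the Prony model's own
generative form, for recovery tests) and pulsatile pressure/volume
waveforms emulating 1 s, 1000 Hz left-ventricular catheterization records
at a rodent heart rate (default 420 bpm, fundamental 7 Hz).

The pressure/volume morphology is a harmonic synthesis — a DC offset plus
``n_harmonics`` cosines at multiples of the heart-rate fundamental with
decaying amplitudes — rather than a mechanistic elastance model.  That
keeps every noiseless waveform exactly representable by a modest Prony
model (2*n_harmonics + 1 poles), so fits against it have closed-form
ground truth, while still producing a realistic pulsatile spectrum whose
power peaks at the heart rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .prony import PronyComponent, Signal

__all__ = [
    "PVSimConfig",
    "SCENARIOS",
    "make_damped_sinusoids",
    "make_pv_waveforms",
    "perturb_to_shock",
    "scenario_config",
]

#: Named (contractility_scale, volume_scale) presets for group-structure
#: smoke tests: shock narrows both the developed pressure and the stroke
#: volume; resuscitation restores them most of the way.
SCENARIOS = {
    "baseline": (1.0, 1.0),
    "shock": (0.55, 0.5),
    "resuscitation": (0.9, 0.85),
}


@dataclass(frozen=True)
class PVSimConfig:
    """Configuration of the synthetic pressure/volume generator.

    Defaults emulate a rat left-ventricular record: 420 bpm, 1 s at
    1000 Hz, pressure spanning 8-120 mmHg and volume 200-400 uL.
    """

    heart_rate_bpm: float = 420.0
    sampling_rate: float = 1000.0
    duration: float = 1.0
    n_harmonics: int = 6
    systolic_pressure: float = 120.0
    diastolic_pressure: float = 8.0
    end_diastolic_volume: float = 400.0
    end_systolic_volume: float = 200.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.heart_rate_bpm <= 0 or self.sampling_rate <= 0:
            raise ValueError("heart rate and sampling rate must be positive")
        if self.n_harmonics < 2:
            raise ValueError("n_harmonics must be >= 2")
        if self.systolic_pressure <= self.diastolic_pressure:
            raise ValueError("systolic pressure must exceed diastolic")
        if self.end_diastolic_volume <= self.end_systolic_volume:
            raise ValueError("end-diastolic volume must exceed end-systolic")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.duration * self.sampling_rate < 4:
            raise ValueError("duration x sampling_rate must be >= 4")

    @property
    def fundamental_hz(self) -> float:
        return self.heart_rate_bpm / 60.0


def make_damped_sinusoids(
    components, sampling_rate: float, duration: float
) -> tuple[Signal, tuple[PronyComponent, ...]]:
    """Exact sum of damped cosines with physical-unit parameters.

    Returns the sampled signal together with the generating components
    (the ground truth record) for recovery tests.
    """
    components = tuple(components)
    if not components:
        raise ValueError("at least one component is required")
    m = int(round(duration * sampling_rate))
    t = np.arange(m) / sampling_rate
    y = np.zeros(m)
    for c in components:
        y += c.amplitude * np.exp(c.damping * t) * np.cos(
            2 * math.pi * c.frequency * t + c.phase
        )
    return Signal(samples=y, sampling_rate=sampling_rate, label="damped_sinusoids"), components


def _harmonic_shape(
    t: np.ndarray, f0: float, n_harmonics: int, peak_time: float, decay: float
) -> np.ndarray:
    """sum_k k^-decay cos(2 pi k f0 (t - peak_time)): a pulse peaking at
    peak_time each cycle, sharper for smaller decay."""
    u = np.zeros_like(t)
    for k in range(1, n_harmonics + 1):
        u += k**-decay * np.cos(2 * math.pi * k * f0 * (t - peak_time))
    return u


def make_pv_waveforms(
    config: PVSimConfig,
) -> tuple[Signal, Signal, dict]:
    """Pulsatile pressure and volume waveforms plus their ground truth.

    Pressure is a harmonic pulse (amplitude decay 1/k) normalised to span
    [diastolic, systolic]; volume is a smoother pulse (decay 1/k^2) peaking
    half a cycle later — the ventricle is fullest just before ejection and
    emptiest after the pressure peak — normalised to [ESV, EDV].  Optional
    white Gaussian noise is added from a single seeded generator, so equal
    seeds give bitwise-identical output.

    The ground-truth dict records, per signal, the affine mapping and the
    exact cosine components (frequency k*f0, amplitude, phase) of the
    noiseless waveform.
    """
    f0 = config.fundamental_hz
    m = int(round(config.duration * config.sampling_rate))
    t = np.arange(m) / config.sampling_rate
    period = 1.0 / f0

    def shaped(peak_time, decay, lo, hi, label):
        u = _harmonic_shape(t, f0, config.n_harmonics, peak_time, decay)
        umin, umax = u.min(), u.max()
        scale = (hi - lo) / (umax - umin)
        offset = lo - scale * umin
        y = offset + scale * u
        comps = tuple(
            PronyComponent(
                amplitude=scale * k**-decay,
                damping=0.0,
                frequency=k * f0,
                phase=-2 * math.pi * k * f0 * peak_time,
            )
            for k in range(1, config.n_harmonics + 1)
        )
        truth = {
            "label": label,
            "mean_term": offset,
            "components": comps,
            "fundamental_hz": f0,
        }
        return y, truth

    p_peak = 0.3 * period
    y_p, truth_p = shaped(
        p_peak, 1.0, config.diastolic_pressure, config.systolic_pressure, "pressure"
    )
    y_v, truth_v = shaped(
        p_peak + 0.5 * period,
        2.0,
        config.end_systolic_volume,
        config.end_diastolic_volume,
        "volume",
    )

    rng = np.random.default_rng(config.seed)
    if config.noise_sd > 0:
        y_p = y_p + rng.normal(0.0, config.noise_sd, m)
        y_v = y_v + rng.normal(0.0, config.noise_sd, m)

    pressure = Signal(samples=y_p, sampling_rate=config.sampling_rate, label="pressure")
    volume = Signal(samples=y_v, sampling_rate=config.sampling_rate, label="volume")
    truth = {"pressure": truth_p, "volume": truth_v, "config": config}
    return pressure, volume, truth


def perturb_to_shock(
    config: PVSimConfig, contractility_scale: float, volume_scale: float
) -> PVSimConfig:
    """Derived config with scaled developed pressure and stroke volume.

    The pressure span (systolic - diastolic) is multiplied by
    ``contractility_scale`` about the diastolic floor, and the volume span
    (EDV - ESV) by ``volume_scale`` about ESV.
    """
    if contractility_scale <= 0 or volume_scale <= 0:
        raise ValueError("scales must be positive")
    new_sys = config.diastolic_pressure + contractility_scale * (
        config.systolic_pressure - config.diastolic_pressure
    )
    new_edv = config.end_systolic_volume + volume_scale * (
        config.end_diastolic_volume - config.end_systolic_volume
    )
    return replace(config, systolic_pressure=new_sys, end_diastolic_volume=new_edv)


def scenario_config(config: PVSimConfig, scenario: str, *, seed: int | None = None) -> PVSimConfig:
    """Apply a named scenario preset (see SCENARIOS), optionally reseeding."""
    try:
        cs, vs = SCENARIOS[scenario]
    except KeyError:
        raise ValueError(f"unknown scenario {scenario!r}; choose from {sorted(SCENARIOS)}")
    out = perturb_to_shock(config, cs, vs)
    if seed is not None:
        out = replace(out, seed=seed)
    return out
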