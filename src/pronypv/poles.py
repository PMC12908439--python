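"""Complex-pole stability analysis and pole-diagram metrics.

A pole mu = exp(sigma + 2j*pi*f) is stable when |mu| <= 1 (sigma <= 0): its
component does not grow in time.  Poles exactly on the unit circle are
undamped cosines, so a pole set confined to the unit circle is a Fourier
series; deviation from the circle measures damping content.  The metrics
here summarise a fitted pole diagram: importance weights alpha_i =
|C_i|/max|C_i|, the importance-weighted mean pole angle, the dispersion
1/std(|C_i|), and two unit-circle deviation measures (mean distance of the
five farthest poles, and the count at least 0.2 radial units away).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .prony import PronyModel, Signal, fit_coefficients, evaluate_model, r_squared

__all__ = [
    "PoleMetrics",
    "PoleRatios",
    "STABILITY_TOL",
    "OFF_CIRCLE_THRESHOLD",
    "classify_poles",
    "stable_refit",
    "pole_metrics",
    "pole_ratio",
]

#: Numerical slack on the unit-circle boundary when classifying stability:
#: a pole at |mu| = 1 is stable, and poles of fitted undamped cosines land
#: within roughly 1e-11 of the circle (companion-eigenvalue float error), so
#: the boundary carries a small outward tolerance.  At 1000 Hz this admits
#: per-second growth rates below ~1e-6/s as "stable", far under anything a
#: physiological signal resolves.
STABILITY_TOL = 1e-9

#: Default radial distance from the unit circle beyond which a pole counts
#: as "off the circle" (significant damping), in either direction.
OFF_CIRCLE_THRESHOLD = 0.2


@dataclass(frozen=True)
class PoleMetrics:
    """Per-signal pole-diagram summary."""

    importance: np.ndarray  # alpha_i in [0, 1], max = 1
    mean_angle_deg: float
    dispersion: float  # 1 / std(|C_i|), +inf if all equal (flagged)
    top5_mean_distance: float
    n_off_unit_circle: int
    n_stable: int
    n_unstable: int
    dispersion_infinite: bool = False
    fewer_than_five: bool = False


@dataclass(frozen=True)
class PoleRatios:
    """Pressure/volume ratios of the unit-circle deviation metrics."""

    top5_distance: float
    off_circle: float


def classify_poles(model: PronyModel, *, tol: float = STABILITY_TOL) -> np.ndarray:
    """Boolean stability mask: pole i stable iff |mu_i| <= 1 (+ tol)."""
    return np.abs(model.poles) <= 1.0 + tol


def stable_refit(signal: Signal, model: PronyModel) -> PronyModel:
    """Refit keeping only the stable poles of an existing model.

    The stable pole subset is retained and the complex coefficients are
    re-solved against the original signal at the model's scale d.  The
    returned model carries the new R^2; the number of removed poles is
    ``model.n_components - refit.n_components``.

    Raises
    ------
    ValueError
        If the model has no stable pole.
    """
    mask = classify_poles(model)
    if not mask.any():
        raise ValueError("model has no stable poles; nothing to refit")
    kept = model.poles[mask]
    coeffs = fit_coefficients(signal, kept, model.scale_d)
    order = np.lexsort((np.angle(kept), -np.abs(coeffs)))
    refit = PronyModel(
        poles=kept[order],
        coefficients=coeffs[order],
        n_components=int(mask.sum()),
        scale_d=model.scale_d,
        sampling_rate=model.sampling_rate,
        source_length=model.source_length,
        label=model.label,
    )
    recon = evaluate_model(refit, np.arange(len(signal)))
    refit.r_squared = r_squared(signal.samples, recon)
    return refit


def pole_metrics(
    model: PronyModel,
    subset: str = "all",
    *,
    threshold: float = OFF_CIRCLE_THRESHOLD,
    as_printed: bool = False,
) -> PoleMetrics:
    """Pole-diagram metrics over all poles or the stable subset.

    alpha_i = |C_i| / max|C_i|; theta_i is the principal pole angle in
    degrees.  The mean angle is the importance-weighted mean
    sum(alpha_i * theta_i) / sum(alpha_i); ``as_printed=True`` swaps the
    denominator for sum(theta_i).  Dispersion is 1/s with s the (n-1)
    standard deviation of the raw |C_i| (+inf when all weights are equal).
    distance_i = ||mu_i| - 1|; the top-5 mean distance averages the five
    largest (all of them when fewer than five poles, flagged), and
    n_off_unit_circle counts distance_i >= threshold.
    """
    if subset not in {"all", "stable_only"}:
        raise ValueError("subset must be 'all' or 'stable_only'")
    if model.n_components < 1:
        raise ValueError("model has no components")
    stable = classify_poles(model)
    keep = stable if subset == "stable_only" else np.ones(len(stable), bool)
    if not keep.any():
        raise ValueError(f"subset {subset!r} selects no poles")
    mu = model.poles[keep]
    cmag = np.abs(model.coefficients[keep])

    alpha = cmag / cmag.max() if cmag.max() > 0 else np.ones_like(cmag)
    theta = np.degrees(np.angle(mu))
    denom = theta.sum() if as_printed else alpha.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        mean_angle = float(np.sum(alpha * theta) / denom) if denom != 0 else math.inf

    if cmag.size >= 2:
        s = float(np.std(cmag, ddof=1))
    else:
        s = 0.0
    infinite = s == 0.0
    if infinite:
        warnings.warn(
            "all coefficient magnitudes equal: dispersion is infinite",
            RuntimeWarning,
            stacklevel=2,
        )
    dispersion = math.inf if infinite else 1.0 / s

    dist = np.abs(np.abs(mu) - 1.0)
    few = dist.size < 5
    top5 = float(np.mean(np.sort(dist)[-5:])) if not few else float(np.mean(dist))
    n_off = int(np.count_nonzero(dist >= threshold))

    return PoleMetrics(
        importance=alpha,
        mean_angle_deg=mean_angle,
        dispersion=dispersion,
        top5_mean_distance=top5,
        n_off_unit_circle=n_off,
        n_stable=int(stable.sum()),
        n_unstable=int((~stable).sum()),
        dispersion_infinite=infinite,
        fewer_than_five=few,
    )


def pole_ratio(metrics_pressure: PoleMetrics, metrics_volume: PoleMetrics) -> PoleRatios:
    """Pressure/volume ratio of both unit-circle deviation metrics.

    Raises
    ------
    ZeroDivisionError
        If either volume-side denominator is zero.
    """
    if metrics_volume.top5_mean_distance == 0:
        raise ZeroDivisionError("volume top-5 distance is zero; ratio undefined")
    if metrics_volume.n_off_unit_circle == 0:
        raise ZeroDivisionError("volume off-circle count is zero; ratio undefined")
    return PoleRatios(
        top5_distance=metrics_pressure.top5_mean_distance
        / metrics_volume.top5_mean_distance,
        off_circle=metrics_pressure.n_off_unit_circle
        / metrics_volume.n_off_unit_circle,
    )
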