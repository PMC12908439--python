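"""Prony decomposition of uniformly sampled signals.

The Prony method fits an evenly sampled real signal ``y(t_k)`` to a sum of
exponentially damped sinusoids

    y(t_k) = sum_i A_i * exp(sigma_i * t_k) * cos(2*pi*f_i*t_k + phi_i)

by (1) solving a linear-prediction (Hankel) system for the coefficients of
the signal's characteristic polynomial, (2) rooting that polynomial via its
companion matrix to obtain the complex poles ``mu_i = exp(sigma_i +
2j*pi*f_i)``, and (3) solving a Vandermonde least-squares problem for the
complex amplitudes ``C_i = A_i * exp(1j*phi_i)``.

High sampling rates make the Vandermonde system severely ill-conditioned, so
the sample index is rescaled by a factor ``d`` (the basis becomes
``mu_i ** (k/d)``) and ``d`` is chosen to maximise the coefficient of
determination R^2 between the reconstruction and the raw signal.  Fitted
damping/frequency values are per *scaled* time unit; multiply by ``SR/d``
to convert to 1/s and Hz.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg as sla

__all__ = [
    "Signal",
    "LinearPrediction",
    "PronyComponent",
    "PronyModel",
    "ConvergenceError",
    "solve_linear_prediction",
    "poles_from_lp",
    "fit_coefficients",
    "components_from_poles",
    "physical_components",
    "evaluate_model",
    "r_squared",
    "optimize_scale",
    "prony_fit",
]

logger = logging.getLogger("pronypv")

#: Relative singular-value cutoff for the truncated pseudoinverse used in the
#: Vandermonde coefficient solve.  Singular values below this fraction of the
#: largest are discarded.
PINV_CUTOFF = 1e-13

#: Number of logarithmically spaced candidate scale factors in the coarse
#: grid of :func:`optimize_scale`.
D_GRID_POINTS = 25

#: Coarse d-grid size used *per candidate N* during the auto-N search of
#: :func:`prony_fit`; the winning N gets the full golden-section refinement.
D_GRID_POINTS_COARSE = 5

#: Relative convergence tolerance on d for the golden-section refinement.
D_REFINE_TOL = 1e-10

GOLDEN = (math.sqrt(5.0) - 1.0) / 2.0


class ConvergenceError(RuntimeError):
    """Raised when no candidate time-scale factor yields a finite fit."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Signal:
    """A uniformly sampled real time series.

    Parameters
    ----------
    samples
        Real, finite sample values in signal units (e.g. mmHg or uL).
    sampling_rate
        Samples per second (Hz), strictly positive.
    label
        Free-text name, e.g. ``"pressure"``.
    t0
        Time of the first sample in seconds.  Samples sit implicitly at
        ``t_k = t0 + k / sampling_rate``.
    """

    samples: np.ndarray
    sampling_rate: float
    label: str = ""
    t0: float = 0.0

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim != 1 or samples.size < 4:
            raise ValueError("signal must be 1-D with at least 4 samples")
        if not np.all(np.isfinite(samples)):
            raise ValueError("signal samples must all be finite")
        if not (self.sampling_rate > 0 and np.isfinite(self.sampling_rate)):
            raise ValueError("sampling_rate must be positive and finite")
        object.__setattr__(self, "samples", samples)

    def __len__(self) -> int:
        return self.samples.size

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds."""
        return self.t0 + np.arange(len(self)) / self.sampling_rate

    @property
    def duration(self) -> float:
        """Record length in seconds (M / SR)."""
        return len(self) / self.sampling_rate


@dataclass(frozen=True)
class LinearPrediction:
    """Linear-prediction coefficients a_0..a_{N-1} of the Hankel system."""

    coefficients: np.ndarray
    n_poles: int
    residual_norm: float = 0.0

    def __post_init__(self) -> None:
        coeffs = np.asarray(self.coefficients, dtype=float)
        if coeffs.size != self.n_poles:
            raise ValueError("coefficient count must equal n_poles")
        object.__setattr__(self, "coefficients", coeffs)


@dataclass(frozen=True)
class PronyComponent:
    """One damped sinusoid ``A * exp(sigma*t) * cos(2*pi*f*t + phi)``.

    Units of ``damping`` and ``frequency`` depend on context: per scaled
    time unit straight out of a fit, or 1/s and Hz after conversion by
    ``SR/d`` (see :func:`physical_components`).
    """

    amplitude: float
    damping: float
    frequency: float
    phase: float

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")
        phase = self.phase
        if np.isfinite(phase) and not (-math.pi < phase <= math.pi):
            phase = math.atan2(math.sin(phase), math.cos(phase))
            if phase <= -math.pi:  # atan2 returns [-pi, pi]
                phase = math.pi
            object.__setattr__(self, "phase", phase)


@dataclass
class PronyModel:
    """Fitted Prony series: poles mu_i, complex coefficients C_i, scale d.

    The reconstruction is ``y_k = Re sum_i C_i * mu_i ** (k/d)``.  Poles are
    ordered by descending coefficient magnitude (importance), ties broken by
    ascending pole phase, so "top-k" selections are deterministic.
    """

    poles: np.ndarray
    coefficients: np.ndarray
    n_components: int
    scale_d: float
    sampling_rate: float
    source_length: int
    r_squared: float | None = None
    label: str = ""
    imag_residual: float = field(default=0.0, compare=False)

    def __post_init__(self) -> None:
        poles = np.asarray(self.poles, dtype=complex)
        coeffs = np.asarray(self.coefficients, dtype=complex)
        if poles.size != coeffs.size or poles.size != self.n_components:
            raise ValueError("poles and coefficients must both have length N")
        if self.n_components > self.source_length // 2:
            raise ValueError(
                f"N={self.n_components} exceeds floor(M/2)="
                f"{self.source_length // 2}"
            )
        if not self.scale_d > 0:
            raise ValueError("scale_d must be positive")
        self.poles = poles
        self.coefficients = coeffs


# ---------------------------------------------------------------------------
# Linear prediction (Hankel system)
# ---------------------------------------------------------------------------


def solve_linear_prediction(signal: Signal, n_poles: int) -> LinearPrediction:
    """Solve the linear-prediction Hankel system for a signal.

    Each sample ``y_l`` (l >= N) is modelled as a linear combination of the
    N preceding samples; stacking all such rows gives an (M-N) x N Hankel
    system solved here in the least-squares sense.

    Raises
    ------
    ValueError
        If ``n_poles`` is outside ``[1, floor(M/2)]``.
    """
    y = signal.samples
    m = y.size
    n = int(n_poles)
    if not 1 <= n <= m // 2:
        raise ValueError(f"n_poles must be in [1, {m // 2}], got {n_poles}")
    # Row l (l = N..M-1): y_l = sum_j a_j * y_{l-1-j}
    hankel = sla.hankel(y[: m - n], y[m - n - 1 : m - 1])[:, ::-1]
    rhs = y[n:]
    a, _, rank, _ = sla.lstsq(hankel, rhs, lapack_driver="gelsd")
    if rank < n:
        warnings.warn(
            f"linear-prediction system is numerically singular "
            f"(rank {rank} < {n}); using minimum-norm least squares",
            RuntimeWarning,
            stacklevel=2,
        )
    residual = float(np.linalg.norm(hankel @ a - rhs))
    return LinearPrediction(coefficients=a, n_poles=n, residual_norm=residual)


def poles_from_lp(lp: LinearPrediction) -> np.ndarray:
    """Roots of the monic characteristic polynomial of the LP coefficients.

    The polynomial is ``x^N - a_0 x^{N-1} - ... - a_{N-1}``; roots are
    computed from its companion matrix and returned sorted by descending
    magnitude, ties by ascending phase.
    """
    a = np.asarray(lp.coefficients, dtype=float)
    if a.size < 1:
        raise ValueError("linear prediction must have at least one coefficient")
    poly = np.concatenate(([1.0], -a))
    roots = np.roots(poly)
    # pad with zero roots if leading coefficients vanish (np.roots drops them)
    if roots.size < a.size:
        roots = np.concatenate([roots, np.zeros(a.size - roots.size, complex)])
    order = np.lexsort((np.angle(roots), -np.abs(roots)))
    return roots[order]


# ---------------------------------------------------------------------------
# Vandermonde coefficient solve
# ---------------------------------------------------------------------------


def _power_matrix(poles: np.ndarray, tau: np.ndarray) -> np.ndarray:
    """V[k, i] = poles[i] ** tau[k] via the principal complex logarithm.

    A pole exactly at zero contributes the column ``0**tau`` (1 at tau=0,
    0 elsewhere).
    """
    poles = np.asarray(poles, dtype=complex)
    tau = np.asarray(tau, dtype=float)
    out = np.empty((tau.size, poles.size), dtype=complex)
    zero = poles == 0
    if np.any(~zero):
        with np.errstate(over="ignore", invalid="ignore"):
            out[:, ~zero] = np.exp(np.outer(tau, np.log(poles[~zero])))
    if np.any(zero):
        col = np.where(tau == 0, 1.0 + 0j, 0.0 + 0j)
        out[:, zero] = col[:, None]
    return out


def _solve_coefficients(
    vmat: np.ndarray, y: np.ndarray, cutoff: float, driver: str
) -> np.ndarray | None:
    """Truncated least-squares solve; None if the basis is non-finite."""
    if not np.all(np.isfinite(vmat)):
        return None
    c, _, _, _ = sla.lstsq(vmat, y.astype(complex), cond=cutoff, lapack_driver=driver)
    return c


def fit_coefficients(
    signal: Signal,
    poles,
    scale_d: float,
    *,
    cutoff: float = PINV_CUTOFF,
) -> np.ndarray:
    """Complex amplitudes C minimising ||y - V C|| for given poles.

    ``V[k, i] = mu_i ** (k / scale_d)``; the system is solved with an
    SVD-truncated pseudoinverse (relative singular-value cutoff
    ``cutoff``), which also handles rank-deficient Vandermonde bases.
    """
    poles = np.asarray(poles, dtype=complex)
    if poles.size == 0:
        raise ValueError("pole list must not be empty")
    if not scale_d > 0:
        raise ValueError("scale_d must be positive")
    tau = np.arange(len(signal)) / float(scale_d)
    vmat = _power_matrix(poles, tau)
    c = _solve_coefficients(vmat, signal.samples, cutoff, "gelsd")
    if c is None:
        raise ConvergenceError(
            f"Vandermonde basis overflows at scale_d={scale_d}; "
            "increase scale_d"
        )
    return c


# ---------------------------------------------------------------------------
# Component extraction
# ---------------------------------------------------------------------------


def components_from_poles(poles, coefficients) -> list[PronyComponent]:
    """Per-pole damped-sinusoid parameters in scaled time units.

    damping = ln|mu|, frequency = arg(mu)/2pi (cycles per scaled unit),
    amplitude = |C|, phase = arg(C).  A pole at zero yields damping -inf
    (flagged with a warning, component retained).
    """
    poles = np.asarray(poles, dtype=complex)
    coefficients = np.asarray(coefficients, dtype=complex)
    if poles.size != coefficients.size:
        raise ValueError("poles and coefficients must have equal length")
    mags = np.abs(poles)
    if np.any(mags == 0):
        warnings.warn(
            "pole at the origin: damping is -inf", RuntimeWarning, stacklevel=2
        )
    with np.errstate(divide="ignore"):
        sigma = np.log(mags)
    freq = np.angle(poles) / (2 * math.pi)
    return [
        PronyComponent(
            amplitude=float(abs(c)),
            damping=float(s),
            frequency=float(f),
            phase=float(np.angle(c)),
        )
        for s, f, c in zip(sigma, freq, coefficients)
    ]


def _conjugate_pairs(poles: np.ndarray, atol: float = 1e-8):
    """Greedily pair each pole of positive imaginary part with its conjugate.

    Returns (pairs, singles): pairs as (i_pos, i_neg) index tuples and
    singles as leftover indices (real poles or unmatched strays).
    """
    poles = np.asarray(poles, dtype=complex)
    n = poles.size
    used = np.zeros(n, dtype=bool)
    pairs: list[tuple[int, int]] = []
    singles: list[int] = []
    pos = [i for i in range(n) if poles[i].imag > atol * (1 + abs(poles[i]))]
    neg = [i for i in range(n) if poles[i].imag < -atol * (1 + abs(poles[i]))]
    for i in pos:
        best, best_d = -1, np.inf
        for j in neg:
            if used[j]:
                continue
            dist = abs(poles[j] - np.conj(poles[i]))
            if dist < best_d:
                best, best_d = j, dist
        if best >= 0 and best_d <= atol * (1 + abs(poles[i])):
            used[i] = used[best] = True
            pairs.append((i, best))
    singles = [i for i in range(n) if not used[i]]
    return pairs, singles


def physical_components(
    model: PronyModel, *, fold: bool = True
) -> list[PronyComponent]:
    """Components in physical units: damping in 1/s, frequency in Hz.

    Scaled-unit parameters are multiplied by ``SR / d``.  With ``fold=True``
    conjugate pole pairs are merged into one real cosine component with
    f >= 0 and amplitude ``2|C|`` (so a fitted unit cosine reports amplitude
    1); unpaired (real-axis) poles keep amplitude ``|C|``.
    """
    factor = model.sampling_rate / model.scale_d
    raw = components_from_poles(model.poles, model.coefficients)
    if not fold:
        return [
            PronyComponent(c.amplitude, c.damping * factor, c.frequency * factor, c.phase)
            for c in raw
        ]
    pairs, singles = _conjugate_pairs(model.poles)
    out: list[PronyComponent] = []
    for i_pos, _ in pairs:
        c = raw[i_pos]
        out.append(
            PronyComponent(2 * c.amplitude, c.damping * factor, c.frequency * factor, c.phase)
        )
    for i in singles:
        c = raw[i]
        out.append(
            PronyComponent(c.amplitude, c.damping * factor, abs(c.frequency) * factor, c.phase)
        )
    out.sort(key=lambda c: (-c.amplitude, c.frequency))
    return out


# ---------------------------------------------------------------------------
# Model evaluation and goodness of fit
# ---------------------------------------------------------------------------


def evaluate_model(model: PronyModel, sample_indices) -> np.ndarray:
    """Real part of ``sum_i C_i mu_i**(k/d)`` at the given sample indices.

    The magnitude of the discarded imaginary part is recorded on
    ``model.imag_residual`` (max over the evaluated points).
    """
    idx = np.asarray(sample_indices, dtype=float)
    if model.n_components == 0:
        model.imag_residual = 0.0
        return np.zeros(idx.size)
    tau = idx / model.scale_d
    vals = _power_matrix(model.poles, tau) @ model.coefficients
    model.imag_residual = float(np.max(np.abs(vals.imag), initial=0.0))
    return vals.real


def r_squared(observed, fitted) -> float:
    """Coefficient of determination 1 - SS_res / SS_tot (may be negative)."""
    obs = np.asarray(observed, dtype=float)
    fit = np.asarray(fitted, dtype=float)
    if obs.size != fit.size or obs.size < 2:
        raise ValueError("observed and fitted must have equal length >= 2")
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("R^2 is undefined for a constant observed signal")
    ss_res = float(np.sum((obs - fit) ** 2))
    return 1.0 - ss_res / ss_tot


# ---------------------------------------------------------------------------
# Scale-factor optimisation and the end-to-end fit
# ---------------------------------------------------------------------------


def _score_scale(
    y: np.ndarray, poles: np.ndarray, d: float, cutoff: float, driver: str
) -> tuple[float, np.ndarray | None]:
    """R^2 of the coefficient fit at scale d; (-inf, None) if non-finite."""
    tau = np.arange(y.size) / d
    vmat = _power_matrix(poles, tau)
    c = _solve_coefficients(vmat, y, cutoff, driver)
    if c is None:
        return -np.inf, None
    recon = (vmat @ c).real
    if not np.all(np.isfinite(recon)):
        return -np.inf, None
    try:
        r2 = r_squared(y, recon)
    except ValueError:
        return -np.inf, None
    return (r2, c) if np.isfinite(r2) else (-np.inf, None)


def _refine_scale(
    y: np.ndarray,
    poles: np.ndarray,
    log_lo: float,
    log_hi: float,
    best: tuple[float, float],
    cutoff: float,
    driver: str,
) -> tuple[float, float]:
    """Golden-section ascent of R^2 over log10(d) in [log_lo, log_hi].

    ``best`` is the incumbent (d, r2); the better of incumbent and refined
    point is returned, so refinement never loses ground.
    """
    a, b = log_lo, log_hi
    x1 = b - GOLDEN * (b - a)
    x2 = a + GOLDEN * (b - a)
    f1, _ = _score_scale(y, poles, 10**x1, cutoff, driver)
    f2, _ = _score_scale(y, poles, 10**x2, cutoff, driver)
    best_d, best_r2 = best
    for _ in range(80):
        if b - a <= D_REFINE_TOL * max(1.0, abs(a)):
            break
        if f1 >= f2:
            b, x2, f2 = x2, x1, f1
            x1 = b - GOLDEN * (b - a)
            f1, _ = _score_scale(y, poles, 10**x1, cutoff, driver)
        else:
            a, x1, f1 = x1, x2, f2
            x2 = a + GOLDEN * (b - a)
            f2, _ = _score_scale(y, poles, 10**x2, cutoff, driver)
        for x, fx in ((x1, f1), (x2, f2)):
            if fx > best_r2:
                best_d, best_r2 = 10**x, fx
    return best_d, best_r2


def optimize_scale(
    signal: Signal,
    n_poles: int,
    *,
    grid_points: int = D_GRID_POINTS,
    cutoff: float = PINV_CUTOFF,
) -> float:
    """Time-scale factor d maximising R^2 of the full Prony fit.

    A ``grid_points``-point logarithmic grid of d over [1, SR] is scanned,
    then the bracket around the grid maximum is refined by golden-section
    search.  Deterministic and derivative-free.

    Raises
    ------
    ConvergenceError
        If every candidate d yields a non-finite R^2; the message names the
        best attempted d.
    """
    poles = poles_from_lp(solve_linear_prediction(signal, n_poles))
    y = signal.samples
    grid = np.logspace(0.0, math.log10(signal.sampling_rate), grid_points)
    scores = [_score_scale(y, poles, d, cutoff, "gelsy")[0] for d in grid]
    k = int(np.argmax(scores))
    if not np.isfinite(scores[k]):
        raise ConvergenceError(
            f"no finite R^2 over d grid [1, {signal.sampling_rate}]; "
            f"best attempt d={grid[k]:.6g}"
        )
    lo = math.log10(grid[max(k - 1, 0)])
    hi = math.log10(grid[min(k + 1, grid.size - 1)])
    best_d, _ = _refine_scale(
        y, poles, lo, hi, (float(grid[k]), scores[k]), cutoff, "gelsy"
    )
    return float(best_d)


def _order_by_importance(poles: np.ndarray, coeffs: np.ndarray):
    order = np.lexsort((np.angle(poles), -np.abs(coeffs)))
    return poles[order], coeffs[order]


def _candidate_n_grid(m: int) -> list[int]:
    """Default auto-N candidates: multiples of floor(M/20) up to floor(M/2)."""
    step = max(1, m // 20)
    grid = list(range(step, m // 2 + 1, step))
    return grid or [1]


def prony_fit(
    signal: Signal,
    n_poles: int | str = "auto",
    scale_d: float | str = "auto",
    *,
    n_grid: list[int] | None = None,
    cutoff: float = PINV_CUTOFF,
) -> PronyModel:
    """End-to-end Prony fit: linear prediction -> poles -> coefficients.

    Parameters
    ----------
    signal
        The sampled signal (M >= 4).
    n_poles
        Model order N, or ``"auto"`` to search ``n_grid`` (default:
        multiples of floor(M/20) capped at floor(M/2)) and keep the
        R^2-maximising order.
    scale_d
        Time-scale factor, or ``"auto"`` to optimise it.  During an auto-N
        search each candidate order is scored on a coarse d grid and the
        winning order receives the full golden-section refinement.
    """
    m = len(signal)
    if m < 4:
        raise ValueError("signal must have at least 4 samples")
    y = signal.samples

    if n_poles == "auto":
        candidates = list(n_grid) if n_grid is not None else _candidate_n_grid(m)
        candidates = [n for n in candidates if 1 <= n <= m // 2]
        if not candidates:
            raise ValueError("auto n_poles grid is empty")
    else:
        candidates = [int(n_poles)]

    auto_d = scale_d == "auto"
    coarse = (
        np.logspace(0.0, math.log10(signal.sampling_rate), D_GRID_POINTS_COARSE)
        if auto_d
        else np.array([float(scale_d)])
    )
    if not auto_d and not float(scale_d) > 0:
        raise ValueError("scale_d must be positive")

    best = None  # (r2, n, d, poles)
    pole_cache: dict[int, np.ndarray] = {}
    for n in candidates:
        poles = poles_from_lp(solve_linear_prediction(signal, n))
        pole_cache[n] = poles
        for d in coarse:
            r2, _ = _score_scale(y, poles, float(d), cutoff, "gelsy")
            logger.debug("auto search: N=%d d=%.6g R2=%.8f", n, d, r2)
            if best is None or r2 > best[0]:
                best = (r2, n, float(d), poles)
    assert best is not None
    r2_best, n_best, d_best, poles = best
    if not np.isfinite(r2_best):
        raise ConvergenceError(
            f"no finite R^2 for any candidate (best attempt N={n_best}, "
            f"d={d_best:.6g})"
        )

    if auto_d:
        # refine d at the winning order over the full 25-point grid + golden
        grid = np.logspace(0.0, math.log10(signal.sampling_rate), D_GRID_POINTS)
        scores = [_score_scale(y, poles, float(d), cutoff, "gelsy")[0] for d in grid]
        k = int(np.argmax(scores))
        if scores[k] > r2_best:
            d_best, r2_best = float(grid[k]), scores[k]
        lo = math.log10(grid[max(k - 1, 0)])
        hi = math.log10(grid[min(k + 1, grid.size - 1)])
        d_best, r2_best = _refine_scale(
            y, poles, lo, hi, (d_best, r2_best), cutoff, "gelsy"
        )

    # final coefficients with the SVD-truncated solve
    tau = np.arange(m) / d_best
    vmat = _power_matrix(poles, tau)
    coeffs = _solve_coefficients(vmat, y, cutoff, "gelsd")
    if coeffs is None:
        raise ConvergenceError(f"basis overflow at final scale d={d_best:.6g}")
    recon = (vmat @ coeffs).real
    r2 = r_squared(y, recon)
    poles_o, coeffs_o = _order_by_importance(poles, coeffs)
    logger.info(
        "prony_fit %s: N=%d d=%.6g R2=%.8f", signal.label or "signal", n_best, d_best, r2
    )
    model = PronyModel(
        poles=poles_o,
        coefficients=coeffs_o,
        n_components=n_best,
        scale_d=d_best,
        sampling_rate=signal.sampling_rate,
        source_length=m,
        r_squared=r2,
        label=signal.label,
    )
    model.imag_residual = float(np.max(np.abs((vmat @ coeffs).imag), initial=0.0))
    return model
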