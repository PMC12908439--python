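"""File formats and the end-to-end pipeline runner.

Signals travel as delimited text (comma or tab) with a ``time_s`` column;
models and transfer functions serialise to JSON with complex numbers as
[re, im] pairs; spectra, component tables, pole tables and Bode curves are
written as TSV, ready for external plotting or statistics tools.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import poles as pole_mod
from . import spectra as spectra_mod
from . import transfer as transfer_mod
from .prony import PronyModel, Signal, physical_components, prony_fit

__all__ = [
    "FormatError",
    "RunConfig",
    "read_timeseries",
    "write_timeseries",
    "model_to_json",
    "model_from_json",
    "components_table",
    "pole_table",
    "spectrum_frame",
    "bode_frame",
    "run_pipeline",
]

logger = logging.getLogger("pronypv")

#: Relative tolerance on the time step when validating uniform sampling.
TIME_STEP_RTOL = 1e-6

TIME_COLUMN = "time_s"


class FormatError(ValueError):
    """A file does not match the expected delimited time-series format."""


# ---------------------------------------------------------------------------
# Time-series files
# ---------------------------------------------------------------------------


def read_timeseries(path, columns=None) -> dict[str, Signal]:
    """Read labelled signals from a delimited text file.

    The file must have a header with a ``time_s`` column; the delimiter
    (comma or tab) is sniffed.  Sampling uniformity is validated against a
    relative step tolerance of 1e-6 and the sampling rate is inferred from
    the median step.

    Returns a dict mapping column name to :class:`Signal`.
    """
    path = Path(path)
    frame = pd.read_csv(path, sep=None, engine="python")
    if TIME_COLUMN not in frame.columns:
        raise FormatError(f"{path}: missing required column {TIME_COLUMN!r}")
    if columns is None:
        columns = [c for c in frame.columns if c != TIME_COLUMN]
    missing = [c for c in columns if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    t = frame[TIME_COLUMN].to_numpy(dtype=float)
    if t.size < 4:
        raise FormatError(f"{path}: need at least 4 rows")
    steps = np.diff(t)
    dt = float(np.median(steps))
    if dt <= 0:
        raise FormatError(f"{path}: time column is not increasing")
    worst = int(np.argmax(np.abs(steps - dt)))
    if abs(steps[worst] - dt) > TIME_STEP_RTOL * dt:
        raise FormatError(
            f"{path}: non-uniform sampling; worst step {steps[worst]:.9g} s at "
            f"row {worst + 1} vs median {dt:.9g} s"
        )
    rate = 1.0 / dt
    return {
        c: Signal(
            samples=frame[c].to_numpy(dtype=float),
            sampling_rate=rate,
            label=c,
            t0=float(t[0]),
        )
        for c in columns
    }


def write_timeseries(path, signals: dict[str, Signal], *, sep: str = "\t") -> None:
    """Write signals sharing a time base to one delimited file."""
    labels = list(signals)
    first = signals[labels[0]]
    data = {TIME_COLUMN: first.times}
    for name in labels:
        sig = signals[name]
        if len(sig) != len(first) or sig.sampling_rate != first.sampling_rate:
            raise ValueError("all signals must share length and sampling rate")
        data[name] = sig.samples
    pd.DataFrame(data).to_csv(path, sep=sep, index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# Model serialisation
# ---------------------------------------------------------------------------


def _complex_list(values) -> list[list[float]]:
    return [[float(v.real), float(v.imag)] for v in np.asarray(values, complex)]


def model_to_json(model: PronyModel) -> dict:
    """JSON-ready dict for a model; complex numbers as [re, im] pairs."""
    return {
        "poles": _complex_list(model.poles),
        "coefficients": _complex_list(model.coefficients),
        "n_components": model.n_components,
        "scale_d": model.scale_d,
        "sampling_rate": model.sampling_rate,
        "source_length": model.source_length,
        "r_squared": model.r_squared,
        "label": model.label,
    }


def model_from_json(payload: dict) -> PronyModel:
    poles = np.array([complex(re, im) for re, im in payload["poles"]])
    coeffs = np.array([complex(re, im) for re, im in payload["coefficients"]])
    return PronyModel(
        poles=poles,
        coefficients=coeffs,
        n_components=payload["n_components"],
        scale_d=payload["scale_d"],
        sampling_rate=payload["sampling_rate"],
        source_length=payload["source_length"],
        r_squared=payload.get("r_squared"),
        label=payload.get("label", ""),
    )


def save_model(path, model: PronyModel) -> None:
    Path(path).write_text(json.dumps(model_to_json(model), indent=1))


def load_model(path) -> PronyModel:
    return model_from_json(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# Tables
# ---------------------------------------------------------------------------


def components_table(model: PronyModel) -> pd.DataFrame:
    """Per-pole component table in physical units with importance weights."""
    comps = physical_components(model, fold=False)
    cmag = np.abs(model.coefficients)
    alpha = cmag / cmag.max() if cmag.size and cmag.max() > 0 else cmag
    return pd.DataFrame(
        {
            "amplitude": [c.amplitude for c in comps],
            "damping_per_s": [c.damping for c in comps],
            "frequency_hz": [c.frequency for c in comps],
            "phase_rad": [c.phase for c in comps],
            "importance": alpha,
        }
    )


def pole_table(model: PronyModel) -> pd.DataFrame:
    """Pole diagram table: location, radius, angle, importance, stability."""
    stable = pole_mod.classify_poles(model)
    cmag = np.abs(model.coefficients)
    alpha = cmag / cmag.max() if cmag.size and cmag.max() > 0 else cmag
    return pd.DataFrame(
        {
            "re": model.poles.real,
            "im": model.poles.imag,
            "radius": np.abs(model.poles),
            "angle_deg": np.degrees(np.angle(model.poles)),
            "importance": alpha,
            "stable": stable,
        }
    )


def spectrum_frame(spectrum: spectra_mod.Spectrum) -> pd.DataFrame:
    return pd.DataFrame(
        {"frequency_hz": spectrum.frequencies, "value": spectrum.values}
    )


def bode_frame(curve: transfer_mod.BodeCurve) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "frequency_hz": curve.frequencies_hz,
            "magnitude_db": curve.magnitude_db,
            "magnitude_linear": curve.magnitude,
            "phase_deg": curve.phase_deg,
        }
    )


def metrics_row(metrics: pole_mod.PoleMetrics) -> dict:
    return {
        "mean_angle_deg": metrics.mean_angle_deg,
        "dispersion": metrics.dispersion,
        "top5_mean_distance": metrics.top5_mean_distance,
        "n_off_unit_circle": metrics.n_off_unit_circle,
        "n_stable": metrics.n_stable,
        "n_unstable": metrics.n_unstable,
        "dispersion_infinite": metrics.dispersion_infinite,
        "fewer_than_five": metrics.fewer_than_five,
    }


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Configuration of the full analysis pipeline."""

    inputs: list  # paths to delimited time-series files
    columns: list[str] | None = None  # signal columns (None = all non-time)
    n_poles: int | str = "auto"
    scale_d: float | str = "auto"
    subset: str = "all"  # pole-metric subset: all | stable_only
    threshold: float = pole_mod.OFF_CIRCLE_THRESHOLD
    bode_grid: tuple[float, float, float] = (1.0, 100.0, 1.0)
    out_dir: str = "pronypv_out"
    pressure_column: str = "pressure_mmHg"
    volume_column: str = "volume_uL"
    as_printed_mean_angle: bool = False

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")
        f_min, f_max, step = self.bode_grid
        if step <= 0 or f_max < f_min:
            raise ValueError("invalid Bode grid")


def _process_signal(sig: Signal, cfg: RunConfig, out: Path, stem: str) -> PronyModel:
    model = prony_fit(sig, cfg.n_poles, cfg.scale_d)
    save_model(out / f"{stem}_{sig.label}_model.json", model)
    components_table(model).to_csv(
        out / f"{stem}_{sig.label}_components.tsv", sep="\t", index=False
    )
    pole_table(model).to_csv(
        out / f"{stem}_{sig.label}_poles.tsv", sep="\t", index=False
    )
    metrics = pole_mod.pole_metrics(
        model,
        cfg.subset,
        threshold=cfg.threshold,
        as_printed=cfg.as_printed_mean_angle,
    )
    (out / f"{stem}_{sig.label}_metrics.json").write_text(
        json.dumps(metrics_row(metrics), indent=1)
    )
    return model


def run_pipeline(config: RunConfig) -> dict:
    """Run the whole analysis for each input file; write results to disk.

    Per input: a Prony model (JSON), component and pole tables (TSV), and
    pole metrics (JSON).  When both the pressure and volume columns are
    present, also the transfer function (JSON) and its Bode curve (TSV).
    Stage failures are logged with the stage name and input label and do
    not stop the remaining inputs.

    Returns a summary dict with per-input results and an ``errors`` list;
    the pipeline failed iff ``errors`` is nonempty.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"inputs": {}, "errors": []}
    for raw_path in config.inputs:
        path = Path(raw_path)
        stem = path.stem
        entry: dict = {}
        summary["inputs"][str(path)] = entry
        try:
            signals = read_timeseries(path, config.columns)
        except Exception as exc:  # noqa: BLE001 - reported, run continues
            logger.error("read %s: %s", path, exc)
            summary["errors"].append(f"read[{path}]: {exc}")
            continue
        models: dict[str, PronyModel] = {}
        for label, sig in signals.items():
            try:
                models[label] = _process_signal(sig, config, out, stem)
                entry[label] = {
                    "r_squared": models[label].r_squared,
                    "n_components": models[label].n_components,
                    "scale_d": models[label].scale_d,
                }
            except Exception as exc:  # noqa: BLE001
                logger.error("fit %s/%s: %s", path, label, exc)
                summary["errors"].append(f"fit[{path}:{label}]: {exc}")
        p, v = config.pressure_column, config.volume_column
        if p in models and v in models:
            try:
                tf = transfer_mod.build_transfer_function(models[p], models[v])
                f_min, f_max, step = config.bode_grid
                curve = transfer_mod.bode(tf, f_min, f_max, step)
                bode_frame(curve).to_csv(
                    out / f"{stem}_bode.tsv", sep="\t", index=False
                )
                tf_payload = {
                    "numerator_components": [
                        [c.amplitude, c.damping, c.frequency, c.phase]
                        for c in tf.numerator_components
                    ],
                    "denominator_components": [
                        [c.amplitude, c.damping, c.frequency, c.phase]
                        for c in tf.denominator_components
                    ],
                    "pressure_poles": _complex_list(tf.pressure_poles),
                    "volume_poles": _complex_list(tf.volume_poles),
                }
                (out / f"{stem}_transfer.json").write_text(
                    json.dumps(tf_payload, indent=1)
                )
                entry["transfer_function"] = True
            except Exception as exc:  # noqa: BLE001
                logger.error("transfer %s: %s", path, exc)
                summary["errors"].append(f"transfer[{path}]: {exc}")
    return summary
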