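import warnings

import numpy as np
import pytest

import pronypv as pv


@pytest.fixture(scope="session")
def pv250():
    """Well-conditioned synthetic PV pair: 1 s at 250 Hz, 420 bpm, noiseless.

    At this rate the waveform's 13 generating poles (6 harmonic pairs plus
    DC) are well separated on the unit circle, so the minimal-order fit is
    exact; models are fitted once for the whole session.
    """
    cfg = pv.PVSimConfig(sampling_rate=250.0)
    pressure, volume, truth = pv.make_pv_waveforms(cfg)
    model_p = pv.prony_fit(pressure, 13, 1.0)
    model_v = pv.prony_fit(volume, 13, 1.0)
    return {
        "config": cfg,
        "pressure": pressure,
        "volume": volume,
        "truth": truth,
        "model_p": model_p,
        "model_v": model_v,
    }


@pytest.fixture(scope="session")
def pressure_1khz():
    """The default-scale noiseless pressure waveform (1 s, 1000 Hz, 420 bpm)."""
    pressure, _, _ = pv.make_pv_waveforms(pv.PVSimConfig())
    return pressure


def conj_closed_pole_set(rng, n_pairs, radius_lo=0.9, radius_hi=1.02):
    """Random conjugate-closed pole set with well-separated angles."""
    angles = np.sort(rng.uniform(0.3, np.pi - 0.3, n_pairs))
    # enforce minimum separation so the recovery problem stays well posed
    angles += np.arange(n_pairs) * 0.05
    radii = rng.uniform(radius_lo, radius_hi, n_pairs)
    upper = radii * np.exp(1j * angles)
    return np.concatenate([upper, np.conj(upper)])


@pytest.fixture(autouse=True)
def _quiet_singular_lp():
    """Rank-deficient LP warnings are expected for low-rank synthetic signals."""
    with warnings.catch_warnings():
        warnings.filterwarnings(
            "ignore", message="linear-prediction system is numerically singular"
        )
        yield
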