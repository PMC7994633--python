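import dataclasses

import numpy as np
import pytest

from noxep.eeg_sim import (
    CHEP_CALIBRATION,
    LEP_CALIBRATION,
    EPOCH_N_SAMPLES,
    SFREQ,
    TRIGGER_INDEX,
    Component,
    EPGroundTruth,
)


@pytest.fixture
def times_ms():
    return (np.arange(EPOCH_N_SAMPLES) - TRIGGER_INDEX) / SFREQ * 1000.0


@pytest.fixture
def noiseless_lep():
    return dataclasses.replace(LEP_CALIBRATION, noise_rms=0.0, latency_jitter_sd=0.0)


@pytest.fixture
def noiseless_chep():
    return dataclasses.replace(CHEP_CALIBRATION, noise_rms=0.0, latency_jitter_sd=0.0)


@pytest.fixture
def separated_truth():
    """Widely separated narrow components: overlap between bumps is below
    double precision, so peak values equal component amplitudes exactly."""
    return EPGroundTruth(
        n1=Component(200.0, -8.0, 15.0),
        n2=Component(600.0, -12.0, 15.0),
        p2=Component(1200.0, 9.0, 15.0),
        latency_jitter_sd=0.0,
        noise_rms=0.0,
    )


def vertex_template(truth: EPGroundTruth, times_ms: np.ndarray) -> np.ndarray:
    """Independent oracle: the noiseless vertex trace as an explicit sum of
    ground-truth Gaussians (N2 + P2 ride on Cz; references are silent)."""
    out = np.zeros_like(times_ms)
    for comp in (truth.n2, truth.p2):
        out += comp.amplitude_uv * np.exp(
            -((times_ms - comp.latency_ms) ** 2) / (2 * comp.width_ms**2)
        )
    return out


def contralateral_template(truth: EPGroundTruth, times_ms: np.ndarray) -> np.ndarray:
    comp = truth.n1
    return comp.amplitude_uv * np.exp(
        -((times_ms - comp.latency_ms) ** 2) / (2 * comp.width_ms**2)
    )
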