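"""Synthetic trigger-locked EEG with known evoked-potential ground truth.

Each evoked component (N1, N2, P2) is a Gaussian bump ``A * exp(-(t - L')^2 /
(2 sigma_w^2))`` with per-trial latency jitter ``L' = L + Normal(0, jitter_sd)``,
injected into the channels that carry it in the standard montage:

* N1 -> the electrode contralateral to the stimulated arm (C4 for left-side
  stimulation, C3 for right), analysed against an Fz reference;
* N2 and P2 -> the vertex electrode Cz, analysed against linked ears (A1/A2).

Reference channels (Fz, A1, A2) carry background noise only by default, so the
montage subtraction leaves component amplitudes intact. The background is
independent 1/f^beta noise per channel, scaled to a target RMS.

Epochs span [-1 s, 2 s) around the trigger at 4000 Hz (12000 samples, t = 0 at
index 4000). Sessions can be produced either as ready-made epoch stacks or as
a continuous multi-channel recording with 8-12 s inter-stimulus intervals,
for exercising the continuous preprocessing path.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

logger = logging.getLogger(__name__)

SFREQ = 4000.0
EPOCH_TMIN = -1.0
EPOCH_TMAX = 2.0  # half-open: [-1, 2)
EPOCH_N_SAMPLES = int(round((EPOCH_TMAX - EPOCH_TMIN) * SFREQ))  # 12000
TRIGGER_INDEX = int(round(-EPOCH_TMIN * SFREQ))  # 4000

DEFAULT_CHANNELS = ("Cz", "C3", "C4", "Fz", "A1", "A2")


@dataclass(frozen=True)
class Component:
    """One Gaussian evoked component: peak latency (ms), peak amplitude (uV),
    and Gaussian width SD (ms)."""

    latency_ms: float
    amplitude_uv: float
    width_ms: float


@dataclass(frozen=True)
class EPGroundTruth:
    """Ground-truth evoked-potential parameters for one session.

    ``noise_rms`` is the per-channel background RMS in uV; ``noise_exponent``
    the 1/f^beta spectral exponent; ``latency_jitter_sd`` the SD (ms) of the
    trial-to-trial latency jitter shared convention across components.
    """

    n1: Component
    n2: Component
    p2: Component
    latency_jitter_sd: float = 10.0
    noise_rms: float = 12.0
    noise_exponent: float = 1.0

    def __post_init__(self) -> None:
        if not (self.n1.latency_ms < self.n2.latency_ms < self.p2.latency_ms):
            raise ValueError("component latencies must be ordered N1 < N2 < P2")
        if self.n1.amplitude_uv >= 0 or self.n2.amplitude_uv >= 0:
            raise ValueError("N1 and N2 amplitudes must be negative")
        if self.p2.amplitude_uv <= 0:
            raise ValueError("P2 amplitude must be positive")
        if self.noise_rms < 0:
            raise ValueError("noise_rms must be >= 0")

    @property
    def n2p2_uv(self) -> float:
        return self.p2.amplitude_uv - self.n2.amplitude_uv


#: Session-mean calibrations for the two stimulation modalities
#: (contact heat vs laser), cohort means. Widths are the generator's own
#: morphology choice: early components are narrower than late ones.
CHEP_CALIBRATION = EPGroundTruth(
    n1=Component(336.0, -3.6, 15.0),
    n2=Component(392.0, -10.6, 25.0),
    p2=Component(494.0, 13.0, 40.0),
)
LEP_CALIBRATION = EPGroundTruth(
    n1=Component(175.0, -7.1, 15.0),
    n2=Component(211.0, -18.9, 25.0),
    p2=Component(322.0, 16.8, 40.0),
)

#: Between-subject SDs matching the calibrations above:
#: {component: (latency_sd_ms, amplitude_sd_uv)}.
CHEP_POPULATION_SD = {"n1": (33.0, 2.5), "n2": (37.0, 6.3), "p2": (49.0, 7.4)}
LEP_POPULATION_SD = {"n1": (23.0, 4.5), "n2": (19.0, 8.6), "p2": (26.0, 7.2)}


def calibration(modality: str) -> EPGroundTruth:
    """Cohort-mean ground truth for ``'chep'`` or ``'lep'``."""
    if modality == "chep":
        return CHEP_CALIBRATION
    if modality == "lep":
        return LEP_CALIBRATION
    raise ValueError(f"unknown modality {modality!r}")


def sample_ground_truth(
    modality: str, rng: np.random.Generator, max_tries: int = 1000
) -> EPGroundTruth:
    """Draw one subject's ground truth from the modality's population.

    Latencies and amplitudes are sampled from Gaussians centred on the
    calibration means with the between-subject SDs; draws violating the
    physiological constraints (latency order, N1/N2 negative by at least
    0.5 uV, P2 positive by at least 0.5 uV) are rejected and redrawn.
    """
    mean = calibration(modality)
    sds = CHEP_POPULATION_SD if modality == "chep" else LEP_POPULATION_SD
    for _ in range(max_tries):
        comps = {}
        for name in ("n1", "n2", "p2"):
            m: Component = getattr(mean, name)
            lat_sd, amp_sd = sds[name]
            comps[name] = Component(
                latency_ms=float(rng.normal(m.latency_ms, lat_sd)),
                amplitude_uv=float(rng.normal(m.amplitude_uv, amp_sd)),
                width_ms=m.width_ms,
            )
        ok = (
            0 < comps["n1"].latency_ms < comps["n2"].latency_ms < comps["p2"].latency_ms
            and comps["n1"].amplitude_uv <= -0.5
            and comps["n2"].amplitude_uv <= -0.5
            and comps["p2"].amplitude_uv >= 0.5
        )
        if ok:
            return replace(mean, **comps)
    raise RuntimeError("could not sample a valid ground truth")


@dataclass(frozen=True)
class StimulusTrain:
    """Parameters of one stimulation train.

    Laser trains carry pulse energy (J); contact-heat trains carry thermode
    temperatures (metadata only — no skin-heating model is simulated).
    """

    modality: str  # 'contact_heat' or 'laser'
    n_stimuli: int = 20
    isi_range: tuple[float, float] = (8.0, 12.0)
    energy: float | None = None
    peak_temperature: float = 52.0
    baseline_temperature: float = 35.0
    heating_rate: float = 70.0  # deg C / s
    cooling_rate: float = 40.0
    pulse_ms: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.modality not in ("contact_heat", "laser"):
            raise ValueError("modality must be 'contact_heat' or 'laser'")
        if self.n_stimuli < 1:
            raise ValueError("n_stimuli must be >= 1")
        lo, hi = self.isi_range
        if not (0 < lo <= hi):
            raise ValueError("invalid isi_range")


@dataclass
class SyntheticRecording:
    """Continuous multi-channel record with triggers and its ground truth."""

    channel_labels: tuple[str, ...]
    sfreq: float
    data: np.ndarray  # channels x samples, uV
    trigger_samples: np.ndarray  # strictly increasing sample indices
    ground_truth: EPGroundTruth
    stimulated_side: str = "left"
    seed: int = 0

    def __post_init__(self) -> None:
        trig = np.asarray(self.trigger_samples)
        if trig.size and not np.all(np.diff(trig) > 0):
            raise ValueError("triggers must be strictly increasing")
        n = self.data.shape[1]
        pre = int(round(-EPOCH_TMIN * self.sfreq))
        post = int(round(EPOCH_TMAX * self.sfreq))
        if trig.size and (trig.min() < pre or trig.max() + post > n):
            raise ValueError("every trigger needs >=1 s before and >=2 s after")


def powerlaw_noise(
    shape: tuple[int, ...],
    rng: np.random.Generator,
    exponent: float = 1.0,
    rms: float = 1.0,
    sfreq: float = SFREQ,
) -> np.ndarray:
    """Gaussian 1/f^beta noise along the last axis, scaled to a target RMS.

    Synthesised in the frequency domain: independent complex-Gaussian rFFT
    coefficients weighted by f^(-beta/2) (DC = 0), transformed back and scaled
    so each trace's sample standard deviation equals ``rms`` exactly.
    """
    n = shape[-1]
    freqs = np.fft.rfftfreq(n, d=1.0 / sfreq)
    weights = np.zeros_like(freqs)
    weights[1:] = freqs[1:] ** (-exponent / 2.0)
    spec_shape = shape[:-1] + (freqs.size,)
    spec = rng.normal(size=spec_shape) + 1j * rng.normal(size=spec_shape)
    spec *= weights
    x = np.fft.irfft(spec, n=n, axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x * (rms / sd)


def _contralateral_channel(stimulated_side: str) -> str:
    if stimulated_side == "left":
        return "C4"
    if stimulated_side == "right":
        return "C3"
    raise ValueError("stimulated_side must be 'left' or 'right'")


def _component_channels(truth: EPGroundTruth, stimulated_side: str) -> dict[str, list[str]]:
    return {
        "n1": [_contralateral_channel(stimulated_side)],
        "n2": ["Cz"],
        "p2": ["Cz"],
    }


def _jittered_latency(
    comp: Component, jitter_sd: float, rng: np.random.Generator, max_tries: int = 100
) -> float:
    """Latency (ms) with Gaussian jitter, resampled if outside [0, 2000) ms."""
    if jitter_sd == 0:
        return comp.latency_ms
    for _ in range(max_tries):
        lat = comp.latency_ms + rng.normal(0.0, jitter_sd)
        if 0.0 <= lat < 2000.0:
            return lat
    logger.warning(
        "latency jitter kept leaving the post-stimulus window for component at "
        "%.0f ms; using the unjittered latency", comp.latency_ms
    )
    return comp.latency_ms


def _add_bumps(
    data: np.ndarray,
    times_ms: np.ndarray,
    truth: EPGroundTruth,
    stimulated_side: str,
    rng: np.random.Generator,
    channel_labels: tuple[str, ...],
) -> None:
    """Add one trial's jittered component bumps to ``data`` (channels x time),
    in place. ``times_ms`` is the trigger-locked time axis of ``data``."""
    chan_map = _component_channels(truth, stimulated_side)
    index = {c: i for i, c in enumerate(channel_labels)}
    for name in ("n1", "n2", "p2"):
        comp: Component = getattr(truth, name)
        lat = _jittered_latency(comp, truth.latency_jitter_sd, rng)
        bump = comp.amplitude_uv * np.exp(
            -((times_ms - lat) ** 2) / (2.0 * comp.width_ms**2)
        )
        for ch in chan_map[name]:
            data[index[ch]] += bump


def synthesize_epoch(
    truth: EPGroundTruth,
    seed: int | np.random.Generator = 0,
    stimulated_side: str = "left",
    channel_labels: tuple[str, ...] = DEFAULT_CHANNELS,
) -> np.ndarray:
    """One trigger-locked epoch: channels x 12000 samples spanning [-1, 2) s."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    times_ms = (np.arange(EPOCH_N_SAMPLES) - TRIGGER_INDEX) / SFREQ * 1000.0
    if truth.noise_rms > 0:
        data = powerlaw_noise(
            (len(channel_labels), EPOCH_N_SAMPLES),
            rng,
            exponent=truth.noise_exponent,
            rms=truth.noise_rms,
        )
    else:
        data = np.zeros((len(channel_labels), EPOCH_N_SAMPLES))
    _add_bumps(data, times_ms, truth, stimulated_side, rng, channel_labels)
    return data


def synthesize_session(
    truth: EPGroundTruth,
    train: StimulusTrain,
    continuous: bool = False,
    seed: int | np.random.Generator = 0,
    stimulated_side: str = "left",
    channel_labels: tuple[str, ...] = DEFAULT_CHANNELS,
):
    """Simulate one acquisition session.

    With ``continuous=False`` returns an :class:`~noxep.preprocess.EpochSet`
    of ``train.n_stimuli`` independent, baseline-corrected epochs. With
    ``continuous=True`` returns a :class:`SyntheticRecording` whose triggers
    are spaced uniformly within ``train.isi_range`` and whose epochs can be
    cut out by the preprocessing stage.
    """
    from .preprocess import EpochSet, baseline_correct  # local import, avoids a cycle

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if not continuous:
        epochs = np.stack(
            [
                synthesize_epoch(truth, rng, stimulated_side, channel_labels)
                for _ in range(train.n_stimuli)
            ]
        )
        return EpochSet(
            data=baseline_correct(epochs, TRIGGER_INDEX),
            channel_labels=channel_labels,
            sfreq=SFREQ,
            tmin=EPOCH_TMIN,
            ground_truth=truth,
            stimulated_side=stimulated_side,
            provenance={"generator": "synthesize_session", "continuous": False},
        )

    lead, tail = 5.0, 5.0
    gaps = rng.uniform(train.isi_range[0], train.isi_range[1], size=train.n_stimuli - 1)
    trigger_times = lead + np.concatenate([[0.0], np.cumsum(gaps)])
    duration = trigger_times[-1] + tail
    n_samples = int(round(duration * SFREQ))
    triggers = np.round(trigger_times * SFREQ).astype(int)
    if n_samples < triggers[-1] + int(EPOCH_TMAX * SFREQ):
        raise ValueError("record too short for the requested trigger train")
    if truth.noise_rms > 0:
        data = powerlaw_noise(
            (len(channel_labels), n_samples),
            rng,
            exponent=truth.noise_exponent,
            rms=truth.noise_rms,
        )
    else:
        data = np.zeros((len(channel_labels), n_samples))
    t_ms = np.arange(n_samples) / SFREQ * 1000.0
    for trig in triggers:
        trig_ms = trig / SFREQ * 1000.0
        # restrict bump evaluation to the local epoch for speed
        sl = slice(trig - TRIGGER_INDEX, trig + EPOCH_N_SAMPLES - TRIGGER_INDEX)
        _add_bumps(
            data[:, sl], t_ms[sl] - trig_ms, truth, stimulated_side, rng, channel_labels
        )
    return SyntheticRecording(
        channel_labels=channel_labels,
        sfreq=SFREQ,
        data=data,
        trigger_samples=triggers,
        ground_truth=truth,
        stimulated_side=stimulated_side,
    )
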