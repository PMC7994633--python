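"""EEG preprocessing: FIR bandpass, epoching, artifact rejection, montages.

The bandpass is a Hamming-windowed linear-phase FIR built as the cascade of a
1 Hz high-pass (1 Hz transition band) and a 40 Hz low-pass (10 Hz transition
band), applied zero-phase by compensating the known group delay of the
linear-phase kernel, so component latencies are unbiased. Filtering is applied
to the continuous record before epoching to keep filter transients away from
epoch edges.

Epochs span [-1 s, 2 s) around each trigger (t = 0 at index 4000 at 4000 Hz)
and are baseline-corrected by subtracting each channel's mean over the full
pre-stimulus second.

Artifact handling is a transparent peak-to-peak amplitude criterion (default
150 uV): flagged epochs stay in the container, marked rejected, and are
excluded from averages.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import signal

logger = logging.getLogger(__name__)

DEFAULT_LOW_HZ = 1.0
DEFAULT_HIGH_HZ = 40.0
LOW_TRANSITION_HZ = 1.0
HIGH_TRANSITION_HZ = 10.0
#: Hamming-window transition-width rule: numtaps ~ 3.3 * fs / transition_bw
HAMMING_TB_FACTOR = 3.3
DEFAULT_REJECT_UV = 150.0


def _odd(n: int) -> int:
    return n if n % 2 == 1 else n + 1


@lru_cache(maxsize=8)
def design_bandpass(
    sfreq: float,
    low: float = DEFAULT_LOW_HZ,
    high: float = DEFAULT_HIGH_HZ,
    low_transition: float = LOW_TRANSITION_HZ,
    high_transition: float = HIGH_TRANSITION_HZ,
) -> np.ndarray:
    """Design the bandpass kernel (cascade of high-pass and low-pass taps).

    Each stage's length follows the Hamming transition-width rule; the -6 dB
    cutoffs sit at ``low`` and ``high``. The returned kernel is linear-phase
    with an odd number of taps.
    """
    if sfreq <= 2 * high:
        raise ValueError("sample rate must exceed twice the upper edge")
    n_hp = _odd(int(np.ceil(HAMMING_TB_FACTOR * sfreq / low_transition)))
    n_lp = _odd(int(np.ceil(HAMMING_TB_FACTOR * sfreq / high_transition)))
    hp = signal.firwin(n_hp, low, fs=sfreq, window="hamming", pass_zero=False)
    lp = signal.firwin(n_lp, high, fs=sfreq, window="hamming", pass_zero=True)
    return np.convolve(hp, lp)


@lru_cache(maxsize=8)
def design_lowpass(
    sfreq: float,
    high: float = DEFAULT_HIGH_HZ,
    high_transition: float = HIGH_TRANSITION_HZ,
) -> np.ndarray:
    """The low-pass half of the bandpass, short enough for 3 s epochs."""
    n_lp = _odd(int(np.ceil(HAMMING_TB_FACTOR * sfreq / high_transition)))
    return signal.firwin(n_lp, high, fs=sfreq, window="hamming", pass_zero=True)


def apply_fir(data: np.ndarray, taps: np.ndarray) -> np.ndarray:
    """Zero-phase application of a linear-phase FIR along the last axis.

    Forward convolution followed by removal of the kernel's (N-1)/2-sample
    group delay. Raises if the signal is shorter than the kernel.
    """
    n = data.shape[-1]
    if n < taps.size:
        raise ValueError(
            f"signal length {n} is shorter than the filter length {taps.size}"
        )
    delay = (taps.size - 1) // 2
    full = signal.fftconvolve(data, taps[(np.newaxis,) * (data.ndim - 1)], axes=-1)
    return full[..., delay : delay + n]


def bandpass(recording, low: float = DEFAULT_LOW_HZ, high: float = DEFAULT_HIGH_HZ):
    """Bandpass-filter a continuous recording (returns a filtered copy).

    Accepts a :class:`~noxep.eeg_sim.SyntheticRecording` or a bare
    channels x samples array together with nothing else (arrays are filtered
    at the array's native axis; pass recordings for provenance tracking).
    """
    from dataclasses import replace

    from .eeg_sim import SyntheticRecording

    if isinstance(recording, SyntheticRecording):
        taps = design_bandpass(recording.sfreq, low, high)
        return replace(recording, data=apply_fir(recording.data, taps))
    raise TypeError("bandpass expects a SyntheticRecording; use apply_fir for raw arrays")


@dataclass
class EpochSet:
    """Trigger-locked epochs: epochs x channels x time, in uV.

    ``tmin`` is the epoch start relative to the trigger (s); the time axis is
    half-open ``[tmin, tmin + n/sfreq)``. ``rejected`` lists epoch indices
    excluded from averages. ``ground_truth`` rides along for simulated data.
    """

    data: np.ndarray
    channel_labels: tuple[str, ...]
    sfreq: float
    tmin: float = -1.0
    rejected: list[int] = field(default_factory=list)
    ground_truth: object = None
    stimulated_side: str = "left"
    provenance: dict = field(default_factory=dict)

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def times(self) -> np.ndarray:
        return self.tmin + np.arange(self.data.shape[-1]) / self.sfreq

    @property
    def trigger_index(self) -> int:
        return int(round(-self.tmin * self.sfreq))

    def kept_indices(self) -> np.ndarray:
        mask = np.ones(self.n_epochs, dtype=bool)
        mask[list(self.rejected)] = False
        return np.flatnonzero(mask)

    def average(self) -> np.ndarray:
        """Channels x time average over non-rejected epochs."""
        kept = self.kept_indices()
        if kept.size == 0:
            raise ValueError("no usable epochs: all have been rejected")
        return self.data[kept].mean(axis=0)

    def channel(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"required channel {label!r} is missing") from None


def baseline_correct(data: np.ndarray, trigger_index: int) -> np.ndarray:
    """Subtract each channel's mean over the pre-stimulus interval."""
    baseline = data[..., :trigger_index].mean(axis=-1, keepdims=True)
    return data - baseline


def epoch(recording, triggers=None) -> EpochSet:
    """Cut a continuous recording into baseline-corrected [-1, 2) s epochs.

    Triggers closer than 1 s to the start or 2 s to the end of the record are
    skipped with a warning rather than raising.
    """
    from .eeg_sim import SyntheticRecording

    if isinstance(recording, SyntheticRecording):
        data, sfreq = recording.data, recording.sfreq
        if triggers is None:
            triggers = recording.trigger_samples
        labels = recording.channel_labels
        truth, side = recording.ground_truth, recording.stimulated_side
    else:
        raise TypeError("epoch expects a SyntheticRecording")

    pre = int(round(1.0 * sfreq))
    post = int(round(2.0 * sfreq))
    n = data.shape[1]
    epochs = []
    for trig in np.asarray(triggers, dtype=int):
        if trig - pre < 0 or trig + post > n:
            logger.warning("trigger at sample %d too close to record edge; skipped", trig)
            continue
        epochs.append(data[:, trig - pre : trig + post])
    if not epochs:
        raise ValueError("no trigger yields a complete epoch")
    stack = baseline_correct(np.stack(epochs), pre)
    return EpochSet(
        data=stack,
        channel_labels=tuple(labels),
        sfreq=sfreq,
        tmin=-1.0,
        ground_truth=truth,
        stimulated_side=side,
        provenance={"source": "epoch", "n_triggers": len(triggers)},
    )


def reject_artifacts(
    epochs: EpochSet,
    criterion_uv: float = DEFAULT_REJECT_UV,
    channels: tuple[str, ...] | None = None,
) -> EpochSet:
    """Mark epochs whose peak-to-peak amplitude exceeds the criterion.

    Inspects all channels by default (pass ``channels`` to restrict). Flagged
    epochs are recorded in ``rejected`` — never deleted. Raises if every epoch
    is rejected (the session is unusable).
    """
    if criterion_uv <= 0:
        raise ValueError("criterion must be > 0")
    if channels is None:
        idx = np.arange(len(epochs.channel_labels))
    else:
        idx = np.array([epochs.channel(c) for c in channels])
    ptp = epochs.data[:, idx, :].max(axis=-1) - epochs.data[:, idx, :].min(axis=-1)
    bad = np.flatnonzero((ptp > criterion_uv).any(axis=1))
    rejected = sorted(set(epochs.rejected) | set(bad.tolist()))
    if len(rejected) == epochs.n_epochs:
        raise ValueError("all epochs exceed the artifact criterion: session unusable")
    epochs.rejected = rejected
    epochs.provenance["reject_criterion_uv"] = criterion_uv
    return epochs


def derive_montages(
    epochs: EpochSet, stimulated_side: str | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Per-epoch vertex and contralateral analysis traces.

    vertex        = Cz - mean(A1, A2)      (N2/P2 complex)
    contralateral = C4 - Fz  (left-side stimulation) or C3 - Fz (right)

    Returns two arrays of shape (n_epochs, n_times).
    """
    side = stimulated_side or epochs.stimulated_side
    if side not in ("left", "right"):
        raise ValueError("stimulated_side must be 'left' or 'right'")
    cz = epochs.data[:, epochs.channel("Cz")]
    a1 = epochs.data[:, epochs.channel("A1")]
    a2 = epochs.data[:, epochs.channel("A2")]
    contra_label = "C4" if side == "left" else "C3"
    contra = epochs.data[:, epochs.channel(contra_label)]
    fz = epochs.data[:, epochs.channel("Fz")]
    vertex = cz - (a1 + a2) / 2.0
    contralateral = contra - fz
    return vertex, contralateral
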