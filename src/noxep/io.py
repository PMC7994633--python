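"""Persistence helpers: epoch containers (.npz + JSON metadata), rating and
session tables (CSV), ground truth / match results (JSON), and optional EDF
reading through MNE when it is installed."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .eeg_sim import Component, EPGroundTruth
from .preprocess import EpochSet


def _truth_to_dict(truth: EPGroundTruth) -> dict:
    return dataclasses.asdict(truth)


def _truth_from_dict(d: dict) -> EPGroundTruth:
    return EPGroundTruth(
        n1=Component(**d["n1"]),
        n2=Component(**d["n2"]),
        p2=Component(**d["p2"]),
        latency_jitter_sd=d["latency_jitter_sd"],
        noise_rms=d["noise_rms"],
        noise_exponent=d["noise_exponent"],
    )


def save_epochs(path, epochs: EpochSet) -> None:
    """Write an EpochSet as ``<path>.npz`` data plus a ``<path>.json`` side-car
    (channel labels, rejection list, ground truth, provenance)."""
    path = Path(path)
    np.savez_compressed(path.with_suffix(".npz"), data=epochs.data)
    meta = {
        "channel_labels": list(epochs.channel_labels),
        "sfreq": epochs.sfreq,
        "tmin": epochs.tmin,
        "rejected": list(map(int, epochs.rejected)),
        "stimulated_side": epochs.stimulated_side,
        "provenance": epochs.provenance,
        "ground_truth": _truth_to_dict(epochs.ground_truth)
        if isinstance(epochs.ground_truth, EPGroundTruth)
        else None,
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def load_epochs(path) -> EpochSet:
    path = Path(path)
    data = np.load(path.with_suffix(".npz"))["data"]
    meta = json.loads(path.with_suffix(".json").read_text())
    truth = _truth_from_dict(meta["ground_truth"]) if meta.get("ground_truth") else None
    return EpochSet(
        data=data,
        channel_labels=tuple(meta["channel_labels"]),
        sfreq=meta["sfreq"],
        tmin=meta["tmin"],
        rejected=meta["rejected"],
        ground_truth=truth,
        stimulated_side=meta.get("stimulated_side", "left"),
        provenance=meta.get("provenance", {}),
    )


def save_recording(path, rec) -> None:
    """Write a continuous SyntheticRecording as ``<path>.npz`` + JSON side-car."""
    path = Path(path)
    np.savez_compressed(
        path.with_suffix(".npz"), data=rec.data, trigger_samples=rec.trigger_samples
    )
    meta = {
        "kind": "recording",
        "channel_labels": list(rec.channel_labels),
        "sfreq": rec.sfreq,
        "stimulated_side": rec.stimulated_side,
        "seed": rec.seed,
        "ground_truth": _truth_to_dict(rec.ground_truth),
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def load_recording(path):
    from .eeg_sim import SyntheticRecording

    path = Path(path)
    arrays = np.load(path.with_suffix(".npz"))
    meta = json.loads(path.with_suffix(".json").read_text())
    return SyntheticRecording(
        channel_labels=tuple(meta["channel_labels"]),
        sfreq=meta["sfreq"],
        data=arrays["data"],
        trigger_samples=arrays["trigger_samples"],
        ground_truth=_truth_from_dict(meta["ground_truth"]),
        stimulated_side=meta.get("stimulated_side", "left"),
        seed=meta.get("seed", 0),
    )


def read_raw_edf(path, trigger_channel: str | None = None):
    """Load a continuous EDF recording via MNE (optional dependency).

    Returns (channels x samples array in uV, sfreq, channel labels). Trigger
    extraction is left to the caller's event side-car or the named trigger
    channel's onsets.
    """
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - depends on extras
        raise ImportError("EDF reading requires the optional 'mne' dependency") from exc
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data() * 1e6  # V -> uV
    return data, float(raw.info["sfreq"]), list(raw.ch_names)


def staircase_trajectory_frame(runs: dict) -> pd.DataFrame:
    """Tidy trajectory table (trial, staircase, energy, rating) from the two
    StaircaseRun objects."""
    rows = []
    for sid, run in runs.items():
        for i, (energy, rating) in enumerate(run.trials, start=1):
            rows.append(
                {"staircase": sid, "trial": i, "energy_j": energy, "rating_nrs": rating}
            )
    return pd.DataFrame(rows)
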