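"""End-to-end study orchestration.

Simulates the four-arm within-subject design — {contact heat, laser} x
{sham, capsaicin} — for a cohort of synthetic observers and runs every
downstream stage: familiarization and intensity matching, pinprick blocks,
per-session thermal ratings, evoked-potential sessions with extraction, and
the paired statistical reports. All randomness derives from one seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .eeg_sim import StimulusTrain, sample_ground_truth
from .extract import SNR_GATE_DB, extract_session
from .io import staircase_trajectory_frame
from .observers import make_cohort, simulate_pinprick_block
from .preprocess import DEFAULT_REJECT_UV, reject_artifacts
from .psychophys import hyperalgesia_delta, session_thermal_mean
from .staircase import familiarization_target, run_matching
from .stats import FAMILY_ALPHA, N_FAMILY_COMPARISONS, build_reports, icc_a_k, pearson_r

MODALITIES = ("chep", "lep")
CONDITIONS = ("sham", "capsaicin")


@dataclass
class StudyConfig:
    """Configuration of one simulated study run."""

    n_subjects: int = 20
    seed: int = 1
    n_intolerant: int = 0  # subjects dropping out at familiarization
    n_stimuli: int = 20
    n_familiarization: int = 11
    noise_rms_uv: float = 12.0
    latency_jitter_sd_ms: float = 10.0
    capsaicin_thermal_delta_nrs: float = 0.0  # no thermal sensitization
    reject_criterion_uv: float = DEFAULT_REJECT_UV
    snr_gate_db: float = SNR_GATE_DB
    family_alpha: float = FAMILY_ALPHA
    m_comparisons: int = N_FAMILY_COMPARISONS
    stimulated_side: str = "left"
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        for name in ("noise_rms_uv", "reject_criterion_uv"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        kwargs = {k: v for k, v in d.items() if k in known}
        kwargs["extras"] = {k: v for k, v in d.items() if k not in known}
        return cls(**kwargs)


@dataclass
class StudyResult:
    sessions: pd.DataFrame
    hyperalgesia: pd.DataFrame
    matching: pd.DataFrame
    trajectories: pd.DataFrame
    reports: dict
    manifest: dict

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.sessions.to_csv(out / "sessions.csv", index=False)
        self.hyperalgesia.to_csv(out / "hyperalgesia.csv", index=False)
        self.matching.to_csv(out / "matching.csv", index=False)
        self.trajectories.to_csv(out / "staircase_trajectories.csv", index=False)
        for name, report in self.reports.items():
            report.to_csv(out / f"report_{name}.csv")
        (out / "manifest.json").write_text(json.dumps(self.manifest, indent=1))


def run_study(config: StudyConfig) -> StudyResult:
    """Run the full four-arm study and return tables, reports, and manifest."""
    root = np.random.SeedSequence(config.seed)
    cohort_seed, *subject_seeds = [
        int(s.generate_state(1)[0] % (2**31 - 1))
        for s in root.spawn(config.n_subjects + 1)
    ]
    cohort = make_cohort(config.n_subjects, cohort_seed)
    analyzed = cohort[config.n_intolerant :]  # intolerant subjects never complete

    session_rows, hyper_rows, match_rows, traj_frames = [], [], [], []
    for observer, sseed in zip(analyzed, subject_seeds):
        rng = np.random.default_rng(sseed)
        stage = _subject_stages(observer, config, rng)
        session_rows.extend(stage["sessions"])
        hyper_rows.extend(stage["hyperalgesia"])
        match_rows.append(stage["matching"])
        traj_frames.append(stage["trajectory"])

    sessions = pd.DataFrame(session_rows)
    hyper = pd.DataFrame(hyper_rows)
    matching = pd.DataFrame(match_rows)
    trajectories = pd.concat(traj_frames, ignore_index=True)

    sham = sessions[(sessions["condition"] == "sham") & (sessions["modality"] == "lep")]
    paired = matching.set_index("subject").join(
        sham.set_index("subject")["mean_nrs"].rename("laser_mean_nrs")
    ).dropna(subset=["target_nrs", "laser_mean_nrs"])
    if len(paired) >= 5:  # ICC/r need a minimal cohort
        match_icc = icc_a_k(paired[["target_nrs", "laser_mean_nrs"]].to_numpy()).value
        match_r = pearson_r(paired["target_nrs"], paired["laser_mean_nrs"])
    else:
        match_icc = match_r = float("nan")

    reports = build_reports(sessions, hyper)
    manifest = {
        "package": "noxep",
        "version": __version__,
        "config": {k: v for k, v in dataclasses.asdict(config).items()},
        "n_analyzed": len(analyzed),
        "matching_icc_a2": match_icc,
        "matching_pearson_r": match_r,
        "decisions": {
            "tie_rule": "hold",
            "baseline_window_s": [-1.0, 0.0],
            "filter": "Hamming FIR 1-40 Hz, transitions 1/10 Hz, zero-phase",
            "detection_smoothing": "40 Hz low-pass on averages",
            "snr_gate_db": config.snr_gate_db,
            "presence_multiplier": "sqrt(2)",
            "n2_onset_fraction": 0.5,
            "reject_criterion_uv": config.reject_criterion_uv,
            "adjusted_alpha": round(config.family_alpha / config.m_comparisons, 3),
            "absent_component_amplitude_uv": 0.0,
        },
    }
    return StudyResult(sessions, hyper, matching, trajectories, reports, manifest)


def _subject_stages(observer, config: StudyConfig, rng: np.random.Generator) -> dict:
    """All four sessions of one subject."""
    fam = observer.simulate_heat_session(config.n_familiarization)
    target = familiarization_target(fam)
    runs, match = run_matching(observer.simulate_rating, target, seed=rng)
    traj = staircase_trajectory_frame(runs)
    traj.insert(0, "subject", observer.subject_id)

    truths = {
        m: sample_ground_truth(m, rng) for m in MODALITIES
    }
    sessions, hyper = [], []
    for modality in MODALITIES:
        for condition in CONDITIONS:
            pre = simulate_pinprick_block(observer, modality, condition, "pre", rng=rng)
            post = simulate_pinprick_block(observer, modality, condition, "post", rng=rng)
            hyper.append(
                {
                    "subject": observer.subject_id,
                    "modality": modality,
                    "condition": condition,
                    "delta_nrs": hyperalgesia_delta(pre, post),
                }
            )
            if modality == "chep":
                shift = (
                    config.capsaicin_thermal_delta_nrs if condition == "capsaicin" else 0.0
                )
                ratings = np.clip(
                    observer.simulate_heat_session(config.n_stimuli) + shift, 0, 10
                )
            else:
                ratings = [
                    observer.simulate_rating(match.matched_energy)
                    for _ in range(config.n_stimuli)
                ]
            truth = dataclasses.replace(
                truths[modality],
                noise_rms=config.noise_rms_uv,
                latency_jitter_sd=config.latency_jitter_sd_ms,
            )
            train = StimulusTrain(
                modality="contact_heat" if modality == "chep" else "laser",
                n_stimuli=config.n_stimuli,
            )
            epochs = _make_session(truth, train, rng, config)
            result = extract_session(
                epochs, modality, config.stimulated_side, snr_gate_db=config.snr_gate_db
            )
            row = {
                "subject": observer.subject_id,
                "modality": modality,
                "condition": condition,
                "matched_energy_j": match.matched_energy if modality == "lep" else np.nan,
                "mean_nrs": session_thermal_mean(ratings, config.n_stimuli),
            }
            row.update(result.to_row())
            sessions.append(row)
    return {
        "sessions": sessions,
        "hyperalgesia": hyper,
        "matching": {
            "subject": observer.subject_id,
            "target_nrs": target.target_nrs,
            "matched_energy_j": match.matched_energy,
            "correction_applied": match.correction_applied,
            "diverged": match.diverged,
        },
        "trajectory": traj,
    }


def _make_session(truth, train, rng, config: StudyConfig):
    from .eeg_sim import synthesize_session

    epochs = synthesize_session(truth, train, continuous=False, seed=rng)
    return reject_artifacts(epochs, config.reject_criterion_uv)
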