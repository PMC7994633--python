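# noxep

Analysis pipeline for **intensity-matched nociceptive evoked potentials**:
laser-evoked (LEP) and contact-heat-evoked (CHEP) brain responses compared at
equal perceived pain, plus the capsaicin secondary-hyperalgesia side of such a
study. The package is aimed at pain-neurophysiology researchers who want the
computational stages of this paradigm — adaptive intensity matching, evoked-
potential extraction with an SNR gate, pinprick hyperalgesia aggregation, and
the paired statistical layer — as tested, reusable code. Because no public
recordings exist for the paradigm, a first-class synthetic-data module
generates psychophysical observers and trigger-locked EEG with known ground
truth, so every stage is validated in closed loop.

## What it implements

- **Double random staircase (DRS) matching.** Two interleaved staircases
  adjust laser energy toward the subject's contact-heat pain level on the 0–10
  numeric rating scale (NRS): start 1.5 J; +0.5 J while no pain is felt;
  ±0.25 J when the rating is below/above the target; matched intensity = mean
  of the two per-staircase median energies, +0.25 J if the median ratings fall
  short of the target.
- **EEG preprocessing.** Zero-phase Hamming-windowed FIR bandpass (1–40 Hz),
  epoching to [−1 s, 2 s) at 4000 Hz, full-pre-second baseline correction,
  peak-to-peak artifact flagging, vertex (Cz − linked ears) and contralateral
  (C3/C4 − Fz) montages.
- **SNR-gated N1/N2/P2 extraction.** Session SNR
  `20·log₁₀(RMS_roi/RMS_pre)`; sessions under 3 dB are excluded. Deterministic
  peak rules mark N2 (most negative in window), P2 (most positive, after N2)
  and N1 (contralateral, before the N2 onset); a peak counts as present only
  above √2 × pre-trigger RMS, and absent components enter statistics at 0 µV.
- **Psychophysics.** Pinprick blocks (7 forces × 5 repetitions) collapsed to
  block means; secondary hyperalgesia as post−pre cream deltas; per-session
  thermal rating means.
- **Statistics.** Paired t-tests over the 7-outcome family (N1/N2/P2 latency
  and amplitude, N2P2) with Bonferroni α = 0.05/7 ≈ 0.007, Pearson
  correlation, and the two-way random-effects absolute-agreement
  average-measures intraclass correlation ICC(A,2) computed from the ANOVA
  mean squares: `ICC(A,k) = (MSR − MSE) / (MSR + (MSC − MSE)/n)`.
- **Orchestration.** `run_study` simulates the full 2 × 2 within-subject
  design ({CHEP, LEP} × {sham, capsaicin}) and emits session tables,
  trajectories, comparison reports and a manifest; a `noxep` CLI wraps each
  stage (`simulate`, `match`, `preprocess`, `extract`, `pinprick`, `compare`,
  `run`).

## Worked example

```python
import numpy as np
from noxep import (Observer, familiarization_target, run_matching,
                   synthesize_session, extract_session,
                   LEP_CALIBRATION, StimulusTrain)

obs = Observer(subject_id="S01", pain_threshold_energy=1.0, slope=2.5,
               rating_noise_sd=0.5, heat_mean_nrs=3.0, heat_sd_nrs=1.6, seed=42)

fam = obs.simulate_heat_session(11)          # 11 familiarization heat stimuli
target = familiarization_target(fam)         # first discarded -> mean of 10
runs, match = run_matching(obs.simulate_rating, target, seed=42)
print(target.target_nrs, match.matched_energy, match.correction_applied)
# 2.5 2.25 True

laser = [obs.simulate_rating(match.matched_energy) for _ in range(20)]
print(np.mean(laser))
# 3.1

epochs = synthesize_session(LEP_CALIBRATION, StimulusTrain(modality="laser"), seed=42)
result = extract_session(epochs, "lep")
print(round(result.session_snr_db, 2), round(result.n2.latency_ms),
      round(result.n2.amplitude_uv, 1), round(result.n2p2_amplitude_uv, 1))
# 8.62 203 -20.1 33.2
```

The observer's familiarization ratings average to a 2.5 NRS target; the
staircases settle around 2.0–2.25 J and, because the median ratings
under-shoot the target, the +0.25 J correction fires, giving a matched
intensity of 2.25 J at which 20 laser stimuli are perceived at a mean 3.1 NRS
— the closed loop of the matching protocol. The synthetic laser session
(true N2 −18.9 µV at 211 ms, P2 +16.8 µV at 322 ms, 12 µV 1/f noise) passes
the 3 dB gate at 8.6 dB and the extractor recovers N2 at 203 ms / −20.1 µV
and an N2P2 of 33.2 µV from the 20-epoch average.

The same loop at cohort scale:

```python
from noxep import StudyConfig, run_study
res = run_study(StudyConfig(n_subjects=20, seed=1))
print(round(res.manifest["matching_icc_a2"], 3))   # 0.967
res.reports["baseline"].table                       # CHEP-vs-LEP paired tests
```

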