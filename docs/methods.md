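# Methods

`noxep` implements the computational core of an intensity-matched comparison of
laser-evoked (LEP) and contact-heat-evoked (CHEP) potentials, exercised
end-to-end on synthetic observers and synthetic EEG. No public recordings exist
for this paradigm, so every stage is validated in closed loop: the generator
plants known psychometric functions and evoked components, the analysis chain
runs blind, and the validation experiments measure recovery.

## Synthetic observers

A subject is a piecewise-linear psychometric function with additive Gaussian
rating noise on the 0–10 numeric rating scale (NRS):

    rating(E) = clip(round(s · max(0, E − E0) + ε), 0, 10),   ε ~ N(0, σ_r)

with pain threshold `E0` (default 1.0 J), slope `s` (2.5 NRS/J) and rating
noise `σ_r` (0.5 NRS). Rounding to integers mirrors how subjects report on an
integer scale; it is the simplest monotone model consistent with that scale.
Contact-heat ratings are drawn directly from a per-subject
`round(clip(N(μ_h, σ_h)))` distribution (defaults 3.0 ± 1.6 NRS, the typical
sham-session level), because the contact-heat stimulator runs at a fixed
temperature and needs no energy→rating mapping. Between-subject variation in
the cohort generator: heat means N(3.0, 1.6) clipped to [0, 8], thresholds
N(1.0, 0.15) J floored at 0.25 J.

Ratings and evoked-potential amplitudes are deliberately left uncoupled: the
study this emulates found no correlation between single-session EP outcomes
and perceived intensity, so the generator does not model one.

### Pinprick blocks

A block is 7 calibrated forces (8–512 mN) × 5 repetitions in randomized order.
Per-force base ratings rise linearly 1.0 → 4.0 NRS across the force set (block
mean 2.5), with per-rating noise SD 0.5 and a per-subject offset SD 0.4.
Post-cream blocks are shifted by a condition effect — (−0.1, +0.1) NRS for
sham/capsaicin in contact-heat sessions, (0.0, +0.2) in laser sessions — plus
a per-subject×phase deviation of SD 0.16. With 35 ratings per block this puts
the SD of the post−pre block-mean difference at
`sqrt(0.16² + 2·(0.5/√35)²) ≈ 0.2` NRS, so the capsaicin−sham contrast of
+0.2 NRS is detectable with ~85% power in a 20-subject paired design —
the regime the protocol operates in.

## Synthetic EEG

Epochs span [−1 s, 2 s) around the trigger at 4000 Hz (12000 samples, t = 0 at
index 4000, half-open convention). Each component is a Gaussian bump
`A·exp(−(t − L′)²/(2σ_w²))` with per-trial jitter `L′ = L + N(0, σ_j)`
(σ_j default 10 ms, resampled if it leaves the post-stimulus window). Widths
default to σ_w = 15/25/40 ms for N1/N2/P2 — early components narrower than
late ones; the Gaussian shape itself is a modelling choice that makes latency
and amplitude ground truth unambiguous. Channel placement follows the analysis
montage: N2/P2 on Cz, N1 on the electrode contralateral to the stimulated arm
(C4 for left-side stimulation); Fz, A1 and A2 carry background noise only, so
montage subtraction leaves amplitudes intact (leakage is not modelled).

Background noise is independent per channel: 1/f^β Gaussian noise (β = 1)
synthesized by rFFT spectral shaping, scaled to an exact per-trace RMS.
Default 12 µV per channel was chosen so that a 20-epoch laser-session average
lands at ~10 dB session SNR (contact-heat ~6–7 dB) — representative values
for this kind of recording. Continuous mode places triggers with uniform
8–12 s inter-stimulus intervals and a 5 s lead-in/tail.

Calibrations: the two modality ground truths are

|        | N1          | N2           | P2          |
|--------|-------------|--------------|-------------|
| CHEP   | 336 ms, −3.6 µV | 392 ms, −10.6 µV | 494 ms, +13.0 µV |
| LEP    | 175 ms, −7.1 µV | 211 ms, −18.9 µV | 322 ms, +16.8 µV |

with between-subject SDs of (33, 2.5)/(37, 6.3)/(49, 7.4) for CHEP and
(23, 4.5)/(19, 8.6)/(26, 7.2) for LEP (latency ms, amplitude µV). Per-subject
draws are rejected until latencies are ordered and amplitudes keep their signs
(|A| ≥ 0.5 µV), which shifts population means negligibly.

What the generator does *not* emulate: eye-blink/EMG artifacts beyond
amplitude outliers, habituation across trials, channel cross-talk, line noise,
and any biophysical skin-heating or transduction dynamics (thermode ramp rates
and laser pulse geometry are metadata only). Passing tests therefore
demonstrate correctness of the algorithms under the stated noise model, not
robustness to every pathology of real scalp EEG.

## Intensity matching (double random staircase)

Two staircases start at 1.5 J and run a fixed 10 trials each, interleaved in a
seeded random order constrained to at most three consecutive trials of the
same staircase. Update rule per stimulus: rating 0 → +0.5 J; rating below the
target → +0.25 J; above → −0.25 J; exactly at the (possibly fractional) target
→ hold. The hold rule is a design choice — only "lower" and "higher" behaviour
is prescribed by the protocol — and `tie="down"` is available. Energies are
clamped to [0.25, 5.0] J with a logged warning; the 5 J cap is a safety
analogue preventing runaway with pathological observers.

The matched intensity is the mean of the two per-staircase median energies; if
the mean of the two median ratings falls short of the target, 0.25 J is added
(subjects tend to under-rate laser stimuli near the match point). Medians over
an even count are the mean of the two central values, so each staircase median
lies on a 0.125 J grid and the matched energy on a 0.0625 J grid. Staircases
with zero reversals are flagged as non-converged, and a median-energy
disagreement above 1 J raises a divergence flag; in both cases the average is
still reported, flagged rather than guessed at. The target itself is the mean
of 11 familiarization contact-heat ratings after discarding the first
(novelty/surprise).

## Preprocessing

The 1–40 Hz bandpass is a Hamming-windowed linear-phase FIR: the cascade of a
1 Hz high-pass with a 1 Hz transition band and a 40 Hz low-pass with a 10 Hz
transition band (lengths from the ~3.3·fs/Δf Hamming rule; 14521 taps at
4000 Hz). A literal first-order FIR cannot realize this response; the
transition-band design is the standard reading of that toolbox phrasing.
Application is zero-phase (forward convolution with exact group-delay removal)
so latencies are unbiased. Measured response: passband ripple < 0.4% over
2–35 Hz, > 50 dB attenuation at 0.25 Hz and 60 Hz. Filtering precedes epoching
in continuous mode to keep transients away from epoch edges.

Baseline correction subtracts each channel's mean over the full pre-stimulus
second (the protocol does not specify the window; the full second is the
conservative choice and is flagged as an interpretation). Artifact handling is
a transparent peak-to-peak criterion (150 µV default) standing in for
ICA-based removal, which is out of scope; rejected epochs are flagged, never
deleted. Montages: vertex = Cz − mean(A1, A2); contralateral = C4 − Fz or
C3 − Fz according to the stimulated side.

## Extraction

Session SNR is `20·log10(RMS_roi / RMS_pre)` on the vertex average — the
voltage-dB convention, equivalently 10·log10 of the power ratio — with the
region of interest 150–550 ms (LEP) or 300–650 ms (CHEP) and the full
pre-stimulus second as reference (the 500 ms pre-trigger interval is used for
component presence instead; both windows are configurable). Sessions below
3 dB are excluded and carry no components. An exactly-zero pre-trigger trace
(noiseless synthetic input) is treated as infinite SNR rather than an error.

Peak rules replace two-reviewer visual marking: N2 is the most negative sample
of the vertex average in its search window (LEP 150–300 ms, CHEP 300–500 ms —
centred on the calibration means, configurable), P2 the most positive in its
window (250–450 / 400–650 ms) constrained to follow N2. N1 is the most
negative sample of the contralateral average between the start of the SNR
region and the onset of N2, must be an interior extremum (a minimum on a
window boundary is a flank, not a peak), and is absent whenever N2 is absent.
N2 onset is the last pre-peak crossing of 50% of the N2 amplitude on the
vertex trace: with the default component widths a 10% criterion would place
the onset *before* the canonical LEP N1 peak (175 ms vs ~157 ms) and misclassify
a correct N1, so the half-amplitude crossing is the default
(`onset_fraction` configurable). A component is present only if its peak
magnitude reaches √2 × RMS of the 500 ms pre-trigger interval (a 3 dB margin
consistent with the session gate); absent components carry amplitude 0 µV and
no latency, so amplitude comparisons keep the pair while latency comparisons
lose it.

Peak picking runs on averages smoothed with the 40 Hz low-pass half of the
filter only. Two numerical facts drive this: (i) a 1 Hz Hamming-FIR high-pass
removes the sub-1 Hz spectral mass of a σ = 25–40 ms Gaussian, i.e. 12–20% of
its peak, which would bias amplitude recovery against ground truth; (ii) on an
unsmoothed broadband average, a single-sample extremum measures the local
noise maximum rather than the evoked peak. Continuous recordings still receive
the full 1–40 Hz bandpass in preprocessing; the recovery experiments run on
epoch-mode generator output where only the detection low-pass applies. With
overlapping calibrated components the noiseless composite-trace extremum sits
~0.7–2 ms off the bump centre (the P2 tail pulls N2 slightly earlier); exact
recovery is therefore defined against the composite template, with looser
bands against the bump centres.

## Statistics

Paired two-sided t-tests per outcome over the seven-outcome family (N1/N2/P2
latency and amplitude, N2P2 peak-to-peak), Bonferroni-adjusted to
α = 0.05/7 reported as 0.007. Pairing is per subject with pairwise deletion,
so degrees of freedom vary by outcome exactly as the absent-component
convention dictates. All-zero differences return t = 0, p = 1; constant
nonzero differences are degenerate and raise. The intraclass correlation is
McGraw–Wong ICC(A,k): two-way random effects, absolute agreement, average
measures, computed from the ANOVA mean squares as
`(MSR − MSE) / (MSR + (MSC − MSE)/n)` with k = 2; a non-positive denominator
is returned flagged, and the consistency variant ICC(C,k) is available for
sensitivity analysis. Pearson correlation validates the matching alongside the
ICC. p-values print to three decimals with "< 0.001" below that.

## Validation experiments and problem sizes

- Matching closed loop: 20 observers × 50 replicates; ICC(A,2) between heat
  targets and matched-laser mean ratings, typically ≈ 0.95.
- Parameter recovery: 100 sessions per modality with component parameters
  fixed at the calibration means (noise and jitter vary per session). Fixing
  the parameters makes the ±5 ms latency band meaningful: sampling them from
  the between-subject SDs would put the standard error of the recovered mean
  at ~4 ms for CHEPs and the band would fail a quarter of seeds for a perfect
  extractor.
- SNR gate: 10 sessions each at noise levels straddling the boundary
  (expected ≈ 1 dB and ≈ 10 dB); the gate's decision is compared per session
  against an independently computed ground-truth RMS ratio.
- Null calibration: 1000 replicates of a 19-subject, 7-outcome null; per-test
  rejection ≈ 0.05, family-wise error compared to the 0.05 bound with a
  one-sided 95% binomial sampling allowance (the theoretical FWER under
  Bonferroni, 1 − (1 − 0.05/7)⁷ ≈ 0.0488, sits so close to the bound that the
  raw observed proportion exceeds it by sampling noise alone in ~45% of runs).

## Known limitations

- The observer model has no lapses, drift, habituation or sequential
  dependence; staircase convergence results are upper bounds on real behaviour.
- Detection rates for small components (CHEP N1 especially) depend strongly on
  the √2 presence multiplier and the noise level; the defaults yield lower N1
  detection rates than trained human reviewers report.
- EDF export is not provided (recordings persist as .npz + JSON side-car);
  EDF reading is available when `mne` is installed.
- The pipeline models no carry-over between the four randomized sessions.
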