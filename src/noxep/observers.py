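"""Synthetic psychophysical observers.

A simulated subject maps stimulus energy to a 0-10 numeric rating scale (NRS)
response and produces contact-heat rating series and pinprick rating blocks.
The observer model is deliberately simple: a piecewise-linear psychometric
function (zero below the pain threshold, linear drive above it) plus Gaussian
rating noise, rounded to the integer NRS grid and clipped to [0, 10]. Rounding
mirrors how subjects actually report on an integer scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

NRS_MIN = 0
NRS_MAX = 10

#: Fixed pinprick force set (mN), ascending.
PINPRICK_FORCES_MN = (8, 16, 32, 64, 128, 256, 512)

#: Mean rating for each pinprick force at the cohort baseline, 8 -> 512 mN.
#: Monotone in force; block mean 2.5 NRS, a typical mildly painful range.
PINPRICK_BASE_RATINGS = (1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0)

#: Post-minus-pre cream shifts (NRS) of the pinprick block mean, keyed by
#: (session modality, condition). Capsaicin induces secondary mechanical
#: hyperalgesia; sham does not.
PINPRICK_DELTA = {
    ("chep", "sham"): -0.1,
    ("chep", "capsaicin"): 0.1,
    ("lep", "sham"): 0.0,
    ("lep", "capsaicin"): 0.2,
}

#: SD of the per-subject, per-phase deviation of the pinprick shift. Together
#: with the per-rating noise (SD 0.5 over 35 ratings) this puts the SD of the
#: post-pre block-mean difference at ~0.2 NRS.
PINPRICK_DELTA_SD = 0.16
PINPRICK_RATING_NOISE_SD = 0.5
PINPRICK_SUBJECT_OFFSET_SD = 0.4


def _to_nrs(values: np.ndarray) -> np.ndarray:
    """Round to the integer NRS grid and clip to [0, 10]."""
    return np.clip(np.rint(values), NRS_MIN, NRS_MAX).astype(int)


@dataclass
class Observer:
    """Piecewise-linear psychometric observer.

    Parameters
    ----------
    subject_id : str
        Label carried through all generated tables.
    pain_threshold_energy : float
        Laser energy (J) at which the rating drive leaves zero. Must be > 0.
    slope : float
        Rating drive per joule above threshold (NRS/J). Must be > 0.
    rating_noise_sd : float
        SD of the additive Gaussian rating noise (NRS units), >= 0.
    heat_mean_nrs, heat_sd_nrs : float
        Mean and SD of this subject's contact-heat rating distribution
        (defaults 3.0 +/- 1.6 NRS, the cohort-typical sham level).
    seed : int
        Seeds the observer's private random stream; identical seeds give
        identical rating sequences.
    """

    subject_id: str = "S00"
    pain_threshold_energy: float = 1.0
    slope: float = 2.5
    rating_noise_sd: float = 0.5
    heat_mean_nrs: float = 3.0
    heat_sd_nrs: float = 1.6
    seed: int = 0
    _rng: np.random.Generator = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.pain_threshold_energy <= 0:
            raise ValueError("pain_threshold_energy must be > 0")
        if self.slope <= 0:
            raise ValueError("slope must be > 0")
        if self.rating_noise_sd < 0:
            raise ValueError("rating_noise_sd must be >= 0")
        self._rng = np.random.default_rng(self.seed)

    def reset(self) -> None:
        """Rewind the observer's random stream to its seed."""
        self._rng = np.random.default_rng(self.seed)

    def simulate_rating(self, energy: float) -> int:
        """Rate a single laser stimulus of the given energy (J).

        Returns ``clip(round(slope * max(0, energy - threshold) + eps), 0, 10)``
        with ``eps ~ Normal(0, rating_noise_sd)``.
        """
        if energy < 0:
            raise ValueError(f"stimulus energy must be >= 0, got {energy}")
        drive = self.slope * max(0.0, energy - self.pain_threshold_energy)
        eps = self._rng.normal(0.0, self.rating_noise_sd) if self.rating_noise_sd else 0.0
        return int(_to_nrs(np.asarray(drive + eps)))

    def simulate_heat_session(self, n_stimuli: int = 20) -> np.ndarray:
        """Rate a train of contact-heat stimuli (fixed-temperature device).

        Ratings are drawn i.i.d. from round(clip(Normal(heat_mean, heat_sd))).
        """
        raw = self._rng.normal(self.heat_mean_nrs, self.heat_sd_nrs, size=n_stimuli)
        return _to_nrs(raw)


def simulate_pinprick_block(
    observer: Observer,
    modality: str,
    condition: str,
    phase: str,
    subject_offset: float = 0.0,
    phase_delta: float | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Generate one pinprick rating block (7 forces x 5 repetitions).

    ``phase`` is ``pre`` or ``post`` (cream application). The post block's
    ratings are shifted by the condition's hyperalgesia effect plus a
    per-subject random deviation; force order is randomized as in the bedside
    protocol (order does not affect the analysis, which averages all 35).

    Returns a tidy frame: subject, condition, phase, force_mN, rep, nrs.
    """
    if phase not in ("pre", "post"):
        raise ValueError("phase must be 'pre' or 'post'")
    if condition not in ("sham", "capsaicin"):
        raise ValueError("condition must be 'sham' or 'capsaicin'")
    rng = rng if rng is not None else observer._rng
    if phase_delta is None:
        phase_delta = (
            PINPRICK_DELTA[(modality, condition)] + rng.normal(0, PINPRICK_DELTA_SD)
            if phase == "post"
            else 0.0
        )
    rows = []
    order = np.repeat(np.arange(7), 5)
    rng.shuffle(order)
    reps = {k: 0 for k in range(7)}
    for k in order:
        reps[k] += 1
        raw = (
            PINPRICK_BASE_RATINGS[k]
            + subject_offset
            + phase_delta
            + rng.normal(0, PINPRICK_RATING_NOISE_SD)
        )
        rows.append(
            {
                "subject": observer.subject_id,
                "condition": condition,
                "phase": phase,
                "force_mN": PINPRICK_FORCES_MN[k],
                "rep": reps[k],
                "nrs": int(_to_nrs(np.asarray(raw))),
            }
        )
    return pd.DataFrame(rows)


def make_cohort(
    n_subjects: int,
    seed: int,
    heat_mean_population: tuple[float, float] = (3.0, 1.6),
    threshold_population: tuple[float, float] = (1.0, 0.15),
    slope: float = 2.5,
    rating_noise_sd: float = 0.5,
    heat_sd_nrs: float = 1.6,
) -> list[Observer]:
    """Draw a cohort of observers with between-subject variation.

    Per-subject contact-heat mean ratings are drawn from the population
    distribution (default 3.0 +/- 1.6 NRS); laser pain thresholds vary mildly
    around 1.0 J. Values are clipped to physically/behaviourally sensible
    ranges (threshold > 0.25 J, heat mean within [0, 8]).
    """
    rng = np.random.default_rng(seed)
    cohort = []
    for i in range(n_subjects):
        heat_mean = float(np.clip(rng.normal(*heat_mean_population), 0.0, 8.0))
        thr = float(np.clip(rng.normal(*threshold_population), 0.25, None))
        cohort.append(
            Observer(
                subject_id=f"S{i + 1:02d}",
                pain_threshold_energy=thr,
                slope=slope,
                rating_noise_sd=rating_noise_sd,
                heat_mean_nrs=heat_mean,
                heat_sd_nrs=heat_sd_nrs,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        )
    return cohort
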