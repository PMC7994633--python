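"""Double random staircase (DRS) intensity matching.

Two concurrent staircases, randomly interspersed, adjust laser pulse energy
toward a perceptual target: the subject's mean contact-heat pain rating. The
update rule per stimulus:

* rating 0 (no pain felt)      -> energy + 0.5 J
* 0 < rating < target          -> energy + 0.25 J
* rating > target              -> energy - 0.25 J
* rating == target             -> hold (configurable tie rule)

Each staircase runs a fixed 10 trials from 1.5 J. The matched intensity is the
mean of the two per-staircase median energies; if the mean of the two median
ratings falls short of the target, 0.25 J is added (subjects tend to
under-rate laser stimuli near the match point).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from statistics import median
from typing import Callable

import numpy as np

logger = logging.getLogger(__name__)

START_ENERGY = 1.5
STEP_LARGE = 0.5
STEP_SMALL = 0.25
N_TRIALS_PER_STAIRCASE = 10
ENERGY_CAP = 5.0
MAX_CONSECUTIVE = 3
DIVERGENCE_LIMIT = 1.0  # |median_A - median_B| beyond this is flagged


@dataclass(frozen=True)
class MatchingTarget:
    """Perceptual target: mean of the familiarization contact-heat ratings
    after discarding the first (novelty/surprise) stimulus."""

    target_nrs: float
    n_familiarization: int = 11

    def __post_init__(self) -> None:
        if not 0 <= self.target_nrs <= 10:
            raise ValueError("target_nrs must lie in [0, 10]")

    @property
    def n_used(self) -> int:
        return self.n_familiarization - 1


def familiarization_target(ratings) -> MatchingTarget:
    """Build the matching target from exactly 11 familiarization ratings,
    discarding the first."""
    ratings = np.asarray(ratings, dtype=float)
    if ratings.shape != (11,):
        raise ValueError(f"expected exactly 11 familiarization ratings, got {ratings.shape}")
    return MatchingTarget(target_nrs=float(ratings[1:].mean()), n_familiarization=11)


@dataclass
class StaircaseRun:
    """Trajectory of one staircase: ordered (energy, rating) pairs."""

    staircase_id: str  # 'A' or 'B'
    trials: list[tuple[float, int]] = field(default_factory=list)
    start_energy: float = START_ENERGY
    step_large: float = STEP_LARGE
    step_small: float = STEP_SMALL
    energy_cap: float = ENERGY_CAP

    @property
    def energies(self) -> list[float]:
        return [e for e, _ in self.trials]

    @property
    def ratings(self) -> list[int]:
        return [r for _, r in self.trials]

    @property
    def median_energy(self) -> float:
        return float(median(self.energies))

    @property
    def median_nrs(self) -> float:
        return float(median(self.ratings))

    @property
    def n_reversals(self) -> int:
        steps = np.sign(np.diff(self.energies))
        steps = steps[steps != 0]
        return int(np.sum(np.diff(steps) != 0))


@dataclass(frozen=True)
class MatchResult:
    """Outcome of the matching procedure."""

    median_energy_a: float
    median_energy_b: float
    median_nrs_a: float
    median_nrs_b: float
    matched_energy: float
    correction_applied: bool
    diverged: bool = False
    non_converged: tuple[str, ...] = ()


def next_energy(
    current: float,
    rating: int,
    target: float,
    step_large: float = STEP_LARGE,
    step_small: float = STEP_SMALL,
    energy_cap: float = ENERGY_CAP,
    tie: str = "hold",
) -> float:
    """Energy for the next stimulus of this staircase (J).

    The tie rule (rating exactly at target) defaults to holding the current
    energy; ``tie='down'`` steps down instead.
    """
    if current <= 0:
        raise ValueError("current energy must be > 0")
    if not 0 <= rating <= 10:
        raise ValueError("rating must lie in [0, 10]")
    if tie not in ("hold", "down"):
        raise ValueError("tie must be 'hold' or 'down'")
    if rating == 0:
        nxt = current + step_large
    elif rating < target:
        nxt = current + step_small
    elif rating > target:
        nxt = current - step_small
    else:
        nxt = current - step_small if tie == "down" else current
    clamped = min(max(nxt, step_small), energy_cap)
    if clamped != nxt:
        logger.warning("staircase energy %.2f J clamped to %.2f J", nxt, clamped)
    return round(clamped, 6)


def _interleaving(rng: np.random.Generator, n_per: int, max_run: int = MAX_CONSECUTIVE) -> list[str]:
    """Random A/B order with n_per of each and no run longer than max_run."""
    labels = ["A"] * n_per + ["B"] * n_per
    for _ in range(10_000):
        order = list(rng.permutation(labels))
        run, longest = 1, 1
        for prev, cur in zip(order, order[1:]):
            run = run + 1 if cur == prev else 1
            longest = max(longest, run)
        if longest <= max_run:
            return order
    raise RuntimeError("failed to draw a constrained interleaving")


def run_matching(
    rate: Callable[[float], int],
    target: MatchingTarget,
    seed: int | np.random.Generator = 0,
    n_trials: int = N_TRIALS_PER_STAIRCASE,
    energy_cap: float = ENERGY_CAP,
    tie: str = "hold",
    order: list[str] | None = None,
) -> tuple[dict[str, StaircaseRun], MatchResult]:
    """Run the full two-staircase matching procedure.

    ``rate`` maps a stimulus energy (J) to an integer NRS rating — a synthetic
    observer's ``simulate_rating`` or any callback. The interleaving order is
    a seeded random permutation with at most three consecutive trials of the
    same staircase (pass ``order`` to override). On a callback failure the
    partial trajectories are attached to the raised exception.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if order is None:
        order = _interleaving(rng, n_trials)
    runs = {
        sid: StaircaseRun(staircase_id=sid, energy_cap=energy_cap) for sid in ("A", "B")
    }
    current = {"A": START_ENERGY, "B": START_ENERGY}
    for sid in order:
        energy = current[sid]
        try:
            rating = int(rate(energy))
        except Exception as exc:
            exc.staircase_runs = runs  # preserve partial trajectories
            raise
        runs[sid].trials.append((energy, rating))
        current[sid] = next_energy(
            energy, rating, target.target_nrs, energy_cap=energy_cap, tie=tie
        )

    med_e = {sid: runs[sid].median_energy for sid in ("A", "B")}
    med_r = {sid: runs[sid].median_nrs for sid in ("A", "B")}
    matched = (med_e["A"] + med_e["B"]) / 2.0
    correction = (med_r["A"] + med_r["B"]) / 2.0 < target.target_nrs
    if correction:
        matched += STEP_SMALL
    diverged = abs(med_e["A"] - med_e["B"]) > DIVERGENCE_LIMIT
    if diverged:
        logger.warning(
            "staircases diverged: median energies %.2f vs %.2f J", med_e["A"], med_e["B"]
        )
    non_converged = tuple(sid for sid in ("A", "B") if runs[sid].n_reversals == 0)
    result = MatchResult(
        median_energy_a=med_e["A"],
        median_energy_b=med_e["B"],
        median_nrs_a=med_r["A"],
        median_nrs_b=med_r["B"],
        matched_energy=round(matched, 6),
        correction_applied=bool(correction),
        diverged=diverged,
        non_converged=non_converged,
    )
    return runs, result
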