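"""Pinprick and thermal rating aggregation; secondary-hyperalgesia deltas.

A pinprick block is 7 calibrated forces (8-512 mN) x 5 repetitions = 35
ratings collected before or after cream application. The analysis collapses
the block to its overall mean; mechanical hyperalgesia is the post-minus-pre
difference of block means, compared between capsaicin and sham.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .observers import PINPRICK_FORCES_MN

N_REPS_PER_FORCE = 5
N_BLOCK_RATINGS = len(PINPRICK_FORCES_MN) * N_REPS_PER_FORCE  # 35


def validate_block(block: pd.DataFrame) -> pd.DataFrame:
    """Check a tidy pinprick block (columns force_mN, nrs; 35 rows, each force
    exactly five times)."""
    if len(block) != N_BLOCK_RATINGS:
        raise ValueError(f"pinprick block must have {N_BLOCK_RATINGS} ratings, got {len(block)}")
    counts = block["force_mN"].value_counts()
    expected = set(PINPRICK_FORCES_MN)
    if set(counts.index) != expected or not (counts == N_REPS_PER_FORCE).all():
        raise ValueError("each of the 7 forces must appear exactly 5 times")
    if (block["nrs"] < 0).any() or (block["nrs"] > 10).any():
        raise ValueError("ratings must lie in [0, 10]")
    return block


def block_mean(block: pd.DataFrame) -> float:
    """Arithmetic mean of all 35 ratings of one block."""
    validate_block(block)
    return float(block["nrs"].mean())


def per_force_means(block: pd.DataFrame) -> pd.Series:
    """Diagnostic only: mean rating per force (the analysis uses block_mean)."""
    validate_block(block)
    return block.groupby("force_mN")["nrs"].mean()


def hyperalgesia_delta(pre: pd.DataFrame, post: pd.DataFrame) -> float:
    """Post-minus-pre block-mean difference (NRS).

    Both blocks must come from the same subject/condition session.
    """
    for key in ("subject", "condition"):
        if key in pre.columns and key in post.columns:
            if set(pre[key].unique()) != set(post[key].unique()):
                raise ValueError(f"pre and post blocks disagree on {key}")
    return block_mean(post) - block_mean(pre)


def session_thermal_mean(ratings, expected_n: int = 20) -> float:
    """Mean NRS over a session's per-stimulus thermal ratings.

    Warns (and averages what is available) if the count differs from the
    nominal 20-stimulus train.
    """
    ratings = np.asarray(ratings, dtype=float)
    if ratings.size != expected_n:
        warnings.warn(
            f"expected {expected_n} ratings, got {ratings.size}; averaging available ones",
            stacklevel=2,
        )
    if ratings.size == 0:
        raise ValueError("no ratings to average")
    return float(ratings.mean())
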