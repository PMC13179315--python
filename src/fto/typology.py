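"""Perceptual transition typology: the five-way partition of the FTO line.

Transitions with |FTO| below 100 ms are perceived as *smooth*; silences (and
overlaps) of 700 ms or more are perceived as unusually long.  On the real
FTO line (milliseconds):

=================  =======================
category           FTO range
=================  =======================
long_overlap       fto ≤ −700
overlap            −700 < fto ≤ −100
smooth             −100 < fto < 100
gap                100 ≤ fto < 700
long_gap           fto ≥ 700
=================  =======================

The partition is exhaustive and mutually exclusive for every finite value.
"""

from __future__ import annotations

import logging
import math
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .turn_extraction import TransitionTable

__all__ = [
    "CATEGORIES",
    "SMOOTH_THRESHOLD_MS",
    "LONG_THRESHOLD_MS",
    "categorise",
    "categorise_array",
    "category_proportions",
]

logger = logging.getLogger(__name__)

#: Category labels ordered from most negative to most positive FTO.
CATEGORIES = ("long_overlap", "overlap", "smooth", "gap", "long_gap")

SMOOTH_THRESHOLD_MS = 100.0
LONG_THRESHOLD_MS = 700.0


def categorise(fto_ms: float) -> str:
    """Map one signed FTO (ms) to its perceptual transition category."""
    if not math.isfinite(fto_ms):
        raise ValueError(f"FTO must be finite, got {fto_ms!r}")
    if fto_ms <= -LONG_THRESHOLD_MS:
        return "long_overlap"
    if fto_ms <= -SMOOTH_THRESHOLD_MS:
        return "overlap"
    if fto_ms < SMOOTH_THRESHOLD_MS:
        return "smooth"
    if fto_ms < LONG_THRESHOLD_MS:
        return "gap"
    return "long_gap"


def categorise_array(fto_ms: Iterable[float]) -> np.ndarray:
    """Vectorised :func:`categorise` for an array of finite FTO values."""
    x = np.asarray(list(fto_ms) if not isinstance(fto_ms, np.ndarray) else fto_ms, float)
    if not np.all(np.isfinite(x)):
        raise ValueError("FTO values must be finite")
    out = np.empty(x.shape, dtype=object)
    out[x <= -LONG_THRESHOLD_MS] = "long_overlap"
    out[(x > -LONG_THRESHOLD_MS) & (x <= -SMOOTH_THRESHOLD_MS)] = "overlap"
    out[(x > -SMOOTH_THRESHOLD_MS) & (x < SMOOTH_THRESHOLD_MS)] = "smooth"
    out[(x >= SMOOTH_THRESHOLD_MS) & (x < LONG_THRESHOLD_MS)] = "gap"
    out[x >= LONG_THRESHOLD_MS] = "long_gap"
    return out


def category_proportions(
    table: TransitionTable | pd.DataFrame,
    by: Sequence[str] = ("group",),
) -> pd.DataFrame:
    """Proportions of the five transition categories per grouping.

    Expects a table already filtered to floor transfers (gaps and
    between-speaker overlaps).  Returns one row per grouping with the five
    category columns in :data:`CATEGORIES` order; each row sums to 1.
    Groupings with no transitions are simply absent (logged).
    """
    df = table.df if isinstance(table, TransitionTable) else table
    df = df[df["type"].isin(["gap", "between_overlap"])].copy()
    if df["fto_ms"].isna().any():
        raise ValueError("filtered table contains rows without FTO")
    if df.empty:
        logger.info("category_proportions: empty table")
        return pd.DataFrame(columns=[*by, *CATEGORIES])
    df["category"] = categorise_array(df["fto_ms"].to_numpy())
    counts = (
        df.groupby([*by, "category"], observed=True).size().unstack("category", fill_value=0)
    )
    for cat in CATEGORIES:
        if cat not in counts.columns:
            counts[cat] = 0
    counts = counts[list(CATEGORIES)]
    props = counts.div(counts.sum(axis=1), axis=0)
    return props.reset_index()
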