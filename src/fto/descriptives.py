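"""Summary statistics for turn-timing: FTO summaries, type mixtures, balance.

These are the corpus-level descriptives of a turn-timing study: mean/SD/
median FTO by any combination of group, context and dyad; the three-way
transition-type mixture (within-speaker overlaps included); the speaker
balance score of each dyad; and a tidy per-transition export for density
plots.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .annotation_io import DyadAnnotation
from .turn_extraction import TRANSITION_TYPES, TransitionTable

__all__ = [
    "DyadSummary",
    "summarise_fto",
    "type_proportions",
    "speaker_balance",
    "export_density_data",
    "DENSITY_REFERENCE_LINES_MS",
]

logger = logging.getLogger(__name__)

#: Reference lines drawn on FTO density plots: no-gap-no-overlap (0 ms), the
#: typical-transition value (200 ms) and the unusually-long threshold (700 ms).
DENSITY_REFERENCE_LINES_MS = (0, 200, 700)


@dataclass(frozen=True)
class DyadSummary:
    """Turn-timing summary of one dyad (in one context or pooled)."""

    dyad_id: str
    group: str | None
    context: str  # a context name or "all"
    n_transitions: int
    mean_fto_ms: float
    sd_fto_ms: float | None  # None when n < 2
    median_fto_ms: float
    balance_score: float | None = None  # percentage points, [0, 100]


def _as_df(table: TransitionTable | pd.DataFrame) -> pd.DataFrame:
    return table.df if isinstance(table, TransitionTable) else table


def summarise_fto(
    table: TransitionTable | pd.DataFrame,
    by: Sequence[str] = ("group", "context"),
) -> pd.DataFrame:
    """Mean, sample SD and median FTO (ms) per grouping.

    The table must already be filtered to floor transfers.  SD uses the
    sample convention (ddof=1) and is NaN for singleton groups; medians of
    even-sized samples are the midpoint of the two central values.
    """
    df = _as_df(table)
    if df["fto_ms"].isna().any():
        raise ValueError("summarise_fto expects a table filtered to floor transfers")
    if not by:
        df = df.assign(_all="all")
        by = ["_all"]
    out = (
        df.groupby(list(by), observed=True)["fto_ms"]
        .agg(
            n_transitions="size",
            mean_fto_ms="mean",
            sd_fto_ms=lambda x: x.std(ddof=1),
            median_fto_ms="median",
        )
        .reset_index()
    )
    return out.drop(columns=["_all"], errors="ignore")


def type_proportions(
    table: TransitionTable | pd.DataFrame,
    by: Sequence[str] = ("group",),
) -> pd.DataFrame:
    """Proportions of within-speaker overlaps, between-speaker overlaps and
    gaps per grouping, on the *unfiltered* table; rows sum to 1."""
    df = _as_df(table)
    counts = (
        df.groupby([*by, "type"], observed=True).size().unstack("type", fill_value=0)
    )
    for t in TRANSITION_TYPES:
        if t not in counts.columns:
            counts[t] = 0
    counts = counts[list(TRANSITION_TYPES)]
    props = counts.div(counts.sum(axis=1), axis=0)
    return props.reset_index()


def speaker_balance(annotation: DyadAnnotation) -> float:
    """Absolute difference of the two speakers' percentage speaking time.

    Percentages use the dyad's combined speech time as denominator, making
    the score comparable across contexts with different amounts of silence.
    0 means perfectly balanced contributions; 100 means one speaker talked
    exclusively.  Raises on an entirely silent dyad.
    """
    dur_a = annotation.tier_a.speech_duration()
    dur_b = annotation.tier_b.speech_duration()
    total = dur_a + dur_b
    if total <= 0:
        raise ValueError(f"dyad {annotation.dyad_id}: both tiers silent, balance undefined")
    return abs(dur_a - dur_b) / total * 100.0


def export_density_data(
    table: TransitionTable | pd.DataFrame,
    by: Sequence[str] = ("group",),
) -> pd.DataFrame:
    """Tidy per-transition export for FTO density plots.

    One row per floor transfer with its grouping keys and ``fto_ms``; the
    standard reference lines (0, 200, 700 ms) are attached as a DataFrame
    attribute ``reference_lines_ms`` so plotting code need not re-state them.
    """
    df = _as_df(table)
    df = df[df["type"].isin(["gap", "between_overlap"])]
    out = df[[*by, "fto_ms"]].reset_index(drop=True).copy()
    out.attrs["reference_lines_ms"] = DENSITY_REFERENCE_LINES_MS
    return out
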