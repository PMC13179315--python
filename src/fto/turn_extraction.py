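"""Talkspurt extraction, floor-transfer detection and FTO computation.

A *talkspurt* is a maximal stretch of one speaker's speech bounded by
silences of at least the minimum silence length.  Scanning both speakers'
talkspurts in onset order while tracking the current floor holder yields the
three transition types of dyadic turn-taking:

* **gap** — the floor changes hands across a silence (FTO ≥ 0);
* **between-speaker overlap** — the floor changes hands while both speakers
  talk simultaneously (FTO < 0);
* **within-speaker overlap** — the non-floor-holder speaks entirely inside a
  single talkspurt of the floor holder without taking the floor (typically a
  backchannel); no FTO is defined and these rows are excluded from the FTO
  analysis.

The Floor Transfer Offset (FTO) of a transfer is the signed time from the
end of the floor holder's final talkspurt to the onset of the next speaker's
first talkspurt, reported in integer milliseconds.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .annotation_io import DyadAnnotation, IntervalTier

__all__ = [
    "TRANSITION_TYPES",
    "TABLE_COLUMNS",
    "Talkspurt",
    "Transition",
    "TransitionTable",
    "extract_talkspurts",
    "extract_transitions",
    "filter_for_fto",
]

logger = logging.getLogger(__name__)

TRANSITION_TYPES = ("gap", "between_overlap", "within_overlap")

TABLE_COLUMNS = [
    "dyad_id",
    "group",
    "context",
    "type",
    "fto_ms",
    "prev_speaker",
    "next_speaker",
    "anchor_time_s",
]


@dataclass(frozen=True)
class Talkspurt:
    """A maximal speech stretch of one speaker."""

    speaker_id: str
    start: float
    end: float

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass(frozen=True)
class Transition:
    """One turn-taking event; ``fto_ms`` is None for within-speaker overlaps."""

    dyad_id: str
    group: str | None
    context: str | None
    type: str
    fto_ms: int | None
    prev_speaker: str
    next_speaker: str
    anchor_time_s: float


@dataclass
class TransitionTable:
    """Long-format table of transitions — the backbone of the analysis.

    Wraps a pandas DataFrame with :data:`TABLE_COLUMNS` plus a provenance
    dict recording where the rows came from and with which parameters.
    """

    df: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in TABLE_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"transition table missing columns: {missing}")
        self.df = (
            self.df.sort_values(["dyad_id", "context", "anchor_time_s"], kind="stable")
            .reset_index(drop=True)
        )

    def __len__(self) -> int:
        return len(self.df)

    @property
    def rows(self) -> list[Transition]:
        out = []
        for r in self.df.itertuples(index=False):
            fto = None if pd.isna(r.fto_ms) else int(r.fto_ms)
            out.append(
                Transition(
                    r.dyad_id,
                    None if pd.isna(r.group) else r.group,
                    None if pd.isna(r.context) else r.context,
                    r.type,
                    fto,
                    r.prev_speaker,
                    r.next_speaker,
                    float(r.anchor_time_s),
                )
            )
        return out

    @classmethod
    def from_transitions(
        cls, transitions: Iterable[Transition], provenance: dict | None = None
    ) -> "TransitionTable":
        recs = [
            (
                t.dyad_id,
                t.group,
                t.context,
                t.type,
                np.nan if t.fto_ms is None else float(t.fto_ms),
                t.prev_speaker,
                t.next_speaker,
                t.anchor_time_s,
            )
            for t in transitions
        ]
        df = pd.DataFrame(recs, columns=TABLE_COLUMNS)
        return cls(df, provenance or {})

    @classmethod
    def concat(cls, tables: Sequence["TransitionTable"]) -> "TransitionTable":
        if not tables:
            return cls(pd.DataFrame(columns=TABLE_COLUMNS))
        df = pd.concat([t.df for t in tables], ignore_index=True)
        prov: dict = {"merged_from": [t.provenance for t in tables if t.provenance]}
        return cls(df, prov)

    def to_csv(self, path: str | Path, *, sidecar: bool = True) -> None:
        path = Path(path)
        out = self.df.copy()
        out["fto_ms"] = out["fto_ms"].astype("Int64")
        out.to_csv(path, index=False)
        if sidecar:
            path.with_suffix(".provenance.json").write_text(
                json.dumps(self.provenance, indent=2, default=str)
            )

    @classmethod
    def read_csv(cls, path: str | Path) -> "TransitionTable":
        path = Path(path)
        df = pd.read_csv(path)
        df["fto_ms"] = pd.to_numeric(df["fto_ms"], errors="coerce")
        sidecar = path.with_suffix(".provenance.json")
        prov = json.loads(sidecar.read_text()) if sidecar.exists() else {}
        return cls(df, prov)

    def type_counts(self) -> dict[str, int]:
        counts = self.df["type"].value_counts().to_dict()
        return {t: int(counts.get(t, 0)) for t in TRANSITION_TYPES}


# ---------------------------------------------------------------------------
# Extraction
# ---------------------------------------------------------------------------


def extract_talkspurts(tier: IntervalTier) -> list[Talkspurt]:
    """One talkspurt per maximal speech interval, in temporal order."""
    return [
        Talkspurt(tier.speaker_id, iv.start, iv.end) for iv in tier.speech_intervals()
    ]


def _initial_floor_holder(starts, ends, speakers) -> str:
    """Earliest onset holds the floor; simultaneous starts go to the spurt
    ending later, then to the lexicographically smaller speaker id."""
    first = starts == starts.min()
    if first.sum() == 1:
        return speakers[int(np.argmax(first))]
    cand = np.flatnonzero(first)
    latest = cand[ends[cand] == ends[cand].max()]
    if len(latest) > 1:
        choice = min(speakers[i] for i in latest)
        logger.info("simultaneous identical starts; floor given to %r", choice)
        return choice
    return speakers[int(latest[0])]


def extract_transitions(annotation: DyadAnnotation) -> TransitionTable:
    """Detect all floor transfers and within-speaker overlaps of a dyad.

    Both tiers must already be normalised (silences ≥ the minimum silence
    length).  Talkspurts of both speakers are processed in onset order with
    a running floor holder F:

    * a talkspurt T by the other speaker B that lies strictly inside a single
      talkspurt of F (some F-spurt starts strictly before T and ends strictly
      after it) is a within-speaker overlap — the floor does not move;
    * otherwise the floor transfers to B with
      ``FTO = T.start − max{end of F-spurts starting at or before T.start}``;
      FTO ≥ 0 is a gap, FTO < 0 a between-speaker overlap (classified on the
      rounded millisecond value, so |FTO| < 0.5 ms counts as a gap);
    * consecutive talkspurts by the same speaker produce no transition
      (within-speaker pause).

    When two talkspurts share identical boundaries neither strictly contains
    the other, so the floor transfers with FTO = −duration.
    """
    spurts = sorted(
        extract_talkspurts(annotation.tier_a) + extract_talkspurts(annotation.tier_b),
        key=lambda s: (s.start, s.end, s.speaker_id),
    )
    if not spurts:
        return TransitionTable(
            pd.DataFrame(columns=TABLE_COLUMNS),
            {"dyad_id": annotation.dyad_id, "n_talkspurts": 0},
        )

    starts = np.array([s.start for s in spurts])
    ends = np.array([s.end for s in spurts])
    speakers = [s.speaker_id for s in spurts]
    spk_arr = np.array(speakers)

    floor = _initial_floor_holder(starts, ends, speakers)
    transitions: list[Transition] = []
    n_dropped = 0

    for i, spurt in enumerate(spurts):
        if spurt.speaker_id == floor:
            continue
        is_floor = spk_arr == floor
        strict_mask = is_floor & (starts < spurt.start - 1e-12)
        le_mask = is_floor & (starts <= spurt.start + 1e-12)
        max_end_strict = ends[strict_mask].max() if strict_mask.any() else -np.inf
        if max_end_strict > spurt.end + 1e-12:
            transitions.append(
                Transition(
                    annotation.dyad_id,
                    annotation.group,
                    annotation.context,
                    "within_overlap",
                    None,
                    floor,
                    spurt.speaker_id,
                    spurt.start,
                )
            )
            continue
        if not le_mask.any():
            # floor holder's turn end is not available — drop, mirroring the
            # exclusion of transitions with unlabelled turn ends
            n_dropped += 1
            logger.warning(
                "dyad %s: dropped transfer at %.3f s (no preceding floor-holder end)",
                annotation.dyad_id,
                spurt.start,
            )
            floor = spurt.speaker_id
            continue
        anchor = float(ends[le_mask].max())
        fto_ms = int(np.rint((spurt.start - anchor) * 1000.0))
        transitions.append(
            Transition(
                annotation.dyad_id,
                annotation.group,
                annotation.context,
                "gap" if fto_ms >= 0 else "between_overlap",
                fto_ms,
                floor,
                spurt.speaker_id,
                anchor,
            )
        )
        floor = spurt.speaker_id

    provenance = {
        "dyad_id": annotation.dyad_id,
        "group": annotation.group,
        "context": annotation.context,
        "n_talkspurts": len(spurts),
        "n_dropped_unanchored": n_dropped,
    }
    return TransitionTable.from_transitions(transitions, provenance)


def filter_for_fto(table: TransitionTable) -> TransitionTable:
    """Keep only true floor transfers (gaps and between-speaker overlaps).

    Within-speaker overlaps carry no FTO and are excluded from the
    turn-timing analysis; the excluded count is recorded in provenance.
    """
    keep = table.df["type"].isin(["gap", "between_overlap"])
    n_excluded = int((~keep).sum())
    prov = dict(table.provenance)
    prov.update({"n_excluded_within_overlap": n_excluded, "n_retained": int(keep.sum())})
    logger.info("excluded %d within-speaker overlaps", n_excluded)
    return TransitionTable(table.df[keep].reset_index(drop=True), prov)
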