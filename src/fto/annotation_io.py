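"""Reading, validating, normalising and writing two-speaker interval annotations.

The pipeline consumes per-dyad, per-context pairs of interval tiers marking
speech versus silence, one tier per speaker, in Praat TextGrid format (both
the "long" and "short" text dialects) or as a plain interval CSV.  Annotation
conventions follow standard turn-timing practice: silences shorter than a
minimum silence length (200 ms by default) are not treated as breaks in
speech, so :func:`normalise_tier` absorbs them into the surrounding talk.

Time is held in seconds (floats) internally; downstream modules report floor
transfer offsets in integer milliseconds.  Intervals are half-open
``[start, end)`` — two intervals are adjacent exactly when ``prev.end ==
next.start``.
"""

from __future__ import annotations

import io
import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "GROUPS",
    "CONTEXTS",
    "MIN_SILENCE_S",
    "DEFAULT_SILENCE_LABELS",
    "Interval",
    "IntervalTier",
    "DyadAnnotation",
    "AnnotationError",
    "TierNotFoundError",
    "TextGridFormatError",
    "ValidationError",
    "read_textgrid",
    "write_textgrid",
    "normalise_tier",
    "read_interval_csv",
    "write_interval_csv",
    "load_metadata",
    "load_corpus",
]

logger = logging.getLogger(__name__)

#: Diagnostic groups of the study design (reference level first).
GROUPS = ("ASD", "non-ASD")

#: Conversational contexts in their fixed presentation order.
CONTEXTS = ("Introduction", "Tangram", "Discussion")

#: Minimum silence length in seconds: shorter within-speaker silences are not
#: breaks in speech and are absorbed by :func:`normalise_tier`.
MIN_SILENCE_S = 0.200

#: Interval labels interpreted as silence (after whitespace stripping).
DEFAULT_SILENCE_LABELS = frozenset({"", "sil", "<p>"})

_TIME_EPS = 1e-9


class AnnotationError(Exception):
    """Base class for annotation input errors."""


class TierNotFoundError(AnnotationError):
    """A requested tier name is absent from the TextGrid."""


class TextGridFormatError(AnnotationError):
    """The file is not a parseable interval-tier TextGrid."""


class ValidationError(AnnotationError):
    """An annotation violates the interval-tier invariants."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Interval:
    """A labelled half-open time interval ``[start, end)`` in seconds."""

    start: float
    end: float
    kind: str  # "speech" | "silence"

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass(frozen=True)
class IntervalTier:
    """One speaker's speech/silence timeline.

    Intervals tile ``[0, total_duration]``: they are sorted, non-overlapping
    and gap-free (construction inserts silence into uncovered stretches).
    """

    speaker_id: str
    intervals: tuple[Interval, ...]
    total_duration: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "intervals", tuple(self.intervals))
        self.validate()

    def validate(self) -> None:
        if self.total_duration <= 0:
            raise ValidationError(f"tier {self.speaker_id!r}: non-positive duration")
        prev_end = 0.0
        for iv in self.intervals:
            if iv.end <= iv.start + _TIME_EPS:
                raise ValidationError(
                    f"tier {self.speaker_id!r}: empty/negative interval "
                    f"[{iv.start}, {iv.end}]"
                )
            if iv.start < prev_end - _TIME_EPS:
                raise ValidationError(
                    f"tier {self.speaker_id!r}: overlapping intervals at {iv.start:.3f}"
                )
            if iv.kind not in ("speech", "silence"):
                raise ValidationError(f"unknown interval kind {iv.kind!r}")
            prev_end = iv.end
        if self.intervals and self.intervals[-1].end > self.total_duration + 1e-6:
            raise ValidationError(
                f"tier {self.speaker_id!r}: interval ends beyond total duration"
            )

    @classmethod
    def from_speech_intervals(
        cls,
        speaker_id: str,
        speech: Iterable[tuple[float, float]],
        total_duration: float,
    ) -> "IntervalTier":
        """Build a gap-free tier from speech spans, tiling silence between them."""
        spans = sorted((float(a), float(b)) for a, b in speech)
        out: list[Interval] = []
        cursor = 0.0
        for a, b in spans:
            if a > cursor + _TIME_EPS:
                out.append(Interval(cursor, a, "silence"))
            out.append(Interval(a, b, "speech"))
            cursor = b
        if cursor < total_duration - _TIME_EPS:
            out.append(Interval(cursor, total_duration, "silence"))
        return cls(speaker_id, tuple(out), total_duration)

    def speech_intervals(self) -> list[Interval]:
        return [iv for iv in self.intervals if iv.kind == "speech"]

    def speech_duration(self) -> float:
        return sum(iv.duration for iv in self.intervals if iv.kind == "speech")


@dataclass(frozen=True)
class DyadAnnotation:
    """The two-channel speech/silence timeline for one dyad in one context."""

    dyad_id: str
    tier_a: IntervalTier
    tier_b: IntervalTier
    group: str | None = None
    context: str | None = None

    def __post_init__(self) -> None:
        if self.tier_a.speaker_id == self.tier_b.speaker_id:
            raise ValidationError("the two tiers must have distinct speaker ids")
        if abs(self.tier_a.total_duration - self.tier_b.total_duration) > 1e-3:
            raise ValidationError("tiers must share total_duration")
        if self.group is not None and self.group not in GROUPS:
            raise ValidationError(f"unknown group {self.group!r}; expected one of {GROUPS}")
        if self.context is not None and self.context not in CONTEXTS:
            raise ValidationError(
                f"unknown context {self.context!r}; expected one of {CONTEXTS}"
            )

    @property
    def total_duration(self) -> float:
        return self.tier_a.total_duration

    def tiers(self) -> tuple[IntervalTier, IntervalTier]:
        return (self.tier_a, self.tier_b)

    def normalised(self, min_silence_s: float = MIN_SILENCE_S) -> "DyadAnnotation":
        """Return a copy with both tiers passed through :func:`normalise_tier`."""
        return replace(
            self,
            tier_a=normalise_tier(self.tier_a, min_silence_s),
            tier_b=normalise_tier(self.tier_b, min_silence_s),
        )


# ---------------------------------------------------------------------------
# TextGrid parsing
# ---------------------------------------------------------------------------


def _decode_textgrid_bytes(raw: bytes) -> str:
    if raw.startswith(b"\xff\xfe") or raw.startswith(b"\xfe\xff"):
        return raw.decode("utf-16")
    if raw.startswith(b"\xef\xbb\xbf"):
        return raw.decode("utf-8-sig")
    try:
        return raw.decode("utf-8")
    except UnicodeDecodeError:
        return raw.decode("latin-1")


_STRUCT_RE = re.compile(r"^\s*(item|intervals|points)\s*\[\d*\]\s*:?\s*$")


def _tokenise_textgrid(text: str) -> list[str]:
    """Flatten either TextGrid dialect into a stream of value tokens.

    In the long dialect values sit right of ``=`` and structural lines
    (``item [1]:`` …) are skipped; in the short dialect every non-empty line
    after the two header lines is a value.
    """
    lines = text.splitlines()
    if not lines or "ooTextFile" not in lines[0]:
        raise TextGridFormatError("not an ooTextFile TextGrid")
    tokens: list[str] = []
    for line in lines[1:]:
        stripped = line.strip()
        if not stripped or stripped.startswith("Object class"):
            continue
        if "<exists>" in stripped:
            tokens.append("<exists>")
            continue
        if "=" in stripped and not stripped.startswith('"'):
            # long dialect: keyword = value (also "intervals: size = n")
            tokens.append(stripped.split("=", 1)[1].strip())
        elif _STRUCT_RE.match(stripped) or stripped.endswith("[]:"):
            continue
        else:
            tokens.append(stripped)
    return tokens


def _unquote(token: str) -> str:
    token = token.strip()
    if len(token) >= 2 and token.startswith('"') and token.endswith('"'):
        return token[1:-1].replace('""', '"')
    return token


class _TokenStream:
    def __init__(self, tokens: Sequence[str]):
        self._tokens = list(tokens)
        self._i = 0

    def next(self) -> str:
        if self._i >= len(self._tokens):
            raise TextGridFormatError("unexpected end of TextGrid")
        tok = self._tokens[self._i]
        self._i += 1
        return tok

    def next_float(self) -> float:
        tok = self.next()
        try:
            return float(tok)
        except ValueError as exc:
            raise TextGridFormatError(f"expected a number, got {tok!r}") from exc

    def next_int(self) -> int:
        return int(self.next_float())

    def next_str(self) -> str:
        return _unquote(self.next())


def _parse_textgrid(text: str) -> dict[str, tuple[str, list[tuple[float, float, str]]]]:
    """Parse a TextGrid into ``{tier_name: (tier_class, [(xmin, xmax, label)])}``.

    Point tiers are recorded with an empty interval list so that requesting
    one by name raises a format error rather than a missing-tier error.
    """
    stream = _TokenStream(_tokenise_textgrid(text))
    stream.next_float()  # global xmin
    stream.next_float()  # global xmax
    tok = stream.next()
    if tok != "<exists>":
        raise TextGridFormatError("TextGrid has no tiers (<exists> flag missing)")
    n_tiers = stream.next_int()
    tiers: dict[str, tuple[str, list[tuple[float, float, str]]]] = {}
    for _ in range(n_tiers):
        tier_class = stream.next_str()
        name = stream.next_str()
        stream.next_float()  # tier xmin
        stream.next_float()  # tier xmax
        size = stream.next_int()
        if tier_class == "IntervalTier":
            ivs = []
            for _ in range(size):
                xmin = stream.next_float()
                xmax = stream.next_float()
                label = stream.next_str()
                ivs.append((xmin, xmax, label))
            tiers[name] = (tier_class, ivs)
        elif tier_class == "TextTier":
            for _ in range(size):
                stream.next_float()
                stream.next_str()
            tiers[name] = (tier_class, [])
        else:
            raise TextGridFormatError(f"unknown tier class {tier_class!r}")
    return tiers


def _tier_from_raw(
    name: str,
    raw: list[tuple[float, float, str]],
    total_duration: float,
    silence_labels: frozenset[str],
) -> IntervalTier:
    speech: list[tuple[float, float]] = []
    prev_end = 0.0
    for xmin, xmax, label in sorted(raw):
        if xmin < prev_end - 1e-6:
            raise ValidationError(f"tier {name!r}: overlapping intervals at {xmin:.3f}")
        prev_end = xmax
        if label.strip() not in silence_labels:
            speech.append((xmin, xmax))
    # merge adjacent speech spans (zero-width gaps)
    merged: list[tuple[float, float]] = []
    for a, b in speech:
        if merged and a <= merged[-1][1] + _TIME_EPS:
            merged[-1] = (merged[-1][0], max(merged[-1][1], b))
        else:
            merged.append((a, b))
    return IntervalTier.from_speech_intervals(name, merged, total_duration)


def read_textgrid(
    path: str | Path,
    tier_names: tuple[str, str],
    *,
    dyad_id: str | None = None,
    group: str | None = None,
    context: str | None = None,
    silence_labels: Iterable[str] = DEFAULT_SILENCE_LABELS,
) -> DyadAnnotation:
    """Read a two-speaker TextGrid (long or short dialect) into a :class:`DyadAnnotation`.

    Blank labels — and any label in ``silence_labels`` after whitespace
    stripping — map to silence; every other label counts as speech.

    Raises
    ------
    TierNotFoundError
        if either of ``tier_names`` is missing.
    TextGridFormatError
        if the file is not a parseable TextGrid, or a requested tier is a
        point tier.
    ValidationError
        if a tier contains overlapping intervals.
    """
    path = Path(path)
    text = _decode_textgrid_bytes(path.read_bytes())
    tiers = _parse_textgrid(text)
    silence_set = frozenset(s.strip() for s in silence_labels)
    built: list[IntervalTier] = []
    total = max(
        (max((iv[1] for iv in raw), default=0.0) for _, raw in tiers.values()),
        default=0.0,
    )
    for name in tier_names:
        if name not in tiers:
            raise TierNotFoundError(
                f"tier {name!r} not found in {path.name}; present: {sorted(tiers)}"
            )
        tier_class, raw = tiers[name]
        if tier_class != "IntervalTier":
            raise TextGridFormatError(f"tier {name!r} in {path.name} is a point tier")
        built.append(_tier_from_raw(name, raw, total, silence_set))
    return DyadAnnotation(
        dyad_id=dyad_id or path.stem,
        tier_a=built[0],
        tier_b=built[1],
        group=group,
        context=context,
    )


# ---------------------------------------------------------------------------
# TextGrid writing
# ---------------------------------------------------------------------------


def _quote(label: str) -> str:
    return '"' + label.replace('"', '""') + '"'


def _tier_rows(tier: IntervalTier) -> list[tuple[float, float, str]]:
    rows = [(iv.start, iv.end, "" if iv.kind == "silence" else "speech") for iv in tier.intervals]
    if not rows:
        rows = [(0.0, tier.total_duration, "")]
    return rows


def write_textgrid(
    annotation: DyadAnnotation,
    path: str | Path,
    *,
    dialect: str = "long",
) -> None:
    """Write a :class:`DyadAnnotation` as a two-tier TextGrid.

    Speech intervals are labelled ``speech`` and silences get empty labels,
    so ``read_textgrid(write_textgrid(x))`` is the identity up to rounding
    (times are written with microsecond precision, well inside the 1 ms
    round-trip tolerance).
    """
    if dialect not in ("long", "short"):
        raise ValueError(f"unknown TextGrid dialect {dialect!r}")
    for tier in annotation.tiers():
        tier.validate()
    total = annotation.total_duration
    buf = io.StringIO()
    w = buf.write
    if dialect == "long":
        w('File type = "ooTextFile"\nObject class = "TextGrid"\n\n')
        w(f"xmin = 0\nxmax = {total:.6f}\ntiers? <exists>\nsize = 2\nitem []:\n")
        for t_idx, tier in enumerate(annotation.tiers(), start=1):
            rows = _tier_rows(tier)
            w(f"    item [{t_idx}]:\n")
            w('        class = "IntervalTier"\n')
            w(f"        name = {_quote(tier.speaker_id)}\n")
            w(f"        xmin = 0\n        xmax = {total:.6f}\n")
            w(f"        intervals: size = {len(rows)}\n")
            for i_idx, (a, b, label) in enumerate(rows, start=1):
                w(f"        intervals [{i_idx}]:\n")
                w(f"            xmin = {a:.6f}\n            xmax = {b:.6f}\n")
                w(f"            text = {_quote(label)}\n")
    else:
        w('File type = "ooTextFile"\nObject class = "TextGrid"\n\n')
        w(f"0\n{total:.6f}\n<exists>\n2\n")
        for tier in annotation.tiers():
            rows = _tier_rows(tier)
            w(f'"IntervalTier"\n{_quote(tier.speaker_id)}\n0\n{total:.6f}\n{len(rows)}\n')
            for a, b, label in rows:
                w(f"{a:.6f}\n{b:.6f}\n{_quote(label)}\n")
    Path(path).write_text(buf.getvalue(), encoding="utf-8")


# ---------------------------------------------------------------------------
# Normalisation
# ---------------------------------------------------------------------------


def normalise_tier(tier: IntervalTier, min_silence_s: float = MIN_SILENCE_S) -> IntervalTier:
    """Absorb sub-threshold internal silences into the surrounding speech.

    Every silence strictly between two speech intervals whose duration is
    shorter than ``min_silence_s`` is merged into one continuous stretch of
    speech; silences of at least ``min_silence_s`` — and leading/trailing
    silence, whatever its length — are left untouched.  Idempotent, and
    conserves total tier duration.
    """
    speech = [(iv.start, iv.end) for iv in tier.intervals if iv.kind == "speech"]
    if not speech:
        return tier
    merged: list[tuple[float, float]] = [speech[0]]
    for a, b in speech[1:]:
        prev_a, prev_b = merged[-1]
        if a - prev_b < min_silence_s - _TIME_EPS:
            merged[-1] = (prev_a, b)
        else:
            merged.append((a, b))
    return IntervalTier.from_speech_intervals(tier.speaker_id, merged, tier.total_duration)


# ---------------------------------------------------------------------------
# Interval CSV and corpus metadata
# ---------------------------------------------------------------------------

_CSV_COLUMNS = ["dyad_id", "speaker", "start_s", "end_s", "kind"]


def write_interval_csv(annotation: DyadAnnotation, path: str | Path) -> None:
    """Write the annotation as a long-format interval CSV (alternate to TextGrid)."""
    rows = []
    for tier in annotation.tiers():
        for iv in tier.intervals:
            rows.append((annotation.dyad_id, tier.speaker_id, iv.start, iv.end, iv.kind))
    pd.DataFrame(rows, columns=_CSV_COLUMNS).to_csv(path, index=False)


def read_interval_csv(
    path: str | Path,
    *,
    dyad_id: str | None = None,
    group: str | None = None,
    context: str | None = None,
    total_duration: float | None = None,
) -> DyadAnnotation:
    """Read an interval CSV with columns (dyad_id, speaker, start_s, end_s, kind).

    Silence rows are optional: tiers are rebuilt from the speech rows and
    silence is tiled into the uncovered stretches.
    """
    df = pd.read_csv(path)
    missing = [c for c in _CSV_COLUMNS if c not in df.columns]
    if missing:
        raise AnnotationError(f"interval CSV missing columns: {missing}")
    if dyad_id is not None:
        df = df[df["dyad_id"] == dyad_id]
    elif df["dyad_id"].nunique() != 1:
        raise AnnotationError("interval CSV holds multiple dyads; pass dyad_id")
    speakers = sorted(df["speaker"].unique())
    if len(speakers) != 2:
        raise AnnotationError(f"expected 2 speakers, found {speakers}")
    total = float(total_duration if total_duration is not None else df["end_s"].max())
    tiers = []
    for spk in speakers:
        sub = df[(df["speaker"] == spk) & (df["kind"] == "speech")]
        tiers.append(
            IntervalTier.from_speech_intervals(
                str(spk), list(zip(sub["start_s"], sub["end_s"])), total
            )
        )
    return DyadAnnotation(
        dyad_id=str(df["dyad_id"].iloc[0]),
        tier_a=tiers[0],
        tier_b=tiers[1],
        group=group,
        context=context,
    )


_METADATA_COLUMNS = ["dyad_id", "group", "context", "path", "tier_a", "tier_b"]


def load_metadata(path: str | Path) -> pd.DataFrame:
    """Load the corpus metadata CSV (dyad_id, group, context, path, tier_a, tier_b)."""
    df = pd.read_csv(path)
    missing = [c for c in _METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise AnnotationError(f"metadata CSV missing columns: {missing}")
    bad_groups = set(df["group"]) - set(GROUPS)
    if bad_groups:
        raise AnnotationError(f"metadata has unknown groups: {sorted(bad_groups)}")
    bad_ctx = set(df["context"]) - set(CONTEXTS)
    if bad_ctx:
        raise AnnotationError(f"metadata has unknown contexts: {sorted(bad_ctx)}")
    return df


def load_corpus(
    metadata_path: str | Path,
    *,
    base_dir: str | Path | None = None,
    silence_labels: Iterable[str] = DEFAULT_SILENCE_LABELS,
) -> list[DyadAnnotation]:
    """Load every dyad×context annotation listed in a metadata CSV."""
    metadata_path = Path(metadata_path)
    base = Path(base_dir) if base_dir is not None else metadata_path.parent
    out = []
    for row in load_metadata(metadata_path).itertuples(index=False):
        file_path = Path(row.path)
        if not file_path.is_absolute():
            file_path = base / file_path
        out.append(
            read_textgrid(
                file_path,
                (row.tier_a, row.tier_b),
                dyad_id=row.dyad_id,
                group=row.group,
                context=row.context,
                silence_labels=silence_labels,
            )
        )
    return out
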