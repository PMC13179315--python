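"""Independent reference implementations used as test oracles.

Deliberately written in a different style from the package code: plain
Python loops, full re-scans of all talkspurt pairs at every event, no
incremental state beyond the floor holder.  Slow but simple to audit.
"""

from __future__ import annotations


def brute_force_transitions(
    spurts_a: list[tuple[float, float]],
    spurts_b: list[tuple[float, float]],
    id_a: str = "S1",
    id_b: str = "S2",
) -> list[tuple]:
    """Reference floor-transfer detector enumerating all talkspurt pairs.

    Returns (type, fto_ms, prev, next, anchor) tuples in event order.
    """
    everything = [(s, e, id_a) for s, e in spurts_a] + [
        (s, e, id_b) for s, e in spurts_b
    ]
    everything.sort(key=lambda t: (t[0], t[1], t[2]))
    if not everything:
        return []

    # initial floor: earliest start, then later end, then smaller speaker id
    first_start = min(s for s, _, _ in everything)
    firsts = [t for t in everything if t[0] == first_start]
    max_end = max(e for _, e, _ in firsts)
    floor = min(spk for _, e, spk in firsts if e == max_end)

    events = []
    for s, e, spk in everything:
        if spk == floor:
            continue
        floor_spurts = [(a, b) for a, b, f in everything if f == floor]
        if any(a < s and b > e for a, b in floor_spurts):
            events.append(("within_overlap", None, floor, spk, s))
            continue
        prior_ends = [b for a, b in floor_spurts if a <= s]
        if not prior_ends:
            floor = spk
            continue
        anchor = max(prior_ends)
        fto_ms = round((s - anchor) * 1000)
        kind = "gap" if fto_ms >= 0 else "between_overlap"
        events.append((kind, fto_ms, floor, spk, anchor))
        floor = spk
    return events


def random_grid_timeline(rng, max_spurts: int = 6, grid: float = 0.1, horizon: float = 10.0):
    """Random two-speaker timeline on a time grid with ≥200 ms same-speaker
    separation; returns (spurts_a, spurts_b)."""
    n_total = int(rng.integers(1, max_spurts + 1))
    n_a = int(rng.integers(0, n_total + 1))
    counts = (n_a, n_total - n_a)
    out = []
    for n in counts:
        spurts: list[tuple[float, float]] = []
        attempts = 0
        while len(spurts) < n and attempts < 200:
            attempts += 1
            start = round(float(rng.integers(0, int(horizon / grid) - 2)) * grid, 3)
            dur = round(float(rng.integers(2, 31)) * grid, 3)
            end = round(min(start + dur, horizon), 3)
            if end - start < 2 * grid - 1e-9:
                continue
            ok = all(
                end + 2 * grid - 1e-9 <= s or start >= e + 2 * grid - 1e-9
                for s, e in spurts
            )
            if ok:
                spurts.append((start, end))
        out.append(sorted(spurts))
    return out[0], out[1]


def enumerate_coarse_timelines(horizon: int = 6, max_per_speaker: int = 2):
    """Exhaustively enumerate two-speaker timelines on a 1-second grid.

    Each speaker has 0..max_per_speaker spurts with integer boundaries in
    [0, horizon] and at least 1 s between their own spurts.  Yields
    (spurts_a, spurts_b) pairs, skipping the doubly-empty timeline.
    """
    singles = [
        (float(s), float(e)) for s in range(horizon) for e in range(s + 1, horizon + 1)
    ]
    layouts: list[list[tuple[float, float]]] = [[]]
    layouts += [[iv] for iv in singles]
    if max_per_speaker >= 2:
        for first in singles:
            for second in singles:
                if second[0] >= first[1] + 1.0:
                    layouts.append([first, second])
    for a in layouts:
        for b in layouts:
            if a or b:
                yield a, b
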