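"""Synthetic dyadic-conversation corpora with known ground truth.

The generator builds two-channel talkspurt timelines per dyad and context by
alternating floor holders: each turn draws a log-normal duration, a sequence
of transition events from a type mixture (within-speaker overlap /
between-speaker overlap / gap), and — for floor transfers — a signed FTO
from the dyad's ex-Gaussian.  The next speaker's onset is placed exactly at
``turn_end + FTO``, within-speaker overlaps are placed strictly inside the
current turn with at least 200 ms clearance from its edges, and every
within-speaker silence is at least 200 ms, so the extraction pipeline
recovers every injected transition exactly (type label for label, FTO to
the millisecond).  That round-trip exactness is the module's core
guarantee and the backbone of the test suite.

Sign handling has two modes.  In ``"exgauss"`` mode a single ex-Gaussian
draw decides both the transfer's FTO and its gap/overlap label, so the
empirical FTO mean converges to ``mu + tau`` per cell.  In ``"fixed"`` mode
(the study-scale preset) the gap/overlap split follows the configured type
mixture and the ex-Gaussian is truncated to the matching sign; the preset's
per-cell parameters are calibrated so that the resulting sign-split mixture
reproduces the target mean/SD/median FTO summaries.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import optimize

from .annotation_io import CONTEXTS, GROUPS, MIN_SILENCE_S, DyadAnnotation, IntervalTier, write_textgrid
from .exgauss import ExGaussParams, exgauss_logpdf
from .turn_extraction import TABLE_COLUMNS

__all__ = [
    "CellParams",
    "SimulationConfig",
    "SimTruth",
    "CorpusResult",
    "REFERENCE_SUMMARY",
    "REFERENCE_TYPE_MIXTURE",
    "sign_split_moments",
    "calibrate_cell",
    "paper_preset",
    "simulate_dyad",
    "simulate_corpus",
]

logger = logging.getLogger(__name__)

_CLEAR_S = 0.200  # clearance around within-speaker overlaps, and minimum silence

# ---------------------------------------------------------------------------
# Published summary targets for the study-scale preset
# ---------------------------------------------------------------------------

#: Group×context FTO summaries (mean, SD, median; ms) that the study-scale
#: preset is calibrated to reproduce.
REFERENCE_SUMMARY: dict[tuple[str, str], tuple[float, float, float]] = {
    ("ASD", "Introduction"): (446.0, 933.0, 299.0),
    ("ASD", "Tangram"): (663.0, 1188.0, 370.0),
    ("ASD", "Discussion"): (403.0, 887.0, 265.0),
    ("non-ASD", "Introduction"): (91.0, 459.0, 117.0),
    ("non-ASD", "Tangram"): (316.0, 706.0, 197.0),
    ("non-ASD", "Discussion"): (164.0, 695.0, 137.0),
}

#: Transition-type mixtures per group: (within-speaker overlap,
#: between-speaker overlap, gap).
REFERENCE_TYPE_MIXTURE: dict[str, tuple[float, float, float]] = {
    "ASD": (0.181, 0.196, 0.623),
    "non-ASD": (0.249, 0.247, 0.504),
}

#: Pooled per-group FTO summaries (mean, SD, median; ms).
REFERENCE_GROUP_SUMMARY: dict[str, tuple[float, float, float]] = {
    "ASD": (512.0, 1027.0, 307.0),
    "non-ASD": (188.0, 634.0, 149.0),
}


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CellParams:
    """Generative parameters for one group×context cell."""

    exgauss: ExGaussParams
    p_within: float
    p_between: float
    p_gap: float
    turn_mean_s: float = 2.6
    turn_sigma_log: float = 0.6

    def __post_init__(self) -> None:
        total = self.p_within + self.p_between + self.p_gap
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"type mixture must sum to 1, got {total}")
        if min(self.p_within, self.p_between, self.p_gap) < 0:
            raise ValueError("mixture probabilities must be non-negative")
        if self.turn_mean_s <= 0.4:
            raise ValueError("mean turn duration too short to host transitions")

    @property
    def p_gap_conditional(self) -> float:
        """Probability that a floor transfer is a gap (rather than an overlap)."""
        transfer = self.p_between + self.p_gap
        if transfer <= 0:
            raise ValueError("mixture assigns zero probability to floor transfers")
        return self.p_gap / transfer


@dataclass(frozen=True)
class SimulationConfig:
    """Full generative specification of a synthetic corpus."""

    cells: dict[tuple[str, str], CellParams]
    n_dyads: dict[str, int] = field(default_factory=lambda: {"ASD": 9, "non-ASD": 14})
    contexts: tuple[str, ...] = CONTEXTS
    context_duration_s: float = 600.0
    dyad_sd_mu_ms: float = 150.0
    dyad_sd_logit_within: float = 0.3
    p_pause: float = 0.15  # chance of a ≥200 ms within-speaker pause per turn
    within_dur_range_s: tuple[float, float] = (0.2, 0.8)
    sign_split: str = "fixed"  # "fixed" | "exgauss"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sign_split not in ("fixed", "exgauss"):
            raise ValueError(f"unknown sign_split mode {self.sign_split!r}")
        if min(self.n_dyads.values()) < 1:
            raise ValueError("need at least one dyad per group")
        if self.context_duration_s < 10:
            raise ValueError("context too short to host a conversation")
        for g in self.n_dyads:
            if g not in GROUPS:
                raise ValueError(f"unknown group {g!r}")
            for c in self.contexts:
                if (g, c) not in self.cells:
                    raise ValueError(f"missing cell parameters for ({g}, {c})")
        lo, hi = self.within_dur_range_s
        if not (MIN_SILENCE_S <= lo <= hi):
            raise ValueError("within-overlap durations must be ≥ the minimum silence")


@dataclass
class SimTruth:
    """Ground truth of a simulation: injected transitions and realised params."""

    transitions: pd.DataFrame  # TABLE_COLUMNS
    dyad_params: pd.DataFrame  # dyad_id, group, mu_shift_ms, p_within per context
    counters: dict = field(default_factory=dict)


@dataclass
class CorpusResult:
    annotations: list[DyadAnnotation]
    truth: SimTruth
    metadata: pd.DataFrame
    config: SimulationConfig


# ---------------------------------------------------------------------------
# Sign-split mixture moments and preset calibration
# ---------------------------------------------------------------------------


def _density_grid(params: ExGaussParams, n: int = 20001) -> tuple[np.ndarray, np.ndarray]:
    lo = params.mu - 7.0 * params.sigma
    hi = params.mu + 7.0 * params.sigma + 14.0 * params.tau
    x = np.linspace(lo, hi, n)
    f = np.exp(exgauss_logpdf(x, params))
    return x, f


def sign_split_moments(
    params: ExGaussParams, p_gap_conditional: float
) -> dict[str, float]:
    """Mean/SD/median of the sign-split FTO mixture, by numeric integration.

    The mixture reweights the ex-Gaussian so that a fraction
    ``p_gap_conditional`` of transfers is non-negative (gaps) and the rest
    negative (overlaps); it equals the plain ex-Gaussian when
    ``p_gap_conditional`` matches the distribution's own P(X ≥ 0).
    """
    x, f = _density_grid(params)
    dx = x[1] - x[0]
    pos = x >= 0
    p_plus = float(np.trapezoid(np.where(pos, f, 0.0), x))
    p_minus = max(1.0 - p_plus, 1e-12)
    p_plus = max(p_plus, 1e-12)
    w = np.where(pos, p_gap_conditional / p_plus, (1.0 - p_gap_conditional) / p_minus)
    g = f * w
    norm = float(np.trapezoid(g, x))
    g = g / norm
    m1 = float(np.trapezoid(x * g, x))
    m2 = float(np.trapezoid(x**2 * g, x))
    sd = float(np.sqrt(max(m2 - m1**2, 1e-12)))
    cdf = np.cumsum(g) * dx
    median = float(np.interp(0.5, cdf, x))
    return {"mean": m1, "sd": sd, "median": median, "p_positive": p_plus}


def _fit_mu_sigma(tau: float, mean_ms: float, sd_ms: float, p_gap_cond: float):
    """Solve (mu, sigma) so the sign-split mixture hits the target mean and SD
    at a fixed tau.  Residuals are in units of 10 ms."""

    def res(theta):
        params = ExGaussParams(theta[0], float(np.exp(theta[1])), tau)
        mom = sign_split_moments(params, p_gap_cond)
        return np.array([(mom["mean"] - mean_ms) / 10.0, (mom["sd"] - sd_ms) / 10.0])

    sigma0 = max(np.sqrt(max(sd_ms**2 - tau**2, (0.05 * sd_ms) ** 2)), 20.0)
    return optimize.least_squares(
        res, np.array([mean_ms - tau, np.log(sigma0)]), method="lm", xtol=1e-12, ftol=1e-12
    )


def calibrate_cell(
    mean_ms: float,
    sd_ms: float,
    median_ms: float,
    p_gap_conditional: float,
) -> ExGaussParams:
    """Find ex-Gaussian parameters whose sign-split mixture matches targets.

    Two-stage solve: for each candidate tau, (mu, sigma) are fitted so the
    mixture mean and SD match the targets exactly; the remaining degree of
    freedom (tau) is then chosen to bring the mixture median as close to its
    target as the family allows.  Real FTO distributions are more sharply
    peaked than an ex-Gaussian, so published medians can sit below the
    feasible range at the published mean/SD — in that case the calibrated
    median is the closest attainable value (logged).
    """

    def solved(tau: float) -> ExGaussParams | None:
        r = _fit_mu_sigma(tau, mean_ms, sd_ms, p_gap_conditional)
        if r.cost > 0.05:  # mean/SD not attainable at this tau
            return None
        return ExGaussParams(float(r.x[0]), float(np.exp(r.x[1])), tau)

    best: tuple[float, ExGaussParams] | None = None
    for frac in np.linspace(0.15, 1.05, 15):
        params = solved(frac * sd_ms)
        if params is None:
            continue
        err = abs(sign_split_moments(params, p_gap_conditional)["median"] - median_ms)
        if best is None or err < best[0]:
            best = (err, params)
    if best is None:
        raise ValueError(
            f"no ex-Gaussian reproduces mean={mean_ms}, sd={sd_ms} at split "
            f"{p_gap_conditional:.3f}"
        )

    def med_err(log_tau: float) -> float:
        params = solved(float(np.exp(log_tau)))
        if params is None:
            return 1e9
        return abs(sign_split_moments(params, p_gap_conditional)["median"] - median_ms)

    tau0 = best[1].tau
    r = optimize.minimize_scalar(
        med_err,
        bounds=(np.log(tau0 * 0.8), np.log(tau0 * 1.25)),
        method="bounded",
        options={"xatol": 2e-3},
    )
    params = solved(float(np.exp(r.x))) or best[1]
    achieved = sign_split_moments(params, p_gap_conditional)
    if abs(achieved["median"] - median_ms) > 5.0:
        logger.info(
            "median %s ms not attainable at mean=%s sd=%s; calibrated to %.0f ms",
            median_ms,
            mean_ms,
            sd_ms,
            achieved["median"],
        )
    return params


_CELL_CACHE: dict[tuple[str, str], CellParams] = {}
_PRESET_CACHE: dict[tuple, SimulationConfig] = {}


def _calibrated_cells() -> dict[tuple[str, str], CellParams]:
    if not _CELL_CACHE:
        for (group, context), (mean, sd, median) in REFERENCE_SUMMARY.items():
            p_w, p_b, p_g = REFERENCE_TYPE_MIXTURE[group]
            p_gap_cond = p_g / (p_b + p_g)
            params = calibrate_cell(mean, sd, median, p_gap_cond)
            _CELL_CACHE[(group, context)] = CellParams(
                exgauss=params, p_within=p_w, p_between=p_b, p_gap=p_g
            )
    return dict(_CELL_CACHE)


def paper_preset(
    seed: int = 0,
    *,
    n_dyads: dict[str, int] | None = None,
    context_duration_s: float = 600.0,
    dyad_sd_mu_ms: float = 150.0,
) -> SimulationConfig:
    """The study-scale preset: 9 ASD + 14 non-ASD dyads, three 10-minute
    contexts, cells calibrated to the published group×context FTO summaries
    and per-group transition-type mixtures."""
    n_dyads = dict(n_dyads or {"ASD": 9, "non-ASD": 14})
    key = (seed, tuple(sorted(n_dyads.items())), context_duration_s, dyad_sd_mu_ms)
    if key in _PRESET_CACHE:
        return _PRESET_CACHE[key]
    cells = _calibrated_cells()
    cfg = SimulationConfig(
        cells=cells,
        n_dyads=n_dyads,
        context_duration_s=context_duration_s,
        dyad_sd_mu_ms=dyad_sd_mu_ms,
        seed=seed,
    )
    _PRESET_CACHE[key] = cfg
    return cfg


# ---------------------------------------------------------------------------
# Timeline simulation
# ---------------------------------------------------------------------------


def _draw_fto_s(
    cell: CellParams,
    mu_shift_ms: float,
    want: str | None,
    fto_lo_s: float,
    sign_split: str,
    rng: np.random.Generator,
) -> tuple[float, str, bool]:
    """Draw one transfer FTO in seconds.

    ``want`` fixes the type ("gap"/"between_overlap") in fixed mode; in
    exgauss mode the draw's own (rounded-ms) sign decides the label.
    Returns (fto_s, type, clipped).
    """
    p = cell.exgauss
    mu = p.mu + mu_shift_ms
    for _ in range(400):
        x_ms = rng.normal(mu, p.sigma) + rng.exponential(p.tau)
        x_s = x_ms / 1000.0
        label = "gap" if int(np.rint(x_ms)) >= 0 else "between_overlap"
        if sign_split == "exgauss":
            if label == "gap" or x_s >= fto_lo_s:
                return x_s, label, False
        elif label == want and (label == "gap" or x_s >= fto_lo_s):
            return x_s, label, False
    # fall back to a clipped feasible value
    if want == "between_overlap" and fto_lo_s <= -0.001:
        return max(fto_lo_s, -0.4), "between_overlap", True
    return max(0.0, rng.exponential(max(p.tau, 1.0)) / 1000.0), "gap", True


def _simulate_timeline(
    cell: CellParams,
    duration_s: float,
    mu_shift_ms: float,
    p_within: float,
    p_pause: float,
    within_range: tuple[float, float],
    sign_split: str,
    rng: np.random.Generator,
):
    """Build one dyad-context timeline; returns (spurts_by_speaker, truth_rows, counters)."""
    log_mu = np.log(cell.turn_mean_s) - cell.turn_sigma_log**2 / 2.0

    def draw_duration(min_dur: float) -> float:
        d = float(np.clip(rng.lognormal(log_mu, cell.turn_sigma_log), 0.4, 15.0))
        return max(d, min_dur)

    p_transfer_between = (1.0 - cell.p_gap_conditional)

    spurts: dict[str, list[tuple[float, float]]] = {"S1": [], "S2": []}
    last_end = {"S1": -np.inf, "S2": -np.inf}
    truth: list[tuple] = []  # (type, fto_ms, prev, next, anchor)
    counters = {
        "skipped_within": 0,
        "clipped_fto": 0,
        "between_converted_to_gap": 0,
        # transfers whose next turn fell outside the recording window; the
        # censoring is size-biased toward large FTOs (as in any fixed-length
        # recording), so tests bound its effect via this count
        "censored_final_transfers": 0,
    }

    cur, other = "S1", "S2"
    turn_start = float(rng.uniform(0.3, 1.2))
    min_dur = 0.0
    must_end_after = -np.inf
    pending: tuple | None = None

    while True:
        dur = draw_duration(min_dur)
        turn_end = turn_start + dur
        final = False
        if turn_end > duration_s:
            turn_end = duration_s
            final = True
            if turn_end - turn_start < 0.3 or turn_end < must_end_after:
                # discard this turn and the pending transfer into it
                counters["censored_final_transfers"] += int(pending is not None)
                break
        if pending is not None:
            truth.append(pending)
            pending = None

        if final:
            spurts[cur].append((turn_start, turn_end))
            last_end[cur] = turn_end
            break

        # events within the turn: zero or more within-overlaps, then a transfer
        placed_within = False
        while True:
            if rng.random() >= p_within:
                break
            lo_len, hi_len = within_range
            ws_min = max(turn_start + _CLEAR_S, last_end[other] + _CLEAR_S)
            space = turn_end - _CLEAR_S - ws_min
            if space < lo_len:
                counters["skipped_within"] += 1
                continue
            length = float(rng.uniform(lo_len, min(hi_len, space)))
            ws = float(rng.uniform(ws_min, turn_end - _CLEAR_S - length))
            spurts[other].append((ws, ws + length))
            last_end[other] = ws + length
            truth.append(("within_overlap", None, cur, other, ws))
            placed_within = True

        want = (
            "between_overlap" if rng.random() < p_transfer_between else "gap"
        )
        fto_lo_s = max(last_end[other] + _CLEAR_S, turn_start + 0.05) - turn_end
        if want == "between_overlap" and fto_lo_s > -0.001:
            want = "gap"
            counters["between_converted_to_gap"] += 1
        fto_s, label, clipped = _draw_fto_s(
            cell, mu_shift_ms, want, fto_lo_s, sign_split, rng
        )
        counters["clipped_fto"] += int(clipped)

        # emit the current turn, optionally split by a within-speaker pause;
        # a turn that itself started in overlap is never split, because its
        # first segment could then end inside the previous holder's talkspurt
        # and read back as a within-speaker overlap
        split = (
            not placed_within
            and label == "gap"
            and must_end_after < turn_start
            and dur >= 1.6
            and rng.random() < p_pause
        )
        if split:
            pause = float(rng.uniform(0.25, 0.6))
            cut = float(rng.uniform(turn_start + 0.5, turn_end - pause - 0.5))
            spurts[cur].append((turn_start, cut))
            spurts[cur].append((cut + pause, turn_end))
        else:
            spurts[cur].append((turn_start, turn_end))
        last_end[cur] = turn_end

        onset = turn_end + fto_s
        pending = (label, int(np.rint(fto_s * 1000.0)), cur, other, turn_end)
        if onset > duration_s - 0.5:
            counters["censored_final_transfers"] += 1
            break
        must_end_after = turn_end + 0.1 if label == "between_overlap" else -np.inf
        min_dur = (-fto_s + 0.3) if label == "between_overlap" else 0.0
        turn_start = onset
        cur, other = other, cur

    return spurts, truth, counters


def simulate_dyad(
    config: SimulationConfig,
    dyad_index: int,
    group: str,
    context: str,
    rng: np.random.Generator,
    *,
    dyad_id: str | None = None,
    mu_shift_ms: float = 0.0,
    logit_within_shift: float = 0.0,
) -> tuple[DyadAnnotation, pd.DataFrame, dict]:
    """Simulate one dyad in one context.

    Returns the annotation, the injected-transition truth rows (transition
    table columns) and the event counters.  The same seed always produces
    the same timeline.
    """
    cell = config.cells[(group, context)]
    base_logit = np.log(cell.p_within / (1.0 - cell.p_within)) if cell.p_within > 0 else -np.inf
    p_within = (
        0.0
        if cell.p_within == 0
        else float(1.0 / (1.0 + np.exp(-(base_logit + logit_within_shift))))
    )
    spurts, truth_rows, counters = _simulate_timeline(
        cell,
        config.context_duration_s,
        mu_shift_ms,
        p_within,
        config.p_pause,
        config.within_dur_range_s,
        config.sign_split,
        rng,
    )
    did = dyad_id or f"{'A' if group == 'ASD' else 'N'}{dyad_index:02d}"
    tier_a = IntervalTier.from_speech_intervals("S1", spurts["S1"], config.context_duration_s)
    tier_b = IntervalTier.from_speech_intervals("S2", spurts["S2"], config.context_duration_s)
    ann = DyadAnnotation(dyad_id=did, tier_a=tier_a, tier_b=tier_b, group=group, context=context)
    truth = pd.DataFrame(
        [
            (did, group, context, t, np.nan if fto is None else float(fto), prev, nxt, anchor)
            for (t, fto, prev, nxt, anchor) in truth_rows
        ],
        columns=TABLE_COLUMNS,
    )
    return ann, truth, counters


def simulate_corpus(
    config: SimulationConfig,
    out_dir: str | Path | None = None,
) -> CorpusResult:
    """Simulate the full corpus: every dyad of both groups in every context.

    Per-dyad random effects (a Gaussian shift of the ex-Gaussian location and
    a logit-scale shift of the within-overlap rate) are drawn once per dyad
    and shared across its contexts.  With ``out_dir`` set, TextGrids plus
    metadata/truth CSVs are written through the annotation layer.
    """
    rng = np.random.default_rng(config.seed)
    annotations: list[DyadAnnotation] = []
    truths: list[pd.DataFrame] = []
    dyad_records = []
    meta_records = []
    counters: dict[str, int] = {}
    for group in GROUPS:
        if group not in config.n_dyads:
            continue
        for i in range(1, config.n_dyads[group] + 1):
            mu_shift = float(rng.normal(0.0, config.dyad_sd_mu_ms))
            lw_shift = float(rng.normal(0.0, config.dyad_sd_logit_within))
            dyad_id = f"{'A' if group == 'ASD' else 'N'}{i:02d}"
            dyad_records.append(
                {
                    "dyad_id": dyad_id,
                    "group": group,
                    "mu_shift_ms": mu_shift,
                    "logit_within_shift": lw_shift,
                }
            )
            for context in config.contexts:
                ann, truth, c = simulate_dyad(
                    config,
                    i,
                    group,
                    context,
                    rng,
                    dyad_id=dyad_id,
                    mu_shift_ms=mu_shift,
                    logit_within_shift=lw_shift,
                )
                annotations.append(ann)
                truths.append(truth)
                for k, v in c.items():
                    counters[k] = counters.get(k, 0) + v
                meta_records.append(
                    {
                        "dyad_id": dyad_id,
                        "group": group,
                        "context": context,
                        "path": f"{dyad_id}_{context}.TextGrid",
                        "tier_a": "S1",
                        "tier_b": "S2",
                    }
                )
    truth = SimTruth(
        transitions=pd.concat(truths, ignore_index=True),
        dyad_params=pd.DataFrame(dyad_records),
        counters=counters,
    )
    metadata = pd.DataFrame(meta_records)
    result = CorpusResult(annotations, truth, metadata, config)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for ann in annotations:
            write_textgrid(ann, out / f"{ann.dyad_id}_{ann.context}.TextGrid")
        metadata.to_csv(out / "metadata.csv", index=False)
        truth.transitions.to_csv(out / "truth_transitions.csv", index=False)
        truth.dyad_params.to_csv(out / "truth_dyad_params.csv", index=False)
        (out / "truth_counters.json").write_text(json.dumps(counters, indent=2))
        (out / "config.json").write_text(_config_json(config))
    return result


def _config_json(config: SimulationConfig) -> str:
    raw = asdict(config)
    raw["cells"] = {
        f"{g}|{c}": asdict(cp) for (g, c), cp in config.cells.items()
    }
    return json.dumps(raw, indent=2, default=str)
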