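"""Drosophila sleep scoring, screen hit calling, and arousal analysis.

Activity comes from a Drosophila activity monitor (DAM): infrared beam
crossings counted per minute per fly.  Sleep is the standard behavioral
definition - any maximal run of >= 5 consecutive minutes with zero counts.
On top of the per-animal architecture this module implements the screen rule
(line mean outside the pooled-animal mean +/- 2 SD band), homeostatic rebound
after deprivation, and the two stimulus-based depth-of-sleep measures
(escalating-intensity arousal threshold, fixed-intensity reactivity binned by
prior immobility).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from sleepv2g.stats import StatResult, welch_ttest

MINUTES_PER_DAY = 1440
LIGHTS_OFF_ZT_MIN = 720  # 12:12 LD cycle


@dataclass
class ActivityTrace:
    animal_id: str
    line: str
    counts: np.ndarray  # per-minute beam crossings, int, >= 0
    t0_zt: int = 0  # ZT minutes at trace start

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 1 or self.counts.size == 0:
            raise ValueError("counts must be a nonempty 1-D array")
        if np.any(self.counts < 0):
            raise ValueError("negative activity counts")

    @property
    def n_minutes(self) -> int:
        return int(self.counts.size)

    @property
    def n_days(self) -> float:
        return self.n_minutes / MINUTES_PER_DAY

    def zt_minutes(self) -> np.ndarray:
        return (self.t0_zt + np.arange(self.n_minutes)) % MINUTES_PER_DAY


@dataclass(frozen=True)
class SleepBout:
    start_minute: int
    duration_min: int


@dataclass
class SleepSummary:
    """Per-animal sleep architecture, expressed per day for multi-day traces."""

    total_sleep_min: float
    day_sleep_min: float
    night_sleep_min: float
    bout_number: float
    bout_number_day: float
    bout_number_night: float
    mean_bout_length_min: float | None
    waking_activity: float | None  # counts per waking minute; None if no wake
    n_days: float


def runs_of_true(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as (start, length) pairs."""
    mask = np.asarray(mask, dtype=bool)
    padded = np.concatenate([[False], mask, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, ends = edges[::2], edges[1::2]
    return [(int(s), int(e - s)) for s, e in zip(starts, ends)]


def score_fly_sleep(
    counts: np.ndarray, immobility_threshold_min: int = 5
) -> tuple[np.ndarray, list[SleepBout]]:
    """Score per-minute sleep state from activity counts.

    A minute is immobile iff counts == 0; maximal immobile runs of length
    >= ``immobility_threshold_min`` are sleep bouts, and every minute inside a
    bout is a sleep minute.  A run truncated by the trace end still counts if
    its observed length reaches the threshold.
    """
    counts = np.asarray(counts)
    if np.any(counts < 0):
        raise ValueError("negative activity counts")
    if immobility_threshold_min < 1:
        raise ValueError("immobility threshold must be >= 1 minute")
    state = np.zeros(counts.size, dtype=bool)
    bouts = []
    for start, length in runs_of_true(counts == 0):
        if length >= immobility_threshold_min:
            state[start : start + length] = True
            bouts.append(SleepBout(start, length))
    return state, bouts


def summarize_fly_sleep(
    state: np.ndarray, trace: ActivityTrace, bouts: list[SleepBout] | None = None
) -> SleepSummary:
    """Day/night sleep totals, bout metrics, and waking activity.

    Day is ZT0-ZT720, night ZT720-ZT1440; sleep minutes are attributed
    minute-by-minute (a bout spanning lights-off contributes to both phases),
    bout counts by the phase of the bout's start minute.  Multi-day traces are
    reduced to per-day values by dividing by the number of recorded days.
    """
    state = np.asarray(state, dtype=bool)
    if state.size != trace.n_minutes:
        raise ValueError("sleep state and trace have different lengths")
    if bouts is None:
        bouts = [SleepBout(s, l) for s, l in runs_of_true(state)]
    zt = trace.zt_minutes()
    day_mask = zt < LIGHTS_OFF_ZT_MIN
    n_days = trace.n_days
    total = state.sum() / n_days
    day_sleep = (state & day_mask).sum() / n_days
    night_sleep = (state & ~day_mask).sum() / n_days
    n_day_bouts = sum(1 for b in bouts if day_mask[b.start_minute])
    wake = ~state
    waking_activity = (
        float(trace.counts[wake].sum() / wake.sum()) if wake.any() else None
    )
    mean_bout = (
        float(np.mean([b.duration_min for b in bouts])) if bouts else None
    )
    return SleepSummary(
        total_sleep_min=float(total),
        day_sleep_min=float(day_sleep),
        night_sleep_min=float(night_sleep),
        bout_number=len(bouts) / n_days,
        bout_number_day=n_day_bouts / n_days,
        bout_number_night=(len(bouts) - n_day_bouts) / n_days,
        mean_bout_length_min=mean_bout,
        waking_activity=waking_activity,
        n_days=n_days,
    )


def is_dead(counts: np.ndarray, min_trailing_zero_min: int = MINUTES_PER_DAY) -> bool:
    """Flag animals with zero activity from some point through the trace end.

    Standard DAM hygiene: a fly that never moves again for the final
    ``min_trailing_zero_min`` minutes (default one full day) is treated as
    dead rather than as a very long sleeper.
    """
    counts = np.asarray(counts)
    nz = np.flatnonzero(counts)
    trailing = counts.size if nz.size == 0 else counts.size - int(nz[-1]) - 1
    return trailing >= min_trailing_zero_min


@dataclass(frozen=True)
class ScreenCall:
    line_id: str
    mean_total_sleep: float
    band_low: float
    band_high: float
    call: str  # "short" | "long" | "none"


def call_screen_hits(
    line_totals: Mapping[str, Sequence[float]],
    reference: str | Sequence[str] = "all_animals",
    k_sd: float = 2.0,
) -> list[ScreenCall]:
    """Call short/long sleep lines against a pooled-animal +/- k SD band.

    ``line_totals`` maps line id to per-animal total sleep (min/day).  The
    reference pool is every animal tested (``"all_animals"``) or the animals
    of an explicit collection of control lines.  The band is the pooled
    animal-level mean +/- ``k_sd`` x sample SD; a line is "long" if its mean
    exceeds band_high, "short" if below band_low, otherwise "none".
    """
    if isinstance(reference, str):
        if reference != "all_animals":
            raise ValueError("reference must be 'all_animals' or a list of line ids")
        pool_lines = list(line_totals)
    else:
        pool_lines = list(reference)
        unknown = [l for l in pool_lines if l not in line_totals]
        if unknown:
            raise ValueError(f"unknown control lines: {unknown}")
    pool = np.concatenate(
        [np.asarray(line_totals[l], dtype=float) for l in pool_lines]
    ) if pool_lines else np.empty(0)
    if pool.size < 2:
        raise ValueError("reference pool needs at least 2 animals")
    mu, sd = float(pool.mean()), float(pool.std(ddof=1))
    lo, hi = mu - k_sd * sd, mu + k_sd * sd
    calls = []
    for line_id in sorted(line_totals):
        m = float(np.mean(line_totals[line_id]))
        call = "long" if m > hi else ("short" if m < lo else "none")
        calls.append(ScreenCall(line_id, m, lo, hi, call))
    return calls


def percent_rebound(
    baseline_day_sleep: Sequence[float], recovery_day_sleep: Sequence[float]
) -> tuple[np.ndarray, list[int]]:
    """Per-animal percent change in daytime sleep after deprivation.

    Returns (percent changes for usable animals, indices of animals excluded
    because their baseline was zero).
    """
    base = np.asarray(baseline_day_sleep, dtype=float)
    rec = np.asarray(recovery_day_sleep, dtype=float)
    if base.shape != rec.shape:
        raise ValueError("baseline and recovery must be paired per animal")
    excluded = list(np.flatnonzero(base == 0))
    ok = base != 0
    pct = 100.0 * (rec[ok] - base[ok]) / base[ok]
    return pct, excluded


def compare_rebound(pct_a, pct_b) -> StatResult:
    """Between-genotype comparison of percent rebound (Welch t)."""
    return welch_ttest(pct_a, pct_b)


@dataclass(frozen=True)
class StimulusEvent:
    time_s: int
    intensity_g: float

    def __post_init__(self) -> None:
        if self.intensity_g <= 0:
            raise ValueError("stimulus intensity must be > 0")


@dataclass(frozen=True)
class ArousalResult:
    excluded: bool  # fly not asleep at first-stimulus onset
    threshold_g: float | None  # None when excluded or censored
    censored: bool  # no response at any intensity


def _responded(movement_mm: np.ndarray, t_s: int, window_s: int, response_mm: float) -> bool:
    w = movement_mm[t_s + 1 : t_s + 1 + window_s]
    return bool(np.any(w > response_mm))


def arousal_threshold(
    movement_mm: np.ndarray,
    trials: Sequence[Sequence[StimulusEvent]],
    sleep_state: np.ndarray,
    response_mm: float = 3.0,
    response_window_s: int = 60,
) -> list[ArousalResult]:
    """Per-trial arousal threshold from escalating-intensity stimulus series.

    ``movement_mm`` is a per-second displacement trace; a response is any
    displacement > ``response_mm`` within ``response_window_s`` seconds after
    a stimulus.  Trials where the fly is awake (per the 5-min immobility
    rule) at first-stimulus onset are excluded; if no intensity elicits a
    response the trial is right-censored at the maximum intensity.
    """
    movement_mm = np.asarray(movement_mm, dtype=float)
    sleep_state = np.asarray(sleep_state, dtype=bool)
    results = []
    for trial in trials:
        intens = [ev.intensity_g for ev in trial]
        if any(b <= a for a, b in zip(intens, intens[1:])):
            raise ValueError("stimulus intensities must be strictly increasing")
        onset_minute = trial[0].time_s // 60
        if not sleep_state[onset_minute]:
            results.append(ArousalResult(True, None, False))
            continue
        threshold = None
        for ev in trial:
            if _responded(movement_mm, ev.time_s, response_window_s, response_mm):
                threshold = ev.intensity_g
                break
        results.append(ArousalResult(False, threshold, threshold is None))
    return results


def immobility_duration_min(sleep_state: np.ndarray, minute: int) -> int:
    """Minutes asleep up to and including ``minute`` (0 if awake)."""
    sleep_state = np.asarray(sleep_state, dtype=bool)
    if not sleep_state[minute]:
        return 0
    start = minute
    while start > 0 and sleep_state[start - 1]:
        start -= 1
    return minute - start + 1


def reactivity(
    movement_mm: np.ndarray,
    stimuli: Sequence[StimulusEvent],
    sleep_state: np.ndarray,
    response_mm: float = 3.0,
    response_window_s: int = 60,
    bin_width_min: int = 5,
    bin_start_min: int = 5,
) -> pd.DataFrame:
    """Proportion of sleeping trials responding, per immobility-duration bin.

    Each stimulus delivered while the fly is asleep is one trial, assigned to
    a bin by how long the fly had been immobile at onset.  Bins with zero
    trials are omitted.  Columns: bin_low, bin_high, bin_mid, trials,
    responders, proportion.
    """
    movement_mm = np.asarray(movement_mm, dtype=float)
    sleep_state = np.asarray(sleep_state, dtype=bool)
    rows: dict[int, list[int]] = {}
    for ev in stimuli:
        minute = ev.time_s // 60
        dur = immobility_duration_min(sleep_state, minute)
        if dur < bin_start_min:
            continue  # awake or below the minimum immobility defining sleep
        b = (dur - bin_start_min) // bin_width_min
        resp = _responded(movement_mm, ev.time_s, response_window_s, response_mm)
        rows.setdefault(b, []).append(int(resp))
    out = []
    for b in sorted(rows):
        trials = rows[b]
        lo = bin_start_min + b * bin_width_min
        out.append(
            {
                "bin_low": lo,
                "bin_high": lo + bin_width_min,
                "bin_mid": lo + bin_width_min / 2,
                "trials": len(trials),
                "responders": int(np.sum(trials)),
                "proportion": float(np.mean(trials)),
            }
        )
    return pd.DataFrame(
        out, columns=["bin_low", "bin_high", "bin_mid", "trials", "responders", "proportion"]
    )


def pool_reactivity(tables: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Pool per-fly reactivity tables into one table per bin."""
    allrows = pd.concat(tables, ignore_index=True)
    g = allrows.groupby(["bin_low", "bin_high", "bin_mid"], as_index=False)[
        ["trials", "responders"]
    ].sum()
    g["proportion"] = g["responders"] / g["trials"]
    return g


def compare_reactivity(table_a: pd.DataFrame, table_b: pd.DataFrame):
    """Covariate-adjusted group comparison of reactivity (ANCOVA elevation).

    Fits proportion ~ bin midpoint + group by weighted least squares (weights
    = trials per bin) on the two pooled bin tables and reports the group
    coefficient: the vertical shift of group b relative to group a at equal
    immobility duration.  Returns (estimate, se, p_value, fitted results).
    """
    import statsmodels.api as sm

    frames = []
    for grp, tab in (("a", table_a), ("b", table_b)):
        t = tab[["bin_mid", "trials", "proportion"]].copy()
        t["group"] = 1.0 if grp == "b" else 0.0
        frames.append(t)
    data = pd.concat(frames, ignore_index=True)
    X = sm.add_constant(data[["bin_mid", "group"]])
    fit = sm.WLS(data["proportion"], X, weights=data["trials"]).fit()
    return (
        float(fit.params["group"]),
        float(fit.bse["group"]),
        float(fit.pvalues["group"]),
        fit,
    )
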