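"""Larval zebrafish sleep scoring and group comparison.

Tracking exports report movement as seconds-of-motion per minute.  A minute
with less than 0.5 s of movement is one minute of sleep; any maximal run of
sleep minutes (length >= 1) is a bout.  Larvae are raised on a 14:10 cycle
(lights on 09:00, off 23:00); after removing an acclimation period the
analysis window is two full day/night cycles.  Group contrasts use the Welch
t-test by default, and F0 crispants enter the analysis only when their
headloop/standard PCR ratio shows mutation efficiency > 0.9.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from sleepv2g.fly import runs_of_true
from sleepv2g.stats import StatResult, pooled_ttest, welch_ttest

MINUTES_PER_DAY = 1440
LIGHTS_ON_MIN = 9 * 60  # 09:00
LIGHTS_OFF_MIN = 23 * 60  # 23:00
SLEEP_THRESHOLD_SEC = 0.5


@dataclass
class ZfTrace:
    larva_id: str
    group: str  # e.g. "scramble" | "ko"
    movement_sec: np.ndarray  # seconds of movement per minute, in [0, 60]
    clock_start_min: int = LIGHTS_ON_MIN  # time of day at trace start, minutes
    lights_on_min: int = LIGHTS_ON_MIN
    lights_off_min: int = LIGHTS_OFF_MIN

    def __post_init__(self) -> None:
        self.movement_sec = np.asarray(self.movement_sec, dtype=float)
        if self.movement_sec.ndim != 1 or self.movement_sec.size == 0:
            raise ValueError("movement_sec must be a nonempty 1-D array")
        if np.any((self.movement_sec < 0) | (self.movement_sec > 60)):
            raise ValueError("movement seconds per minute must lie in [0, 60]")

    @property
    def n_minutes(self) -> int:
        return int(self.movement_sec.size)

    def minute_of_day(self) -> np.ndarray:
        return (self.clock_start_min + np.arange(self.n_minutes)) % MINUTES_PER_DAY

    def day_mask(self) -> np.ndarray:
        mod = self.minute_of_day()
        return (mod >= self.lights_on_min) & (mod < self.lights_off_min)


def score_zf_sleep(trace: ZfTrace, threshold_sec: float = SLEEP_THRESHOLD_SEC) -> np.ndarray:
    """Per-minute sleep state: strict ``movement < threshold`` is sleep."""
    return trace.movement_sec < threshold_sec


@dataclass
class ZfBoutSummary:
    bouts: list[tuple[int, int]]  # (start_minute, duration)
    day_bout_number: int
    night_bout_number: int
    day_mean_bout_min: float | None
    night_mean_bout_min: float | None


def zf_bouts(state: np.ndarray, day_mask: np.ndarray) -> ZfBoutSummary:
    """Bout list and per-phase counts/mean lengths.

    Every maximal run of sleep minutes is a bout (no minimum length); a bout
    is attributed to the phase containing its start minute.
    """
    state = np.asarray(state, dtype=bool)
    day_mask = np.asarray(day_mask, dtype=bool)
    if state.size != day_mask.size:
        raise ValueError("state and day mask have different lengths")
    bouts = runs_of_true(state)
    day_lens = [l for s, l in bouts if day_mask[s]]
    night_lens = [l for s, l in bouts if not day_mask[s]]
    return ZfBoutSummary(
        bouts=bouts,
        day_bout_number=len(day_lens),
        night_bout_number=len(night_lens),
        day_mean_bout_min=float(np.mean(day_lens)) if day_lens else None,
        night_mean_bout_min=float(np.mean(night_lens)) if night_lens else None,
    )


def zf_waking_activity(
    trace: ZfTrace, state: np.ndarray, reduction: str = "hourly_mean"
) -> tuple[float | None, pd.Series]:
    """Waking activity in seconds per awake minute, summarized per clock hour.

    Each full hour of recording contributes (sum of movement over wake
    minutes) / (number of wake minutes); fully-asleep hours are undefined and
    excluded.  ``reduction`` picks the per-larva scalar: "hourly_mean" (mean
    of defined hourly values) or "overall" (all wake minutes pooled).
    """
    state = np.asarray(state, dtype=bool)
    if state.size != trace.n_minutes:
        raise ValueError("state and trace have different lengths")
    wake = ~state
    hour = (trace.clock_start_min + np.arange(trace.n_minutes)) // 60
    per_hour = {}
    for h in np.unique(hour):
        sel = hour == h
        n_wake = int(wake[sel].sum())
        if n_wake == 0:
            continue
        per_hour[int(h)] = float(trace.movement_sec[sel & wake].sum() / n_wake)
    series = pd.Series(per_hour, dtype=float)
    if reduction == "hourly_mean":
        value = float(series.mean()) if len(series) else None
    elif reduction == "overall":
        value = float(trace.movement_sec[wake].sum() / wake.sum()) if wake.any() else None
    else:
        raise ValueError(f"unknown reduction {reduction!r}")
    return value, series


@dataclass
class ZfSleepSummary:
    """Cumulative day/night sleep and bout architecture over the analysis window."""

    day_sleep_min: float
    night_sleep_min: float
    day_bout_number: int
    night_bout_number: int
    night_mean_bout_min: float | None
    waking_activity: float | None


def summarize_zf(trace: ZfTrace, state: np.ndarray) -> ZfSleepSummary:
    state = np.asarray(state, dtype=bool)
    day = trace.day_mask()
    bouts = zf_bouts(state, day)
    activity, _ = zf_waking_activity(trace, state)
    return ZfSleepSummary(
        day_sleep_min=float((state & day).sum()),
        night_sleep_min=float((state & ~day).sum()),
        day_bout_number=bouts.day_bout_number,
        night_bout_number=bouts.night_bout_number,
        night_mean_bout_min=bouts.night_mean_bout_min,
        waking_activity=activity,
    )


def trim_acclimation(trace: ZfTrace, analysis_days: int = 2) -> ZfTrace:
    """Drop everything before the first lights-on, keep exact day/night cycles.

    The retained window starts at the first 09:00 boundary at or after the
    recording start and spans ``analysis_days`` x 1440 minutes (two days and
    two nights by default).
    """
    if analysis_days < 1:
        raise ValueError("analysis_days must be >= 1")
    offset = (trace.lights_on_min - trace.clock_start_min) % MINUTES_PER_DAY
    keep = analysis_days * MINUTES_PER_DAY
    if offset + keep > trace.n_minutes:
        raise ValueError(
            f"trace too short: need {offset + keep} minutes, have {trace.n_minutes}"
        )
    return replace(
        trace,
        movement_sec=trace.movement_sec[offset : offset + keep].copy(),
        clock_start_min=trace.lights_on_min,
    )


def zf_group_compare(a: Sequence[float], b: Sequence[float], force_welch: bool = True) -> StatResult:
    """Two-sample comparison of per-larva values (Welch by default).

    With ``force_welch=False`` an F-ratio pre-test (alpha = 0.05) picks the
    pooled form when variances are compatible - provided for completeness;
    the Welch default avoids an unspecified pre-test.
    """
    if force_welch:
        return welch_ttest(a, b)
    from scipy import stats as sps

    a_ = np.asarray(a, dtype=float)
    b_ = np.asarray(b, dtype=float)
    f = a_.var(ddof=1) / b_.var(ddof=1)
    dfa, dfb = a_.size - 1, b_.size - 1
    p_var = 2 * min(sps.f.sf(f, dfa, dfb), sps.f.cdf(f, dfa, dfb))
    return welch_ttest(a, b) if p_var < 0.05 else pooled_ttest(a, b)


@dataclass(frozen=True)
class GenotypeCall:
    larva_id: str
    headloop_intensity: float
    standard_intensity: float
    efficiency: float
    included: bool


def mutation_efficiency(
    larva_id: str,
    headloop_intensity: float,
    standard_intensity: float,
    cutoff: float = 0.9,
) -> GenotypeCall:
    """Headloop/standard PCR band ratio; include iff efficiency > cutoff.

    Headloop PCR suppresses amplification of wild-type alleles, so the ratio
    of headloop to standard product estimates the mutated-allele fraction in
    an F0 crispant.
    """
    if headloop_intensity < 0:
        raise ValueError("headloop intensity must be >= 0")
    if standard_intensity <= 0:
        raise ValueError("standard PCR intensity must be > 0")
    eff = headloop_intensity / standard_intensity
    return GenotypeCall(larva_id, headloop_intensity, standard_intensity, eff, eff > cutoff)
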