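"""Descriptive sleep and seizure metrics over labeled hypnograms.

Computes, per analysis window: counts and rates of SWDs, NREM (behavioral
sleep) episodes and micro-arousals; total sleep and micro-arousal time;
percentage of the window asleep; and the sleep fragmentation index

    SFI = number of sleep episodes / total sleep duration in hours,

undefined (``None``) when the window contains no sleep.  Analysis windows
can be given as offsets or derived from wall-clock time (dark-phase
windows 21:00-24:00 and 03:00-06:00 of a 12:12 light/dark cycle).

A rule-based grouping of longitudinal SWD rates into epilepsy severity
phenotypes (none / minor / mild / severe) is included; its cut-offs are
heuristic, modeled on reported group trajectories, and fully configurable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .eeg_io import BS, MA, SWD, Interval, IntervalSet

__all__ = [
    "SleepMetrics",
    "compute_metrics",
    "dark_phase_windows",
    "EpiphenotypeCutoffs",
    "classify_epiphenotype",
]


@dataclass
class SleepMetrics:
    """Per-window sleep/seizure summary.  Rates are per hour of window."""

    window: tuple[float, float, str]
    n_swd: int
    n_bs_episodes: int
    n_ma: int
    total_bs_s: float
    total_ma_s: float
    n_swd_per_h: float
    n_bs_episodes_per_h: float
    n_ma_per_h: float
    sfi: float | None
    pct_bs: float

    def to_dict(self) -> dict:
        d = {
            "window_start_s": self.window[0],
            "window_end_s": self.window[1],
            "window_name": self.window[2],
        }
        for k in ("n_swd", "n_bs_episodes", "n_ma", "total_bs_s",
                  "total_ma_s", "n_swd_per_h", "n_bs_episodes_per_h",
                  "n_ma_per_h", "sfi", "pct_bs"):
            d[k] = getattr(self, k)
        return d


def _clip(states: IntervalSet, start: float, end: float) -> list[Interval]:
    out = []
    for iv in states:
        a, b = max(iv.onset_s, start), min(iv.offset_s, end)
        if b > a:
            out.append(Interval(a, b, iv.label))
    return out


def compute_metrics(states: IntervalSet, window: tuple[float, float],
                    name: str = "") -> SleepMetrics:
    """Summarise a labeled hypnogram over ``[start, end]`` seconds.

    Episodes straddling a window boundary count once per window they
    intersect, with clipped durations, so duration totals are
    additive-consistent across disjoint windows.
    """
    start, end = float(window[0]), float(window[1])
    if not end > start:
        raise ValueError("window must have positive length")
    clipped = _clip(states, start, end)
    hours = (end - start) / 3600.0
    bs = [iv for iv in clipped if iv.label == BS]
    ma = [iv for iv in clipped if iv.label == MA]
    swd = [iv for iv in clipped if iv.label == SWD]
    total_bs = sum(iv.duration_s for iv in bs)
    total_ma = sum(iv.duration_s for iv in ma)
    sfi = len(bs) / (total_bs / 3600.0) if total_bs > 0 else None
    return SleepMetrics(
        window=(start, end, name),
        n_swd=len(swd),
        n_bs_episodes=len(bs),
        n_ma=len(ma),
        total_bs_s=total_bs,
        total_ma_s=total_ma,
        n_swd_per_h=len(swd) / hours,
        n_bs_episodes_per_h=len(bs) / hours,
        n_ma_per_h=len(ma) / hours,
        sfi=sfi,
        pct_bs=100.0 * total_bs / (end - start),
    )


#: dark-phase analysis windows as (name, start, end) seconds since midnight
_DARK_WINDOWS = (("dark_begin", 21 * 3600.0, 24 * 3600.0),
                 ("dark_end", 3 * 3600.0, 6 * 3600.0))


def dark_phase_windows(start_time: float | str | None, duration_s: float
                       ) -> list[tuple[str, float, float]]:
    """Dark-phase windows expressed in recording-relative seconds.

    ``start_time`` is the recording start as seconds since midnight or an
    ``"HH:MM"``/``"HH:MM:SS"`` string.  Windows not covered at all by the
    recording are omitted with a warning; partially covered windows are
    clipped.  Recordings spanning several days yield one window per night
    (suffixed ``_2``, ``_3``, ... from the second occurrence on).
    """
    if start_time is None:
        raise ValueError("recording has no start_time: pass explicit "
                         "window offsets instead")
    if isinstance(start_time, str):
        parts = [int(p) for p in start_time.split(":")]
        while len(parts) < 3:
            parts.append(0)
        start_time = parts[0] * 3600.0 + parts[1] * 60.0 + parts[2]
    out: list[tuple[str, float, float]] = []
    counts: dict[str, int] = {}
    n_days = int((start_time + duration_s) // 86400) + 1
    for day in range(n_days):
        for name, w0, w1 in _DARK_WINDOWS:
            rel0 = w0 + 86400.0 * day - start_time
            rel1 = w1 + 86400.0 * day - start_time
            a, b = max(rel0, 0.0), min(rel1, duration_s)
            if b > a:
                counts[name] = counts.get(name, 0) + 1
                label = name if counts[name] == 1 else f"{name}_{counts[name]}"
                out.append((label, a, b))
    for name, _, _ in _DARK_WINDOWS:
        if name not in counts:
            warnings.warn(f"recording does not span the {name} window; "
                          f"omitted", stacklevel=2)
    return sorted(out, key=lambda w: w[1])


@dataclass
class EpiphenotypeCutoffs:
    """Heuristic SWD-rate cut-offs (per hour) for severity grouping."""

    minor_max_rate: float = 0.5   # rates at 5 and 7 months below this
    mild_max_rate_5m: float = 3.0
    severe_min_rate_5m: float = 5.0


def classify_epiphenotype(rates_by_age: dict[int, float],
                          cutoffs: EpiphenotypeCutoffs | None = None) -> str:
    """Classify a longitudinal SWD-rate trajectory (ages 5, 7, 9 months).

    Returns one of ``none`` (no SWDs at any age), ``minor`` (seizures only
    at 9 months), ``mild`` (low rate at 5 months, increasing after),
    ``severe`` (high rate already at 5 months) or ``indeterminate`` when
    the required age points are missing or no rule matches.
    """
    cut = cutoffs or EpiphenotypeCutoffs()
    r5 = rates_by_age.get(5)
    r7 = rates_by_age.get(7)
    r9 = rates_by_age.get(9)
    if r5 is None or r7 is None or r9 is None:
        return "indeterminate"
    if r5 == 0 and r7 == 0 and r9 == 0:
        return "none"
    if r5 >= cut.severe_min_rate_5m:
        return "severe"
    if r5 < cut.minor_max_rate and r7 < cut.minor_max_rate and r9 > 0:
        return "minor"
    if r5 < cut.mild_max_rate_5m and r5 < r7 < r9:
        return "mild"
    return "indeterminate"
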