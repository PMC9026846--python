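"""Micro-arousal classification within behavioral sleep.

A micro-arousal (MA) is a brief waking intrusion into sleep that does not
count as an awakening: a 3-15 s stretch of the waking state immediately
preceded by at least 10 s of uninterrupted behavioral sleep and followed
by sleep.  Waking episodes longer than 15 s remain wakefulness; wake
fragments shorter than 3 s flanked by sleep on both sides are below the
scorable-arousal floor and are absorbed back into sleep (configurable).
An SWD interrupting the preceding sleep run resets the "uninterrupted
sleep" requirement -- a seizure is not sleep.
"""

from __future__ import annotations

from dataclasses import dataclass

from .eeg_io import AW, BS, MA, Interval, IntervalSet

__all__ = ["MicroArousalParams", "classify_arousals"]


@dataclass
class MicroArousalParams:
    min_ma_s: float = 3.0
    max_ma_s: float = 15.0
    min_preceding_sleep_s: float = 10.0
    #: minimum sleep required after the candidate (guards against calling a
    #: terminal awakening truncated by the recording end a micro-arousal)
    trailing_sleep_s: float = 1.0
    #: absorb wake fragments shorter than min_ma_s flanked by sleep into BS
    absorb_short: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.min_ma_s < self.max_ma_s:
            raise ValueError("require 0 < min_ma_s < max_ma_s")
        if self.min_preceding_sleep_s <= 0:
            raise ValueError("min_preceding_sleep_s must be positive")


def _coalesce(runs: list[Interval]) -> list[Interval]:
    out: list[Interval] = []
    for iv in runs:
        if out and out[-1].label == iv.label and \
                abs(out[-1].offset_s - iv.onset_s) < 1e-9:
            out[-1] = Interval(out[-1].onset_s, iv.offset_s, iv.label)
        else:
            out.append(iv)
    return out


def classify_arousals(states: IntervalSet,
                      params: MicroArousalParams | None = None
                      ) -> IntervalSet:
    """Relabel qualifying wake intrusions as micro-arousals.

    The input must tile its span (no gaps).  Runs are processed left to
    right: sub-threshold wake fragments between sleep runs are absorbed
    first (extending the surrounding sleep run for subsequent candidates),
    then each remaining wake run of 3-15 s with enough uninterrupted sleep
    before and sleep after is relabeled ``MA``.  The operation is
    idempotent and preserves the tiling.
    """
    params = params or MicroArousalParams()
    runs = _coalesce(sorted(states, key=lambda iv: iv.onset_s))
    for a, b in zip(runs, runs[1:]):
        if abs(a.offset_s - b.onset_s) > 1e-6:
            raise ValueError(f"input does not tile its span: gap between "
                             f"{a} and {b}")
    i = 0
    while i < len(runs):
        iv = runs[i]
        if iv.label != AW:
            i += 1
            continue
        prev = runs[i - 1] if i > 0 else None
        nxt = runs[i + 1] if i + 1 < len(runs) else None
        prev_bs = prev is not None and prev.label == BS
        nxt_bs = nxt is not None and nxt.label == BS
        dur = iv.duration_s
        if params.absorb_short and dur < params.min_ma_s and prev_bs and nxt_bs:
            runs[i] = Interval(iv.onset_s, iv.offset_s, BS)
            runs = _coalesce(runs)
            i = max(i - 1, 0)
            continue
        if (params.min_ma_s <= dur <= params.max_ma_s and prev_bs and nxt_bs
                and prev.duration_s >= params.min_preceding_sleep_s
                and nxt.duration_s >= params.trailing_sleep_s):
            runs[i] = Interval(iv.onset_s, iv.offset_s, MA)
        i += 1
    return IntervalSet(runs)
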