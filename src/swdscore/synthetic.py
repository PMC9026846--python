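"""Synthetic multichannel rodent EEG with ground-truth state labels.

The generator produces 3-channel "epidural" EEG (two frontal, one
occipital) from a state schedule, so every detector in the package can be
validated against known labels without animal data.  Per-state spectral
recipes (amplitudes in arbitrary microvolt-like units):

wake (``AW``)
    low-voltage broadband 1/f noise plus bursty 6-8 Hz theta.
behavioral sleep (``BS``, NREM)
    high-amplitude 1-4 Hz delta, a continuous 5-9 Hz mid-frequency
    oscillation (the 5-10 Hz wavelet power of which is the sleep marker),
    bursty 11-13 Hz sleep spindles (0.5-1 s), low broadband noise.
spike-wave discharge (``SWD``)
    a repetitive spike-wave train at a per-event fundamental of 8-10 Hz:
    a sharp biphasic spike (Gaussian derivative, ~25 ms wide, carrying
    harmonics into the 15-18 Hz band) riding on a slow wave at the
    fundamental; peak amplitude 8x the NREM background RMS by default,
    bilaterally near-synchronous (inter-channel jitter <= 10 ms) with the
    occipital channel attenuated; ongoing background is suppressed.
micro-arousal (``MA``)
    a 3-15 s wake-spectrum insertion inside sleep.

An artifact-injection mode adds pure sinusoidal bursts (default 16 Hz,
amplitude comparable to the ongoing activity) that drive the SWD energy
characteristic over threshold without spike-wave morphology -- the case
the extrema-validation criterion must reject.

The generator is deterministic under a fixed seed.  It emulates the
spectral and morphological features the detectors rely on, not full
physiology (no REM, no state-transition microstructure, no 1/f knee).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal as sp_signal

from .eeg_io import AW, BS, MA, SWD, Interval, IntervalSet, Recording
from .wavelet import moving_average

__all__ = [
    "SimulationConfig",
    "simulate",
    "make_schedule",
    "default_hour_config",
    "evaluate",
    "duration_agreement",
]


@dataclass
class SimulationConfig:
    """Everything the generator needs; defaults are the study conditions.

    ``schedule`` is a list of ``(state, duration_s)`` pairs tiling the
    recording.  ``artifacts`` holds ``(onset_s, duration_s)`` pairs of
    sinusoidal artifact bursts superimposed on the scheduled states.
    """

    fs: float = 400.0
    n_channels: int = 3
    schedule: list[tuple[str, float]] = field(default_factory=list)
    seed: int = 0

    # wake recipe (microvolts)
    wake_broadband_sd: float = 20.0
    wake_theta_sd: float = 8.0
    theta_band: tuple[float, float] = (6.0, 8.0)
    theta_duty: float = 0.4

    # NREM recipe
    nrem_delta_sd: float = 40.0
    delta_band: tuple[float, float] = (1.0, 4.0)
    nrem_mid_sd: float = 20.0
    mid_band: tuple[float, float] = (5.0, 9.0)
    spindle_sd: float = 25.0
    spindle_band: tuple[float, float] = (11.0, 13.0)
    spindle_duty: float = 0.25
    nrem_broadband_sd: float = 10.0

    # SWD recipe
    swd_freq_range: tuple[float, float] = (8.0, 10.0)
    swd_amplitude_factor: float = 8.0   # spike peak over NREM background RMS
    swd_spike_width_s: float = 0.008    # Gaussian-derivative sigma (~25 ms wide)
    swd_wave_frac: float = 0.3          # slow-wave amplitude as fraction of spike
    swd_noise_frac: float = 0.15        # residual broadband during SWD
    swd_channel_jitter_s: float = 0.010
    occipital_swd_gain: float = 0.7

    # artifact injection
    artifacts: list[tuple[float, float]] = field(default_factory=list)
    artifact_freq: float = 16.0
    artifact_amplitude: float = 30.0

    transition_ramp_s: float = 0.5

    def __post_init__(self) -> None:
        if self.fs <= 0 or self.n_channels < 1:
            raise ValueError("fs must be > 0 and n_channels >= 1")
        lo, hi = self.swd_freq_range
        if not 8.0 <= lo <= hi <= 10.0:
            raise ValueError("SWD fundamental must stay within 8-10 Hz")
        for state, dur in self.schedule:
            if dur <= 0:
                raise ValueError(f"non-positive duration for state {state}")
            if state == MA and not 3.0 <= dur <= 15.0:
                raise ValueError(f"MA of {dur} s violates the 3-15 s range")
            if state == SWD and dur < 2.0:
                raise ValueError(f"SWD of {dur} s violates the >=2 s minimum")
            if state not in (AW, BS, SWD, MA):
                raise ValueError(f"unknown state '{state}'")

    @property
    def nrem_rms(self) -> float:
        """Analytic RMS of the NREM recipe (the SWD amplitude reference)."""
        return math.sqrt(self.nrem_delta_sd ** 2 + self.nrem_mid_sd ** 2
                         + self.spindle_duty * self.spindle_sd ** 2
                         + self.nrem_broadband_sd ** 2)


# ---------------------------------------------------------------------------
# Schedule construction
# ---------------------------------------------------------------------------

def make_schedule(duration_s: float = 3600.0,
                  rng: np.random.Generator | int | None = 0,
                  wake_dwell: tuple[float, float] = (45.0, 120.0),
                  nrem_dwell: tuple[float, float] = (120.0, 210.0),
                  swd_rate_per_h: tuple[float, float] = (10.0, 20.0),
                  swd_duration: tuple[float, float] = (2.0, 10.0),
                  ma_per_nrem_episode: float = 0.7,
                  ma_duration: tuple[float, float] = (3.0, 15.0),
                  event_margin_s: float = 12.0,
                  ) -> list[tuple[str, float]]:
    """Random wake/NREM alternation with embedded SWDs and micro-arousals.

    Builds an alternating wake/sleep schedule, then places SWDs (at a
    rate drawn from ``swd_rate_per_h``, scaled by the recording length)
    and Bernoulli-thinned micro-arousals inside sleep episodes, keeping
    ``event_margin_s`` clear of episode edges and of each other so every
    event has an undisturbed pre-onset baseline.  SWDs that cannot be
    placed without violating the margins are skipped.
    """
    rng = np.random.default_rng(rng)
    # alternating background, starting awake
    runs: list[tuple[str, float]] = []
    t, state = 0.0, AW
    while t < duration_s:
        lo, hi = wake_dwell if state == AW else nrem_dwell
        dur = min(float(rng.uniform(lo, hi)), duration_s - t)
        runs.append((state, dur))
        t += dur
        state = BS if state == AW else AW

    # candidate insertion slots inside NREM runs
    events: list[tuple[float, float, str]] = []  # (onset, dur, label)

    def _try_place(dur: float, label: str, episode: tuple[float, float]) -> bool:
        e0, e1 = episode
        lo = e0 + event_margin_s
        hi = e1 - event_margin_s - dur
        if hi <= lo:
            return False
        for _ in range(20):
            onset = float(rng.uniform(lo, hi))
            ok = all(onset + dur + event_margin_s <= o or
                     o + d + event_margin_s <= onset
                     for o, d, _lab in events)
            if ok:
                events.append((onset, dur, label))
                return True
        return False

    episodes = []
    t = 0.0
    for state, dur in runs:
        if state == BS:
            episodes.append((t, t + dur))
        t += dur

    target_swd = max(1, int(round(
        rng.uniform(*swd_rate_per_h) * duration_s / 3600.0)))
    placed = 0
    for _ in range(200):
        if placed >= target_swd or not episodes:
            break
        ep = episodes[int(rng.integers(len(episodes)))]
        if _try_place(float(rng.uniform(*swd_duration)), SWD, ep):
            placed += 1
    for ep in episodes:
        if rng.random() < ma_per_nrem_episode:
            _try_place(float(rng.uniform(*ma_duration)), MA, ep)

    # splice events into the background runs
    edges: list[tuple[float, str]] = []
    t = 0.0
    for state, dur in runs:
        edges.append((t, state))
        t += dur
    boundaries = sorted([(o, lab, o + d) for o, d, lab in events])
    schedule: list[tuple[str, float]] = []

    def _bg_state(time: float) -> str:
        state = edges[0][1]
        for t0, s in edges:
            if t0 <= time + 1e-9:
                state = s
            else:
                break
        return state

    points = sorted({0.0, duration_s}
                    | {t0 for t0, _ in edges}
                    | {b[0] for b in boundaries} | {b[2] for b in boundaries})
    for a, b in zip(points, points[1:]):
        label = _bg_state(a)
        for o, lab, e in boundaries:
            if o <= a + 1e-9 and b <= e + 1e-9:
                label = lab
        schedule.append((label, b - a))
    # merge consecutive identical states
    merged: list[tuple[str, float]] = []
    for state, dur in schedule:
        if merged and merged[-1][0] == state:
            merged[-1] = (state, merged[-1][1] + dur)
        else:
            merged.append((state, dur))
    return merged


def default_hour_config(seed: int = 0, duration_s: float = 3600.0,
                        **overrides) -> SimulationConfig:
    """One-hour 3-channel recording under the default study conditions."""
    schedule = make_schedule(duration_s, rng=np.random.default_rng(seed))
    return SimulationConfig(schedule=schedule, seed=seed, **overrides)


# ---------------------------------------------------------------------------
# Signal synthesis
# ---------------------------------------------------------------------------

def _pink_noise(rng: np.random.Generator, n: int, fs: float, sd: float,
                f_lo: float = 0.5, exponent: float = 1.0) -> np.ndarray:
    """Power-law background noise, high-passed at ``f_lo``.

    Amplitude spectrum ~ ``f**-exponent`` (power ~ ``f**-2`` by default,
    the typical broadband EEG slope), normalised to ``sd``.
    """
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    gain = np.zeros_like(f)
    nz = f >= f_lo
    gain[nz] = f[nz] ** -exponent
    x = np.fft.irfft(spec * gain, n)
    return x * (sd / max(x.std(), 1e-30))


def _band_noise(rng: np.random.Generator, n: int, fs: float,
                band: tuple[float, float], sd: float) -> np.ndarray:
    nyq = fs / 2.0
    sos = sp_signal.butter(4, [band[0] / nyq, band[1] / nyq],
                           btype="bandpass", output="sos")
    x = sp_signal.sosfiltfilt(sos, rng.standard_normal(n))
    return x * (sd / max(x.std(), 1e-30))


def _burst_envelope(rng: np.random.Generator, n: int, fs: float,
                    duty: float, timescale_s: float) -> np.ndarray:
    """0/1 burst gate with the given duty cycle, smoothed at the edges."""
    slow = ndimage.gaussian_filter1d(rng.standard_normal(n),
                                     sigma=timescale_s * fs)
    thr = np.quantile(slow, 1.0 - duty)
    env = (slow > thr).astype(float)
    return moving_average(env, max(2, int(round(0.25 * fs))))


def _smooth_gate(mask: np.ndarray, fs: float, ramp_s: float) -> np.ndarray:
    k = max(2, int(round(ramp_s * fs)))
    return moving_average(mask.astype(float), k)


def _spike_wave_train(t: np.ndarray, onset: float, f0: float, phase: float,
                      amp: float, sigma: float, wave_frac: float
                      ) -> np.ndarray:
    """Periodic spike-wave complex: sharp biphasic spike + slow wave."""
    cycle = (t - onset) * f0 + phase
    frac = cycle - np.floor(cycle)          # position within the cycle [0, 1)
    u = (frac - 0.5) / (sigma * f0)         # spike centred mid-cycle
    spike = -u * np.exp(0.5 * (1.0 - u ** 2))   # peak amplitude 1
    wave = wave_frac * np.sin(2.0 * math.pi * frac)
    return amp * (spike + wave)


def simulate(config: SimulationConfig) -> tuple[Recording, IntervalSet]:
    """Generate a recording and its ground-truth interval tiling.

    Deterministic for a fixed ``config.seed``: the same configuration
    always yields bit-identical sample streams.
    """
    if not config.schedule:
        raise ValueError("config.schedule is empty")
    fs = config.fs
    rng = np.random.default_rng(config.seed)

    # sample-aligned state boundaries so truth matches the signal gating
    edges_s = np.concatenate(([0.0], np.cumsum([d for _, d in config.schedule])))
    edges = np.round(edges_s * fs).astype(int)
    n = int(edges[-1])
    states = [s for s, _ in config.schedule]
    truth = IntervalSet([Interval(edges[i] / fs, edges[i + 1] / fs, states[i])
                         for i in range(len(states))
                         if edges[i + 1] > edges[i]])

    code = np.zeros(n, dtype=np.int8)        # 0 wake-like, 1 NREM, 2 SWD
    for i, state in enumerate(states):
        if state == BS:
            code[edges[i]:edges[i + 1]] = 1
        elif state == SWD:
            code[edges[i]:edges[i + 1]] = 2

    gate_wake = _smooth_gate(code == 0, fs, config.transition_ramp_s)
    gate_nrem = _smooth_gate(code == 1, fs, config.transition_ramp_s)
    gate_swd = (code == 2).astype(float)     # sharp onset by construction
    t_axis = np.arange(n) / fs

    # per-event SWD parameters shared across channels (bilateral synchrony)
    swd_events = [(edges[i] / fs, edges[i + 1] / fs,
                   float(rng.uniform(*config.swd_freq_range)),
                   float(rng.uniform(0.0, 1.0)))
                  for i, s in enumerate(states) if s == SWD]
    amp = config.swd_amplitude_factor * config.nrem_rms

    channels = []
    for c in range(config.n_channels):
        x = np.zeros(n)
        # wake-like activity (wake and micro-arousals share the recipe)
        x += gate_wake * _pink_noise(rng, n, fs, config.wake_broadband_sd)
        x += gate_wake * _burst_envelope(rng, n, fs, config.theta_duty, 1.0) \
            * _band_noise(rng, n, fs, config.theta_band, config.wake_theta_sd)
        # NREM
        x += gate_nrem * _band_noise(rng, n, fs, config.delta_band,
                                     config.nrem_delta_sd)
        x += gate_nrem * _band_noise(rng, n, fs, config.mid_band,
                                     config.nrem_mid_sd)
        x += gate_nrem * _burst_envelope(rng, n, fs, config.spindle_duty, 0.4) \
            * _band_noise(rng, n, fs, config.spindle_band, config.spindle_sd)
        x += gate_nrem * _pink_noise(rng, n, fs, config.nrem_broadband_sd)
        # SWD train with per-channel jitter, occipital attenuation
        gain = config.occipital_swd_gain if c == 2 else 1.0
        jitter = float(rng.uniform(-config.swd_channel_jitter_s,
                                   config.swd_channel_jitter_s))
        for t0, t1, f0, phase in swd_events:
            i0, i1 = int(round(t0 * fs)), int(round(t1 * fs))
            seg = t_axis[i0:i1] - jitter
            x[i0:i1] += gain * _spike_wave_train(
                seg, t0, f0, phase, amp, config.swd_spike_width_s,
                config.swd_wave_frac)
        x += gate_swd * _pink_noise(rng, n, fs,
                                    config.swd_noise_frac
                                    * config.wake_broadband_sd)
        # artifact bursts ride on top of the scheduled state
        for a0, a_dur in config.artifacts:
            i0 = int(round(a0 * fs))
            i1 = min(n, int(round((a0 + a_dur) * fs)))
            if i1 <= i0:
                continue
            seg = t_axis[i0:i1]
            taper = sp_signal.windows.tukey(i1 - i0, alpha=min(
                1.0, 0.5 / max(a_dur, 1e-9)))
            x[i0:i1] += config.artifact_amplitude * taper * np.sin(
                2.0 * math.pi * config.artifact_freq * seg)
        channels.append(x)

    labels = ["FrL", "FrR", "Occ"][: config.n_channels]
    labels += [f"ch{i}" for i in range(len(labels), config.n_channels)]
    rec = Recording(np.asarray(channels), fs, labels)
    return rec, truth


# ---------------------------------------------------------------------------
# Evaluation against ground truth
# ---------------------------------------------------------------------------

def _overlap(a: list[Interval], b: list[Interval]) -> float:
    """Total intersection duration of two per-label interval lists."""
    total = 0.0
    for iv in a:
        for jv in b:
            total += max(0.0, min(iv.offset_s, jv.offset_s)
                         - max(iv.onset_s, jv.onset_s))
    return total


def duration_agreement(detected: IntervalSet, truth: IntervalSet,
                       label: str) -> float | None:
    """Percent of truth time of ``label`` also labeled so by the detector."""
    t = truth.for_label(label)
    denom = sum(iv.duration_s for iv in t)
    if denom == 0:
        return None
    return 100.0 * _overlap(detected.for_label(label), t) / denom


def evaluate(detected: IntervalSet, truth: IntervalSet,
             labels: tuple[str, ...] = (AW, BS, SWD, MA),
             span_tol_s: float = 0.5) -> dict:
    """Per-state duration agreement plus event precision/recall.

    ``duration_agreement[label]`` is 100 x (time labeled ``label`` by both)
    / (time labeled ``label`` in truth), ``None`` when truth contains no
    such time.  Event precision/recall counts an interval as matched when
    a same-label counterpart overlaps at least half of it.  Both sets must
    cover the same span (within ``span_tol_s``).
    """
    if len(detected) and len(truth):
        d0, d1 = detected.span()
        t0, t1 = truth.span()
        if abs(d0 - t0) > span_tol_s or abs(d1 - t1) > span_tol_s:
            raise ValueError(f"span mismatch: detected {d0:.2f}-{d1:.2f} s "
                             f"vs truth {t0:.2f}-{t1:.2f} s")
    report: dict = {"duration_agreement": {}, "event_precision": {},
                    "event_recall": {}}

    def _matched(iv: Interval, pool: list[Interval]) -> bool:
        return any(min(iv.offset_s, jv.offset_s) - max(iv.onset_s, jv.onset_s)
                   >= 0.5 * iv.duration_s for jv in pool)

    for label in labels:
        det = detected.for_label(label)
        tru = truth.for_label(label)
        report["duration_agreement"][label] = duration_agreement(
            detected, truth, label)
        report["event_precision"][label] = (
            100.0 * sum(_matched(iv, tru) for iv in det) / len(det)
            if det else None)
        report["event_recall"][label] = (
            100.0 * sum(_matched(iv, det) for iv in tru) / len(tru)
            if tru else None)
    return report
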