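# Methods

## Scope and model

`swdscore` scores three-channel epidural EEG from rodents prone to absence
epilepsy into four vigilance states: wakefulness (AW), behavioral/NREM
sleep (BS), spike-wave discharges (SWD) and micro-arousals (MA), and
derives sleep-fragmentation metrics from the resulting hypnogram.  REM and
intermediate sleep states are out of scope.  All decisions are made from
the EEG alone (no EMG/EOG), at full sample resolution (no epoching).

The physical premises are spectral. A spike-wave discharge is a train of
spike-wave complexes with an 8–10 Hz fundamental; the sharp spike carries
harmonics well above the fundamental, so the 15–18 Hz band is selectively
elevated relative to the delta (2.5–4.5 Hz) and spindle (10.5–12.5 Hz)
bands. Behavioral sleep raises 5–10 Hz power (mid-frequency oscillations
and spindle skirts), while wake EEG is low-voltage and desynchronized.

## Wavelet energy

Each channel is transformed with the complex Morlet continuous wavelet
transform, central parameter `Ω₀ = 2π`, so the wavelet scale maps onto
Fourier frequency. The CWT is evaluated per frequency by FFT convolution
with an L2-normalised (unit-energy) wavelet; the signal is extended by
reflection past the widest wavelet support, which keeps band energy
stationary at the recording borders (zero extension would attenuate the
wide low-frequency kernels there and bias the energy ratios the detectors
use). Band energy is `E_band(t) = Σ_f |W(f,t)|²` over a uniform 0.25 Hz
grid inside each band — at least 8 grid points in the narrowest (2 Hz)
band. Every band-energy series is smoothed by a centered moving average
of total length 0.25 s ("integral energy"); edge windows are truncated
rather than padded, so a constant series maps to itself.

## SWD detection

1. Per channel, the characteristic `ε_sw = E[15–18] / (E[2.5–4.5] +
   E[10.5–12.5])` is formed from the smoothed band energies, with a
   denominator floor of `1e-12 ×` the series maximum for flat-signal
   robustness. Channels are averaged, and the result smoothed over a
   centered window of total length `τ = 3 s`. A configuration switch
   (`tau_window_mult = 3`) reproduces a literal ±1.5·τ window instead;
   the default keeps the smoothing scale at about the shortest event the
   method must resolve (2 s).
2. Thresholds are adaptive per recording: `SW↑ = 1.75 × mean(⟨ε̃_sw⟩)`
   and `SW↓ = 1.55 × mean(⟨ε̃_sw⟩)`, the mean taken over the whole
   recording. Because the characteristic is a ratio, every decision is
   invariant under amplitude scaling of the raw EEG (verified to within
   one sample under a 7.3× gain change).
3. Hysteresis: an event opens where the characteristic strictly exceeds
   `SW↑` and closes at the first subsequent sample strictly below `SW↓`;
   an event open at the recording end closes there.
4. Edge refinement: the τ-scale smoothing that makes detection robust
   also widens each event by roughly τ/2 per side. Each detected segment
   is therefore trimmed to the connected region around its fine-scale
   (0.25 s-smoothed) characteristic peak that stays above `SW↓`. The
   minimum-duration rule (2 s) is applied to the refined interval.
   Refinement is a config switch (`refine_edges`).
5. Extrema validation: for each candidate `[t↑, t↓]`, strict local maxima
   and minima of the 1–100 Hz zero-phase band-passed signal (the band-pass
   removes DC-drift pseudo-extrema) are collected inside the event and in
   a baseline window of 5 s ending 1 s before onset (`[t↑−6, t↑−1]`).
   `Xmax` is the mean maximum amplitude in the event over the mean maximum
   amplitude in the baseline, `Xmin` likewise on the negated signal;
   channel values are averaged. The candidate is accepted iff
   `Xmax + Xmin > 6` (strict; a tie is invalid). The mean-amplitude form
   makes the fixed bound duration-independent — it reads as "event peaks
   ≈ 3× baseline peaks"; a raw-sum mode is available via
   `extrema_mode="sum"`. If the baseline window starts before the
   recording, validation is skipped and the event accepted with a
   `validated=False` flag.

This validation is what separates true discharges from oscillatory
artifacts: a sinusoidal burst of ongoing-activity amplitude can cross the
energy threshold (its power falls in the 15–18 Hz band) but its extrema
are not several-fold larger than baseline, so the criterion rejects it.

## Sleep/wake detection and micro-arousals

The sleep characteristic is the channel-mean smoothed 5–10 Hz band
energy, further smoothed over 10 s. Detected SWD spans are bridged by
linear interpolation *before* that smoothing and before thresholds are
computed: the seizure fundamental lies inside 5–10 Hz, and without
masking, a few minutes of seizure activity inflate the recording mean
enough to push the sleep threshold above the sleep level. For the same
robustness reason, the threshold mean is computed on the characteristic
clipped at its 99th percentile.

Thresholds are again a hysteresis pair, `BS↑`/`BS↓`, expressed as
multipliers of the recording-mean characteristic. The multipliers are
calibration constants, not published values; the defaults (1.0 and 0.75)
were calibrated on the synthetic suite and are exposed in the
configuration. Sleep opens above `BS↑`, closes below `BS↓`; the
complement is wake; detected SWD spans are overlaid with label precedence
(a seizure arises from drowsiness but is a distinct state).

Micro-arousals are then resolved on the resulting tiling: a wake run of
3–15 s (inclusive) immediately preceded by ≥ 10 s of uninterrupted sleep
and followed by ≥ 1 s of sleep becomes MA. An SWD interrupting the
preceding sleep run resets the "uninterrupted" requirement. Wake
fragments shorter than 3 s flanked by sleep are absorbed into sleep
(below the scorable-arousal floor; switchable). The 1-s trailing-sleep
requirement prevents a terminal awakening truncated by the recording end
from being scored as a micro-arousal. The operation is idempotent.

Finally, sleep/wake episodes shorter than 20 s are merged into their
longer flanking episode. SWD and MA intervals are never relabeled, and
they do not interrupt an episode for this rule: same-label runs connected
across SWD/MA intervals count as one episode (a seizure inside a sleep
bout does not turn the surrounding sleep into two sub-threshold
fragments).

## Metrics

Per analysis window: counts and per-hour rates of SWDs, sleep episodes
and micro-arousals; total sleep and micro-arousal time; percent asleep;
and the sleep fragmentation index `SFI = episodes / hours of sleep`,
reported as missing when the window contains no sleep. Episodes
straddling a window boundary count once per window with clipped
durations, which keeps duration totals additive across disjoint windows.
Dark-phase windows (21:00–24:00 and 03:00–06:00 under a 12:12 light/dark
cycle) are derived from the recording's wall-clock start time.

The epilepsy-severity classifier groups longitudinal SWD rates at 5, 7
and 9 months into none / minor / mild / severe. No published numeric
rule exists; the cut-offs (minor: < 0.5/h at 5 and 7 months with seizures
at 9; mild: < 3/h at 5 months and increasing; severe: ≥ 5/h at 5 months)
are heuristics modeled on reported group trajectories and are fully
configurable.

## Synthetic generator

The generator emulates the spectral and morphological features the
detectors rely on. Backgrounds are power-law noise with power ∝ f⁻²
(the typical broadband EEG slope) high-passed at 0.5 Hz. Wake adds
bursty 6–8 Hz theta (sd 8 µV on a 20 µV background); NREM adds 1–4 Hz
delta (sd 40 µV), a continuous 5–9 Hz oscillation (sd 20 µV), bursty
11–13 Hz spindles (sd 25 µV, duty 0.25) and a 10 µV broadband floor.
Spike-wave complexes are a periodic Gaussian-derivative spike (σ = 8 ms,
~25 ms wide, harmonics into 15–18 Hz) plus a slow wave at the per-event
fundamental (drawn uniformly in 8–10 Hz), with spike peak 8× the NREM
RMS, inter-channel jitter ≤ 10 ms (bilateral synchrony) and 0.7×
amplitude on the occipital channel; ongoing background is suppressed to
15% during the discharge. State gates use 0.5 s ramps except the SWD
(sharp onset). All state boundaries are rounded to whole samples so the
ground-truth tiling matches the signal gating exactly, and a fixed seed
yields bit-identical output.

The default one-hour condition alternates wake (45–120 s dwells) with
NREM (120–210 s dwells), inserts 10–20 SWDs of 2–10 s and roughly one
micro-arousal (3–15 s) per sleep episode, all placed ≥ 12 s from episode
edges and from each other so every event has an undisturbed pre-onset
baseline. The artifact-injection mode superimposes a tapered 16 Hz
sinusoid of 30 µV — comparable to ongoing activity — used to exercise the
rejection path.

What the generator does *not* emulate: REM, state-transition
microstructure, movement artifacts other than sinusoidal bursts,
electrode drift, inter-animal spectral variability, or nonstationarity
within a state. Passing the synthetic suite therefore demonstrates that
the implementation realises the method and that the method separates the
states it was designed for under its own spectral premises — not
clinical-grade performance on arbitrary real recordings.

## Numerical choices and problem sizes

- Frequency grid 0.25 Hz; Morlet evaluated per frequency with FFTs of
  `next_fast_len` length; band energies accumulated frequency-by-frequency
  so memory stays flat for hour-long recordings.
- Ratio denominators floored at `1e-12 ×` series maximum.
- Ties: threshold crossings are strict (`>` up, `<` down); the extrema
  criterion is strict; 15 s wake is still MA, 16 s is wake; 3 s is MA,
  2.999 s is absorbed.
- Degenerate inputs: flat signals produce zero characteristics and no
  events; an empty interval file round-trips as a header-only CSV.
- The validation suites use ten one-hour recordings for the accuracy
  surfaces, 50 ninety-second trials for artifact rejection, and a
  five-minute recording for the amplitude-invariance check; these sizes
  give stable means while keeping a full run of suite plus acceptance
  script within a few minutes on one core.

## Known limitations

- The sleep-threshold multipliers are synthetic-suite calibrations; real
  recordings will need per-laboratory calibration (the printed SWD
  multipliers 1.75/1.55 transfer as published).
- Micro-arousal boundary agreement is coarse (the 10-s sleep smoothing
  cannot resolve arousals much shorter than ~6 s), consistent with MA
  being a count/rate instrument rather than a boundary instrument here.
- EDF export writes plain 16-bit continuous EDF (one-second records,
  integer sampling rates only); EDF+ annotations are ignored on read.
- Units are treated as opaque throughout; every detector decision is
  ratio-based.
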