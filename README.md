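# swdscore

Automatic scoring of **spike-wave discharges (SWDs)**, **NREM sleep**,
**wakefulness** and **micro-arousals** in multichannel rodent epidural
EEG, plus the sleep-fragmentation metrics built on top of the resulting
hypnogram. The package is aimed at experimental neurophysiologists
working with genetic absence-epilepsy models (WAG/Rij, GAERS and similar
strains), where long unattended recordings make manual scoring the
bottleneck.

## Method

All detection is built on the complex Morlet continuous wavelet
transform (Ω₀ = 2π, so scale maps onto Fourier frequency) of each EEG
channel x_i(t). Band-integrated instantaneous energy
E_Δf(t) = Σ_{f∈Δf} |W_i(f,t)|² is computed in four bands (Hz):
Δf₁ = [2.5, 4.5], Δf₂ = [10.5, 12.5], Δf₃ = [15, 18], Δf₄ = [5, 10],
and smoothed by a short centered moving average.

**SWD detection.** The spike of each 8–10 Hz spike-wave complex carries
harmonics into Δf₃, so the channel-averaged, τ = 3 s smoothed ratio

    ε_sw(t) = E_Δf₃(t) / (E_Δf₁(t) + E_Δf₂(t))

rises sharply during a discharge. Events are cut out by a hysteresis
pair of per-recording adaptive thresholds, SW↑ = 1.75·⟨ε_sw⟩ and
SW↓ = 1.55·⟨ε_sw⟩, kept if ≥ 2 s long, and validated by an extrema
criterion: mean local-extrema amplitudes inside the event, relative to a
pre-onset baseline window ([t↑−6, t↑−1] s), must satisfy
Xmax + Xmin > 6. The validation rejects oscillatory artifacts that
cross the energy threshold without spike-wave morphology.

**Sleep/wake.** Behavioral sleep elevates 5–10 Hz power; the smoothed
Δf₄ characteristic with hysteresis thresholds BS↑/BS↓ (multipliers of
the recording mean) yields the sleep/wake tiling, with detected SWDs
masked out of the characteristic and overlaid with label precedence.

**Micro-arousals.** Wake intrusions of 3–15 s preceded by ≥ 10 s of
uninterrupted sleep and followed by sleep are relabeled MA; longer
awakenings stay wake; sub-3-s fragments are absorbed.

**Metrics.** Per analysis window (e.g. the dark-phase windows
21:00–24:00 and 03:00–06:00): SWD/sleep-episode/micro-arousal counts and
per-hour rates, total sleep time, and the sleep fragmentation index
SFI = sleep episodes ÷ hours of sleep.

A deterministic synthetic-EEG generator produces three-channel
recordings with known state schedules (wake theta, NREM delta + spindles
+ 5–9 Hz oscillations, bilaterally synchronous spike-wave trains,
artifact bursts), so every detector is validated against ground truth
without animal data. See `docs/methods.md` for the full model,
parameter table rationale, and limitations.

## Worked example

```sh
# 1. generate a 10-minute synthetic recording with known ground truth
swdscore simulate --seed 7 --duration 600 --out-dir demo/

# 2. score it (hypnogram, SWD event table, metrics)
swdscore detect demo/recording.csv --out-dir demo/out/

# 3. compare the detected hypnogram with the ground truth
swdscore evaluate demo/out/hypnogram.csv demo/truth.csv
```

The evaluation prints per-state duration agreement and event
precision/recall, e.g.

```
{
  "duration_agreement": {
    "AW": 99.71715962622595,
    "BS": 98.14235057342746,
    "SWD": 100.0,
    "MA": 100.0
  },
  ...
}
```

meaning 99.7% of true wake time, 98.1% of true sleep time and all of the
true seizure time were labeled correctly on this recording.
`demo/out/swd_events.csv` lists each discharge with onset `t_up`, offset
`t_down` and its validation ratios `x_max`, `x_min`;
`demo/out/metrics.json` holds the per-window counts and rates — here the
3 injected seizures (18/h over the 10-minute window), 6 sleep episodes,
1 micro-arousal and 51.3% time asleep.

The same pipeline runs on real data: `swdscore detect recording.edf`
accepts EDF/EDF+ or delimited text (with a sampling-rate sidecar or
`--fs`), and every constant above is overridable through a YAML config
(`--config`).

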