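"""Morlet continuous wavelet transform and band-limited energy series.

The detectors are built on three primitives:

1. the complex Morlet CWT ``W(f, t)`` of each EEG channel, computed
   per-frequency by FFT convolution with an L2-normalised (unit-energy)
   Morlet wavelet of central parameter ``omega0 = 2*pi`` -- with this
   choice the wavelet scale maps directly onto Fourier frequency ``f``;
2. the instantaneous band energy ``E_band(t) = sum_{f in band} |W(f, t)|^2``
   summed over a uniform frequency grid inside a named band; and
3. a short centered moving average ("integral energy") of that series.

Four analysis bands are used by default (Hz): 2.5-4.5 (delta/slow-wave,
``swd_low``), 10.5-12.5 (spindle, ``swd_mid``), 15-18 (spike-harmonic,
``swd_high``) and 5-10 (sleep, ``sleep``).  Spike-wave discharges elevate
the 15-18 Hz band relative to the two lower bands because the sharp spike
of each spike-wave complex carries harmonics of the 8-10 Hz fundamental;
behavioral sleep elevates the 5-10 Hz band.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import fft as sp_fft

from .eeg_io import Recording

__all__ = [
    "DEFAULT_BANDS",
    "WaveletConfig",
    "BandEnergySeries",
    "morlet_cwt",
    "band_energy",
    "smooth_energy",
    "band_energy_series",
    "moving_average",
]

#: Default analysis bands (Hz).
DEFAULT_BANDS: dict[str, tuple[float, float]] = {
    "swd_low": (2.5, 4.5),
    "swd_mid": (10.5, 12.5),
    "swd_high": (15.0, 18.0),
    "sleep": (5.0, 10.0),
}


@dataclass
class WaveletConfig:
    """Parameters of the wavelet-energy computation.

    omega0
        Morlet central parameter (dimensionless).  The default ``2*pi``
        makes the wavelet time scale coincide with Fourier frequency.
    bands
        Named frequency intervals in Hz.
    freq_step
        Spacing of the uniform frequency grid inside each band (Hz).
    energy_window_s
        Total length of the centered moving average applied to each band
        energy series (the "integral energy"); 0.25 s by default.
    """

    omega0: float = 2.0 * math.pi
    bands: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BANDS))
    freq_step: float = 0.25
    energy_window_s: float = 0.25

    def __post_init__(self) -> None:
        if self.omega0 <= 0:
            raise ValueError("omega0 must be positive")
        if self.freq_step <= 0:
            raise ValueError("freq_step must be positive")
        widths = []
        for name, (lo, hi) in self.bands.items():
            if not lo < hi:
                raise ValueError(f"band {name}: lower bound must be < upper")
            widths.append(hi - lo)
        if widths and self.freq_step > min(widths):
            raise ValueError("freq_step exceeds the narrowest band width")

    def band_freqs(self, band: str | tuple[float, float]) -> np.ndarray:
        """Uniform frequency grid covering a band (inclusive of both edges)."""
        lo, hi = self.bands[band] if isinstance(band, str) else band
        n = int(round((hi - lo) / self.freq_step))
        return lo + self.freq_step * np.arange(n + 1)


@dataclass
class BandEnergySeries:
    """Per-sample band-integrated CWT energy for one channel and band."""

    values: np.ndarray
    fs: float
    band: str = ""
    channel: str = ""
    smoothed: bool = False
    window_s: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)


# ---------------------------------------------------------------------------
# CWT core
# ---------------------------------------------------------------------------

def _as_signal(rec, channel):
    if isinstance(rec, Recording):
        if channel is None:
            raise ValueError("channel label required for a Recording")
        idx = rec.channel_labels.index(channel) if isinstance(channel, str) \
            else int(channel)
        return rec.signals[idx], rec.fs
    raise TypeError("expected a Recording")


def _cwt_rows(x: np.ndarray, fs: float, freqs: np.ndarray, omega0: float):
    """Yield (freq, complex coefficient row) for each requested frequency.

    Per-frequency FFT convolution with the L2-normalised analytic Morlet
    wavelet: for scale ``s = omega0 / (2 pi f)`` the frequency-domain
    window is ``(4 pi s)^(1/4)-style`` Gaussian ``exp(-(s w - omega0)^2/2)``
    restricted to positive frequencies.  The global constant is chosen so
    that the wavelet has unit L2 norm; all detector decisions are ratio
    based and insensitive to it.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n == 0:
        raise ValueError("empty signal")
    nyq = fs / 2.0
    for f in freqs:
        if not 0.0 < f < nyq:
            raise ValueError(f"frequency {f} Hz outside (0, Nyquist={nyq})")
    # reflect past the widest wavelet support: keeps band energy stationary
    # near the borders (zero padding would attenuate wide low-frequency
    # wavelets there and bias energy ratios at the recording edges)
    s_max = omega0 / (2.0 * math.pi * float(np.min(freqs)))
    pad = int(min(n - 1, math.ceil(8.0 * s_max * fs)))
    if pad > 0:
        x = np.pad(x, pad, mode="reflect")
    nfft = sp_fft.next_fast_len(x.size + pad, real=False)
    xf = sp_fft.fft(x, nfft)
    w = 2.0 * math.pi * sp_fft.fftfreq(nfft, d=1.0 / fs)
    pos = w > 0
    for f in freqs:
        s = omega0 / (2.0 * math.pi * f)
        psi_hat = np.zeros(nfft)
        # L2 normalisation: ||psi_s||_2 = 1  =>  amplitude ~ sqrt(s)
        psi_hat[pos] = (math.pi ** -0.25) * math.sqrt(2.0 * s * fs) * np.exp(
            -0.5 * (s * w[pos] - omega0) ** 2)
        row = sp_fft.ifft(xf * psi_hat)[pad:pad + n]
        yield f, row


def morlet_cwt(rec: Recording, channel, freqs, cfg: WaveletConfig | None = None
               ) -> np.ndarray:
    """Complex Morlet CWT coefficients, shape ``(len(freqs), n_samples)``.

    Frequencies must lie strictly inside ``(0, fs/2)``.  Edge samples
    within one wavelet e-folding time of the borders are computed like any
    other sample (the detectors use recording-wide averages and are
    insensitive to them).
    """
    cfg = cfg or WaveletConfig()
    x, fs = _as_signal(rec, channel)
    freqs = np.atleast_1d(np.asarray(freqs, dtype=float))
    out = np.empty((freqs.size, x.size), dtype=complex)
    for i, (_, row) in enumerate(_cwt_rows(x, fs, freqs, cfg.omega0)):
        out[i] = row
    return out


def band_energy(coeffs: np.ndarray, freqs, band: tuple[float, float],
                fs: float = 0.0, channel: str = "", name: str = ""
                ) -> BandEnergySeries:
    """Sum ``|W(f, t)|^2`` over the grid frequencies inside ``band``.

    ``freqs`` is the frequency grid of the coefficient rows.  Raises if no
    grid frequency falls inside the band.
    """
    freqs = np.atleast_1d(np.asarray(freqs, dtype=float))
    lo, hi = band
    mask = (freqs >= lo - 1e-9) & (freqs <= hi + 1e-9)
    if not mask.any():
        raise ValueError(f"band {band} not covered by the coefficient grid")
    values = np.sum(np.abs(coeffs[mask]) ** 2, axis=0)
    return BandEnergySeries(values, fs=fs, band=name or f"{lo}-{hi}Hz",
                            channel=channel)


def moving_average(values: np.ndarray, window_samples: int) -> np.ndarray:
    """Centered moving average with truncated windows at the edges.

    The window covers ``window_samples`` points; at the borders only the
    in-range part contributes (the divisor shrinks accordingly), so a
    constant series maps to itself exactly.
    """
    if window_samples < 2:
        raise ValueError("smoothing window must cover at least 2 samples")
    x = np.asarray(values, dtype=float)
    n = x.size
    left = (window_samples - 1) // 2
    right = window_samples // 2
    csum = np.concatenate(([0.0], np.cumsum(x)))
    hi = np.minimum(np.arange(n) + right + 1, n)
    lo = np.maximum(np.arange(n) - left, 0)
    return (csum[hi] - csum[lo]) / (hi - lo)


def smooth_energy(series: BandEnergySeries, window_s: float) -> BandEnergySeries:
    """Centered moving average of a band energy series over ``window_s``."""
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    k = int(round(window_s * series.fs))
    out = moving_average(series.values, k)
    return replace(series, values=out, smoothed=True, window_s=window_s)


def band_energy_series(rec: Recording, channel, band,
                       cfg: WaveletConfig | None = None,
                       smooth_window_s: float | None = None
                       ) -> BandEnergySeries:
    """Band energy of one channel computed without storing the CWT matrix.

    Accumulates ``|W(f, t)|^2`` frequency by frequency, which keeps memory
    flat for hour-long recordings, then (optionally) applies the integral
    smoothing.  ``smooth_window_s=None`` uses ``cfg.energy_window_s``;
    pass ``0`` to skip smoothing.
    """
    cfg = cfg or WaveletConfig()
    x, fs = _as_signal(rec, channel)
    freqs = cfg.band_freqs(band)
    acc = np.zeros(x.size)
    for _, row in _cwt_rows(x, fs, freqs, cfg.omega0):
        acc += np.abs(row) ** 2
    name = band if isinstance(band, str) else f"{band[0]}-{band[1]}Hz"
    series = BandEnergySeries(acc, fs=fs, band=name,
                              channel=str(channel))
    window = cfg.energy_window_s if smooth_window_s is None else smooth_window_s
    if window:
        series = smooth_energy(series, window)
    return series
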