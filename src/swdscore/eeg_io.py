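"""Reading and writing EEG recordings and labeled interval files.

A :class:`Recording` is the in-memory container every detector consumes:
a (channels x samples) float array in source amplitude units (treated as
opaque -- all detectors work with ratios), a sampling rate and channel
labels.  Labeled time intervals (wake ``AW``, behavioral sleep ``BS``,
spike-wave discharge ``SWD``, micro-arousal ``MA``) travel in
:class:`IntervalSet` objects and round-trip losslessly through plain
delimited text.

EDF/EDF+ continuous files are read through :mod:`mne`; annotations embedded
in EDF+ files are ignored (ground truth travels in separate interval
files).  A minimal 16-bit continuous EDF writer is provided so synthetic
recordings can be exported and the EDF read path exercised.
"""

from __future__ import annotations

import datetime
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LABELS",
    "AW",
    "BS",
    "SWD",
    "MA",
    "FormatError",
    "ConfigurationError",
    "Recording",
    "Interval",
    "IntervalSet",
    "read_recording",
    "write_recording",
    "read_intervals",
    "write_intervals",
]

AW = "AW"
BS = "BS"
SWD = "SWD"
MA = "MA"
LABELS = (AW, BS, SWD, MA)


class FormatError(ValueError):
    """Input file violates the expected format (e.g. ragged columns)."""


class ConfigurationError(ValueError):
    """Required configuration (e.g. sampling rate for CSV input) is missing."""


@dataclass
class Recording:
    """Multichannel EEG recording.

    Parameters
    ----------
    signals
        Array of shape ``(n_channels, n_samples)``; amplitude units are
        opaque (typically microvolts).
    fs
        Sampling rate in samples per second.
    channel_labels
        One label per channel.
    start_time
        Optional wall-clock start, seconds since midnight; used for
        clock-based analysis windows.
    """

    signals: np.ndarray
    fs: float
    channel_labels: list[str] = field(default_factory=list)
    start_time: float | None = None

    def __post_init__(self) -> None:
        self.signals = np.atleast_2d(np.asarray(self.signals, dtype=float))
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if self.signals.ndim != 2 or self.signals.shape[0] < 1:
            raise ValueError("signals must be a (n_channels, n_samples) array")
        if not self.channel_labels:
            self.channel_labels = [f"ch{i}" for i in range(self.signals.shape[0])]
        if len(self.channel_labels) != self.signals.shape[0]:
            raise ValueError("one label per channel required")

    @property
    def n_channels(self) -> int:
        return self.signals.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signals.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def scaled(self, factor: float) -> "Recording":
        """Return a copy with all amplitudes multiplied by ``factor``."""
        return Recording(self.signals * factor, self.fs,
                         list(self.channel_labels), self.start_time)


class Interval(NamedTuple):
    onset_s: float
    offset_s: float
    label: str

    @property
    def duration_s(self) -> float:
        return self.offset_s - self.onset_s


@dataclass
class IntervalSet:
    """Sorted collection of labeled, per-label non-overlapping intervals."""

    intervals: list[Interval] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.intervals = [Interval(float(a), float(b), str(lab))
                          for a, b, lab in self.intervals]
        self.intervals.sort(key=lambda iv: (iv.onset_s, iv.offset_s))
        self.validate()

    def validate(self, duration_s: float | None = None) -> None:
        last_end: dict[str, float] = {}
        for iv in self.intervals:
            if not iv.onset_s < iv.offset_s:
                raise ValueError(f"empty or inverted interval {iv}")
            if iv.onset_s < 0:
                raise ValueError(f"negative onset in {iv}")
            if duration_s is not None and iv.offset_s > duration_s + 1e-9:
                raise ValueError(f"{iv} extends past recording end {duration_s}")
            if iv.label in last_end and iv.onset_s < last_end[iv.label] - 1e-9:
                raise ValueError(f"overlapping '{iv.label}' intervals at {iv}")
            last_end[iv.label] = max(last_end.get(iv.label, 0.0), iv.offset_s)

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    def __eq__(self, other) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        return self.intervals == other.intervals

    def for_label(self, label: str) -> list[Interval]:
        return [iv for iv in self.intervals if iv.label == label]

    def total_duration(self, label: str | None = None) -> float:
        return sum(iv.duration_s for iv in self.intervals
                   if label is None or iv.label == label)

    def labels(self) -> set[str]:
        return {iv.label for iv in self.intervals}

    def span(self) -> tuple[float, float]:
        if not self.intervals:
            raise ValueError("empty interval set has no span")
        return (min(iv.onset_s for iv in self.intervals),
                max(iv.offset_s for iv in self.intervals))

    def tiles(self, duration_s: float, tol: float = 1e-6) -> bool:
        """True if the intervals partition ``[0, duration_s]`` exactly."""
        if not self.intervals:
            return duration_s <= tol
        ivs = sorted(self.intervals, key=lambda iv: iv.onset_s)
        if abs(ivs[0].onset_s) > tol or abs(ivs[-1].offset_s - duration_s) > tol:
            return False
        return all(abs(a.offset_s - b.onset_s) <= tol
                   for a, b in zip(ivs, ivs[1:]))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "onset_s": [iv.onset_s for iv in self.intervals],
                "offset_s": [iv.offset_s for iv in self.intervals],
                "label": [iv.label for iv in self.intervals],
                "duration_s": [iv.duration_s for iv in self.intervals],
            }
        )


# ---------------------------------------------------------------------------
# Recording I/O
# ---------------------------------------------------------------------------

def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt.lower()
    suffix = path.suffix.lower()
    if suffix == ".edf":
        return "edf"
    if suffix in (".csv", ".txt", ".tsv"):
        return "csv"
    raise ConfigurationError(f"cannot infer format from {path.name}; pass format=")


def _sidecar_fs(path: Path) -> float | None:
    """Look for ``<file>.json`` / ``<file>.yaml`` sidecar holding the rate."""
    for suffix, loader in ((".json", json.loads), (".yaml", None), (".yml", None)):
        side = path.with_suffix(path.suffix + suffix)
        if side.exists():
            text = side.read_text()
            if loader is None:
                import yaml

                meta = yaml.safe_load(text)
            else:
                meta = loader(text)
            if isinstance(meta, dict) and "fs" in meta:
                return float(meta["fs"])
    return None


def read_recording(path: str | Path, fmt: str | None = None,
                   fs: float | None = None) -> Recording:
    """Read an EEG recording from EDF/EDF+ or delimited text.

    The sample stream is never resampled or filtered.  For CSV input
    (one header row of channel labels, one column per channel) the
    sampling rate must come from ``fs`` or a ``<file>.json``/``.yaml``
    sidecar with an ``fs`` key.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    kind = _infer_format(path, fmt)
    if kind == "edf":
        return _read_edf(path)
    if kind == "csv":
        return _read_csv(path, fs)
    raise ConfigurationError(f"unknown format '{kind}'")


def _read_edf(path: Path) -> Recording:
    import mne

    try:
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    except Exception as exc:  # mne raises various types for corrupt files
        raise FormatError(f"cannot parse EDF file {path}: {exc}") from exc
    data = raw.get_data() * 1e6  # mne stores volts; recordings carry uV
    start_time = None
    meas = raw.info.get("meas_date")
    if isinstance(meas, datetime.datetime):
        start_time = float(meas.hour * 3600 + meas.minute * 60 + meas.second)
    return Recording(data, float(raw.info["sfreq"]), list(raw.ch_names),
                     start_time=start_time)


def _read_csv(path: Path, fs: float | None) -> Recording:
    if fs is None:
        fs = _sidecar_fs(path)
    if fs is None:
        raise ConfigurationError(
            f"sampling rate for CSV input {path.name} not given: pass fs= or "
            f"provide a sidecar {path.name}.json with {{\"fs\": ...}}")
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise FormatError(f"cannot parse CSV file {path}: {exc}") from exc
    if df.isna().any().any():
        raise FormatError(f"{path.name}: channel columns have unequal lengths")
    return Recording(df.to_numpy(dtype=float).T, float(fs),
                     [str(c) for c in df.columns])


def write_recording(rec: Recording, path: str | Path,
                    fmt: str | None = None) -> None:
    """Write a recording as CSV (with an ``fs`` sidecar) or 16-bit EDF."""
    path = Path(path)
    kind = _infer_format(path, fmt)
    if kind == "csv":
        pd.DataFrame(rec.signals.T, columns=rec.channel_labels).to_csv(
            path, index=False)
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps({"fs": rec.fs}))
    elif kind == "edf":
        _write_edf(rec, path)
    else:
        raise ConfigurationError(f"unknown format '{kind}'")


def _edf_field(value, width: int) -> bytes:
    text = f"{value}"
    if len(text) > width:
        text = f"{float(value):.{max(width - 7, 1)}g}" if not isinstance(
            value, str) else text[:width]
    return text[:width].ljust(width).encode("ascii")


def _write_edf(rec: Recording, path: Path) -> None:
    """Minimal continuous 16-bit EDF writer (1 s data records).

    The sampling rate must be a whole number of samples per second.  A
    recording whose length is not a whole number of seconds is zero-padded
    to the next full record.
    """
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ConfigurationError("EDF export requires an integer sampling rate")
    ns = int(round(fs))
    n_records = math.ceil(rec.n_samples / ns)
    n_ch = rec.n_channels

    if rec.start_time is not None:
        t = int(rec.start_time) % 86400
        start = f"{t // 3600:02d}.{t % 3600 // 60:02d}.{t % 60:02d}"
    else:
        start = "00.00.00"

    pmins, pmaxs, scaled = [], [], []
    for x in rec.signals:
        lo, hi = float(np.min(x)), float(np.max(x))
        if hi - lo < 1e-12:
            lo, hi = lo - 1.0, hi + 1.0
        pmins.append(lo)
        pmaxs.append(hi)
        dig = np.round((x - lo) / (hi - lo) * 65534.0 - 32767.0)
        padded = np.full(n_records * ns, dig[-1] if len(dig) else 0.0)
        padded[: len(dig)] = dig
        scaled.append(padded.astype("<i2"))

    header = b"".join([
        _edf_field("0", 8),
        _edf_field("X X X X", 80),
        _edf_field("Startdate X X X X", 80),
        _edf_field("01.01.01", 8),
        _edf_field(start, 8),
        _edf_field(256 + 256 * n_ch, 8),
        _edf_field("", 44),
        _edf_field(n_records, 8),
        _edf_field(1, 8),
        _edf_field(n_ch, 4),
    ])
    header += b"".join(_edf_field(lab, 16) for lab in rec.channel_labels)
    header += b"".join(_edf_field("", 80) for _ in range(n_ch))
    header += b"".join(_edf_field("uV", 8) for _ in range(n_ch))
    header += b"".join(_edf_field(f"{v:.6g}"[:8], 8) for v in pmins)
    header += b"".join(_edf_field(f"{v:.6g}"[:8], 8) for v in pmaxs)
    header += b"".join(_edf_field(-32767, 8) for _ in range(n_ch))
    header += b"".join(_edf_field(32767, 8) for _ in range(n_ch))
    header += b"".join(_edf_field("", 80) for _ in range(n_ch))
    header += b"".join(_edf_field(ns, 8) for _ in range(n_ch))
    header += b"".join(_edf_field("", 32) for _ in range(n_ch))

    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_records):
            for c in range(n_ch):
                fh.write(scaled[c][r * ns:(r + 1) * ns].tobytes())


# ---------------------------------------------------------------------------
# Interval I/O
# ---------------------------------------------------------------------------

def write_intervals(intervals: IntervalSet, path: str | Path) -> None:
    """Write intervals as delimited text (onset_s, offset_s, label, duration_s)."""
    intervals.to_dataframe().to_csv(Path(path), index=False)


def read_intervals(path: str | Path) -> IntervalSet:
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    df = pd.read_csv(path)
    required = {"onset_s", "offset_s", "label"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path.name}: expected columns {sorted(required)}")
    return IntervalSet([Interval(row.onset_s, row.offset_s, str(row.label))
                        for row in df.itertuples()])


def intervals_from_pairs(pairs: Iterable[Sequence], label: str) -> IntervalSet:
    """Convenience: build an IntervalSet from (onset, offset) pairs."""
    return IntervalSet([Interval(a, b, label) for a, b in pairs])
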