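"""Audio and label-track I/O.

Recordings are held as float waveforms in [-1, 1] with an explicit sample
rate; annotation tracks are ordered, non-overlapping timed intervals with
classes ``break`` / ``normal`` / ``wheeze`` (the Audacity label-track TSV
dialect on disk).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import numpy as np
from scipy.io import wavfile
from scipy.signal import resample_poly

__all__ = [
    "AudioRecording",
    "LabelInterval",
    "SoftLabelTrack",
    "CLASSES",
    "CLASS_TO_INDEX",
    "CANONICAL_SAMPLE_RATE",
    "AudioFormatError",
    "LabelTrackError",
    "read_wav",
    "write_wav",
    "read_label_track",
    "write_label_track",
    "resample",
]

logger = logging.getLogger(__name__)

#: Class names in hard-label order (0=break, 1=normal, 2=wheeze).
CLASSES = ("break", "normal", "wheeze")
CLASS_TO_INDEX = {name: i for i, name in enumerate(CLASSES)}

#: All pipeline entry points normalize recordings to this rate.
CANONICAL_SAMPLE_RATE = 16_000


class AudioFormatError(ValueError):
    """Raised for unreadable or unsupported audio files."""


class LabelTrackError(ValueError):
    """Raised for malformed label-track files or interval lists."""


@dataclass(frozen=True)
class AudioRecording:
    """A mono waveform plus its sample rate.

    Parameters
    ----------
    samples
        1-D float array of amplitudes, expected within [-1, 1].
    sample_rate
        Samples per second; must be a positive integer.
    """

    samples: np.ndarray
    sample_rate: int

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 1:
            raise ValueError(f"samples must be 1-D, got shape {samples.shape}")
        if not np.all(np.isfinite(samples)):
            raise ValueError("samples contain non-finite values")
        if not (isinstance(self.sample_rate, (int, np.integer)) and self.sample_rate > 0):
            raise ValueError(f"sample_rate must be a positive integer, got {self.sample_rate!r}")
        object.__setattr__(self, "samples", samples)
        object.__setattr__(self, "sample_rate", int(self.sample_rate))

    @property
    def duration_s(self) -> float:
        """Length of the recording in seconds."""
        return len(self.samples) / self.sample_rate

    def __len__(self) -> int:
        return len(self.samples)


@dataclass(frozen=True)
class LabelInterval:
    start_s: float
    end_s: float
    label: str

    def __post_init__(self) -> None:
        if self.label not in CLASSES:
            raise LabelTrackError(f"unknown label {self.label!r}; expected one of {CLASSES}")
        if not self.start_s < self.end_s:
            raise LabelTrackError(
                f"interval start must precede end, got [{self.start_s}, {self.end_s}]"
            )

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass(frozen=True)
class SoftLabelTrack:
    """Ordered, non-overlapping class intervals over a recording."""

    intervals: tuple[LabelInterval, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        intervals = tuple(self.intervals)
        for prev, cur in zip(intervals, intervals[1:]):
            if cur.start_s < prev.start_s:
                raise LabelTrackError("intervals must be sorted by start time")
            # strict float comparison: abutting intervals share a boundary
            if cur.start_s < prev.end_s:
                raise LabelTrackError(
                    f"intervals overlap: [{prev.start_s}, {prev.end_s}] and "
                    f"[{cur.start_s}, {cur.end_s}]"
                )
        object.__setattr__(self, "intervals", intervals)

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    @property
    def span(self) -> tuple[float, float]:
        """(first start, last end); (0.0, 0.0) for an empty track."""
        if not self.intervals:
            return (0.0, 0.0)
        return (self.intervals[0].start_s, self.intervals[-1].end_s)

    def shifted(self, offset_s: float) -> "SoftLabelTrack":
        return SoftLabelTrack(
            tuple(
                LabelInterval(iv.start_s + offset_s, iv.end_s + offset_s, iv.label)
                for iv in self.intervals
            )
        )


def read_wav(path: str | Path) -> AudioRecording:
    """Read a PCM WAV file as a mono recording scaled to [-1, 1].

    Multi-channel input is downmixed by averaging across channels.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"audio file not found: {path}")
    try:
        sr, data = wavfile.read(path)
    except Exception as exc:  # scipy raises bare ValueError on bad RIFF
        raise AudioFormatError(f"cannot read {path} as WAV: {exc}") from exc

    if data.dtype == np.int16:
        samples = data.astype(np.float64) / 32768.0
    elif data.dtype == np.int32:
        samples = data.astype(np.float64) / 2147483648.0
    elif data.dtype == np.uint8:
        samples = (data.astype(np.float64) - 128.0) / 128.0
    elif data.dtype in (np.float32, np.float64):
        samples = data.astype(np.float64)
    else:
        raise AudioFormatError(f"unsupported WAV sample format {data.dtype} in {path}")

    if samples.ndim == 2:
        samples = samples.mean(axis=1)
    samples = np.clip(samples, -1.0, 1.0)
    return AudioRecording(samples=samples, sample_rate=int(sr))


def write_wav(recording: AudioRecording, path: str | Path) -> None:
    """Write a recording as 16-bit PCM mono WAV.

    Samples outside [-1, 1] are clipped with a warning.
    """
    samples = recording.samples
    peak = np.max(np.abs(samples)) if len(samples) else 0.0
    if peak > 1.0:
        warnings.warn(
            f"samples exceed [-1, 1] (peak {peak:.3f}); clipping on write", stacklevel=2
        )
        samples = np.clip(samples, -1.0, 1.0)
    pcm = np.clip(np.round(samples * 32768.0), -32768, 32767).astype(np.int16)
    wavfile.write(Path(path), recording.sample_rate, pcm)


def read_label_track(path: str | Path) -> SoftLabelTrack:
    """Parse an Audacity label-track TSV (start, end, label per line)."""
    path = Path(path)
    intervals: list[LabelInterval] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise LabelTrackError(
                    f"{path}:{lineno}: expected 'start<TAB>end<TAB>label', got {raw!r}"
                )
            try:
                start_s, end_s = float(parts[0]), float(parts[1])
            except ValueError as exc:
                raise LabelTrackError(f"{path}:{lineno}: non-numeric time: {exc}") from exc
            label = parts[2].strip().lower()
            try:
                intervals.append(LabelInterval(start_s, end_s, label))
            except LabelTrackError as exc:
                raise LabelTrackError(f"{path}:{lineno}: {exc}") from exc
    intervals.sort(key=lambda iv: iv.start_s)
    try:
        return SoftLabelTrack(tuple(intervals))
    except LabelTrackError as exc:
        raise LabelTrackError(f"{path}: {exc}") from exc


def write_label_track(track: SoftLabelTrack, path: str | Path) -> None:
    """Write a track in Audacity label-track TSV format."""
    with open(Path(path), "w", encoding="utf-8") as fh:
        for iv in track:
            fh.write(f"{iv.start_s:.6f}\t{iv.end_s:.6f}\t{iv.label}\n")


def resample(recording: AudioRecording, target_sr: int) -> AudioRecording:
    """Band-limited resampling to ``target_sr``; identity when rates match."""
    if not target_sr > 0:
        raise ValueError(f"target_sr must be positive, got {target_sr}")
    if target_sr == recording.sample_rate:
        return recording
    ratio = Fraction(int(target_sr), int(recording.sample_rate))
    out = resample_poly(recording.samples, ratio.numerator, ratio.denominator)
    out = np.clip(out, -1.0, 1.0)
    return AudioRecording(samples=out, sample_rate=int(target_sr))
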