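"""Feature extraction and label preparation.

Recordings are sliced into 25-ms analysis segments advanced at a 10-ms hop
(centered framing), converted to 128-band Mel log-energies in dB, and paired
with per-segment integer labels 0/1/2 (break/normal/wheeze) derived from the
interval annotation. Pitch-shift augmentation and stationary spectral-gating
noise reduction operate on the raw waveform.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.fft import irfft, rfft
from scipy.ndimage import uniform_filter
from scipy.signal import get_window
from scipy.signal import resample as _fft_resample

from .audio_io import CLASS_TO_INDEX, AudioRecording, SoftLabelTrack

__all__ = [
    "FrameSpec",
    "FeatureMatrix",
    "AugmentSpec",
    "DB_FLOOR",
    "n_frames",
    "mel_filterbank",
    "mel_center_frequencies",
    "extract_mel",
    "hard_label",
    "pitch_shift",
    "augment",
    "spectral_gate",
]

#: dB floor of the Mel features (reference power 1.0).
DB_FLOOR = -80.0


@dataclass(frozen=True)
class FrameSpec:
    """Segment framing convention: window/hop in milliseconds."""

    win_ms: float = 25.0
    hop_ms: float = 10.0
    centered: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.hop_ms <= self.win_ms:
            raise ValueError("require 0 < hop_ms <= win_ms")

    def win_samples(self, sample_rate: int) -> int:
        return int(round(self.win_ms * sample_rate / 1000.0))

    def hop_samples(self, sample_rate: int) -> int:
        return int(round(self.hop_ms * sample_rate / 1000.0))


@dataclass(frozen=True)
class FeatureMatrix:
    """Per-segment Mel log-energy rows plus segment center times."""

    features: np.ndarray  # (n_segments, n_mels), dB
    frame_times: np.ndarray  # (n_segments,), seconds

    def __post_init__(self) -> None:
        features = np.asarray(self.features, dtype=np.float64)
        frame_times = np.asarray(self.frame_times, dtype=np.float64)
        if features.ndim != 2:
            raise ValueError("features must be 2-D (segments x mel bands)")
        if len(frame_times) != features.shape[0]:
            raise ValueError("frame_times length must match feature rows")
        if not np.all(np.isfinite(features)):
            raise ValueError("features contain non-finite values")
        object.__setattr__(self, "features", features)
        object.__setattr__(self, "frame_times", frame_times)

    @property
    def n_segments(self) -> int:
        return self.features.shape[0]

    @property
    def n_mels(self) -> int:
        return self.features.shape[1]


@dataclass(frozen=True)
class AugmentSpec:
    """Pitch-shift augmentation: semitone offsets plus the original."""

    semitones: tuple[float, ...] = (-3.5, -2.0, 2.0, 3.5)
    keep_original: bool = True

    def __post_init__(self) -> None:
        semitones = tuple(float(s) for s in self.semitones)
        if len(set(semitones)) != len(semitones):
            raise ValueError("duplicate semitone values")
        if not all(np.isfinite(semitones)):
            raise ValueError("semitone values must be finite")
        object.__setattr__(self, "semitones", semitones)


def n_frames(n_samples: int, sample_rate: int, spec: FrameSpec = FrameSpec()) -> int:
    """Number of analysis segments for an ``n_samples``-long recording.

    Centered framing yields ``1 + n_samples // hop`` for non-empty input
    (an 8,000-sample chunk at 16 kHz gives 51 segments at the defaults);
    uncentered framing fits whole windows only.
    """
    if n_samples < 0:
        raise ValueError("n_samples must be >= 0")
    if n_samples == 0:
        return 0
    hop = spec.hop_samples(sample_rate)
    if spec.centered:
        return 1 + n_samples // hop
    win = spec.win_samples(sample_rate)
    if n_samples < win:
        return 0
    return 1 + (n_samples - win) // hop


def _hz_to_mel(f: np.ndarray | float) -> np.ndarray | float:
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=np.float64) / 700.0)


def _mel_to_hz(m: np.ndarray | float) -> np.ndarray | float:
    return 700.0 * (10.0 ** (np.asarray(m, dtype=np.float64) / 2595.0) - 1.0)


def mel_center_frequencies(n_mels: int, sample_rate: int) -> np.ndarray:
    """Center frequencies (Hz) of the triangular Mel filters, 0 Hz–Nyquist."""
    edges = _mel_to_hz(np.linspace(0.0, _hz_to_mel(sample_rate / 2.0), n_mels + 2))
    return edges[1:-1]


def mel_filterbank(n_mels: int, n_fft: int, sample_rate: int) -> np.ndarray:
    """Area-normalized triangular Mel filterbank, shape (n_mels, n_fft//2+1)."""
    n_bins = n_fft // 2 + 1
    if n_mels > n_bins:
        raise ValueError(
            f"n_mels={n_mels} exceeds the {n_bins} resolvable bins of n_fft={n_fft}"
        )
    fft_freqs = np.linspace(0.0, sample_rate / 2.0, n_bins)
    edges = _mel_to_hz(np.linspace(0.0, _hz_to_mel(sample_rate / 2.0), n_mels + 2))
    fb = np.zeros((n_mels, n_bins))
    for m in range(n_mels):
        lo, center, hi = edges[m], edges[m + 1], edges[m + 2]
        rise = (fft_freqs - lo) / max(center - lo, 1e-12)
        fall = (hi - fft_freqs) / max(hi - center, 1e-12)
        fb[m] = np.maximum(0.0, np.minimum(rise, fall))
        fb[m] *= 2.0 / (hi - lo)  # Slaney-style area normalization
    return fb


def _frame_signal(samples: np.ndarray, win: int, hop: int, centered: bool) -> np.ndarray:
    """Slice a waveform into (n_frames, win) windows per the framing contract."""
    if centered:
        pad = win // 2
        padded = np.pad(samples, (pad, pad + win))  # headroom for the last frame
        count = 1 + len(samples) // hop
    else:
        padded = samples
        count = 1 + (len(samples) - win) // hop if len(samples) >= win else 0
    if count <= 0:
        return np.zeros((0, win))
    idx = np.arange(win)[None, :] + hop * np.arange(count)[:, None]
    return padded[idx]


def extract_mel(
    recording: AudioRecording,
    spec: FrameSpec = FrameSpec(),
    n_mels: int = 128,
    n_fft: int = 512,
) -> FeatureMatrix:
    """Per-segment Mel log-energies in dB.

    The waveform is peak-normalized per recording, framed with a Hann taper,
    and each power spectrum is pooled through the Mel filterbank. dB uses a
    fixed reference of 1.0 with a floor of ``DB_FLOOR`` so values are
    comparable across streaming chunks.
    """
    if len(recording) == 0:
        return FeatureMatrix(np.zeros((0, n_mels)), np.zeros(0))
    sr = recording.sample_rate
    win = spec.win_samples(sr)
    hop = spec.hop_samples(sr)
    if win > n_fft:
        raise ValueError(f"window of {win} samples exceeds n_fft={n_fft}")

    samples = recording.samples
    peak = np.max(np.abs(samples))
    if peak > 0:
        samples = samples / peak

    frames = _frame_signal(samples, win, hop, spec.centered)
    window = get_window("hann", win, fftbins=True)
    spectra = np.abs(rfft(frames * window, n=n_fft, axis=1)) ** 2
    fb = mel_filterbank(n_mels, n_fft, sr)
    mel_power = spectra @ fb.T
    db = 10.0 * np.log10(np.maximum(mel_power, 10.0 ** (DB_FLOOR / 10.0)))
    times = hop / sr * np.arange(frames.shape[0])
    return FeatureMatrix(db, times)


def hard_label(
    track: SoftLabelTrack,
    n_segments: int,
    spec: FrameSpec = FrameSpec(),
    ratio: float = 1.0,
) -> np.ndarray:
    """Assign one integer class (0/1/2) to each analysis segment.

    A segment takes an interval's class outright when its overlap fraction
    with that single interval reaches ``ratio``; otherwise it falls back to
    the class with maximal overlap (ties broken toward the lower class
    index). Every segment is labeled; a segment with zero coverage by the
    track is an error.
    """
    if not 0.0 < ratio <= 1.0:
        raise ValueError("ratio must lie in (0, 1]")
    if n_segments == 0:
        return np.zeros(0, dtype=np.int64)
    if len(track) == 0:
        raise ValueError("empty label track cannot cover any segment")

    win_s = spec.win_ms / 1000.0
    hop_s = spec.hop_ms / 1000.0
    starts = np.array([iv.start_s for iv in track])
    ends = np.array([iv.end_s for iv in track])
    classes = np.array([CLASS_TO_INDEX[iv.label] for iv in track])

    labels = np.empty(n_segments, dtype=np.int64)
    for i in range(n_segments):
        if spec.centered:
            center = i * hop_s
            seg_lo, seg_hi = center - win_s / 2.0, center + win_s / 2.0
        else:
            seg_lo = i * hop_s
            seg_hi = seg_lo + win_s
        overlap = np.maximum(0.0, np.minimum(seg_hi, ends) - np.maximum(seg_lo, starts))
        covered = overlap.sum()
        if covered <= 0.0:
            raise ValueError(
                f"segment {i} ([{seg_lo:.4f}, {seg_hi:.4f}] s) is not covered by the track"
            )
        per_class = np.zeros(3)
        np.add.at(per_class, classes, overlap)
        frac = per_class / covered
        if np.max(frac) >= ratio:
            labels[i] = int(np.argmax(frac))  # argmax ties break low
        else:
            labels[i] = int(np.argmax(per_class))
    return labels


def _stft(samples: np.ndarray, n_fft: int, hop: int) -> np.ndarray:
    window = get_window("hann", n_fft, fftbins=True)
    frames = _frame_signal(samples, n_fft, hop, centered=True)
    return rfft(frames * window, axis=1).T  # (n_bins, n_frames)


def _istft(stft_matrix: np.ndarray, n_fft: int, hop: int, length: int) -> np.ndarray:
    window = get_window("hann", n_fft, fftbins=True)
    frames = irfft(stft_matrix.T, n=n_fft, axis=1) * window
    n_frames_ = frames.shape[0]
    pad = n_fft // 2
    out = np.zeros(n_frames_ * hop + n_fft)
    norm = np.zeros_like(out)
    wsq = window**2
    for t in range(n_frames_):
        out[t * hop : t * hop + n_fft] += frames[t]
        norm[t * hop : t * hop + n_fft] += wsq
    out = out[pad : pad + length]
    norm = norm[pad : pad + length]
    good = norm > 1e-10
    out[good] /= norm[good]
    return out


def _phase_vocoder(stft_matrix: np.ndarray, rate: float, hop: int) -> np.ndarray:
    """Time-stretch an STFT by ``rate`` (rate < 1 lengthens)."""
    n_bins, n_cols = stft_matrix.shape
    time_steps = np.arange(0.0, n_cols, rate)
    phi_advance = np.linspace(0.0, np.pi * hop, n_bins)
    padded = np.concatenate([stft_matrix, np.zeros((n_bins, 2))], axis=1)
    stretched = np.zeros((n_bins, len(time_steps)), dtype=complex)
    phase_acc = np.angle(stft_matrix[:, 0])
    for i, step in enumerate(time_steps):
        idx = int(step)
        frac = step - idx
        a, b = padded[:, idx], padded[:, idx + 1]
        mag = (1.0 - frac) * np.abs(a) + frac * np.abs(b)
        stretched[:, i] = mag * np.exp(1j * phase_acc)
        dphase = np.angle(b) - np.angle(a) - phi_advance
        dphase -= 2.0 * np.pi * np.round(dphase / (2.0 * np.pi))
        phase_acc += phi_advance + dphase
    return stretched


def pitch_shift(recording: AudioRecording, semitones: float) -> AudioRecording:
    """Shift all frequencies by ``2**(semitones/12)`` preserving duration.

    Phase-vocoder time stretch followed by resampling back to the original
    length, mirroring the standard audio-library implementation.
    """
    if abs(semitones) > 24:
        raise ValueError("pitch shifts beyond two octaves are not plausible augmentation")
    if len(recording) == 0:
        raise ValueError("cannot pitch-shift an empty recording")
    if semitones == 0:
        return recording

    n_fft, hop = 2048, 512
    rate = 2.0 ** (-semitones / 12.0)
    stretched_stft = _phase_vocoder(_stft(recording.samples, n_fft, hop), rate, hop)
    stretched_len = int(round(len(recording) / rate))
    stretched = _istft(stretched_stft, n_fft, hop, stretched_len)
    out = _fft_resample(stretched, len(recording))
    peak = np.max(np.abs(out))
    if peak > 1.0:
        out = out / peak
    return AudioRecording(samples=out, sample_rate=recording.sample_rate)


def augment(
    recording: AudioRecording,
    track: SoftLabelTrack,
    spec: AugmentSpec = AugmentSpec(),
) -> list[tuple[AudioRecording, SoftLabelTrack]]:
    """Pitch-shifted variants of a labeled recording.

    Pitch shifting preserves timing, so each variant reuses the input track.
    """
    out: list[tuple[AudioRecording, SoftLabelTrack]] = []
    if spec.keep_original:
        out.append((recording, track))
    for semitones in spec.semitones:
        out.append((pitch_shift(recording, semitones), track))
    return out


def spectral_gate(
    recording: AudioRecording,
    noise_profile: AudioRecording | None = None,
    n_std: float = 0.1,
    stationary: bool = True,
    n_fft: int = 1024,
) -> AudioRecording:
    """Stationary spectral-gating noise reduction.

    Per-frequency noise statistics (mean and standard deviation of the dB
    magnitude) come from ``noise_profile`` when given, otherwise from the
    recording itself; STFT cells below ``mean + n_std * std`` are suppressed
    through a smoothed soft mask and the waveform is rebuilt by inverse STFT.
    """
    if len(recording) == 0:
        return recording
    hop = n_fft // 4
    stft_matrix = _stft(recording.samples, n_fft, hop)
    mag_db = 20.0 * np.log10(np.abs(stft_matrix) + 1e-12)

    ref = recording if noise_profile is None else noise_profile
    if ref.sample_rate != recording.sample_rate:
        raise ValueError("noise profile sample rate differs from recording")
    ref_db = mag_db if noise_profile is None else 20.0 * np.log10(
        np.abs(_stft(ref.samples, n_fft, hop)) + 1e-12
    )
    noise_mean = ref_db.mean(axis=1, keepdims=True)
    noise_std = ref_db.std(axis=1, keepdims=True)
    threshold = noise_mean + n_std * noise_std

    # smoothing the dB image before thresholding shrinks the variance of
    # noise cells, separating them cleanly from coherent signal energy
    smoothed_db = uniform_filter(mag_db, size=(3, 5), mode="nearest")
    if not stationary:
        # local (time-varying) threshold: smooth the dB track per frequency
        local = uniform_filter(mag_db, size=(1, 25), mode="nearest")
        threshold = np.maximum(threshold, local)
    # soft sigmoid gain over the dB distance to the threshold, then broad
    # smoothing: hard masks cut cliffs into the spectrum that read as
    # spurious tonal peaks ("musical noise") downstream
    gain = 1.0 / (1.0 + np.exp(-(smoothed_db - threshold) / 3.0))
    gain = uniform_filter(gain, size=(7, 5), mode="nearest")
    floor_gain = 0.08
    gain = floor_gain + (1.0 - floor_gain) * gain

    cleaned = _istft(stft_matrix * gain, n_fft, hop, len(recording))
    peak = np.max(np.abs(cleaned))
    if peak > 1.0:
        cleaned = cleaned / peak
    return AudioRecording(samples=cleaned, sample_rate=recording.sample_rate)
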