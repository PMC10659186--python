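import numpy as np
import pytest

from wheezecount import (
    AudioRecording,
    AugmentSpec,
    FrameSpec,
    LabelInterval,
    SoftLabelTrack,
    augment,
    extract_mel,
    hard_label,
    mix_noise,
    n_frames,
    pitch_shift,
    spectral_gate,
)
from wheezecount.preprocess import DB_FLOOR, mel_center_frequencies, mel_filterbank

from conftest import dominant_frequency


class TestFrameSpec:
    def test_defaults(self):
        spec = FrameSpec()
        assert spec.win_samples(16_000) == 400
        assert spec.hop_samples(16_000) == 160

    def test_invalid_hop(self):
        with pytest.raises(ValueError):
            FrameSpec(win_ms=10, hop_ms=25)


class TestNFrames:
    def test_half_second_chunk_is_51(self):
        assert n_frames(8_000, 16_000) == 51

    def test_empty(self):
        assert n_frames(0, 16_000) == 0

    def test_derived_example(self):
        assert n_frames(1_600, 16_000) == 11  # 1 + floor(1600/160)

    def test_uncentered(self):
        spec = FrameSpec(centered=False)
        assert n_frames(400, 16_000, spec) == 1
        assert n_frames(399, 16_000, spec) == 0
        assert n_frames(8_000, 16_000, spec) == 1 + (8_000 - 400) // 160

    @pytest.mark.parametrize("n", list(range(0, 32_001, 1_600)))
    def test_matches_extract_mel_rows(self, n):
        rec = AudioRecording(0.1 * np.sin(np.arange(n)), 16_000)
        assert extract_mel(rec).n_segments == n_frames(n, 16_000)


class TestExtractMel:
    def test_shape_51_by_128(self, rng):
        rec = AudioRecording(rng.uniform(-0.5, 0.5, 8_000), 16_000)
        fm = extract_mel(rec)
        assert fm.features.shape == (51, 128)

    def test_all_zero_hits_floor(self):
        fm = extract_mel(AudioRecording(np.zeros(1_600), 16_000))
        assert np.all(fm.features == DB_FLOOR)

    def test_tone_peaks_at_nearest_mel_band(self, tone_440):
        fm = extract_mel(tone_440)
        centers = mel_center_frequencies(128, 16_000)
        # FFT-bin discretization (31.25 Hz at n_fft=512) can land the energy
        # in a neighboring narrow filter; allow one bin-width of slack
        peak_centers = centers[np.argmax(fm.features, axis=1)]
        assert np.all(np.abs(peak_centers[2:-2] - 440.0) < 32.0)

    def test_frame_times(self, rng):
        rec = AudioRecording(rng.uniform(-0.5, 0.5, 1_600), 16_000)
        fm = extract_mel(rec)
        assert fm.frame_times[0] == 0.0
        assert np.allclose(np.diff(fm.frame_times), 0.010)

    def test_too_many_mels_rejected(self, tone_440):
        with pytest.raises(ValueError, match="n_mels"):
            extract_mel(tone_440, n_mels=300)

    def test_gain_invariance(self, rng):
        samples = rng.uniform(-0.2, 0.2, 8_000)
        a = extract_mel(AudioRecording(samples, 16_000))
        b = extract_mel(AudioRecording(np.clip(4 * samples, -1, 1), 16_000))
        assert np.allclose(a.features, b.features, atol=1e-6)


class TestMelFilterbank:
    def test_shape(self):
        fb = mel_filterbank(128, 512, 16_000)
        assert fb.shape == (128, 257)

    def test_nonnegative(self):
        assert np.all(mel_filterbank(64, 512, 16_000) >= 0)

    def test_centers_monotone(self):
        centers = mel_center_frequencies(128, 16_000)
        assert np.all(np.diff(centers) > 0)
        assert 0 < centers[0] and centers[-1] < 8_000


def _aligned_track():
    # boundaries on segment centers: 10-ms hop, centered 25-ms windows
    return SoftLabelTrack(
        (
            LabelInterval(0.0, 1.0, "normal"),
            LabelInterval(1.0, 2.0, "wheeze"),
            LabelInterval(2.0, 3.0, "break"),
        )
    )


class TestHardLabel:
    def test_full_containment(self):
        track = _aligned_track()
        labels = hard_label(track, n_frames(48_000, 16_000))
        # segments well inside each interval get that interval's class
        assert labels[50] == 1
        assert labels[150] == 2
        assert labels[250] == 0

    def test_every_segment_labeled(self):
        labels = hard_label(_aligned_track(), n_frames(48_000, 16_000))
        assert len(labels) == n_frames(48_000, 16_000)
        assert set(np.unique(labels)) <= {0, 1, 2}

    def test_majority_fallback(self):
        # a segment straddling 60% normal / 40% wheeze takes normal at r=1
        track = SoftLabelTrack(
            (LabelInterval(0.0, 0.5101, "normal"), LabelInterval(0.5101, 1.0, "wheeze"))
        )
        labels = hard_label(track, n_frames(16_000, 16_000))
        # segment 51 is centered at 0.51: spans [0.4975, 0.5225], 0.0126 s
        # of normal vs 0.0124 s of wheeze
        assert labels[51] == 1

    def test_pure_track_reproduced_exactly(self):
        track = _aligned_track()
        labels = hard_label(track, n_frames(48_000, 16_000))
        for i, lab in enumerate(labels):
            center = i * 0.010
            expected = 1 if center < 1.0 else (2 if center < 2.0 else 0)
            lo, hi = center - 0.0125, center + 0.0125
            straddles = (lo < 1.0 < hi) or (lo < 2.0 < hi)
            if not straddles:
                assert lab == expected, f"segment {i}"

    def test_uncovered_segment_rejected(self):
        track = SoftLabelTrack((LabelInterval(0.0, 0.5, "normal"),))
        with pytest.raises(ValueError, match="not covered"):
            hard_label(track, 200)

    def test_bad_ratio(self):
        with pytest.raises(ValueError):
            hard_label(_aligned_track(), 10, ratio=0.0)

    def test_zero_segments(self):
        assert len(hard_label(_aligned_track(), 0)) == 0


class TestPitchShift:
    def test_identity(self, tone_440):
        out = pitch_shift(tone_440, 0)
        corr = np.corrcoef(out.samples, tone_440.samples)[0, 1]
        assert corr >= 0.999

    def test_octave_up(self, tone_440):
        out = pitch_shift(tone_440, 12)
        assert dominant_frequency(out.samples, 16_000) == pytest.approx(880.0, abs=5.0)

    def test_length_preserved(self, rng):
        rec = AudioRecording(rng.uniform(-0.5, 0.5, 12_345), 16_000)
        for semitones in (-3.5, 2.0):
            assert len(pitch_shift(rec, semitones)) == 12_345

    def test_implausible_shift_rejected(self, tone_440):
        with pytest.raises(ValueError):
            pitch_shift(tone_440, 25)


class TestAugment:
    def test_default_yields_five(self, tone_440):
        track = SoftLabelTrack((LabelInterval(0.0, 1.0, "normal"),))
        out = augment(tone_440, track, AugmentSpec())
        assert len(out) == 5

    def test_empty_semitones_identity(self, tone_440):
        track = SoftLabelTrack((LabelInterval(0.0, 1.0, "normal"),))
        out = augment(tone_440, track, AugmentSpec(semitones=(), keep_original=True))
        assert len(out) == 1
        assert out[0][0] is tone_440

    def test_tracks_unchanged(self, tone_440):
        track = SoftLabelTrack((LabelInterval(0.0, 1.0, "normal"),))
        for _, t in augment(tone_440, track, AugmentSpec(semitones=(2.0,))):
            assert t == track

    def test_duplicate_semitones_rejected(self):
        with pytest.raises(ValueError):
            AugmentSpec(semitones=(2.0, 2.0))


class TestSpectralGate:
    def test_all_zero_passthrough(self):
        out = spectral_gate(AudioRecording(np.zeros(8_000), 16_000))
        assert np.allclose(out.samples, 0.0)

    def test_snr_improvement_on_noisy_tone(self, rng):
        t = np.arange(32_000) / 16_000
        clean = 0.3 * np.sin(2 * np.pi * 440.0 * t)
        noise = 0.3 * rng.standard_normal(48_000)
        noisy = mix_noise(
            AudioRecording(clean, 16_000),
            AudioRecording(noise[:32_000], 16_000),
            0.0,
        )
        profile = AudioRecording(np.clip(noise[32_000:], -1, 1), 16_000)
        gated = spectral_gate(noisy, noise_profile=profile, n_std=0.5)

        def snr(x):
            err = x - clean
            return 10 * np.log10(np.mean(clean**2) / np.mean(err**2))

        assert snr(gated.samples) >= snr(noisy.samples) + 6.0

    def test_length_preserved(self, rng):
        rec = AudioRecording(rng.uniform(-0.5, 0.5, 10_001), 16_000)
        assert len(spectral_gate(rec)) == 10_001
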