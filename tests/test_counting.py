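"""Counting layer tests, including the independent pseudo-code oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.signal import find_peaks

from wheezecount import (
    CountingParams,
    count_offline,
    generate_recording,
    hard_label,
    n_frames,
    one_hot_probs,
    stream_init,
    stream_report,
    stream_update,
)
from wheezecount.counting import (
    BreathGroup,
    Peak,
    argmax_labels,
    classify_group,
    find_label_peaks,
    segment_breaths,
)
from wheezecount.synthetic import SimConfig


# --------------------------------------------------------------------------
# independent oracle: a literal transcription of the offline pseudo-code
# built on scipy's generic peak finder, sharing no code with the package
# --------------------------------------------------------------------------
def brute_force_offline(labels, gap=100):
    """Count (respiration, normal, wheeze) from a {0,1,2} label sequence."""
    padded = np.concatenate([[-1], np.asarray(labels), [-1]])
    peak_pos, _ = find_peaks(padded, height=0.5)
    idx = peak_pos - 1
    heights = padded[peak_pos]
    if len(idx) == 0:
        return 0, 0, 0
    groups = []
    current = [0]
    for j in range(1, len(idx)):
        if idx[j] - idx[j - 1] >= gap:
            groups.append(current)
            current = []
        current.append(j)
    groups.append(current)
    n_wheeze = sum(1 for g in groups if np.mean(heights[g]) > 1.0)
    n_normal = sum(1 for g in groups if np.mean(heights[g]) == 1.0)
    return len(groups), n_normal, n_wheeze


def labels_to_probs(labels):
    return one_hot_probs(np.asarray(labels))


class TestArgmaxLabels:
    def test_basic(self):
        assert argmax_labels(np.array([[0.1, 0.2, 0.7]])).tolist() == [2]

    def test_tie_goes_low(self):
        assert argmax_labels(np.array([[0.4, 0.4, 0.2]])).tolist() == [0]

    def test_empty(self):
        assert argmax_labels(np.zeros((0, 3))).tolist() == []

    def test_rejects_bad_width(self):
        with pytest.raises(ValueError):
            argmax_labels(np.zeros((4, 2)))


class TestFindLabelPeaks:
    def test_plateau_midpoint(self):
        peaks = find_label_peaks([0, 1, 1, 1, 0])
        assert peaks == [Peak(index=2, height=1)]

    def test_nested_runs_only_top_is_peak(self):
        peaks = find_label_peaks([0, 1, 2, 2, 1, 0])
        assert peaks == [Peak(index=2, height=2)]

    def test_all_zero(self):
        assert find_label_peaks([0, 0, 0]) == []

    def test_boundary_plateau_qualifies(self):
        assert find_label_peaks([1, 1, 0]) == [Peak(index=0, height=1)]
        # run spans indices 1-2; lower-middle is 1
        assert find_label_peaks([0, 2, 2]) == [Peak(index=1, height=2)]

    def test_even_plateau_lower_middle(self):
        assert find_label_peaks([0, 1, 1, 0]) == [Peak(index=1, height=1)]

    @given(st.lists(st.integers(0, 2), min_size=0, max_size=60))
    @settings(max_examples=200, deadline=None)
    def test_matches_scipy_oracle(self, labels):
        labels = np.asarray(labels, dtype=np.int64)
        ours = find_label_peaks(labels)
        padded = np.concatenate([[-1], labels, [-1]])
        pos, _ = find_peaks(padded, height=0.5)
        assert [p.index for p in ours] == (pos - 1).tolist()
        assert [p.height for p in ours] == padded[pos].tolist()


class TestSegmentBreaths:
    def test_split_at_gap(self):
        peaks = [Peak(10, 1), Peak(200, 1)]
        groups = segment_breaths(peaks, 100)
        assert len(groups) == 2

    def test_no_split_below_gap(self):
        peaks = [Peak(10, 1), Peak(60, 2)]
        groups = segment_breaths(peaks, 100)
        assert len(groups) == 1
        assert groups[0].avg_p == 1.5

    def test_gap_exactly_threshold_splits(self):
        # d >= threshold per the formal pseudo-code reading
        assert len(segment_breaths([Peak(0, 1), Peak(100, 1)], 100)) == 2
        assert len(segment_breaths([Peak(0, 1), Peak(99, 1)], 100)) == 1

    def test_empty(self):
        assert segment_breaths([], 100) == []


class TestClassifyGroup:
    def test_mixed_heights_wheeze(self):
        group = BreathGroup((Peak(0, 1), Peak(5, 2)), 0, 5)
        assert group.avg_p == 1.5
        assert classify_group(group) == "wheeze"

    def test_all_normal(self):
        group = BreathGroup((Peak(0, 1), Peak(3, 1), Peak(6, 1)), 0, 6)
        assert classify_group(group) == "normal"

    def test_single_wheeze_peak(self):
        assert classify_group(BreathGroup((Peak(0, 2),), 0, 0)) == "wheeze"


class TestCountOffline:
    def test_hand_trace(self):
        # plateau of 1s, long break, then a breath containing a wheeze run
        labels = [1] * 30 + [0] * 150 + [1, 1, 2, 2, 2, 1]
        report = count_offline(labels_to_probs(labels))
        assert (report.n_respiration, report.n_normal, report.n_wheeze) == (2, 1, 1)

    def test_all_break(self):
        report = count_offline(labels_to_probs([0] * 500))
        assert (report.n_respiration, report.n_normal, report.n_wheeze) == (0, 0, 0)
        assert report.wheeze_rate == 0.0
        assert not report.wheeze_rate_defined

    def test_event_timestamps_use_hop(self):
        labels = [0] * 10 + [1] * 20 + [0] * 200 + [2] * 20
        report = count_offline(labels_to_probs(labels))
        assert report.events[0] == (pytest.approx(0.19), "normal")  # midpoint 19
        assert report.events[1][1] == "wheeze"

    def test_oracle_equivalence_random(self):
        rng = np.random.default_rng(0)
        for _ in range(300):
            n = int(rng.integers(50, 2000))
            labels = rng.choice([0, 1, 2], size=n, p=[0.75, 0.15, 0.10])
            report = count_offline(labels_to_probs(labels))
            assert (
                report.n_respiration,
                report.n_normal,
                report.n_wheeze,
            ) == brute_force_offline(labels)

    def test_conservation_invariant(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            labels = rng.choice([0, 1, 2], size=500, p=[0.6, 0.3, 0.1])
            report = count_offline(labels_to_probs(labels))
            assert report.n_respiration == report.n_normal + report.n_wheeze


class TestStreaming:
    def test_fresh_state(self):
        state = stream_init()
        assert state.wheeze_toggle is False
        assert state.wheeze_score == 0 and state.break_score == 0
        report = stream_report(state)
        assert (report.n_respiration, report.n_wheeze) == (0, 0)
        assert not report.pending
        assert stream_init() == stream_init()

    def _chunk(self, label, n, p=0.9):
        probs = np.full((n, 3), (1 - p) / 2)
        probs[:, label] = p
        return probs

    def test_wheeze_then_break_counts_one(self):
        state = stream_init()
        state, _ = stream_update(state, self._chunk(2, 3, 0.7))
        assert state.wheeze_toggle is True
        state, events = stream_update(state, self._chunk(0, 3, 0.9))
        assert state.wheeze_toggle is False
        assert state.n_wheeze == 1
        assert [cls for _, cls in events] == ["wheeze"]

    def test_interrupted_run_resets(self):
        state = stream_init()
        state, _ = stream_update(state, self._chunk(2, 2, 0.7))
        state, _ = stream_update(state, self._chunk(1, 1, 0.8))
        assert state.wheeze_toggle is False
        assert state.wheeze_score == 0

    def test_run_split_across_chunks(self):
        state = stream_init()
        state, _ = stream_update(state, self._chunk(2, 2, 0.7))
        assert state.wheeze_toggle is False
        state, _ = stream_update(state, self._chunk(2, 1, 0.7))
        assert state.wheeze_toggle is True

    def test_subthreshold_argmax_does_not_score(self):
        state = stream_init()
        probs = np.array([[0.25, 0.25, 0.5]] * 5)  # argmax wheeze but p < 0.6
        state, _ = stream_update(state, probs)
        assert state.wheeze_toggle is False and state.wheeze_score == 0

    def test_pending_wheeze_not_counted(self):
        state = stream_init()
        state, _ = stream_update(state, self._chunk(2, 3, 0.7))
        report = stream_report(state)
        assert report.n_wheeze == 0
        assert report.pending

    def test_chunk_invariance(self):
        rng = np.random.default_rng(3)
        for trial in range(100):
            n = int(rng.integers(100, 600))
            probs = rng.dirichlet([0.6, 0.3, 0.3], size=n)
            whole = stream_init()
            stream_update(whole, probs)
            for chunk_size in (17, 51, 102):
                state = stream_init()
                for i in range(0, n, chunk_size):
                    stream_update(state, probs[i : i + chunk_size])
                assert state.n_wheeze == whole.n_wheeze, f"trial {trial} chunk {chunk_size}"
                assert state.n_normal == whole.n_normal

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(4)
        for _ in range(30):
            probs = rng.dirichlet([0.5, 0.4, 0.4], size=400)
            counts = []
            for thr in (0.4, 0.6, 0.8):
                state = stream_init()
                stream_update(state, probs, CountingParams(prob_threshold=thr))
                counts.append(state.n_wheeze)
            assert counts[0] >= counts[1] >= counts[2]

    def test_streaming_matches_offline_on_separated_onehot(self):
        config = SimConfig(n_breaths=6, wheeze_prob=0.5, pause_s=1.4, seed=11)
        _, track, truth = generate_recording(config)
        count = n_frames(round(track.span[1] * 16000), 16000)
        probs = one_hot_probs(hard_label(track, count))
        offline = count_offline(probs)
        state = stream_init()
        for i in range(0, len(probs), 51):
            stream_update(state, probs[i : i + 51])
        assert state.n_wheeze == offline.n_wheeze == truth.n_wheeze


class TestGroundTruthRecovery:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_oracle_probs_recover_truth(self, seed):
        config = SimConfig(n_breaths=5, wheeze_prob=0.5, pause_s=1.3, seed=seed)
        _, track, truth = generate_recording(config)
        count = n_frames(round(track.span[1] * config.sample_rate), config.sample_rate)
        labels = hard_label(track, count)
        report = count_offline(one_hot_probs(labels))
        assert report.n_respiration == truth.n_breaths
        assert report.n_wheeze == truth.n_wheeze


class TestCountingParams:
    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            CountingParams(gap_threshold=0)
        with pytest.raises(ValueError):
            CountingParams(prob_threshold=-0.1)
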