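"""Breath-cycle and wheeze-event counting from per-segment probabilities.

Two counters operate on the classifier's (N, 3) probability output:

* the **offline** counter collapses probabilities to argmax labels, finds
  plateau-aware local maxima among the nonzero labels, groups peaks whose
  spacing stays below a gap threshold into breath cycles, and calls a cycle
  a wheeze when the mean peak height exceeds 1;
* the **streaming** counter is a hysteresis state machine: a run of
  ``run_length`` confident wheeze segments arms a toggle, a subsequent run
  of confident break segments releases it and counts one wheeze event.
  State persists across 0.5-s chunks, so arbitrary chunkings agree.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Peak",
    "BreathGroup",
    "CountReport",
    "CountingParams",
    "StreamState",
    "argmax_labels",
    "find_label_peaks",
    "segment_breaths",
    "classify_group",
    "count_offline",
    "stream_init",
    "stream_update",
    "stream_report",
    "one_hot_probs",
]


@dataclass(frozen=True)
class CountingParams:
    """Tunables of both counters.

    ``gap_threshold`` is measured in segments (100 segments at a 10-ms hop is
    about one second); a breath cycle is complete when the spacing between
    consecutive peaks reaches it. The streaming counter needs ``run_length``
    consecutive segments whose target-class probability is both the argmax
    and at least ``prob_threshold``.
    """

    gap_threshold: int = 100
    prob_threshold: float = 0.6
    run_length: int = 3
    chunk_s: float = 0.5
    hop_s: float = 0.010

    def __post_init__(self) -> None:
        for name in ("gap_threshold", "prob_threshold", "run_length", "chunk_s", "hop_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class Peak:
    """A local maximum of the label sequence: segment index + label value."""

    index: int
    height: int

    def __post_init__(self) -> None:
        if self.height not in (1, 2):
            raise ValueError("peak height must be 1 or 2")


@dataclass(frozen=True)
class BreathGroup:
    """Consecutive peaks closer than the gap threshold: one breath cycle."""

    peaks: tuple[Peak, ...]
    start_idx: int
    end_idx: int

    @property
    def avg_p(self) -> float:
        """Mean peak height; > 1 marks the cycle as wheezing."""
        return float(np.mean([p.height for p in self.peaks]))


@dataclass(frozen=True)
class CountReport:
    """Breath totals plus time-stamped events."""

    n_respiration: int = 0
    n_normal: int = 0
    n_wheeze: int = 0
    events: tuple[tuple[float, str], ...] = ()
    pending: bool = False  # streaming only: a wheeze toggle is armed

    def __post_init__(self) -> None:
        if self.n_respiration != self.n_normal + self.n_wheeze:
            raise ValueError("n_respiration must equal n_normal + n_wheeze")

    @property
    def wheeze_rate(self) -> float:
        """Wheeze events per breath cycle; 0 (flagged) with zero breaths."""
        return self.n_wheeze / self.n_respiration if self.n_respiration else 0.0

    @property
    def wheeze_rate_defined(self) -> bool:
        return self.n_respiration > 0

    def as_dict(self) -> dict:
        return {
            "n_respiration": self.n_respiration,
            "n_normal": self.n_normal,
            "n_wheeze": self.n_wheeze,
            "wheeze_rate": self.wheeze_rate,
            "wheeze_rate_defined": self.wheeze_rate_defined,
            "events": [{"time_s": t, "class": c} for t, c in self.events],
            "pending": self.pending,
        }


def argmax_labels(probs: np.ndarray) -> np.ndarray:
    """Collapse (N, 3) probabilities to integer labels; ties go low."""
    probs = np.asarray(probs, dtype=np.float64)
    if probs.size == 0:
        return np.zeros(0, dtype=np.int64)
    if probs.ndim != 2 or probs.shape[1] != 3:
        raise ValueError(f"expected (N, 3) probabilities, got shape {probs.shape}")
    return probs.argmax(axis=1).astype(np.int64)


def find_label_peaks(labels: np.ndarray) -> list[Peak]:
    """Plateau-aware local maxima of a {0,1,2} label sequence.

    A peak is a maximal run of equal nonzero values strictly greater than
    both neighboring runs, with sequence boundaries counting as minus
    infinity (so boundary plateaus qualify). The peak sits at the run
    midpoint, lower-middle for even run lengths.
    """
    labels = np.asarray(labels, dtype=np.int64)
    if labels.size == 0:
        return []
    if not np.isin(labels, [0, 1, 2]).all():
        raise ValueError("labels must be in {0, 1, 2}")

    # run-length encode
    change = np.flatnonzero(np.diff(labels)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [len(labels)]])
    values = labels[starts]

    peaks: list[Peak] = []
    for r, (start, end, value) in enumerate(zip(starts, ends, values)):
        if value == 0:
            continue
        left = values[r - 1] if r > 0 else -np.inf
        right = values[r + 1] if r < len(values) - 1 else -np.inf
        if value > left and value > right:
            mid = (start + end - 1) // 2
            peaks.append(Peak(index=int(mid), height=int(value)))
    return peaks


def segment_breaths(peaks: list[Peak], gap_threshold: int = 100) -> list[BreathGroup]:
    """Group ordered peaks into breath cycles.

    A split happens between consecutive peaks whose index difference ``d``
    satisfies ``d >= gap_threshold``; the trailing group is always flushed.
    """
    if not peaks:
        return []
    groups: list[BreathGroup] = []
    current: list[Peak] = [peaks[0]]
    for prev, cur in zip(peaks, peaks[1:]):
        if cur.index - prev.index >= gap_threshold:
            groups.append(
                BreathGroup(tuple(current), current[0].index, current[-1].index)
            )
            current = [cur]
        else:
            current.append(cur)
    groups.append(BreathGroup(tuple(current), current[0].index, current[-1].index))
    return groups


def classify_group(group: BreathGroup) -> str:
    """``wheeze`` when the mean peak height exceeds 1, else ``normal``."""
    if not group.peaks:
        raise ValueError("cannot classify an empty breath group")
    return "wheeze" if group.avg_p > 1.0 else "normal"


def count_offline(probs: np.ndarray, params: CountingParams = CountingParams()) -> CountReport:
    """Offline counter over a whole recording's probability sequence."""
    labels = argmax_labels(probs)
    peaks = find_label_peaks(labels)
    groups = segment_breaths(peaks, params.gap_threshold)
    n_wheeze = 0
    n_normal = 0
    events: list[tuple[float, str]] = []
    for group in groups:
        cls = classify_group(group)
        if cls == "wheeze":
            n_wheeze += 1
        else:
            n_normal += 1
        events.append((group.start_idx * params.hop_s, cls))
    return CountReport(
        n_respiration=n_wheeze + n_normal,
        n_normal=n_normal,
        n_wheeze=n_wheeze,
        events=tuple(events),
    )


@dataclass
class StreamState:
    """Mutable state of the streaming counter.

    ``wheeze_toggle``/``wheeze_score``/``break_score`` implement the
    published wheeze state machine. The normal-breath tracker
    (``normal_armed``/``normal_score``/``normal_break_score``) is a
    documented extension so streaming reports can carry full breath totals;
    arming the wheeze toggle absorbs a pending normal breath.
    """

    wheeze_toggle: bool = False
    wheeze_score: int = 0
    break_score: int = 0
    segments_seen: int = 0
    n_wheeze: int = 0
    n_normal: int = 0
    events: list[tuple[float, str]] = field(default_factory=list)
    normal_armed: bool = False
    normal_score: int = 0
    normal_break_score: int = 0
    normal_start_idx: int = 0
    wheeze_start_idx: int = 0


def stream_init() -> StreamState:
    """Fresh streaming state: toggle off, all scores and counts zero."""
    return StreamState()


def stream_update(
    state: StreamState,
    probs_chunk: np.ndarray,
    params: CountingParams = CountingParams(),
) -> tuple[StreamState, list[tuple[float, str]]]:
    """Feed one chunk of (N, 3) probabilities through the state machine.

    Mutates and returns ``state`` along with events emitted during this
    chunk. Scores and the toggle persist across chunk boundaries, so the
    result is independent of how the sequence is chunked.
    """
    probs_chunk = np.asarray(probs_chunk, dtype=np.float64)
    if probs_chunk.size and (probs_chunk.ndim != 2 or probs_chunk.shape[1] != 3):
        raise ValueError(f"expected (N, 3) chunk, got shape {probs_chunk.shape}")
    emitted: list[tuple[float, str]] = []
    thr = params.prob_threshold
    for row in probs_chunk.reshape(-1, 3):
        idx = state.segments_seen
        label = int(np.argmax(row))
        wheeze_hit = label == 2 and row[2] >= thr
        break_hit = label == 0 and row[0] >= thr
        normal_hit = label == 1 and row[1] >= thr

        if not state.wheeze_toggle:
            state.wheeze_score = state.wheeze_score + 1 if wheeze_hit else 0
            if state.wheeze_score == 1:
                state.wheeze_start_idx = idx
            if state.wheeze_score >= params.run_length:
                state.wheeze_toggle = True
                state.wheeze_score = 0
                state.break_score = 0
                # the wheezing breath absorbs any normal breath in progress
                state.normal_armed = False
                state.normal_score = 0
        else:
            state.break_score = state.break_score + 1 if break_hit else 0
            if state.break_score >= params.run_length:
                state.wheeze_toggle = False
                state.break_score = 0
                state.n_wheeze += 1
                event = (state.wheeze_start_idx * params.hop_s, "wheeze")
                state.events.append(event)
                emitted.append(event)

        # normal-breath tracker (extension; see class docstring)
        if not state.wheeze_toggle:
            if not state.normal_armed:
                state.normal_score = state.normal_score + 1 if normal_hit else 0
                if state.normal_score == 1:
                    state.normal_start_idx = idx
                if state.normal_score >= params.run_length:
                    state.normal_armed = True
                    state.normal_score = 0
                    state.normal_break_score = 0
            else:
                state.normal_break_score = (
                    state.normal_break_score + 1 if break_hit else 0
                )
                if state.normal_break_score >= params.run_length:
                    state.normal_armed = False
                    state.normal_break_score = 0
                    state.n_normal += 1
                    event = (state.normal_start_idx * params.hop_s, "normal")
                    state.events.append(event)
                    emitted.append(event)

        state.segments_seen += 1
    return state, emitted


def stream_report(state: StreamState) -> CountReport:
    """Snapshot of the running counts; an armed toggle is flagged pending."""
    return CountReport(
        n_respiration=state.n_wheeze + state.n_normal,
        n_normal=state.n_normal,
        n_wheeze=state.n_wheeze,
        events=tuple(state.events),
        pending=state.wheeze_toggle or state.normal_armed,
    )


def one_hot_probs(labels: np.ndarray) -> np.ndarray:
    """Oracle probabilities: 1 on the labeled class, 0 elsewhere."""
    labels = np.asarray(labels, dtype=np.int64)
    probs = np.zeros((len(labels), 3))
    probs[np.arange(len(labels)), labels] = 1.0
    return probs
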