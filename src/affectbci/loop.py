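"""Closed-loop orchestration: calibration schedule and rest/action trials.

The calibration schedule presents three classes of generated music —
sad (valence 0, arousal 0), neutral (0.5, 0.5), happy (1, 1) — twice for
20 s each in a pseudo-random order with no immediate class repeats, every
excerpt followed by a 10-s silent idle period (180 s total).

The online protocol is a sequence of rest/action trials.  A trial is
15 s of rest with no music, during which the decoder score is logged in
the background; the mean rest score assigns the task (mean < 0.5 → drive
the music toward happy, otherwise toward sad), a 2-s cue gap follows, and
then a 30-s action period in which every 0.5-s score update s sets the
music engine's inputs to valence = arousal = s.

The session runner operates on simulated time over a sample source (for
example :class:`affectbci.synth.Responder`); an optional engine callback
receives the parameter updates so the feedback stream can be rendered to
MIDI afterwards.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .decoder import AffectModel, Score
from .music import AffectPoint, Trajectory, generate_sequence, MusicSequence

__all__ = [
    "CLASS_AFFECT",
    "StimulusSchedule",
    "TrialRecord",
    "SessionRecord",
    "FeedbackRecorder",
    "build_calibration_schedule",
    "assign_task",
    "run_trial",
    "run_session",
    "REST_S",
    "CUE_S",
    "ACTION_S",
]

#: Affect coordinates of the three calibration stimulus classes.
CLASS_AFFECT = {
    "sad": AffectPoint(0.0, 0.0),
    "neutral": AffectPoint(0.5, 0.5),
    "happy": AffectPoint(1.0, 1.0),
}

EXCERPT_S = 20.0
IDLE_S = 10.0

REST_S = 15.0
CUE_S = 2.0
ACTION_S = 30.0
TRIAL_S = REST_S + CUE_S + ACTION_S  # 47 s

LEAD_IN_S = 4.0  # one analysis window of pre-roll before the first trial


@dataclass(frozen=True)
class StimulusSchedule:
    """Ordered calibration stimulus plan.

    Each entry is (label, affect-or-None, duration s).  Music classes each
    appear exactly twice at 20 s, consecutive excerpts differ in class,
    and every excerpt is followed by a 10-s idle period.
    """

    entries: tuple[tuple[str, AffectPoint | None, float], ...]

    def __post_init__(self) -> None:
        music = [e for e in self.entries if e[0] in CLASS_AFFECT]
        counts = {c: 0 for c in CLASS_AFFECT}
        for label, _, dur in music:
            counts[label] += 1
            if dur != EXCERPT_S:
                raise ValueError("music excerpts must last 20 s")
        if any(c != 2 for c in counts.values()):
            raise ValueError("each music class must appear exactly twice")
        for a, b in zip(music, music[1:]):
            if a[0] == b[0]:
                raise ValueError("consecutive excerpts share a class")
        seq = [e[0] for e in self.entries]
        for i, label in enumerate(seq):
            if label in CLASS_AFFECT:
                if i + 1 >= len(seq) or seq[i + 1] != "idle":
                    raise ValueError("every excerpt must be followed by idle")

    @property
    def total_duration(self) -> float:
        return sum(dur for _, _, dur in self.entries)

    def to_events(self) -> list[tuple[float, float, str]]:
        """(onset, duration, label) triples in schedule order."""
        events = []
        t = 0.0
        for label, _, dur in self.entries:
            events.append((t, dur, label))
            t += dur
        return events

    def to_trajectory_segments(self) -> list[tuple[float, float, AffectPoint]]:
        """(start, duration, affect) of the music excerpts only."""
        out = []
        t = 0.0
        for label, affect, dur in self.entries:
            if affect is not None:
                out.append((t, dur, affect))
            t += dur
        return out


def build_calibration_schedule(seed: int) -> StimulusSchedule:
    """Pseudo-randomized calibration schedule: 3 classes x 2 excerpts.

    Orders the six 20-s excerpts so that no two consecutive excerpts share
    a class, then appends a 10-s idle period after every excerpt (six idle
    periods → 120 idle observations downstream); 180 s total.
    """
    rng = np.random.default_rng(seed)
    pool = ["sad", "sad", "neutral", "neutral", "happy", "happy"]
    while True:
        order = list(rng.permutation(pool))
        if all(a != b for a, b in zip(order, order[1:])):
            break
    entries: list[tuple[str, AffectPoint | None, float]] = []
    for label in order:
        entries.append((label, CLASS_AFFECT[label], EXCERPT_S))
        entries.append(("idle", None, IDLE_S))
    return StimulusSchedule(entries=tuple(entries))


def assign_task(rest_scores: Sequence[Score | float]) -> str:
    """Task from the mean resting score: < 0.5 → ``to_happy`` (drive the
    music toward happy), >= 0.5 → ``to_sad``."""
    values = [s.value if isinstance(s, Score) else float(s) for s in rest_scores]
    if len(values) == 0:
        raise ValueError("empty rest-score sequence")
    return "to_happy" if float(np.mean(values)) < 0.5 else "to_sad"


@dataclass
class TrialRecord:
    """One rest/action trial: score traces, task, and period features."""

    index: int
    task: str
    rest_scores: list[Score]
    action_scores: list[Score]
    rest_mean: float
    action_mean: float
    engine_updates: list[tuple[float, float]] = field(default_factory=list)
    segments: dict[str, np.ndarray] = field(default_factory=dict)
    start_time: float = 0.0
    valid: bool = True


@dataclass
class SessionRecord:
    """A full online session: trials, the model used, optional mood items."""

    participant: str
    trials: list[TrialRecord]
    model: AffectModel
    mood_ratings: list[int] | None = None
    seed: int | None = None

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def trials_of(self, task: str) -> list[TrialRecord]:
        return [t for t in self.trials if t.task == task and t.valid]


class FeedbackRecorder:
    """Collects engine parameter updates; can render the feedback stream.

    During each action period the engine input is valence = arousal =
    latest score; rest and cue periods are silent.
    """

    def __init__(self) -> None:
        self.updates: list[tuple[float, float]] = []

    def update(self, time: float, score_value: float) -> None:
        self.updates.append((time, score_value))

    def render(self, seed: int, tail_s: float = 0.5) -> MusicSequence:
        if not self.updates:
            raise ValueError("no engine updates recorded")
        t0 = self.updates[0][0]
        points = [(t - t0, s, s) for t, s in self.updates]
        if points[0][0] != 0.0:
            points.insert(0, (0.0, points[0][1], points[0][2]))
        traj = Trajectory.from_breakpoints(points)
        total = self.updates[-1][0] - t0 + tail_s
        return generate_sequence(traj, total, seed)


class _SessionState:
    """Rolling sample buffer plus simulated-time bookkeeping."""

    def __init__(self, model: AffectModel, source, capacity_s: float):
        if tuple(getattr(source, "channel_names", model.channel_names)) != (
            tuple(model.channel_names)
        ):
            raise ValueError("source montage does not match the model")
        self.model = model
        self.source = source
        self.fs = model.fs
        self.block = int(round(model.step_s * self.fs))
        self.win = int(round(model.window_s * self.fs))
        n = int(round(capacity_s * self.fs)) + self.block
        self.buf = np.zeros((len(model.channel_names), n))
        self.pos = 0  # samples written so far

    @property
    def time(self) -> float:
        return self.pos / self.fs

    def advance(self, phase: str, task: str | None) -> bool:
        """Pull one 0.5-s block from the source; False on exhaustion."""
        try:
            block = self.source.next_block(self.block, phase, task)
        except StopIteration:
            return False
        if block is None:
            return False
        block = np.asarray(block, dtype=float)
        if block.shape != (self.buf.shape[0], self.block):
            raise ValueError("source returned a block of the wrong shape")
        self.buf[:, self.pos : self.pos + self.block] = block
        self.pos += self.block
        return True

    def latest_score(self) -> Score:
        data = self.buf[:, self.pos - self.win : self.pos]
        return self.model.score_window(data, time=self.time)

    def window_features(self, start: float) -> np.ndarray:
        i0 = int(round(start * self.fs))
        from .decoder import _segment_features

        return _segment_features(
            self.buf[:, i0 : i0 + self.win],
            self.fs,
            self.model.band_defs,
            self.model.filter_order,
            self.model.ripple_db,
        )


def _run_one_trial(
    state: _SessionState, index: int, engine=None
) -> TrialRecord:
    model = state.model
    t0 = state.time
    n_rest = int(round(REST_S / model.step_s))
    n_cue = int(round(CUE_S / model.step_s))
    n_action = int(round(ACTION_S / model.step_s))

    rest_scores: list[Score] = []
    for _ in range(n_rest):
        if not state.advance("rest", None):
            return _invalid_trial(index, t0, rest_scores, [])
        rest_scores.append(state.latest_score())
    task = assign_task(rest_scores)

    for _ in range(n_cue):
        if not state.advance("cue", task):
            return _invalid_trial(index, t0, rest_scores, [], task)

    action_scores: list[Score] = []
    updates: list[tuple[float, float]] = []
    for _ in range(n_action):
        if not state.advance("action", task):
            return _invalid_trial(
                index, t0, rest_scores, action_scores, task, updates
            )
        s = state.latest_score()
        action_scores.append(s)
        updates.append((s.time, s.value))
        if engine is not None:
            engine.update(s.time, s.value)

    return TrialRecord(
        index=index,
        task=task,
        rest_scores=rest_scores,
        action_scores=action_scores,
        rest_mean=float(np.mean([s.value for s in rest_scores])),
        action_mean=float(np.mean([s.value for s in action_scores])),
        engine_updates=updates,
        start_time=t0,
    )


def _invalid_trial(
    index, t0, rest_scores, action_scores, task="", updates=None
) -> TrialRecord:
    warnings.warn(f"sample source exhausted during trial {index}")
    return TrialRecord(
        index=index,
        task=task,
        rest_scores=rest_scores,
        action_scores=action_scores,
        rest_mean=float(np.mean([s.value for s in rest_scores]))
        if rest_scores
        else float("nan"),
        action_mean=float(np.mean([s.value for s in action_scores]))
        if action_scores
        else float("nan"),
        engine_updates=updates or [],
        start_time=t0,
        valid=False,
    )


def _attach_segments(state: _SessionState, trial: TrialRecord) -> None:
    """Per-period feature observations, windows labeled by start time."""
    if not trial.valid:
        return
    model = state.model
    rest_start = trial.start_time
    action_start = trial.start_time + REST_S + CUE_S
    for period, start, dur in (
        ("rest", rest_start, REST_S),
        ("action", action_start, ACTION_S),
    ):
        n = int(round(dur / model.step_s))
        feats = [
            state.window_features(start + k * model.step_s) for k in range(n)
        ]
        trial.segments[period] = np.asarray(feats)


def run_trial(model: AffectModel, eeg_source, engine=None) -> TrialRecord:
    """Run a single standalone rest/action trial on a sample source.

    Prepends one analysis window of lead-in (so the first rest score has a
    full 4-s history, reaching back into whatever precedes the trial) and
    one window of tail (so the last action windows are full length), then
    logs scores, assigns the task from the mean rest score, and records
    the 60 engine parameter updates of the action period.
    """
    state = _SessionState(model, eeg_source, LEAD_IN_S + TRIAL_S + LEAD_IN_S)
    for _ in range(int(round(LEAD_IN_S / model.step_s))):
        if not state.advance("lead_in", None):
            raise ValueError("sample source exhausted during lead-in")
    trial = _run_one_trial(state, 0, engine=engine)
    for _ in range(int(round(LEAD_IN_S / model.step_s))):
        if not state.advance("tail", None):
            break
    _attach_segments(state, trial)
    return trial


def run_session(
    model: AffectModel,
    eeg_source,
    n_trials: int,
    seed: int | None = None,
    participant: str = "sim",
    engine=None,
    mood_ratings: list[int] | None = None,
) -> SessionRecord:
    """Run ``n_trials`` consecutive trials with full logging.

    Deterministic for a deterministic source: the score traces, tasks and
    per-period feature observations depend only on the model and the
    source's own seeding.  ``seed`` is recorded for provenance (and used
    by callers that render the feedback stream).
    """
    if n_trials < 0:
        raise ValueError("n_trials must be >= 0")
    record = SessionRecord(
        participant=participant,
        trials=[],
        model=model,
        mood_ratings=mood_ratings,
        seed=seed,
    )
    if n_trials == 0:
        return record
    total = LEAD_IN_S + n_trials * TRIAL_S + LEAD_IN_S
    state = _SessionState(model, eeg_source, total)
    for _ in range(int(round(LEAD_IN_S / model.step_s))):
        if not state.advance("lead_in", None):
            raise ValueError("sample source exhausted during lead-in")
    for i in range(n_trials):
        trial = _run_one_trial(state, i, engine=engine)
        record.trials.append(trial)
        if not trial.valid:
            break
    for _ in range(int(round(LEAD_IN_S / model.step_s))):
        if not state.advance("tail", None):
            break
    for trial in record.trials:
        _attach_segments(state, trial)
    return record
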