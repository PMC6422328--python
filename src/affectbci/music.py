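"""Rule-based affective music generation.

The generator maps a point in the two-dimensional valence/arousal space
onto five music-structural parameters and emits a stream of timed MIDI
note events.  The musical surface is a small chamber texture in C major
pitch material: a probabilistic eighth-note piano voice over sustained
cello/bass roots, harmonized by a I-IV-V-I progression in one of the seven
church modes.  Arousal drives tempo, rhythmic density and loudness;
valence drives pitch register and the harmonic mode, the modes being
ordered from positive to negative perceived valence
(Lydian, Ionian, Mixolydian, Dorian, Aeolian, Phrygian, Locrian).

All randomness flows through a single seeded generator, so a trajectory
plus a seed fully determines the note stream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterator, Sequence

import numpy as np

from .midi import NoteEvent

__all__ = [
    "AffectPoint",
    "MusicParams",
    "Chord",
    "ChordProgression",
    "Trajectory",
    "MusicSequence",
    "MODE_NAMES",
    "affect_to_params",
    "mode_to_progression",
    "sample_bar",
    "generate_sequence",
]

#: Church modes ordered from positive (index 1) to negative (index 7) valence.
MODE_NAMES = (
    "Lydian",
    "Ionian",
    "Mixolydian",
    "Dorian",
    "Aeolian",
    "Phrygian",
    "Locrian",
)

# Tonic pitch class of each mode when the pitch material is C major:
# the mode is the diatonic rotation of C major starting on that degree.
_MODE_TONIC_PC = {
    "Lydian": 5,      # F
    "Ionian": 0,      # C
    "Mixolydian": 7,  # G
    "Dorian": 2,      # D
    "Aeolian": 9,     # A
    "Phrygian": 4,    # E
    "Locrian": 11,    # B
}

_C_MAJOR_PCS = (0, 2, 4, 5, 7, 9, 11)

_PC_NAMES = {0: "C", 2: "D", 4: "E", 5: "F", 7: "G", 9: "A", 11: "B"}

#: MIDI note numbers of the three register anchors.
REGISTER_BASES = {"C3": 48, "C4": 60, "C5": 72}

SLOTS_PER_BAR = 8  # eighth-note grid slots per bar
BARS_PER_PROGRESSION = 4

VELOCITY_FLOOR = 50


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def _clamp(x: float, lo: float, hi: float) -> float:
    return min(max(x, lo), hi)


@dataclass(frozen=True)
class AffectPoint:
    """A point in valence/arousal space; coordinates are clamped to [0, 1]."""

    valence: float
    arousal: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "valence", _clamp(float(self.valence), 0.0, 1.0))
        object.__setattr__(self, "arousal", _clamp(float(self.arousal), 0.0, 1.0))


@dataclass(frozen=True)
class MusicParams:
    """The five music-structural parameters controlling generation.

    note_dur
        Eighth-note duration in seconds (tempo), in [0.15, 0.3].
    p_note
        Probability that an eighth-note grid slot sounds (rhythmic roughness).
    vel_lo, vel_hi
        Inclusive MIDI-velocity bounds for piano notes (relative loudness).
    register_probs
        Probability triple over the (C3, C4, C5) registers (overall pitch).
    mode_index
        Harmonic mode on the 7-step valence-ordered scale, 1 = Lydian.
    """

    note_dur: float
    p_note: float
    vel_lo: int
    vel_hi: int
    register_probs: tuple[float, float, float]
    mode_index: int

    def __post_init__(self) -> None:
        if not (0.15 - 1e-9 <= self.note_dur <= 0.3 + 1e-9):
            raise ValueError(f"note_dur {self.note_dur} outside [0.15, 0.3]")
        if not (0.0 <= self.p_note <= 1.0):
            raise ValueError(f"p_note {self.p_note} outside [0, 1]")
        if not (VELOCITY_FLOOR <= self.vel_lo <= self.vel_hi <= 100):
            raise ValueError(
                f"velocity bounds ({self.vel_lo}, {self.vel_hi}) invalid"
            )
        if abs(sum(self.register_probs) - 1.0) > 1e-9:
            raise ValueError("register_probs must sum to 1")
        if self.mode_index not in range(1, 8):
            raise ValueError(f"mode_index {self.mode_index} outside 1..7")

    @property
    def mode_name(self) -> str:
        return MODE_NAMES[self.mode_index - 1]


@dataclass(frozen=True)
class Chord:
    """A diatonic triad: root pitch class, quality, and member pitch classes."""

    root_pc: int
    quality: str  # "maj" | "min" | "dim"
    pitch_classes: tuple[int, int, int]

    @property
    def name(self) -> str:
        return f"{_PC_NAMES[self.root_pc]}_{self.quality}"


@dataclass(frozen=True)
class ChordProgression:
    """Four-bar I-IV-V-I progression in one church mode."""

    mode_name: str
    chords: tuple[Chord, Chord, Chord, Chord]

    def __post_init__(self) -> None:
        if len(self.chords) != 4:
            raise ValueError("progression must contain exactly 4 chords")
        if self.chords[0] != self.chords[3]:
            raise ValueError("progression must return to the tonic chord")

    @property
    def scale_pcs(self) -> tuple[int, ...]:
        return mode_scale(MODE_NAMES.index(self.mode_name) + 1)


@dataclass(frozen=True)
class Trajectory:
    """Piecewise-constant affect trajectory: (time, AffectPoint) breakpoints.

    Times must be strictly increasing and start at 0; the affect value is
    held between breakpoints (zero-order hold), so continuous ramps are
    expressed as dense breakpoints.
    """

    points: tuple[tuple[float, AffectPoint], ...]

    def __post_init__(self) -> None:
        if len(self.points) == 0:
            raise ValueError("trajectory must contain at least one breakpoint")
        times = [t for t, _ in self.points]
        if times[0] != 0.0:
            raise ValueError("trajectory must start at time 0")
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("trajectory times must be strictly increasing")

    @classmethod
    def constant(cls, point: AffectPoint) -> "Trajectory":
        return cls(((0.0, point),))

    @classmethod
    def from_breakpoints(
        cls, breakpoints: Sequence[tuple[float, float, float]]
    ) -> "Trajectory":
        """Build from (time, valence, arousal) triples."""
        return cls(
            tuple((float(t), AffectPoint(v, a)) for t, v, a in breakpoints)
        )

    def at(self, t: float) -> AffectPoint:
        """Affect point active at time ``t`` (zero-order hold)."""
        current = self.points[0][1]
        for bt, p in self.points:
            if bt <= t + 1e-12:
                current = p
            else:
                break
        return current


def affect_to_params(
    p: AffectPoint, pitch_rule: str = "monotone"
) -> MusicParams:
    """Map a valence/arousal point onto the five music parameters.

    Tempo, rhythm and loudness are driven by arousal::

        note_dur = 0.3 - 0.15 * arousal          (s per eighth note)
        p_note   = arousal
        velocity ~ uniform integer {50, ..., round(40 * arousal + 60)}

    Register and harmonic mode are driven by valence.  The default
    ``"monotone"`` pitch rule moves all register mass from C3 (valence 0)
    through C4 to C5 (valence 1); the ``"as-printed"`` variant keeps the
    original piecewise form in which low valence concentrates mass on C4.
    The mode index discretizes ``7 - 6 * valence`` (half-up) onto the
    valence-ordered scale, so valence 1 selects Lydian and valence 0
    Locrian.
    """
    val, aro = p.valence, p.arousal
    note_dur = 0.3 - aro * 0.15
    p_note = aro
    vel_hi = _round_half_up(40.0 * aro + 60.0)

    if pitch_rule == "monotone":
        if val < 0.5:
            p3 = 1.0 - 2.0 * val
            p5 = 0.0
        else:
            p3 = 0.0
            p5 = 2.0 * (val - 0.5)
    elif pitch_rule == "as-printed":
        if val < 0.5:
            p3 = 2.0 * val
            p5 = 0.0
        else:
            p3 = 0.0
            p5 = 2.0 * (val - 0.5)
    else:
        raise ValueError(f"unknown pitch_rule {pitch_rule!r}")
    p4 = 1.0 - p3 - p5

    mode_index = min(max(_round_half_up(7.0 - 6.0 * val), 1), 7)

    return MusicParams(
        note_dur=note_dur,
        p_note=p_note,
        vel_lo=VELOCITY_FLOOR,
        vel_hi=vel_hi,
        register_probs=(p3, p4, p5),
        mode_index=mode_index,
    )


def mode_scale(mode_index: int) -> tuple[int, ...]:
    """Seven scale pitch classes of the mode, ascending from its tonic."""
    if mode_index not in range(1, 8):
        raise ValueError(f"mode_index {mode_index} outside 1..7")
    tonic = _MODE_TONIC_PC[MODE_NAMES[mode_index - 1]]
    start = _C_MAJOR_PCS.index(tonic)
    return tuple(_C_MAJOR_PCS[(start + i) % 7] for i in range(7))


def _triad(scale: tuple[int, ...], degree: int) -> Chord:
    """Diatonic triad on a 0-based scale degree (stacked thirds)."""
    pcs = tuple(scale[(degree + 2 * i) % 7] for i in range(3))
    third = (pcs[1] - pcs[0]) % 12
    fifth = (pcs[2] - pcs[0]) % 12
    if fifth == 6:
        quality = "dim"
    elif third == 4:
        quality = "maj"
    else:
        quality = "min"
    return Chord(root_pc=pcs[0], quality=quality, pitch_classes=pcs)


def mode_to_progression(mode_index: int) -> ChordProgression:
    """I-IV-V-I triads of the selected church mode over C-major material.

    The middle chords are the triads on the 4th and 5th scale degrees.
    When the degree-4 (subdominant) triad is diminished — which happens
    only in Lydian, whose raised fourth degree carries a leading-tone
    sonority — the diminished chord is placed after the dominant so that
    it resolves directly to the tonic (Lydian: F_maj C_maj B_dim F_maj).
    """
    scale = mode_scale(mode_index)
    tonic = _triad(scale, 0)
    sub = _triad(scale, 3)
    dom = _triad(scale, 4)
    if sub.quality == "dim":
        middle = (dom, sub)
    else:
        middle = (sub, dom)
    return ChordProgression(
        mode_name=MODE_NAMES[mode_index - 1],
        chords=(tonic, middle[0], middle[1], tonic),
    )


_REGISTER_KEYS = ("C3", "C4", "C5")


def _sample_slots(
    params_at: Callable[[float], MusicParams],
    chord: Chord,
    bar_start: float,
    rng: np.random.Generator,
) -> tuple[list[NoteEvent], float, list[tuple[float, float]]]:
    """Sample one bar slot by slot; parameters may change at slot boundaries.

    Returns the events, the bar's total duration, and the (time, note_dur)
    pairs at which the tempo actually changed.
    """
    events: list[NoteEvent] = []
    tempo_changes: list[tuple[float, float]] = []
    t = bar_start
    last_dur = None
    for _ in range(SLOTS_PER_BAR):
        params = params_at(t)
        if params.note_dur != last_dur:
            tempo_changes.append((t, params.note_dur))
            last_dur = params.note_dur
        if rng.random() < params.p_note:
            reg = _REGISTER_KEYS[
                rng.choice(3, p=np.asarray(params.register_probs))
            ]
            pc = chord.pitch_classes[rng.integers(0, 3)]
            pitch = REGISTER_BASES[reg] + pc
            velocity = int(rng.integers(params.vel_lo, params.vel_hi + 1))
            events.append(
                NoteEvent(
                    onset=t,
                    duration=params.note_dur,
                    pitch=pitch,
                    velocity=velocity,
                    voice="piano",
                )
            )
        t += params.note_dur
    bar_dur = t - bar_start
    # sustained harmonic support: chord root on cello, doubled an octave
    # below on bass, held for the whole bar
    support_vel = _round_half_up(
        (params_at(bar_start).vel_lo + params_at(bar_start).vel_hi) / 2.0
    )
    root_pitch = REGISTER_BASES["C3"] + chord.root_pc
    events.append(
        NoteEvent(
            onset=bar_start,
            duration=bar_dur,
            pitch=root_pitch,
            velocity=support_vel,
            voice="cello",
        )
    )
    events.append(
        NoteEvent(
            onset=bar_start,
            duration=bar_dur,
            pitch=root_pitch - 12,
            velocity=support_vel,
            voice="bass",
        )
    )
    return events, bar_dur, tempo_changes


def sample_bar(
    params: MusicParams,
    chord: Chord,
    bar_start: float,
    rng: np.random.Generator,
) -> list[NoteEvent]:
    """Sample one 8-slot bar under fixed parameters.

    Each eighth-note slot sounds independently with probability ``p_note``;
    a sounded piano note draws its register from ``register_probs``, its
    pitch uniformly from the chord tones placed in that register's octave,
    and its velocity uniformly (integer, inclusive) from the loudness
    range.  The chord root is sustained for the bar on cello and doubled
    an octave lower on bass.
    """
    events, _, _ = _sample_slots(lambda _t: params, chord, bar_start, rng)
    return events


@dataclass
class MusicSequence:
    """A generated note stream plus its tempo map.

    Behaves as a sequence of :class:`NoteEvent`; ``tempo_map`` holds
    (time_s, eighth-note duration_s) change points for MIDI rendering.
    """

    events: list[NoteEvent] = field(default_factory=list)
    tempo_map: list[tuple[float, float]] = field(default_factory=list)

    def __iter__(self) -> Iterator[NoteEvent]:
        return iter(self.events)

    def __len__(self) -> int:
        return len(self.events)

    def __getitem__(self, i):
        return self.events[i]


def generate_sequence(
    traj: Trajectory,
    total_dur: float,
    seed: int | np.random.Generator,
    pitch_rule: str = "monotone",
) -> MusicSequence:
    """Generate a continuous note stream following an affect trajectory.

    Bars are generated back to back; the chord progression advances one
    chord per bar and cycles every four bars.  Tempo, rhythm, loudness and
    register parameters update at the next eighth-note boundary after a
    trajectory breakpoint; mode (and hence chord) changes are quantized to
    bar boundaries, so transitions are seamless — no note is cut mid-way.
    Identical (trajectory, seed) pairs produce identical streams.
    """
    if total_dur <= 0:
        raise ValueError("total_dur must be positive")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    params_at = lambda t: affect_to_params(traj.at(t), pitch_rule=pitch_rule)

    seq = MusicSequence()
    t = 0.0
    bar_index = 0
    last_dur = None
    while t < total_dur - 1e-9:
        mode_index = params_at(t).mode_index  # mode fixed at the bar boundary
        progression = mode_to_progression(mode_index)
        chord = progression.chords[bar_index % BARS_PER_PROGRESSION]
        events, bar_dur, tempo_changes = _sample_slots(
            params_at, chord, t, rng
        )
        seq.events.extend(events)
        for ct, dur in tempo_changes:
            if dur != last_dur:
                seq.tempo_map.append((ct, dur))
                last_dur = dur
        t += bar_dur
        bar_index += 1
    seq.events.sort(key=lambda e: (e.onset, e.voice, e.pitch))
    return seq
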