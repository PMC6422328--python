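"""Minimal Standard MIDI File (format 1) writing and reading.

Covers exactly what the music engine needs: one tempo/meta track plus one
track per voice (piano, cello, bass), note-on/note-off pairs, track-name
and set-tempo meta events.  Time is stored in ticks at a fixed resolution
of 960 ticks per quarter note; the quarter-note duration is twice the
engine's eighth-note duration, so tempo meta events follow the tempo
parameter of the generated stream.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass
from typing import Iterable, Sequence

__all__ = ["NoteEvent", "VOICES", "render_midi", "read_midi"]

VOICES = ("piano", "cello", "bass")

DIVISION = 960  # ticks per quarter note
DEFAULT_NOTE_DUR = 0.25  # eighth-note seconds when no tempo map is given


@dataclass(frozen=True)
class NoteEvent:
    """One timed note: onset/duration in seconds, MIDI pitch and velocity."""

    onset: float
    duration: float
    pitch: int
    velocity: int
    voice: str

    def __post_init__(self) -> None:
        if self.onset < 0:
            raise ValueError("onset must be >= 0")
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        if not (0 <= self.pitch <= 127):
            raise ValueError("pitch outside MIDI range")
        if not (1 <= self.velocity <= 127):
            raise ValueError("velocity outside 1..127")
        if self.voice not in VOICES:
            raise ValueError(f"unknown voice {self.voice!r}")


def _encode_varint(value: int) -> bytes:
    if value < 0:
        raise ValueError("negative delta time")
    out = [value & 0x7F]
    value >>= 7
    while value:
        out.append(0x80 | (value & 0x7F))
        value >>= 7
    return bytes(reversed(out))


class _TempoMap:
    """Piecewise-constant tempo: seconds <-> ticks, both directions exact
    with respect to the integer microsecond tempi actually stored."""

    def __init__(self, changes: Sequence[tuple[float, float]]):
        # changes: (time_s, eighth-note duration_s), first at t=0
        if not changes or changes[0][0] != 0.0:
            changes = [(0.0, DEFAULT_NOTE_DUR)] + [
                c for c in changes if c[0] > 0.0
            ]
        self.times: list[float] = []
        self.tempi_us: list[int] = []
        self.tick_offsets: list[float] = []
        acc = 0.0
        prev_t = 0.0
        prev_tempo = None
        for t, note_dur in changes:
            tempo_us = int(round(2_000_000.0 * note_dur))
            if prev_tempo is not None:
                acc += (t - prev_t) * 1e6 / prev_tempo * DIVISION
            if tempo_us == prev_tempo:
                continue
            self.times.append(t)
            self.tempi_us.append(tempo_us)
            self.tick_offsets.append(acc)
            prev_t, prev_tempo = t, tempo_us
        # keep prev markers for appended queries
        self._last_t = prev_t

    def to_ticks(self, t: float) -> int:
        i = 0
        for j, tj in enumerate(self.times):
            if tj <= t + 1e-12:
                i = j
            else:
                break
        ticks = self.tick_offsets[i] + (t - self.times[i]) * 1e6 / (
            self.tempi_us[i]
        ) * DIVISION
        return int(round(ticks))


class _TickClock:
    """Reader-side tempo map keyed on ticks."""

    def __init__(self, division: int = DIVISION) -> None:
        self.division = division
        self.tick_points: list[int] = [0]
        self.tempi_us: list[int] = [500_000]
        self.time_offsets: list[float] = [0.0]

    def add_tempo(self, tick: int, tempo_us: int) -> None:
        last_tick = self.tick_points[-1]
        last_time = self.time_offsets[-1]
        dt = (tick - last_tick) * self.tempi_us[-1] / (1e6 * self.division)
        if tick == 0 and len(self.tick_points) == 1:
            self.tempi_us[0] = tempo_us
            return
        self.tick_points.append(tick)
        self.tempi_us.append(tempo_us)
        self.time_offsets.append(last_time + dt)

    def to_seconds(self, tick: int) -> float:
        i = 0
        for j, tj in enumerate(self.tick_points):
            if tj <= tick:
                i = j
            else:
                break
        return self.time_offsets[i] + (tick - self.tick_points[i]) * (
            self.tempi_us[i]
        ) / (1e6 * self.division)


def _meta(delta: int, meta_type: int, data: bytes) -> bytes:
    return (
        _encode_varint(delta)
        + bytes([0xFF, meta_type])
        + _encode_varint(len(data))
        + data
    )


def _track_chunk(payload: bytes) -> bytes:
    return b"MTrk" + struct.pack(">I", len(payload)) + payload


def render_midi(
    events: Iterable[NoteEvent],
    path,
    tempo_map: Sequence[tuple[float, float]] | None = None,
) -> None:
    """Write events to a format-1 Standard MIDI File.

    One track per voice (plus a leading tempo/meta track); tempo meta
    events follow ``tempo_map`` — (time_s, eighth-note duration_s) change
    points — so the stored tempo is consistent with the generated
    note-duration parameter.  A :class:`~affectbci.music.MusicSequence`
    can be passed directly as ``events``; its own tempo map is used unless
    one is given explicitly.
    """
    if tempo_map is None:
        tempo_map = getattr(events, "tempo_map", None)
    event_list = list(events)
    if not event_list:
        raise ValueError("no events to render")
    tmap = _TempoMap(list(tempo_map) if tempo_map else [])

    chunks: list[bytes] = []

    # track 0: tempo map
    payload = b""
    prev_tick = 0
    for t, tempo_us in zip(tmap.times, tmap.tempi_us):
        tick = tmap.to_ticks(t)
        payload += _meta(
            tick - prev_tick, 0x51, struct.pack(">I", tempo_us)[1:]
        )
        prev_tick = tick
    payload += _meta(0, 0x2F, b"")
    chunks.append(_track_chunk(payload))

    # one track per voice, in canonical order; empty voices yield an
    # empty (name + end-of-track only) track
    for ch, voice in enumerate(VOICES):
        payload = _meta(0, 0x03, voice.encode("ascii"))
        msgs: list[tuple[int, int, bytes]] = []  # (tick, order, bytes)
        for ev in event_list:
            if ev.voice != voice:
                continue
            on_tick = tmap.to_ticks(ev.onset)
            off_tick = max(tmap.to_ticks(ev.onset + ev.duration), on_tick + 1)
            msgs.append(
                (on_tick, 1, bytes([0x90 | ch, ev.pitch, ev.velocity]))
            )
            msgs.append((off_tick, 0, bytes([0x80 | ch, ev.pitch, 0])))
        msgs.sort(key=lambda m: (m[0], m[1]))
        prev_tick = 0
        for tick, _, data in msgs:
            payload += _encode_varint(tick - prev_tick) + data
            prev_tick = tick
        payload += _meta(0, 0x2F, b"")
        chunks.append(_track_chunk(payload))

    header = b"MThd" + struct.pack(">IHHH", 6, 1, len(chunks), DIVISION)
    with open(path, "wb") as fh:
        fh.write(header)
        for c in chunks:
            fh.write(c)


def _read_varint(data: bytes, pos: int) -> tuple[int, int]:
    value = 0
    while True:
        byte = data[pos]
        pos += 1
        value = (value << 7) | (byte & 0x7F)
        if not byte & 0x80:
            return value, pos


def read_midi(path) -> list[NoteEvent]:
    """Parse a Standard MIDI File back into note events (seconds).

    Handles running status and skips events the writer never emits.  The
    voice is taken from each track's name meta event; note-on with
    velocity 0 counts as note-off.
    """
    with open(path, "rb") as fh:
        data = fh.read()
    if data[:4] != b"MThd":
        raise ValueError("not a Standard MIDI File")
    _, _fmt, ntracks, division = struct.unpack(">IHHH", data[4:14])
    pos = 14

    tracks: list[tuple[str | None, list[tuple[int, int, int, int]]]] = []
    clock = _TickClock(division)
    for _ in range(ntracks):
        if data[pos : pos + 4] != b"MTrk":
            raise ValueError("bad track chunk")
        (length,) = struct.unpack(">I", data[pos + 4 : pos + 8])
        body = data[pos + 8 : pos + 8 + length]
        pos += 8 + length

        name: str | None = None
        raw: list[tuple[int, int, int, int]] = []  # tick, status, d1, d2
        tick = 0
        p = 0
        running = 0
        while p < len(body):
            delta, p = _read_varint(body, p)
            tick += delta
            status = body[p]
            if status & 0x80:
                p += 1
            else:
                status = running
            if status == 0xFF:
                meta_type = body[p]
                p += 1
                mlen, p = _read_varint(body, p)
                payload = body[p : p + mlen]
                p += mlen
                if meta_type == 0x03:
                    name = payload.decode("ascii", errors="replace")
                elif meta_type == 0x51:
                    clock.add_tempo(
                        tick, int.from_bytes(payload, "big")
                    )
            elif status in (0xF0, 0xF7):
                slen, p = _read_varint(body, p)
                p += slen
            else:
                running = status
                kind = status & 0xF0
                n_data = 1 if kind in (0xC0, 0xD0) else 2
                d = body[p : p + n_data]
                p += n_data
                if kind in (0x90, 0x80):
                    raw.append((tick, kind, d[0], d[1]))
        tracks.append((name, raw))

    events: list[NoteEvent] = []
    for name, raw in tracks:
        voice = name if name in VOICES else None
        if voice is None:
            continue
        pending: dict[int, list[tuple[int, int]]] = {}
        for tick, kind, pitch, vel in raw:
            if kind == 0x90 and vel > 0:
                pending.setdefault(pitch, []).append((tick, vel))
            else:
                if pending.get(pitch):
                    on_tick, on_vel = pending[pitch].pop(0)
                    onset = clock.to_seconds(on_tick)
                    offset = clock.to_seconds(tick)
                    events.append(
                        NoteEvent(
                            onset=onset,
                            duration=max(offset - onset, 1e-6),
                            pitch=pitch,
                            velocity=on_vel,
                            voice=voice,
                        )
                    )
    events.sort(key=lambda e: (e.onset, e.voice, e.pitch))
    return events
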