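"""Note-event data model and I/O.

Monophonic melodies are represented as ordered sequences of note events
(integer MIDI pitch, onset in seconds, duration in seconds).  Two on-disk
formats are supported: Standard MIDI Files (format 0/1) and plain CSV note
tables with columns ``pitch,onset,duration``.  Validation is strict — a file
that violates the monophony or pitch-range invariants raises, it is never
silently clamped.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import pandas as pd

__all__ = [
    "NoteEvent",
    "NoteSequence",
    "Corpus",
    "read_midi",
    "write_midi",
    "read_notes_table",
    "write_notes_table",
]

PITCH_ALPHABET_SIZE = 128


@dataclass(frozen=True)
class NoteEvent:
    """A single monophonic note: MIDI pitch, onset and duration in seconds."""

    pitch: int
    onset: float
    duration: float

    def __post_init__(self) -> None:
        if not (0 <= int(self.pitch) <= 127):
            raise ValueError(f"pitch {self.pitch} outside MIDI range 0-127")
        if int(self.pitch) != self.pitch:
            raise ValueError(f"pitch must be integral, got {self.pitch}")
        if self.onset < 0:
            raise ValueError(f"onset {self.onset} must be >= 0")
        if self.duration <= 0:
            raise ValueError(f"duration {self.duration} must be > 0")


@dataclass
class NoteSequence:
    """An ordered, non-empty, monophonic sequence of notes for one composition."""

    notes: list[NoteEvent]
    composition_id: str = "untitled"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.notes:
            raise ValueError("NoteSequence must contain at least one note")
        onsets = [n.onset for n in self.notes]
        for a, b in zip(onsets, onsets[1:]):
            if b <= a:
                raise ValueError(
                    f"onsets must be strictly increasing (monophony): {a} -> {b}"
                )

    def __len__(self) -> int:
        return len(self.notes)

    def __iter__(self) -> Iterator[NoteEvent]:
        return iter(self.notes)

    @property
    def pitches(self) -> list[int]:
        return [n.pitch for n in self.notes]

    @property
    def onsets(self) -> list[float]:
        return [n.onset for n in self.notes]

    @property
    def durations(self) -> list[float]:
        return [n.duration for n in self.notes]


@dataclass
class Corpus:
    """A named collection of note sequences with unique composition ids."""

    sequences: list[NoteSequence]
    name: str = "corpus"

    def __post_init__(self) -> None:
        if not self.sequences:
            raise ValueError("Corpus must contain at least one sequence")
        ids = [s.composition_id for s in self.sequences]
        if len(set(ids)) != len(ids):
            raise ValueError("composition_ids must be unique within a corpus")

    def __len__(self) -> int:
        return len(self.sequences)

    def __iter__(self) -> Iterator[NoteSequence]:
        return iter(self.sequences)

    @property
    def n_notes(self) -> int:
        return sum(len(s) for s in self.sequences)


# ---------------------------------------------------------------------------
# CSV note tables
# ---------------------------------------------------------------------------

_TABLE_COLUMNS = ["pitch", "onset", "duration"]


def write_notes_table(seq: NoteSequence, path: str | Path) -> None:
    """Write a sequence as a comma-separated note table (header required)."""
    df = pd.DataFrame(
        {
            "pitch": seq.pitches,
            "onset": seq.onsets,
            "duration": seq.durations,
        }
    )
    df.to_csv(path, index=False)


def read_notes_table(path: str | Path, composition_id: str | None = None) -> NoteSequence:
    """Read a CSV note table with columns pitch, onset, duration."""
    df = pd.read_csv(path)
    missing = [c for c in _TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"note table {path} missing columns {missing}")
    notes = [
        NoteEvent(int(p), float(o), float(d))
        for p, o, d in zip(df["pitch"], df["onset"], df["duration"])
    ]
    cid = composition_id if composition_id is not None else Path(path).stem
    return NoteSequence(notes, composition_id=cid)


# ---------------------------------------------------------------------------
# Standard MIDI files (minimal format 0/1 codec)
# ---------------------------------------------------------------------------


def _read_varlen(data: bytes, i: int) -> tuple[int, int]:
    value = 0
    while True:
        byte = data[i]
        i += 1
        value = (value << 7) | (byte & 0x7F)
        if not byte & 0x80:
            return value, i


def _encode_varlen(value: int) -> bytes:
    out = [value & 0x7F]
    value >>= 7
    while value:
        out.append((value & 0x7F) | 0x80)
        value >>= 7
    return bytes(reversed(out))


def _parse_track(data: bytes) -> list[tuple[int, int, int, int]]:
    """Return (tick, kind, a, b) events; kind 0=note-off, 1=note-on, 2=tempo."""
    events = []
    tick = 0
    i = 0
    status = 0
    while i < len(data):
        delta, i = _read_varlen(data, i)
        tick += delta
        byte = data[i]
        if byte & 0x80:
            status = byte
            i += 1
        elif status == 0:
            raise ValueError("running status before any status byte")
        kind = status & 0xF0
        if status == 0xFF:  # meta event
            meta_type = data[i]
            length, j = _read_varlen(data, i + 1)
            payload = data[j : j + length]
            i = j + length
            if meta_type == 0x51:
                tempo = int.from_bytes(payload, "big")
                events.append((tick, 2, tempo, 0))
            if meta_type == 0x2F:
                break
        elif status in (0xF0, 0xF7):  # sysex: skip
            length, j = _read_varlen(data, i)
            i = j + length
        elif kind in (0x80, 0x90):
            pitch, vel = data[i], data[i + 1]
            i += 2
            if kind == 0x90 and vel > 0:
                events.append((tick, 1, pitch, vel))
            else:
                events.append((tick, 0, pitch, 0))
        elif kind in (0xA0, 0xB0, 0xE0):
            i += 2
        elif kind in (0xC0, 0xD0):
            i += 1
        else:
            raise ValueError(f"unsupported MIDI status byte 0x{status:02x}")
    return events


def _ticks_to_seconds(events: list[tuple[int, int, int, int]], ppq: int) -> dict[int, float]:
    """Map event ticks to seconds using the tempo map (default 120 bpm)."""
    tempo_changes = sorted(
        [(t, v) for t, kind, v, _ in events if kind == 2] or [(0, 500_000)]
    )
    if tempo_changes[0][0] > 0:
        tempo_changes.insert(0, (0, 500_000))
    ticks = sorted({t for t, *_ in events})
    out: dict[int, float] = {}
    seconds = 0.0
    prev_tick = 0
    ti = 0
    tempo = tempo_changes[0][1]
    for tick in ticks:
        while ti + 1 < len(tempo_changes) and tempo_changes[ti + 1][0] <= tick:
            ct, next_tempo = tempo_changes[ti + 1]
            seconds += (ct - prev_tick) * tempo / ppq / 1e6
            prev_tick = ct
            tempo = next_tempo
            ti += 1
        out[tick] = seconds + (tick - prev_tick) * tempo / ppq / 1e6
    return out


def read_midi(path: str | Path, on_polyphony: str = "reject") -> NoteSequence:
    """Read a format 0/1 Standard MIDI File as a monophonic NoteSequence.

    Parameters
    ----------
    path : path to the .mid file.
    on_polyphony : ``"reject"`` (default) raises on overlapping notes;
        ``"flatten"`` truncates the sounding note at the next onset.
    """
    if on_polyphony not in ("reject", "flatten"):
        raise ValueError("on_polyphony must be 'reject' or 'flatten'")
    raw = Path(path).read_bytes()
    if raw[:4] != b"MThd":
        raise ValueError(f"{path} is not a Standard MIDI File")
    hlen, fmt, n_tracks, division = struct.unpack(">IHHH", raw[4:14])
    if division & 0x8000:
        raise ValueError("SMPTE time division not supported")
    if fmt not in (0, 1):
        raise ValueError(f"unsupported MIDI format {fmt}")
    ppq = division
    events: list[tuple[int, int, int, int]] = []
    i = 8 + hlen
    for _ in range(n_tracks):
        if raw[i : i + 4] != b"MTrk":
            raise ValueError("malformed MIDI: missing MTrk chunk")
        length = struct.unpack(">I", raw[i + 4 : i + 8])[0]
        events.extend(_parse_track(raw[i + 8 : i + 8 + length]))
        i += 8 + length
    if not any(kind == 1 for _, kind, *_ in events):
        raise ValueError(f"{path} contains no note-on events")
    tick_sec = _ticks_to_seconds(events, ppq)
    # stable order: note-offs before note-ons at the same tick
    events.sort(key=lambda e: (e[0], e[1]))
    notes: list[NoteEvent] = []
    active: tuple[int, float] | None = None  # (pitch, onset seconds)
    for tick, kind, a, _ in events:
        t = tick_sec[tick]
        if kind == 1:
            if active is not None:
                if on_polyphony == "reject":
                    raise ValueError(
                        f"polyphony at {t:.3f}s: note {a} overlaps sounding note "
                        f"{active[0]} (use on_polyphony='flatten' to truncate)"
                    )
                if t > active[1]:
                    notes.append(NoteEvent(active[0], active[1], t - active[1]))
                active = None
            active = (a, t)
        elif kind == 0 and active is not None and a == active[0]:
            if t > active[1]:
                notes.append(NoteEvent(active[0], active[1], t - active[1]))
            active = None
    if active is not None:
        raise ValueError("note-on without matching note-off")
    return NoteSequence(notes, composition_id=Path(path).stem)


def write_midi(seq: NoteSequence, path: str | Path, ppq: int = 480, tempo: int = 500_000) -> None:
    """Write a NoteSequence as a single-track format-0 MIDI file."""
    sec_per_tick = tempo / ppq / 1e6
    track = bytearray()
    track += _encode_varlen(0) + bytes([0xFF, 0x51, 0x03]) + tempo.to_bytes(3, "big")
    pending: list[tuple[int, int, int]] = []  # (tick, kind(off=0/on=1), pitch)
    for n in seq.notes:
        on = round(n.onset / sec_per_tick)
        off = round((n.onset + n.duration) / sec_per_tick)
        off = max(off, on + 1)  # zero-length notes are unreadable
        pending.append((on, 1, n.pitch))
        pending.append((off, 0, n.pitch))
    pending.sort(key=lambda e: (e[0], e[1]))
    prev = 0
    for tick, kind, pitch in pending:
        track += _encode_varlen(tick - prev)
        track += bytes([0x90 if kind else 0x80, pitch, 100 if kind else 0])
        prev = tick
    track += _encode_varlen(0) + bytes([0xFF, 0x2F, 0x00])
    with open(path, "wb") as fh:
        fh.write(b"MThd" + struct.pack(">IHHH", 6, 0, 1, ppq))
        fh.write(b"MTrk" + struct.pack(">I", len(track)) + bytes(track))


def _quantized(seq: NoteSequence, ppq: int = 480, tempo: int = 500_000) -> NoteSequence:
    """The sequence after MIDI tick quantization (write_midi's rounding)."""
    spt = tempo / ppq / 1e6
    notes = []
    for n in seq.notes:
        on = round(n.onset / spt)
        off = max(round((n.onset + n.duration) / spt), on + 1)
        notes.append(NoteEvent(n.pitch, on * spt, (off - on) * spt))
    return NoteSequence(notes, composition_id=seq.composition_id, metadata=seq.metadata)
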