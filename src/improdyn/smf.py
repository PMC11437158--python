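"""Minimal Standard MIDI File (SMF) reader/writer.

Supports what monophonic melody analysis needs: format 0/1 reading with
running status and note-on/note-off pairing, and format 0 writing (single
track, 480 ticks per quarter note, one tempo event). Times are exchanged in
ticks; callers convert to beats via the file's division.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass
from pathlib import Path

from .errors import MidiFormatError

DEFAULT_DIVISION = 480


@dataclass(frozen=True)
class RawNote:
    """A matched note-on/note-off pair, in absolute ticks."""

    pitch: int
    onset_ticks: int
    duration_ticks: int
    channel: int = 0


def _write_varlen(value: int) -> bytes:
    if value < 0:
        raise ValueError("negative delta time")
    chunks = [value & 0x7F]
    value >>= 7
    while value:
        chunks.append(0x80 | (value & 0x7F))
        value >>= 7
    return bytes(reversed(chunks))


def _read_varlen(data: bytes, pos: int) -> tuple[int, int]:
    value = 0
    for _ in range(4):
        if pos >= len(data):
            raise MidiFormatError("truncated variable-length quantity")
        byte = data[pos]
        pos += 1
        value = (value << 7) | (byte & 0x7F)
        if not byte & 0x80:
            return value, pos
    raise MidiFormatError("variable-length quantity longer than 4 bytes")


def write_smf(
    path: str | Path,
    notes: list[RawNote],
    division: int = DEFAULT_DIVISION,
    tempo_bpm: float = 120.0,
) -> None:
    """Write notes as a format-0 SMF with a single tempo event."""
    events: list[tuple[int, int, bytes]] = []  # (tick, order, message)
    for note in notes:
        if not 0 <= note.pitch <= 127:
            raise ValueError(f"pitch {note.pitch} outside MIDI range")
        on = bytes([0x90 | note.channel, note.pitch, 64])
        off = bytes([0x80 | note.channel, note.pitch, 0])
        events.append((note.onset_ticks, 1, on))
        events.append((note.onset_ticks + note.duration_ticks, 0, off))
    events.sort(key=lambda e: (e[0], e[1]))

    track = bytearray()
    tempo = round(60_000_000 / tempo_bpm)
    track += _write_varlen(0) + bytes([0xFF, 0x51, 0x03]) + tempo.to_bytes(3, "big")
    tick = 0
    for abs_tick, _, msg in events:
        track += _write_varlen(abs_tick - tick) + msg
        tick = abs_tick
    track += _write_varlen(0) + bytes([0xFF, 0x2F, 0x00])

    with open(path, "wb") as fh:
        fh.write(b"MThd" + struct.pack(">IHHH", 6, 0, 1, division))
        fh.write(b"MTrk" + struct.pack(">I", len(track)) + bytes(track))


def read_smf(path: str | Path) -> tuple[list[RawNote], int, float]:
    """Read an SMF, returning (notes, division, tempo_bpm).

    All tracks are merged; only the first tempo event is honoured (melody
    fixtures written by this package carry exactly one).
    """
    data = Path(path).read_bytes()
    if len(data) < 14 or data[:4] != b"MThd":
        raise MidiFormatError("missing MThd header")
    header_len, fmt, ntrks, division = struct.unpack(">IHHH", data[4:14])
    if header_len != 6:
        raise MidiFormatError(f"unexpected MThd length {header_len}")
    if fmt not in (0, 1):
        raise MidiFormatError(f"unsupported SMF format {fmt}")
    if division & 0x8000:
        raise MidiFormatError("SMPTE time division not supported")

    pos = 14
    notes: list[RawNote] = []
    tempo_bpm = 120.0
    tempo_seen = False
    for _ in range(ntrks):
        if data[pos : pos + 4] != b"MTrk":
            raise MidiFormatError("missing MTrk chunk")
        (length,) = struct.unpack(">I", data[pos + 4 : pos + 8])
        track = data[pos + 8 : pos + 8 + length]
        pos += 8 + length
        got_tempo, track_notes = _parse_track(track)
        if got_tempo is not None and not tempo_seen:
            tempo_bpm = got_tempo
            tempo_seen = True
        notes.extend(track_notes)

    notes.sort(key=lambda n: (n.onset_ticks, n.pitch))
    return notes, division, tempo_bpm


def _parse_track(track: bytes) -> tuple[float | None, list[RawNote]]:
    tick = 0
    p = 0
    status = 0
    tempo_bpm: float | None = None
    open_notes: dict[tuple[int, int], int] = {}  # (channel, pitch) -> onset tick
    notes: list[RawNote] = []
    while p < len(track):
        delta, p = _read_varlen(track, p)
        tick += delta
        if p >= len(track):
            raise MidiFormatError("truncated track")
        byte = track[p]
        if byte >= 0x80:
            status = byte
            p += 1
        elif status == 0:
            raise MidiFormatError("data byte with no running status")
        kind = status & 0xF0
        channel = status & 0x0F
        if status == 0xFF:  # meta event
            if p + 1 >= len(track):
                raise MidiFormatError("truncated meta event")
            meta_type = track[p]
            length, p = _read_varlen(track, p + 1)
            payload = track[p : p + length]
            p += length
            if meta_type == 0x51 and length == 3 and tempo_bpm is None:
                tempo_bpm = 60_000_000 / int.from_bytes(payload, "big")
            if meta_type == 0x2F:
                break
            status = 0  # meta events cancel running status
        elif status in (0xF0, 0xF7):  # sysex
            length, p = _read_varlen(track, p)
            p += length
            status = 0
        elif kind in (0x90, 0x80):
            if p + 1 >= len(track):
                raise MidiFormatError("truncated note event")
            pitch, velocity = track[p], track[p + 1]
            p += 2
            key = (channel, pitch)
            if kind == 0x90 and velocity > 0:
                open_notes.setdefault(key, tick)
            else:  # note off, or note on with velocity 0
                onset = open_notes.pop(key, None)
                if onset is not None:
                    notes.append(RawNote(pitch, onset, tick - onset, channel))
        elif kind in (0xA0, 0xB0, 0xE0):  # two data bytes, ignored
            p += 2
        elif kind in (0xC0, 0xD0):  # one data byte, ignored
            p += 1
        else:
            raise MidiFormatError(f"unexpected status byte 0x{status:02X}")
    return tempo_bpm, notes
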