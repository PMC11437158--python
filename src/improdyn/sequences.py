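"""Tone streams and their symbolizations.

A monophonic melody is represented as a :class:`ToneSequence` of pitch /
onset / duration events (times in beats, quarter note = 1). Three
symbolizations feed the statistical-learning model:

* ``pitch`` — the MIDI note numbers themselves;
* ``rhythm`` — note durations quantized to a small closed set of duration
  classes (nearest class in log2 space, ties broken toward the shorter
  class);
* ``pitch_rhythm`` — (pitch, duration-class) pairs.

Alphabets are corpus-wide by default: the model learns over the whole
corpus, so per-piece alphabets would make probabilities incomparable
across pieces.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Hashable, Iterable, Sequence

import numpy as np
import pandas as pd

from . import smf
from .errors import DataError, MonophonyError, ParameterError

#: Default duration classes, in beats. A small closed set keeps the rhythm
#: alphabet finite, as the Markov model requires.
DEFAULT_DURATION_CLASSES: tuple[float, ...] = (0.25, 0.5, 1.0, 2.0)

#: Legato tolerance: overlaps up to 1/32 beat truncate the earlier note;
#: anything larger is treated as polyphony.
OVERLAP_TOLERANCE: float = 1.0 / 32.0

STREAM_KINDS = ("pitch", "rhythm", "pitch_rhythm")


@dataclass(frozen=True)
class ToneEvent:
    """One note: MIDI pitch, onset and duration in beats."""

    pitch: int
    onset: float
    duration: float

    def __post_init__(self) -> None:
        if not 0 <= self.pitch <= 127:
            raise DataError(f"pitch {self.pitch} outside MIDI range 0-127")
        if self.onset < 0:
            raise DataError(f"negative onset {self.onset}")
        if self.duration <= 0:
            raise DataError(f"non-positive duration {self.duration}")


@dataclass(frozen=True)
class ToneSequence:
    """A monophonic piece plus its corpus metadata."""

    events: tuple[ToneEvent, ...]
    piece_id: str = ""
    year: int | None = None
    style: str | None = None
    instrument: str | None = None
    player: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "events", tuple(self.events))
        onsets = [e.onset for e in self.events]
        if onsets != sorted(onsets):
            raise DataError("events must be sorted by onset")

    def __len__(self) -> int:
        return len(self.events)

    @property
    def pitches(self) -> np.ndarray:
        return np.array([e.pitch for e in self.events], dtype=int)

    @property
    def durations(self) -> np.ndarray:
        return np.array([e.duration for e in self.events], dtype=float)

    @property
    def onsets(self) -> np.ndarray:
        return np.array([e.onset for e in self.events], dtype=float)

    @property
    def total_beats(self) -> float:
        if not self.events:
            return 0.0
        last = self.events[-1]
        return last.onset + last.duration


@dataclass(frozen=True)
class SymbolSequence:
    """A piece recoded over a finite alphabet."""

    symbols: tuple[Hashable, ...]
    alphabet: tuple[Hashable, ...]
    stream_kind: str
    piece_id: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "symbols", tuple(self.symbols))
        object.__setattr__(self, "alphabet", tuple(self.alphabet))
        if len(self.symbols) < 1:
            raise DataError("symbol sequence must be non-empty")
        if len(set(self.alphabet)) != len(self.alphabet):
            raise DataError("alphabet contains duplicates")
        members = set(self.alphabet)
        for s in self.symbols:
            if s not in members:
                raise DataError(f"symbol {s!r} not in alphabet")

    def __len__(self) -> int:
        return len(self.symbols)


# ---------------------------------------------------------------------------
# MIDI I/O


def read_midi(
    path: str | Path,
    piece_id: str = "",
    overlap_tolerance: float = OVERLAP_TOLERANCE,
) -> ToneSequence:
    """Read a Standard MIDI File as a monophonic tone sequence.

    Note-on/note-off pairs are matched by pitch and channel; ticks are
    converted to beats via the file's division. Legato overlaps within
    ``overlap_tolerance`` beats truncate the earlier note; larger overlaps
    raise :class:`MonophonyError` naming the first offending onset.
    """
    notes, division, _tempo = smf.read_smf(path)
    raw = [
        ToneEvent(n.pitch, n.onset_ticks / division, n.duration_ticks / division)
        for n in notes
    ]
    events: list[ToneEvent] = []
    for ev in raw:
        if events:
            prev = events[-1]
            overlap = (prev.onset + prev.duration) - ev.onset
            if overlap > overlap_tolerance:
                raise MonophonyError(
                    f"overlapping notes at onset {ev.onset:g} beats "
                    f"(overlap {overlap:g} > tolerance {overlap_tolerance:g})"
                )
            if overlap > 0:  # legato: truncate the earlier note
                events[-1] = replace(prev, duration=ev.onset - prev.onset)
        events.append(ev)
    return ToneSequence(tuple(events), piece_id=piece_id or Path(path).stem)


def write_midi(
    tones: ToneSequence,
    path: str | Path,
    tempo_bpm: float = 120.0,
    division: int = smf.DEFAULT_DIVISION,
) -> None:
    """Write a tone sequence as a format-0 SMF (single track)."""
    notes = [
        smf.RawNote(
            e.pitch,
            round(e.onset * division),
            max(1, round(e.duration * division)),
        )
        for e in tones.events
    ]
    smf.write_smf(path, notes, division=division, tempo_bpm=tempo_bpm)


# ---------------------------------------------------------------------------
# Duration quantization


def quantize_duration(
    duration: float,
    classes: Sequence[float] = DEFAULT_DURATION_CLASSES,
) -> float:
    """Map a duration (beats) to its nearest class in log2 space.

    Ties (a duration at the geometric midpoint of two classes) break toward
    the shorter class.
    """
    if duration <= 0:
        raise DataError(f"non-positive duration {duration}")
    ordered = sorted(classes)
    dists = [abs(math.log2(duration) - math.log2(c)) for c in ordered]
    best = min(dists)
    for c, d in zip(ordered, dists):
        if d <= best + 1e-9:
            return c
    raise AssertionError("unreachable")


# ---------------------------------------------------------------------------
# Symbolization


def to_pitch_sequence(
    tones: ToneSequence,
    alphabet: Sequence[int] | None = None,
) -> SymbolSequence:
    """Pitch stream: symbols are the MIDI note numbers in order."""
    if len(tones) == 0:
        raise DataError("empty tone sequence")
    symbols = tuple(int(e.pitch) for e in tones.events)
    alpha = tuple(alphabet) if alphabet is not None else tuple(sorted(set(symbols)))
    return SymbolSequence(symbols, alpha, "pitch", tones.piece_id)


def to_rhythm_sequence(
    tones: ToneSequence,
    classes: Sequence[float] = DEFAULT_DURATION_CLASSES,
    use_ioi: bool = False,
) -> SymbolSequence:
    """Rhythm stream: quantized note durations (or inter-onset intervals).

    The default symbol is the note's own duration; ``use_ioi=True`` switches
    to inter-onset intervals (the last event falls back to its duration,
    having no successor).
    """
    if len(tones) == 0:
        raise DataError("empty tone sequence")
    if use_ioi:
        onsets = tones.onsets
        values = list(np.diff(onsets)) + [tones.events[-1].duration]
    else:
        values = list(tones.durations)
    symbols = tuple(quantize_duration(v, classes) for v in values)
    return SymbolSequence(symbols, tuple(sorted(classes)), "rhythm", tones.piece_id)


def to_pitch_rhythm_sequence(
    tones: ToneSequence,
    classes: Sequence[float] = DEFAULT_DURATION_CLASSES,
    alphabet: Sequence[tuple[int, float]] | None = None,
) -> SymbolSequence:
    """Combined stream: symbols are (pitch, duration-class) pairs."""
    if len(tones) == 0:
        raise DataError("empty tone sequence")
    symbols = tuple(
        (int(e.pitch), quantize_duration(e.duration, classes)) for e in tones.events
    )
    alpha = tuple(alphabet) if alphabet is not None else tuple(sorted(set(symbols)))
    return SymbolSequence(symbols, alpha, "pitch_rhythm", tones.piece_id)


def symbolize_corpus(
    pieces: Iterable[ToneSequence],
    stream_kind: str,
    classes: Sequence[float] = DEFAULT_DURATION_CLASSES,
    use_ioi: bool = False,
) -> list[SymbolSequence]:
    """Symbolize every piece over one shared, corpus-wide alphabet."""
    pieces = list(pieces)
    if not pieces:
        raise DataError("empty corpus")
    if stream_kind not in STREAM_KINDS:
        raise ParameterError(f"unknown stream kind {stream_kind!r}")
    if stream_kind == "pitch":
        alphabet = tuple(sorted({int(p) for t in pieces for p in t.pitches}))
        return [to_pitch_sequence(t, alphabet) for t in pieces]
    if stream_kind == "rhythm":
        return [to_rhythm_sequence(t, classes, use_ioi) for t in pieces]
    alphabet = tuple(
        sorted(
            {
                (int(e.pitch), quantize_duration(e.duration, classes))
                for t in pieces
                for e in t.events
            }
        )
    )
    return [to_pitch_rhythm_sequence(t, classes, alphabet) for t in pieces]


# ---------------------------------------------------------------------------
# Text export


def sequences_to_csv(seqs: Iterable[SymbolSequence], path: str | Path) -> None:
    rows = [
        {"piece_id": s.piece_id, "index": i, "symbol": repr(sym)}
        for s in seqs
        for i, sym in enumerate(s.symbols)
    ]
    pd.DataFrame(rows, columns=["piece_id", "index", "symbol"]).to_csv(
        path, index=False
    )


def alphabet_to_json(seq: SymbolSequence, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(
            {"stream_kind": seq.stream_kind, "alphabet": [repr(a) for a in seq.alphabet]},
            fh,
            indent=2,
        )
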