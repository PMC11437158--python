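"""Era-structured synthetic corpora and audio fixtures.

Real corpora of improvised melodies (hundreds of solos spanning most of a
century, annotated with year, style, instrument and player) cannot ship
with a test suite, so every downstream stage is exercised on synthetic
stand-ins with known ground truth:

* an :class:`EraSpec` holds an era-specific first-order Markov transition
  matrix over a pitch alphabet, drawn row-wise from a symmetric Dirichlet
  whose concentration controls transition entropy (small concentration =
  peaked, idiomatic transitions; large = near-uniform);
* pieces are sampled from those chains with i.i.d. durations from a small
  duration-class distribution;
* audio comes from a simple additive synthesizer, and amplitude-modulation
  fixtures with exactly known envelope-cycle boundaries feed the acoustic
  cycle analysis.

Every operation is a pure function of its arguments including the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .errors import DataError, ParameterError
from .sequences import (
    DEFAULT_DURATION_CLASSES,
    ToneEvent,
    ToneSequence,
    write_midi,
)

#: Style and instrument vocabularies used to tag synthetic pieces; drawn
#: from the vocabulary of annotated jazz-solo corpora.
STYLES = (
    "Bebop", "Cool", "Free", "Fusion", "Hardbop", "Postbop", "Swing", "Traditional",
)
INSTRUMENTS = (
    "alto saxophone", "baritone saxophone", "clarinet", "cornet", "guitar",
    "piano", "soprano saxophone", "trombone", "trumpet", "tenor saxophone",
    "vibraphone",
)

DEFAULT_BASE_PITCH = 60  # pitch alphabet starts at middle C


def _row_entropies_bits(matrix: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(matrix > 0, matrix * np.log2(matrix), 0.0)
    return -terms.sum(axis=1)


@dataclass(frozen=True)
class EraSpec:
    """Generative description of one stylistic era."""

    era_label: str
    year_range: tuple[int, int]
    transition_matrix: np.ndarray
    duration_dist: np.ndarray
    pitch_alphabet: tuple[int, ...]
    duration_classes: tuple[float, ...] = DEFAULT_DURATION_CLASSES

    def __post_init__(self) -> None:
        tm = np.asarray(self.transition_matrix, dtype=float)
        dd = np.asarray(self.duration_dist, dtype=float)
        object.__setattr__(self, "transition_matrix", tm)
        object.__setattr__(self, "duration_dist", dd)
        if self.year_range[0] > self.year_range[1]:
            raise ParameterError(f"invalid year range {self.year_range}")
        if tm.ndim != 2 or tm.shape[0] != tm.shape[1]:
            raise ParameterError("transition matrix must be square")
        if tm.shape[0] != len(self.pitch_alphabet):
            raise ParameterError("matrix size does not match pitch alphabet")
        if (tm < 0).any() or (tm > 1).any():
            raise ParameterError("transition probabilities outside [0, 1]")
        if np.abs(tm.sum(axis=1) - 1.0).max() > 1e-9:
            raise ParameterError("transition matrix rows must sum to 1")
        if abs(dd.sum() - 1.0) > 1e-9 or (dd < 0).any():
            raise ParameterError("duration distribution must be a probability vector")
        if len(dd) != len(self.duration_classes):
            raise ParameterError("duration distribution size mismatch")

    @property
    def n_pitches(self) -> int:
        return len(self.pitch_alphabet)

    @property
    def target_entropy(self) -> float:
        """Mean transition-row entropy in bits (descriptive)."""
        return float(_row_entropies_bits(self.transition_matrix).mean())


def make_era_spec(
    n_pitches: int,
    concentration: float,
    seed: int,
    era_label: str = "era",
    year_range: tuple[int, int] = (1925, 2009),
    duration_dist: Sequence[float] | None = None,
    duration_classes: Sequence[float] = DEFAULT_DURATION_CLASSES,
    base_pitch: int = DEFAULT_BASE_PITCH,
) -> EraSpec:
    """Draw an era's transition matrix from a symmetric Dirichlet.

    Smaller ``concentration`` gives lower-entropy (more idiomatic) rows;
    ``concentration -> inf`` approaches uniform transitions. Deterministic
    given ``seed``.
    """
    if n_pitches < 2:
        raise ParameterError("n_pitches must be >= 2")
    if concentration <= 0:
        raise ParameterError(f"concentration must be positive, got {concentration}")
    rng = np.random.default_rng(seed)
    matrix = rng.dirichlet(np.full(n_pitches, concentration), size=n_pitches)
    if duration_dist is None:
        duration_dist = np.full(len(duration_classes), 1.0 / len(duration_classes))
    return EraSpec(
        era_label=era_label,
        year_range=tuple(year_range),
        transition_matrix=matrix,
        duration_dist=np.asarray(duration_dist, dtype=float),
        pitch_alphabet=tuple(range(base_pitch, base_pitch + n_pitches)),
        duration_classes=tuple(duration_classes),
    )


def sample_piece(
    spec: EraSpec,
    length: int,
    seed: int,
    piece_id: str = "",
    year: int | None = None,
    style: str | None = None,
    instrument: str | None = None,
    player: str | None = None,
) -> ToneSequence:
    """Sample one piece from an era's Markov chain.

    The first pitch is uniform over the alphabet (maximum-entropy default;
    piece onsets are not modelled); later pitches follow the transition
    matrix. Durations are i.i.d. from the era's duration-class
    distribution; onsets are cumulative durations.
    """
    if length < 2:
        raise ParameterError("piece length must be >= 2")
    rng = np.random.default_rng(seed)
    k = spec.n_pitches
    states = np.empty(length, dtype=int)
    states[0] = rng.integers(k)
    for t in range(1, length):
        states[t] = rng.choice(k, p=spec.transition_matrix[states[t - 1]])
    durations = rng.choice(
        np.asarray(spec.duration_classes), size=length, p=spec.duration_dist
    )
    onsets = np.concatenate(([0.0], np.cumsum(durations[:-1])))
    events = tuple(
        ToneEvent(spec.pitch_alphabet[s], float(o), float(d))
        for s, o, d in zip(states, onsets, durations)
    )
    return ToneSequence(
        events,
        piece_id=piece_id,
        year=year,
        style=style,
        instrument=instrument,
        player=player,
    )


def sample_corpus(
    era_specs: Sequence[EraSpec],
    pieces_per_era: int,
    length_range: tuple[int, int],
    seed: int,
    out_dir: str | Path | None = None,
) -> tuple[pd.DataFrame, dict[str, ToneSequence]]:
    """Sample an era-structured corpus.

    Piece lengths are uniform on ``length_range`` (inclusive), years
    uniform within each era's range; style, instrument and player tags are
    drawn from fixed vocabularies. Returns the manifest (columns piece_id,
    era, year, style, instrument, player, path) and the pieces keyed by
    id. If ``out_dir`` is given every piece is also written as a format-0
    Standard MIDI File and the manifest as manifest.csv.
    """
    if len(era_specs) == 0:
        raise ParameterError("need at least one era spec")
    if pieces_per_era < 1:
        raise ParameterError("pieces_per_era must be >= 1")
    lo, hi = length_range
    if not 2 <= lo <= hi:
        raise ParameterError(f"invalid length range {length_range}")
    rng = np.random.default_rng(seed)
    players = tuple(f"player_{i:02d}" for i in range(1, 13))

    rows = []
    pieces: dict[str, ToneSequence] = {}
    for spec in era_specs:
        for i in range(pieces_per_era):
            piece_id = f"{spec.era_label}_{i:03d}"
            year = int(rng.integers(spec.year_range[0], spec.year_range[1] + 1))
            style = STYLES[rng.integers(len(STYLES))]
            instrument = INSTRUMENTS[rng.integers(len(INSTRUMENTS))]
            player = players[rng.integers(len(players))]
            length = int(rng.integers(lo, hi + 1))
            piece = sample_piece(
                spec,
                length,
                seed=int(rng.integers(2**31)),
                piece_id=piece_id,
                year=year,
                style=style,
                instrument=instrument,
                player=player,
            )
            path = ""
            if out_dir is not None:
                out_dir = Path(out_dir)
                out_dir.mkdir(parents=True, exist_ok=True)
                path = str(out_dir / f"{piece_id}.mid")
                write_midi(piece, path)
            rows.append(
                {
                    "piece_id": piece_id,
                    "era": spec.era_label,
                    "year": year,
                    "style": style,
                    "instrument": instrument,
                    "player": player,
                    "path": path,
                }
            )
            pieces[piece_id] = piece
    manifest = pd.DataFrame(rows)
    if manifest["piece_id"].duplicated().any():
        raise ParameterError("era labels must be distinct (duplicate piece ids)")
    if out_dir is not None:
        manifest.to_csv(Path(out_dir) / "manifest.csv", index=False)
    return manifest, pieces


# ---------------------------------------------------------------------------
# Audio synthesis


def render_wav(
    tones: ToneSequence,
    sample_rate: int = 22050,
    tempo: float = 120.0,
    n_harmonics: int = 4,
    ramp_ms: float = 10.0,
) -> np.ndarray:
    """Render a tone sequence as a mono waveform (additive synthesis).

    Each note is a fundamental plus ``n_harmonics - 1`` overtones at 1/k
    amplitude, with cosine on/off ramps of ``ramp_ms`` to avoid clicks
    that would create spurious envelope troughs. Tempo converts beats to
    seconds (quarter note = 60/tempo s). Peak amplitude is normalized to
    0.9.
    """
    if len(tones) == 0:
        raise DataError("cannot render an empty tone sequence")
    if sample_rate < 8000:
        raise ParameterError("sample_rate must be >= 8000 Hz")
    if tempo <= 0:
        raise ParameterError("tempo must be positive")
    sec_per_beat = 60.0 / tempo
    total = round(tones.total_beats * sec_per_beat * sample_rate)
    out = np.zeros(total, dtype=float)
    for ev in tones.events:
        start = round(ev.onset * sec_per_beat * sample_rate)
        n = round(ev.duration * sec_per_beat * sample_rate)
        if n <= 0:
            continue
        t = np.arange(n) / sample_rate
        freq = 440.0 * 2.0 ** ((ev.pitch - 69) / 12.0)
        note = np.zeros(n)
        for k in range(1, n_harmonics + 1):
            if k * freq < sample_rate / 2:
                note += np.sin(2 * np.pi * k * freq * t) / k
        ramp = min(int(ramp_ms / 1000 * sample_rate), n // 2)
        if ramp > 0:
            window = 0.5 * (1 - np.cos(np.pi * np.arange(ramp) / ramp))
            note[:ramp] *= window
            note[-ramp:] *= window[::-1]
        end = min(start + n, total)
        if end > start:
            out[start:end] += note[: end - start]
    peak = np.abs(out).max()
    if peak > 0:
        out *= 0.9 / peak
    return out


def write_wav(path: str | Path, wave: np.ndarray, sample_rate: int) -> None:
    """Write a waveform as 16-bit PCM RIFF WAV."""
    scaled = np.clip(wave, -1.0, 1.0)
    wavfile.write(path, sample_rate, (scaled * 32767).astype(np.int16))


def make_am_signal(
    cycle_lengths_ms: Sequence[float],
    sample_rate: int = 1000,
) -> np.ndarray:
    """Concatenated raised-cosine envelope bumps, one per cycle.

    Each cycle of length L ms becomes a raised-cosine bump of
    round(L * sr / 1000) samples that starts at exactly 0, so envelope
    troughs sit exactly at cycle boundaries. Used as ground truth for the
    trough / cycle-length analysis.
    """
    cycle_lengths_ms = list(cycle_lengths_ms)
    if not cycle_lengths_ms:
        raise ParameterError("need at least one cycle")
    if any(c <= 0 for c in cycle_lengths_ms):
        raise ParameterError("all cycle lengths must be positive")
    bumps = []
    for length_ms in cycle_lengths_ms:
        n = round(length_ms * sample_rate / 1000.0)
        if n < 2:
            raise ParameterError(f"cycle {length_ms} ms too short at {sample_rate} Hz")
        k = np.arange(n)
        bumps.append(0.5 * (1 - np.cos(2 * np.pi * k / n)))
    return np.concatenate(bumps)
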