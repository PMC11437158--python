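"""Online hierarchical Bayesian statistical learning over symbol sequences.

The model is a first-order Markov chain with a symmetric Dirichlet prior on
every context's transition distribution. The Dirichlet parameters act as
pseudo-counts: with prior weight ``alpha0`` per symbol and observed counts
``n(ctx, s)``, the predictive probability is

    P(s | ctx) = (n(ctx, s) + alpha0) / (N(ctx) + K * alpha0)

with K the alphabet size. Learning is online: each observed transition
increments one count. Per observed tone the model emits

* predictive probability and information content -log2 P (surprisal),
* uncertainty: Shannon entropy of the context's predictive distribution
  *before* the observation (the listener's prospective uncertainty),
* Bayesian surprise: KL divergence between the context's predictive
  distribution before and after the count update (how much one observation
  reshapes beliefs).

Reliability of a context's probabilities is the inverse of the mean
Dirichlet marginal variance of that context's posterior — confidence that
grows as evidence accumulates. Transition pairs whose (normalized)
reliability x probability product exceeds a threshold ``c`` are chunked
into units; recoding the sequence with those units and repeating the
learning yields a hierarchy of progressively longer units.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Hashable, Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .errors import AlphabetError, DataError, ParameterError
from .sequences import SymbolSequence

#: Default chunking threshold. Suitable for corpus-scale runs where each
#: context accumulates tens of observations; see docs/methods.md.
DEFAULT_CHUNK_THRESHOLD: float = 5.0


# ---------------------------------------------------------------------------
# Information-theoretic primitives (bits throughout)


def information_content(p: float) -> float:
    """Surprisal -log2(p) of an event with probability ``p``.

    ``p`` must lie in (0, 1]; zero or negative probabilities are a domain
    error and are never clipped silently.
    """
    if not 0.0 < p <= 1.0:
        raise ParameterError(f"probability {p} outside (0, 1]")
    return -math.log2(p)


def kl_divergence(p: Sequence[float], q: Sequence[float]) -> float:
    """KL divergence D(P||Q) in bits; terms with P(i)=0 contribute 0."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ParameterError("P and Q must have the same length")
    for name, v in (("P", p), ("Q", q)):
        if abs(v.sum() - 1.0) > 1e-9:
            raise ParameterError(f"{name} does not sum to 1 (sum={v.sum()!r})")
        if (v < 0).any():
            raise ParameterError(f"{name} has negative entries")
    support = p > 0
    if (q[support] <= 0).any():
        raise ParameterError("Q must be positive wherever P is (absolute continuity)")
    return float(np.sum(p[support] * np.log2(p[support] / q[support])))


def _entropy_bits(probs: np.ndarray) -> float:
    nz = probs[probs > 0]
    return float(-np.sum(nz * np.log2(nz)))


def _dirichlet_mean_variance(alpha: np.ndarray) -> float:
    total = alpha.sum()
    var = alpha * (total - alpha) / (total**2 * (total + 1.0))
    return float(var.mean())


# ---------------------------------------------------------------------------
# Records and model


@dataclass(frozen=True)
class SurpriseRecord:
    """Per-tone output of one online observation."""

    index: int
    probability: float
    information_content: float
    surprise_kl: float
    uncertainty: float


@dataclass(frozen=True)
class ChunkInventory:
    """Units created at one hierarchy level.

    ``units`` holds ((context, next), unit_id, score) triples; the unit id
    is simply the (context, next) tuple, so nested chunks compose
    structurally.
    """

    level: int
    units: tuple[tuple[tuple[Hashable, Hashable], Hashable, float], ...]
    threshold_c: float

    @property
    def pair_map(self) -> dict[tuple[Hashable, Hashable], Hashable]:
        return {pair: unit for pair, unit, _ in self.units}

    def __len__(self) -> int:
        return len(self.units)


class DirichletMarkovModel:
    """Order-1 Markov model with symmetric Dirichlet prior (pseudo-counts).

    Parameters
    ----------
    alphabet : sequence of hashables
        The (ordered) finite symbol set. Order fixes the meaning of
        probability vectors returned by :meth:`predictive_row`.
    alpha0 : float, default 1.0
        Prior pseudo-count per symbol.
    level : int, default 1
        Hierarchy level index (bookkeeping only).
    """

    def __init__(
        self,
        alphabet: Sequence[Hashable],
        alpha0: float = 1.0,
        level: int = 1,
    ) -> None:
        alphabet = tuple(alphabet)
        if len(set(alphabet)) != len(alphabet):
            raise ParameterError("alphabet contains duplicates")
        if len(alphabet) < 2:
            raise ParameterError("alphabet must have at least 2 symbols")
        if alpha0 <= 0:
            raise ParameterError(f"alpha0 must be positive, got {alpha0}")
        self.alphabet = alphabet
        self.alpha0 = float(alpha0)
        self.level = int(level)
        self._index = {s: i for i, s in enumerate(alphabet)}
        self.counts = np.zeros((len(alphabet), len(alphabet)), dtype=float)

    # -- basic queries ------------------------------------------------------

    @property
    def n_symbols(self) -> int:
        return len(self.alphabet)

    def _idx(self, symbol: Hashable) -> int:
        try:
            return self._index[symbol]
        except KeyError:
            raise AlphabetError(f"symbol {symbol!r} not in alphabet") from None

    def predictive_row(self, context: Hashable) -> np.ndarray:
        """Predictive distribution over the next symbol, given ``context``."""
        row = self.counts[self._idx(context)] + self.alpha0
        return row / row.sum()

    def predictive_prob(self, context: Hashable, nxt: Hashable) -> float:
        return float(self.predictive_row(context)[self._idx(nxt)])

    def context_entropy(self, context: Hashable) -> float:
        """Entropy (bits) of the context's predictive distribution."""
        return _entropy_bits(self.predictive_row(context))

    def reliability(self, context: Hashable) -> float:
        """Inverse mean Dirichlet marginal variance of the context's posterior."""
        alpha = self.counts[self._idx(context)] + self.alpha0
        return 1.0 / _dirichlet_mean_variance(alpha)

    def prior_reliability(self) -> float:
        """Reliability of a context with no observations (prior baseline)."""
        return 1.0 / _dirichlet_mean_variance(
            np.full(self.n_symbols, self.alpha0)
        )

    # -- learning -----------------------------------------------------------

    def observe(
        self, context: Hashable, nxt: Hashable, index: int = 0
    ) -> SurpriseRecord:
        """Observe one transition; return its surprise/uncertainty record.

        Probability, information content and uncertainty are evaluated on
        the predictive distribution *before* the count update; Bayesian
        surprise is the KL divergence from the pre-update to the
        post-update predictive distribution of the same context.
        """
        i, j = self._idx(context), self._idx(nxt)
        before = self.predictive_row(context)
        prob = float(before[j])
        uncertainty = _entropy_bits(before)
        self.counts[i, j] += 1.0
        after = self.predictive_row(context)
        return SurpriseRecord(
            index=index,
            probability=prob,
            information_content=-math.log2(prob),
            surprise_kl=kl_divergence(before, after),
            uncertainty=uncertainty,
        )

    def process_sequence(self, seq: SymbolSequence | Sequence[Hashable]) -> list[SurpriseRecord]:
        """Online pass over a sequence; one record per transition (n-1 total)."""
        symbols = seq.symbols if isinstance(seq, SymbolSequence) else tuple(seq)
        if len(symbols) < 2:
            raise DataError("sequence must contain at least 2 symbols")
        return [
            self.observe(symbols[t - 1], symbols[t], index=t)
            for t in range(1, len(symbols))
        ]

    def copy(self) -> "DirichletMarkovModel":
        clone = DirichletMarkovModel(self.alphabet, self.alpha0, self.level)
        clone.counts = self.counts.copy()
        return clone

    # -- serialization ------------------------------------------------------

    def to_json(self, path: str | Path | None = None) -> str:
        doc = json.dumps(
            {
                "alphabet": [repr(s) for s in self.alphabet],
                "alpha0": self.alpha0,
                "level": self.level,
                "counts": self.counts.tolist(),
            },
            indent=2,
        )
        if path is not None:
            Path(path).write_text(doc)
        return doc

    @classmethod
    def from_json(cls, doc: str) -> "DirichletMarkovModel":
        data = json.loads(doc)
        # alphabets round-trip through repr/eval of plain literals
        import ast

        alphabet = [ast.literal_eval(s) for s in data["alphabet"]]
        model = cls(alphabet, data["alpha0"], data["level"])
        model.counts = np.asarray(data["counts"], dtype=float)
        return model


# ---------------------------------------------------------------------------
# Chunking and hierarchy


def chunk_scores(
    model: DirichletMarkovModel,
) -> dict[tuple[Hashable, Hashable], float]:
    """Normalized reliability x probability score per observed pair.

    Probability is already a normalized quantity in [0, 1]. Reliability is
    unbounded and grows with evidence, so it is normalized by the prior
    reliability: the score of pair (a, b) is

        (reliability(a) / prior_reliability) * P(b | a).

    The reliability gain over the prior is 1 for an unobserved context and
    grows roughly linearly with the context's observation count, which is
    why the chunking threshold ``c`` scales with sample length.
    """
    prior = model.prior_reliability()
    scores: dict[tuple[Hashable, Hashable], float] = {}
    for i, a in enumerate(model.alphabet):
        observed = np.nonzero(model.counts[i] > 0)[0]
        if observed.size == 0:
            continue
        gain = model.reliability(a) / prior
        row = model.predictive_row(a)
        for j in observed:
            scores[(a, model.alphabet[j])] = gain * float(row[j])
    return scores


def detect_chunks(
    model: DirichletMarkovModel,
    seq: SymbolSequence | None = None,
    c: float = DEFAULT_CHUNK_THRESHOLD,
) -> ChunkInventory:
    """Chunk observed transition pairs whose score exceeds ``c``.

    ``seq`` optionally restricts candidates to pairs adjacent in that
    sequence (by construction the model's counts already contain exactly
    the observed pairs, so passing the processed sequence is equivalent).
    ``c = 0`` chunks every observed pair (all scores are strictly
    positive); the threshold comparison is ``score >= c`` so that limit is
    exact.
    """
    if c < 0:
        raise ParameterError(f"chunk threshold must be non-negative, got {c}")
    scores = chunk_scores(model)
    if seq is not None:
        symbols = seq.symbols
        adjacent = set(zip(symbols[:-1], symbols[1:]))
        scores = {pair: s for pair, s in scores.items() if pair in adjacent}
    units = tuple(
        (pair, pair, score)
        for pair, score in sorted(scores.items(), key=lambda kv: (-kv[1], str(kv[0])))
        if score >= c
    )
    return ChunkInventory(level=model.level, units=units, threshold_c=c)


def recode_with_chunks(
    seq: SymbolSequence, inventory: ChunkInventory
) -> SymbolSequence:
    """Greedy left-to-right, non-overlapping replacement of chunked pairs.

    Each matched (a, b) pair becomes its unit symbol; the new alphabet is
    the old one plus the unit ids in inventory order. With an empty
    inventory the output equals the input.
    """
    pair_map = inventory.pair_map
    out: list[Hashable] = []
    symbols = seq.symbols
    i = 0
    while i < len(symbols):
        if i + 1 < len(symbols) and (symbols[i], symbols[i + 1]) in pair_map:
            out.append(pair_map[(symbols[i], symbols[i + 1])])
            i += 2
        else:
            out.append(symbols[i])
            i += 1
    new_units = [u for _, u, _ in inventory.units if u not in set(seq.alphabet)]
    alphabet = tuple(seq.alphabet) + tuple(new_units)
    return SymbolSequence(tuple(out), alphabet, seq.stream_kind, seq.piece_id)


def build_hierarchy(
    seq: SymbolSequence,
    c: float = DEFAULT_CHUNK_THRESHOLD,
    max_levels: int = 5,
    alpha0: float = 1.0,
) -> list[tuple[DirichletMarkovModel, ChunkInventory, SymbolSequence]]:
    """Cascade of learn / chunk / recode passes.

    Each level trains a fresh model on the current sequence, chunks
    qualifying pairs, and recodes; the cascade stops when an inventory is
    empty, the recoded sequence becomes too short, or ``max_levels`` is
    reached. Returns one (model, inventory, recoded sequence) triple per
    level.
    """
    if max_levels < 1:
        raise ParameterError("max_levels must be >= 1")
    levels = []
    current = seq
    for level in range(1, max_levels + 1):
        model = DirichletMarkovModel(current.alphabet, alpha0=alpha0, level=level)
        model.process_sequence(current)
        inventory = detect_chunks(model, current, c)
        recoded = recode_with_chunks(current, inventory)
        levels.append((model, inventory, recoded))
        if len(inventory) == 0 or len(recoded) < 2 or len(recoded) == len(current):
            break
        current = recoded
    return levels


def inventory_to_json(
    inventories: Iterable[ChunkInventory], path: str | Path | None = None
) -> str:
    doc = json.dumps(
        [
            {
                "level": inv.level,
                "threshold_c": inv.threshold_c,
                "normalization": "reliability gain over prior x raw probability",
                "units": [
                    {"pair": [repr(a) for a in pair], "score": score}
                    for pair, _, score in inv.units
                ],
            }
            for inv in inventories
        ],
        indent=2,
    )
    if path is not None:
        Path(path).write_text(doc)
    return doc


# ---------------------------------------------------------------------------
# Corpus-level estimator


class SurpriseLearner(BaseEstimator):
    """Corpus-level online surprise/uncertainty learner (sklearn-style).

    ``fit`` runs one cumulative online pass over the given sequences in the
    given order (callers wanting the chronological regime sort by year
    first), recording each piece's per-tone time course during the pass.
    The first event of each piece has no within-piece context: its record
    carries the uniform-prior entropy log2(K) as uncertainty and NaN for
    probability/surprise, so surprise time courses start at the second
    tone.

    Parameters
    ----------
    alpha0 : float, default 1.0
        Symmetric Dirichlet prior pseudo-count per symbol.
    reset_per_piece : bool, default False
        Restart from the prior for every piece instead of learning
        cumulatively across the corpus.
    alphabet : sequence, optional
        Shared alphabet; defaults to the (identical) alphabet of the input
        sequences.

    Attributes
    ----------
    model_ : DirichletMarkovModel
        Final model state after the pass (last piece's model when
        ``reset_per_piece``).
    records_ : dict[str, pandas.DataFrame]
        Per-piece time courses with columns event_index, probability,
        information_content, surprise_kl, uncertainty.
    """

    def __init__(
        self,
        alpha0: float = 1.0,
        reset_per_piece: bool = False,
        alphabet: Sequence[Hashable] | None = None,
    ) -> None:
        self.alpha0 = alpha0
        self.reset_per_piece = reset_per_piece
        self.alphabet = alphabet

    def fit(self, X: Sequence[SymbolSequence], y=None) -> "SurpriseLearner":
        X = list(X)
        if not X:
            raise DataError("no sequences to fit")
        alphabet = tuple(self.alphabet) if self.alphabet is not None else X[0].alphabet
        for seq in X:
            if set(seq.alphabet) - set(alphabet):
                raise DataError(
                    f"piece {seq.piece_id!r} uses symbols outside the shared alphabet"
                )
        model = DirichletMarkovModel(alphabet, alpha0=self.alpha0)
        records: dict[str, pd.DataFrame] = {}
        for seq in X:
            if self.reset_per_piece:
                model = DirichletMarkovModel(alphabet, alpha0=self.alpha0)
            rows = [
                {
                    "event_index": 0,
                    "probability": np.nan,
                    "information_content": np.nan,
                    "surprise_kl": np.nan,
                    "uncertainty": math.log2(len(alphabet)),
                }
            ]
            for rec in model.process_sequence(seq):
                rows.append(
                    {
                        "event_index": rec.index,
                        "probability": rec.probability,
                        "information_content": rec.information_content,
                        "surprise_kl": rec.surprise_kl,
                        "uncertainty": rec.uncertainty,
                    }
                )
            key = seq.piece_id or f"piece_{len(records)}"
            records[key] = pd.DataFrame(rows)
        self.model_ = model
        self.records_ = records
        self.n_sequences_ = len(X)
        return self

    def timecourse(self, piece_id: str, feature: str) -> np.ndarray:
        """One piece's series for ``feature`` in {surprise, uncertainty,
        information_content, probability}; NaN lead-ins are dropped."""
        column = {"surprise": "surprise_kl"}.get(feature, feature)
        frame = self.records_[piece_id]
        if column not in frame.columns:
            raise ParameterError(f"unknown feature {feature!r}")
        return frame[column].dropna().to_numpy()

    def timecourses(self, feature: str) -> dict[str, np.ndarray]:
        return {pid: self.timecourse(pid, feature) for pid in self.records_}

    def to_frame(self, stream_kind: str = "") -> pd.DataFrame:
        """All records as one long DataFrame (CSV-ready)."""
        frames = []
        for pid, frame in self.records_.items():
            f = frame.copy()
            f.insert(0, "piece_id", pid)
            if stream_kind:
                f["stream_kind"] = stream_kind
            frames.append(f)
        return pd.concat(frames, ignore_index=True)
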