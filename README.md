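# improdyn

Surprise and uncertainty dynamics of improvised melodies.

`improdyn` is a research toolkit for studying how the *predictability* of
improvised music — rather than its raw acoustics — changes across stylistic
eras. It implements an online hierarchical Bayesian statistical-learning
model over monophonic tone sequences, plus the downstream analyses needed
to compare whole corpora of pieces: time-course standardization, 2-D
embedding, era-separability scoring, and an amplitude-envelope
rhythm-cycle analysis. Because real annotated corpora (e.g. databases of
transcribed jazz solos) cannot ship with a test suite, the package
includes a first-class synthetic-corpus generator with known ground truth
for every stage.

It is intended for computational music-cognition researchers who want a
reproducible pipeline from MIDI (or synthetic) melodies to per-tone
information dynamics and corpus-level summaries.

## The model

Melodies are recoded as symbol sequences over a finite alphabet — pitch,
duration class (rhythm), or (pitch, duration) pairs — and fed to a
first-order Markov model with a symmetric Dirichlet prior acting as
pseudo-counts. With prior weight α₀ per symbol and observed transition
counts n(eₙ, eₙ₊₁), the predictive probability is

    P(eₙ₊₁ | eₙ) = (n(eₙ, eₙ₊₁) + α₀) / (N(eₙ) + K·α₀)

For every tone the model emits, *online*:

* **information content** I(eₙ₊₁) = −log₂ P(eₙ₊₁ | eₙ) — surprisal;
* **uncertainty** H(eₙ₊₁) = −Σₑ P(e | eₙ) log₂ P(e | eₙ) — entropy of the
  predictive distribution *before* the tone is heard;
* **Bayesian surprise** D_KL(P‖Q) = Σᵢ P(i) log₂(P(i)/Q(i)) between the
  context's predictive distribution before (P) and after (Q) the single
  count update — how much one tone reshapes beliefs.

The Dirichlet posterior also yields a **reliability** per context (inverse
mean marginal variance — confidence in the probability estimates).
Transition pairs whose normalized reliability × probability product
exceeds a threshold *c* (default 5) are **chunked** into units; recoding
the sequence and relearning yields a hierarchy of progressively longer
units, the way letters form words and words form phrases.

Downstream, per-piece surprise/uncertainty time courses are linearly
interpolated to a common length, embedded in 2-D with t-SNE (perplexity 2,
random state 40, early exaggeration 20), and scored for era separability
with leave-one-out k-NN label accuracy. The acoustic module extracts the
sub-40 Hz amplitude modulator of a signal, detects envelope troughs (cycle
boundaries), and computes adjacent-cycle rhythm rates c₁/(c₁+c₂) — 0.5 is
a 1:1 cycle ratio, 1/3 and 2/3 the 1:2 and 2:1 ratios — and their density.

## Worked example

```python
import numpy as np
from improdyn import (make_era_spec, sample_piece, to_pitch_sequence,
                      DirichletMarkovModel, rhythm_rates)
from improdyn.experiments import era_separation_medians

# An "era" = a Markov process over 12 pitches; low Dirichlet concentration
# means peaked, idiomatic transitions.
spec = make_era_spec(n_pitches=12, concentration=0.1, seed=1, era_label="bebop")
print(f"mean transition-row entropy: {spec.target_entropy:.3f} bits")

piece = sample_piece(spec, length=200, seed=2, piece_id="demo")
seq = to_pitch_sequence(piece)
model = DirichletMarkovModel(seq.alphabet, alpha0=1.0)
records = model.process_sequence(seq)
print(f"first tone : surprise {records[0].surprise_kl:.4f} bits, "
      f"uncertainty {records[0].uncertainty:.4f} bits")
print(f"last tone  : surprise {records[-1].surprise_kl:.4f} bits, "
      f"uncertainty {records[-1].uncertainty:.4f} bits")

# Two-era corpus: era-specific pitch transitions, shared rhythm.
scores = era_separation_medians(seed=2025, n_runs=5)
print(f"era separation (kNN accuracy): pitch {scores['pitch']:.3f}, "
      f"rhythm {scores['rhythm']:.3f}")

print(f"rhythm rate of [500, 500] ms cycles: {rhythm_rates([500., 500.])[0]}")
```

prints

```
mean transition-row entropy: 1.180 bits
first tone : surprise 0.0321 bits, uncertainty 3.5850 bits
last tone  : surprise 0.0001 bits, uncertainty 2.0962 bits
era separation (kNN accuracy): pitch 1.000, rhythm 0.475
rhythm rate of [500, 500] ms cycles: 0.5
```

Reading the numbers: the model starts at maximal uncertainty
(log₂ 12 ≈ 3.585 bits) and, as it internalizes the era's peaked transition
structure, both surprise and uncertainty fall. At the corpus level, pitch
uncertainty dynamics identify a piece's era perfectly (accuracy 1.0) while
the era-neutral rhythm stream stays at chance (≈ 0.5) — predictability
structure, not rhythm, carries the era signal. Two equal envelope cycles
give the 1:1 rhythm rate 0.5.

## Layout

| module | contents |
| --- | --- |
| `improdyn.synthetic` | era specs, corpus sampling, additive synthesis, AM fixtures |
| `improdyn.sequences` | tone events, MIDI read/write, pitch/rhythm/pair symbolization |
| `improdyn.smf` | minimal Standard MIDI File parser/writer |
| `improdyn.hbsl` | Dirichlet–Markov model, surprise/uncertainty, chunking, hierarchy |
| `improdyn.dynamics` | interpolation, corpus matrices, t-SNE embedding, era kNN score |
| `improdyn.acoustics` | z-scoring, demodulation, scalograms, troughs, rhythm rates |
| `improdyn.experiments` | end-to-end era-separation pipeline on synthetic corpora |

See `docs/methods.md` for the modeling choices, parameter defaults and
known limitations.
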