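# Methods

This note documents the models and procedures implemented in `improdyn`,
the defaults that matter, the choices made where the design was genuinely
open, and what the synthetic-data experiments do and do not show.

## Statistical-learning model

The core is an order-1 Markov model over a finite symbol alphabet with a
symmetric Dirichlet prior, learned online: one count increment per
observed transition. The Dirichlet reading matters only through its
pseudo-count arithmetic (predictive probability) and its posterior
variance (reliability); no sampling is involved, so the model is exact
and deterministic.

Conventions:

* **Base-2 logarithms everywhere.** Information content, entropy and KL
  divergence are all reported in bits so the three per-tone quantities
  share a unit.
* **Uncertainty is prospective.** It is the entropy of the context's
  predictive distribution *before* the observed tone — the uncertainty a
  listener has while predicting, not after hearing.
* **Bayesian surprise is local.** Only the updated context's predictive
  row changes under one observation, so the KL divergence is taken
  between that row before and after the increment; all other rows are
  untouched by construction.
* **First tone of a piece.** It has no within-piece context. Its record
  carries the uniform-prior entropy log₂ K as uncertainty and NaN for
  probability/surprise; surprise time courses therefore start at the
  second tone. This is stated in the output rather than silently dropped.
* **Markov order is fixed at 1.** Higher orders and mixtures are out of
  scope.

Tunables: `alpha0` (prior pseudo-count per symbol, default 1.0 — one
phantom observation per transition; smaller values make early surprise
spikier), and `reset_per_piece` on the corpus learner (default False:
one cumulative pass in the order given).

### Reliability

Reliability of a context is defined as the inverse of the mean Dirichlet
marginal variance of that context's posterior,

    rel(ctx) = 1 / mean_i [ αᵢ(α₀ₜ − αᵢ) / (α₀ₜ²(α₀ₜ + 1)) ],  αᵢ = α₀ + nᵢ.

It equals 12 for a two-symbol uniform prior (Beta(1,1) variance 1/12) and
grows roughly linearly with a context's observation count. One subtlety:
reliability is *not* monotone in every single observation — observing a
rare symbol in an otherwise near-deterministic context briefly raises the
posterior variance (e.g. two-symbol counts (10,1)→(10,2) drop reliability
from 145 to 93.6). What is monotone, and what the tests assert, is growth
under proportional accumulation of evidence and under repetition of the
dominant transition.

### Chunking normalization

Chunking multiplies a "normalized" probability and reliability and
compares the product with a constant c (default 5). Probability is
already a normalized quantity in [0, 1] and is used raw. Reliability is
unbounded, so it is normalized by the *prior* reliability of an
unobserved context:

    score(a, b) = [rel(a) / rel_prior] · P(b | a),  chunk when score ≥ c.

This choice has three properties that alternatives (e.g. min–max scaling
of both factors across observed pairs) lack:

1. it is scale-aware — on structureless i.i.d. noise every score stays
   small (empirically < 4.5 across alphabet sizes 5–20 at realistic
   sample lengths), so noise is never chunked at c = 5, whereas any
   purely relative scaling stretches noise fluctuations to the top of
   the range and produces spurious chunks;
2. planted regularities separate cleanly (a bigram whose context is
   always followed by the same symbol scores ≥ 25 at 500 events;
   strictly repeating patterns score ≈ 70);
3. it explains why the threshold must be chosen relative to sample
   length: the reliability gain grows with the context's observation
   count, so longer corpora need a larger c.

The comparison is `score ≥ c` so that the degenerate threshold c = 0
chunks exactly the observed pairs (all scores are strictly positive);
for any continuous score distribution this differs from a strict
inequality only on a measure-zero set. Negative thresholds are rejected.

Hierarchy building re-trains a fresh model per level on the recoded
sequence (unit symbols are (left, right) tuples, so nested chunks
compose structurally) and stops on an empty inventory, on a fixed-point
recoding, or at `max_levels`. Per-tone surprise/uncertainty reported by
the corpus learner come from level-1 learning only; hierarchy levels are
computed and exportable but do not alter the time courses.

### Learning regime for corpus experiments

The corpus learner supports a cumulative pass (default) and a per-piece
reset. For the era-separation experiment the package uses **per-piece
reset**, and this is a deliberate, load-bearing choice: in a cumulative
chronological pass, a piece's position in the pass is perfectly
correlated with its era, and the amplitude of uncertainty fluctuations
shrinks mechanically as corpus counts grow — so even streams with no
era-specific structure at all (rhythm drawn from one shared distribution)
become separable by pass position (measured: rhythm kNN accuracy ≈ 0.9
cumulative vs ≈ 0.48 reset). Only the reset regime isolates the signal
of interest — per-piece sequence structure — and reproduces the expected
contrast (pitch separable, shared rhythm at chance).

## Symbolization

* Onsets and durations are in beats (quarter note = 1), derived from the
  MIDI file's tick division; tempo only matters for audio rendering.
* The rhythm symbol is the note's own duration, quantized to the classes
  {0.25, 0.5, 1, 2} beats by nearest log2 distance, ties toward the
  shorter class; inter-onset intervals are available as a switch.
  Durations outside the class range clamp to the nearest extreme class.
* Alphabets are corpus-wide (shared across pieces) so probabilities are
  comparable across pieces; per-piece alphabets are available by simply
  symbolizing pieces individually.
* Monophony: overlaps up to 1/32 beat are treated as legato and truncate
  the earlier note; larger overlaps are an error naming the offending
  onset.

## Synthetic corpus

The generator emulates an era-tagged corpus of monophonic improvisations:
each era is a transition matrix over a 12-pitch alphabet drawn row-wise
from a symmetric Dirichlet (concentration is the entropy knob: 0.05 gives
peaked idiomatic rows, 50 near-uniform rows), with years uniform in the
era's range and style/instrument/player tags from fixed vocabularies.
Piece lengths default to 150–400 tones (realistic solo lengths), the
first pitch is uniform (piece onsets are not modelled), and durations are
i.i.d. over the four duration classes — so rhythm carries no era signal
by construction in the two-era experiment. What the generator does *not*
emulate: melodic contour and tonality constraints, swing timing,
polyphony, velocity, player-specific idioms, or any dependence between
pitch and duration. Passing tests therefore demonstrate that the pipeline
recovers planted probabilistic structure, not that real corpora contain
such structure.

Audio: a deliberately simple additive synthesizer (4 harmonics at 1/k
amplitude, 10 ms cosine ramps to avoid clicks that would create spurious
envelope troughs), and raised-cosine amplitude-modulation fixtures whose
envelope troughs sit exactly at cycle boundaries.

## Dynamics and embedding

Time courses are resampled by piecewise-linear interpolation on a
normalized [0, 1] index grid to the length of the longest piece
(endpoints preserved exactly; output is bounded by the input's range).
t-SNE runs with perplexity 2, random state 40, early exaggeration 20,
PCA initialization, Euclidean distances on the interpolated rows; with a
fixed random state it is deterministic for a given input and library
version, but coordinates are implementation-dependent, so only
neighborhood structure (not absolute positions) is meaningful. Era
separability is a leave-one-out k-NN accuracy (k = 3, Euclidean, vote
ties broken by the single nearest neighbour) — a deliberately simple
score; no significance testing beyond label permutation is attempted.
Surprise embeddings default to the KL-surprise series; information
content is available as a switch.

## Acoustic rhythm analysis

* Signals are z-scored (population SD) so intensity cannot leak into
  modulation features.
* Demodulation is Hilbert magnitude followed by a zero-phase 4th-order
  Butterworth low-pass at 40 Hz, floored at 0; the carrier is the signal
  divided by the floored modulator. This is a deliberately simple
  demodulator honoring the modulator-below-40 Hz / carrier-above-40 Hz
  contract; it is not a probabilistic amplitude-demodulation inference,
  and absolute modulator power values depend on this choice (cycle-ratio
  logic does not).
* Scalograms use an analytic Morlet wavelet (`cmor1.5-1.0`) on 48
  log-spaced frequencies per band; mean power is the time average of the
  squared magnitude.
* Trough detection is two-stage. Candidates are local minima of a
  zero-phase 20 Hz low-pass copy of the envelope (half the modulation
  band) with minimum separation 50 ms (one cycle at 20 Hz) and
  prominence ≥ 5% of the dynamic range. Each candidate is then refined
  on the raw envelope by "sqrt-V" flank intersection: near a minimum
  that touches its baseline the envelope is locally quadratic, so its
  square root has linear flanks meeting at the trough; lines are fitted
  to the flanks at 2–20% of the local rise (inside the quadratic regime,
  with good SNR) and intersected. The refinement is exact on noiseless
  cycle fixtures — a smoothed argmin alone is biased toward the
  lower-curvature side between unequal cycles — and keeps troughs within
  a few samples under 1% additive noise.
* Cycle lengths are distances between consecutive troughs in ms; rhythm
  rates are c₁/(c₁+c₂) per adjacent pair; rate densities use 51 uniform
  bins on (0, 1). The odd bin count places the landmark 1:1 rate 0.5 at
  a bin *center*: with an even count 0.5 is a bin edge and a symmetric
  near-isochronous rate distribution splits its mass between two bins,
  making the modal bin ill-defined.
* A planted list of k cycles yields k−2 interior cycle lengths (the
  outermost cycles have no flanking troughs); round-trip checks compare
  those.
* Group summaries (per decade, style, instrument, player) are plain
  means over per-piece values with group sizes reported.

## Problem sizes used in tests

The test suite and experiments run on sizes chosen to exercise the
statistics they check: 2 eras × 20 pieces of 150–400 tones for era
separation (5-run medians), 10,000-tone pieces for transition-matrix
recovery, 100 random fixtures of 3–20 cycles for the acoustic round
trip, and 100 random short sequences for the brute-force equivalence
check.

## Known limitations

* Order-1 Markov only; no forgetting/decay, no variable-order models.
* The chunk-score normalization is one defensible reading of
  "normalized reliability × probability"; other normalizations change
  which pairs cross a given c.
* t-SNE coordinates are not comparable across library versions; only
  separation statistics are asserted.
* The synthesizer and demodulator are intentionally minimal; absolute
  acoustic power values should not be compared against other toolchains.
* The MIDI layer targets monophonic format 0/1 files; SMPTE divisions
  and multi-tempo beat mapping are unsupported.
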