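"""Unit and property tests for the online Dirichlet-Markov learner."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from improdyn.errors import AlphabetError, DataError, ParameterError
from improdyn.hbsl import (
    DirichletMarkovModel,
    SurpriseLearner,
    build_hierarchy,
    chunk_scores,
    detect_chunks,
    information_content,
    kl_divergence,
    recode_with_chunks,
)
from improdyn.sequences import SymbolSequence

from oracle_hbsl import bruteforce_records

ABC = tuple("ABCDEFGHIJKLMNOPQRST")


def make_seq(symbols, alphabet=None, kind="pitch"):
    alphabet = alphabet or tuple(dict.fromkeys(symbols))
    return SymbolSequence(tuple(symbols), tuple(alphabet), kind, "test")


# ---------------------------------------------------------------------------
# information content / KL


@pytest.mark.parametrize(
    "p,expected", [(0.5, 1.0), (1.0, 0.0), (0.25, 2.0)]
)
def test_information_content_closed_form(p, expected):
    assert information_content(p) == pytest.approx(expected, abs=1e-12)


@pytest.mark.parametrize("p", [0.0, -0.1, 1.5])
def test_information_content_domain_error(p):
    with pytest.raises(ParameterError):
        information_content(p)


def test_kl_divergence_values():
    assert kl_divergence([0.5, 0.5], [0.5, 0.5]) == 0.0
    assert kl_divergence([1.0, 0.0], [0.5, 0.5]) == pytest.approx(1.0, abs=1e-12)
    expected = 0.5 * math.log2(0.75) + 0.5 * math.log2(1.5)
    assert kl_divergence([0.5, 0.5], [2 / 3, 1 / 3]) == pytest.approx(
        expected, abs=1e-12
    )


def test_kl_divergence_absolute_continuity():
    with pytest.raises(ParameterError):
        kl_divergence([0.5, 0.5], [1.0, 0.0])


# ---------------------------------------------------------------------------
# predictive probabilities, entropy, reliability


def test_uniform_prior_predictive():
    m = DirichletMarkovModel(ABC[:12], alpha0=1.0)
    assert m.predictive_prob("A", "B") == pytest.approx(1 / 12, abs=1e-12)
    assert m.context_entropy("C") == pytest.approx(math.log2(12), abs=1e-9)


def test_pseudo_count_update():
    m = DirichletMarkovModel(ABC[:12], alpha0=1.0)
    m.observe("A", "B")
    assert m.predictive_prob("A", "B") == pytest.approx(2 / 13, abs=1e-12)
    assert m.predictive_row("A").sum() == pytest.approx(1.0, abs=1e-9)


def test_entropy_two_symbol_counts():
    m = DirichletMarkovModel(("A", "B"), alpha0=1.0)
    m.counts[0] = [3, 1]  # posterior (4/6, 2/6)
    expected = -(4 / 6) * math.log2(4 / 6) - (2 / 6) * math.log2(2 / 6)
    assert m.context_entropy("A") == pytest.approx(expected, abs=1e-9)
    assert round(expected, 4) == 0.9183


def test_entropy_decreases_toward_delta():
    m = DirichletMarkovModel(("A", "B"), alpha0=1.0)
    previous = m.context_entropy("A")
    for _ in range(200):
        m.observe("A", "B")
        current = m.context_entropy("A")
        assert current < previous
        previous = current
    assert previous < 0.1


def test_prior_reliability_two_symbols():
    # Dirichlet(1,1): each marginal variance = 1*1 / (4*3) = 1/12
    m = DirichletMarkovModel(("A", "B"), alpha0=1.0)
    assert m.reliability("A") == pytest.approx(12.0, abs=1e-9)
    assert m.prior_reliability() == pytest.approx(12.0, abs=1e-9)


def test_prior_reliability_matches_monte_carlo(rng):
    m = DirichletMarkovModel(ABC[:4], alpha0=1.0)
    m.counts[0] = [5, 2, 0, 1]
    alpha = m.counts[0] + 1.0
    draws = rng.dirichlet(alpha, size=200_000)
    mc_rel = 1.0 / draws.var(axis=0, ddof=0).mean()
    assert m.reliability("A") == pytest.approx(mc_rel, rel=0.02)


def test_reliability_identical_counts_equal():
    m = DirichletMarkovModel(ABC[:5], alpha0=1.0)
    m.counts[0] = [4, 1, 0, 2, 0]
    m.counts[3] = [4, 1, 0, 2, 0]
    assert m.reliability("A") == m.reliability("D")


def test_reliability_grows_with_accumulating_evidence(rng):
    """Reliability increases when evidence accumulates proportionally and
    when the dominant transition keeps being observed."""
    for _ in range(20):
        k = int(rng.integers(2, 8))
        counts = rng.integers(0, 20, size=k).astype(float)
        m = DirichletMarkovModel(ABC[:k], alpha0=1.0)
        m.counts[0] = counts
        r1 = m.reliability("A")
        m.counts[0] = counts * 2  # same composition, twice the evidence
        assert m.reliability("A") > r1
        m.counts[0] = counts
        dominant = ABC[int(np.argmax(counts))]
        m.observe("A", dominant)
        assert m.reliability("A") > r1


# ---------------------------------------------------------------------------
# observe / process_sequence


def test_observe_first_transition_composition():
    m = DirichletMarkovModel(("A", "B"), alpha0=1.0)
    rec = m.observe("A", "B", index=1)
    assert rec.uncertainty == pytest.approx(1.0, abs=1e-12)
    assert rec.probability == pytest.approx(0.5, abs=1e-12)
    assert rec.information_content == pytest.approx(1.0, abs=1e-12)
    expected_kl = 0.5 * math.log2(0.75) + 0.5 * math.log2(1.5)
    assert rec.surprise_kl == pytest.approx(expected_kl, abs=1e-9)


def test_repeated_observation_surprise_decreases():
    m = DirichletMarkovModel(("A", "B"), alpha0=1.0)
    previous = math.inf
    for _ in range(50):
        rec = m.observe("A", "B")
        assert rec.surprise_kl < previous
        previous = rec.surprise_kl


def test_observation_locality():
    m = DirichletMarkovModel(ABC[:5], alpha0=1.0)
    before = {c: m.predictive_row(c).copy() for c in "BCDE"}
    m.observe("A", "C")
    for c in "BCDE":
        np.testing.assert_array_equal(m.predictive_row(c), before[c])


def test_unknown_symbol_raises():
    m = DirichletMarkovModel(("A", "B"))
    with pytest.raises(AlphabetError):
        m.observe("A", "Z")
    with pytest.raises(AlphabetError):
        m.context_entropy("Z")


def test_process_sequence_length_and_short_input():
    m = DirichletMarkovModel(("A", "B"))
    recs = m.process_sequence(make_seq("ABABAB"))
    assert len(recs) == 5
    with pytest.raises(DataError):
        DirichletMarkovModel(("A", "B")).process_sequence(make_seq("A", ("A", "B")))


def test_cyclic_sequence_uncertainty_monotone_across_cycles():
    m = DirichletMarkovModel(("A", "B"))
    recs = m.process_sequence(make_seq("AB" * 50))
    unc = [r.uncertainty for r in recs]
    # compare the same position across successive cycles after the first
    for pos in range(2):
        per_cycle = unc[pos + 2 :: 2]
        assert all(b <= a + 1e-12 for a, b in zip(per_cycle, per_cycle[1:]))
    assert unc[-1] < 0.2


def test_iid_uniform_uncertainty_converges_to_log_k(rng):
    symbols = [ABC[i] for i in rng.integers(0, 4, size=10_000)]
    m = DirichletMarkovModel(ABC[:4])
    recs = m.process_sequence(make_seq(symbols, ABC[:4]))
    last_half = [r.uncertainty for r in recs[len(recs) // 2 :]]
    assert abs(np.mean(last_half) - 2.0) < 0.2


def test_online_matches_bruteforce_oracle():
    rng = np.random.default_rng(77)
    for _ in range(30):
        k = int(rng.integers(2, 6))
        n = int(rng.integers(5, 51))
        alphabet = ABC[:k]
        symbols = [alphabet[i] for i in rng.integers(0, k, size=n)]
        m = DirichletMarkovModel(alphabet)
        recs = m.process_sequence(make_seq(symbols, alphabet))
        expected = bruteforce_records(symbols, alphabet)
        for rec, exp in zip(recs, expected):
            assert rec.probability == pytest.approx(exp["probability"], abs=1e-9)
            assert rec.uncertainty == pytest.approx(exp["uncertainty"], abs=1e-9)
            assert rec.surprise_kl == pytest.approx(exp["surprise_kl"], abs=1e-9)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    st.lists(st.integers(0, 3), min_size=2, max_size=60),
    st.floats(0.1, 5.0),
)
def test_invariants_under_random_streams(stream, alpha0):
    """Rows stay normalized; surprise non-negative; uncertainty bounded."""
    alphabet = (0, 1, 2, 3)
    m = DirichletMarkovModel(alphabet, alpha0=alpha0)
    for a, b in zip(stream[:-1], stream[1:]):
        rec = m.observe(a, b)
        assert rec.surprise_kl >= 0
        assert 0 <= rec.uncertainty <= math.log2(4) + 1e-12
    for s in alphabet:
        assert m.predictive_row(s).sum() == pytest.approx(1.0, abs=1e-9)


# ---------------------------------------------------------------------------
# chunking and hierarchy


def planted_ab_sequence(seed, n=500, p_ab=0.2):
    """AB bigrams planted among uniform noise over 8 other symbols."""
    r = np.random.default_rng(seed)
    out = []
    while len(out) < n:
        if r.random() < p_ab:
            out += ["A", "B"]
        else:
            out.append(ABC[2:10][r.integers(8)])
    return make_seq(out[:n], ABC[:10])


def test_planted_bigram_is_chunked_noise_is_not():
    seq = planted_ab_sequence(seed=11)
    m = DirichletMarkovModel(seq.alphabet)
    m.process_sequence(seq)
    inv = detect_chunks(m, seq, c=5.0)
    pairs = set(inv.pair_map)
    assert ("A", "B") in pairs
    noise = set(ABC[2:10])
    assert not any(a in noise and b in noise for a, b in pairs)
    assert not any(a in noise or b in noise for a, b in pairs if (a, b) != ("A", "B")), pairs


def test_chunk_threshold_limits():
    seq = planted_ab_sequence(seed=3)
    m = DirichletMarkovModel(seq.alphabet)
    m.process_sequence(seq)
    assert len(detect_chunks(m, seq, c=math.inf)) == 0
    observed = {
        (a, b) for a, b in zip(seq.symbols[:-1], seq.symbols[1:])
    }
    inv_all = detect_chunks(m, seq, c=0.0)
    assert set(inv_all.pair_map) == observed
    with pytest.raises(ParameterError):
        detect_chunks(m, seq, c=-1.0)


def test_chunk_detection_deterministic():
    seq = planted_ab_sequence(seed=11)
    invs = []
    for _ in range(2):
        m = DirichletMarkovModel(seq.alphabet)
        m.process_sequence(seq)
        invs.append(detect_chunks(m, seq, c=5.0))
    assert invs[0].units == invs[1].units


def test_recode_greedy_replacement():
    seq = make_seq("ABABC", ("A", "B", "C"))
    inv_units = ((("A", "B"), ("A", "B"), 10.0),)
    from improdyn.hbsl import ChunkInventory

    inv = ChunkInventory(level=1, units=inv_units, threshold_c=5.0)
    out = recode_with_chunks(seq, inv)
    assert out.symbols == (("A", "B"), ("A", "B"), "C")
    assert set(seq.alphabet) <= set(out.alphabet)


def test_recode_nonoverlapping_leftmost():
    from improdyn.hbsl import ChunkInventory

    seq = make_seq("AAA", ("A", "B"))
    inv = ChunkInventory(
        level=1, units=((("A", "A"), ("A", "A"), 10.0),), threshold_c=5.0
    )
    out = recode_with_chunks(seq, inv)
    assert out.symbols == (("A", "A"), "A")


def test_recode_empty_inventory_is_identity():
    from improdyn.hbsl import ChunkInventory

    seq = make_seq("ABAB", ("A", "B"))
    inv = ChunkInventory(level=1, units=(), threshold_c=5.0)
    assert recode_with_chunks(seq, inv).symbols == seq.symbols


def test_hierarchy_on_repeating_pattern_shrinks():
    seq = make_seq("ABCD" * 40, ABC[:4])
    levels = build_hierarchy(seq, c=2.0, max_levels=4)
    assert len(levels) >= 2
    final = levels[-1][2]
    assert len(final) < len(seq)
    assert len(levels[0][1]) > 0


def test_hierarchy_on_noise_terminates_immediately():
    r = np.random.default_rng(5)
    symbols = [ABC[i] for i in r.integers(0, 20, size=1000)]
    seq = make_seq(symbols, ABC[:20])
    levels = build_hierarchy(seq, c=5.0, max_levels=4)
    assert len(levels) == 1
    assert len(levels[0][1]) == 0


def test_hierarchy_respects_max_levels():
    seq = make_seq("ABCD" * 40, ABC[:4])
    levels = build_hierarchy(seq, c=0.5, max_levels=1)
    assert len(levels) == 1


def test_model_json_roundtrip():
    m = DirichletMarkovModel((60, 62, 64), alpha0=0.5)
    m.observe(60, 62)
    m.observe(62, 64)
    clone = DirichletMarkovModel.from_json(m.to_json())
    assert clone.alphabet == m.alphabet
    assert clone.alpha0 == m.alpha0
    np.testing.assert_array_equal(clone.counts, m.counts)


# ---------------------------------------------------------------------------
# corpus-level estimator


def corpus_sequences():
    return [
        make_seq("ABAB" * 10, ("A", "B")),
        make_seq("BABA" * 10, ("A", "B")),
    ]


def test_learner_records_shapes_and_first_event():
    learner = SurpriseLearner().fit(corpus_sequences())
    frame = learner.records_["test"]
    assert len(frame) == 40
    first = frame.iloc[0]
    assert first["uncertainty"] == pytest.approx(1.0)
    assert np.isnan(first["surprise_kl"])
    assert len(learner.timecourse("test", "surprise")) == 39
    assert len(learner.timecourse("test", "uncertainty")) == 40


def test_learner_cumulative_vs_reset_differ():
    seqs = [
        make_seq("ABAB" * 10, ("A", "B")),
        make_seq("ABAB" * 10, ("A", "B"), kind="rhythm"),
    ]
    seqs = [
        SymbolSequence(s.symbols, s.alphabet, s.stream_kind, f"p{i}")
        for i, s in enumerate(seqs)
    ]
    cumulative = SurpriseLearner().fit(seqs)
    reset = SurpriseLearner(reset_per_piece=True).fit(seqs)
    # second piece: the cumulative learner already knows the pattern
    cum_unc = cumulative.records_["p1"]["uncertainty"].iloc[1]
    reset_unc = reset.records_["p1"]["uncertainty"].iloc[1]
    assert cum_unc < reset_unc


def test_learner_sklearn_params_roundtrip():
    learner = SurpriseLearner(alpha0=0.5, reset_per_piece=True)
    params = learner.get_params()
    assert params["alpha0"] == 0.5
    clone = SurpriseLearner(**params)
    assert clone.get_params() == params
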