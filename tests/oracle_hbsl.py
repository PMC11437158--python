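"""Brute-force oracle for the online Dirichlet-Markov model.

Independent of the package implementation: at every step it rebuilds the
full count table from scratch from the observation prefix, using plain
dicts and math.log2, and computes probability, entropy and KL divergence
directly from the definitions.
"""

import math


def _counts_from_prefix(symbols, upto):
    """Count table built from transitions symbols[0:upto] (exclusive end)."""
    table = {}
    for t in range(1, upto):
        pair = (symbols[t - 1], symbols[t])
        table[pair] = table.get(pair, 0) + 1
    return table


def _row(table, alphabet, context, alpha0):
    raw = {s: table.get((context, s), 0) + alpha0 for s in alphabet}
    total = sum(raw.values())
    return {s: v / total for s, v in raw.items()}


def _entropy(row):
    return -sum(p * math.log2(p) for p in row.values() if p > 0)


def _kl(p_row, q_row):
    return sum(
        p * math.log2(p / q_row[s]) for s, p in p_row.items() if p > 0
    )


def bruteforce_records(symbols, alphabet, alpha0=1.0):
    """Per-transition (probability, uncertainty, surprise_kl) triples.

    For transition t (predicting symbols[t] from symbols[t-1]) the count
    table is rebuilt from the prefix before t; uncertainty and probability
    come from that table, surprise from comparing it with the table that
    also includes transition t.
    """
    out = []
    for t in range(1, len(symbols)):
        before_table = _counts_from_prefix(symbols, t)
        after_table = _counts_from_prefix(symbols, t + 1)
        ctx = symbols[t - 1]
        before = _row(before_table, alphabet, ctx, alpha0)
        after = _row(after_table, alphabet, ctx, alpha0)
        out.append(
            {
                "probability": before[symbols[t]],
                "uncertainty": _entropy(before),
                "surprise_kl": _kl(before, after),
            }
        )
    return out
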