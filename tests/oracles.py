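"""Independent brute-force oracles used to verify the implementation.

These deliberately avoid the package's own algorithms: probe matching is a
per-position sliding-window scan, the enrichment score is a step-by-step
Python walk, and hypergeometric tails are exact rational arithmetic or
outright enumeration of draws.
"""

from __future__ import annotations

import itertools
from fractions import Fraction
from math import comb

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def revcomp(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq))


def sliding_window_hits(probes, transcripts, strand_mode="both"):
    """All (probe_id, transcript_id, offset, strand) exact matches, found by
    comparing the probe against every window of every transcript."""
    hits = []
    for probe in probes:
        k = len(probe.sequence)
        queries = []
        if strand_mode in ("forward", "both"):
            queries.append((probe.sequence, "forward"))
        if strand_mode in ("revcomp", "both"):
            queries.append((revcomp(probe.sequence), "revcomp"))
        for tx in transcripts:
            for offset in range(len(tx.sequence) - k + 1):
                window = tx.sequence[offset:offset + k]
                for query, strand in queries:
                    if window == query:
                        hits.append(
                            (probe.probe_id, tx.transcript_id, offset, strand)
                        )
    return sorted(hits)


def brute_running_sum(scores, hit_flags, weight):
    """Step-by-step enrichment-score walk; returns (es, running_values)."""
    n = len(scores)
    nh = sum(hit_flags)
    assert 0 < nh < n
    if weight == 0:
        hit_weights = [1.0 / nh] * n
    else:
        total = sum(abs(s) ** weight for s, h in zip(scores, hit_flags) if h)
        if total == 0:
            hit_weights = [1.0 / nh] * n
        else:
            hit_weights = [abs(s) ** weight / total for s in scores]
    run, values = 0.0, []
    for s, h, w in zip(scores, hit_flags, hit_weights):
        run += w if h else -1.0 / (n - nh)
        values.append(run)
    es = max(values, key=lambda v: (abs(v), -values.index(v)))
    # first extremum on ties, like argmax over |values|
    best = 0
    for i, v in enumerate(values):
        if abs(v) > abs(values[best]):
            best = i
    return values[best], values


def exact_hypergeom_sf(m: int, t: int, n: int, r: int) -> Fraction:
    """P(X >= r) for X ~ Hypergeometric(m, t, n), exact rational."""
    if r == 0:
        return Fraction(1)
    total = Fraction(0)
    for x in range(r, min(t, n) + 1):
        total += Fraction(comb(t, x) * comb(m - t, n - x), comb(m, n))
    return total


def enumerate_hypergeom_sf(m: int, t: int, n: int, r: int) -> Fraction:
    """P(overlap >= r) by enumerating every n-subset of an m-universe whose
    first t elements form the reference set."""
    marked = set(range(t))
    hits = sum(
        1
        for draw in itertools.combinations(range(m), n)
        if len(marked.intersection(draw)) >= r
    )
    return Fraction(hits, comb(m, n))
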