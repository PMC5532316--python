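"""Over-representation analysis (ORA) of a query lncRNA list.

Scores a user-supplied lncRNA list against every drug-induced lncRNA set
with the hypergeometric upper-tail test.  With m lncRNAs in the universe, t
of them in a drug's set, a query of n lncRNAs, and an overlap of r, the
enrichment p-value is

    p = 1 - sum_{x=0}^{r-1} C(t, x) * C(m - t, n - x) / C(m, n)

i.e. the probability of drawing an overlap of at least r when the query is a
uniform draw of n from the universe.  The tail sum is evaluated in log space
for numerical stability; multiple testing across drug sets is corrected with
Benjamini-Hochberg FDR q-values (Benjamini-Yekutieli optionally).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from statsmodels.stats.multitest import multipletests

from .signatures import DrugLncRNASet

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class OraResult:
    drug_name: str
    m: int  # universe size
    t: int  # drug-set size within the universe
    n: int  # query size within the universe
    r: int  # overlap size
    p_value: float
    q_value: float
    overlap_members: frozenset[str]


def _check_counts(m: int, t: int, n: int, r: int) -> None:
    if m < 1:
        raise ValueError(f"universe size m={m} must be >= 1")
    if not 0 <= t <= m:
        raise ValueError(f"set size t={t} violates 0 <= t <= m={m}")
    if not 0 <= n <= m:
        raise ValueError(f"query size n={n} violates 0 <= n <= m={m}")
    if not 0 <= r <= min(t, n):
        raise ValueError(f"overlap r={r} violates 0 <= r <= min(t={t}, n={n})")


def _log_comb(a: int, b: int) -> float:
    return math.lgamma(a + 1) - math.lgamma(b + 1) - math.lgamma(a - b + 1)


def hypergeom_pvalue(m: int, t: int, n: int, r: int) -> float:
    """Upper-tail hypergeometric probability P(X >= r).

    Computed as the direct tail sum over x = r .. min(t, n) in log space
    (log-sum-exp over log binomial coefficients), which is both stable and
    exactly the complement of the partial sum up to r - 1.  Returns 1.0 when
    r = 0 (the empty-sum case).
    """
    _check_counts(m, t, n, r)
    x_lo = max(r, n - (m - t))  # below this, C(m-t, n-x) vanishes
    x_hi = min(t, n)
    if r == 0:
        return 1.0
    if x_lo > x_hi:
        return 0.0
    log_denom = _log_comb(m, n)
    log_terms = [
        _log_comb(t, x) + _log_comb(m - t, n - x) - log_denom
        for x in range(x_lo, x_hi + 1)
    ]
    peak = max(log_terms)
    total = peak + math.log(sum(math.exp(lt - peak) for lt in log_terms))
    return min(1.0, math.exp(total))


def bh_fdr(p_values: Sequence[float], method: str = "fdr_bh") -> list[float]:
    """Benjamini-Hochberg step-up q-values (``fdr_by`` for the Yekutieli
    variant), returned in the input order and clipped to [0, 1]."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if method not in ("fdr_bh", "fdr_by"):
        raise ValueError(f"unknown FDR method {method!r}")
    _, q, _, _ = multipletests(p, method=method)
    return [float(v) for v in q]


def ora_enrich(
    query: Iterable[str],
    drug_sets: Sequence[DrugLncRNASet],
    universe: Iterable[str],
    min_set_size: int = 1,
    max_set_size: int | None = None,
    fdr_method: str = "fdr_bh",
) -> list[OraResult]:
    """Score a query lncRNA list against every drug-induced lncRNA set.

    Query and sets are intersected with the universe before counting
    (out-of-universe identifiers are logged and ignored).  One result per
    tested set; q-values are computed across all tested sets, and output is
    sorted by ascending p-value with ties broken by drug name.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("universe is empty")
    query = set(query)
    dropped_query = query - universe
    if dropped_query:
        logger.info(
            "%d query ids outside the universe ignored", len(dropped_query)
        )
    query &= universe
    if not query:
        raise ValueError("query is empty after intersection with the universe")

    m = len(universe)
    max_size = max_set_size if max_set_size is not None else m

    tested: list[tuple[DrugLncRNASet, set[str]]] = []
    for ds in drug_sets:
        members = set(ds.members) & universe
        out = len(ds.members) - len(members)
        if out:
            logger.info(
                "drug %s: %d members outside the universe ignored",
                ds.drug_name, out,
            )
        if not min_set_size <= len(members) <= max_size:
            logger.info(
                "drug %s excluded by size filter (%d members)",
                ds.drug_name, len(members),
            )
            continue
        tested.append((ds, members))

    p_values = []
    partial = []
    for ds, members in tested:
        overlap = frozenset(query & members)
        p = hypergeom_pvalue(m, len(members), len(query), len(overlap))
        p_values.append(p)
        partial.append((ds.drug_name, len(members), len(overlap), overlap))

    q_values = bh_fdr(p_values, method=fdr_method) if p_values else []

    results = [
        OraResult(
            drug_name=name,
            m=m,
            t=t,
            n=len(query),
            r=r,
            p_value=p,
            q_value=q,
            overlap_members=overlap,
        )
        for (name, t, r, overlap), p, q in zip(partial, p_values, q_values)
    ]
    results.sort(key=lambda res: (res.p_value, res.drug_name))
    return results
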