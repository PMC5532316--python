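"""LncRNA-set enrichment analysis (LSEA).

A GSEA-style test of whether the members of a drug-induced lncRNA set
concentrate at the top or bottom of a ranked lncRNA list derived from a
two-class expression profile (e.g. disease vs normal).  The pipeline is:

1. rank every lncRNA by a class-separation metric (signal-to-noise by
   default);
2. walk down the ranked list, increasing a running-sum statistic at each set
   member and decreasing it at each non-member; the enrichment score ES is
   the maximum deviation from zero of this random walk.  With weight
   exponent 0 the walk uses uniform steps (+1/Nh at hits, -1/(N-Nh) at
   misses) and terminates at exactly zero; with weight exponent 1 hit steps
   are proportional to |ranking score|, the modern GSEA default;
3. assess significance by permutation: relabel samples (phenotype mode) or
   redraw member sets (gene-set mode), recompute ES, and report the
   normalized enrichment score (NES), nominal p-value, a sign-stratified
   permutation FDR q-value, and a family-wise error rate (FWER) p-value
   from the distribution of the maximum |NES| across sets per permutation.

All p-value estimators use the add-one convention (1 + exceedances) /
(1 + draws) so that no reported p-value is exactly zero.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .ora import bh_fdr
from .signatures import DrugLncRNASet, validate_expression_matrix

logger = logging.getLogger(__name__)


class RankMetric(str, Enum):
    SIGNAL2NOISE = "signal2noise"
    T_STAT = "t_stat"
    DIFF_OF_MEANS = "diff_of_means"


class PermutationMode(str, Enum):
    AUTO = "auto"
    PHENOTYPE = "phenotype"
    GENE_SET = "gene_set"


#: Minimum per-class sample count for phenotype permutation under ``auto``;
#: below this the label space is too small for a stable permutation null and
#: gene-set permutation is used instead (the usual GSEA guidance).
PHENOTYPE_MIN_PER_CLASS = 7


@dataclass(frozen=True)
class LseaParams:
    metric: RankMetric = RankMetric.SIGNAL2NOISE
    weight_exponent: float = 1.0
    n_permutations: int = 1000
    permutation_mode: PermutationMode = PermutationMode.AUTO
    seed: int = 0
    min_set_size: int = 3
    fdr_method: str = "permutation"  # or "fdr_bh" on nominal p-values

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if self.min_set_size < 1:
            raise ValueError("min_set_size must be >= 1")
        if self.weight_exponent not in (0, 1, 0.0, 1.0):
            raise ValueError("weight_exponent must be 0 or 1")


@dataclass
class RankedList:
    """Gene ids sorted by ranking score, descending; ties broken by id."""

    genes: list[str]
    scores: np.ndarray  # aligned with genes

    def __post_init__(self) -> None:
        if len(self.genes) != len(self.scores):
            raise ValueError("genes and scores differ in length")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate gene ids in ranked list")


@dataclass
class LseaResult:
    drug_name: str
    es: float
    nes: float
    p_nominal: float
    q_fdr: float
    p_fwer: float
    leading_edge: frozenset[str]
    overlap_size: int
    nes_defined: bool = True


def validate_class_labels(
    labels: Mapping[str, int], expr: pd.DataFrame
) -> tuple[list[str], list[str]]:
    """Check the 0/1 phenotype labels and return (class0, class1) samples."""
    class0 = sorted(s for s, v in labels.items() if v == 0)
    class1 = sorted(s for s, v in labels.items() if v == 1)
    bad = {s: v for s, v in labels.items() if v not in (0, 1)}
    if bad:
        raise ValueError(f"labels must be 0 or 1; got {bad}")
    if not class0 or not class1:
        raise ValueError("both classes must be non-empty")
    missing = [s for s in labels if s not in expr.columns]
    if missing:
        raise KeyError(f"labeled samples absent from matrix: {missing[:5]}")
    return class0, class1


def _score_matrix(
    x1: np.ndarray, x0: np.ndarray, metric: RankMetric
) -> np.ndarray:
    """Per-gene class-separation scores; x1/x0 are (genes, samples) blocks."""
    mu1 = x1.mean(axis=1)
    mu0 = x0.mean(axis=1)
    if metric is RankMetric.DIFF_OF_MEANS:
        return mu1 - mu0
    s1 = x1.std(axis=1, ddof=1)
    s0 = x0.std(axis=1, ddof=1)
    if metric is RankMetric.SIGNAL2NOISE:
        # GSEA-style floor keeps near-constant genes from exploding the ratio
        s1 = np.maximum(s1, np.maximum(0.2 * np.abs(mu1), 0.2))
        s0 = np.maximum(s0, np.maximum(0.2 * np.abs(mu0), 0.2))
        return (mu1 - mu0) / (s1 + s0)
    # Welch t statistic; zero-variance genes with equal means score 0
    denom = np.sqrt(s1**2 / x1.shape[1] + s0**2 / x0.shape[1])
    diff = mu1 - mu0
    out = np.zeros_like(diff)
    nz = denom > 0
    out[nz] = diff[nz] / denom[nz]
    out[~nz & (diff != 0)] = np.sign(diff[~nz & (diff != 0)]) * np.inf
    return out


def rank_genes(
    expr: pd.DataFrame,
    labels: Mapping[str, int],
    metric: RankMetric = RankMetric.SIGNAL2NOISE,
) -> RankedList:
    """Rank genes by class separation, descending.

    signal2noise and t_stat need at least two samples per class; with fewer
    the metric falls back to diff_of_means (logged).  Ties are broken by
    gene id, ascending, so the ordering is fully deterministic.
    """
    validate_expression_matrix(expr)
    metric = RankMetric(metric)
    class0, class1 = validate_class_labels(labels, expr)
    if metric is not RankMetric.DIFF_OF_MEANS and (
        len(class0) < 2 or len(class1) < 2
    ):
        logger.warning(
            "%s requires >= 2 samples per class; falling back to diff_of_means",
            metric.value,
        )
        metric = RankMetric.DIFF_OF_MEANS

    x1 = expr[class1].to_numpy(dtype=float)
    x0 = expr[class0].to_numpy(dtype=float)
    scores = _score_matrix(x1, x0, metric)
    order = sorted(
        range(len(scores)), key=lambda i: (-scores[i], expr.index[i])
    )
    return RankedList(
        genes=[expr.index[i] for i in order],
        scores=np.asarray([scores[i] for i in order], dtype=float),
    )


def _walk(
    scores: np.ndarray, hit_mask: np.ndarray, weight_exponent: float
) -> np.ndarray:
    """Running-sum statistic over a ranked list given a member mask."""
    n = hit_mask.size
    nh = int(hit_mask.sum())
    if nh == 0:
        raise ValueError("no set members present in the ranked list")
    if nh == n:
        raise ValueError("set covers the entire ranked list; ES undefined")
    steps = np.full(n, -1.0 / (n - nh))
    if weight_exponent == 0:
        steps[hit_mask] = 1.0 / nh
    else:
        w = np.abs(scores[hit_mask]) ** weight_exponent
        total = w.sum()
        if total == 0:  # all hit scores zero: weights collapse to uniform
            steps[hit_mask] = 1.0 / nh
        else:
            steps[hit_mask] = w / total
    return np.cumsum(steps)


def enrichment_score(
    ranked: RankedList,
    members: set[str],
    weight_exponent: float = 1.0,
) -> tuple[float, np.ndarray, frozenset[str]]:
    """ES, full running sum, and leading edge for one set.

    The ES is the signed running-sum value of maximal absolute deviation
    from zero (first such position on ties).  The leading edge contains the
    set members at or before the extremum for a positive ES, and strictly
    after it for a negative ES.
    """
    hit_mask = np.array([g in members for g in ranked.genes], dtype=bool)
    run = _walk(ranked.scores, hit_mask, weight_exponent)
    ext = int(np.argmax(np.abs(run)))
    es = float(run[ext])
    if es > 0:
        le = {g for i, g in enumerate(ranked.genes) if hit_mask[i] and i <= ext}
    elif es < 0:
        le = {g for i, g in enumerate(ranked.genes) if hit_mask[i] and i > ext}
    else:
        le = set()
    return es, run, frozenset(le)


def _observed_es(
    ranked: RankedList,
    member_masks: np.ndarray,
    weight_exponent: float,
) -> np.ndarray:
    out = np.empty(member_masks.shape[0])
    for j in range(member_masks.shape[0]):
        run = _walk(ranked.scores, member_masks[j], weight_exponent)
        k = int(np.argmax(np.abs(run)))
        out[j] = run[k]
    return out


def permutation_null(
    expr: pd.DataFrame,
    labels: Mapping[str, int],
    drug_sets: Sequence[DrugLncRNASet],
    params: LseaParams,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Null ES samples, shape (n_sets, n_permutations).

    Phenotype mode permutes the 0/1 sample labels uniformly at random,
    re-ranks, and recomputes every set's ES — preserving inter-gene
    correlation.  Gene-set mode keeps the observed ranking and redraws each
    set's members uniformly from the ranked universe (same size).
    """
    rng = rng if rng is not None else np.random.default_rng(params.seed)
    class0, class1 = validate_class_labels(labels, expr)
    ranked = rank_genes(expr, labels, params.metric)
    gene_pos = {g: i for i, g in enumerate(ranked.genes)}
    masks = np.zeros((len(drug_sets), len(ranked.genes)), dtype=bool)
    for j, ds in enumerate(drug_sets):
        for g in ds.members:
            if g in gene_pos:
                masks[j, gene_pos[g]] = True

    n_sets = len(drug_sets)
    null = np.empty((n_sets, params.n_permutations))

    mode = params.permutation_mode
    if mode is PermutationMode.AUTO:
        mode = (
            PermutationMode.PHENOTYPE
            if min(len(class0), len(class1)) >= PHENOTYPE_MIN_PER_CLASS
            else PermutationMode.GENE_SET
        )
        logger.info(
            "auto permutation mode resolved to %s (%d/%d samples per class)",
            mode.value, len(class0), len(class1),
        )

    if mode is PermutationMode.PHENOTYPE:
        if len(class0) < 2 or len(class1) < 2:
            raise ValueError(
                "phenotype permutation needs >= 2 samples per class; "
                "use gene_set permutation mode instead"
            )
        samples = class0 + class1
        base = np.array([0] * len(class0) + [1] * len(class1))
        sub = expr[samples]
        for k in range(params.n_permutations):
            perm = rng.permutation(base)
            plabels = dict(zip(samples, (int(v) for v in perm)))
            pranked = rank_genes(sub, plabels, params.metric)
            pos = {g: i for i, g in enumerate(pranked.genes)}
            reorder = np.array([pos[g] for g in ranked.genes])
            for j in range(n_sets):
                pmask = np.zeros(len(ranked.genes), dtype=bool)
                pmask[reorder[masks[j]]] = True
                run = _walk(pranked.scores, pmask, params.weight_exponent)
                null[j, k] = run[int(np.argmax(np.abs(run)))]
    else:
        n_genes = len(ranked.genes)
        for j in range(n_sets):
            size = int(masks[j].sum())
            for k in range(params.n_permutations):
                idx = rng.choice(n_genes, size=size, replace=False)
                pmask = np.zeros(n_genes, dtype=bool)
                pmask[idx] = True
                run = _walk(ranked.scores, pmask, params.weight_exponent)
                null[j, k] = run[int(np.argmax(np.abs(run)))]
    return null


def _nes(es: float, null_row: np.ndarray) -> tuple[float, bool]:
    """Normalize an ES by the mean |null ES| of matching sign."""
    if es == 0:
        return 0.0, True
    same = null_row[null_row > 0] if es > 0 else null_row[null_row < 0]
    if same.size == 0:
        return math.nan, False
    return es / float(np.abs(same).mean()), True


def normalize_and_test(
    set_names: Sequence[str],
    observed_es: np.ndarray,
    null_es: np.ndarray,
    leading_edges: Sequence[frozenset[str]],
    overlap_sizes: Sequence[int],
    fdr_method: str = "permutation",
) -> list[LseaResult]:
    """Turn observed and null ES into NES / p / q / FWER per set.

    NES divides each ES (observed and null alike) by the set's mean |null
    ES| of matching sign.  The nominal p-value compares |ES| with the
    same-sign null tail; the FWER p-value compares |NES| with the
    per-permutation maximum |null NES| over all sets; the FDR q-value is the
    sign-stratified ratio of pooled-null to observed NES tail fractions,
    clipped to [0, 1] and made monotone (``fdr_method="fdr_bh"`` applies
    Benjamini-Hochberg to the nominal p-values instead).
    """
    n_sets, n_perm = null_es.shape
    if len(set_names) != n_sets or observed_es.shape[0] != n_sets:
        raise ValueError("inconsistent set counts")
    if n_perm < 1:
        raise ValueError("need at least one null sample per set")

    nes = np.empty(n_sets)
    defined = np.ones(n_sets, dtype=bool)
    p_nom = np.empty(n_sets)
    for j in range(n_sets):
        es = observed_es[j]
        nes[j], defined[j] = _nes(es, null_es[j])
        if es == 0:
            p_nom[j] = 1.0
        else:
            same = null_es[j][null_es[j] > 0] if es > 0 else null_es[j][null_es[j] < 0]
            p_nom[j] = (1 + int((np.abs(same) >= abs(es)).sum())) / (1 + same.size)

    # Null NES: same per-set, sign-matched denominators as the observed NES.
    null_nes = np.full_like(null_es, np.nan)
    for j in range(n_sets):
        row = null_es[j]
        pos, neg = row[row > 0], row[row < 0]
        if pos.size:
            null_nes[j, row > 0] = row[row > 0] / np.abs(pos).mean()
        if neg.size:
            null_nes[j, row < 0] = row[row < 0] / np.abs(neg).mean()
        null_nes[j, row == 0] = 0.0

    # FWER: distribution of the per-permutation maximum |null NES|.
    with np.errstate(invalid="ignore"):
        col_max = np.nanmax(np.abs(null_nes), axis=0)
    p_fwer = np.ones(n_sets)
    for j in range(n_sets):
        if defined[j]:
            exceed = int((col_max >= abs(nes[j])).sum())
            p_fwer[j] = (1 + exceed) / (1 + n_perm)

    if fdr_method == "fdr_bh":
        q = np.asarray(bh_fdr(list(p_nom)))
    else:
        q = _permutation_fdr(nes, null_nes, defined)

    results = [
        LseaResult(
            drug_name=set_names[j],
            es=float(observed_es[j]),
            nes=float(nes[j]),
            p_nominal=float(p_nom[j]),
            q_fdr=float(q[j]),
            p_fwer=float(p_fwer[j]),
            leading_edge=leading_edges[j],
            overlap_size=int(overlap_sizes[j]),
            nes_defined=bool(defined[j]),
        )
        for j in range(n_sets)
    ]
    results.sort(
        key=lambda r: (not r.nes_defined, r.p_nominal, -abs(r.nes) if r.nes_defined else 0.0, r.drug_name)
    )
    return results


def _permutation_fdr(
    nes: np.ndarray, null_nes: np.ndarray, defined: np.ndarray
) -> np.ndarray:
    """Sign-stratified pooled-null FDR on NES, clipped and made monotone."""
    pooled = null_nes[np.isfinite(null_nes)]
    obs = nes[defined]
    q = np.ones(nes.size)
    for j in range(nes.size):
        if not defined[j]:
            continue
        v = nes[j]
        if v >= 0:
            n_pos = int((pooled >= 0).sum())
            num = (pooled >= v).sum() / n_pos if n_pos else 1.0
            d_pos = int((obs >= 0).sum())
            den = (obs >= v).sum() / d_pos if d_pos else 1.0
        else:
            n_neg = int((pooled <= 0).sum())
            num = (pooled <= v).sum() / n_neg if n_neg else 1.0
            d_neg = int((obs <= 0).sum())
            den = (obs <= v).sum() / d_neg if d_neg else 1.0
        q[j] = min(1.0, num / den) if den > 0 else 1.0
    # monotone within each sign: a more extreme NES never has a larger q
    for sign in (1, -1):
        idx = [j for j in range(nes.size) if defined[j] and (nes[j] >= 0) == (sign > 0)]
        idx.sort(key=lambda j: -abs(nes[j]))  # most extreme first
        running = math.inf
        for j in idx:
            running = min(running, q[j])
            q[j] = running
    return q


def lsea(
    expr: pd.DataFrame,
    labels: Mapping[str, int],
    drug_sets: Sequence[DrugLncRNASet],
    params: LseaParams | None = None,
) -> list[LseaResult]:
    """Full LSEA: rank, score every drug set, and test by permutation.

    Sets are first restricted to members present among the matrix rows and
    filtered to at least ``params.min_set_size`` surviving members.  The
    result is deterministic for a fixed ``params.seed``.
    """
    params = params or LseaParams()
    validate_expression_matrix(expr)
    genes = set(expr.index)

    surviving: list[DrugLncRNASet] = []
    overlaps: dict[str, int] = {}
    for ds in drug_sets:
        k = len(set(ds.members) & genes)
        overlaps[ds.drug_name] = k
        if k >= params.min_set_size and k < len(genes):
            surviving.append(ds)
        else:
            logger.info(
                "drug %s excluded: %d members in matrix (min %d)",
                ds.drug_name, k, params.min_set_size,
            )
    if not surviving:
        raise ValueError(
            f"no drug set has >= {params.min_set_size} members in the "
            f"expression matrix; overlap counts: {overlaps}"
        )

    ranked = rank_genes(expr, labels, params.metric)
    names, es_list, les, sizes = [], [], [], []
    gene_pos = {g: i for i, g in enumerate(ranked.genes)}
    masks = np.zeros((len(surviving), len(ranked.genes)), dtype=bool)
    for j, ds in enumerate(surviving):
        es, _, le = enrichment_score(
            ranked, set(ds.members), params.weight_exponent
        )
        names.append(ds.drug_name)
        es_list.append(es)
        les.append(le)
        sizes.append(overlaps[ds.drug_name])
        for g in ds.members:
            if g in gene_pos:
                masks[j, gene_pos[g]] = True

    rng = np.random.default_rng(params.seed)
    null = permutation_null(expr, labels, surviving, params, rng=rng)
    return normalize_and_test(
        names, np.asarray(es_list), null, les, sizes, params.fdr_method
    )
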